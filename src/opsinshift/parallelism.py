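"""Vector analysis of parallel phenotypic change with a permutation null.

Each species' phenotypic change between an ancestral and a derived photic
environment is summarized as a 2-D vector in (predicted sensitivity index,
relative cyp27c1 expression) space, connecting the two population means.
Parallelism across species is quantified by the sums of all pairwise
differences in vector direction (angles γ) and magnitude (lengths ΔL):
with 7 species this is 21 pairwise comparisons per colonization event.

The null model randomizes species identity within each environment: in each
permuted dataset a pseudo-species' vector connects one randomly drawn
individual from the ancestral environment to one from the derived
environment.  The permutation p-value is the fraction of null datasets whose
sums of pairwise differences are strictly smaller than the observed sums,
with the add-one convention p = (k + 1)/(n_perm + 1), so p is never 0 and
ties count against rejection.  Note the deliberate asymmetry: observed
vectors connect population means while null vectors connect single
individuals.

Because nm and relative-expression units are incommensurable and angles are
scale-dependent, each axis is by default standardized by the standard
deviation of the population means before vectors are built
(``scale="sd"``); ``scale="none"`` keeps raw axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from opsinshift.counts_io import COLONIZATION_EVENTS

logger = logging.getLogger(__name__)

EVENTS: tuple[str, ...] = tuple(COLONIZATION_EVENTS)
SCOPES: tuple[str, ...] = EVENTS + ("combined",)


@dataclass(frozen=True)
class SpeciesVector:
    """Directed phenotypic change of one species between two environments."""

    species: str
    event: str
    dx: float
    dy: float

    @property
    def length(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    @property
    def angle_deg(self) -> float:
        """Direction in the plane, degrees counter-clockwise from +x, in (-180, 180]."""
        return float(np.degrees(np.arctan2(self.dy, self.dx)))


@dataclass
class ParallelismResult:
    """Observed pairwise-difference sums, their permutation null, and p-values."""

    scope: str
    observed_sum_angle: float
    observed_sum_length: float
    null_sum_angle: np.ndarray = field(repr=False)
    null_sum_length: np.ndarray = field(repr=False)
    p_angle: float
    p_length: float
    n_perm: int
    n_species_per_event: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scope": [self.scope, self.scope],
                "statistic": ["sum_angle", "sum_length"],
                "observed": [self.observed_sum_angle, self.observed_sum_length],
                "p": [self.p_angle, self.p_length],
                "n_perm": [self.n_perm, self.n_perm],
            }
        )


def _require_columns(profiles: pd.DataFrame) -> None:
    needed = {"species", "environment", "sensitivity_index", "cyp_rel"}
    missing = needed - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles table missing column(s) {sorted(missing)}")


def axis_scales(profiles: pd.DataFrame, scale: str = "sd") -> np.ndarray:
    """Per-axis divisors used before vector construction.

    ``scale="sd"`` returns the standard deviation of the population
    (species × environment) means of each axis; ``scale="none"`` returns
    ones.  Axes with zero spread fall back to 1.
    """
    if scale not in {"sd", "none"}:
        raise ValueError("scale must be 'sd' or 'none'")
    if scale == "none":
        return np.ones(2)
    means = profiles.groupby(["species", "environment"])[
        ["sensitivity_index", "cyp_rel"]
    ].mean()
    sd = means.to_numpy().std(axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    return sd


def build_species_vectors(
    profiles: pd.DataFrame,
    event: str,
    scale: str = "sd",
    scales: np.ndarray | None = None,
) -> list[SpeciesVector]:
    """One vector per species from ancestral- to derived-environment mean.

    ``profiles`` holds one row per individual with columns species,
    environment, sensitivity_index, cyp_rel.  Species missing either
    environment of the event are excluded with a warning.  Vectors are
    differences of population means after axis scaling, so they are
    invariant to rigid translation of the phenotype plane.
    """
    _require_columns(profiles)
    if event not in COLONIZATION_EVENTS:
        raise ValueError(f"unknown event {event!r}; expected one of {EVENTS}")
    anc, der = (e.value for e in COLONIZATION_EVENTS[event])
    if scales is None:
        scales = axis_scales(profiles, scale)

    vectors = []
    for species, group in profiles.groupby("species", sort=True):
        anc_rows = group[group["environment"] == anc]
        der_rows = group[group["environment"] == der]
        if anc_rows.empty or der_rows.empty:
            logger.warning(
                "species %s lacks individuals in %s; excluded from event %s",
                species,
                anc if anc_rows.empty else der,
                event,
            )
            continue
        anc_mean = anc_rows[["sensitivity_index", "cyp_rel"]].mean().to_numpy() / scales
        der_mean = der_rows[["sensitivity_index", "cyp_rel"]].mean().to_numpy() / scales
        delta = der_mean - anc_mean
        vectors.append(SpeciesVector(species=str(species), event=event, dx=delta[0], dy=delta[1]))
    return vectors


def angle_between(v1, v2) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    Raises ``ValueError`` for a zero-length vector (the angle is undefined;
    callers skip such pairs).
    """
    a = np.asarray([v1.dx, v1.dy] if isinstance(v1, SpeciesVector) else v1, dtype=float)
    b = np.asarray([v2.dx, v2.dy] if isinstance(v2, SpeciesVector) else v2, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for zero-length vector")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def pairwise_difference_sums(vectors: list[SpeciesVector]) -> tuple[float, float]:
    """Sums of pairwise angle differences and pairwise |length| differences.

    Over all n(n-1)/2 unordered pairs.  Pairs involving a zero-length
    vector are skipped in the angle sum (logged) but retained in the
    length sum.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors for pairwise sums")
    coords = np.array([[v.dx, v.dy] for v in vectors], dtype=float)
    return _sums_from_coords(coords[None, :, :])


def _sums_from_coords(coords: np.ndarray) -> tuple[float, float] | tuple[np.ndarray, np.ndarray]:
    """Pairwise-difference sums for a (R, S, 2) stack of vector sets.

    Returns (sum_angle, sum_length) as scalars for R == 1 and arrays
    otherwise.  Zero-length vectors contribute to length sums but their
    pairs are excluded from angle sums.
    """
    lengths = np.linalg.norm(coords, axis=2)  # (R, S)
    r, s = lengths.shape
    iu, ju = np.triu_indices(s, k=1)

    safe = np.where(lengths[:, :, None] > 0, lengths[:, :, None], 1.0)
    dirs = coords / safe
    cos = np.einsum("rik,rjk->rij", dirs, dirs)
    pair_cos = np.clip(cos[:, iu, ju], -1.0, 1.0)
    angles = np.degrees(np.arccos(pair_cos))
    defined = (lengths[:, iu] > 0) & (lengths[:, ju] > 0)
    if not defined.all():
        logger.warning(
            "%d vector pair(s) skipped in angle sums (zero-length vector)",
            int((~defined).sum()),
        )
    sum_angle = np.where(defined, angles, 0.0).sum(axis=1)
    sum_length = np.abs(lengths[:, iu] - lengths[:, ju]).sum(axis=1)
    if r == 1:
        return float(sum_angle[0]), float(sum_length[0])
    return sum_angle, sum_length


def _event_arrays(profiles: pd.DataFrame, event: str, scales: np.ndarray):
    """Observed vectors plus per-environment individual pools for one event.

    Returns (species roster, observed coords (S, 2), ancestral points
    (Na, 2), derived points (Nd, 2)).  Only individuals of species present
    in both environments enter the pools, so exclusions apply consistently
    to observed and null datasets.
    """
    anc, der = (e.value for e in COLONIZATION_EVENTS[event])
    vectors = build_species_vectors(profiles, event, scales=scales)
    roster = [v.species for v in vectors]
    if len(roster) < 2:
        raise ValueError(f"event {event}: fewer than two species with both environments")
    obs = np.array([[v.dx, v.dy] for v in vectors])
    pool = profiles[profiles["species"].isin(roster)]
    pts_anc = (
        pool[pool["environment"] == anc][["sensitivity_index", "cyp_rel"]].to_numpy()
        / scales
    )
    pts_der = (
        pool[pool["environment"] == der][["sensitivity_index", "cyp_rel"]].to_numpy()
        / scales
    )
    return roster, obs, pts_anc, pts_der


def _null_coords(
    rng: np.random.Generator,
    pts_anc: np.ndarray,
    pts_der: np.ndarray,
    n_species: int,
    n_perm: int,
) -> np.ndarray:
    """Null vector stacks (n_perm, S, 2): species identity randomized within
    each environment, one individual drawn per pseudo-species and environment."""
    pick_anc = _ordered_picks(rng, len(pts_anc), n_species, n_perm)
    pick_der = _ordered_picks(rng, len(pts_der), n_species, n_perm)
    return pts_der[pick_der] - pts_anc[pick_anc]


def _ordered_picks(rng, pool_size: int, k: int, n_perm: int) -> np.ndarray:
    """(n_perm, k) indices: k distinct individuals drawn per permutation."""
    if pool_size < k:
        raise ValueError("fewer individuals than species in an environment pool")
    keys = rng.random((n_perm, pool_size))
    return np.argsort(keys, axis=1)[:, :k]


def permutation_test(
    profiles: pd.DataFrame,
    scope: str = "combined",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    scale: str = "sd",
) -> ParallelismResult:
    """Permutation test of parallelism in direction and magnitude of change.

    ``scope`` is one colonization event or ``"combined"`` (sums added over
    both events, observed and within each permutation).  ``seed`` is
    required (an int or a Generator): results are reproducible by contract.

    Returns p-values for the angle and length statistics separately; each
    lies in [1/(n_perm+1), 1].
    """
    _require_columns(profiles)
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = EVENTS if scope == "combined" else (scope,)
    scales = axis_scales(profiles, scale)

    obs_angle = 0.0
    obs_length = 0.0
    null_angle = np.zeros(n_perm)
    null_length = np.zeros(n_perm)
    n_species = {}
    for event in events:
        roster, obs, pts_anc, pts_der = _event_arrays(profiles, event, scales)
        n_species[event] = len(roster)
        ev_angle, ev_length = _sums_from_coords(obs[None, :, :])
        obs_angle += ev_angle
        obs_length += ev_length
        coords = _null_coords(rng, pts_anc, pts_der, len(roster), n_perm)
        na, nl = _sums_from_coords(coords)
        null_angle += na
        null_length += nl

    p_angle = (int((null_angle < obs_angle).sum()) + 1) / (n_perm + 1)
    p_length = (int((null_length < obs_length).sum()) + 1) / (n_perm + 1)
    return ParallelismResult(
        scope=scope,
        observed_sum_angle=obs_angle,
        observed_sum_length=obs_length,
        null_sum_angle=null_angle,
        null_sum_length=null_length,
        p_angle=p_angle,
        p_length=p_length,
        n_perm=n_perm,
        n_species_per_event=n_species,
    )
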