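"""Synthetic retinal-transcriptome data with the structure the analysis assumes.

The generator emulates the sampling design of the field study the pipeline
is built for: 7 species sampled in 3 photic environments (river, great
lake, crater lake), 5-6 individuals per population with one population of
3, and library sizes log-normal around a median of 1.4 million reads.

Opsin expression is compositional: each species has a baseline opsin
profile (a point on the 7-simplex, drawn around a long-wavelength template
dominated by sws2a, rh2aβ/α and lws), environments displace that profile
toward short-wavelength opsins on the centered log-ratio (clr) scale — so
shifts compose additively and stay on the simplex — and individuals add
clr-scale noise.  Counts are multinomial given an opsin read budget (a
fixed, configurable fraction of library size; absolute budgets do not
affect any proportion-based statistic).  cyp27c1 counts are negative
binomial with an environment-dependent mean (highest in the turbid great
lake) and moderate overdispersion.  An optional "switch species" swaps
sws2a→sws2b and gains rh2b in the crater lake, emulating the one species
in the study system that changes its expressed opsin subset.

Every dataset is returned together with its ground truth (true per-individual
proportions, true sensitivity indices, the clr displacement applied per
environment) so tests can score estimates against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from opsinshift.consensus import BASES, PileupColumn
from opsinshift.counts_io import CONE_OPSINS, Environment, SampleRecord
from opsinshift.expression import sensitivity_index

ENVIRONMENTS: tuple[str, ...] = tuple(e.value for e in Environment)

#: Long-wavelength opsin subset template (simplex point): most expression in
#: sws2a, rh2aβ, rh2aα and lws, trace levels elsewhere.
_BASELINE_TEMPLATE = np.array([0.01, 0.01, 0.18, 0.01, 0.25, 0.15, 0.39])

#: clr-scale direction of the short-wavelength shift: up-weights sws1/sws2b/
#: sws2a/rh2b at the expense of rh2aα and lws.
_SHORT_SHIFT_DIRECTION = np.array([1.5, 1.0, 0.5, 0.5, 0.0, -1.5, -2.0])

#: Per-environment multiplier of the shift magnitude (river ancestral = 0;
#: the crater-lake shift is the most pronounced).
_ENV_SHIFT_LEVEL = {"river": 0.0, "great_lake": 1.0, "crater_lake": 2.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameter bundle for the count-table generator.

    ``cyp_mean_per_million`` gives the negative-binomial mean of cyp27c1
    expression per environment on the reads-per-million scale;
    ``cyp_dispersion`` is the NB size parameter (smaller = more
    overdispersed).  ``species_sd`` and ``individual_sd`` are clr-scale
    standard deviations of species baseline jitter and individual noise.
    """

    n_species: int = 7
    n_per_population: int = 5
    small_population: tuple[int, str] | None = None  # (species index, environment)
    library_size_median: float = 1.4e6
    library_size_sigma: float = 0.4
    opsin_budget_fraction: float = 0.005
    species_sd: float = 0.4
    individual_sd: float = 0.15
    shift_magnitude: float = 0.35
    cyp_mean_per_million: dict[str, float] = field(
        default_factory=lambda: {"river": 25.0, "great_lake": 60.0, "crater_lake": 15.0}
    )
    cyp_dispersion: float = 8.0
    switch_species: int | None = None  # species index that swaps opsin subset in the crater lake


@dataclass
class GroundTruth:
    """What the generator actually simulated, for scoring estimates."""

    true_proportions: pd.DataFrame  # per individual, columns = CONE_OPSINS
    true_sensitivity: pd.Series  # per individual, nm
    env_shift_clr: dict[str, np.ndarray]  # clr displacement per environment
    species_baselines: np.ndarray  # (n_species, 7) simplex points
    planted_variants: list[dict] = field(default_factory=list)


_PRESETS = ("null", "parallel_weak", "parallel_strong", "paper_like")


def preset(name: str) -> SimulationConfig:
    """Named parameter bundles.

    ``null``: fully exchangeable — no species or environment effects
    (zero shift, zero species jitter, flat cyp means); the permutation
    test must calibrate to its nominal level on this preset.
    ``parallel_weak`` / ``parallel_strong``: all species share the same
    short-wavelength displacement, with small individual noise; strong
    uses a larger displacement and a strongly ordered cyp environment
    profile.  ``paper_like``: the study design — species baseline
    variation, one n=3 population, and a switch species that changes its
    opsin subset in the crater lake.
    """
    if name == "null":
        return SimulationConfig(
            species_sd=0.0,
            shift_magnitude=0.0,
            cyp_mean_per_million={e: 40.0 for e in ENVIRONMENTS},
        )
    if name == "parallel_weak":
        return SimulationConfig(shift_magnitude=0.15)
    if name == "parallel_strong":
        return SimulationConfig(
            shift_magnitude=0.5,
            individual_sd=0.12,
            cyp_mean_per_million={"river": 25.0, "great_lake": 80.0, "crater_lake": 10.0},
        )
    if name == "paper_like":
        return SimulationConfig(
            n_per_population=6,
            small_population=(1, "great_lake"),
            switch_species=0,
        )
    raise ValueError(f"unknown preset {name!r}; available: {_PRESETS}")


def _clr_to_simplex(clr: np.ndarray) -> np.ndarray:
    expo = np.exp(clr - clr.max(axis=-1, keepdims=True))
    return expo / expo.sum(axis=-1, keepdims=True)


def _simplex_to_clr(p: np.ndarray) -> np.ndarray:
    logp = np.log(np.clip(p, 1e-12, None))
    return logp - logp.mean(axis=-1, keepdims=True)


def _switch_subset(p: np.ndarray) -> np.ndarray:
    """Swap sws2a expression into sws2b and move rh2aα mass into rh2b."""
    q = p.copy()
    idx = {o: j for j, o in enumerate(CONE_OPSINS)}
    q[idx["sws2b"]], q[idx["sws2a"]] = p[idx["sws2a"]], p[idx["sws2b"]]
    q[idx["rh2b"]], q[idx["rh2aa"]] = p[idx["rh2aa"]], p[idx["rh2b"]]
    return q


def generate_counts(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, list[SampleRecord], GroundTruth]:
    """Simulate a count table, its sample metadata, and the ground truth.

    Per individual: true opsin proportions are softmax(clr baseline +
    environment shift + individual noise); opsin counts are multinomial
    with budget = ``opsin_budget_fraction`` × library size; cyp27c1 is
    negative binomial.  Byte-identical output under a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.n_species < 2:
        raise ValueError("need at least two species")
    if not 0 < config.opsin_budget_fraction < 1:
        raise ValueError("opsin_budget_fraction must be in (0, 1)")
    if any(m < 0 for m in config.cyp_mean_per_million.values()):
        raise ValueError("cyp27c1 means must be non-negative")

    base_clr = _simplex_to_clr(_BASELINE_TEMPLATE)
    species_clr = base_clr + config.species_sd * rng.standard_normal(
        (config.n_species, len(CONE_OPSINS))
    )
    baselines = _clr_to_simplex(species_clr)
    env_shift = {
        env: config.shift_magnitude * _ENV_SHIFT_LEVEL[env] * _SHORT_SHIFT_DIRECTION
        for env in ENVIRONMENTS
    }

    rows = []
    records = []
    true_props = []
    ids = []
    for s in range(config.n_species):
        species = f"species_{s + 1:02d}"
        for env in ENVIRONMENTS:
            n = config.n_per_population
            if config.small_population == (s, env):
                n = 3
            clr_pop = species_clr[s] + env_shift[env]
            for k in range(n):
                sample_id = f"{species}.{env}.{k + 1}"
                clr_ind = clr_pop + config.individual_sd * rng.standard_normal(
                    len(CONE_OPSINS)
                )
                p = _clr_to_simplex(clr_ind)
                if config.switch_species == s and env == "crater_lake":
                    p = _switch_subset(p)
                library = int(
                    np.round(
                        config.library_size_median
                        * np.exp(config.library_size_sigma * rng.standard_normal())
                    )
                )
                library = max(library, 10_000)
                budget = max(int(round(config.opsin_budget_fraction * library)), 100)
                opsin_counts = rng.multinomial(budget, p)
                mean_cyp = config.cyp_mean_per_million[env] * library / 1e6
                if mean_cyp == 0:
                    cyp = 0
                else:
                    size = config.cyp_dispersion
                    cyp = int(rng.negative_binomial(size, size / (size + mean_cyp)))
                row = dict(zip(CONE_OPSINS, opsin_counts.tolist()))
                row["cyp27c1"] = cyp
                row["total_reads"] = library
                rows.append(row)
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        species=species,
                        environment=Environment(env),
                    )
                )
                true_props.append(p)
                ids.append(sample_id)

    counts = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    truth_props = pd.DataFrame(
        np.asarray(true_props), index=counts.index, columns=list(CONE_OPSINS)
    )
    truth = GroundTruth(
        true_proportions=truth_props,
        true_sensitivity=pd.Series(
            [sensitivity_index(row) for row in truth_props.to_numpy()],
            index=counts.index,
            name="true_sensitivity",
        ),
        env_shift_clr=env_shift,
        species_baselines=baselines,
    )
    return counts, records, truth


def generate_pileup(
    genotype: tuple[str, str],
    coverage: int,
    error_rate: float,
    seed: int | np.random.Generator,
) -> list[PileupColumn]:
    """Simulate per-site base counts for a diploid genotype.

    ``genotype`` is the pair of haplotype sequences (equal length, A/C/G/T).
    At each site, ``coverage`` reads are drawn binomially from the two
    alleles (0.5/0.5); each read is independently replaced by a uniform
    random one of the other three bases with probability ``error_rate``.
    Coverage 0 yields empty columns (consensus N downstream).
    """
    hap1, hap2 = (h.upper() for h in genotype)
    if len(hap1) != len(hap2):
        raise ValueError("haplotypes must have equal length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    columns = []
    others = {b: [x for x in BASES if x != b] for b in BASES}
    for pos, (b1, b2) in enumerate(zip(hap1, hap2), start=1):
        counts = dict.fromkeys(BASES, 0)
        if coverage > 0:
            n1 = int(rng.binomial(coverage, 0.5)) if b1 != b2 else coverage
            for base, n_reads in ((b1, n1), (b2, coverage - n1)):
                if n_reads == 0:
                    continue
                n_err = int(rng.binomial(n_reads, error_rate)) if error_rate else 0
                counts[base] += n_reads - n_err
                for wrong in rng.choice(others[base], size=n_err):
                    counts[wrong] += 1
        columns.append(
            PileupColumn(
                position=pos, a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"]
            )
        )
    return columns


def plant_heterozygote(reference: str, position: int, alt: str) -> tuple[str, str]:
    """Diploid genotype heterozygous for ``alt`` at 1-based ``position``."""
    reference = reference.upper()
    if not 1 <= position <= len(reference):
        raise ValueError("position outside reference")
    if alt not in BASES:
        raise ValueError(f"alt base must be one of {BASES}")
    if reference[position - 1] == alt:
        raise ValueError("alt equals the reference base")
    hap2 = reference[: position - 1] + alt + reference[position:]
    return reference, hap2


def with_seeded_small_population(config: SimulationConfig) -> SimulationConfig:
    """paper_like helper: ensure exactly one n=3 population is present."""
    if config.small_population is not None:
        return config
    return replace(config, small_population=(1, "great_lake"))
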