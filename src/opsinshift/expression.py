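"""Proportional opsin expression and derived visual-sensitivity measures.

Proportional expression of cone opsin *i* in a sample is its read count
divided by the summed read counts of all seven cone opsins.  The predicted
sensitivity index is the expression-weighted mean of the pigments' peak
absorptions:

    X = Σ_i PE_i · λmax_i

which summarizes the retina's predicted spectral tuning in nm.  cyp27c1
expression (a proxy for vitamin-A1 → A2 chromophore conversion, which
red-shifts all pigments) is normalized either as reads per million
(absolute) or relative to the highest value within each species.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from opsinshift.counts_io import CONE_OPSINS, default_lambda_max

logger = logging.getLogger(__name__)

SINGLE_CONE_OPSINS: tuple[str, ...] = ("sws1", "sws2b", "sws2a")


def proportional_expression(counts) -> pd.Series:
    """Proportional expression (PE) over the seven cone opsins.

    ``counts`` is a mapping, Series, or length-7 sequence of non-negative
    per-opsin read counts in the order of :data:`CONE_OPSINS`.  cyp27c1 and
    total read counts are not part of the denominator.

    Raises ``ValueError`` if every cone opsin count is zero.
    """
    if isinstance(counts, Mapping) or isinstance(counts, pd.Series):
        values = np.asarray([counts[o] for o in CONE_OPSINS], dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
        if values.shape != (len(CONE_OPSINS),):
            raise ValueError(f"expected {len(CONE_OPSINS)} opsin counts, got {values.shape}")
    if np.any(values < 0):
        raise ValueError("opsin counts must be non-negative")
    total = values.sum()
    if total == 0:
        raise ValueError("no cone opsin expression: all opsin counts are zero")
    return pd.Series(values / total, index=list(CONE_OPSINS), name="pe")


def sensitivity_index(pe, lambda_max: Mapping[str, float] | None = None) -> float:
    """Predicted sensitivity index (nm): Σ PE_i · λmax_i.

    ``pe`` must sum to 1 (tolerance 1e-6).  With the default λmax table the
    result lies in [360, 560] nm.
    """
    if lambda_max is None:
        lambda_max = default_lambda_max()
    if isinstance(pe, Mapping) or isinstance(pe, pd.Series):
        values = np.asarray([pe[o] for o in CONE_OPSINS], dtype=float)
    else:
        values = np.asarray(pe, dtype=float)
    if abs(values.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportional expression must sum to 1, got {values.sum()!r}")
    lam = np.asarray([lambda_max[o] for o in CONE_OPSINS], dtype=float)
    return float(values @ lam)


def rh2a_ratio(pe) -> float:
    """Proportion of rh2aβ among total rh2a expression: pe[rh2ab]/(pe[rh2ab]+pe[rh2aa]).

    Returns ``nan`` (undefined) when neither paralog is expressed; undefined
    values are excluded from downstream ratio tests, never from other
    measures.
    """
    b = float(pe["rh2ab"])
    a = float(pe["rh2aa"])
    denom = a + b
    if denom == 0:
        return float("nan")
    return b / denom


def single_cone_fraction(pe) -> float:
    """Total proportional expression of the single-cone (short-λ) opsins."""
    return float(sum(pe[o] for o in SINGLE_CONE_OPSINS))


def cyp27c1_per_million(cyp_count, total_reads):
    """cyp27c1 reads per one million reads: count · 1e6 / total_reads."""
    cyp = np.asarray(cyp_count, dtype=float)
    total = np.asarray(total_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_reads must be positive")
    out = cyp * 1e6 / total
    return float(out) if out.ndim == 0 else out


def cyp27c1_species_relative(values: pd.Series, species: pd.Series) -> pd.Series:
    """Scale cyp27c1 values to [0, 1] relative to each species' maximum.

    The highest value within each species maps to 1, which removes
    among-species variation in overall expression level.  A species whose
    maximum is 0 gets all zeros (with a warning).  Scale-invariant within
    species.
    """
    values = pd.Series(values, dtype=float)
    species = pd.Series(species, index=values.index)
    out = pd.Series(np.nan, index=values.index, name="cyp_rel")
    for sp, group in values.groupby(species):
        top = group.max()
        if top == 0:
            logger.warning("species %s: all cyp27c1 values are 0; relative values set to 0", sp)
            out.loc[group.index] = 0.0
        else:
            out.loc[group.index] = group / top
    return out


def profile_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    lambda_max: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample tidy table of all expression measures.

    Joins a validated count table (indexed by sample id) with metadata
    (columns species, environment) and returns one row per sample with the
    seven ``pe_*`` columns, ``single_cone_fraction``, ``rh2a_ratio`` (NaN
    when undefined), ``lws_fraction``, ``sensitivity_index`` (nm),
    ``cyp_per_million`` and species-relative ``cyp_rel``.
    """
    if lambda_max is None:
        lambda_max = default_lambda_max()
    missing = counts.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {list(missing)}")

    pe = counts[list(CONE_OPSINS)].to_numpy(dtype=float)
    row_sums = pe.sum(axis=1)
    if np.any(row_sums == 0):
        bad = counts.index[row_sums == 0][0]
        raise ValueError(f"no cone opsin expression for sample {bad!r}")
    pe = pe / row_sums[:, None]

    lam = np.asarray([lambda_max[o] for o in CONE_OPSINS], dtype=float)
    out = pd.DataFrame(index=counts.index)
    out["species"] = metadata.loc[counts.index, "species"]
    out["environment"] = metadata.loc[counts.index, "environment"]
    for j, opsin in enumerate(CONE_OPSINS):
        out[f"pe_{opsin}"] = pe[:, j]
    idx = {o: j for j, o in enumerate(CONE_OPSINS)}
    out["single_cone_fraction"] = pe[:, [idx[o] for o in SINGLE_CONE_OPSINS]].sum(axis=1)
    rh2a_total = pe[:, idx["rh2ab"]] + pe[:, idx["rh2aa"]]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rh2a_ratio"] = np.where(
            rh2a_total > 0, pe[:, idx["rh2ab"]] / rh2a_total, np.nan
        )
    out["lws_fraction"] = pe[:, idx["lws"]]
    out["sensitivity_index"] = pe @ lam
    out["cyp_per_million"] = cyp27c1_per_million(
        counts["cyp27c1"].to_numpy(), counts["total_reads"].to_numpy()
    )
    out["cyp_rel"] = cyp27c1_species_relative(out["cyp_per_million"], out["species"])
    return out
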