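"""Rank-based statistics: Scheirer-Ray-Hare, Kruskal-Wallis, FDR, rank maintenance.

All tests operate on mid-ranks, so they are invariant to monotone
transformations of the response.  The Scheirer-Ray-Hare test is the
nonparametric analogue of two-way ANOVA: the response is replaced by its
ranks over all N observations, two-way sums of squares are computed on the
ranks, and each term's statistic H = SS_term / MS_total is referred to a
chi-square distribution, where MS_total = SS_total/(N-1) is computed from
the realized (possibly tied) ranks and therefore absorbs the tie correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SRHResult:
    """Scheirer-Ray-Hare test result: one (H, df, p) triple per term."""

    h_species: float
    h_environment: float
    h_interaction: float
    df_species: int
    df_environment: int
    df_interaction: int
    p_species: float
    p_environment: float
    p_interaction: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["species", "environment", "interaction"],
                "H": [self.h_species, self.h_environment, self.h_interaction],
                "df": [self.df_species, self.df_environment, self.df_interaction],
                "p": [self.p_species, self.p_environment, self.p_interaction],
            }
        )


@dataclass(frozen=True)
class RankMaintenanceResult:
    """Spearman correlation with an exact permutation p-value."""

    rho: float
    p: float
    n: int
    alternative: str


def scheirer_ray_hare(values, factor_a, factor_b) -> SRHResult:
    """Two-factor rank test (nonparametric analogue of two-way ANOVA).

    ``values`` are ranked over all observations (mid-ranks for ties); the
    two-way ANOVA sums of squares of the ranks are divided by
    MS_total = SS_total/(N-1), giving chi-square statistics for factor A,
    factor B, and their interaction with (a-1), (b-1), and (a-1)(b-1)
    degrees of freedom.  Sums of squares are Type II, which coincides with
    the sequential decomposition on balanced designs and is
    order-independent on unbalanced ones.

    Requires at least two levels of each factor and at least one
    observation per occupied cell.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise ValueError("values and factors must have equal length")
    a_levels = np.unique(factor_a)
    b_levels = np.unique(factor_b)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError(
            "each factor needs >= 2 levels; for a single factor use kruskal_wallis"
        )

    n = len(values)
    ranks = st.rankdata(values)
    ms_total = ((ranks - ranks.mean()) ** 2).sum() / (n - 1)

    frame = pd.DataFrame({"r": ranks, "a": factor_a.astype(str), "b": factor_b.astype(str)})
    model = smf.ols("r ~ C(a) * C(b)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)

    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b

    if ms_total == 0:  # all observations identical: no rank variance
        h_a = h_b = h_ab = 0.0
    else:
        h_a = float(table.loc["C(a)", "sum_sq"] / ms_total)
        h_b = float(table.loc["C(b)", "sum_sq"] / ms_total)
        h_ab = float(table.loc["C(a):C(b)", "sum_sq"] / ms_total)

    return SRHResult(
        h_species=h_a,
        h_environment=h_b,
        h_interaction=h_ab,
        df_species=df_a,
        df_environment=df_b,
        df_interaction=df_ab,
        p_species=float(st.chi2.sf(h_a, df_a)),
        p_environment=float(st.chi2.sf(h_b, df_b)),
        p_interaction=float(st.chi2.sf(h_ab, df_ab)),
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected via mid-ranks) and its chi-square p.

    ``groups`` labels each observation; requires >= 2 non-empty groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    h, p = st.kruskal(*samples)
    return float(h), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _exact_spearman_pvalue(x_ranks: np.ndarray, rho_obs: float, alternative: str) -> float:
    """Exact permutation p for Spearman's rho by full enumeration of n! orders."""
    n = len(x_ranks)
    x = x_ranks - x_ranks.mean()
    denom_x = math.sqrt(float(x @ x))
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(range(n)):
        y = base[list(perm)]
        yc = y - y.mean()
        rho = float(x @ yc) / (denom_x * math.sqrt(float(yc @ yc)))
        total += 1
        if alternative == "greater":
            count += rho >= rho_obs - tol
        elif alternative == "less":
            count += rho <= rho_obs + tol
        else:
            count += abs(rho) >= abs(rho_obs) - tol
    return count / total


def rank_maintenance(
    means_env1: pd.Series,
    means_env2: pd.Series,
    alternative: str = "greater",
) -> RankMaintenanceResult:
    """Test whether the rank order of species is maintained between environments.

    ``means_env1`` and ``means_env2`` are species-indexed mean phenotypes
    (e.g. mean predicted sensitivity index) in two environments; the species
    sets must match and n >= 3.  Returns Spearman's rho and a permutation
    p-value, exact (full n! enumeration) for n <= 8 and the large-sample
    approximation otherwise.  The default one-sided alternative is
    maintenance, i.e. positive association; ``alternative="two-sided"`` is
    available.
    """
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    m1 = pd.Series(means_env1, dtype=float)
    m2 = pd.Series(means_env2, dtype=float)
    if set(m1.index) != set(m2.index):
        raise ValueError("species sets differ between environments")
    m2 = m2.reindex(m1.index)
    n = len(m1)
    if n < 3:
        raise ValueError("rank maintenance requires at least 3 species")

    rho = float(st.spearmanr(m1.to_numpy(), m2.to_numpy()).statistic)
    if n <= 8:
        x_ranks = st.rankdata(m1.to_numpy())
        p = _exact_spearman_pvalue(x_ranks, rho, alternative)
    else:
        p = float(
            st.spearmanr(m1.to_numpy(), m2.to_numpy(), alternative=alternative).pvalue
        )
    return RankMaintenanceResult(rho=rho, p=p, n=n, alternative=alternative)


def per_species_kw_table(
    profiles: pd.DataFrame,
    measures: tuple[str, ...] = ("single_cone_fraction", "rh2a_ratio", "lws_fraction", "cyp_rel"),
    fdr_family: str = "per-measure",
) -> pd.DataFrame:
    """Kruskal-Wallis across environments, per species and measure, with BH FDR.

    Each measure is tested within each species across its environments
    (rows with undefined values are dropped for that measure only).  With
    ``fdr_family="per-measure"`` the BH correction is applied separately per
    measure across species; ``"global"`` corrects all tests as one family.
    """
    if fdr_family not in {"per-measure", "global"}:
        raise ValueError("fdr_family must be 'per-measure' or 'global'")
    rows = []
    for measure in measures:
        for species, group in profiles.groupby("species"):
            data = group[[measure, "environment"]].dropna()
            if data["environment"].nunique() < 2 or len(data) < 3:
                continue
            h, p = kruskal_wallis(data[measure].to_numpy(), data["environment"].to_numpy())
            rows.append({"measure": measure, "species": species, "H": h, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    if fdr_family == "per-measure":
        for measure in table["measure"].unique():
            mask = table["measure"] == measure
            table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    else:
        table["q"] = bh_fdr(table["p"].to_numpy())
    return table
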