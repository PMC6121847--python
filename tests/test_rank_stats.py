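import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from opsinshift.rank_stats import (
    bh_fdr,
    kruskal_wallis,
    per_species_kw_table,
    rank_maintenance,
    scheirer_ray_hare,
)


def srh_oracle_balanced(values, a, b):
    """Brute-force rank sums of squares for a balanced two-way layout.

    Independent of the implementation under test: mid-ranks, then the
    classical balanced-design SS decomposition from cell/marginal means.
    """
    values = np.asarray(values, float)
    a = np.asarray(a)
    b = np.asarray(b)
    r = st.rankdata(values)
    grand = r.mean()
    n = len(r)
    a_levels, b_levels = np.unique(a), np.unique(b)
    n_cell = n / (len(a_levels) * len(b_levels))
    ss_a = sum(
        (a == ai).sum() * (r[a == ai].mean() - grand) ** 2 for ai in a_levels
    )
    ss_b = sum(
        (b == bi).sum() * (r[b == bi].mean() - grand) ** 2 for bi in b_levels
    )
    ss_cells = sum(
        n_cell * (r[(a == ai) & (b == bi)].mean() - grand) ** 2
        for ai in a_levels
        for bi in b_levels
    )
    ss_ab = ss_cells - ss_a - ss_b
    ms_total = ((r - grand) ** 2).sum() / (n - 1)
    return ss_a / ms_total, ss_b / ms_total, ss_ab / ms_total


class TestScheirerRayHare:
    def test_matches_brute_force_on_balanced_2x2(self):
        rng = np.random.default_rng(7)
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        values = rng.normal(size=12) + (a == "a2") * 1.5
        h_a, h_b, h_ab = srh_oracle_balanced(values, a, b)
        res = scheirer_ray_hare(values, a, b)
        assert res.h_species == pytest.approx(h_a, abs=1e-9)
        assert res.h_environment == pytest.approx(h_b, abs=1e-9)
        assert res.h_interaction == pytest.approx(h_ab, abs=1e-9)
        assert (res.df_species, res.df_environment, res.df_interaction) == (1, 1, 1)

    def test_all_equal_observations_give_zero_statistics(self):
        values = np.ones(12)
        a = np.repeat(["x", "y"], 6)
        b = np.tile(["u", "v"], 6)
        res = scheirer_ray_hare(values, a, b)
        assert res.h_species == res.h_environment == res.h_interaction == 0.0

    def test_invariant_to_observation_order(self):
        rng = np.random.default_rng(3)
        a = np.repeat(list("pqr"), 8)
        b = np.tile(np.repeat(["u", "v"], 4), 3)
        values = rng.normal(size=24)
        res = scheirer_ray_hare(values, a, b)
        perm = rng.permutation(24)
        res_p = scheirer_ray_hare(values[perm], a[perm], b[perm])
        assert res_p.h_species == pytest.approx(res.h_species)
        assert res_p.h_interaction == pytest.approx(res.h_interaction)

    def test_monotone_transformation_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(5)
        a = np.repeat(["x", "y"], 10)
        b = np.tile(["u", "v"], 10)
        values = rng.normal(size=20)
        res = scheirer_ray_hare(values, a, b)
        res_t = scheirer_ray_hare(np.exp(values), a, b)
        assert res_t.h_species == pytest.approx(res.h_species)
        assert res_t.h_environment == pytest.approx(res.h_environment)

    def test_single_level_factor_directs_to_kruskal_wallis(self):
        with pytest.raises(ValueError, match="kruskal_wallis"):
            scheirer_ray_hare([1, 2, 3, 4], ["a", "a", "b", "b"], ["u", "u", "u", "u"])

    def test_type_i_error_calibrated_under_null(self):
        # exchangeable data at the study design size: 7 species x 3 environments x 5
        rng = np.random.default_rng(11)
        a = np.repeat([f"s{i}" for i in range(7)], 15)
        b = np.tile(np.repeat(["r", "g", "c"], 5), 7)
        n_sim, alpha = 300, 0.05
        rejections = np.zeros(3)
        for _ in range(n_sim):
            values = rng.normal(size=105)
            res = scheirer_ray_hare(values, a, b)
            rejections += np.array(
                [res.p_species, res.p_environment, res.p_interaction]
            ) < alpha
        low, high = st.binom.ppf([0.005, 0.995], n_sim, alpha)
        assert np.all(rejections >= low) and np.all(rejections <= high)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_relabeling_groups_leaves_h_unchanged(self):
        values = [3.1, 0.2, 5.5, 2.2, 9.0, 1.1]
        h1, _ = kruskal_wallis(values, ["a", "a", "b", "b", "c", "c"])
        h2, _ = kruskal_wallis(values, ["z", "z", "q", "q", "m", "m"])
        assert h1 == pytest.approx(h2)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(19)
        groups = np.repeat(["a", "b", "c"], 5)
        n_sim, alpha = 10_000, 0.05
        count = 0
        for _ in range(n_sim):
            _, p = kruskal_wallis(rng.normal(size=15), groups)
            count += p < alpha
        low, high = st.binom.ppf([0.005, 0.995], n_sim, alpha)
        assert low <= count <= high


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_preserving_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRankMaintenance:
    def test_perfect_maintenance_n7(self):
        species = [f"sp{i}" for i in range(7)]
        m1 = pd.Series(np.arange(7, dtype=float), index=species)
        m2 = pd.Series(np.arange(7, dtype=float) * 2 + 1, index=species)
        res = rank_maintenance(m1, m2)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 5040)

    def test_exact_p_matches_enumeration_oracle(self):
        # independent oracle: enumerate all 4! orderings and count rho >= observed
        species = list("abcd")
        m1 = pd.Series([1.0, 2.0, 3.0, 4.0], index=species)
        m2 = pd.Series([2.0, 1.0, 4.0, 3.0], index=species)
        rho_obs = st.spearmanr(m1, m2).statistic
        count = 0
        for perm in itertools.permutations(range(4)):
            rho = st.spearmanr([1, 2, 3, 4], perm).statistic
            count += rho >= rho_obs - 1e-12
        res = rank_maintenance(m1, m2)
        assert res.p == pytest.approx(count / 24)

    def test_reversed_order_gives_minus_one(self):
        species = list("abcde")
        m1 = pd.Series(np.arange(5.0), index=species)
        m2 = pd.Series(np.arange(5.0)[::-1], index=species)
        res = rank_maintenance(m1, m2)
        assert res.rho == pytest.approx(-1.0)
        assert res.p == pytest.approx(1.0)  # one-sided toward maintenance

    def test_invariant_to_monotone_transformation(self):
        species = list("abcdef")
        rng = np.random.default_rng(4)
        m1 = pd.Series(rng.normal(size=6), index=species)
        m2 = pd.Series(rng.normal(size=6), index=species)
        res = rank_maintenance(m1, m2)
        res_t = rank_maintenance(np.exp(m1), m2 ** 3)
        assert res_t.rho == pytest.approx(res.rho)
        assert res_t.p == pytest.approx(res.p)

    def test_mismatched_species_sets_rejected(self):
        m1 = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        m2 = pd.Series([1.0, 2.0, 3.0], index=list("abd"))
        with pytest.raises(ValueError, match="species sets differ"):
            rank_maintenance(m1, m2)


class TestPerSpeciesKW:
    def test_families_and_fdr_modes(self, paper_like_profiles):
        table = per_species_kw_table(paper_like_profiles)
        assert set(table["measure"]) <= {
            "single_cone_fraction",
            "rh2a_ratio",
            "lws_fraction",
            "cyp_rel",
        }
        # per-measure family: q within each measure is BH of that measure's p's
        for measure, group in table.groupby("measure"):
            assert np.allclose(group["q"], bh_fdr(group["p"].to_numpy()))
        table_g = per_species_kw_table(paper_like_profiles, fdr_family="global")
        assert np.allclose(table_g["q"], bh_fdr(table_g["p"].to_numpy()))
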