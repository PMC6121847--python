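import itertools
import math

import numpy as np
import pandas as pd
import pytest

from opsinshift import simulate
from opsinshift.counts_io import metadata_frame
from opsinshift.expression import profile_table
from opsinshift.parallelism import (
    SpeciesVector,
    angle_between,
    axis_scales,
    build_species_vectors,
    pairwise_difference_sums,
    permutation_test,
)


def _profiles(preset_name, seed, **overrides):
    from dataclasses import replace

    cfg = replace(simulate.preset(preset_name), **overrides)
    counts, records, _ = simulate.generate_counts(cfg, seed)
    return profile_table(counts, metadata_frame(records))


class TestSpeciesVectors:
    def test_seven_species_in_seven_vectors_out(self, paper_like_profiles):
        vectors = build_species_vectors(paper_like_profiles, "colonization_1")
        assert len(vectors) == 7

    def test_identical_means_give_zero_vector(self):
        rows = []
        for env in ("river", "great_lake"):
            for k in range(3):
                rows.append(
                    {"species": "sp", "environment": env, "sensitivity_index": 500.0 + k, "cyp_rel": 0.5}
                )
            rows.append(
                {"species": "sp2", "environment": env, "sensitivity_index": 480.0, "cyp_rel": 0.2}
            )
        prof = pd.DataFrame(rows)
        vectors = build_species_vectors(prof, "colonization_1", scale="none")
        v = {x.species: x for x in vectors}
        assert v["sp"].length == pytest.approx(0.0)

    def test_translation_invariance(self, paper_like_profiles):
        prof = paper_like_profiles.copy()
        scales = axis_scales(prof)
        base = build_species_vectors(prof, "colonization_2", scales=scales)
        shifted = prof.copy()
        shifted["sensitivity_index"] += 13.0
        shifted["cyp_rel"] += 0.37
        moved = build_species_vectors(shifted, "colonization_2", scales=scales)
        for v1, v2 in zip(base, moved):
            assert v1.dx == pytest.approx(v2.dx, abs=1e-9)
            assert v1.dy == pytest.approx(v2.dy, abs=1e-9)

    def test_species_missing_environment_excluded_with_warning(self, caplog):
        prof = pd.DataFrame(
            {
                "species": ["a", "a", "b"],
                "environment": ["river", "great_lake", "river"],
                "sensitivity_index": [500.0, 490.0, 510.0],
                "cyp_rel": [0.5, 0.6, 0.7],
            }
        )
        with caplog.at_level("WARNING"):
            vectors = build_species_vectors(prof, "colonization_1", scale="none")
        assert [v.species for v in vectors] == ["a"]
        assert any("lacks individuals" in r.message for r in caplog.records)


class TestAngles:
    @pytest.mark.parametrize(
        "v1, v2, expected",
        [((1.0, 2.0), (1.0, 2.0), 0.0), ((1.0, 2.0), (-1.0, -2.0), 180.0), ((1.0, 0.0), (0.0, 1.0), 90.0)],
    )
    def test_reference_angles(self, v1, v2, expected):
        assert angle_between(v1, v2) == pytest.approx(expected, abs=1e-5)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle_between((0.0, 0.0), (1.0, 0.0))


class TestPairwiseSums:
    def test_seven_vectors_give_21_pairs(self):
        rng = np.random.default_rng(0)
        vectors = [
            SpeciesVector(f"s{i}", "colonization_1", *rng.normal(size=2)) for i in range(7)
        ]
        sum_angle, sum_length = pairwise_difference_sums(vectors)
        # independent oracle: explicit loop over the 21 unordered pairs
        oracle_angle = sum(
            angle_between(a, b) for a, b in itertools.combinations(vectors, 2)
        )
        oracle_length = sum(
            abs(a.length - b.length) for a, b in itertools.combinations(vectors, 2)
        )
        assert len(list(itertools.combinations(vectors, 2))) == 21
        assert sum_angle == pytest.approx(oracle_angle)
        assert sum_length == pytest.approx(oracle_length)

    def test_identical_vectors_give_zero_sums(self):
        vectors = [SpeciesVector(f"s{i}", "colonization_1", 1.0, 2.0) for i in range(4)]
        sum_angle, sum_length = pairwise_difference_sums(vectors)
        assert sum_angle == pytest.approx(0.0, abs=1e-4)
        assert sum_length == pytest.approx(0.0, abs=1e-12)

    def test_hand_enumerated_unit_vectors(self):
        vectors = [
            SpeciesVector("a", "colonization_1", 1.0, 0.0),
            SpeciesVector("b", "colonization_1", 0.0, 1.0),
            SpeciesVector("c", "colonization_1", -1.0, 0.0),
        ]
        sum_angle, _ = pairwise_difference_sums(vectors)
        assert sum_angle == pytest.approx(360.0)

    def test_zero_length_vector_skipped_in_angle_kept_in_length(self, caplog):
        vectors = [
            SpeciesVector("a", "colonization_1", 1.0, 0.0),
            SpeciesVector("b", "colonization_1", 0.0, 0.0),
            SpeciesVector("c", "colonization_1", 0.0, 1.0),
        ]
        with caplog.at_level("WARNING"):
            sum_angle, sum_length = pairwise_difference_sums(vectors)
        assert sum_angle == pytest.approx(90.0)  # only the a-c pair is defined
        assert sum_length == pytest.approx(1.0 + 1.0 + 0.0)


class TestPermutationTest:
    def test_determinism_and_p_floor(self, paper_like_profiles):
        r1 = permutation_test(paper_like_profiles, scope="combined", n_perm=199, seed=5)
        r2 = permutation_test(paper_like_profiles, scope="combined", n_perm=199, seed=5)
        assert r1.p_angle == r2.p_angle and r1.p_length == r2.p_length
        assert np.array_equal(r1.null_sum_angle, r2.null_sum_angle)
        for p in (r1.p_angle, r1.p_length):
            assert 1 / 200 <= p <= 1.0

    def test_seed_required(self, paper_like_profiles):
        with pytest.raises(ValueError, match="seed"):
            permutation_test(paper_like_profiles, scope="combined", n_perm=99)

    def test_species_order_invariance_of_observed_sums(self, paper_like_profiles):
        shuffled = paper_like_profiles.sample(frac=1.0, random_state=0)
        r1 = permutation_test(paper_like_profiles, scope="colonization_1", n_perm=49, seed=9)
        r2 = permutation_test(shuffled, scope="colonization_1", n_perm=49, seed=9)
        assert r1.observed_sum_angle == pytest.approx(r2.observed_sum_angle)
        assert r1.observed_sum_length == pytest.approx(r2.observed_sum_length)

    def test_matches_exhaustive_enumeration_on_small_toy(self):
        # 3 species x 2 individuals per population: the null for one event
        # enumerates exactly (6P3)^2 = 14400 equally likely datasets
        prof = _profiles("null", seed=123, n_species=3, n_per_population=2)
        scales = axis_scales(prof)
        anc, der = "great_lake", "crater_lake"
        pools = {
            env: prof[prof["environment"] == env][["sensitivity_index", "cyp_rel"]].to_numpy()
            / scales
            for env in (anc, der)
        }
        obs_vectors = build_species_vectors(prof, "colonization_2", scales=scales)
        obs_angle, _ = pairwise_difference_sums(obs_vectors)

        def angle_sum(coords):
            total = 0.0
            for a, b in itertools.combinations(range(len(coords)), 2):
                va, vb = coords[a], coords[b]
                cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
                total += math.degrees(math.acos(max(-1.0, min(1.0, cos))))
            return total

        smaller = 0
        total = 0
        for pa in itertools.permutations(range(6), 3):
            anc_pts = pools[anc][list(pa)]
            for pd_ in itertools.permutations(range(6), 3):
                coords = pools[der][list(pd_)] - anc_pts
                smaller += angle_sum(coords) < obs_angle
                total += 1
        p_exact = smaller / total

        res = permutation_test(prof, scope="colonization_2", n_perm=4999, seed=77)
        mc_err = 3 * math.sqrt(p_exact * (1 - p_exact) / 4999) + 2 / 5000
        assert abs(res.p_angle - p_exact) < mc_err

    def test_null_preset_p_values_roughly_uniform(self):
        # fully exchangeable data: rejection at 0.05 within the binomial 99% CI
        import scipy.stats as st

        rng = np.random.default_rng(31)
        n_rep, n_perm = 120, 99
        rejections = 0
        cfg = simulate.preset("null")
        for _ in range(n_rep):
            counts, records, _ = simulate.generate_counts(cfg, rng)
            prof = profile_table(counts, metadata_frame(records))
            res = permutation_test(prof, scope="combined", n_perm=n_perm, seed=rng)
            rejections += res.p_angle <= 0.05
        low, high = st.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert low <= rejections <= high

    def test_parallel_preset_detected(self):
        prof = _profiles("parallel_strong", seed=55)
        res = permutation_test(prof, scope="combined", n_perm=199, seed=56)
        assert res.p_angle < 0.05
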