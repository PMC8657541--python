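import dataclasses
import itertools

import numpy as np
import pytest

from metconn import (
    ConfigurationError,
    EdgeComparisonResult,
    PermutationConfig,
    SyntheticCohortSpec,
    ValidationError,
    classify_edges,
    compute_suvr,
    permutation_edge_test,
    simulate_cohort,
)

from .conftest import make_table


def exact_permutation_p(values, n_a, clamp=1e-6):
    """Independent oracle: exact p by enumerating all equal-size splits.

    Brute force over all C(n, n_a) label assignments using numpy only;
    observed split is the first n_a rows vs the rest.
    """
    n = values.shape[0]

    def delta_z(idx_a):
        idx_b = [i for i in range(n) if i not in idx_a]
        r_a = np.corrcoef(values[list(idx_a)], rowvar=False)
        r_b = np.corrcoef(values[idx_b], rowvar=False)
        za = np.arctanh(np.clip(r_a, -1 + clamp, 1 - clamp))
        zb = np.arctanh(np.clip(r_b, -1 + clamp, 1 - clamp))
        return za - zb

    obs = np.abs(delta_z(tuple(range(n_a))))
    count = np.zeros_like(obs)
    total = 0
    for subset in itertools.combinations(range(n), n_a):
        count += np.abs(delta_z(subset)) >= obs
        total += 1
    return count / total


class TestExactOracle:
    def test_monte_carlo_agrees_with_exhaustive_enumeration(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas, group_sizes={"KO": 4, "WT": 4}, seed=17
        )
        suvr = compute_suvr(simulate_cohort(spec))
        n_perm = 5000
        results = permutation_edge_test(
            suvr, "KO", "WT", PermutationConfig(n_permutations=n_perm, seed=5)
        )
        p_exact = exact_permutation_p(suvr.values, n_a=4)
        names = small_atlas.names
        for res in results:
            i, j = names.index(res.region_i), names.index(res.region_j)
            pe = p_exact[i, j]
            # binomial 99% CI around the exact p, plus add-one smoothing slack
            half_width = 2.576 * np.sqrt(pe * (1 - pe) / n_perm) + 1.0 / (n_perm + 1)
            assert abs(res.p_value - pe) <= half_width, (res.region_i, res.region_j)


class TestNullBehaviour:
    def test_identical_groups_give_p_one_everywhere(self, small_atlas):
        rng = np.random.default_rng(3)
        block = 1.0 + 0.1 * rng.standard_normal((7, small_atlas.n_regions))
        values = np.vstack([block, block])  # KO rows copy WT rows exactly
        table = make_table(small_atlas, np.abs(values), groups=["KO"] * 7 + ["WT"] * 7)
        suvr = compute_suvr(table)
        results = permutation_edge_test(
            suvr, "KO", "WT", PermutationConfig(n_permutations=200, seed=0)
        )
        assert all(r.p_value == 1.0 for r in results)
        assert all(r.tier == "ns" and r.direction == "none" for r in results)

    def test_p_values_within_bounds(self, small_suvr):
        n_perm = 99
        results = permutation_edge_test(
            small_suvr, "KO", "WT", PermutationConfig(n_permutations=n_perm, seed=1)
        )
        p = np.array([r.p_value for r in results])
        assert np.all(p >= 1.0 / (n_perm + 1))
        assert np.all(p <= 1.0)


class TestSymmetry:
    def test_group_swap_flips_direction_and_preserves_p(self, small_suvr):
        config = PermutationConfig(n_permutations=300, seed=9)
        ab = permutation_edge_test(small_suvr, "KO", "WT", config)
        ba = permutation_edge_test(small_suvr, "WT", "KO", config)
        flip = {"increased": "decreased", "decreased": "increased", "none": "none"}
        for x, y in zip(ab, ba):
            assert y.delta_z == pytest.approx(-x.delta_z, abs=1e-12)
            assert y.p_value == x.p_value
            assert y.tier == x.tier
            assert y.direction == flip[x.direction]

    def test_determinism_under_seed(self, small_suvr):
        config = PermutationConfig(n_permutations=150, seed=42)
        a = permutation_edge_test(small_suvr, "KO", "WT", config)
        b = permutation_edge_test(small_suvr, "KO", "WT", config)
        assert a == b

    def test_edge_count_and_ordering(self, small_suvr):
        results = permutation_edge_test(
            small_suvr, "KO", "WT", PermutationConfig(n_permutations=50, seed=2)
        )
        n = small_suvr.atlas.n_regions
        assert len(results) == n * (n - 1) // 2
        names = small_suvr.atlas.names
        for r in results:
            assert names.index(r.region_i) < names.index(r.region_j)


def edge(p, delta):
    return EdgeComparisonResult(
        region_i="A",
        region_j="B",
        r_a=0.0,
        r_b=0.0,
        z_a=0.0,
        z_b=0.0,
        delta_z=delta,
        p_value=p,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "p, delta, tier, direction",
        [
            (0.003, 1.0, "p<0.005", "increased"),
            (0.03, -1.0, "p<0.05", "decreased"),
            (0.05, 1.0, "ns", "none"),  # strict inequality at the boundary
            (0.007, -0.2, "p<0.01", "decreased"),
            (0.5, 0.3, "ns", "none"),
        ],
    )
    def test_tier_and_direction(self, p, delta, tier, direction):
        out = classify_edges([edge(p, delta)])[0]
        assert out.tier == tier
        assert out.direction == direction

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            classify_edges([])

    def test_custom_thresholds(self):
        out = classify_edges([edge(0.08, 1.0)], thresholds=(0.1,))[0]
        assert out.tier == "p<0.1"
        assert out.direction == "increased"

    def test_classification_is_pure(self):
        e = edge(0.03, 1.0)
        before = dataclasses.replace(e)
        classify_edges([e])
        assert e == before


class TestConfigValidation:
    def test_thresholds_must_decrease(self):
        with pytest.raises(ConfigurationError, match="decreasing"):
            PermutationConfig(thresholds=(0.01, 0.05))

    def test_thresholds_must_be_probabilities(self):
        with pytest.raises(ConfigurationError, match="0, 1"):
            PermutationConfig(thresholds=(1.5, 0.5))

    def test_positive_permutation_count(self):
        with pytest.raises(ConfigurationError, match="n_permutations"):
            PermutationConfig(n_permutations=0)

    def test_group_size_floor_enforced(self, small_atlas):
        values = np.abs(
            1 + 0.1 * np.random.default_rng(0).standard_normal((5, 6))
        )
        table = make_table(small_atlas, values, groups=["KO"] * 2 + ["WT"] * 3)
        suvr = compute_suvr(table)
        with pytest.raises(ValidationError, match="at least 3"):
            permutation_edge_test(
                suvr, "KO", "WT", PermutationConfig(n_permutations=10, seed=0)
            )
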