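import numpy as np
import pytest
from scipy import linalg

from metconn import (
    ConfigurationError,
    EdgeEffect,
    SyntheticCohortSpec,
    ValidationError,
    exchangeable_correlation,
    nearest_correlation,
    simulate_cohort,
    target_correlations,
)


class TestNearestCorrelation:
    def test_identity_is_fixed_point(self):
        m = np.eye(5)
        assert np.array_equal(nearest_correlation(m), m)

    def test_psd_matrix_returned_unchanged(self):
        m = exchangeable_correlation(6, 0.4)  # PSD for rho in [-0.2, 1]
        out = nearest_correlation(m)
        assert np.max(np.abs(out - m)) < 1e-12

    def test_non_psd_projected_to_valid_correlation(self):
        # r12 = r13 = r23 = -0.9 is far outside the correlation cone
        m = np.full((3, 3), -0.9)
        np.fill_diagonal(m, 1.0)
        out = nearest_correlation(m)
        # verify with an independent eigensolver
        eigvals = linalg.eigvalsh(out)
        assert eigvals.min() >= -1e-10
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)
        assert np.all(np.abs(out) <= 1.0 + 1e-12)

    def test_non_symmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            nearest_correlation(m)

    def test_bad_diagonal_rejected(self):
        m = np.eye(3) * 2.0
        with pytest.raises(ValidationError, match="diagonal"):
            nearest_correlation(m)


class TestDeterminism:
    def test_same_spec_and_seed_bit_identical(self, small_atlas):
        def run():
            spec = SyntheticCohortSpec(
                atlas=small_atlas, group_sizes={"KO": 7, "WT": 7}, seed=7
            )
            return simulate_cohort(spec)

        a, b = run(), run()
        assert np.array_equal(a.values, b.values)
        assert a.subject_ids == b.subject_ids

    def test_adding_a_group_keeps_existing_draws(self, small_atlas):
        two = simulate_cohort(
            SyntheticCohortSpec(
                atlas=small_atlas, group_sizes={"KO": 5, "WT": 5}, seed=9
            )
        )
        three = simulate_cohort(
            SyntheticCohortSpec(
                atlas=small_atlas,
                group_sizes={"KO": 5, "WT": 5, "XX": 5},
                seed=9,
            )
        )
        assert np.array_equal(two.group_values("KO"), three.group_values("KO"))
        assert np.array_equal(two.group_values("WT"), three.group_values("WT"))


class TestCorrelationTargets:
    def test_exchangeable_structure_recovered_at_large_n(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas,
            group_sizes={"G": 2000},
            base_correlation=("exchangeable", 0.3),
            cv=0.1,
            seed=21,
        )
        table = simulate_cohort(spec)
        r = np.corrcoef(table.values, rowvar=False)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.max(np.abs(off - 0.3)) < 0.05

    def test_injected_edge_effect_recovered(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas,
            group_sizes={"KO": 2000, "WT": 2000},
            base_correlation="identity",
            edge_effects=[EdgeEffect("cortex_L", "cortex_R", "KO", 0.9)],
            cv=0.1,
            seed=22,
        )
        table = simulate_cohort(spec)
        i = small_atlas.index_of("cortex_L")
        j = small_atlas.index_of("cortex_R")
        r_ko = np.corrcoef(table.group_values("KO"), rowvar=False)[i, j]
        r_wt = np.corrcoef(table.group_values("WT"), rowvar=False)[i, j]
        assert abs(r_ko - 0.9) < 0.05
        assert abs(r_wt) < 0.05

    def test_truncation_bias_negligible_at_moderate_cv(self, small_atlas):
        # averaging edge correlations over replicate cohorts isolates the
        # rejection-truncation bias from per-edge sampling noise
        deviations = []
        for seed in range(10):
            spec = SyntheticCohortSpec(
                atlas=small_atlas,
                group_sizes={"G": 2000},
                base_correlation="identity",
                cv=0.15,
                seed=100 + seed,
            )
            table = simulate_cohort(spec)
            r = np.corrcoef(table.values, rowvar=False)
            deviations.append(r[~np.eye(r.shape[0], dtype=bool)].mean())
        assert abs(np.mean(deviations)) < 0.01

    def test_ground_truth_matches_effect_injection(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas,
            group_sizes={"KO": 7, "WT": 7},
            edge_effects=[EdgeEffect("cortex_L", "thalamus_R", "KO", 0.6)],
            seed=1,
        )
        sigmas = target_correlations(spec)
        i = small_atlas.index_of("cortex_L")
        j = small_atlas.index_of("thalamus_R")
        assert sigmas["KO"][i, j] == pytest.approx(0.6)
        assert sigmas["WT"][i, j] == 0.0


class TestGuards:
    def test_positivity_of_output(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas, group_sizes={"G": 100}, cv=0.3, seed=2
        )
        assert np.all(simulate_cohort(spec).values > 0)

    def test_excessive_cv_raises_configuration_error(self, small_atlas):
        spec = SyntheticCohortSpec(
            atlas=small_atlas, group_sizes={"G": 500}, cv=5.0, seed=2
        )
        with pytest.raises(ConfigurationError, match="rejection rate"):
            simulate_cohort(spec)

    def test_small_group_rejected(self, small_atlas):
        with pytest.raises(ConfigurationError, match="size"):
            SyntheticCohortSpec(atlas=small_atlas, group_sizes={"G": 2}, seed=0)

    def test_target_r_bounds(self):
        with pytest.raises(ConfigurationError, match="target_r"):
            EdgeEffect("A", "B", "KO", 1.0)

    def test_effect_group_must_exist(self, small_atlas):
        with pytest.raises(ConfigurationError, match="not in group_sizes"):
            SyntheticCohortSpec(
                atlas=small_atlas,
                group_sizes={"KO": 4},
                edge_effects=[EdgeEffect("cortex_L", "cortex_R", "ZZ", 0.5)],
                seed=0,
            )
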