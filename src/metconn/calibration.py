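"""Monte-Carlo calibration and power studies of the permutation edge test.

Two replicate experiments used for validation and reporting:

* :func:`type_i_error_study` — simulate many *null* cohorts (both groups
  share one correlation structure), run the edge test on each, and measure
  how often edges are flagged at a nominal level.  A valid test keeps the
  mean flagged fraction at (or conservatively below) the nominal level and
  its p-value distribution stochastically no smaller than uniform.

* :func:`detection_study` — inject a known single-edge correlation
  difference between groups and measure the fraction of replicate cohorts
  in which that edge is detected.  Replicate k reuses the same derived seed
  at every effect size (common random numbers), so detection curves are
  directly comparable across effect sizes without replicate-level noise
  dominating the comparison.

Seeds derived from the root seed stay below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas import Region, VOIAtlas
from .permutation import PermutationConfig, permutation_edge_test
from .simulate import EdgeEffect, SyntheticCohortSpec, simulate_cohort
from .suvr import compute_suvr

_SEED_MOD = 2**31 - 1


def study_atlas(n_regions: int) -> VOIAtlas:
    """Generic atlas for simulation studies: regions v01..vNN plus a
    bilateral reference pool (last two regions)."""
    if n_regions < 3:
        raise ValueError("study atlas needs >= 3 regions")
    regions = [Region(f"v{k:02d}", "NA", False) for k in range(1, n_regions - 1)]
    regions += [Region("ref_L", "L", True), Region("ref_R", "R", True)]
    return VOIAtlas(tuple(regions))


def _derived_seed(root: int, k: int) -> int:
    return (root * 100_003 + k) % _SEED_MOD


@dataclass
class TypeIErrorResult:
    """Outcome of a null-cohort calibration study."""

    fractions: np.ndarray  # per-cohort fraction of edges with p < alpha
    p_values: np.ndarray  # pooled p-values, all cohorts x all edges
    alpha: float

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())

    def ks_dplus(self) -> float:
        """One-sided Kolmogorov statistic D+ = sup(ECDF - uniform CDF).

        Large D+ means the pooled p-values are stochastically smaller than
        uniform, i.e. the test is anti-conservative.
        """
        p = np.sort(self.p_values)
        n = p.size
        ecdf = np.arange(1, n + 1) / n
        return float(np.max(ecdf - p))


def type_i_error_study(
    n_cohorts: int = 200,
    n_regions: int = 20,
    rho: float = 0.3,
    group_sizes: dict[str, int] | None = None,
    n_permutations: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    cv: float = 0.1,
) -> TypeIErrorResult:
    """False-positive calibration on null cohorts (shared correlation)."""
    atlas = study_atlas(n_regions)
    sizes = dict(group_sizes or {"KO": 7, "WT": 7})
    group_a, group_b = list(sizes)
    fractions = np.empty(n_cohorts)
    pooled = []
    for k in range(n_cohorts):
        s = _derived_seed(seed, k)
        spec = SyntheticCohortSpec(
            atlas=atlas,
            group_sizes=sizes,
            base_correlation=("exchangeable", rho),
            cv=cv,
            seed=s,
        )
        suvr = compute_suvr(simulate_cohort(spec))
        results = permutation_edge_test(
            suvr,
            group_a,
            group_b,
            PermutationConfig(n_permutations=n_permutations, seed=s + 1),
        )
        p = np.array([r.p_value for r in results])
        fractions[k] = np.mean(p < alpha)
        pooled.append(p)
    return TypeIErrorResult(fractions, np.concatenate(pooled), alpha)


@dataclass
class DetectionResult:
    """Detection rates of an injected edge effect across effect sizes."""

    target_rs: tuple[float, ...]
    rates: dict[float, float] = field(default_factory=dict)
    edge: tuple[str, str] = ("v01", "v02")


def detection_study(
    target_rs: Sequence[float] = (0.0, 0.3, 0.6, 0.9),
    n_replicates: int = 200,
    n_regions: int = 6,
    group_sizes: dict[str, int] | None = None,
    n_permutations: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    cv: float = 0.1,
) -> DetectionResult:
    """Power to detect a single injected edge effect at level ``alpha``.

    The base structure is identity (all edges null); in the first-listed
    group the edge (v01, v02) is set to each target correlation in turn.
    With common random numbers across effect sizes, rates are comparable
    replicate for replicate.
    """
    atlas = study_atlas(n_regions)
    sizes = dict(group_sizes or {"KO": 7, "WT": 7})
    group_a, group_b = list(sizes)
    edge = ("v01", "v02")
    result = DetectionResult(tuple(target_rs), edge=edge)
    for target in target_rs:
        hits = 0
        for k in range(n_replicates):
            s = _derived_seed(seed, k)  # same seed for every target r
            effects = (
                [EdgeEffect(edge[0], edge[1], group_a, target)] if target else []
            )
            spec = SyntheticCohortSpec(
                atlas=atlas,
                group_sizes=sizes,
                base_correlation="identity",
                edge_effects=effects,
                cv=cv,
                seed=s,
            )
            suvr = compute_suvr(simulate_cohort(spec))
            results = permutation_edge_test(
                suvr,
                group_a,
                group_b,
                PermutationConfig(n_permutations=n_permutations, seed=s + 1),
            )
            hit = any(
                r.p_value < alpha
                for r in results
                if {r.region_i, r.region_j} == set(edge)
            )
            hits += int(hit)
        result.rates[float(target)] = hits / n_replicates
    return result
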