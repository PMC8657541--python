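"""Group-label permutation test for edge-wise connectivity differences.

For every unordered region pair (edge) the observed statistic is the
difference in Fisher-z connectivity between the two groups,
``delta_z = z_a - z_b`` (group a conventionally the mutant).  The null
distribution is built by pooling the subjects of both groups and randomly
re-partitioning them ``n_permutations`` times into pseudo-groups of the
original sizes; both correlation matrices are recomputed and Fisher
transformed (same clamp) for each re-partition, and the two-sided p-value
of an edge is

    p = (1 + #{perm : |delta_z_perm| >= |delta_z_obs|}) / (n_permutations + 1)

The add-one smoothing keeps p in [1/(N+1), 1] and, together with counting
ties toward the numerator, makes the test conservative (valid at every
nominal level).  One permutation stream is shared across all edges.
Significant edges are classified by the sign of delta_z (increased /
decreased) and tiered by the smallest significance threshold their p-value
passes (strict inequality), by default 0.05 > 0.01 > 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .network import DEFAULT_CLAMP_EPSILON, correlation_matrix, fisher_transform, fisher_z
from .uptake import SubjectTable, require_two_groups

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005)
NS = "ns"

# Permutations that reproduce the observed grouping are exact ties, but the
# batched null statistic follows a different floating-point summation order
# than the observed one; without slack such ties would be dropped about half
# the time, biasing p downward.  Gaps between genuinely distinct |delta_z|
# values in continuous data are many orders of magnitude larger than this.
TIE_ATOL = 1e-9


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the label-permutation test."""

    n_permutations: int = 5000
    seed: int = 0
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        t = tuple(self.thresholds)
        if any(not 0.0 < x < 1.0 for x in t):
            raise ConfigurationError("thresholds must lie in (0, 1)")
        if any(a <= b for a, b in zip(t, t[1:])):
            raise ConfigurationError("thresholds must be strictly decreasing")
        object.__setattr__(self, "thresholds", t)


@dataclass
class EdgeComparisonResult:
    """Comparison of one edge (region pair, i < j in atlas order)."""

    region_i: str
    region_j: str
    r_a: float
    r_b: float
    z_a: float
    z_b: float
    delta_z: float
    p_value: float
    direction: str = "none"
    tier: str = NS


def tier_label(threshold: float) -> str:
    return f"p<{threshold:g}"


def _batch_group_corr(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson correlation matrices for many row subsets at once.

    x : (n_pool, R) data; idx : (P, n) row indices -> (P, R, R) correlations.
    Raises if any region has zero variance within any subset.
    """
    sub = x[idx]  # (P, n, R)
    sub = sub - sub.mean(axis=1, keepdims=True)
    cov = np.einsum("pnr,pns->prs", sub, sub, optimize=True)
    var = np.einsum("prr->pr", cov)
    if np.any(var <= 0.0):
        raise ValidationError(
            "zero-variance region in a permuted pseudo-group; "
            "input data are degenerate"
        )
    denom = np.sqrt(var)
    r = cov / (denom[:, :, None] * denom[:, None, :])
    return np.clip(r, -1.0, 1.0)


def permutation_edge_test(
    suvr: SubjectTable,
    group_a: str,
    group_b: str,
    config: PermutationConfig = PermutationConfig(),
) -> list[EdgeComparisonResult]:
    """Test every edge for a between-group difference in Fisher z.

    Deterministic given ``config.seed``.  The pooled subject order is the
    table's row order, so swapping ``group_a``/``group_b`` (with equal
    group sizes) reuses the identical permutation stream: every delta_z is
    negated, directions swap, and every p-value is preserved.
    """
    require_two_groups(suvr, group_a, group_b)
    atlas = suvr.atlas
    names = atlas.names
    n_regions = atlas.n_regions

    net_a = fisher_transform(correlation_matrix(suvr, group_a), config.clamp_epsilon)
    net_b = fisher_transform(correlation_matrix(suvr, group_b), config.clamp_epsilon)
    delta_obs = net_a.z_matrix - net_b.z_matrix

    # pooled subjects in table row order
    pool_idx = [i for i, g in enumerate(suvr.groups) if g in (group_a, group_b)]
    x = suvr.values[pool_idx]
    n_a = suvr.groups.count(group_a)
    n_pool = len(pool_idx)

    rng = np.random.default_rng(config.seed)
    perms = np.empty((config.n_permutations, n_pool), dtype=np.intp)
    for k in range(config.n_permutations):
        perms[k] = rng.permutation(n_pool)

    abs_obs = np.abs(delta_obs)
    ge_count = np.zeros((n_regions, n_regions), dtype=np.int64)
    chunk = max(1, int(4_000_000 / (n_regions * n_regions)))
    for start in range(0, config.n_permutations, chunk):
        block = perms[start : start + chunk]
        r_pa = _batch_group_corr(x, block[:, :n_a])
        r_pb = _batch_group_corr(x, block[:, n_a:])
        delta_perm = fisher_z(r_pa, config.clamp_epsilon) - fisher_z(
            r_pb, config.clamp_epsilon
        )
        ge_count += (np.abs(delta_perm) >= abs_obs - TIE_ATOL).sum(axis=0)
    p = (1.0 + ge_count) / (config.n_permutations + 1.0)

    results = []
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            results.append(
                EdgeComparisonResult(
                    region_i=names[i],
                    region_j=names[j],
                    r_a=float(net_a.r_matrix[i, j]),
                    r_b=float(net_b.r_matrix[i, j]),
                    z_a=float(net_a.z_matrix[i, j]),
                    z_b=float(net_b.z_matrix[i, j]),
                    delta_z=float(delta_obs[i, j]),
                    p_value=float(p[i, j]),
                )
            )
    return classify_edges(results, config.thresholds)


def classify_edges(
    results: list[EdgeComparisonResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[EdgeComparisonResult]:
    """Assign significance tier and direction to each edge.

    Tier is the smallest threshold with ``p < threshold`` (strict), else
    ``ns``; direction follows the sign of delta_z for significant edges.
    """
    if not results:
        raise ValidationError("empty result list")
    ordered = sorted(thresholds, reverse=True)  # descending
    out = []
    for res in results:
        tier = NS
        for t in ordered:
            if res.p_value < t:
                tier = tier_label(t)
        if tier == NS or res.delta_z == 0.0:
            direction = "none"
            tier = tier if res.delta_z != 0.0 else NS
        else:
            direction = "increased" if res.delta_z > 0 else "decreased"
        out.append(replace(res, tier=tier, direction=direction))
    return out


def results_to_frame(results: list[EdgeComparisonResult]) -> pd.DataFrame:
    """Edge results as a DataFrame, one row per unordered pair."""
    return pd.DataFrame(
        {
            "region_i": [r.region_i for r in results],
            "region_j": [r.region_j for r in results],
            "r_a": [r.r_a for r in results],
            "r_b": [r.r_b for r in results],
            "z_a": [r.z_a for r in results],
            "z_b": [r.z_b for r in results],
            "delta_z": [r.delta_z for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "tier": [r.tier for r in results],
        }
    )


def annotate_bh(results: list[EdgeComparisonResult]) -> pd.DataFrame:
    """Edge frame with a Benjamini-Hochberg adjusted q-value column.

    Annotation only — tiers and directions are untouched; permutation
    p-values over 1378 edges are uncorrected by design, and q-values let
    the reader judge the multiplicity burden.
    """
    frame = results_to_frame(results)
    frame["q_value"] = stats.false_discovery_control(frame["p_value"].to_numpy())
    return frame
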