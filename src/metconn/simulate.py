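"""Synthetic two-group cohorts with known interregional correlation.

Stands in for the study's unavailable PET scans: two groups of mice, each
subject contributing one positive uptake value per VOI, with a per-group
target correlation matrix and the ability to inject known edge-level
correlation differences between groups (e.g. set r(A, B) = 0.9 in the
knockout group only).

Model
-----
Subjects of group *g* are i.i.d. draws from a multivariate Gaussian with
per-region mean ``mean_uptake``, per-region SD ``cv * mean_uptake``, and
correlation ``Sigma_g = nearest_correlation(base with g's edge effects)``.
Draws containing any non-positive value are rejected and redrawn, keeping
uptake strictly positive; with the SUVR-like default scale (mean 1, cv 0.1)
rejection is vanishingly rare and the realized correlations are unaffected
to well below sampling noise.

Randomness: one root seed; independent child streams are spawned per group
in lexicographic group-label order, so adding or renaming one group never
perturbs another group's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .atlas import VOIAtlas
from .errors import ConfigurationError, ValidationError
from .uptake import UptakeTable

__all__ = [
    "EdgeEffect",
    "SyntheticCohortSpec",
    "exchangeable_correlation",
    "nearest_correlation",
    "simulate_cohort",
    "target_correlations",
]


def exchangeable_correlation(n_regions: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix: 1 on the diagonal, ``rho`` everywhere else.

    Positive semidefinite for rho in [-1/(n-1), 1].
    """
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must be in [-1, 1], got {rho}")
    m = np.full((n_regions, n_regions), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


def _check_correlation_input(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ValidationError("correlation matrix must have unit diagonal")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    return m


def nearest_correlation(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the correlation cone.

    Alternates eigenvalue clipping at zero with diagonal renormalization
    until the update is below ``tol`` (or ``max_iter``).  A matrix that is
    already positive semidefinite is returned unchanged.  The result is
    symmetric, has exact unit diagonal, and eigenvalues >= -1e-10.
    """
    m = _check_correlation_input(matrix)
    eigvals = np.linalg.eigvalsh(m)
    if eigvals[0] >= -1e-12:
        return m.copy()
    out = m
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        w = np.clip(w, 0.0, None)
        proj = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(proj), 1e-300, None))
        proj = proj / np.outer(d, d)
        proj = (proj + proj.T) / 2.0
        np.fill_diagonal(proj, 1.0)
        delta = np.max(np.abs(proj - out))
        out = proj
        if delta < tol and np.linalg.eigvalsh(out)[0] >= -1e-10:
            break
    return out


@dataclass(frozen=True)
class EdgeEffect:
    """Force r(region_i, region_j) to ``target_r`` in one group's matrix."""

    region_i: str
    region_j: str
    group: str
    target_r: float

    def __post_init__(self) -> None:
        if not -1.0 < self.target_r < 1.0:
            raise ConfigurationError(
                f"target_r must be in (-1, 1), got {self.target_r}"
            )
        if self.region_i == self.region_j:
            raise ConfigurationError("edge effect regions must differ")


@dataclass
class SyntheticCohortSpec:
    """Full description of a simulated cohort.

    Parameters
    ----------
    atlas
        Region set; defines dimensionality and column order.
    group_sizes
        Map group label -> number of subjects (each >= 3).
    base_correlation
        Square matrix shared by all groups before edge effects, or the
        preset ``"identity"``, or ``("exchangeable", rho)``.
    edge_effects
        Per-group single-edge overrides applied to the base matrix.
    mean_uptake
        Per-region positive means; default 1.0 (1.2 for reference regions),
        an SUVR-like scale.
    cv
        Coefficient of variation (SD/mean), scalar or per-region; default 0.1.
    seed
        Root seed for the generator.
    """

    atlas: VOIAtlas
    group_sizes: dict[str, int]
    base_correlation: Union[str, tuple, np.ndarray] = "identity"
    edge_effects: Sequence[EdgeEffect] = field(default_factory=tuple)
    mean_uptake: Optional[np.ndarray] = None
    cv: Union[float, np.ndarray] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ConfigurationError("group_sizes must name at least one group")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ConfigurationError(f"group {g!r}: size must be >= 3, got {n}")
        if self.mean_uptake is None:
            mu = np.ones(self.atlas.n_regions)
            for name in self.atlas.reference_names:
                mu[self.atlas.index_of(name)] = 1.2
            self.mean_uptake = mu
        else:
            self.mean_uptake = np.asarray(self.mean_uptake, dtype=float)
            if self.mean_uptake.shape != (self.atlas.n_regions,):
                raise ConfigurationError("mean_uptake must have one entry per region")
            if np.any(self.mean_uptake <= 0):
                raise ConfigurationError("mean_uptake must be strictly positive")
        cv = np.broadcast_to(np.asarray(self.cv, dtype=float), (self.atlas.n_regions,))
        if np.any(cv <= 0):
            raise ConfigurationError("cv must be strictly positive")
        self.cv = cv.copy()
        for eff in self.edge_effects:
            if eff.group not in self.group_sizes:
                raise ConfigurationError(
                    f"edge effect group {eff.group!r} not in group_sizes"
                )
            self.atlas.index_of(eff.region_i)
            self.atlas.index_of(eff.region_j)

    def base_matrix(self) -> np.ndarray:
        n = self.atlas.n_regions
        base = self.base_correlation
        if isinstance(base, str):
            if base == "identity":
                return np.eye(n)
            raise ConfigurationError(f"unknown correlation preset {base!r}")
        if isinstance(base, tuple):
            kind, rho = base
            if kind != "exchangeable":
                raise ConfigurationError(f"unknown correlation preset {kind!r}")
            return exchangeable_correlation(n, float(rho))
        m = _check_correlation_input(np.asarray(base, dtype=float))
        if m.shape != (n, n):
            raise ConfigurationError("base_correlation shape must match atlas size")
        return m


def target_correlations(spec: SyntheticCohortSpec) -> dict[str, np.ndarray]:
    """The exact per-group correlation matrix the simulator samples from.

    Edge effects are written into the base matrix and the result is
    projected to the nearest valid correlation matrix; this post-projection
    Sigma_g is the ground truth against which sample correlations converge.
    """
    base = spec.base_matrix()
    out: dict[str, np.ndarray] = {}
    for group in spec.group_sizes:
        sigma = base.copy()
        for eff in spec.edge_effects:
            if eff.group == group:
                i = spec.atlas.index_of(eff.region_i)
                j = spec.atlas.index_of(eff.region_j)
                sigma[i, j] = sigma[j, i] = eff.target_r
        out[group] = nearest_correlation(sigma)
    return out


def _factor(sigma: np.ndarray) -> np.ndarray:
    """Square root factor L with L @ L.T = sigma (eigendecomposition based,
    valid for singular PSD matrices)."""
    w, v = np.linalg.eigh(sigma)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_group(
    rng: np.random.Generator,
    n: int,
    mean: np.ndarray,
    sd: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """Draw n rows, rejecting any row containing a non-positive value."""
    factor = _factor(sigma)
    rows: list[np.ndarray] = []
    drawn = 0
    while len(rows) < n:
        need = n - len(rows)
        z = rng.standard_normal((need, sigma.shape[0]))
        x = mean + (z @ factor.T) * sd
        drawn += need
        for row in x:
            if np.all(row > 0):
                rows.append(row)
        if drawn >= 1000 and len(rows) / drawn < 0.5:
            raise ConfigurationError(
                f"rejection rate {1 - len(rows) / drawn:.0%} exceeds 50% over "
                f"{drawn} draws; cv too large for positive uptake"
            )
    return np.array(rows)


def simulate_cohort(spec: SyntheticCohortSpec) -> UptakeTable:
    """Simulate an uptake table from a cohort spec.

    Deterministic: identical spec and seed give a bit-identical table.
    Subjects are named ``<group>_<k>`` and emitted group by group in the
    order groups appear in ``group_sizes``.
    """
    sigmas = target_correlations(spec)
    # independent child streams per group, lexicographic label order
    ordered = sorted(spec.group_sizes)
    children = np.random.SeedSequence(spec.seed).spawn(len(ordered))
    rng_by_group = {g: np.random.default_rng(s) for g, s in zip(ordered, children)}

    sd = spec.cv * spec.mean_uptake
    ids: list[str] = []
    groups: list[str] = []
    blocks: list[np.ndarray] = []
    for group, n in spec.group_sizes.items():
        x = _draw_group(rng_by_group[group], n, spec.mean_uptake, sd, sigmas[group])
        blocks.append(x)
        ids.extend(f"{group}_{k + 1:02d}" for k in range(n))
        groups.extend([group] * n)
    return UptakeTable(ids, groups, np.vstack(blocks), spec.atlas)
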