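"""Per-group interregional correlation networks and the Fisher transform.

Metabolic connectivity here is inter-subject correlation: within one group,
each subject contributes a single SUVR value per region, and the Pearson
correlation between two regions is computed across the group's subjects.
With R regions this yields an R x R symmetric correlation matrix per group
— the group's network — whose off-diagonal entries are the edges.

For group comparison the correlations are variance-stabilized with the
Fisher transformation z = atanh(r) = 0.5 * ln((1+r)/(1-r)).  With small
groups a sample correlation can hit +/-1 exactly, where z diverges, so r is
clamped to [-1+eps, 1-eps] (eps = 1e-6 by default) before the transform;
every edge then has a finite, testable z.  Diagonal z is set to 0 by
convention — self-edges are never tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ValidationError
from .uptake import SubjectTable

DEFAULT_CLAMP_EPSILON = 1e-6


@dataclass
class GroupNetwork:
    """One group's correlation network (r, and z once transformed)."""

    group: str
    n_subjects: int
    region_names: list[str]
    r_matrix: np.ndarray
    z_matrix: Optional[np.ndarray] = None
    clamp_epsilon: Optional[float] = None


def correlation_matrix(table: SubjectTable, group: str) -> GroupNetwork:
    """Inter-subject Pearson correlation matrix for one group.

    Requires at least 3 subjects in the group and nonzero variance in every
    region (a zero-variance region typically signals a sole reference
    region whose SUVR is identically 1 — a mis-specified reference pool).
    """
    x = table.group_values(group)
    n = x.shape[0]
    if n < 3:
        raise ValidationError(f"group {group!r} has {n} subjects; need >= 3")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        name = table.atlas.names[int(np.argmax(sd == 0))]
        raise ValidationError(
            f"region {name!r} has zero variance in group {group!r}; "
            "correlation undefined (check the reference pool)"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return GroupNetwork(
        group=group, n_subjects=n, region_names=table.atlas.names, r_matrix=r
    )


def fisher_z(r: np.ndarray, clamp_epsilon: float = DEFAULT_CLAMP_EPSILON) -> np.ndarray:
    """Element-wise Fisher z = atanh(r) after clamping r to [-1+eps, 1-eps]."""
    if not 0.0 < clamp_epsilon < 1.0:
        raise ConfigurationError(
            f"clamp_epsilon must be in (0, 1), got {clamp_epsilon}"
        )
    return np.arctanh(np.clip(r, -1.0 + clamp_epsilon, 1.0 - clamp_epsilon))


def fisher_transform(
    network: GroupNetwork, clamp_epsilon: float = DEFAULT_CLAMP_EPSILON
) -> GroupNetwork:
    """Fill a network's z matrix (diagonal forced to 0)."""
    z = fisher_z(network.r_matrix, clamp_epsilon)
    np.fill_diagonal(z, 0.0)
    network.z_matrix = z
    network.clamp_epsilon = clamp_epsilon
    return network
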