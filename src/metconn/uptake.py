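"""Subject-by-region uptake tables and their CSV serialization.

An :class:`UptakeTable` holds strictly positive regional tracer uptake for a
cohort of subjects, one row per subject, columns ordered by the atlas.  The
same container (via the shared base class) also carries SUVR values after
reference normalization.

CSV convention: comma-separated, UTF-8, header row ``subject_id,group``
followed by one column per atlas region.  Region columns are matched to the
atlas by exact, case-sensitive name and re-ordered to atlas order on read,
so input column order never leaks into downstream matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .atlas import VOIAtlas
from .errors import SchemaError, ValidationError

ID_COLUMNS = ("subject_id", "group")


@dataclass
class SubjectTable:
    """Subjects x regions matrix with group labels, ordered by an atlas."""

    subject_ids: list[str]
    groups: list[str]
    values: np.ndarray  # (n_subjects, n_regions), float64
    atlas: VOIAtlas

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D subjects x regions matrix")
        n_sub, n_reg = self.values.shape
        if len(self.subject_ids) != n_sub or len(self.groups) != n_sub:
            raise ValidationError("subject_ids/groups length must match value rows")
        if len(set(self.subject_ids)) != n_sub:
            raise ValidationError("subject ids must be unique")
        if n_reg != self.atlas.n_regions:
            raise ValidationError(
                f"value columns ({n_reg}) != atlas regions ({self.atlas.n_regions})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must all be finite")
        self._check_positive()

    def _check_positive(self) -> None:
        bad = np.argwhere(self.values <= 0)
        if bad.size:
            s, r = bad[0]
            raise ValidationError(
                f"non-positive value for subject {self.subject_ids[s]!r}, "
                f"region {self.atlas.names[r]!r}: {self.values[s, r]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def group_values(self, group: str) -> np.ndarray:
        """Rows of ``values`` belonging to one group (copy)."""
        mask = np.asarray([g == group for g in self.groups])
        if not mask.any():
            raise ValidationError(f"no subjects in group {group!r}")
        return self.values[mask].copy()

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.atlas.names)
        frame.insert(0, "group", self.groups)
        frame.insert(0, "subject_id", self.subject_ids)
        return frame


@dataclass
class UptakeTable(SubjectTable):
    """Raw regional uptake (arbitrary positive activity units)."""


@dataclass
class SUVRTable(SubjectTable):
    """Reference-normalized uptake ratios (dimensionless).

    ``reference_definition`` records which regions were pooled and how, for
    provenance in pipeline metadata.
    """

    reference_definition: dict = field(default_factory=dict)


def _table_from_frame(
    frame: pd.DataFrame, atlas: VOIAtlas, source: str
) -> tuple[list[str], list[str], np.ndarray]:
    for col in ID_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{source}: missing required column {col!r}")
    missing = [n for n in atlas.names if n not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing region columns {missing}")
    extra = [c for c in frame.columns if c not in ID_COLUMNS and c not in atlas.names]
    if extra:
        raise SchemaError(f"{source}: unknown columns not in atlas: {extra}")
    values = frame[atlas.names].to_numpy(dtype=float)  # atlas order, not file order
    return (
        [str(s) for s in frame["subject_id"]],
        [str(g) for g in frame["group"]],
        values,
    )


def read_uptake(path: Union[str, Path], atlas: VOIAtlas) -> UptakeTable:
    """Read an uptake CSV and validate it against an atlas.

    Row (subject) order is preserved; region columns are re-ordered to atlas
    order whatever their order in the file.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    ids, groups, values = _table_from_frame(frame, atlas, str(path))
    return UptakeTable(ids, groups, values, atlas)


def write_uptake(table: SubjectTable, path: Union[str, Path]) -> None:
    """Write a table as CSV at full float precision (read/write round-trips
    to bit-identical values)."""
    frame = table.to_frame()
    frame.to_csv(path, index=False, float_format=None)


def read_suvr(path: Union[str, Path], atlas: VOIAtlas) -> SUVRTable:
    """Read a previously written SUVR CSV (same schema as uptake)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    ids, groups, values = _table_from_frame(frame, atlas, str(path))
    return SUVRTable(ids, groups, values, atlas)


def require_two_groups(
    table: SubjectTable, group_a: str, group_b: str, min_size: int = 3
) -> None:
    """Validate a table for a two-group comparison workflow."""
    counts = {g: table.groups.count(g) for g in (group_a, group_b)}
    for g, c in counts.items():
        if c < min_size:
            raise ValidationError(
                f"group {g!r} has {c} subjects; at least {min_size} required"
            )
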