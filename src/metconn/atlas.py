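"""Volume-of-interest (VOI) atlas: the ordered node set of the brain network.

An atlas is an ordered list of named brain regions with a hemisphere label
and a reference-region flag.  The atlas order is authoritative: every matrix
produced downstream (uptake, SUVR, correlation, Fisher z) uses it as its
row/column order, regardless of the column order of input files.

The packaged default atlas holds 53 mouse-brain VOIs (left and right), with
the bilateral medulla flagged as the reference region used for SUVR
normalization.  The region list is a best-effort reconstruction from
published edge tables and is illustrative: any user-supplied atlas with at
least one reference region is equally valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import AtlasFormatError

HEMISPHERES = ("L", "R", "NA")


@dataclass(frozen=True)
class Region:
    """A single named VOI."""

    name: str
    hemisphere: str = "NA"
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise AtlasFormatError("region name must be non-empty")
        if self.hemisphere not in HEMISPHERES:
            raise AtlasFormatError(
                f"region {self.name!r}: hemisphere must be one of "
                f"{HEMISPHERES}, got {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class VOIAtlas:
    """Ordered collection of regions defining matrix row/column order.

    Invariants (enforced at construction): region names are unique and
    non-empty, and at least one region is flagged ``is_reference``.
    """

    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AtlasFormatError(f"duplicate region names: {dupes}")
        if not any(r.is_reference for r in self.regions):
            raise AtlasFormatError("atlas must flag at least one reference region")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def reference_names(self) -> list[str]:
        """Names of all regions flagged as reference, in atlas order."""
        return [r.name for r in self.regions if r.is_reference]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def __len__(self) -> int:
        return self.n_regions

    def __iter__(self) -> Iterable[Region]:
        return iter(self.regions)


def _regions_from_records(records: list[dict]) -> VOIAtlas:
    regions = []
    for i, rec in enumerate(records):
        if not isinstance(rec, dict) or "name" not in rec:
            raise AtlasFormatError(f"atlas entry {i} is not a region record: {rec!r}")
        regions.append(
            Region(
                name=str(rec["name"]),
                hemisphere=str(rec.get("hemisphere", "NA")),
                is_reference=bool(rec.get("is_reference", False)),
            )
        )
    return VOIAtlas(tuple(regions))


def read_atlas(path: Union[str, Path]) -> VOIAtlas:
    """Read a VOI atlas from a JSON file.

    The file is a JSON array of ``{"name", "hemisphere", "is_reference"}``
    records; region order in the file defines atlas order.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AtlasFormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise AtlasFormatError(f"{path}: atlas JSON must be an array of regions")
    return _regions_from_records(records)


def write_atlas(atlas: VOIAtlas, path: Union[str, Path]) -> None:
    """Write an atlas as JSON, preserving region order."""
    records = [
        {"name": r.name, "hemisphere": r.hemisphere, "is_reference": r.is_reference}
        for r in atlas.regions
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def default_atlas() -> VOIAtlas:
    """The packaged 53-VOI mouse brain atlas (bilateral medulla reference)."""
    text = resources.files("metconn.data").joinpath("default_atlas.json").read_text()
    return _regions_from_records(json.loads(text))
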