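"""Human-readable and graph exports of edge comparison results."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import networkx as nx
import pandas as pd

from .atlas import VOIAtlas
from .permutation import (
    DEFAULT_THRESHOLDS,
    NS,
    EdgeComparisonResult,
    tier_label,
)

_INC = "Increased Correlation between Two Nodes"
_DEC = "Decreased Correlation between Two Nodes"


def _tier_order(thresholds: Sequence[float]) -> list[str]:
    # largest threshold first, matching the published table layout
    return [tier_label(t) for t in sorted(thresholds, reverse=True)]


def significant_frame(
    results: list[EdgeComparisonResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Significant edges only: direction, region pair, tier.

    Rows are ordered by tier block (least to most stringent threshold),
    then direction (increased before decreased), then region names — a
    deterministic order even among tied p-values.
    """
    tiers = _tier_order(thresholds)
    rows = []
    for tier in tiers:
        for direction in ("increased", "decreased"):
            picked = sorted(
                (r for r in results if r.tier == tier and r.direction == direction),
                key=lambda r: (r.region_i, r.region_j),
            )
            rows.extend(
                {
                    "direction": r.direction,
                    "region_i": r.region_i,
                    "region_j": r.region_j,
                    "tier": r.tier,
                    "p_value": r.p_value,
                    "delta_z": r.delta_z,
                }
                for r in picked
            )
    return pd.DataFrame(
        rows, columns=["direction", "region_i", "region_j", "tier", "p_value", "delta_z"]
    )


def render_edge_table(
    results: list[EdgeComparisonResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> str:
    """Plain-text table of significant edges, blocked by significance tier.

    Increased and decreased edges are printed side by side, with the tier
    label on the first row of each block; an all-ns result set renders the
    headers only.
    """
    blocks = []
    for tier in _tier_order(thresholds):
        inc = sorted(
            (r for r in results if r.tier == tier and r.direction == "increased"),
            key=lambda r: (r.region_i, r.region_j),
        )
        dec = sorted(
            (r for r in results if r.tier == tier and r.direction == "decreased"),
            key=lambda r: (r.region_i, r.region_j),
        )
        rows = []
        for k in range(max(len(inc), len(dec))):
            left = f"{inc[k].region_i} -- {inc[k].region_j}" if k < len(inc) else ""
            right = f"{dec[k].region_i} -- {dec[k].region_j}" if k < len(dec) else ""
            rows.append((left, right, tier if k == 0 else ""))
        if rows:
            blocks.append(rows)

    all_rows = [r for block in blocks for r in block]
    w1 = max([len(_INC)] + [len(r[0]) for r in all_rows])
    w2 = max([len(_DEC)] + [len(r[1]) for r in all_rows])
    lines = [f"{_INC:<{w1}}  {_DEC:<{w2}}  p-Value"]
    lines.append("-" * len(lines[0]))
    for left, right, tier in all_rows:
        lines.append(f"{left:<{w1}}  {right:<{w2}}  {tier}")
    return "\n".join(lines) + "\n"


def to_graphml(
    results: list[EdgeComparisonResult],
    atlas: VOIAtlas,
    path: Union[str, Path],
    significant_only: bool = False,
) -> None:
    """Export the comparison as GraphML.

    Nodes are atlas regions (hemisphere attribute); edges carry delta_z,
    p-value and tier.  With ``significant_only`` only non-ns edges are kept
    — the network-figure view of the result.
    """
    graph = nx.Graph()
    for region in atlas:
        graph.add_node(
            region.name, hemisphere=region.hemisphere, is_reference=region.is_reference
        )
    for r in results:
        if significant_only and r.tier == NS:
            continue
        graph.add_edge(
            r.region_i,
            r.region_j,
            delta_z=r.delta_z,
            p=r.p_value,
            tier=r.tier,
            direction=r.direction,
        )
    nx.write_graphml(graph, str(path))
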