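"""End-to-end orchestration: (simulate) -> SUVR -> networks -> edge test.

A :class:`RunConfig` captures every input and parameter of a run; it
round-trips losslessly to YAML or JSON, and all randomness flows from its
single seed.  ``run_pipeline`` writes a complete artifact set under the
output directory and guarantees byte-identical outputs when re-run with the
same configuration on the same platform.  On failure, partial outputs are
removed and the stage name is attached to the raised error.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .atlas import VOIAtlas, default_atlas, read_atlas
from .errors import ConfigurationError, MetconnError
from .network import DEFAULT_CLAMP_EPSILON, correlation_matrix, fisher_transform
from .permutation import (
    DEFAULT_THRESHOLDS,
    PermutationConfig,
    annotate_bh,
    permutation_edge_test,
    results_to_frame,
)
from .report import render_edge_table, significant_frame, to_graphml
from .simulate import EdgeEffect, SyntheticCohortSpec, simulate_cohort, target_correlations
from .suvr import compute_suvr
from .uptake import read_uptake, write_uptake

log = logging.getLogger("metconn")


@dataclass
class SimulateSection:
    """Simulation parameters of a config file (used when no uptake CSV)."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {"KO": 7, "WT": 7})
    base_correlation: str = "identity"
    rho: float = 0.0
    edge_effects: list[dict] = field(default_factory=list)
    cv: float = 0.1


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    out: str
    atlas: Optional[str] = None  # path; None = packaged default atlas
    uptake: Optional[str] = None  # path; None = simulate
    simulate: Optional[SimulateSection] = None
    group_a: str = "KO"
    group_b: str = "WT"
    reference: Optional[list[str]] = None  # None = atlas default
    n_permutations: int = 5000
    seed: int = 0
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    clamp_epsilon: float = DEFAULT_CLAMP_EPSILON
    graphml: bool = False
    bh_annotation: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        self.clamp_epsilon = float(self.clamp_epsilon)
        if isinstance(self.simulate, dict):
            self.simulate = SimulateSection(**self.simulate)
        if self.uptake is None and self.simulate is None:
            self.simulate = SimulateSection()

    def to_file(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["thresholds"] = list(self.thresholds)
        text = (
            json.dumps(data, indent=1)
            if str(path).endswith(".json")
            else yaml.safe_dump(data, sort_keys=False)
        )
        Path(path).write_text(text, encoding="utf-8")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        try:
            # JSON first: pyyaml's YAML 1.1 resolver misreads exponent
            # notation like 1e-06 as a string
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls(**data)


def _load_atlas(config: RunConfig) -> VOIAtlas:
    return read_atlas(config.atlas) if config.atlas else default_atlas()


def _cohort_spec(config: RunConfig, atlas: VOIAtlas) -> SyntheticCohortSpec:
    sim = config.simulate
    base: Union[str, tuple] = sim.base_correlation
    if base == "exchangeable":
        base = ("exchangeable", sim.rho)
    effects = [EdgeEffect(**e) for e in sim.edge_effects]
    return SyntheticCohortSpec(
        atlas=atlas,
        group_sizes=dict(sim.group_sizes),
        base_correlation=base,
        edge_effects=effects,
        cv=sim.cv,
        seed=config.seed,
    )


def _write_matrix(matrix, names: list[str], path: Path) -> None:
    frame = pd.DataFrame(matrix, index=names, columns=names)
    frame.to_csv(path, index_label="region")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Artifacts written under ``config.out``: ``suvr.csv``, per-group
    ``r_<group>.csv`` / ``z_<group>.csv``, ``edges.csv``,
    ``significant_edges.csv``, ``edge_table.txt``, ``run_metadata.json``;
    plus ``uptake.csv`` and ``ground_truth.json`` for simulated input and
    ``edges.graphml`` when requested.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str) -> Path:
        path = out_dir / name
        written.append(path)
        return path

    try:
        t0 = time.perf_counter()
        stage = "atlas"
        atlas = _load_atlas(config)

        stage = "input"
        ground_truth = None
        if config.uptake:
            table = read_uptake(config.uptake, atlas)
        else:
            spec = _cohort_spec(config, atlas)
            table = simulate_cohort(spec)
            ground_truth = {
                g: sigma.tolist() for g, sigma in target_correlations(spec).items()
            }
            write_uptake(table, emit("uptake.csv"))
        log.info("input: %d subjects x %d regions", table.n_subjects, atlas.n_regions)

        stage = "suvr"
        suvr = compute_suvr(table, config.reference)
        write_uptake(suvr, emit("suvr.csv"))

        stage = "network"
        for group in (config.group_a, config.group_b):
            net = fisher_transform(correlation_matrix(suvr, group), config.clamp_epsilon)
            _write_matrix(net.r_matrix, atlas.names, emit(f"r_{group}.csv"))
            _write_matrix(net.z_matrix, atlas.names, emit(f"z_{group}.csv"))

        stage = "compare"
        perm_config = PermutationConfig(
            n_permutations=config.n_permutations,
            seed=config.seed,
            thresholds=config.thresholds,
            clamp_epsilon=config.clamp_epsilon,
        )
        results = permutation_edge_test(suvr, config.group_a, config.group_b, perm_config)

        stage = "report"
        edges = annotate_bh(results) if config.bh_annotation else results_to_frame(results)
        edges.to_csv(emit("edges.csv"), index=False)
        significant_frame(results, config.thresholds).to_csv(
            emit("significant_edges.csv"), index=False
        )
        emit("edge_table.txt").write_text(
            render_edge_table(results, config.thresholds), encoding="utf-8"
        )
        if config.graphml:
            to_graphml(results, atlas, emit("edges.graphml"))
        if ground_truth is not None:
            emit("ground_truth.json").write_text(
                json.dumps(ground_truth), encoding="utf-8"
            )

        metadata = {
            "software": {"name": "metconn", "version": __version__},
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "thresholds": list(config.thresholds),
            "clamp_epsilon": config.clamp_epsilon,
            "group_a": config.group_a,
            "group_b": config.group_b,
            "n_regions": atlas.n_regions,
            "n_edges": atlas.n_regions * (atlas.n_regions - 1) // 2,
            "group_sizes": {
                g: table.groups.count(g) for g in (config.group_a, config.group_b)
            },
            "reference_definition": suvr.reference_definition,
            "simulated": config.uptake is None,
        }
        emit("run_metadata.json").write_text(
            json.dumps(metadata, indent=1), encoding="utf-8"
        )
        log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
        return out_dir
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, MetconnError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise MetconnError(f"[stage: {stage}] {exc}") from exc
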