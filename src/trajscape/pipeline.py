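"""Full comparative-report orchestration from a config file.

A single run computes, on one analyzed frame set: the per-residue surface
topography and local-flexibility maps, the interaction-persistence
network, and the conformational-substate partition, then writes them with
full provenance (parameter digests, frame counts, every non-printed
default echoed).  Two runs — e.g. the same receptor with two different
ligands — are then compared residue-by-residue, which is the core
comparative readout this toolkit exists for.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flexibility import FluctuationParams, fluctuation_map
from .interactions import InteractionParams, InteractionNetwork, persistence_network
from .maps import ResidueScalarMap
from .model_io import Ensemble, read_ensemble, select
from .substates import ClusterParams, SubstatePartition, cluster_substates, pairwise_rmsd
from .topography import TopographyParams, topography_map

__all__ = ["AnalysisConfig", "ComparativeReport", "run_report", "compare_reports"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Validated configuration for one comparative-analysis run."""

    topology: str
    frames: str | None = None
    truth: str | None = None
    burn_in_fraction: float = 0.5
    analysis_selection: str = "not hetero"
    calpha_selection: str = "calpha"
    exclude_selection: str | None = None  # e.g. a mobile loop left out of clustering
    ligand_selection: str | None = None
    topography: dict = field(default_factory=dict)
    flexibility: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    substates: dict = field(default_factory=dict)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # instantiate parameter blocks up front so invalid values fail early
        self.topography_params = TopographyParams(**self.topography)
        self.flexibility_params = FluctuationParams(**self.flexibility)
        self.interaction_params = InteractionParams(**self.interactions)
        self.cluster_params = ClusterParams(**self.substates)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not Path(cfg.topology).exists():
            raise FileNotFoundError(cfg.topology)
        if cfg.frames is not None and not Path(cfg.frames).exists():
            raise FileNotFoundError(cfg.frames)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ComparativeReport:
    topography: ResidueScalarMap | None
    flexibility: ResidueScalarMap | None
    network: InteractionNetwork | None
    partition: SubstatePartition | None
    metadata: dict
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def write(self, outdir: str, topology=None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.topography is not None:
            self.topography.to_csv(out / "topography.csv")
            if topology is not None:
                self.topography.write_bfactor_pdb(topology, out / "topography_bfactor.pdb")
        if self.flexibility is not None:
            self.flexibility.to_csv(out / "flexibility.csv")
            if topology is not None:
                self.flexibility.write_bfactor_pdb(topology, out / "flexibility_bfactor.pdb")
        if self.network is not None:
            self.network.to_tsv(out / "interactions.tsv")
        if self.partition is not None:
            self.partition.to_json(out / "substates.json")
        meta = dict(self.metadata)
        meta["errors"] = self.errors
        with open(out / "report.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def _region_expr(base: str, exclude: str | None) -> str:
    return f"({base}) and not ({exclude})" if exclude else base


def run_report(config: AnalysisConfig) -> ComparativeReport:
    """Run topography → flexibility → interactions → substates on one ensemble.

    Stage failures on degenerate inputs (e.g. a one-frame ensemble, for
    which a fluctuation width is undefined) are recorded per stage and the
    remaining stages still run; callers should treat a report with
    non-empty ``errors`` as partial.
    """
    ens = read_ensemble(config.topology, config.frames, burn_in_fraction=config.burn_in_fraction)
    st = ens.topology
    analysis_sel = select(st, _region_expr(config.analysis_selection, config.exclude_selection))
    calpha_sel = select(st, _region_expr(config.calpha_selection, config.exclude_selection))

    metadata = {
        "trajscape_version": __version__,
        "topology": config.topology,
        "frames": config.frames,
        "n_frames_total": ens.n_frames,
        "n_frames_analyzed": int(len(ens.analyzed_frame_indices)),
        "burn_in_fraction": config.burn_in_fraction,
        "analysis_selection": analysis_sel.expression,
        "calpha_selection": calpha_sel.expression,
        "seed": config.seed,
        # non-printed defaults, echoed so no result depends on a hidden choice
        "params": {
            "topography": repr(config.topography_params),
            "flexibility": repr(config.flexibility_params),
            "interactions": repr(config.interaction_params),
            "substates": repr(config.cluster_params),
        },
        "digests": {
            "topography": config.topography_params.digest,
            "flexibility": config.flexibility_params.digest,
            "interactions": config.interaction_params.digest,
            "substates": config.cluster_params.digest,
        },
        "stage_seconds": {},
    }
    errors: dict[str, str] = {}
    results: dict = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except (ValueError, KeyError) as exc:
            errors[name] = str(exc)
            logger.warning("stage %s failed: %s", name, exc)
        metadata["stage_seconds"][name] = round(time.perf_counter() - t0, 4)

    stage("topography", lambda: topography_map(ens, analysis_sel, config.topography_params))
    stage("flexibility", lambda: fluctuation_map(ens, analysis_sel, config.flexibility_params))

    def _network():
        pairs = [(analysis_sel, analysis_sel)]
        if config.ligand_selection:
            lig = select(st, config.ligand_selection)
            pairs.append((analysis_sel, lig))
        return persistence_network(ens, pairs, config.interaction_params)

    stage("interactions", _network)

    def _substates():
        mat = pairwise_rmsd(ens, calpha_sel, stride=config.cluster_params.stride)
        return cluster_substates(mat, config.cluster_params)

    stage("substates", _substates)

    report = ComparativeReport(
        topography=results.get("topography"),
        flexibility=results.get("flexibility"),
        network=results.get("interactions"),
        partition=results.get("substates"),
        metadata=metadata,
        errors=errors,
    )
    if config.output_dir:
        report.write(config.output_dir, topology=st)
    return report


def compare_reports(report_a: ComparativeReport, report_b: ComparativeReport) -> dict[str, pd.DataFrame]:
    """Per-residue difference tables (a − b) for the scalar maps.

    Residues present on only one side are marked missing, never zero-filled.
    A parameter-digest mismatch between the two runs is a warning: the
    difference is then comparing maps computed under different settings.
    """
    out: dict[str, pd.DataFrame] = {}
    for name in ("topography", "flexibility"):
        ma, mb = getattr(report_a, name), getattr(report_b, name)
        if ma is None or mb is None:
            continue
        if ma.params_digest != mb.params_digest:
            logger.warning("compare_reports: %s params digests differ (%s vs %s)",
                           name, ma.params_digest, mb.params_digest)
        out[name] = ma.difference(mb)
    if not out:
        raise ValueError("reports share no comparable scalar maps")
    return out
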