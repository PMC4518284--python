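"""End-to-end orchestration: phantom/volume -> mask -> skeleton -> graph -> report.

A run is fully described by a :class:`RunConfig` (single YAML/JSON file with
per-stage sections; flags override the file).  Every artifact — mask,
skeleton, distance map, radius map, graph, per-segment CSV, summary CSV and
a provenance record (config + seed + package version) — is written to the
output directory, and the same config + seed reproduces the summary CSV
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .phantom import (GroundTruthGraph, InjurySpec, PhantomSpec, apply_injury,
                      degrade_volume, generate_tree, rasterize_tree)
from .segmentation import segment_vessels
from .skeletonization import (euclidean_distance_map, prune_spurs,
                              radius_from_edm, thinning_3d)
from .vessel_graph import MorphometryReport, build_graph, summarize_roi
from .volume_io import ROI, Volume3D, read_volume, write_mask, write_volume

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run; every field has a default."""

    input_path: str | None = None          # read a volume instead of a phantom
    phantom: dict = field(default_factory=dict)    # PhantomSpec overrides
    injury: dict | None = None             # InjurySpec fields, or None
    threshold: float | None = None         # fixed threshold; None = isodata
    min_component_voxels: int = 3
    prune_length_um: float = 0.0
    chamfer: bool = False
    trunk_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    min_branch_voxels: int = 5
    roi: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trunk_axis"] = list(self.trunk_axis)
        if self.roi is not None:
            d["roi"] = [list(self.roi[0]), list(self.roi[1])]
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "trunk_axis" in d:
            d["trunk_axis"] = tuple(d["trunk_axis"])
        if d.get("roi") is not None:
            d["roi"] = (tuple(d["roi"][0]), tuple(d["roi"][1]))
        return RunConfig(**d)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    params = dict(config.phantom)
    params.setdefault("rng_seed", config.seed)
    for key in ("grid_shape", "voxel_spacing_um", "radius_range_um", "trunk_span_frac"):
        if key in params:
            params[key] = tuple(params[key])
    return PhantomSpec(**params)


def run_pipeline(config: RunConfig, out_dir) -> MorphometryReport:
    """Execute every stage and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vasculometry")
    root.addHandler(log_handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    t_start = time.time()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t_start)

    truth: GroundTruthGraph | None = None
    try:
        if config.input_path:
            stage("read")
            vol = read_volume(config.input_path)
        else:
            stage("phantom")
            spec = _phantom_spec(config)
            truth = generate_tree(spec)
            vol = rasterize_tree(truth, spec)
            if config.injury:
                inj = InjurySpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in config.injury.items()})
                truth, vol = apply_injury(truth, vol, inj, spec)
            vol = degrade_volume(vol, spec)
            truth.write_json(out / "ground_truth.json")
            truth.write_graphml(out / "ground_truth.graphml")
            write_volume(Volume3D(vol.data.astype(np.float32), vol.spacing_um),
                         out / "volume.tif")

        stage("segment")
        mask, thr = segment_vessels(vol, threshold=config.threshold,
                                    min_voxels=config.min_component_voxels)
        logger.info("segmentation: %d foreground voxels", mask.n_foreground())
        write_mask(mask.data, mask.spacing_um, out / "mask.tif")
        if thr is not None:
            (out / "threshold.json").write_text(json.dumps(
                {"threshold": thr.threshold, "iterations": thr.iterations,
                 "history": thr.history}, indent=2))

        stage("skeletonize")
        skel = thinning_3d(mask)
        if config.prune_length_um > 0:
            skel = prune_spurs(skel, config.prune_length_um)
        edm = euclidean_distance_map(mask, chamfer=config.chamfer)
        radii = radius_from_edm(skel, edm)
        write_mask(skel.data, skel.spacing_um, out / "skeleton.tif")
        write_volume(Volume3D(edm.data.astype(np.float32), mask.spacing_um),
                     out / "edm.nii.gz")
        write_volume(Volume3D(radii.data.astype(np.float32), mask.spacing_um),
                     out / "radii.nii.gz")

        stage("graph")
        graph = build_graph(skel, radii)
        logger.info("graph: VN=%d VNN=%d", graph.vn, graph.vnn)
        graph.write_json(out / "vessel_graph.json")
        graph.write_graphml(out / "vessel_graph.graphml")

        stage("report")
        roi = ROI(*config.roi) if config.roi is not None else None
        report = summarize_roi(mask, graph, roi=roi, trunk_axis=config.trunk_axis,
                               min_branch_voxels=config.min_branch_voxels)
        report.segment_table.to_csv(out / "segments.csv", index=False,
                                    float_format=_FLOAT_FMT)
        report.summary_frame().to_csv(out / "summary.csv", index=False,
                                      float_format=_FLOAT_FMT)
        provenance = {
            "config": config.to_dict(),
            "seed": config.seed,
            "package_version": __version__,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
        stage("done")
        return report
    except Exception as exc:  # annotate which stage failed
        logger.exception("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def run_phantom_study(base_config: RunConfig, n_per_arm: int, injury: dict,
                      out_dir, seed: int = 0):
    """Run matched normal/injured phantom arms (seeded replicates).

    Returns ``(normal_reports, injured_reports)``; replicate k of each arm
    uses seed ``seed + k`` so arms are paired by phantom geometry.
    """
    out = Path(out_dir)
    normals, injureds = [], []
    for k in range(n_per_arm):
        cfg_n = dataclasses.replace(base_config, seed=seed + k, injury=None)
        normals.append(run_pipeline(cfg_n, out / f"normal_{k}"))
        cfg_i = dataclasses.replace(base_config, seed=seed + k, injury=injury)
        injureds.append(run_pipeline(cfg_i, out / f"injured_{k}"))
    return normals, injureds
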