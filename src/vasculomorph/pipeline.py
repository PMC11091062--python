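"""End-to-end orchestration: phantom/input -> masks -> graph -> metrics -> report.

The workflow mirrors the classical two-tool chain for vascular micro-CT
(global segmentation and top-hat in one tool, skeleton and morphometry in
another), but with every hand-off explicit: each of the six stages —
``phantom`` (or input loading), ``segment``, ``skeleton``, ``measure``,
``zones``, ``report`` — persists its outputs to the run directory, and a
manifest records the configuration hash, package version and a checksum per
written file.  Stage outputs are pure functions of (inputs, config, seed):
re-running an identical configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .morphometry import metrics_table, network_summary
from .phantom import PhantomSpec, TubeSpec, WedgeParams, make_wedge_tissue, rasterize_phantom
from .segmentation import StructuringElement, remove_background, segment_vessels
from .skeleton import build_graph, distance_map, prune_spurs, save_graph, skeletonize
from .stats import GroupSample, build_report, compare_groups
from .volume import load_mask, load_volume, save_mask, save_volume
from .zonation import circumferential_zones, radial_sectors, zone_contributions, zone_morphometry

__all__ = ["RunConfig", "run_pipeline", "PRESETS"]

logger = logging.getLogger(__name__)

STAGES = ("phantom", "segment", "skeleton", "measure", "zones", "report")

#: named resolution presets for the three scan groups
PRESETS = {
    "groupA-60um": 60.0,
    "groupB-30um": 30.0,
    "groupC-15um": 15.0,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str
    seed: int = 0
    # input: either an inline phantom spec, or paths to TIFF stacks
    phantom: dict | None = None
    volume_path: str | None = None
    tissue_path: str | None = None
    pm_path: str | None = None
    voxel_size_um: tuple[float, float, float] | float | None = None
    # segmentation
    se_radius_vx: int = 2
    tophat_rule: str | float = "max_entropy"
    # skeleton
    prune_um: float = 0.0
    # zonation
    pm_band_um: float | None = None
    sagittal_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    side: str = "lateral"
    # stats
    alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if self.phantom is None and self.volume_path is None:
            raise ValueError("config needs either a phantom spec or a volume_path")
        if self.volume_path is not None and not Path(self.volume_path).exists():
            raise ValueError(f"volume_path does not exist: {self.volume_path}")
        for attr in ("tissue_path", "pm_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} does not exist: {p}")
        if self.phantom is None and self.voxel_size_um is None:
            raise ValueError("voxel_size_um is required when loading a volume")

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    tubes = [TubeSpec(np.asarray(t["centerline"], float),
                      np.asarray(t["radius_um"], float)
                      if np.ndim(t["radius_um"]) else float(t["radius_um"]),
                      float(t.get("intensity", 220.0)), t.get("name", ""))
             for t in d.pop("tubes", [])]
    tissue = d.pop("tissue", None)
    wedge = WedgeParams(**{**tissue, "center_um": tuple(tissue["center_um"])}) if tissue else None
    return PhantomSpec(tubes=tubes, tissue=wedge, **d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; return the run directory.

    A stage failure halts the run, leaving completed intermediates and a
    partial manifest in place.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    written: dict[str, list[Path]] = {}

    def _finish_stage(name: str, paths: list[Path]) -> None:
        written[name] = paths
        manifest["stages"][name] = {
            "files": {p.name: _sha256(p) for p in sorted(paths)},
            "status": "completed",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    # -- stage 1: phantom / input ------------------------------------------
    if config.phantom is not None:
        spec = _phantom_spec_from_dict({**config.phantom, "seed": config.seed})
        vol, truth, gt = rasterize_phantom(spec)
        tissue = make_wedge_tissue(spec) if spec.tissue is not None else None
        pm = None
        paths = [save_volume(vol, out / "volume.tif"),
                 save_mask(truth, out / "truth_mask.tif")]
        paths.append((out / "ground_truth.json"))
        paths[-1].write_text(json.dumps(dataclasses.asdict(gt), sort_keys=True, default=str))
        if tissue is not None:
            paths.append(save_mask(tissue, out / "tissue_mask.tif"))
        vs = spec.voxel_size_um
    else:
        vol = load_volume(config.volume_path, config.voxel_size_um)
        tissue = load_mask(config.tissue_path) if config.tissue_path else None
        pm = load_mask(config.pm_path) if config.pm_path else None
        vs = vol.voxel_size_um
        paths = []
    _finish_stage("phantom", paths)

    # -- stage 2: segmentation ---------------------------------------------
    vol_bg = remove_background(vol, tissue)
    se = StructuringElement(radius_vx=(config.se_radius_vx,) * 3)
    seg = segment_vessels(vol_bg, se=se, tophat_threshold_rule=config.tophat_rule,
                          tissue_mask=tissue)
    paths = [save_mask(seg.entropy_mask, out / "entropy_mask.tif"),
             save_mask(seg.tophat_mask, out / "tophat_mask.tif"),
             save_mask(seg.combined_mask, out / "vessel_mask.tif")]
    p = out / "segmentation.json"
    p.write_text(json.dumps({"t_star": seg.t_star, "tophat_threshold": seg.tophat_threshold},
                            sort_keys=True))
    paths.append(p)
    _finish_stage("segment", paths)

    # -- stage 3: skeleton / graph ------------------------------------------
    dmap = distance_map(seg.combined_mask, vs)
    skel = skeletonize(seg.combined_mask)
    graph = build_graph(skel, dmap)
    if config.prune_um > 0:
        graph = prune_spurs(graph, config.prune_um)
    paths = [save_mask(skel, out / "skeleton.tif")]
    paths += list(save_graph(graph, out / "graph").values())
    _finish_stage("skeleton", paths)

    # -- stage 4: morphometry -----------------------------------------------
    table = metrics_table(graph)
    summary = network_summary(graph, seg.combined_mask, vs)
    p1 = out / "segment_metrics.csv"
    table.to_csv(p1, index=False)
    p2 = out / "network_summary.json"
    summ_d = {k: v for k, v in dataclasses.asdict(summary).items()
              if not k.endswith("histogram")}
    p2.write_text(json.dumps(summ_d, sort_keys=True))
    _finish_stage("measure", [p1, p2])

    # -- stage 5: zonation ----------------------------------------------------
    zone_paths: list[Path] = []
    circ_morph = radial_morph = contribs = None
    zonemap = None
    if tissue is not None:
        circ = circumferential_zones(tissue, vs, pm_mask=pm,
                                     pm_band_um=None if pm is not None else
                                     (config.pm_band_um or _default_pm_band(config, tissue, vs)))
        rad = radial_sectors(tissue, vs, sagittal_axis=config.sagittal_axis, side=config.side)
        from .zonation import ZoneMap

        zonemap = ZoneMap(circ=circ.circ, radial=rad.radial, voxel_size_um=circ.voxel_size_um,
                          meta={**circ.meta, **rad.meta})
        import tifffile

        pz = out / "zones_circumferential.tif"
        tifffile.imwrite(pz, zonemap.circ)
        pr = out / "zones_radial.tif"
        tifffile.imwrite(pr, zonemap.radial)
        legend = out / "zones_legend.json"
        from .zonation import CIRC_LABELS, RADIAL_LABELS

        legend.write_text(json.dumps({"circumferential": CIRC_LABELS,
                                      "radial": RADIAL_LABELS}, sort_keys=True))
        contribs = zone_contributions(zonemap, seg.combined_mask, "circumferential")
        contribs_r = zone_contributions(zonemap, seg.combined_mask, "radial")
        contribs_r["partition"] = "radial"
        contribs["partition"] = "circumferential"
        import pandas as pd

        contribs = pd.concat([contribs, contribs_r], ignore_index=True)
        pc = out / "zone_contributions.csv"
        contribs.to_csv(pc, index=False)
        circ_morph = zone_morphometry(zonemap, graph, "circumferential")
        radial_morph = zone_morphometry(zonemap, graph, "radial")
        zone_paths = [pz, pr, legend, pc]
    _finish_stage("zones", zone_paths)

    # -- stage 6: report ------------------------------------------------------
    comparisons = None
    if zonemap is not None and not table.empty:
        groups = _zone_groups(zonemap, graph, table)
        if len(groups) >= 2 and sum(g.n for g in groups) > len(groups):
            comparisons = {"mean_diameter_by_zone": compare_groups(groups, alpha=config.alpha)}
    report_paths = build_report(
        out / "report",
        summaries={"run": summary},
        circ_morphometry=circ_morph,
        radial_morphometry=radial_morph,
        contributions=contribs,
        comparisons=comparisons,
    )
    _finish_stage("report", list(report_paths.values()))
    return out


def _default_pm_band(config: RunConfig, tissue: np.ndarray, vs) -> float:
    # fallback: 10% of the in-plane tissue extent is a conservative outer band
    extent = np.count_nonzero(tissue.any(axis=0))
    return 0.1 * np.sqrt(extent) * float(np.mean(vs[1:]))


def _zone_groups(zonemap, graph, table) -> list[GroupSample]:
    """Per-zone segment diameter samples for the zone comparison."""
    from .zonation import _point_labels, CIRC_LABELS

    groups = []
    for code, name in sorted(CIRC_LABELS.items()):
        if name == "outside":
            continue
        obs = []
        for s in graph.segments:
            labels = _point_labels(zonemap, s.points_um, "circumferential")
            counts = np.bincount(labels, minlength=5)
            if counts.argmax() == code:
                obs.append(float(np.mean(2.0 * s.radii_um)))
        if obs:
            groups.append(GroupSample(name, np.asarray(obs)))
    return groups
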