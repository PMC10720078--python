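"""End-to-end orchestration: phantom -> segment -> centerline -> measure -> stats.

A run is described by a single declarative config (YAML file or dict).  Each
stage writes its artifacts into the output directory and a manifest records
the config hash, package version, per-stage summaries and artifact hashes,
so that identical config + seed give identical manifests for deterministic
stages.  With ``resume=True`` a stage whose artifacts already exist under the
same config hash is not recomputed.

Config schema (all blocks optional unless a downstream stage needs them)::

    seed: 7
    outdir: runs/demo
    phantom:                  # generate a PA-tree phantom ...
      trunk_radius: 18.0
      branch_radii: [12.0, 12.0]
      trunk_length: 60.0
      branch_lengths: [50.0, 50.0]
      branch_angles: [70.0, 70.0]
      spacing: [1.0, 1.0, 1.0]
      noise_sd: 0.0
    volume: path.nii.gz       # ... or read an existing volume (exactly one)
    segmentation: {hu_lo: -200.0, hu_hi: 500.0, connectivity: 26}
    seed_point: [x, y, z]     # mm; defaults to the phantom trunk midpoint
    roi: {min: [x,y,z], max: [x,y,z]}
    centerline: {smoothing_factor: 0.5, control_spacing: 1.0, spur_length_min: 5.0}
    measurement: {exclusion_margin: 18.0, diameter_offset: 15.0}
    cohort: {n_nonph: 18, n_ph: 41}
    stats: true
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np

from . import __version__
from .centerline import CenterlineConfig, extract_tree, skeletonize
from .cohort import MEASUREMENT_COLUMNS, CohortConfig, attach_categoricals, generate_cohort
from .core_io import Point3D, read_volume, write_centerline_csv, write_centerline_json, write_mask, write_volume
from .morphometry import MeasurementConfig, measure_all
from .phantom import make_pa_tree_spec, rasterize_phantom
from .segmentation import ROIBox, SegmentationConfig, segment_vessel
from . import stats as st

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"config file {path!r} must hold a mapping")
    return cfg


def _validate(config: dict) -> None:
    has_image = ("phantom" in config) + ("volume" in config)
    wants_geometry = any(k in config for k in ("phantom", "volume", "segmentation", "centerline", "measurement"))
    if wants_geometry and has_image != 1:
        raise PipelineConfigError("exactly one image source is required: a 'phantom' block or a 'volume' path")
    if "volume" in config and not os.path.exists(config["volume"]):
        raise PipelineConfigError(f"input volume {config['volume']!r} does not exist")
    if "volume" in config and "seed_point" not in config:
        raise PipelineConfigError("an input volume needs an explicit 'seed_point' (mm)")
    if not wants_geometry and "cohort" not in config:
        raise PipelineConfigError("config drives no stage: add a 'phantom'/'volume' or 'cohort' block")


def run_pipeline(config: dict, outdir: str | None = None, resume: bool = False) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    _validate(config)
    outdir = outdir or config.get("outdir", "pamorph_run")
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = _config_hash(config)
    manifest_path = os.path.join(outdir, "manifest.json")
    old = None
    if resume and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") != chash:
            old = None

    manifest = {"config_hash": chash, "version": __version__, "seed": seed, "stages": {}, "files": {}}

    def stage_done(name: str, files: list[str]) -> bool:
        if old is None or name not in old.get("stages", {}):
            return False
        for f in files:
            p = os.path.join(outdir, f)
            if not os.path.exists(p) or old["files"].get(f) != _file_hash(p):
                return False
        manifest["stages"][name] = old["stages"][name]
        for f in files:
            manifest["files"][f] = old["files"][f]
        return True

    def record(name: str, summary: dict, files: list[str]) -> None:
        manifest["stages"][name] = summary
        for f in files:
            manifest["files"][f] = _file_hash(os.path.join(outdir, f))

    volume = mask = tree = None
    seed_point = None

    if "phantom" in config:
        files = ["volume.nii.gz", "truth.json"]
        pc = dict(config["phantom"])
        pc.setdefault("seed", seed)
        spec = make_pa_tree_spec(**pc)
        vol_path = os.path.join(outdir, "volume.nii.gz")
        if not stage_done("phantom", files):
            volume, truth = rasterize_phantom(spec)
            write_volume(volume, vol_path)
            tdict = {
                name: {"length_mm": t.curve.length, "r_start": t.r_start, "r_end": t.r_end, "volume_mm3": t.volume()}
                for name, t in truth.tubes.items()
            }
            tdict["bifurcation_mm"] = list(spec.bifurcation) if spec.bifurcation else None
            with open(os.path.join(outdir, "truth.json"), "w") as fh:
                json.dump(tdict, fh, indent=1)
            record("phantom", {"grid": list(spec.grid.shape), "tubes": list(spec.tubes)}, files)
        else:
            log.info("phantom: resumed")
        if volume is None:
            volume = read_volume(vol_path)
        trunk = spec.tubes["trunk"]
        seed_point = Point3D.from_array(trunk.curve.point(trunk.curve.length / 2.0))
    elif "volume" in config:
        volume = read_volume(config["volume"])
        record("input", {"path": config["volume"], "shape": list(volume.shape)}, [])

    if "seed_point" in config:
        seed_point = Point3D.from_array(config["seed_point"])

    if volume is not None:
        seg_cfg = SegmentationConfig(**config.get("segmentation", {}))
        roi = None
        if "roi" in config:
            roi = ROIBox(tuple(config["roi"]["min"]), tuple(config["roi"]["max"]))
        mask_path = os.path.join(outdir, "mask.nii.gz")
        if not stage_done("segment", ["mask.nii.gz"]):
            mask = segment_vessel(volume, seed_point, roi, seg_cfg)
            write_mask(mask, mask_path)
            record("segment", {"foreground_voxels": mask.count(), "volume_mm3": mask.volume_mm3()}, ["mask.nii.gz"])
        else:
            from .core_io import read_mask

            mask = read_mask(mask_path)
            log.info("segment: resumed")

        cl_cfg = CenterlineConfig(**config.get("centerline", {}))
        tree = extract_tree(skeletonize(mask), cl_cfg, mask=mask, seed=seed_point)
        write_centerline_csv(tree, os.path.join(outdir, "centerline.csv"))
        write_centerline_json(tree, os.path.join(outdir, "centerline.json"))
        record(
            "centerline",
            {name: round(br.length, 2) for name, br in tree.branches.items()},
            ["centerline.csv", "centerline.json"],
        )

        m_cfg = MeasurementConfig(**config.get("measurement", {}))
        meas = measure_all(volume, mask, tree, m_cfg)
        import pandas as pd

        pd.DataFrame([meas.as_dict()]).to_csv(os.path.join(outdir, "measurements.csv"), index=False)
        record(
            "measure",
            {k: (round(v, 3) if v is not None else None) for k, v in meas.as_dict().items()},
            ["measurements.csv"],
        )

    if "cohort" in config:
        cc = CohortConfig(**{**config["cohort"], "seed": config["cohort"].get("seed", seed)})
        df = attach_categoricals(generate_cohort(cc), seed=seed + 1)
        df.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
        record("cohort", {"n": len(df), "n_ph_label": int((df['group'] == 'PH').sum())}, ["cohort.csv"])

        if config.get("stats", True):
            files = _run_stats(df, outdir)
            record("stats", {"outputs": files}, files)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_stats(df, outdir: str) -> list[str]:
    markers = list(MEASUREMENT_COLUMNS)
    out = []
    st.group_comparison_table(df, ["mPAP", "SPAP", "DPAP"] + markers).to_csv(
        os.path.join(outdir, "group_comparison.csv"), index=False
    )
    out.append("group_comparison.csv")
    st.correlation_matrix(df, markers).to_csv(os.path.join(outdir, "correlations.csv"))
    out.append("correlations.csv")
    st.roc_table(df, markers).to_csv(os.path.join(outdir, "roc.csv"), index=False)
    out.append("roc.csv")
    pairs = [(f"D_{a}", f"V_{a}") for a in ("MPA", "RPA", "LPA")] + [
        (f"A_{a}", f"V_{a}") for a in ("MPA", "RPA", "LPA")
    ]
    st.delong_pairwise(df, pairs).to_csv(os.path.join(outdir, "delong.csv"), index=False)
    out.append("delong.csv")
    y = (df["group"] == "PH").astype(int).to_numpy()
    rows = []
    for m in ("V_MPA", "V_RPA"):
        dca = st.decision_curve(df[m].to_numpy(), y)
        for t, nb, nba in zip(dca.thresholds, dca.nb_model, dca.nb_all):
            rows.append({"marker": m, "threshold": t, "net_benefit": nb, "net_benefit_all": nba})
    import pandas as pd

    pd.DataFrame(rows).to_csv(os.path.join(outdir, "dca.csv"), index=False)
    out.append("dca.csv")
    models = {}
    for resp in ("mPAP", "DPAP", "SPAP"):
        model = st.forward_stepwise(df[markers], df[resp], response_name=resp)
        models[resp] = dataclasses.asdict(model)
    with open(os.path.join(outdir, "models.json"), "w") as fh:
        json.dump(models, fh, indent=1)
    out.append("models.json")
    return out
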