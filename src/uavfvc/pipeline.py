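"""End-to-end orchestration: simulate -> indices -> scale -> segment ->
classify -> evaluate -> map3d -> fvc.

Every stage writes its artifacts to the output directory in plain formats
(TIFF rasters, CSV tables/clouds, GeoJSON polygons, JSON reports), so any
stage can be re-run from disk. A single master seed is split into fixed
per-stage streams, which makes an identical config + seed produce a
byte-identical final report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping

from . import forest as rf
from . import indices as vi
from . import mapping as mp
from . import scene as sim
from . import segmentation as seg
from .raster import write_raster

log = logging.getLogger("uavfvc")


_STAGE_OFFSETS = {"scene": 11, "split": 23, "forest": 37}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed below 2**31 (fixed stage offsets)."""
    return int(
        np.random.SeedSequence([master_seed, _STAGE_OFFSETS[stage]]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    scene: sim.SceneConfig = field(default_factory=sim.SceneConfig)
    weights: seg.SegWeights = field(default_factory=seg.SegWeights)
    scale_start: float = 10.0
    scale_step: float = 10.0
    scale_stop: float = 100.0
    use_terrain: bool = True
    index: str = "auto"               # "auto" or one of the nine index names
    forest: rf.ForestConfig = field(default_factory=rf.ForestConfig)
    train_fraction: float = 0.6
    purge: str | float | None = "auto"
    seed: int = 0

    def validate(self) -> None:
        self.scene.validate()
        self.forest.validate()
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.scale_start <= 0 or self.scale_step <= 0 or self.scale_stop < self.scale_start:
            raise ValueError("invalid scale grid")
        if self.index != "auto" and self.index not in vi.INDEX_NAMES:
            raise ValueError(f"index must be 'auto' or one of {vi.INDEX_NAMES}")

    def scales(self) -> np.ndarray:
        return np.arange(self.scale_start, self.scale_stop + 1e-9, self.scale_step)


def config_from_dict(d: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    scene_d = dict(d.get("scene", {}))
    if scene_d:
        cfg.scene = dataclasses.replace(cfg.scene, **scene_d)
    weights_d = dict(d.get("weights", {}))
    if weights_d:
        if "layer_weights" in weights_d and weights_d["layer_weights"] is not None:
            weights_d["layer_weights"] = tuple(weights_d["layer_weights"])
        cfg.weights = dataclasses.replace(cfg.weights, **weights_d)
    forest_d = dict(d.get("forest", {}))
    if forest_d:
        cfg.forest = dataclasses.replace(cfg.forest, **forest_d)
    for key in (
        "scale_start",
        "scale_step",
        "scale_stop",
        "use_terrain",
        "index",
        "train_fraction",
        "purge",
        "seed",
    ):
        if key in d:
            setattr(cfg, key, d[key])
    return cfg


def segment_features(
    result: seg.SegmentationResult,
    vi_raster: vi.VIRaster,
    elevation: np.ndarray,
    slope: np.ndarray,
) -> pd.DataFrame:
    """One row per segment: band mean/std, mean index, mean terrain, area."""
    labels = result.label_raster
    k = len(result.segments)
    out = pd.DataFrame(index=result.segments.index)
    for c, band in enumerate("rgb"):
        out[f"mean_{band}"] = result.segments[f"mean_{c}"]
        out[f"std_{band}"] = result.segments[f"std_{c}"]
    flat = labels.ravel()

    def seg_mean(arr):
        vals = np.asarray(arr, dtype=np.float64).ravel()
        ok = np.isfinite(vals)
        tot = np.bincount(flat[ok], weights=vals[ok], minlength=k)
        cnt = np.bincount(flat[ok], minlength=k)
        return np.divide(tot, cnt, out=np.zeros(k), where=cnt > 0)

    out["vi_mean"] = seg_mean(vi_raster.values)
    out["elev_mean"] = seg_mean(elevation)
    out["slope_mean"] = seg_mean(slope)
    out["area"] = result.segments["n"]
    return out


def majority_truth_labels(result: seg.SegmentationResult, truth_mask: np.ndarray) -> np.ndarray:
    """Per-segment reference class = majority truth class of its pixels."""
    codes = sim.class_codes(truth_mask)
    flat = result.label_raster.ravel()
    k = len(result.segments)
    tallies = np.zeros((k, len(sim.CLASS_NAMES)), dtype=np.int64)
    np.add.at(tallies, (flat, codes.ravel()), 1)
    win = tallies.argmax(axis=1)
    return np.asarray([sim.CLASS_NAMES[c] for c in win])


def stratified_split(labels: np.ndarray, train_fraction: float, seed: int):
    """Per-class shuffled split; classes with one member go entirely to train."""
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sim.CLASS_NAMES:
        members = np.nonzero(labels == cls)[0]
        if members.size == 0:
            continue
        perm = members[rng.permutation(members.size)]
        n_train = max(1, int(round(train_fraction * members.size)))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(np.array(train_idx, dtype=np.int64)), np.sort(
        np.array(test_idx, dtype=np.int64)
    )


def _write_polygons(path: Path, polys: mp.ClassifiedPolygons) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"class": str(cls)},
            "geometry": geom_mapping(poly),
        }
        for poly, cls in zip(polys.polygons, polys.labels)
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def run(config: PipelineConfig, outdir) -> dict:
    """Run the whole chain and return (and write) the final JSON report."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = {
        "weights": dataclasses.asdict(config.weights),
        "scales": config.scales().tolist(),
        "use_terrain": config.use_terrain,
        "index": config.index,
        "forest": dataclasses.asdict(config.forest),
        "train_fraction": config.train_fraction,
        "purge": config.purge,
        "seed": config.seed,
        "scene_seed": stage_seed(config.seed, "scene"),
        "split_seed": stage_seed(config.seed, "split"),
        "forest_seed": stage_seed(config.seed, "forest"),
    }
    for key, value in resolved.items():
        log.info("resolved parameter %s = %r", key, value)

    stage = "simulate"
    try:
        scene_cfg = dataclasses.replace(config.scene, seed=resolved["scene_seed"])
        scene = sim.generate_scene(scene_cfg)
        scene.write(outdir / "scene")
        tr = scene.rgb.transform

        stage = "indices"
        all_vi = vi.compute_all_indices(scene.rgb)
        for name, raster in all_vi.items():
            write_raster(
                outdir / f"index_{name}.tif", raster.values.astype(np.float32), tr
            )

        stage = "select-index"
        if config.index == "auto":
            report_sel, _ = vi.run_index_selection(scene.rgb, scene.truth_mask, sim.CLASS_NAMES)
            chosen = report_sel.chosen
            selection = report_sel.to_dict()
        else:
            chosen = config.index
            selection = {"chosen": chosen, "ranking": [chosen], "eliminated": {},
                         "mean_stds": {}, "note": "index fixed by config"}
        (outdir / "index_selection.json").write_text(json.dumps(selection, indent=2, sort_keys=True))

        stage = "select-scale"
        spectral = [scene.rgb.r, scene.rgb.g, scene.rgb.b]
        terrain = [scene.elevation, scene.slope] if config.use_terrain else None
        profile = seg.lv_roc(spectral, config.weights, config.scales(), terrain)
        profile.to_frame().to_csv(outdir / "scale_profile.csv", index=False)

        stage = "segment"
        layers = spectral + (terrain if terrain else [])
        result = seg.segment(layers, config.weights, profile.optimal_scale)
        write_raster(outdir / "labels.tif", result.label_raster.astype(np.int32), tr)
        result.segments.to_csv(outdir / "segments.csv")

        stage = "classify"
        feats = segment_features(result, all_vi[chosen], scene.elevation, scene.slope)
        truth_labels = majority_truth_labels(result, scene.truth_mask)
        feats_out = feats.copy()
        feats_out["label"] = truth_labels
        feats_out.to_csv(outdir / "features.csv")
        train_idx, test_idx = stratified_split(
            truth_labels, config.train_fraction, resolved["split_seed"]
        )
        forest_cfg = dataclasses.replace(config.forest, seed=resolved["forest_seed"])
        model = rf.train(
            feats.iloc[train_idx],
            truth_labels[train_idx],
            forest_cfg,
            classes=sim.CLASS_NAMES,
        )
        predicted = rf.predict(model, feats)
        pd.DataFrame(
            {"segment": feats.index, "predicted": predicted, "reference": truth_labels}
        ).to_csv(outdir / "predicted.csv", index=False)

        stage = "evaluate"
        cm, acc = rf.evaluate(
            predicted[test_idx], truth_labels[test_idx], classes=sim.CLASS_NAMES
        )
        cm.to_frame().to_csv(outdir / "confusion_matrix.csv")
        (outdir / "accuracy.json").write_text(
            json.dumps(acc.to_dict(), indent=2, sort_keys=True)
        )

        stage = "map3d"
        class_by_segment = dict(zip(feats.index, predicted))
        polys = mp.segments_to_polygons(result, class_by_segment, tr)
        _write_polygons(outdir / "polygons.geojson", polys)
        mapped = mp.map_polygons(polys, scene.cloud)

        stage = "fvc"
        if config.purge is not None:
            mapped = mp.purge_bare_points(mapped, scene.cloud, config.purge)
        fvc_percent = mp.fvc(mapped.vegetation_point_count, mapped.total_points)
        cloud_out = np.column_stack(
            [
                scene.cloud.xyz,
                scene.cloud.rgb.astype(np.float64),
                mapped.vegetation_mask.astype(np.float64),
            ]
        )
        np.savetxt(
            outdir / "cloud_classified.csv",
            cloud_out,
            delimiter=",",
            header="x,y,z,r,g,b,vegetation",
            comments="",
            fmt=["%.4f", "%.4f", "%.4f", "%d", "%d", "%d", "%d"],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "chosen_index": chosen,
        "index_selection": selection,
        "optimal_scale": profile.optimal_scale,
        "scale_profile": {
            "scales": profile.scales.tolist(),
            "lv": profile.lv.tolist(),
            "roc": [None if not np.isfinite(r) else r for r in profile.roc],
        },
        "n_segments": int(result.n_segments),
        "training": {
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
        },
        "confusion_matrix": {
            "classes": list(cm.classes),
            "counts": cm.counts.tolist(),
        },
        "accuracy": acc.to_dict(),
        "mapping": {
            "M": mapped.m_polygons,
            "N": mapped.n_mapped,
            "Q_percent": mapped.q_percent,
            "vegetation_points": mapped.vegetation_point_count,
            "points_purged": mapped.purged_count,
            "total_points": mapped.total_points,
            "fvc_percent": fvc_percent,
        },
        "truth_fvc_percent": scene.truth_fvc,
        "resolved_parameters": resolved,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
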