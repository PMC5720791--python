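"""Batch orchestration: manifests, run configuration, end-to-end clustering.

A run is described by a :class:`RunConfig` (usually a YAML file): a manifest
of ENVI images with day/condition/training labels, preprocessing settings,
tree and pruning parameters, and an output directory.  ``run_clustering``
executes the full workflow — calibrate, smooth, crop, mask, decompose,
prune, assign, quantify — and writes the model (JSON), one label map per
image (ASCII PGM), per-cluster counts (CSV) and a machine-readable run
record echoing every parameter and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import hsi_io, preprocess
from .errors import ParameterError
from .hsi_io import SpectralCube, SpectralMatrix
from .tree import grow_tree

__all__ = [
    "RunConfig",
    "load_config",
    "load_manifest_images",
    "preprocess_cube",
    "concat_matrices",
    "run_clustering",
]

log = logging.getLogger("xhclust")


@dataclass
class RunConfig:
    manifest: str
    output_dir: str = "xhclust_out"
    # preprocessing
    polyorder: int = 5
    half_window: int = 7
    lo_nm: float = 450.0
    hi_nm: float = 790.0
    background_threshold: float = 0.05
    overexposure_threshold: float = 1.0
    # clustering
    k: int = 7
    max_depth: int = 10
    min_leaf: int = 100
    seed: int = 0
    variant: str = "as_printed"
    parallel: bool = True
    kmeans_iters: int = 1000
    # quantification ROI (optional): (row, col) center and diameter in px
    roi_center: tuple[float, float] | None = None
    roi_diameter_px: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration (flat or nested keys)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    flat: dict = {}
    for key, value in doc.items():
        if isinstance(value, dict) and key in ("preprocess", "xhc", "savgol",
                                               "crop", "mask", "roi"):
            prefix = {"savgol": "", "crop": "", "mask": "", "preprocess": "",
                      "xhc": "", "roi": "roi_"}[key]
            for sub, v in value.items():
                flat[f"{prefix}{sub}"] = v
        else:
            flat[key] = value
    if "center" in flat:
        flat["roi_center"] = tuple(flat.pop("center"))
    if "diameter_px" in flat:
        flat["roi_diameter_px"] = flat.pop("diameter_px")
    if "roi_center" in flat and flat["roi_center"] is not None:
        flat["roi_center"] = tuple(flat["roi_center"])
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(flat) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**flat)


def _load_calibration(entry: dict, base: Path) -> hsi_io.CalibrationSet | None:
    if not entry or "white" not in entry:
        return None
    white = hsi_io.read_envi_cube(base / entry["white"])
    dark = hsi_io.read_envi_cube(base / entry["dark"])
    return hsi_io.CalibrationSet(white=white, dark=dark)


def load_manifest_images(manifest_path) -> list[dict]:
    """Load every image listed in a manifest, calibrating when references
    are given (shared or per-image).  Returns records with the cube plus
    ``id``/``day``/``condition``/``training`` metadata."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    shared_cal = _load_calibration(doc.get("calibration", {}), base)

    records = []
    for entry in doc["images"]:
        image_path = base / entry["image"]
        header = base / entry["header"] if "header" in entry else None
        cube = hsi_io.read_envi_cube(image_path, header)
        cal = _load_calibration(entry, base) or shared_cal
        if cal is not None:
            cube = hsi_io.calibrate_reflectance(cube, cal)
        image_id = entry.get("id", image_path.stem)
        cube.meta["image_id"] = image_id
        records.append({
            "id": image_id,
            "cube": cube,
            "day": entry.get("day"),
            "condition": entry.get("condition"),
            "training": bool(entry.get("training", True)),
        })
    if not records:
        raise ParameterError("manifest lists no images")
    return records


def preprocess_cube(cube: SpectralCube, config: RunConfig
                    ) -> tuple[SpectralMatrix, preprocess.PixelMask]:
    """Smooth, crop and mask one reflectance cube; return matrix + mask."""
    params = preprocess.SmoothingParams(config.polyorder, config.half_window)
    smoothed = preprocess.smooth_cube(cube, params)
    cropped = preprocess.crop_bands(smoothed, config.lo_nm, config.hi_nm)
    mask = preprocess.build_mask(cropped, config.background_threshold,
                                 config.overexposure_threshold)
    matrix = hsi_io.cube_to_matrix(cropped, mask)
    return matrix, mask


def concat_matrices(matrices: list[SpectralMatrix]) -> SpectralMatrix:
    """Concatenate signature matrices column-wise, in manifest order."""
    if not matrices:
        raise ParameterError("nothing to concatenate")
    wl = matrices[0].wavelengths
    for m in matrices[1:]:
        if len(m.wavelengths) != len(wl) or not np.allclose(m.wavelengths, wl):
            raise ParameterError("matrices have inconsistent wavelength axes")
    X = np.hstack([m.X for m in matrices])
    index = [t for m in matrices for t in m.pixel_index]
    return SpectralMatrix(X, index, wl.copy())


def run_clustering(config: RunConfig, images: list[dict] | None = None) -> dict:
    """Execute the full workflow described by ``config``.

    ``images`` may carry pre-loaded manifest records (as from
    ``load_manifest_images``); otherwise the manifest is read from disk.
    Returns the model, per-image cluster maps and the counts table, and
    writes all artifacts under ``config.output_dir``.
    """
    from .render import save_label_pgm

    if images is None:
        images = load_manifest_images(config.manifest)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    processed = []
    for rec in images:
        matrix, mask = preprocess_cube(rec["cube"], config)
        processed.append({**rec, "matrix": matrix, "mask": mask})
        log.info("image %s: %d signatures, %d masked", rec["id"],
                 matrix.n_signatures, mask.count())

    training = [p for p in processed if p["training"]]
    if not training:
        raise ParameterError("no image is marked as training")

    if config.parallel:
        model = _cluster.xhc_parallel(
            [p["matrix"] for p in training], k=config.k,
            max_depth=config.max_depth, min_leaf=config.min_leaf,
            seed=config.seed, variant=config.variant,
            kmeans_iters=config.kmeans_iters)
    else:
        merged = concat_matrices([p["matrix"] for p in training])
        tree = grow_tree(merged, max_depth=config.max_depth,
                         min_leaf=config.min_leaf, seed=config.seed,
                         variant=config.variant)
        model = _cluster.prune_to_k(tree, k=config.k, seed=config.seed,
                                    kmeans_iters=config.kmeans_iters,
                                    variant=config.variant)
    _cluster.save_model(model, out / "model.json")

    roi = None
    if config.roi_center is not None and config.roi_diameter_px is not None:
        shape = processed[0]["cube"].spatial_shape
        roi = preprocess.circular_roi_mask(shape, config.roi_center,
                                           config.roi_diameter_px)

    maps = {}
    rows = []
    for p in processed:
        labels = _cluster.assign(p["matrix"], model)
        cmap = hsi_io.matrix_to_map(labels, p["matrix"].pixel_index,
                                    p["cube"].spatial_shape, k=config.k,
                                    image_id=p["id"])
        maps[p["id"]] = cmap
        save_label_pgm(cmap, out / f"labels_{p['id']}.pgm")
        counts = _cluster.quantify_clusters(cmap, roi)
        for cid in range(1, config.k + 1):
            rows.append({"image_id": p["id"], "day": p["day"],
                         "condition": p["condition"], "cluster_id": cid,
                         "pixel_count": counts[cid],
                         "total_roi_pixels": counts["total"]})

    counts_df = pd.DataFrame(rows)
    counts_df.to_csv(out / "counts.csv", index=False)

    record = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "n_images": len(processed),
        "training_images": [p["id"] for p in training],
        "model_file": "model.json",
    }
    (out / "run_record.json").write_text(json.dumps(record, indent=1))
    return {"model": model, "maps": maps, "counts": counts_df,
            "processed": processed}
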