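"""Stage orchestration: simulate -> preprocess -> stitch -> quantify -> classify.

Each stage reads the previous stage's on-disk artifacts from a working
directory, writes its own outputs plus a JSON provenance block (parameters,
seed, input hashes), and logs a stage-tagged line to stderr.  ``run_all``
chains the five stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__, classify, ncquant, phantom, preprocess, stitch
from .config import PipelineConfig

__all__ = [
    "run_simulate",
    "run_preprocess",
    "run_stitch",
    "run_quantify",
    "run_classify",
    "run_all",
]

log = logging.getLogger("musemargin")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(workdir: Path, stage: str, cfg: PipelineConfig, inputs: list[Path]) -> None:
    block = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "input_hashes": {p.name: _sha256(p) for p in inputs if p.exists()},
    }
    (workdir / f"provenance_{stage}.json").write_text(json.dumps(block, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: required input {path} is missing — run the "
            "preceding stage first"
        )
    return path


# ---------------------------------------------------------------------------


def run_simulate(cfg: PipelineConfig, workdir: str | Path) -> Path:
    """Generate a phantom scene, cut it into vignetted noisy tiles, persist."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    regions = phantom.vertical_strip_layout(
        cfg.scene_width_px, cfg.scene_height_px, cfg.phantom_classes
    )
    spec = phantom.PhantomSpec(
        width_px=cfg.scene_width_px,
        height_px=cfg.scene_height_px,
        regions=regions,
        pixel_pitch_um=cfg.pixel_pitch_um,
        seed=cfg.seed,
    )
    scene, truth = phantom.generate_scene(spec)
    shading = phantom.make_shading_field(
        (cfg.tile_h_px, cfg.tile_w_px), cfg.vignette_strength
    )
    tiles, manifest = phantom.render_tiles(
        scene,
        tile_w_px=cfg.tile_w_px,
        tile_h_px=cfg.tile_h_px,
        overlap_x_um=cfg.overlap_x_um,
        overlap_y_um=cfg.overlap_y_um,
        pixel_pitch_um=cfg.pixel_pitch_um,
        shading=shading,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.seed + 1,
    )
    truth.tile_manifest = manifest
    phantom.write_phantom(
        workdir, scene, truth, tiles, manifest, cfg.pixel_pitch_um, cfg.seed
    )
    _provenance(workdir, "simulate", cfg, [])
    _stage_log("simulate", f"wrote {len(tiles)} tiles to {workdir}")
    return workdir


def run_preprocess(cfg: PipelineConfig, workdir: str | Path) -> Path:
    """Estimate S/V shading from the tile stack and correct every tile."""
    workdir = Path(workdir)
    manifest_path = _require(workdir / "manifest.json", "preprocess")
    meta = json.loads(manifest_path.read_text())
    tile_paths = [
        workdir / "tiles" / f"tile_r{t['grid_row']}_c{t['grid_col']}.tif"
        for t in meta["tiles"]
    ]
    images = [tifffile.imread(_require(p, "preprocess")) for p in tile_paths]
    field = preprocess.estimate_shading(images, sigma_frac=cfg.shading_sigma_frac)
    outdir = workdir / "corrected"
    outdir.mkdir(exist_ok=True)
    for p, img in zip(tile_paths, images):
        tifffile.imwrite(outdir / p.name, preprocess.correct_shading(img, field))
    tifffile.imwrite(workdir / "shading_s.tif", field.s.gain.astype(np.float32))
    tifffile.imwrite(workdir / "shading_v.tif", field.v.gain.astype(np.float32))
    (workdir / "shading.json").write_text(
        json.dumps(
            {
                "channels": ["saturation", "value"],
                "normalisation": "spatial mean 1",
                "estimated_from": "per-tile-set median + Gaussian smoothing",
                "sigma_frac": cfg.shading_sigma_frac,
                "n_tiles": len(images),
            },
            indent=2,
        )
    )
    _provenance(workdir, "preprocess", cfg, [manifest_path])
    _stage_log("preprocess", f"corrected {len(images)} tiles")
    return outdir


def run_stitch(cfg: PipelineConfig, workdir: str | Path) -> Path:
    """Register corrected tiles pairwise, solve placement, blend a mosaic."""
    workdir = Path(workdir)
    manifest_path = _require(workdir / "manifest.json", "stitch")
    meta = json.loads(manifest_path.read_text())
    tiles: list[stitch.Tile] = []
    for t in meta["tiles"]:
        p = _require(
            workdir / "corrected" / f"tile_r{t['grid_row']}_c{t['grid_col']}.tif",
            "stitch",
        )
        tiles.append(
            stitch.Tile(
                image=tifffile.imread(p),
                grid_row=t["grid_row"],
                grid_col=t["grid_col"],
                nominal_offset_px=(float(t["x0_px"]), float(t["y0_px"])),
            )
        )
    links = []
    index = {(t.grid_row, t.grid_col): k for k, t in enumerate(tiles)}
    for (r, c), ka in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            kb = index.get((r + dr, c + dc))
            if kb is None:
                continue
            a, b = tiles[ka], tiles[kb]
            nominal = (
                b.nominal_offset_px[0] - a.nominal_offset_px[0],
                b.nominal_offset_px[1] - a.nominal_offset_px[1],
            )
            offset, score, flagged = stitch.pairwise_offset(
                a, b, nominal=nominal, search_radius_px=cfg.search_radius_px
            )
            links.append(
                stitch.PairLink(
                    index_a=ka,
                    index_b=kb,
                    offset_px=offset,
                    nominal_px=nominal,
                    score=score,
                    flagged=flagged,
                )
            )
    placement = stitch.global_placement(
        len(tiles), links, score_threshold=cfg.score_threshold
    )
    mosaic = stitch.blend(tiles, placement)
    tifffile.imwrite(workdir / "mosaic.tif", mosaic)
    report = {
        "offsets_px": placement.offsets_px,
        "dropped_links": placement.dropped_links,
        "links": [
            {
                "a": lk.index_a,
                "b": lk.index_b,
                "offset_px": list(lk.offset_px),
                "nominal_px": list(lk.nominal_px),
                "score": lk.score,
                "flagged": lk.flagged,
            }
            for lk in placement.links
        ],
    }
    (workdir / "placement.json").write_text(json.dumps(report, indent=2))
    _provenance(workdir, "stitch", cfg, [manifest_path])
    _stage_log(
        "stitch",
        f"placed {len(tiles)} tiles ({placement.dropped_links} links dropped)",
    )
    return workdir / "mosaic.tif"


def run_quantify(cfg: PipelineConfig, workdir: str | Path) -> Path:
    """Segment nuclei on the mosaic red channel and score patches.

    Histogram equalization (written as ``mosaic_enhanced.tif``) serves the
    visual-review output only: the 70%-of-the-top-1% threshold rule presumes
    the raw bright-tail histogram, so segmentation runs on the
    pre-equalization mosaic.
    """
    workdir = Path(workdir)
    mosaic_path = _require(workdir / "mosaic.tif", "quantify")
    mosaic = tifffile.imread(mosaic_path)
    enhanced = preprocess.equalize_rg(mosaic, floor=cfg.equalize_floor)
    tifffile.imwrite(workdir / "mosaic_enhanced.tif", enhanced)
    red = mosaic[:, :, 0]
    nmask = ncquant.segment_nuclei(
        red,
        edge_k=cfg.edge_k,
        closing_radius=cfg.closing_radius,
        threshold_fraction=cfg.threshold_fraction,
        top_percent=cfg.top_percent,
    )
    iio.imwrite(
        workdir / "nuclear_mask.png", nmask.mask.astype(np.uint8) * 255
    )
    grid = ncquant.nc_small_patches(nmask, patch_px=cfg.patch_px)
    table = ncquant.merge_large_patches(
        grid, block=cfg.large_block, zero_limit=cfg.zero_limit
    )
    label_path = workdir / "truth_label_map.png"
    if label_path.exists():
        label_map = np.asarray(iio.imread(label_path))
        mosaic_h, mosaic_w = red.shape
        table = ncquant.label_patches(
            table,
            label_map[:mosaic_h, :mosaic_w],
            phantom.LABEL_CODES,
            patch_px=cfg.patch_px,
            block=cfg.large_block,
        )
    rows, cols = grid.shape
    small = pd.DataFrame(
        {
            "row": np.repeat(np.arange(rows), cols),
            "col": np.tile(np.arange(cols), rows),
            "x0": np.tile(np.arange(cols) * cfg.patch_px, rows),
            "y0": np.repeat(np.arange(rows) * cfg.patch_px, cols),
            "nc": grid.nc.ravel(),
            "n_white": grid.whites.ravel(),
            "n_px": grid.counts.ravel(),
            "partial": grid.partial.ravel(),
        }
    )
    small.to_csv(workdir / "small_patches.csv", index=False)
    table.to_csv(workdir / "large_patches.csv", index=False)
    (workdir / "quantify.json").write_text(
        json.dumps(
            {
                "intensity_threshold": nmask.intensity_threshold,
                "edge_threshold": nmask.edge_threshold,
                "params": nmask.params,
                "patch_px": cfg.patch_px,
                "large_block": cfg.large_block,
                "zero_limit": cfg.zero_limit,
                "n_large_patches": int(len(table)),
                "n_kept": int(table["kept"].sum()),
            },
            indent=2,
        )
    )
    _provenance(workdir, "quantify", cfg, [mosaic_path])
    _stage_log(
        "quantify",
        f"{len(table)} large patches, {int(table['kept'].sum())} kept",
    )
    return workdir / "large_patches.csv"


def run_classify(
    cfg: PipelineConfig,
    workdir: str | Path,
    tables: list[pd.DataFrame] | None = None,
) -> dict:
    """ROC/Youden on kept labelled patches; writes roc.csv + summary.json.

    ``tables`` may supply large-patch tables from several samples (each
    gains a ``sample_id``); by default the single table in ``workdir`` is
    used.
    """
    workdir = Path(workdir)
    if tables is None:
        path = _require(workdir / "large_patches.csv", "classify")
        tables = [pd.read_csv(path)]
    frames = []
    for i, t in enumerate(tables):
        t = t.copy()
        if "sample_id" not in t.columns:
            t["sample_id"] = i
        frames.append(t)
    df = pd.concat(frames, ignore_index=True)
    if "tissue_label" not in df.columns:
        raise ValueError("classification needs labelled patches")
    df = df[df["kept"] & (df["tissue_label"] != "unknown")]
    invasive = df["tissue_label"].isin(phantom.INVASIVE_CLASSES)
    roc = classify.roc_curve(df["nc"].to_numpy(), invasive.to_numpy())
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(workdir / "roc.csv", index=False)
    comparison = None
    if df["sample_id"].nunique() > 1:
        counts = df.groupby("tissue_label")["sample_id"].nunique()
        ok = counts[counts >= 2].index
        sub = df[df["tissue_label"].isin(ok)]
        if sub["tissue_label"].nunique() >= 2:
            comparison = classify.cluster_compare(
                sub["nc"], sub["tissue_label"], sub["sample_id"],
                seed=cfg.seed,
            )
            comparison.to_csv(workdir / "group_comparison.csv", index=False)
    summary = {
        "n_patches": int(len(df)),
        "n_invasive": int(invasive.sum()),
        "n_normal": int((~invasive).sum()),
        "auc": roc.auc,
        "youden_threshold": roc.youden_threshold,
        "j": roc.j,
        "sensitivity_at_cutoff": roc.sens_at_cutoff,
        "specificity_at_cutoff": roc.spec_at_cutoff,
        "mean_nc_by_class": {
            k: float(v) for k, v in df.groupby("tissue_label")["nc"].mean().items()
        },
        "patch_count_by_class": {
            k: int(v) for k, v in df["tissue_label"].value_counts().items()
        },
    }
    (workdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _provenance(workdir, "classify", cfg, [])
    _stage_log("classify", f"AUC {roc.auc:.4f} over {len(df)} patches")
    return summary


def run_all(cfg: PipelineConfig, workdir: str | Path) -> dict:
    """Chain simulate -> preprocess -> stitch -> quantify -> classify."""
    run_simulate(cfg, workdir)
    run_preprocess(cfg, workdir)
    run_stitch(cfg, workdir)
    run_quantify(cfg, workdir)
    return run_classify(cfg, workdir)
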