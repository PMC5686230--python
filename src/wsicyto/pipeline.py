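"""End-to-end whole-slide analysis: registration, de-convolution, tiled
segmentation and cytometry, stitching, and summaries.

``run_panel`` executes the full pipeline on a fluorescence channel set
plus an RGB brightfield image and returns stitched single-cell and gland
tables, summary tables and a run manifest.  ``validate_against_truth``
scores any cell table against the synthetic generator's ground truth by
greedy nearest-centroid matching.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from . import __version__
from .cytometry import (PanelConfig, call_positives, classify_immune,
                        classify_glands_and_epithelial, measure_cells,
                        summarize_panel)
from .registration import (OUTPUT_RESOLUTION, WORK_RES_MOVING,
                           WORK_RES_REFERENCE, register_modalities,
                           warp_to_reference)
from .segmentation import (SegmentationParams, image_histogram, marker_mask,
                           otsu_level, segment_glands, segment_nuclei)
from .stains import StainMatrix, deconvolve
from .synthetic import GroundTruthSlide
from .wsi_io import (ChannelImage, MultiplexSlide, plan_tiles, stitch_cells,
                     extract_tile, write_cell_table, write_rgb_tiff)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Whole-slide run parameters.

    Tile geometry and resolutions default to the standard whole-slide mIHC
    workflow values (2048 px cores padded to 10240 px, 0.64 µm/px output);
    the context may be reduced for small slides.
    """

    core_size: int = 2048
    context_size: int = 10240
    output_resolution: float = OUTPUT_RESOLUTION
    work_res_reference: float = WORK_RES_REFERENCE
    work_res_moving: float = WORK_RES_MOVING
    deconv_downscale: int = 1   # brightfield input already at analysis scale
    nuclear_channel: str = "dapi"
    stain_matrix: StainMatrix | None = None
    segmentation: SegmentationParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stain_matrix is None:
            m = StainMatrix.hdab_default()
            m.names = ("haematoxylin", "gland_stain", "accent_stain")
            self.stain_matrix = m
        if self.segmentation is None:
            self.segmentation = SegmentationParams()


@dataclass
class PanelResult:
    cells: pd.DataFrame
    glands: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    manifest: dict
    transform_json: str


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Deterministic 8-bit scaling of a nonnegative float raster."""
    top = float(np.percentile(arr, 99.9))
    if top <= 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip(np.rint(arr * (255.0 / top)), 0, 255).astype(np.uint8)


def run_panel(fl: MultiplexSlide, bf_rgb: np.ndarray, bf_resolution: float,
              panel: PanelConfig, config: RunConfig | None = None,
              output_dir: str | Path | None = None) -> PanelResult:
    """Run the full tissue-cytometry pipeline on one slide.

    Stages: brightfield colour de-convolution; haematoxylin/nuclear
    registration onto a common grid at ``output_resolution``; tiled gland
    and nucleus segmentation with marker masks; per-cell measurement;
    core-rule stitching; positivity calling and scheme classification;
    summary tables.  Deterministic for fixed inputs and seed.
    """
    cfg = config or RunConfig()
    manifest: dict = {
        "software_version": __version__,
        "panel_scheme": panel.scheme,
        "parameters": {
            "core_size": cfg.core_size, "context_size": cfg.context_size,
            "output_resolution": cfg.output_resolution,
            "work_res_reference": cfg.work_res_reference,
            "work_res_moving": cfg.work_res_moving,
            "deconv_downscale": cfg.deconv_downscale,
            "seed": cfg.seed,
            "sd_multipliers": dict(panel.sd_multipliers),
            "basal_overlap_min": panel.basal_overlap_min,
            "segmentation": asdict(cfg.segmentation),
            "stain_matrix": cfg.stain_matrix.to_dict(),
        },
        "stages": {},
        "counts": {},
    }
    t0 = time.time()

    # ---- channel validation ------------------------------------------------
    needed = [cfg.nuclear_channel] + [panel.marker_channels[m]
                                      for m in panel.markers]
    missing = [c for c in needed if c not in fl]
    if missing:
        raise PipelineError("input", f"missing fluorescence channels {missing} "
                                     f"for {panel.scheme} panel")

    # ---- colour de-convolution --------------------------------------------
    t = time.time()
    conc = deconvolve(bf_rgb, cfg.stain_matrix, downscale=cfg.deconv_downscale)
    conc_res = bf_resolution * cfg.deconv_downscale
    haem_name, gland_stain_name = cfg.stain_matrix.names[:2]
    haem8 = ChannelImage(_to_uint8(conc[haem_name]), conc_res, haem_name)
    manifest["stages"]["deconvolution"] = {
        "seconds": round(time.time() - t, 2),
        "clipped_fraction": conc.clipped_fraction,
    }

    # ---- registration ------------------------------------------------------
    t = time.time()
    try:
        reg = register_modalities(
            haem8, fl[cfg.nuclear_channel],
            work_res_reference=cfg.work_res_reference,
            work_res_moving=cfg.work_res_moving,
            output_resolution=cfg.output_resolution, seed=cfg.seed)
    except Exception as exc:
        raise PipelineError("registration", str(exc)) from exc
    out_res = cfg.output_resolution
    out_shape = (int(np.ceil(bf_rgb.shape[0] * bf_resolution / out_res)),
                 int(np.ceil(bf_rgb.shape[1] * bf_resolution / out_res)))
    manifest["stages"]["registration"] = {
        "seconds": round(time.time() - t, 2),
        "n_matches": reg.n_matches, "n_inliers": reg.n_inliers,
        "rms_residual_px": round(reg.rms_residual_px, 3),
    }

    # ---- resample onto the common grid ------------------------------------
    t = time.time()
    registered: dict[str, np.ndarray] = {}
    for name in dict.fromkeys(needed):
        registered[name] = warp_to_reference(fl[name], reg.transform,
                                             out_shape).pixels
    if panel.scheme == "immune":
        # resample the gland-chromogen concentration map onto the common
        # grid (pixel-centre-at-i*resolution convention)
        factor = out_res / conc_res
        gland_conc = ndi.affine_transform(
            conc[gland_stain_name].astype(np.float32),
            np.diag([factor, factor]), output_shape=out_shape, order=1,
            mode="constant", cval=0.0)
        gland_channel = _to_uint8(gland_conc)
        gland_mode = "global"
    else:
        gland_channel = registered[panel.marker_channels["pan_epi"]]
        gland_mode = "adaptive"
    manifest["stages"]["resampling"] = {"seconds": round(time.time() - t, 2),
                                        "grid_shape": list(out_shape)}

    # ---- whole-slide threshold levels -------------------------------------
    mask_channel_name = panel.marker_channels[panel.mask_marker]
    mask_level = otsu_level(image_histogram(registered[mask_channel_name]))
    gland_level = otsu_level(image_histogram(gland_channel))
    seg = SegmentationParams(**{**asdict(cfg.segmentation),
                                "gland_threshold_mode": gland_mode})

    # ---- tiled segmentation and measurement -------------------------------
    t = time.time()
    tiles = plan_tiles(out_shape, cfg.core_size, cfg.context_size)
    per_tile_cells: list[pd.DataFrame] = []
    per_tile_glands: list[pd.DataFrame] = []
    marker_order = list(panel.markers)
    for tile in tiles:
        dapi_ctx = extract_tile(registered[cfg.nuclear_channel], tile)
        gland_ctx = extract_tile(gland_channel, tile)
        glands_mask = segment_glands(
            gland_ctx, seg,
            level=None if gland_mode == "adaptive" else gland_level.level)
        nuclei_mask = segment_nuclei(dapi_ctx, seg)
        mask_ctx = extract_tile(registered[mask_channel_name], tile)
        mask = marker_mask(mask_ctx, level=mask_level.level)
        channels_ctx = {m: extract_tile(registered[panel.marker_channels[m]],
                                        tile)
                        for m in marker_order}
        cells = measure_cells(nuclei_mask, channels_ctx, glands=glands_mask,
                              masks={panel.mask_marker: mask},
                              resolution=out_res)
        # per-tile gland bookkeeping (context windows hold whole glands)
        gids = np.arange(1, int(glands_mask.max()) + 1)
        if len(gids):
            g_area = ndi.sum_labels(np.ones_like(glands_mask, float),
                                    glands_mask, gids)
            g_cent = np.asarray(ndi.center_of_mass(
                np.ones_like(glands_mask, float), glands_mask, gids))
            gdf = pd.DataFrame({
                "local_gland_id": gids,
                "centroid_row_px": g_cent[:, 0],
                "centroid_col_px": g_cent[:, 1],
                "area_px": g_area,
            })
            cent_row = dict(zip(gids, g_cent[:, 0] + tile.context_origin[0]))
            cent_col = dict(zip(gids, g_cent[:, 1] + tile.context_origin[1]))
        else:
            gdf = pd.DataFrame(columns=["local_gland_id", "centroid_row_px",
                                        "centroid_col_px", "area_px"])
            cent_row, cent_col = {}, {}
        if panel.scheme == "epithelial":
            g_class, cells = classify_glands_and_epithelial(cells, panel)
            gdf = gdf.merge(g_class, left_on="local_gland_id",
                            right_on="gland_id", how="left",
                            suffixes=("", "_cls")).drop(columns=["gland_id"])
            gdf["malignant"] = gdf["malignant"].isna() | gdf["malignant"].eq(True)
            gdf["n_basal_cells"] = pd.to_numeric(
                gdf["n_basal_cells"], errors="coerce").fillna(0).astype(int)
        cells["gland_centroid_row_px"] = cells["gland_id"].map(cent_row)
        cells["gland_centroid_col_px"] = cells["gland_id"].map(cent_col)
        per_tile_cells.append(cells)
        per_tile_glands.append(gdf)
    manifest["stages"]["tiles"] = {"seconds": round(time.time() - t, 2),
                                   "n_tiles": len(tiles)}

    # ---- stitching ---------------------------------------------------------
    t = time.time()
    cells = stitch_cells(per_tile_cells, tiles)
    glands = stitch_cells(per_tile_glands, tiles)
    if len(glands):
        glands = glands.rename(columns={"cell_id": "gland_id"}) \
                       .drop(columns=["local_gland_id"])
    else:
        glands = pd.DataFrame(columns=["gland_id", "centroid_row_px",
                                       "centroid_col_px", "area_px",
                                       "malignant", "n_basal_cells"])
    # remap per-tile gland references to stitched gland ids
    if len(cells):
        cells["gland_id"] = _remap_gland_ids(cells, glands)
        cells["centroid_x_um"] = cells["centroid_col_px"] * out_res
        cells["centroid_y_um"] = cells["centroid_row_px"] * out_res
    manifest["stages"]["stitching"] = {"seconds": round(time.time() - t, 2)}
    manifest["counts"]["cells"] = int(len(cells))
    manifest["counts"]["glands"] = int(len(glands))

    # ---- positivity and classification ------------------------------------
    if len(cells):
        cells = call_positives(cells, marker_order, panel.sd_multipliers)
        if panel.scheme == "immune":
            cells = classify_immune(cells, panel)
    summaries = summarize_panel(cells, panel.scheme) if len(cells) else \
        summarize_panel(pd.DataFrame(columns=["class_label"]), panel.scheme)
    manifest["counts"]["class_distribution"] = {
        str(r.class_label): int(r.n_cells)
        for r in summaries["class_distribution"].itertuples()}
    manifest["total_seconds"] = round(time.time() - t0, 2)

    transform_json = reg.transform.to_json()
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        write_cell_table(output_dir / "cells.csv", cells)
        write_cell_table(output_dir / "glands.csv", glands)
        for name, table in summaries.items():
            table.to_csv(output_dir / f"summary_{name}.csv", index=False)
        (output_dir / "transform.json").write_text(transform_json)
        (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        write_rgb_tiff(output_dir / "class_overlay.tif",
                       class_overlay(cells, out_shape, panel.scheme),
                       resolution=4 * out_res)
    return PanelResult(cells=cells, glands=glands, summaries=summaries,
                       manifest=manifest, transform_json=transform_json)


# fixed class colours for the overlay visualization (RGB)
_CLASS_COLOURS = {
    "epithelial_treg": (220, 40, 40), "stromal_treg": (150, 20, 20),
    "epithelial_th": (250, 160, 30), "stromal_th": (190, 120, 20),
    "epithelial_te": (240, 240, 60), "stromal_te": (180, 180, 40),
    "epithelial_leukocyte_other": (200, 80, 200),
    "stromal_leukocyte_other": (140, 50, 140),
    "epithelial_cell": (60, 180, 80), "other": (120, 120, 120),
    "cancer": (220, 40, 40), "benign_luminal": (60, 180, 80),
    "basal": (60, 100, 230), "stromal": (120, 120, 120),
}


def class_overlay(cells: pd.DataFrame, slide_shape: tuple[int, int],
                  scheme: str, downscale: int = 4,
                  dot_radius: int = 2) -> np.ndarray:
    """Class-visualization raster: cells painted at their centroids.

    A compact whole-slide overview (``downscale``:1) with one coloured dot
    per classified cell; colours are fixed per class label.
    """
    h = max(slide_shape[0] // downscale, 1)
    w = max(slide_shape[1] // downscale, 1)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    if len(cells) == 0 or "class_label" not in cells:
        return rgb
    yy, xx = np.mgrid[-dot_radius:dot_radius + 1, -dot_radius:dot_radius + 1]
    disk = (yy ** 2 + xx ** 2) <= dot_radius ** 2
    dy, dx = yy[disk], xx[disk]
    rows = (cells["centroid_row_px"].to_numpy() / downscale).astype(int)
    cols = (cells["centroid_col_px"].to_numpy() / downscale).astype(int)
    for label, colour in _CLASS_COLOURS.items():
        sel = (cells["class_label"] == label).to_numpy()
        if not sel.any():
            continue
        r = (rows[sel][:, None] + dy[None, :]).clip(0, h - 1).ravel()
        c = (cols[sel][:, None] + dx[None, :]).clip(0, w - 1).ravel()
        rgb[r, c] = colour
    return rgb


def _remap_gland_ids(cells: pd.DataFrame, glands: pd.DataFrame) -> np.ndarray:
    """Match each cell's tile-local gland to its stitched gland id via the
    gland centroid (identical across tiles because contexts hold whole
    glands)."""
    out = np.zeros(len(cells), dtype=int)
    has = cells["gland_id"].to_numpy() > 0
    if not has.any() or len(glands) == 0:
        return out
    tree = cKDTree(glands[["centroid_row_px", "centroid_col_px"]].to_numpy())
    pts = cells.loc[has, ["gland_centroid_row_px",
                          "gland_centroid_col_px"]].to_numpy(float)
    dist, idx = tree.query(pts)
    gid = glands["gland_id"].to_numpy()[idx]
    gid[dist > 25.0] = 0  # no consistent stitched gland found
    out[has] = gid
    return out


# ---------------------------------------------------------------------------
# validation against synthetic ground truth
# ---------------------------------------------------------------------------

# predicted immune labels -> generator class vocabulary
_IMMUNE_TO_TRUTH = {
    "epithelial_treg": "treg", "stromal_treg": "treg",
    "epithelial_th": "th", "stromal_th": "th",
    "epithelial_te": "te", "stromal_te": "te",
    "epithelial_leukocyte_other": "leukocyte_other",
    "stromal_leukocyte_other": "leukocyte_other",
    "epithelial_cell": "epithelial", "other": "stromal",
}


@dataclass
class ValidationResult:
    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    confusion: pd.DataFrame
    class_agreement: float
    compartment_agreement: float
    proportion_errors: pd.DataFrame
    matched_pairs: pd.DataFrame = field(repr=False, default=None)


def validate_against_truth(cells: pd.DataFrame, truth: GroundTruthSlide,
                           match_radius_um: float = 8.0) -> ValidationResult:
    """Score a cell table against planted ground truth.

    One-to-one greedy nearest-centroid matching within ``match_radius_um``
    (reference frame); unmatched truth cells are misses, unmatched
    detections false positives.  Class labels are mapped onto the
    generator's vocabulary before comparison.  Deterministic and invariant
    to input row order.
    """
    truth_cells = truth.cells_in_reference_frame()
    t_xy = truth_cells[["x_ref_um", "y_ref_um"]].to_numpy(float)
    d_xy = cells[["centroid_x_um", "centroid_y_um"]].to_numpy(float) \
        if len(cells) else np.empty((0, 2))

    pairs: list[tuple[float, int, int]] = []
    if len(d_xy) and len(t_xy):
        tree = cKDTree(t_xy)
        cand = tree.query_ball_point(d_xy, r=match_radius_um)
        for di, tis in enumerate(cand):
            for ti in tis:
                d = float(np.hypot(*(d_xy[di] - t_xy[ti])))
                pairs.append((d, ti, di))
        # deterministic order: distance, then truth/detection coordinates
        pairs.sort(key=lambda p: (p[0], tuple(t_xy[p[1]]), tuple(d_xy[p[2]])))
    used_t: set[int] = set()
    used_d: set[int] = set()
    matches: list[tuple[int, int]] = []
    for d, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append((ti, di))

    n_truth, n_det, n_match = len(t_xy), len(d_xy), len(matches)
    recall = n_match / n_truth if n_truth else 0.0
    precision = n_match / n_det if n_det else 0.0

    scheme = truth.config.scheme
    if n_match:
        ti_idx = [m[0] for m in matches]
        di_idx = [m[1] for m in matches]
        true_lab = truth_cells["true_class"].to_numpy()[ti_idx]
        if "class_label" in cells:
            pred_raw = cells["class_label"].to_numpy()[di_idx]
            pred_lab = np.array([_IMMUNE_TO_TRUTH.get(p, p) for p in pred_raw]) \
                if scheme == "immune" else pred_raw
        else:
            pred_lab = np.full(n_match, "unclassified")
        confusion = pd.crosstab(pd.Series(true_lab, name="truth"),
                                pd.Series(pred_lab, name="predicted"))
        agreement = float(np.mean(true_lab == pred_lab))
        true_comp = truth_cells["in_gland"].to_numpy()[ti_idx]
        if "compartment" in cells:
            pred_comp = cells["compartment"].to_numpy()[di_idx] == "epithelial"
        elif "gland_id" in cells:
            pred_comp = cells["gland_id"].to_numpy()[di_idx] > 0
        else:
            pred_comp = np.zeros(n_match, dtype=bool)
        comp_agreement = float(np.mean(true_comp == pred_comp))
        matched = pd.DataFrame({"truth_index": ti_idx, "det_index": di_idx,
                                "true_class": true_lab, "pred_class": pred_lab})
    else:
        confusion = pd.DataFrame()
        agreement = 0.0
        comp_agreement = 0.0
        matched = pd.DataFrame(columns=["truth_index", "det_index",
                                        "true_class", "pred_class"])

    planted = truth.config.class_proportions
    rows = []
    for cls, p in planted.items():
        truth_pct = 100.0 * float((truth_cells["true_class"] == cls).mean()) \
            if n_truth else 0.0
        if len(cells) and "class_label" in cells:
            if scheme == "immune":
                pred = cells["class_label"].map(
                    lambda x: _IMMUNE_TO_TRUTH.get(x, x))
            else:
                pred = cells["class_label"]
            det_pct = 100.0 * float((pred == cls).mean())
        else:
            det_pct = 0.0
        rows.append({"class": cls, "planted_pct": 100.0 * p,
                     "truth_pct": truth_pct, "detected_pct": det_pct,
                     "abs_error_pp": abs(det_pct - 100.0 * p)})
    prop = pd.DataFrame(rows)

    return ValidationResult(n_truth=n_truth, n_detected=n_det,
                            n_matched=n_match, recall=recall,
                            precision=precision, confusion=confusion,
                            class_agreement=agreement,
                            compartment_agreement=comp_agreement,
                            proportion_errors=prop, matched_pairs=matched)


def immune_proportion_recovery(cells: pd.DataFrame,
                               truth: GroundTruthSlide) -> pd.DataFrame:
    """Recovered vs planted immune-population proportions.

    Reports leukocyte / epithelial / stromal percentages of all cells and
    T-subset percentages among leukocytes, with planted reference values
    from the generator configuration.
    """
    planted = truth.config.class_proportions
    leuk_classes = ("treg", "th", "te", "leukocyte_other")
    planted_leuk = sum(planted.get(c, 0.0) for c in leuk_classes)
    pred = cells["class_label"].map(lambda x: _IMMUNE_TO_TRUTH.get(x, x))
    n = len(cells)
    n_leuk = int(pred.isin(leuk_classes).sum())
    rows = [
        ("leukocyte_pct_of_cells", 100.0 * n_leuk / n if n else 0.0,
         100.0 * planted_leuk),
        ("epithelial_pct_of_cells",
         100.0 * float((pred == "epithelial").mean()) if n else 0.0,
         100.0 * planted.get("epithelial", 0.0)),
        ("stromal_pct_of_cells",
         100.0 * float((pred == "stromal").mean()) if n else 0.0,
         100.0 * planted.get("stromal", 0.0)),
    ]
    for t in ("treg", "th", "te"):
        rows.append((f"{t}_pct_of_leukocytes",
                     100.0 * int((pred == t).sum()) / n_leuk if n_leuk else 0.0,
                     100.0 * planted.get(t, 0.0) / planted_leuk))
    df = pd.DataFrame(rows, columns=["quantity", "recovered", "planted"])
    df["abs_error_pp"] = (df.recovered - df.planted).abs()
    return df


def epithelial_recovery_metrics(result: PanelResult, truth: GroundTruthSlide,
                                gland_match_radius_um: float = 60.0) -> dict:
    """Gland-malignancy accuracy and within-gland cell-class agreement.

    Detected glands are matched to planted glands by nearest centroid in
    the reference frame; accuracy is the fraction of matched glands whose
    malignant call equals the planted flag.  Cell agreement is computed,
    over truth-matched cells inside correctly-classified glands, between
    predicted and planted cell classes.
    """
    cfg = truth.config
    t_centers_um = truth.transform.apply_um(np.column_stack([
        truth.glands.x_px * cfg.fl_resolution,
        truth.glands.y_px * cfg.fl_resolution]))
    det = result.glands
    out_res = OUTPUT_RESOLUTION
    if len(det) == 0 or len(t_centers_um) == 0:
        return {"gland_accuracy": 0.0, "n_glands_matched": 0,
                "cell_agreement_in_correct_glands": 0.0}
    d_centers_um = np.column_stack([det.centroid_col_px * out_res,
                                    det.centroid_row_px * out_res])
    tree = cKDTree(d_centers_um)
    dist, idx = tree.query(t_centers_um)
    ok = dist <= gland_match_radius_um
    truth_flag = truth.glands.malignant.to_numpy(bool)
    det_flag = det.malignant.to_numpy(bool)[idx]
    correct = ok & (truth_flag == det_flag)
    accuracy = float(correct.sum() / len(truth_flag))

    # cell agreement within correctly classified glands
    val = validate_against_truth(result.cells, truth)
    matched = val.matched_pairs
    truth_cells = truth.cells
    correct_gland_ids = set(truth.glands.gland_id.to_numpy()[correct])
    in_correct = truth_cells["gland_id"].to_numpy()[
        matched.truth_index.to_numpy()]
    sel = np.array([g in correct_gland_ids for g in in_correct])
    if sel.any():
        agree = float(np.mean(matched.true_class.to_numpy()[sel]
                              == matched.pred_class.to_numpy()[sel]))
    else:
        agree = 0.0
    return {"gland_accuracy": accuracy,
            "n_glands_matched": int(ok.sum()),
            "n_glands_truth": int(len(truth_flag)),
            "cell_agreement_in_correct_glands": agree,
            "validation": val}
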