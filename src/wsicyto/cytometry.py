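"""Per-cell marker quantification and rule-based classification.

Marker intensity is the mean 8-bit value over each segmented nucleus,
normalized to 0-1 by dividing by 255.  A cell is positive for a marker
when its normalized intensity is strictly above ``mean + k * SD`` of all
cells (k = 1 by default, k = 3 for the proliferation marker Ki67, which
is rare enough that a 1-SD cut would admit false positives).

Two hierarchical schemes are implemented:

* immune — CD45-mask overlap splits cells into leukocytes and the rest;
  leukocytes are compartmentalized by gland membership and subtyped as
  T regulatory (CD4+FoxP3+CD8-), T helper (CD4+FoxP3-CD8-) or T effector
  (CD8+CD4-FoxP3-); CD45- cells inside glands are epithelial cells, the
  rest are other (stromal) cells.
* epithelial — a gland is malignant iff it contains no basal cell
  (nucleus with >= 10 % area overlap with the CK5+p63 mask); nuclei in
  malignant glands are cancer cells, nuclei in benign glands are basal
  or benign luminal, nuclei outside glands are stromal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .wsi_io import ChannelImage

IMMUNE_REQUIRED = ("cd45", "cd4", "cd8", "foxp3", "ki67", "pan_epi")
EPITHELIAL_REQUIRED = ("pan_epi", "ck5p63", "amacr", "ar", "ck8", "ck18")

IMMUNE_LABELS = (
    "epithelial_treg", "epithelial_th", "epithelial_te",
    "epithelial_leukocyte_other",
    "stromal_treg", "stromal_th", "stromal_te", "stromal_leukocyte_other",
    "epithelial_cell", "other",
)
EPITHELIAL_LABELS = ("cancer", "benign_luminal", "basal", "stromal")


class CytometryError(ValueError):
    pass


@dataclass
class PanelConfig:
    """Marker panel and classification scheme configuration.

    ``marker_channels`` maps canonical marker names to channel names in the
    registered slide.  ``sd_multipliers`` holds per-marker positivity k
    (default 1; Ki67 defaults to 3).  ``basal_overlap_min`` is the minimum
    nucleus-mask area-overlap fraction used both for CK5+p63 (basal) and
    CD45 (leukocyte) mask calls.
    """

    scheme: str = "immune"
    marker_channels: dict[str, str] = field(default_factory=dict)
    sd_multipliers: dict[str, float] = field(default_factory=dict)
    basal_overlap_min: float = 0.10

    def __post_init__(self) -> None:
        if self.scheme not in ("immune", "epithelial"):
            raise CytometryError(f"unknown scheme {self.scheme!r}")
        required = IMMUNE_REQUIRED if self.scheme == "immune" else EPITHELIAL_REQUIRED
        if not self.marker_channels:
            self.marker_channels = {m: m for m in required}
        missing = [m for m in required if m not in self.marker_channels]
        if missing:
            raise CytometryError(
                f"{self.scheme} panel requires markers {missing}")
        defaults = {"ki67": 3.0}
        for marker in self.marker_channels:
            self.sd_multipliers.setdefault(marker, defaults.get(marker, 1.0))

    @property
    def markers(self) -> list[str]:
        return list(self.marker_channels)

    @property
    def mask_marker(self) -> str:
        """The marker whose Otsu mask drives classification."""
        return "cd45" if self.scheme == "immune" else "ck5p63"


def measure_cells(nuclei: np.ndarray,
                  channels: dict[str, np.ndarray | ChannelImage],
                  glands: np.ndarray | None = None,
                  masks: dict[str, np.ndarray] | None = None,
                  resolution: float = 1.0) -> pd.DataFrame:
    """Measure per-nucleus marker intensities, geometry and memberships.

    Per labelled nucleus: mean raw intensity (0-255) and normalized
    intensity (raw / 255) for every channel, equivalent-circle mean radius,
    centroid (px, and µm via ``resolution``), the id of the containing
    gland (0 = stroma; centroid rule) and, for each binary mask given, the
    fraction of the nucleus area overlapping the mask.
    """
    nuclei = np.asarray(nuclei)
    ids = np.arange(1, int(nuclei.max()) + 1)
    if len(ids) == 0:
        cols = (["label", "centroid_row_px", "centroid_col_px", "area_px",
                 "mean_radius_px", "gland_id"]
                + [f"{m}_raw" for m in (channels or {})]
                + [f"{m}_norm" for m in (channels or {})]
                + [f"{m}_overlap" for m in (masks or {})])
        return pd.DataFrame(columns=cols)

    areas = ndi.sum_labels(np.ones_like(nuclei, dtype=np.float64), nuclei, ids)
    centroids = np.asarray(ndi.center_of_mass(
        np.ones_like(nuclei, dtype=np.float64), nuclei, ids))
    df = pd.DataFrame({
        "label": ids,
        "centroid_row_px": centroids[:, 0],
        "centroid_col_px": centroids[:, 1],
        "area_px": areas,
        "mean_radius_px": np.sqrt(areas / np.pi),
    })

    if glands is not None:
        glands = np.asarray(glands)
        if glands.shape != nuclei.shape:
            raise CytometryError(
                f"gland mask {glands.shape} does not match nuclei {nuclei.shape}")
        rr = np.clip(np.rint(centroids[:, 0]).astype(int), 0, glands.shape[0] - 1)
        cc = np.clip(np.rint(centroids[:, 1]).astype(int), 0, glands.shape[1] - 1)
        df["gland_id"] = glands[rr, cc]
    else:
        df["gland_id"] = 0

    for name, channel in (channels or {}).items():
        px = channel.pixels if isinstance(channel, ChannelImage) else channel
        px = np.asarray(px)
        if px.shape != nuclei.shape:
            raise CytometryError(
                f"channel {name!r} shape {px.shape} does not match nuclei")
        raw = ndi.mean(px.astype(np.float64), nuclei, ids)
        df[f"{name}_raw"] = raw
        df[f"{name}_norm"] = raw / 255.0

    for name, mask in (masks or {}).items():
        mask = np.asarray(mask).astype(np.float64)
        if mask.shape != nuclei.shape:
            raise CytometryError(
                f"mask {name!r} shape {mask.shape} does not match nuclei")
        df[f"{name}_overlap"] = ndi.sum_labels(mask, nuclei, ids) / areas

    df["centroid_x_um"] = df["centroid_col_px"] * resolution
    df["centroid_y_um"] = df["centroid_row_px"] * resolution
    return df


def positivity_threshold(values, k: float = 1.0) -> float:
    """Positivity cut ``mean + k * SD`` (population SD) over all cells.

    Cells are called positive when strictly above the threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise CytometryError("cannot derive a positivity threshold from no cells")
    return float(values.mean() + k * values.std(ddof=0))


def call_positives(cells: pd.DataFrame, markers: list[str],
                   sd_multipliers: dict[str, float] | None = None,
                   suffix: str = "_norm") -> pd.DataFrame:
    """Add ``<marker>_positive`` columns from mean + k*SD thresholds."""
    sd_multipliers = sd_multipliers or {}
    out = cells.copy()
    for marker in markers:
        k = sd_multipliers.get(marker, 1.0)
        col = f"{marker}{suffix}"
        thr = positivity_threshold(out[col], k)
        out[f"{marker}_positive"] = out[col] > thr
        out.attrs[f"{marker}_threshold"] = thr
    return out


def assign_compartment(cells: pd.DataFrame) -> pd.Series:
    """Epithelial iff the centroid lies inside a (hole-filled) gland."""
    return pd.Series(np.where(cells["gland_id"].to_numpy() > 0,
                              "epithelial", "stromal"), index=cells.index)


def classify_immune(cells: pd.DataFrame,
                    panel: PanelConfig | None = None) -> pd.DataFrame:
    """Immune-panel hierarchical classification.

    Requires ``cd45_overlap`` (nucleus/CD45-mask overlap fraction),
    ``gland_id`` and ``cd4_positive``/``cd8_positive``/``foxp3_positive``
    columns.  Adds ``compartment``, ``cell_class`` and ``class_label``.
    """
    panel = panel or PanelConfig(scheme="immune")
    out = cells.copy()
    out["compartment"] = assign_compartment(out)
    is_leuk = out["cd45_overlap"].to_numpy() >= panel.basal_overlap_min
    cd4 = out["cd4_positive"].to_numpy()
    cd8 = out["cd8_positive"].to_numpy()
    foxp3 = out["foxp3_positive"].to_numpy()

    subtype = np.full(len(out), "leukocyte_other", dtype=object)
    subtype[cd4 & foxp3 & ~cd8] = "treg"
    subtype[cd4 & ~foxp3 & ~cd8] = "th"
    subtype[cd8 & ~cd4 & ~foxp3] = "te"

    in_gland = out["gland_id"].to_numpy() > 0
    cell_class = np.where(is_leuk, subtype,
                          np.where(in_gland, "epithelial_cell", "other"))
    label = np.where(
        is_leuk,
        np.char.add(np.char.add(out["compartment"].to_numpy(str), "_"),
                    subtype.astype(str)),
        cell_class)
    out["cell_class"] = cell_class
    out["class_label"] = label
    return out


def classify_glands_and_epithelial(cells: pd.DataFrame,
                                   panel: PanelConfig | None = None,
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Epithelial-panel gland and cell classification.

    A basal cell is a nucleus with >= 10 % area overlap with the CK5+p63
    mask (``ck5p63_overlap`` column).  A gland is malignant iff it contains
    zero basal cells; its nuclei are cancer cells.  Benign-gland nuclei are
    basal or benign luminal; nuclei outside glands are stromal.  Returns
    (gland table, classified cell table).
    """
    panel = panel or PanelConfig(scheme="epithelial")
    out = cells.copy()
    out["compartment"] = assign_compartment(out)
    basal_overlap = out["ck5p63_overlap"].to_numpy() >= panel.basal_overlap_min
    gland_id = out["gland_id"].to_numpy()
    in_gland = gland_id > 0

    gland_ids = np.unique(gland_id[in_gland])
    records = []
    malignant_of = {}
    for gid in gland_ids:
        members = gland_id == gid
        n_basal = int((members & basal_overlap).sum())
        malignant = n_basal == 0
        malignant_of[gid] = malignant
        records.append({"gland_id": int(gid), "n_cells": int(members.sum()),
                        "n_basal_cells": n_basal, "malignant": malignant})
    glands = pd.DataFrame(records,
                          columns=["gland_id", "n_cells", "n_basal_cells",
                                   "malignant"])

    is_malignant = np.array([malignant_of.get(g, False) for g in gland_id])
    label = np.full(len(out), "stromal", dtype=object)
    label[in_gland & is_malignant] = "cancer"
    label[in_gland & ~is_malignant & basal_overlap] = "basal"
    label[in_gland & ~is_malignant & ~basal_overlap] = "benign_luminal"
    out["cell_class"] = label
    out["class_label"] = label
    return glands, out


def summarize_panel(cells: pd.DataFrame, scheme: str) -> dict[str, pd.DataFrame]:
    """Tissue-cytometry summary tables for a classified cell table.

    Always includes ``class_distribution`` (percent of all cells per class
    label).  The immune scheme adds T-class proportions among all leukocytes
    split by compartment, and the Ki67+ fraction per T class per
    compartment; the epithelial scheme adds per-class mean normalized marker
    expression and AR expression stratified by AMACR status within
    cancer/benign-luminal cells.
    """
    labels = IMMUNE_LABELS if scheme == "immune" else EPITHELIAL_LABELS
    n_total = len(cells)
    dist = pd.DataFrame({"class_label": labels})
    if n_total:
        counts = cells["class_label"].value_counts()
        dist["n_cells"] = [int(counts.get(lb, 0)) for lb in labels]
        dist["percent_of_cells"] = 100.0 * dist["n_cells"] / n_total
    else:
        dist["n_cells"] = 0
        dist["percent_of_cells"] = 0.0
    tables = {"class_distribution": dist}

    if scheme == "immune":
        t_classes = ("treg", "th", "te")
        is_leuk = cells["cell_class"].isin(
            t_classes + ("leukocyte_other",)) if n_total else pd.Series(dtype=bool)
        n_leuk = int(is_leuk.sum()) if n_total else 0
        rows = []
        for comp in ("epithelial", "stromal"):
            for t in t_classes:
                if n_total:
                    sel = is_leuk & (cells["compartment"] == comp) \
                        & (cells["cell_class"] == t)
                    n = int(sel.sum())
                    pct = 100.0 * n / n_leuk if n_leuk else 0.0
                    ki = (100.0 * cells.loc[sel, "ki67_positive"].mean()
                          if n and "ki67_positive" in cells else 0.0)
                else:
                    n, pct, ki = 0, 0.0, 0.0
                rows.append({"compartment": comp, "t_class": t, "n_cells": n,
                             "percent_of_leukocytes": pct,
                             "ki67_positive_percent": ki})
        tables["t_cells"] = pd.DataFrame(rows)
        share = pd.DataFrame({
            "compartment": ["epithelial", "stromal"],
            "percent_of_leukocytes": [
                (100.0 * ((cells["compartment"] == c) & is_leuk).sum() / n_leuk)
                if n_leuk else 0.0
                for c in ("epithelial", "stromal")],
        })
        tables["leukocyte_compartments"] = share
    else:
        markers = [c[:-5] for c in cells.columns if c.endswith("_norm")]
        rows = []
        for lb in labels:
            sel = cells["class_label"] == lb if n_total else pd.Series(dtype=bool)
            row = {"class_label": lb, "n_cells": int(sel.sum()) if n_total else 0}
            for m in markers:
                row[f"{m}_norm_mean"] = (float(cells.loc[sel, f"{m}_norm"].mean())
                                         if n_total and sel.any() else 0.0)
            rows.append(row)
        tables["marker_expression"] = pd.DataFrame(rows)
        if n_total and "amacr_positive" in cells and "ar_norm" in cells:
            rows = []
            for lb in ("cancer", "benign_luminal"):
                for status, name in ((True, "amacr_pos"), (False, "amacr_neg")):
                    sel = (cells["class_label"] == lb) \
                        & (cells["amacr_positive"] == status)
                    rows.append({
                        "group": f"{lb}_{name}",
                        "n_cells": int(sel.sum()),
                        "ar_norm_mean": (float(cells.loc[sel, "ar_norm"].mean())
                                         if sel.any() else 0.0)})
            tables["ar_by_amacr"] = pd.DataFrame(rows)
    return tables
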