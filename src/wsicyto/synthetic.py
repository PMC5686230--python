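"""Synthetic whole-slide generator with full ground truth.

Generates a paired fluorescence + brightfield slide emulating glandular
tissue: elliptical epithelial glands with luminal holes and epithelial
rings, stromal and immune cells between them, per-class marker intensity
profiles, autofluorescence background, and a brightfield image rendered
from per-stain concentration maps through the Beer-Lambert forward model
under a planted similarity transform at a different pixel size.  Every
planted quantity (cell positions, classes, marker levels, gland
malignancy, transform, stain concentrations) is returned, so each
pipeline stage has a parameter-recovery oracle.

Cells are drawn as isotropic Gaussians (sigma = radius / 2) on the
nuclear channel; marker channels reuse the footprint scaled by the
cell's marker level.  Nuclei are placed with a hard-core minimum
spacing, as in packed tissue.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .registration import AffineTransform
from .stains import StainMatrix, render_brightfield
from .wsi_io import (ChannelImage, MultiplexSlide, write_channel_tiff,
                     write_rgb_tiff)

IMMUNE_MARKERS = ("cd45", "cd4", "cd8", "foxp3", "ki67", "pan_epi")
EPITHELIAL_MARKERS = ("pan_epi", "ck5p63", "amacr", "ar", "ck8", "ck18")

# cell classes and where the generator places them
IMMUNE_PLACEMENT = {
    "treg": "any", "th": "any", "te": "any", "leukocyte_other": "any",
    "epithelial": "gland_ring", "stromal": "stroma",
}
EPITHELIAL_PLACEMENT = {
    "cancer": "cancer_ring", "benign_luminal": "benign_ring",
    "basal": "benign_outer", "stromal": "stroma",
}

_POS = (200.0, 12.0)   # expressed-marker blob amplitude (mean, sd)
_NEG = (4.0, 2.0)      # baseline amplitude of unexpressed markers

# (class, marker) -> (mean, sd) blob amplitude for expressed markers.
IMMUNE_PROFILES = {
    ("treg", "cd45"): _POS, ("treg", "cd4"): _POS, ("treg", "foxp3"): _POS,
    ("th", "cd45"): _POS, ("th", "cd4"): _POS,
    ("te", "cd45"): _POS, ("te", "cd8"): _POS,
    ("leukocyte_other", "cd45"): _POS,
    ("epithelial", "pan_epi"): _POS,
    ("treg", "ki67"): _POS, ("th", "ki67"): _POS, ("te", "ki67"): _POS,
    ("leukocyte_other", "ki67"): _POS, ("epithelial", "ki67"): _POS,
    ("stromal", "ki67"): _POS,
}
# markers expressed in only part of a class: (class, marker) -> fraction
IMMUNE_POSITIVE_FRACTIONS = {
    ("treg", "ki67"): 0.04, ("th", "ki67"): 0.011, ("te", "ki67"): 0.015,
    ("leukocyte_other", "ki67"): 0.01, ("epithelial", "ki67"): 0.05,
    ("stromal", "ki67"): 0.02,
}
# leukocytes 38 % / epithelium 40 % / stroma 22 %, T subsets within leukocytes
IMMUNE_PROPORTIONS = {
    "treg": 0.018, "th": 0.072, "te": 0.034, "leukocyte_other": 0.256,
    "epithelial": 0.40, "stromal": 0.22,
}

EPITHELIAL_PROFILES = {
    ("cancer", "pan_epi"): _POS, ("cancer", "ck18"): (110.0, 20.0),
    ("cancer", "ck8"): (60.0, 15.0), ("cancer", "amacr"): (160.0, 20.0),
    ("cancer", "ar"): (145.0, 25.0),
    ("benign_luminal", "pan_epi"): _POS, ("benign_luminal", "ck18"): (65.0, 15.0),
    ("benign_luminal", "ck8"): (55.0, 15.0), ("benign_luminal", "amacr"): (160.0, 20.0),
    ("benign_luminal", "ar"): (105.0, 25.0),
    ("basal", "pan_epi"): _POS, ("basal", "ck5p63"): _POS,
    ("basal", "ck18"): (30.0, 10.0), ("basal", "ck8"): (30.0, 10.0),
    ("basal", "ar"): (30.0, 10.0),
}
EPITHELIAL_POSITIVE_FRACTIONS = {
    ("cancer", "amacr"): 0.31, ("benign_luminal", "amacr"): 0.05,
}
# cancer 20 % / benign luminal 11 % / basal 15 % / stroma 54 %
EPITHELIAL_PROPORTIONS = {
    "cancer": 0.20, "benign_luminal": 0.11, "basal": 0.15, "stromal": 0.54,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTransform:
    """Similarity map from fluorescence to brightfield physical coordinates.

    ``x_bf_um = scale * R(rotation) @ x_fl_um + translation_um`` in (x, y).
    """

    rotation_deg: float = 3.0
    scale: float = 1.01
    translation_um: tuple[float, float] = (25.0, 14.0)

    def matrix_um(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        r = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        m = np.eye(3)
        m[:2, :2] = self.scale * r
        m[:2, 2] = self.translation_um
        return m

    def apply_um(self, points_xy_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy_um, dtype=float))
        return pts @ (self.matrix_um()[:2, :2]).T + self.matrix_um()[:2, 2]

    def as_affine(self, src_resolution: float, dst_resolution: float,
                  ) -> AffineTransform:
        """Pixel-grid affine: source px at src_resolution -> dest px."""
        m = self.matrix_um()
        s_in = np.diag([src_resolution, src_resolution, 1.0])
        s_out = np.diag([1.0 / dst_resolution, 1.0 / dst_resolution, 1.0])
        return AffineTransform(s_out @ m @ s_in, dst_resolution)

    def shifted(self, offset_um: tuple[float, float]) -> "PlantedTransform":
        tx, ty = self.translation_um
        return replace(self, translation_um=(tx + offset_um[0], ty + offset_um[1]))


@dataclass
class SlideSimConfig:
    """Study conditions of a synthetic slide.

    Defaults describe a 4096 x 4096 px fluorescence slide at 0.64 µm/px
    (~6.9 mm^2) with ~800 nuclei/mm^2, glandular tissue covering roughly a
    quarter of the section, and the immune-panel class mix (38 % leukocytes,
    40 % epithelial, 22 % stromal cells).
    """

    image_height_px: int = 4096
    image_width_px: int = 4096
    fl_resolution: float = 0.64        # µm/px, fluorescence grid
    bf_resolution: float = 0.80        # µm/px, brightfield grid
    n_glands: int | None = None        # None -> fill ~gland_area_fraction
    gland_axes: tuple[float, float] = (110.0, 230.0)  # semi-axis range, px
    gland_area_fraction: float = 0.26
    fraction_cancer_glands: float = 0.0
    cell_density: float = 800.0        # cells / mm^2
    scheme: str = "immune"
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(IMMUNE_PROPORTIONS))
    placement: dict[str, str] = field(
        default_factory=lambda: dict(IMMUNE_PLACEMENT))
    marker_profiles: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(IMMUNE_PROFILES))
    positive_fractions: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(IMMUNE_POSITIVE_FRACTIONS))
    markers: tuple[str, ...] = IMMUNE_MARKERS
    nuclear_amplitude: tuple[float, float] = (230.0, 8.0)
    cell_radius_px: tuple[float, float] = (18.0, 1.5)
    min_cell_spacing_px: float = 22.0
    lumen_fraction_benign: float = 0.35
    lumen_fraction_cancer: float = 0.25
    pan_epi_field: float = 120.0
    autofluorescence_level: float = 8.0
    noise_sd: float = 2.0
    edge_margin_px: float = 24.0
    ar_amacr_shift: float = -45.0      # AR amplitude shift in AMACR+ cells
    planted_transform: PlantedTransform = field(default_factory=PlantedTransform)
    stain_matrix: StainMatrix | None = None
    haematoxylin_conc: tuple[float, float] = (0.75, 0.05)
    gland_stain_conc: float = 0.45
    accent_stain_conc: float = 0.40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise SimulationError("image size must be positive")
        if self.fl_resolution <= 0 or self.bf_resolution <= 0:
            raise SimulationError("resolutions must be > 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"class proportions must sum to 1, got {total!r}")
        if not 0 <= self.autofluorescence_level <= 255:
            raise SimulationError("autofluorescence level outside 0-255")
        for (cls, marker), (mean, sd) in self.marker_profiles.items():
            if not (0 <= mean <= 255):
                raise SimulationError(
                    f"marker profile mean outside 0-255 for {(cls, marker)}")
        if self.stain_matrix is None:
            self.stain_matrix = StainMatrix.hdab_default()
            # name the stain slots after the chromogens they emulate
            self.stain_matrix.names = ("haematoxylin", "gland_stain",
                                       "accent_stain")

    @property
    def area_mm2(self) -> float:
        h_um = self.image_height_px * self.fl_resolution
        w_um = self.image_width_px * self.fl_resolution
        return (h_um / 1000.0) * (w_um / 1000.0)


def immune_config(**overrides) -> SlideSimConfig:
    """Immune-panel study conditions (leukocyte/epithelial/stromal mix)."""
    overrides.setdefault("class_proportions", dict(IMMUNE_PROPORTIONS))
    overrides.setdefault("placement", dict(IMMUNE_PLACEMENT))
    overrides.setdefault("marker_profiles", dict(IMMUNE_PROFILES))
    overrides.setdefault("positive_fractions", dict(IMMUNE_POSITIVE_FRACTIONS))
    overrides.setdefault("markers", IMMUNE_MARKERS)
    return SlideSimConfig(scheme="immune", **overrides)


def epithelial_config(**overrides) -> SlideSimConfig:
    """Epithelial-panel study conditions (cancer/benign glands, basal cells)."""
    overrides.setdefault("fraction_cancer_glands", 0.35)
    overrides.setdefault("cell_density", 550.0)
    overrides.setdefault("class_proportions", dict(EPITHELIAL_PROPORTIONS))
    overrides.setdefault("placement", dict(EPITHELIAL_PLACEMENT))
    overrides.setdefault("marker_profiles", dict(EPITHELIAL_PROFILES))
    overrides.setdefault("positive_fractions", dict(EPITHELIAL_POSITIVE_FRACTIONS))
    overrides.setdefault("markers", EPITHELIAL_MARKERS)
    return SlideSimConfig(scheme="epithelial", **overrides)


@dataclass
class GroundTruthSlide:
    """Everything the generator planted, for parameter-recovery checks."""

    cells: pd.DataFrame
    glands: pd.DataFrame
    transform: PlantedTransform
    stain_matrix: StainMatrix
    concentration_maps: dict[str, np.ndarray]
    bf_resolution: float
    config: SlideSimConfig

    def cells_in_reference_frame(self) -> pd.DataFrame:
        """Cell table with centroids mapped into the brightfield (reference)
        physical frame, in µm."""
        out = self.cells.copy()
        pts = self.transform.apply_um(
            np.column_stack([out["x_um"], out["y_um"]]))
        out["x_ref_um"] = pts[:, 0]
        out["y_ref_um"] = pts[:, 1]
        return out

    def gland_polygons(self, n_vertices: int = 64) -> list[dict]:
        """Gland outlines as GeoJSON-style polygons (FL frame, µm)."""
        polys = []
        phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        for _, g in self.glands.iterrows():
            ca, sa = math.cos(g.angle_rad), math.sin(g.angle_rad)
            x = g.a_px * np.cos(phi)
            y = g.b_px * np.sin(phi)
            xs = (g.x_px + ca * x - sa * y) * self.config.fl_resolution
            ys = (g.y_px + sa * x + ca * y) * self.config.fl_resolution
            polys.append({
                "type": "Polygon",
                "gland_id": int(g.gland_id),
                "malignant": bool(g.malignant),
                "coordinates": [np.column_stack([xs, ys]).tolist()],
            })
        return polys

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "truth_cells.csv", index=False)
        self.glands.to_csv(directory / "truth_glands.csv", index=False)
        (directory / "truth_glands.geojson.json").write_text(
            json.dumps(self.gland_polygons()))
        meta = {
            "transform": {
                "rotation_deg": self.transform.rotation_deg,
                "scale": self.transform.scale,
                "translation_um": list(self.transform.translation_um),
            },
            "stain_matrix": self.stain_matrix.to_dict(),
            "bf_resolution": self.bf_resolution,
            "fl_resolution": self.config.fl_resolution,
            "scheme": self.config.scheme,
        }
        (directory / "truth_meta.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _stamp_gaussian(canvas: np.ndarray, x: float, y: float, sigma: float,
                    amplitude: float) -> None:
    """Add an isotropic Gaussian blob to a float canvas in place."""
    if amplitude <= 0:
        return
    half = int(math.ceil(3.0 * sigma))
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, canvas.shape[1])
    y0, y1 = max(cy - half, 0), min(cy + half + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    canvas[y0:y1, x0:x1] += np.float32(amplitude) * g.astype(np.float32)


def _add_ring_field(canvas: np.ndarray, gland, inner: float, outer: float,
                    value: float, x_px: float | None = None,
                    y_px: float | None = None, a_px: float | None = None,
                    b_px: float | None = None,
                    angle: float | None = None) -> None:
    """Add a constant annular field for a gland's epithelial ring."""
    x0c = gland.x_px if x_px is None else x_px
    y0c = gland.y_px if y_px is None else y_px
    a = gland.a_px if a_px is None else a_px
    b = gland.b_px if b_px is None else b_px
    th = gland.angle_rad if angle is None else angle
    half = int(math.ceil(max(a, b) * outer)) + 2
    cx, cy = int(round(x0c)), int(round(y0c))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, canvas.shape[1])
    y0, y1 = max(cy - half, 0), min(cy + half + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float32) - np.float32(x0c)
    ys = np.arange(y0, y1, dtype=np.float32) - np.float32(y0c)
    ca, sa = math.cos(th), math.sin(th)
    u = ca * xs[None, :] + sa * ys[:, None]
    v = -sa * xs[None, :] + ca * ys[:, None]
    t = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    canvas[y0:y1, x0:x1] += np.float32(value) * ((t >= inner) & (t <= outer))


class _HardCore:
    """Grid-hash rejection sampler enforcing a minimum centre spacing."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cell = spacing
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def try_add(self, x: float, y: float) -> bool:
        gx, gy = int(x // self.cell), int(y // self.cell)
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for (px, py) in self.grid.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.spacing ** 2:
                        return False
        self.grid.setdefault((gx, gy), []).append((x, y))
        return True


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_glands(config: SlideSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    a_lo, a_hi = config.gland_axes
    h, w = config.image_height_px, config.image_width_px
    pitch = 2 * a_hi + 24
    margin = a_hi + config.edge_margin_px
    xs = np.arange(margin + a_hi, w - margin + 1e-9, pitch)
    ys = np.arange(margin + a_hi, h - margin + 1e-9, pitch)
    sites = [(x, y) for y in ys for x in xs]
    if config.n_glands is None:
        mean_area = math.pi * ((a_lo + a_hi) / 2) ** 2 * 0.75
        n = int(round(config.gland_area_fraction * h * w / mean_area))
        n = min(n, len(sites))
    else:
        n = config.n_glands
    if n > len(sites):
        raise SimulationError(
            f"cannot place {n} glands of max semi-axis {a_hi:.0f} px on a "
            f"{h}x{w} slide (room for {len(sites)})")
    order = rng.permutation(len(sites))[:n]
    n_cancer = int(round(config.fraction_cancer_glands * n))
    rows = []
    for k, site_idx in enumerate(order):
        sx, sy = sites[site_idx]
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(0.55 * a, 0.95 * a)
        angle = rng.uniform(0, math.pi)
        slack = max(pitch / 2 - a - 6, 0.0)
        x = sx + rng.uniform(-slack, slack)
        y = sy + rng.uniform(-slack, slack)
        rows.append((k + 1, x, y, a, b, angle, k < n_cancer))
    df = pd.DataFrame(rows, columns=["gland_id", "x_px", "y_px", "a_px",
                                     "b_px", "angle_rad", "malignant"])
    return df


class _GlandGeometry:
    """Vectorized ellipse geometry over all glands of a slide."""

    def __init__(self, glands: pd.DataFrame):
        self.ids = glands.gland_id.to_numpy(int)
        self.x = glands.x_px.to_numpy(float)
        self.y = glands.y_px.to_numpy(float)
        self.a = glands.a_px.to_numpy(float)
        self.b = glands.b_px.to_numpy(float)
        self.angle = glands.angle_rad.to_numpy(float)
        self.cos = np.cos(self.angle)
        self.sin = np.sin(self.angle)
        self.malignant = glands.malignant.to_numpy(bool)

    def __len__(self) -> int:
        return len(self.ids)

    def containing_gland(self, x: float, y: float) -> int:
        """Planted gland id containing the point (0 if in stroma)."""
        if len(self) == 0:
            return 0
        dx = x - self.x
        dy = y - self.y
        u = self.cos * dx + self.sin * dy
        v = -self.sin * dx + self.cos * dy
        t2 = (u / self.a) ** 2 + (v / self.b) ** 2
        hit = np.flatnonzero(t2 <= 1.0)
        return int(self.ids[hit[0]]) if len(hit) else 0

    def containing_gland_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.zeros(len(x), dtype=int)
        for k in range(len(self)):
            dx = x - self.x[k]
            dy = y - self.y[k]
            u = self.cos[k] * dx + self.sin[k] * dy
            v = -self.sin[k] * dx + self.cos[k] * dy
            t2 = (u / self.a[k]) ** 2 + (v / self.b[k]) ** 2
            out[(t2 <= 1.0) & (out == 0)] = self.ids[k]
        return out

    def sample_in_ring(self, rng, k: int, lo: float, hi: float,
                       ) -> tuple[float, float]:
        t = math.sqrt(rng.uniform(lo ** 2, hi ** 2))
        phi = rng.uniform(0, 2 * math.pi)
        u = self.a[k] * t * math.cos(phi)
        v = self.b[k] * t * math.sin(phi)
        return (self.x[k] + self.cos[k] * u - self.sin[k] * v,
                self.y[k] + self.sin[k] * u + self.cos[k] * v)


def _place_cells(config: SlideSimConfig, glands: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    h, w = config.image_height_px, config.image_width_px
    margin = config.edge_margin_px
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    n_cells = int(round(config.cell_density * config.area_mm2))
    draw = rng.choice(len(classes), size=n_cells, p=probs)

    geom = _GlandGeometry(glands)
    benign_idx = np.flatnonzero(~geom.malignant)
    cancer_idx = np.flatnonzero(geom.malignant)
    all_idx = np.arange(len(geom))
    lum_b = config.lumen_fraction_benign
    lum_c = config.lumen_fraction_cancer
    hard = _HardCore(config.min_cell_spacing_px)

    rows = []
    cell_id = 0
    for cls_idx in draw:
        cls = classes[cls_idx]
        rule = config.placement[cls]
        placed = False
        for _ in range(60):
            if rule == "any":
                x = rng.uniform(margin, w - margin)
                y = rng.uniform(margin, h - margin)
            elif rule == "stroma":
                x = rng.uniform(margin, w - margin)
                y = rng.uniform(margin, h - margin)
                if geom.containing_gland(x, y):
                    continue
            elif rule == "gland_ring":
                if len(all_idx) == 0:
                    break
                k = int(all_idx[rng.integers(len(all_idx))])
                lum = lum_c if geom.malignant[k] else lum_b
                x, y = geom.sample_in_ring(rng, k, lum + 0.03, 0.92)
            elif rule == "benign_ring":
                if len(benign_idx) == 0:
                    break
                k = int(benign_idx[rng.integers(len(benign_idx))])
                x, y = geom.sample_in_ring(rng, k, lum_b + 0.03, 0.84)
            elif rule == "benign_outer":
                if len(benign_idx) == 0:
                    break
                k = int(benign_idx[rng.integers(len(benign_idx))])
                x, y = geom.sample_in_ring(rng, k, 0.80, 0.97)
            elif rule == "cancer_ring":
                if len(cancer_idx) == 0:
                    break
                k = int(cancer_idx[rng.integers(len(cancer_idx))])
                x, y = geom.sample_in_ring(rng, k, lum_c + 0.03, 0.92)
            else:
                raise SimulationError(f"unknown placement rule {rule!r}")
            if not (margin <= x <= w - margin and margin <= y <= h - margin):
                continue
            if hard.try_add(x, y):
                placed = True
                break
        if not placed:
            continue
        cell_id += 1
        radius = float(np.clip(rng.normal(*config.cell_radius_px),
                               config.cell_radius_px[0] - 4,
                               config.cell_radius_px[0] + 4))
        rows.append((cell_id, x, y, radius, cls))

    df = pd.DataFrame(rows, columns=["cell_id", "x_px", "y_px", "radius_px",
                                     "true_class"])
    df["x_um"] = df.x_px * config.fl_resolution
    df["y_um"] = df.y_px * config.fl_resolution
    # ground-truth compartment: inside any gland ellipse (lumen included)
    gland_id = geom.containing_gland_many(df.x_px.to_numpy(),
                                          df.y_px.to_numpy())
    df["gland_id"] = gland_id
    df["in_gland"] = gland_id > 0
    return df


def _draw_marker_levels(config: SlideSimConfig, cells: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    cells = cells.copy()
    amacr_pos = None
    for marker in config.markers:
        amp = np.empty(len(cells))
        pos = np.zeros(len(cells), dtype=bool)
        for cls in config.class_proportions:
            sel = (cells.true_class == cls).to_numpy()
            n = int(sel.sum())
            if n == 0:
                continue
            profile = config.marker_profiles.get((cls, marker))
            if profile is None:
                frac = 0.0
            else:
                frac = config.positive_fractions.get((cls, marker), 1.0)
            is_pos = rng.random(n) < frac
            a = rng.normal(*_NEG, size=n)
            if profile is not None and is_pos.any():
                a[is_pos] = rng.normal(profile[0], profile[1],
                                       size=int(is_pos.sum()))
            amp[sel] = a
            pos[sel] = is_pos
        if marker == "amacr":
            amacr_pos = pos.copy()
        cells[f"{marker}_amp"] = np.clip(amp, 0.0, 255.0)
        cells[f"{marker}_pos"] = pos
    # AR is lower in AMACR-expressing luminal/cancer cells (inverse coupling)
    if "ar" in config.markers and amacr_pos is not None and amacr_pos.any():
        ar = cells["ar_amp"].to_numpy()
        ar[amacr_pos] = np.clip(ar[amacr_pos] + config.ar_amacr_shift, 0, 255)
        cells["ar_amp"] = ar
    cells["nuclear_amp"] = np.clip(
        rng.normal(*config.nuclear_amplitude, size=len(cells)), 0, 255)
    return cells


def _render_fl_channels(config: SlideSimConfig, cells: pd.DataFrame,
                        glands: pd.DataFrame,
                        rng: np.random.Generator) -> MultiplexSlide:
    h, w = config.image_height_px, config.image_width_px
    xs = cells.x_px.to_numpy()
    ys = cells.y_px.to_numpy()
    sigmas = cells.radius_px.to_numpy() / 2.0

    channels: dict[str, ChannelImage] = {}
    for name in ("dapi",) + tuple(config.markers):
        canvas = np.zeros((h, w), dtype=np.float32)
        if name == "dapi":
            amps = cells.nuclear_amp.to_numpy()
        else:
            amps = cells[f"{name}_amp"].to_numpy()
        for x, y, s, a in zip(xs, ys, sigmas, amps):
            _stamp_gaussian(canvas, x, y, s, a)
        if name == "pan_epi":
            for _, g in glands.iterrows():
                lum = (config.lumen_fraction_cancer if g.malignant
                       else config.lumen_fraction_benign)
                _add_ring_field(canvas, g, lum, 1.0, config.pan_epi_field)
        canvas += np.float32(config.autofluorescence_level)
        if config.noise_sd > 0:
            canvas += config.noise_sd * rng.standard_normal(
                canvas.shape, dtype=np.float32)
        px = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        channels[name] = ChannelImage(px, config.fl_resolution, name)
    return MultiplexSlide(channels)


def _render_brightfield_pair(config: SlideSimConfig, cells: pd.DataFrame,
                             glands: pd.DataFrame, rng: np.random.Generator,
                             ) -> tuple[np.ndarray, dict[str, np.ndarray],
                                        PlantedTransform]:
    """Render the brightfield image in its own frame under the planted map."""
    tf = config.planted_transform
    h, w = config.image_height_px, config.image_width_px
    res = config.fl_resolution
    corners_um = np.array([[0, 0], [w * res, 0], [0, h * res],
                           [w * res, h * res]], dtype=float)
    mapped = tf.apply_um(corners_um)
    pad_um = 16 * config.bf_resolution
    offset_um = mapped.min(axis=0) - pad_um
    # fold the canvas offset into the planted transform actually realized
    tf = tf.shifted((-offset_um[0], -offset_um[1]))
    mapped = mapped - offset_um
    bf_w = int(math.ceil(mapped[:, 0].max() / config.bf_resolution)) + 16
    bf_h = int(math.ceil(mapped[:, 1].max() / config.bf_resolution)) + 16

    pts_bf_um = tf.apply_um(np.column_stack([cells.x_um, cells.y_um]))
    x_bf = pts_bf_um[:, 0] / config.bf_resolution
    y_bf = pts_bf_um[:, 1] / config.bf_resolution
    sigma_bf = (cells.radius_px.to_numpy() / 2.0) * res * tf.scale \
        / config.bf_resolution

    haem = np.zeros((bf_h, bf_w), dtype=np.float32)
    conc = rng.normal(*config.haematoxylin_conc, size=len(cells))
    for x, y, s, c in zip(x_bf, y_bf, sigma_bf, np.clip(conc, 0.1, None)):
        _stamp_gaussian(haem, x, y, s, c)

    gland_stain = np.zeros((bf_h, bf_w), dtype=np.float32)
    scale_px = res * tf.scale / config.bf_resolution
    for _, g in glands.iterrows():
        center = tf.apply_um(np.array([[g.x_px * res, g.y_px * res]]))[0]
        lum = (config.lumen_fraction_cancer if g.malignant
               else config.lumen_fraction_benign)
        _add_ring_field(gland_stain, g, lum, 1.0, config.gland_stain_conc,
                        x_px=center[0] / config.bf_resolution,
                        y_px=center[1] / config.bf_resolution,
                        a_px=g.a_px * scale_px, b_px=g.b_px * scale_px,
                        angle=g.angle_rad + math.radians(tf.rotation_deg))

    accent = np.zeros((bf_h, bf_w), dtype=np.float32)
    accent_marker = "ki67" if "ki67" in config.markers else (
        "amacr" if "amacr" in config.markers else None)
    if accent_marker is not None:
        sel = cells[f"{accent_marker}_pos"].to_numpy()
        for x, y, s in zip(x_bf[sel], y_bf[sel], sigma_bf[sel]):
            _stamp_gaussian(accent, x, y, s, config.accent_stain_conc)

    maps = {"haematoxylin": haem, "gland_stain": gland_stain,
            "accent_stain": accent}
    rgb = render_brightfield(maps, config.stain_matrix)
    if config.noise_sd > 0:
        rgb = rgb + config.noise_sd * rng.standard_normal(
            rgb.shape, dtype=np.float32)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return rgb, maps, tf


def generate_slide(config: SlideSimConfig,
                   ) -> tuple[MultiplexSlide, np.ndarray, GroundTruthSlide]:
    """Generate a paired fluorescence/brightfield slide with ground truth.

    Returns the fluorescence channels (nuclear + markers, FL grid), the
    8-bit RGB brightfield raster (BF grid, under the planted transform),
    and the :class:`GroundTruthSlide`.  Identical config (including seed)
    yields bit-identical outputs.
    """
    rng = np.random.default_rng(config.rng_seed)
    glands = _place_glands(config, rng)
    cells = _place_cells(config, glands, rng)
    cells = _draw_marker_levels(config, cells, rng)
    fl = _render_fl_channels(config, cells, glands, rng)
    bf_rgb, conc_maps, realized_tf = _render_brightfield_pair(
        config, cells, glands, rng)

    # invariant: malignant glands contain no basal-class cells
    if "basal" in set(cells.true_class):
        bad = cells.merge(glands[["gland_id", "malignant"]], on="gland_id",
                          how="left")
        flag = bad.malignant.eq(True)
        assert not ((bad.true_class == "basal") & flag).any(), \
            "basal cell planted in a malignant gland"

    truth = GroundTruthSlide(cells=cells, glands=glands,
                             transform=realized_tf,
                             stain_matrix=config.stain_matrix,
                             concentration_maps=conc_maps,
                             bf_resolution=config.bf_resolution,
                             config=config)
    return fl, bf_rgb, truth


def write_slide(directory: str | Path, fl: MultiplexSlide, bf_rgb: np.ndarray,
                truth: GroundTruthSlide) -> None:
    """Write channels as single-plane TIFFs, brightfield as RGB TIFF, and
    ground truth as CSV/JSON, one file per channel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, channel in fl.channels.items():
        write_channel_tiff(directory / f"{name}.tif", channel)
    write_rgb_tiff(directory / "brightfield.tif", bf_rgb,
                   resolution=truth.bf_resolution)
    truth.save(directory)
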