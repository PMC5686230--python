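"""Gland and nucleus segmentation by Otsu thresholding and watershed.

Two parallel pipelines, as used for tissue cytometry:

* epithelial glands — threshold the pan-epithelium channel (global or
  adaptive Otsu), fill lumina, split touching glands by watershed seeded
  at distance-transform maxima;
* cell nuclei — adaptive Otsu on the nuclear channel, split clumps by
  watershed seeded at smoothed intensity maxima, keep objects whose
  equivalent-circle diameter lies in a 20-80 px range.

``otsu_level`` maximizes the between-class variance with exact integer
arithmetic, so its result is the exact argmax over all 256 candidate
levels (ties broken toward the lower level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import closing, disk, remove_small_objects
from skimage.segmentation import relabel_sequential, watershed

from .wsi_io import ChannelImage


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationParams:
    """Tunable parameters of both segmentation pipelines (pixel units).

    ``nucleus_diameter_range`` is the standard 20-80 px object filter at
    0.64 µm/px; the remaining defaults are package choices and fully
    configurable.
    """

    nucleus_diameter_range: tuple[float, float] = (20.0, 80.0)
    adaptive_window: int = 200
    gland_min_area: float = 500.0
    smoothing_sigma: float = 2.0
    gland_threshold_mode: Literal["global", "adaptive"] = "global"
    adaptive_min_contrast: float = 16.0
    gland_seed_min_distance: int = 60
    gland_closing_radius: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_diameter_range
        if not lo < hi:
            raise SegmentationError(
                f"nucleus diameter range must satisfy min < max, got {lo}, {hi}")
        if self.adaptive_window <= 0:
            raise SegmentationError("adaptive_window must be > 0")


class OtsuLevel(NamedTuple):
    level: int
    degenerate: bool


def _as_histogram(histogram) -> np.ndarray:
    h = np.asarray(histogram)
    if h.ndim != 1 or len(h) != 256:
        raise SegmentationError(f"expected a 256-bin histogram, got shape {h.shape}")
    if np.any(h < 0):
        raise SegmentationError("negative histogram counts")
    if h.sum() == 0:
        raise SegmentationError("all-zero histogram")
    return h.astype(np.int64)


def image_histogram(image: np.ndarray | ChannelImage) -> np.ndarray:
    px = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    return np.bincount(px.ravel(), minlength=256)


def otsu_level(histogram) -> OtsuLevel:
    """Exact Otsu threshold of an 8-bit histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split ``{<= t} / {> t}``; foreground is ``pixel > t``.  Maximization is
    done in exact integer arithmetic (the variance ratio
    ``(m0*w1 - m1*w0)^2 / (w0*w1)`` is compared by cross-multiplication),
    so the result equals a brute-force search over all levels, with ties
    broken toward the lower level.  A single-valued histogram returns that
    value with ``degenerate=True``.
    """
    h = _as_histogram(histogram)
    nonzero = np.flatnonzero(h)
    if len(nonzero) == 1:
        return OtsuLevel(int(nonzero[0]), True)

    counts = [int(c) for c in h]
    moments = [i * int(c) for i, c in enumerate(h)]
    total_w = sum(counts)
    total_m = sum(moments)

    best_t = None
    best_num, best_den = -1, 1  # compare num/den fractions exactly
    w0 = m0 = 0
    for t in range(256):
        w0 += counts[t]
        m0 += moments[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        m1 = total_m - m0
        num = (m0 * w1 - m1 * w0) ** 2
        den = w0 * w1
        # num/den > best_num/best_den  <=>  num*best_den > best_num*den
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    return OtsuLevel(int(best_t), False)


def adaptive_otsu(image: np.ndarray | ChannelImage, window: int = 200,
                  min_contrast: float = 16.0) -> np.ndarray:
    """Per-pixel Otsu threshold map from overlapping local windows.

    The image is split into a grid of ``window``-sized blocks; an Otsu level
    is computed per block and bilinearly interpolated between block centres.
    Blocks without a real foreground/background split — single-valued, or
    with class means closer than ``min_contrast`` gray levels (noise-only
    regions, where Otsu would split the noise) — fall back to the global
    Otsu level, so a globally uniform image reduces to the global level
    everywhere.  If the window exceeds the image, the map falls back to the
    global level.
    """
    px = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    if window < 32:
        raise SegmentationError(f"adaptive window must be >= 32 px, got {window}")
    rows, cols = px.shape
    glob = otsu_level(image_histogram(px))
    if window > min(rows, cols):
        return np.full(px.shape, float(glob.level))

    r_edges = _block_edges(rows, window)
    c_edges = _block_edges(cols, window)
    levels = np.empty((len(r_edges) - 1, len(c_edges) - 1))
    centers_r = np.empty(len(r_edges) - 1)
    centers_c = np.empty(len(c_edges) - 1)
    for i in range(len(r_edges) - 1):
        centers_r[i] = (r_edges[i] + r_edges[i + 1] - 1) / 2.0
        for j in range(len(c_edges) - 1):
            block = px[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            hist = np.bincount(block.ravel(), minlength=256)
            lvl = otsu_level(hist)
            levels[i, j] = glob.level if (
                lvl.degenerate or _class_separation(hist, lvl.level)
                < min_contrast) else lvl.level
    for j in range(len(c_edges) - 1):
        centers_c[j] = (c_edges[j] + c_edges[j + 1] - 1) / 2.0

    if np.all(levels == levels.flat[0]):
        # uniform level map: skip interpolation so the constant is exact
        return np.full(px.shape, float(levels.flat[0]))

    rr = np.clip(np.arange(rows, dtype=float), centers_r[0], centers_r[-1])
    cc = np.clip(np.arange(cols, dtype=float), centers_c[0], centers_c[-1])
    ri = np.clip(np.searchsorted(centers_r, rr, side="right") - 1, 0,
                 max(len(centers_r) - 2, 0))
    ci = np.clip(np.searchsorted(centers_c, cc, side="right") - 1, 0,
                 max(len(centers_c) - 2, 0))
    if len(centers_r) > 1:
        fr = (rr - centers_r[ri]) / (centers_r[ri + 1] - centers_r[ri])
    else:
        ri = np.zeros_like(ri)
        fr = np.zeros_like(rr)
    if len(centers_c) > 1:
        fc = (cc - centers_c[ci]) / (centers_c[ci + 1] - centers_c[ci])
    else:
        ci = np.zeros_like(ci)
        fc = np.zeros_like(cc)

    ri1 = np.minimum(ri + 1, len(centers_r) - 1)
    ci1 = np.minimum(ci + 1, len(centers_c) - 1)
    fr = fr[:, None]
    fc = fc[None, :]
    tl = levels[np.ix_(ri, ci)]
    tr = levels[np.ix_(ri, ci1)]
    bl = levels[np.ix_(ri1, ci)]
    br = levels[np.ix_(ri1, ci1)]
    return ((1 - fr) * (1 - fc) * tl + (1 - fr) * fc * tr
            + fr * (1 - fc) * bl + fr * fc * br)


def _class_separation(hist: np.ndarray, level: int) -> float:
    """Difference of the class mean intensities for a histogram split."""
    idx = np.arange(len(hist))
    w0 = hist[:level + 1].sum()
    w1 = hist[level + 1:].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = float((idx[:level + 1] * hist[:level + 1]).sum() / w0)
    mu1 = float((idx[level + 1:] * hist[level + 1:]).sum() / w1)
    return mu1 - mu0


def _block_edges(n: int, window: int) -> list[int]:
    n_blocks = max(n // window, 1)
    edges = [round(i * n / n_blocks) for i in range(n_blocks + 1)]
    return edges


def _relabel(labels: np.ndarray) -> np.ndarray:
    out, _, _ = relabel_sequential(labels)
    return out.astype(np.int32)


def segment_glands(pan_epi: np.ndarray | ChannelImage,
                   params: SegmentationParams | None = None,
                   level: float | None = None) -> np.ndarray:
    """Segment epithelial glands from a pan-epithelium channel.

    Threshold (global or adaptive Otsu per ``params.gland_threshold_mode``),
    close small gaps, fill lumina, split touching glands by watershed seeded
    at distance-transform maxima, and drop objects below ``gland_min_area``.
    ``level`` may supply a whole-slide global threshold when segmenting
    individual tiles.  Returns an integer label mask (0 = background, ids
    contiguous).
    """
    params = params or SegmentationParams()
    px = pan_epi.pixels if isinstance(pan_epi, ChannelImage) else np.asarray(pan_epi)
    smoothed = ndi.gaussian_filter(px.astype(np.float32), params.smoothing_sigma)
    if level is not None:
        thr = float(level)
    else:
        glob = otsu_level(image_histogram(px))
        if glob.degenerate:
            return np.zeros(px.shape, dtype=np.int32)
        if params.gland_threshold_mode == "adaptive":
            thr = adaptive_otsu(px, params.adaptive_window,
                                params.adaptive_min_contrast)
        else:
            thr = float(glob.level)
    binary = smoothed > thr
    if not binary.any():
        return np.zeros(px.shape, dtype=np.int32)
    if params.gland_closing_radius > 0:
        binary = closing(binary, disk(params.gland_closing_radius))
    binary = ndi.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=int(params.gland_min_area) - 1)
    if not binary.any():
        return np.zeros(px.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    seeds = peak_local_max(distance, min_distance=params.gland_seed_min_distance,
                           labels=binary, exclude_border=False)
    markers = np.zeros(px.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    labels = watershed(-distance, markers, mask=binary)
    labels = _remove_small_labels(labels, params.gland_min_area)
    return _relabel(labels)


def segment_nuclei(nuclear: np.ndarray | ChannelImage,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Segment cell nuclei from the nuclear (DAPI/Hoechst) channel.

    Adaptive Otsu binarization, watershed declumping seeded at smoothed
    intensity maxima (minimum seed separation = minimum nucleus diameter),
    then an equivalent-circle-diameter filter retaining objects in
    ``params.nucleus_diameter_range``.
    """
    params = params or SegmentationParams()
    px = nuclear.pixels if isinstance(nuclear, ChannelImage) else np.asarray(nuclear)
    glob = otsu_level(image_histogram(px))
    if glob.degenerate:
        return np.zeros(px.shape, dtype=np.int32)
    thr = adaptive_otsu(px, params.adaptive_window,
                        params.adaptive_min_contrast)
    smoothed = ndi.gaussian_filter(px.astype(np.float32), params.smoothing_sigma)
    binary = smoothed > thr
    if not binary.any():
        return np.zeros(px.shape, dtype=np.int32)

    d_min, d_max = params.nucleus_diameter_range
    min_area = np.pi * (d_min / 2.0) ** 2
    max_area = np.pi * (d_max / 2.0) ** 2
    # seed suppression at half the minimum diameter: peak_local_max uses a
    # Chebyshev (square) footprint, so a full-diameter radius would merge
    # legitimate neighbours on the diagonal
    seeds = peak_local_max(smoothed, min_distance=max(int(round(d_min / 2)), 1),
                           labels=binary, exclude_border=False)
    markers = np.zeros(px.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    labels = watershed(-smoothed, markers, mask=binary)
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    mask_bad = np.isin(labels, bad[bad > 0])
    labels[mask_bad] = 0
    return _relabel(labels)


def _remove_small_labels(labels: np.ndarray, min_area: float) -> np.ndarray:
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero(areas < min_area)
    labels = labels.copy()
    labels[np.isin(labels, bad[bad > 0])] = 0
    return labels


def marker_mask(channel: np.ndarray | ChannelImage,
                level: int | None = None) -> np.ndarray:
    """Binary marker mask: pixels strictly above the global Otsu level.

    ``level`` may be supplied to apply a threshold computed on the whole
    slide when masking individual tiles.  Degenerate (single-valued)
    channels yield an all-false mask.
    """
    px = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    if level is None:
        lvl = otsu_level(image_histogram(px))
        if lvl.degenerate:
            return np.zeros(px.shape, dtype=bool)
        level = lvl.level
    return px > level
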