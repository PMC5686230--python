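"""Statistical tests and imaging QC metrics for tissue cytometry.

Cell-count comparisons use Fisher's exact test (two-tailed, exact
probability-mass method); marker-expression comparisons use the
two-sample Kolmogorov-Smirnov test (marker distributions are far from
normal); continuous associations use Pearson's r.  QC metrics implement
the signal-to-background ratio (S/B) definition used for filter-set
evaluation and the object-wise mean-intensity retention used for the
fluorochrome heat-stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import special, stats
from skimage.feature import peak_local_max
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed

from .segmentation import image_histogram, otsu_level


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    """A test outcome: statistic, p-value, and per-group sample sizes."""

    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise StatsError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class QCParams:
    """QC thresholds: minimum blank-pixel count for background estimation
    and minimum object area for the heat-retention analysis."""

    min_background_pixels: int = 1000
    min_object_area: int = 100

    def __post_init__(self) -> None:
        if self.min_background_pixels <= 0 or self.min_object_area <= 0:
            raise StatsError("QC pixel counts must be positive")


def fisher_exact_2x2(table) -> StatResult:
    """Two-tailed Fisher's exact test on a 2x2 contingency table.

    The two-tailed p-value is the probability-mass rule: the sum of the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise StatsError(f"need a nonnegative 2x2 table, got {t!r}")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError("table has a zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher_exact", float(stats.fisher_exact(t)[0]),
                      float(min(p, 1.0)), (int(t[0].sum()), int(t[1].sum())))


def ks_two_sample(x, y) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum distance between the two empirical CDFs; the
    p-value uses the asymptotic Kolmogorov distribution with effective
    sample size ``n*m/(n+m)`` (sample sizes in tissue cytometry are large
    enough that the asymptotic form is adequate).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise StatsError("both samples must be nonempty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = n * m / (n + m)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return StatResult("ks_two_sample", d, p, (n, m))


def pearson_r(x, y) -> StatResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("samples must have equal length")
    if len(x) < 3:
        raise StatsError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return StatResult("pearson_r", float(res.statistic), float(res.pvalue),
                      (len(x),))


def signal_to_background(signal_pixels, background_pixels,
                         params: QCParams | None = None,
                         noise_threshold: bool = False) -> float:
    """Signal-to-background ratio S/B.

    B is the mean of at least ``min_background_pixels`` visually blank
    pixels; S is the background-corrected mean signal; the ratio is S/B.
    With ``noise_threshold=True``, signal pixels at or below the Otsu level
    of the background histogram are excluded before averaging (an optional
    noise-suppression variant; interpretation of the procedure, off by
    default).
    """
    params = params or QCParams()
    sig = np.asarray(signal_pixels, dtype=float).ravel()
    bg = np.asarray(background_pixels, dtype=float).ravel()
    if len(bg) < params.min_background_pixels:
        raise StatsError(
            f"{len(bg)} background pixels < required "
            f"{params.min_background_pixels}")
    if len(sig) == 0:
        raise StatsError("no signal pixels")
    b = float(bg.mean())
    if b == 0:
        raise StatsError("zero background mean; S/B undefined")
    if noise_threshold:
        level = otsu_level(np.bincount(
            np.clip(np.rint(bg), 0, 255).astype(np.int64), minlength=256)).level
        sig = sig[sig > level]
        if len(sig) == 0:
            raise StatsError("no signal pixels above background noise level")
    s = float(sig.mean()) - b
    return s / b


def heat_retention(pre_image, post_image,
                   params: QCParams | None = None) -> float:
    """Percent retention of object mean intensity between an image pair.

    Objects are segmented on the *pre* image (Otsu binarization, one
    dilation, watershed split at distance-transform peaks) and objects
    larger than ``min_object_area`` pixels are kept; retention is
    ``100 * mean(post object means) / mean(pre object means)`` over the
    same objects.
    """
    params = params or QCParams()
    pre = np.asarray(pre_image, dtype=float)
    post = np.asarray(post_image, dtype=float)
    if pre.shape != post.shape:
        raise StatsError("image pair shapes differ")
    pre8 = np.clip(np.rint(pre), 0, 255).astype(np.uint8)
    level = otsu_level(image_histogram(pre8))
    if level.degenerate:
        raise StatsError("pre image is single-valued; no objects")
    binary = pre8 > level.level
    binary = dilation(binary, disk(1))
    distance = ndi.distance_transform_edt(binary)
    seeds = peak_local_max(distance, min_distance=5, labels=binary,
                           exclude_border=False)
    markers = np.zeros(pre.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    labels = watershed(-distance, markers, mask=binary)

    ids = np.arange(1, int(labels.max()) + 1)
    if len(ids) == 0:
        raise StatsError("no objects found in pre image")
    areas = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    keep = ids[areas > params.min_object_area]
    if len(keep) == 0:
        raise StatsError(
            f"no objects larger than {params.min_object_area} px")
    pre_means = ndi.mean(pre, labels, keep)
    post_means = ndi.mean(post, labels, keep)
    denom = float(np.mean(pre_means))
    if denom == 0:
        raise StatsError("zero mean pre-intensity")
    return 100.0 * float(np.mean(post_means)) / denom
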