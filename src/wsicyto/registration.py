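"""Brightfield-fluorescence registration from nuclear keypoints.

The haematoxylin channel of the de-convolved brightfield image is the
reference; the fluorescence nuclear channel is the moving image.  Both
are downscaled to working resolutions (haematoxylin 1.76 µm/px, nuclear
2.56 µm/px by default), blob keypoints are detected with a
scale-normalized determinant-of-Hessian detector (SURF family),
described by upright scale-normalized local patches, matched with a
ratio + mutual-consistency test, and an affine transform is estimated
by random-sample consensus followed by a least-squares refit on the
inliers.  Registered channels are resampled onto a common grid at
0.64 µm/px in the reference frame.

Transforms use homogeneous 3x3 matrices acting on (x, y) = (col, row)
pixel coordinates, mapping moving -> reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktf
from skimage.feature import match_descriptors as _sk_match
from skimage.measure import ransac as _sk_ransac

from .wsi_io import ChannelImage

WORK_RES_REFERENCE = 1.76  # µm/px, downscaled haematoxylin
WORK_RES_MOVING = 2.56     # µm/px, downscaled nuclear (DAPI/Hoechst)
OUTPUT_RESOLUTION = 0.64   # µm/px of the registered common grid


class RegistrationError(RuntimeError):
    """Registration failure; carries inlier/residual diagnostics."""


@dataclass(frozen=True)
class Keypoint:
    """A blob keypoint: sub-pixel position, scale, orientation, descriptor."""

    position: tuple[float, float]  # (row, col)
    scale: float
    orientation: float
    descriptor: np.ndarray
    response: float = 0.0


@dataclass
class AffineTransform:
    """2-D affine map moving -> reference in (x, y) pixel coordinates.

    ``matrix`` is homogeneous 3x3; ``resolution`` is the µm/px of the pixel
    grids the matrix relates.
    """

    matrix: np.ndarray
    resolution: float = OUTPUT_RESOLUTION

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape == (2, 3):
            m = np.vstack([m, [0.0, 0.0, 1.0]])
        if m.shape != (3, 3):
            raise ValueError(f"affine matrix must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        self.matrix = m

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        out = hom @ self.matrix.T
        return out[:, :2]

    @property
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.resolution)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Composition self(other(.)): apply ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix, self.resolution)

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the similarity part (degrees)."""
        a = self.matrix[:2, :2]
        return float(np.degrees(np.arctan2(a[1, 0], a[0, 0])))

    @property
    def scale(self) -> float:
        a = self.matrix[:2, :2]
        return float(np.sqrt(abs(np.linalg.det(a))))

    def rescaled(self, new_resolution: float) -> "AffineTransform":
        """Express the same physical map between grids at another µm/px."""
        f = self.resolution / new_resolution
        m = self.matrix.copy()
        m[:2, 2] *= f
        return AffineTransform(m, new_resolution)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"matrix": self.matrix.tolist(),
                              "resolution_um_per_px": self.resolution}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "AffineTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(np.asarray(d["matrix"]), float(d["resolution_um_per_px"]))

    @classmethod
    def identity(cls, resolution: float = OUTPUT_RESOLUTION) -> "AffineTransform":
        return cls(np.eye(3), resolution)


@dataclass
class RegistrationResult:
    transform: AffineTransform
    n_keypoints_reference: int
    n_keypoints_moving: int
    n_matches: int
    n_inliers: int
    rms_residual_px: float
    working_resolution: float


# ---------------------------------------------------------------------------
# keypoint detection and description
# ---------------------------------------------------------------------------

_DEFAULT_SIGMAS = (1.6, 2.26, 3.2, 4.53, 6.4, 9.05)
_PATCH_GRID = 12          # descriptor sampled on a 12x12 grid
_PATCH_RADIUS_SIGMAS = 6  # ... spanning +-6 sigma around the keypoint


def detect_and_describe(image: np.ndarray | ChannelImage,
                        sigmas: tuple[float, ...] = _DEFAULT_SIGMAS,
                        threshold: float = 5e-4,
                        max_keypoints: int = 2000) -> list[Keypoint]:
    """Detect blob keypoints and compute upright patch descriptors.

    The detector is a scale-normalized determinant-of-Hessian blob detector
    (``sigma^4 (Ixx Iyy - Ixy^2)`` over a fixed scale ladder) with sub-pixel
    quadratic refinement; descriptors are contrast-normalized local patches
    sampled on a grid proportional to the detected scale, so they are
    comparable across images of different pixel size.  Upright (unrotated)
    patches are used: adequate for the small (<~15 degree) rotations of
    re-mounted slide pairs.  Deterministic for a fixed input.
    """
    px = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    img = px.astype(np.float32) / 255.0
    if min(img.shape) < 16:
        raise RegistrationError(f"image {img.shape} smaller than minimum filter size")

    doh = np.empty((len(sigmas),) + img.shape, dtype=np.float32)
    for k, s in enumerate(sigmas):
        ixx = ndi.gaussian_filter(img, s, order=(0, 2))
        iyy = ndi.gaussian_filter(img, s, order=(2, 0))
        ixy = ndi.gaussian_filter(img, s, order=(1, 1))
        doh[k] = (s ** 4) * (ixx * iyy - ixy * ixy)

    # 3x3x3 local maxima above threshold
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (doh == ndi.maximum_filter(doh, footprint=footprint,
                                           mode="constant", cval=-np.inf))
    candidates = np.argwhere(local_max & (doh > threshold))
    if len(candidates) == 0:
        return []
    responses = doh[tuple(candidates.T)]
    order = np.argsort(-responses, kind="stable")
    candidates = candidates[order[:max_keypoints]]
    responses = responses[order[:max_keypoints]]

    keypoints = []
    for (k, r, c), resp in zip(candidates, responses):
        rr, cc = _subpixel_refine(doh[k], int(r), int(c))
        desc = _patch_descriptor(img, rr, cc, sigmas[k])
        if desc is None:
            continue
        keypoints.append(Keypoint(position=(rr, cc), scale=float(sigmas[k]),
                                  orientation=0.0, descriptor=desc,
                                  response=float(resp)))
    return keypoints


def _subpixel_refine(plane: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Quadratic sub-pixel peak refinement on a 3x3 neighbourhood."""
    if not (0 < r < plane.shape[0] - 1 and 0 < c < plane.shape[1] - 1):
        return float(r), float(c)
    patch = plane[r - 1:r + 2, c - 1:c + 2]
    dr = (patch[2, 1] - patch[0, 1]) / 2.0
    dc = (patch[1, 2] - patch[1, 0]) / 2.0
    drr = patch[2, 1] - 2 * patch[1, 1] + patch[0, 1]
    dcc = patch[1, 2] - 2 * patch[1, 1] + patch[1, 0]
    drc = (patch[2, 2] - patch[2, 0] - patch[0, 2] + patch[0, 0]) / 4.0
    det = drr * dcc - drc * drc
    if abs(det) < 1e-12:
        return float(r), float(c)
    off_r = -(dcc * dr - drc * dc) / det
    off_c = -(drr * dc - drc * dr) / det
    off_r = float(np.clip(off_r, -0.5, 0.5))
    off_c = float(np.clip(off_c, -0.5, 0.5))
    return r + off_r, c + off_c


def _patch_descriptor(img: np.ndarray, r: float, c: float,
                      sigma: float) -> np.ndarray | None:
    radius = _PATCH_RADIUS_SIGMAS * sigma
    lin = np.linspace(-radius, radius, _PATCH_GRID)
    rr = r + lin[:, None] + np.zeros((1, _PATCH_GRID))
    cc = c + lin[None, :] + np.zeros((_PATCH_GRID, 1))
    if (rr.min() < -radius or rr.max() > img.shape[0] - 1 + radius
            or cc.min() < -radius or cc.max() > img.shape[1] - 1 + radius):
        return None
    patch = ndi.map_coordinates(img, [rr.ravel(), cc.ravel()], order=1,
                                mode="nearest")
    patch = patch - patch.mean()
    norm = np.linalg.norm(patch)
    if norm < 1e-12:
        return None
    return (patch / norm).astype(np.float64)


def match_descriptors(a: list[Keypoint], b: list[Keypoint],
                      max_ratio: float = 0.75) -> list[tuple[int, int]]:
    """Mutual nearest-neighbour matches passing a Lowe-style ratio test."""
    if len(a) == 0 or len(b) == 0:
        return []
    da = np.stack([kp.descriptor for kp in a])
    db = np.stack([kp.descriptor for kp in b])
    if da.shape[1] != db.shape[1]:
        raise ValueError("descriptor lengths differ between keypoint sets")
    pairs = _sk_match(da, db, cross_check=True,
                      max_ratio=max_ratio if min(len(a), len(b)) > 1 else 1.0)
    return [tuple(p) for p in pairs]


# ---------------------------------------------------------------------------
# transform estimation
# ---------------------------------------------------------------------------

def least_squares_affine(src_xy: np.ndarray, dst_xy: np.ndarray) -> AffineTransform:
    """Closed-form least-squares affine fit (normal equations), src -> dst."""
    src = np.asarray(src_xy, dtype=float)
    dst = np.asarray(dst_xy, dtype=float)
    if len(src) < 3:
        raise RegistrationError(f"need >= 3 correspondences, got {len(src)}")
    design = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    m = np.eye(3)
    m[:2, :2] = coef[:2].T
    m[:2, 2] = coef[2]
    return AffineTransform(m)


@dataclass
class AffineEstimate:
    transform: AffineTransform
    inliers: np.ndarray
    rms_residual_px: float


def estimate_affine(src_xy: np.ndarray, dst_xy: np.ndarray,
                    residual_threshold: float = 2.0,
                    max_trials: int = 2000,
                    seed: int = 0,
                    min_inliers: int = 3) -> AffineEstimate:
    """Robust affine estimation: RANSAC consensus + least-squares refit.

    ``src``/``dst`` are matched (x, y) positions.  Consensus uses a fixed
    inlier threshold (px) and a seeded sampler, then the transform is refit
    in closed form on the inlier set.  Raises :class:`RegistrationError`
    with diagnostics when fewer than ``min_inliers`` inliers are found.
    """
    src = np.asarray(src_xy, dtype=float)
    dst = np.asarray(dst_xy, dtype=float)
    if len(src) != len(dst):
        raise ValueError("src and dst must have equal length")
    if len(src) < 3:
        raise RegistrationError(f"need >= 3 matches, got {len(src)}")

    if len(src) == 3:
        inliers = np.ones(3, dtype=bool)
    else:
        try:
            _, inliers = _sk_ransac(
                (src, dst), sktf.AffineTransform, min_samples=3,
                residual_threshold=residual_threshold, max_trials=max_trials,
                rng=seed)
        except Exception as exc:  # pragma: no cover - defensive
            raise RegistrationError(f"consensus search failed: {exc}") from exc
        if inliers is None or inliers.sum() < min_inliers:
            n = 0 if inliers is None else int(inliers.sum())
            raise RegistrationError(
                f"only {n} inliers (< {min_inliers}) at threshold "
                f"{residual_threshold} px")
    fit = least_squares_affine(src[inliers], dst[inliers])
    resid = np.linalg.norm(fit.apply(src[inliers]) - dst[inliers], axis=1)
    return AffineEstimate(transform=fit, inliers=inliers,
                          rms_residual_px=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# resampling and full modality registration
# ---------------------------------------------------------------------------

def rescale_channel(image: ChannelImage, target_resolution: float) -> ChannelImage:
    """Anti-aliased resampling of a channel to another µm/px."""
    return _rescale_exact(image, target_resolution)[0]


def _rescale_exact(image: ChannelImage, target_resolution: float,
                   ) -> tuple[ChannelImage, np.ndarray]:
    """Resample a channel and return the exact native->resampled pixel affine.

    ``skimage.transform.rescale`` aligns pixel centres and uses the realized
    integer-size ratio, so the coordinate map is
    ``x_out = (x_in + 0.5) * f' - 0.5`` with ``f' = out_size / in_size`` per
    axis; the returned 3x3 matrix encodes it in (x, y) coordinates.
    """
    factor = image.resolution / target_resolution
    out = sktf.rescale(image.pixels.astype(float) / 255.0, factor,
                       anti_aliasing=factor < 1, order=1)
    fy = out.shape[0] / image.pixels.shape[0]
    fx = out.shape[1] / image.pixels.shape[1]
    m = np.array([[fx, 0.0, 0.5 * fx - 0.5],
                  [0.0, fy, 0.5 * fy - 0.5],
                  [0.0, 0.0, 1.0]])
    px = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return ChannelImage(px, target_resolution, image.channel_name), m


def warp_to_reference(image: ChannelImage, transform: AffineTransform,
                      out_shape: tuple[int, int]) -> ChannelImage:
    """Resample a moving channel onto the reference grid.

    ``transform`` maps moving -> reference pixels at ``transform.resolution``
    (the output grid); the moving image may be at any native resolution.
    Bilinear interpolation, re-quantized to 8 bit.
    """
    native_to_out = np.diag([transform.resolution / image.resolution,
                             transform.resolution / image.resolution, 1.0])
    # output px -> moving output-res px -> moving native px, in (x, y)
    inv = native_to_out @ np.linalg.inv(transform.matrix)
    # scipy's affine_transform works in (row, col) = (y, x)
    (a, b, tx), (c, d, ty) = inv[0], inv[1]
    matrix_rc = np.array([[d, c], [b, a]])
    warped = ndi.affine_transform(image.pixels.astype(np.float32), matrix_rc,
                                  offset=(ty, tx), output_shape=out_shape,
                                  order=1, mode="constant", cval=0.0)
    return ChannelImage(np.clip(np.rint(warped), 0, 255).astype(np.uint8),
                        transform.resolution, image.channel_name)


def register_modalities(haematoxylin: ChannelImage,
                        nuclear_fl: ChannelImage,
                        work_res_reference: float = WORK_RES_REFERENCE,
                        work_res_moving: float = WORK_RES_MOVING,
                        output_resolution: float = OUTPUT_RESOLUTION,
                        residual_threshold: float = 2.0,
                        max_trials: int = 2000,
                        seed: int = 0) -> RegistrationResult:
    """Estimate the affine transform aligning nuclear FL to haematoxylin.

    Both inputs are downscaled to their working resolutions, keypoints are
    detected and matched, and the transform is estimated with the
    haematoxylin channel as the reference.  The returned transform maps
    moving (nuclear FL) pixels to reference pixels on grids at
    ``output_resolution`` µm/px.
    """
    ref_w, a_ref = _rescale_exact(haematoxylin, work_res_reference)
    mov_w, a_mov = _rescale_exact(nuclear_fl, work_res_moving)

    kp_ref = detect_and_describe(ref_w)
    kp_mov = detect_and_describe(mov_w)
    matches = match_descriptors(kp_ref, kp_mov)
    if len(matches) < 3:
        raise RegistrationError(
            f"{len(matches)} descriptor matches (need >= 3); "
            f"keypoints ref={len(kp_ref)} mov={len(kp_mov)}")
    # (x, y) = (col, row)
    ref_xy = np.array([[kp_ref[i].position[1], kp_ref[i].position[0]]
                       for i, _ in matches])
    mov_xy = np.array([[kp_mov[j].position[1], kp_mov[j].position[0]]
                       for _, j in matches])
    est = estimate_affine(mov_xy, ref_xy, residual_threshold=residual_threshold,
                          max_trials=max_trials, seed=seed)

    # convert the working-grid transform to the common output grid, going
    # through the exact native-grid coordinate maps of both resampled images:
    # x_ref_out = S_ref . inv(A_ref) . T . A_mov . inv(S_mov) . x_mov_out
    # where A_* are the native->working maps and S_* scale native px to
    # output px (pixel-centre-at-i*resolution convention).
    t_work = est.transform.matrix
    s_ref = haematoxylin.resolution / output_resolution
    s_mov = output_resolution / nuclear_fl.resolution
    m = (np.diag([s_ref, s_ref, 1.0]) @ np.linalg.inv(a_ref) @ t_work
         @ a_mov @ np.diag([s_mov, s_mov, 1.0]))
    transform = AffineTransform(m, output_resolution)
    return RegistrationResult(
        transform=transform,
        n_keypoints_reference=len(kp_ref),
        n_keypoints_moving=len(kp_mov),
        n_matches=len(matches),
        n_inliers=int(est.inliers.sum()),
        rms_residual_px=est.rms_residual_px,
        working_resolution=work_res_reference,
    )
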