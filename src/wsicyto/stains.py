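"""Colour de-convolution of chromogenic brightfield images.

Chromogen absorbances mix linearly in optical-density space
(Beer-Lambert): ``OD_k = -log10(I_k / 255)`` for each RGB channel ``k``,
and ``OD = C @ M`` where the rows of the stain matrix ``M`` are the unit
OD vectors of the individual stains.  De-convolution inverts ``M`` to
recover per-stain concentration maps; the forward model renders a
brightfield image from concentrations, which gives an exact round-trip
oracle for synthetic slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Published haematoxylin / eosin / DAB unit OD vectors (Ruifrok-Johnston
# convention).  The real VinaGreen / Liquid Permanent Red vectors are not
# published and must be supplied via configuration; these defaults serve
# synthetic fixtures and H-DAB development data.
RUIFROK_HAEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_EOSIN = (0.072, 0.990, 0.105)
RUIFROK_DAB = (0.268, 0.570, 0.776)

DEFAULT_DOWNSCALE = 4  # whole-slide images are 1:4 downscaled before OD conversion


class StainError(ValueError):
    pass


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise StainError("zero-length stain vector")
    return v / norms


@dataclass
class StainMatrix:
    """Three unit-norm stain OD vectors over (R, G, B), one row per stain."""

    vectors: np.ndarray
    names: tuple[str, str, str] = ("stain_1", "stain_2", "stain_3")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise StainError(f"stain matrix must be 3x3, got {v.shape}")
        v = _unit_rows(v)
        if abs(np.linalg.det(v)) < 1e-8:
            raise StainError("stain matrix is singular")
        self.vectors = v

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)

    @classmethod
    def hdab_default(cls) -> "StainMatrix":
        return cls(np.array([RUIFROK_HAEMATOXYLIN, RUIFROK_EOSIN, RUIFROK_DAB]),
                   names=("haematoxylin", "eosin", "dab"))

    def to_dict(self) -> dict:
        return {"names": list(self.names), "vectors": self.vectors.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(np.asarray(d["vectors"], dtype=float),
                   names=tuple(d.get("names", ("stain_1", "stain_2", "stain_3"))))


@dataclass
class ConcentrationMaps:
    """Per-stain concentration rasters plus de-convolution bookkeeping."""

    maps: dict[str, np.ndarray]
    downscale_factor: int = DEFAULT_DOWNSCALE
    clipped_fraction: float = 0.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def stain_names(self) -> list[str]:
        return list(self.maps)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to optical density per channel.

    ``OD_k = -log10(max(I_k, 1) / 255)``; the clamp at 1 keeps OD finite
    for fully absorbed pixels.  Float input is used as-is (32-bit floats
    stay 32-bit; whole-slide maps are memory-bound).
    """
    rgb = np.asarray(rgb)
    if rgb.dtype not in (np.float32, np.float64):
        rgb = rgb.astype(np.float64)
    return -np.log10(np.maximum(rgb, 1.0) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (continuous, before 8-bit quantization)."""
    return 255.0 * np.power(10.0, -np.asarray(od, dtype=float))


def complete_stain_matrix(v1, v2,
                          names: tuple[str, str, str] | None = None) -> StainMatrix:
    """Complete a 2-stain panel to a full 3x3 matrix.

    The third vector is the normalized cross product of the two given unit
    vectors, i.e. the residual colour direction orthogonal to both stains.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    third = np.cross(v1, v2)
    norm = np.linalg.norm(third)
    if norm < 1e-8:
        raise StainError("stain vectors are parallel; cannot complete matrix")
    third = np.abs(third) / norm  # keep OD components nonnegative by convention
    if names is None:
        names = ("stain_1", "stain_2", "residual")
    return StainMatrix(np.stack([v1, v2, third]), names=names)


def render_brightfield(concentration_maps: dict[str, np.ndarray] | ConcentrationMaps,
                       stain_matrix: StainMatrix) -> np.ndarray:
    """Render an RGB brightfield raster from stain concentrations.

    Beer-Lambert forward model: ``I_k = 255 * 10^(-sum_s c_s M[s, k])``,
    clipped to [0, 255].  Returned as float; quantize with
    ``np.rint(...).astype(np.uint8)`` for an 8-bit image.
    """
    if isinstance(concentration_maps, ConcentrationMaps):
        concentration_maps = concentration_maps.maps
    arrays = [np.asarray(concentration_maps[n]) for n in stain_matrix.names]
    dtype = (np.float32 if all(a.dtype == np.float32 for a in arrays)
             else np.float64)
    stack = np.stack([a.astype(dtype, copy=False) for a in arrays], axis=-1)
    if np.any(stack < 0):
        raise StainError("negative stain concentration")
    od = stack @ stain_matrix.vectors.astype(dtype)
    return np.clip(255.0 * np.power(10.0, -od), 0.0, 255.0)


def downscale_area(rgb: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downscale by an integer factor (mimics optical blur)."""
    rgb = np.asarray(rgb)
    if rgb.dtype not in (np.float32, np.float64):
        rgb = rgb.astype(np.float32)
    if factor == 1:
        return rgb
    h, w = rgb.shape[:2]
    th, tw = (h // factor) * factor, (w // factor) * factor
    crop = rgb[:th, :tw]
    shape = (th // factor, factor, tw // factor, factor) + crop.shape[2:]
    return crop.reshape(shape).mean(axis=(1, 3))


def deconvolve(rgb: np.ndarray, matrix: StainMatrix,
               downscale: int = DEFAULT_DOWNSCALE) -> ConcentrationMaps:
    """Separate an RGB brightfield image into per-stain concentration maps.

    The image is area-averaged down by ``downscale`` (whole-slide default
    1:4), converted to OD, and multiplied by the inverse stain matrix.
    Negative concentrations are clipped to zero; the clipped pixel fraction
    is recorded on the result.
    """
    if downscale < 1:
        raise StainError(f"downscale must be >= 1, got {downscale}")
    small = downscale_area(rgb, downscale)
    od = rgb_to_od(small)
    conc = od @ matrix.inverse.astype(od.dtype)
    clipped = float(np.mean(conc < -1e-9))
    conc = np.maximum(conc, 0.0)
    maps = {name: np.ascontiguousarray(conc[..., i])
            for i, name in enumerate(matrix.names)}
    return ConcentrationMaps(maps, downscale_factor=downscale,
                             clipped_fraction=clipped)
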