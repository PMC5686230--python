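"""Image/table I/O and the tile-pad-stitch machinery for whole-slide analysis.

Whole-slide images are processed as a grid of *core* tiles (default
2048 x 2048 px).  Each core is embedded in a larger *context* window
(default 10240 x 10240 px) so that structures that straddle a core
boundary — epithelial glands in particular — are fully visible to the
per-tile analysis.  Results are stitched back by keeping only objects
whose centroid falls inside the half-open core of their tile, which
guarantees each object is reported exactly once.

Conventions: 0-based (row, col) pixel coordinates and half-open pixel
intervals [origin, origin + size) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

DEFAULT_CORE_SIZE = 2048
DEFAULT_CONTEXT_SIZE = 10240


class TilingError(ValueError):
    """Raised for inconsistent tile plans."""


@dataclass(frozen=True)
class ChannelImage:
    """A single named 8-bit channel with physical pixel size.

    Parameters
    ----------
    pixels:
        2-D ``uint8`` raster.
    resolution:
        Pixel size in µm/px (square pixels assumed).
    channel_name:
        Name of the stain/fluorochrome channel (e.g. ``"dapi"``).
    """

    pixels: np.ndarray
    resolution: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"channel raster must be 2-D, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"channel raster must be uint8, got {px.dtype}")
        if not (self.resolution > 0):
            raise ValueError(f"resolution must be > 0 µm/px, got {self.resolution}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MultiplexSlide:
    """Co-registered named channels on a common pixel grid."""

    channels: dict[str, ChannelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        res = {c.resolution for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if len(res) > 1:
            raise ValueError(f"channels disagree on resolution: {res}")

    def __getitem__(self, name: str) -> ChannelImage:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def resolution(self) -> float:
        first = next(iter(self.channels.values()))
        return first.resolution


@dataclass(frozen=True)
class TileSpec:
    """One tile of a slide: a core region plus its padded context window.

    ``core_origin``/``core_shape`` describe the half-open core rectangle in
    slide coordinates; cores of a plan partition the slide exactly.  The
    context window is centred on the core and may extend beyond the slide;
    out-of-slide context pixels are zero-filled on extraction.
    """

    index: int
    core_origin: tuple[int, int]
    core_shape: tuple[int, int]
    context_origin: tuple[int, int]
    context_shape: tuple[int, int]

    def core_slices(self) -> tuple[slice, slice]:
        (r, c), (h, w) = self.core_origin, self.core_shape
        return slice(r, r + h), slice(c, c + w)

    def core_in_context(self) -> tuple[slice, slice]:
        """Core rectangle expressed in context-local coordinates."""
        dr = self.core_origin[0] - self.context_origin[0]
        dc = self.core_origin[1] - self.context_origin[1]
        return (slice(dr, dr + self.core_shape[0]),
                slice(dc, dc + self.core_shape[1]))

    def contains_global(self, row: float, col: float) -> bool:
        """Half-open core membership for a global (row, col) centroid."""
        (r, c), (h, w) = self.core_origin, self.core_shape
        return (r <= row < r + h) and (c <= col < c + w)


def plan_tiles(slide_shape: tuple[int, int],
               core_size: int = DEFAULT_CORE_SIZE,
               context_size: int = DEFAULT_CONTEXT_SIZE) -> list[TileSpec]:
    """Partition a slide into core tiles with centred context windows.

    Produces ``ceil(rows/core) * ceil(cols/core)`` tiles whose cores tile the
    slide exactly (edge cores are clipped to the slide bounds).  Each context
    window has the full ``context_size`` square shape, centred on its core;
    it may extend beyond the slide.
    """
    rows, cols = slide_shape
    if core_size <= 0:
        raise TilingError(f"core_size must be positive, got {core_size}")
    if context_size < core_size:
        raise TilingError(
            f"context_size ({context_size}) must be >= core_size ({core_size})")
    if rows <= 0 or cols <= 0:
        raise TilingError(f"slide shape must be positive, got {slide_shape}")

    tiles: list[TileSpec] = []
    idx = 0
    for r0 in range(0, rows, core_size):
        ch = min(core_size, rows - r0)
        for c0 in range(0, cols, core_size):
            cw = min(core_size, cols - c0)
            # centre context on the (clipped) core
            ctx_r = r0 + ch // 2 - context_size // 2
            ctx_c = c0 + cw // 2 - context_size // 2
            tiles.append(TileSpec(
                index=idx,
                core_origin=(r0, c0),
                core_shape=(ch, cw),
                context_origin=(ctx_r, ctx_c),
                context_shape=(context_size, context_size),
            ))
            idx += 1
    return tiles


def extract_tile(image: np.ndarray | ChannelImage, tile: TileSpec) -> np.ndarray:
    """Extract a tile's context window, zero-filling beyond the slide."""
    px = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    rows, cols = px.shape[:2]
    (r0, c0), (h, w) = tile.context_origin, tile.context_shape
    core_r, core_c = tile.core_origin
    if not (0 <= core_r < rows and 0 <= core_c < cols):
        raise TilingError(f"tile {tile.index} inconsistent with image shape {px.shape}")
    out = np.zeros((h, w) + px.shape[2:], dtype=px.dtype)
    src_r0, src_r1 = max(r0, 0), min(r0 + h, rows)
    src_c0, src_c1 = max(c0, 0), min(c0 + w, cols)
    if src_r0 < src_r1 and src_c0 < src_c1:
        out[src_r0 - r0:src_r1 - r0, src_c0 - c0:src_c1 - c0] = \
            px[src_r0:src_r1, src_c0:src_c1]
    return out


def stitch_cells(per_tile_cells: list[pd.DataFrame],
                 tiles: list[TileSpec],
                 local_row: str = "centroid_row_px",
                 local_col: str = "centroid_col_px") -> pd.DataFrame:
    """Merge per-tile cell tables, deduplicating via the half-open core rule.

    Each table holds context-local centroids for one tile.  A record is kept
    iff its centroid, converted to global slide coordinates, lies inside its
    own tile's half-open core — so a cell detected in several overlapping
    context windows survives exactly once.  Output centroids are global.
    """
    if len(per_tile_cells) != len(tiles):
        raise TilingError(
            f"{len(per_tile_cells)} cell tables for {len(tiles)} tiles")
    kept = []
    for df, tile in zip(per_tile_cells, tiles):
        if df is None or len(df) == 0:
            continue
        df = df.copy()
        g_row = df[local_row].to_numpy(float) + tile.context_origin[0]
        g_col = df[local_col].to_numpy(float) + tile.context_origin[1]
        (r, c), (h, w) = tile.core_origin, tile.core_shape
        in_core = (g_row >= r) & (g_row < r + h) & (g_col >= c) & (g_col < c + w)
        df[local_row] = g_row
        df[local_col] = g_col
        df["tile_index"] = tile.index
        kept.append(df.loc[in_core])
    if not kept:
        return pd.DataFrame(columns=[local_row, local_col, "tile_index"])
    out = pd.concat(kept, ignore_index=True)
    out.insert(0, "cell_id", np.arange(1, len(out) + 1))
    return out


def stitch_labels(per_tile_label_masks: list[np.ndarray],
                  tiles: list[TileSpec],
                  slide_shape: tuple[int, int]) -> np.ndarray:
    """Mosaic per-tile label masks from core regions, keeping ids unique.

    Each tile's mask is given in context-local coordinates; only its core
    region is copied into the mosaic.  Labels are offset per tile and then
    compressed to a contiguous 1..N range.
    """
    if len(per_tile_label_masks) != len(tiles):
        raise TilingError(
            f"{len(per_tile_label_masks)} masks for {len(tiles)} tiles")
    mosaic = np.zeros(slide_shape, dtype=np.int64)
    offset = 0
    for mask, tile in zip(per_tile_label_masks, tiles):
        mask = np.asarray(mask)
        if mask.shape != tuple(tile.context_shape):
            raise TilingError(
                f"tile {tile.index}: mask shape {mask.shape} != context "
                f"{tile.context_shape}")
        core_local = mask[tile.core_in_context()]
        dest = mosaic[tile.core_slices()]
        nz = core_local > 0
        dest[nz] = core_local[nz].astype(np.int64) + offset
        if core_local.max() > 0:
            offset += int(core_local.max())
    # compress ids to contiguous 1..N
    ids = np.unique(mosaic)
    ids = ids[ids > 0]
    lut = np.zeros(int(mosaic.max()) + 1, dtype=np.int64)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[mosaic]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_channel_tiff(path: str | Path, image: ChannelImage) -> None:
    meta = {"resolution_um_per_px": image.resolution,
            "channel_name": image.channel_name}
    tifffile.imwrite(str(path), image.pixels, description=json.dumps(meta))


def read_channel_tiff(path: str | Path,
                      resolution: float | None = None,
                      channel_name: str | None = None) -> ChannelImage:
    with tifffile.TiffFile(str(path)) as tf:
        px = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    res = resolution if resolution is not None else meta.get("resolution_um_per_px")
    if res is None:
        raise ValueError(f"{path}: no resolution stored; pass resolution=")
    name = channel_name or meta.get("channel_name") or Path(path).stem
    return ChannelImage(px.astype(np.uint8), float(res), name)


def write_rgb_tiff(path: str | Path, rgb: np.ndarray,
                   resolution: float | None = None) -> None:
    meta = {"resolution_um_per_px": resolution} if resolution else {}
    tifffile.imwrite(str(path), np.asarray(rgb, dtype=np.uint8),
                     photometric="rgb", description=json.dumps(meta))


def read_rgb_tiff(path: str | Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(str(path)) as tf:
        px = tf.asarray()
        desc = tf.pages[0].description
    res = None
    if desc:
        try:
            res = json.loads(desc).get("resolution_um_per_px")
        except (json.JSONDecodeError, TypeError):
            pass
    return px, res


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        tifffile.imwrite(str(path), labels.astype(np.uint32))
    else:
        tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def write_cell_table(path: str | Path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
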