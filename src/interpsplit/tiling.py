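"""Up-sample / split and merge / down-sample machinery.

A slice is magnified by an integer interpolation ratio ``ir`` (bilinear for
images, nearest-neighbour for masks), cut into fixed-size non-overlapping
tiles, and the inverse path (merge tiles, nearest-neighbour down-sample)
reconstructs a prediction at the original slice resolution.

All four resampling directions share one grid convention: the source
coordinate of output pixel ``o`` is ``(o + 0.5) / ir - 0.5`` (half-pixel
centres), clamped to the source extent, with nearest-neighbour ties resolved
toward the smaller index.  Sharing the convention is what makes
``downsample_nn(upsample_mask(m, ir), ir) == m`` an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InterpolationConfig",
    "TileGrid",
    "TileSet",
    "upsample_image",
    "upsample_mask",
    "split_tiles",
    "count_tiles",
    "count_dataset_tiles",
    "merge_tiles",
    "downsample_nn",
    "prepare_pair",
    "reconstruct_prediction",
]

DEFAULT_TILE_SIZE = 512


def _check_ir(ir) -> int:
    if isinstance(ir, bool) or not isinstance(ir, (int, np.integer)):
        raise ValueError(f"interpolation ratio must be an integer, got {ir!r}")
    if ir < 1:
        raise ValueError(f"interpolation ratio must be >= 1, got {ir}")
    return int(ir)


@dataclass(frozen=True)
class InterpolationConfig:
    """Parameters of one interpolation + split pass."""

    ir: int = 1
    tile_size: int = DEFAULT_TILE_SIZE
    image_interp: str = "bilinear"
    mask_interp: str = "nearest"

    def __post_init__(self) -> None:
        _check_ir(self.ir)
        if self.tile_size < 8:
            raise ValueError(f"tile_size must be >= 8, got {self.tile_size}")
        if self.image_interp != "bilinear":
            raise ValueError("image_interp: only 'bilinear' is supported")
        if self.mask_interp != "nearest":
            raise ValueError("mask_interp: only 'nearest' is supported")


@dataclass(frozen=True)
class TileGrid:
    """Bookkeeping of one split: geometry needed for a lossless merge.

    ``source_shape`` is the pre-interpolation slice shape, ``canvas_shape``
    the interpolated shape before padding, ``padded_shape`` the canvas after
    edge-replicate padding to a multiple of ``tile_size``.  Tiles are ordered
    row-major.
    """

    ir: int
    tile_size: int
    n_rows: int
    n_cols: int
    source_shape: tuple[int, int]
    canvas_shape: tuple[int, int]
    padded_shape: tuple[int, int]

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel bounds ``(r0, r1, c0, c1)`` of a tile on the padded canvas."""
        T = self.tile_size
        return row * T, (row + 1) * T, col * T, (col + 1) * T

    def to_dict(self) -> dict:
        return {
            "ir": self.ir,
            "tile_size": self.tile_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "source_shape": list(self.source_shape),
            "canvas_shape": list(self.canvas_shape),
            "padded_shape": list(self.padded_shape),
            "ordering": "row-major",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TileGrid":
        return cls(
            ir=int(d["ir"]),
            tile_size=int(d["tile_size"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            source_shape=tuple(d["source_shape"]),
            canvas_shape=tuple(d["canvas_shape"]),
            padded_shape=tuple(d["padded_shape"]),
        )


@dataclass
class TileSet:
    """An ordered, row-major list of tiles plus the grid they came from."""

    tiles: list[np.ndarray]
    grid: TileGrid
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.tiles) != self.grid.n_tiles:
            raise ValueError(
                f"tile count {len(self.tiles)} does not match grid "
                f"{self.grid.n_rows}x{self.grid.n_cols}"
            )
        T = self.grid.tile_size
        for i, t in enumerate(self.tiles):
            if t.shape != (T, T):
                raise ValueError(f"tile {i} has shape {t.shape}, expected {(T, T)}")


def _src_coords(n_out: int, ir: int, n_src: int) -> np.ndarray:
    x = (np.arange(n_out) + 0.5) / ir - 0.5
    return np.clip(x, 0.0, float(n_src - 1))


def _nn_up_indices(n_out: int, ir: int, n_src: int) -> np.ndarray:
    # nearest index of (o+0.5)/ir - 0.5, ties toward the smaller index
    x = (np.arange(n_out) + 0.5) / ir - 0.5
    idx = np.ceil(x - 0.5).astype(np.intp)
    return np.clip(idx, 0, n_src - 1)


def _nn_down_indices(n_out: int, ir: int, n_src: int) -> np.ndarray:
    x = (np.arange(n_out) + 0.5) * ir - 0.5
    idx = np.ceil(x - 0.5).astype(np.intp)
    return np.clip(idx, 0, n_src - 1)


def upsample_image(image: np.ndarray, ir: int) -> np.ndarray:
    """Bilinearly up-sample a 2D image by an integer factor.

    ``ir=1`` is the bit-exact identity.  Output dtype is float64 for
    ``ir > 1``; bilinear weights are convex so the output range never
    exceeds the input range.
    """
    ir = _check_ir(ir)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if ir == 1:
        return image.copy()
    h, w = image.shape
    img = image.astype(np.float64, copy=False)
    ys = _src_coords(h * ir, ir, h)
    xs = _src_coords(w * ir, ir, w)
    y0 = np.clip(np.floor(ys).astype(np.intp), 0, max(h - 2, 0))
    x0 = np.clip(np.floor(xs).astype(np.intp), 0, max(w - 2, 0))
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    top = (1.0 - wx) * img[np.ix_(y0, x0)] + wx * img[np.ix_(y0, x1)]
    bot = (1.0 - wx) * img[np.ix_(y1, x0)] + wx * img[np.ix_(y1, x1)]
    return (1.0 - wy) * top + wy * bot


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask is not binary; found values {vals[:10]}")
    return mask


def upsample_mask(mask: np.ndarray, ir: int) -> np.ndarray:
    """Nearest-neighbour up-sample of a binary mask.

    For integer ``ir`` the shared grid convention replicates each source
    pixel into an ``ir x ir`` block, so foreground counts scale by ``ir**2``.
    """
    ir = _check_ir(ir)
    mask = _check_binary(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {mask.shape}")
    if ir == 1:
        return mask.copy()
    h, w = mask.shape
    iy = _nn_up_indices(h * ir, ir, h)
    ix = _nn_up_indices(w * ir, ir, w)
    return mask[np.ix_(iy, ix)]


def count_tiles(height: int, width: int, ir: int, tile_size: int = DEFAULT_TILE_SIZE) -> int:
    """Closed-form tile count: ``ceil(h*ir/T) * ceil(w*ir/T)``."""
    ir = _check_ir(ir)
    if height < 1 or width < 1 or tile_size < 1:
        raise ValueError("height, width and tile_size must be positive")
    n_rows = -(-height * ir // tile_size)
    n_cols = -(-width * ir // tile_size)
    return int(n_rows * n_cols)


def count_dataset_tiles(
    n_slices: int,
    irs: Sequence[int],
    slice_shape: tuple[int, int] = (512, 512),
    tile_size: int = DEFAULT_TILE_SIZE,
) -> int:
    """Total tiles over a dataset of identical slices and a set of ratios."""
    if n_slices < 0:
        raise ValueError("n_slices must be >= 0")
    h, w = slice_shape
    return sum(n_slices * count_tiles(h, w, ir, tile_size) for ir in irs)


def split_tiles(
    image: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    ir: int = 1,
    slice_index: int | None = None,
) -> TileSet:
    """Split a canvas into non-overlapping row-major ``T x T`` tiles.

    Dimensions not divisible by ``tile_size`` are edge-replicate padded up to
    the next multiple; the grid records both shapes so the merge can crop the
    padding back off.  ``ir`` is provenance only (the canvas is assumed to be
    the ``ir``-fold interpolation of a source slice).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2D image, got shape {image.shape}")
    if tile_size < 8:
        raise ValueError(f"tile_size must be >= 8, got {tile_size}")
    ir = _check_ir(ir)
    h, w = image.shape
    if h % ir or w % ir:
        raise ValueError(f"canvas shape {image.shape} is not divisible by ir={ir}")
    T = tile_size
    n_rows = -(-h // T)
    n_cols = -(-w // T)
    ph, pw = n_rows * T, n_cols * T
    canvas = image
    if (ph, pw) != (h, w):
        canvas = np.pad(image, ((0, ph - h), (0, pw - w)), mode="edge")
    grid = TileGrid(
        ir=ir,
        tile_size=T,
        n_rows=n_rows,
        n_cols=n_cols,
        source_shape=(h // ir, w // ir),
        canvas_shape=(h, w),
        padded_shape=(ph, pw),
    )
    tiles = [
        canvas[r * T : (r + 1) * T, c * T : (c + 1) * T].copy()
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return TileSet(tiles=tiles, grid=grid, slice_index=slice_index)


def merge_tiles(tileset: TileSet) -> np.ndarray:
    """Reassemble the padded canvas and crop the padding: exact inverse of
    :func:`split_tiles` (``merge_tiles(split_tiles(x)) == x`` bit-exactly)."""
    grid = tileset.grid
    T = grid.tile_size
    if len(tileset.tiles) != grid.n_tiles:
        raise ValueError("tile count does not match grid")
    canvas = np.empty(grid.padded_shape, dtype=np.result_type(*tileset.tiles))
    k = 0
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            tile = tileset.tiles[k]
            if tile.shape != (T, T):
                raise ValueError(f"tile {k} has shape {tile.shape}, expected {(T, T)}")
            canvas[r * T : (r + 1) * T, c * T : (c + 1) * T] = tile
            k += 1
    h, w = grid.canvas_shape
    return canvas[:h, :w]


def downsample_nn(canvas: np.ndarray, ir: int) -> np.ndarray:
    """Nearest-neighbour down-sample by an integer factor (shared convention).

    Exactly inverts :func:`upsample_mask`.
    """
    ir = _check_ir(ir)
    canvas = np.asarray(canvas)
    if canvas.ndim != 2:
        raise ValueError(f"expected a 2D canvas, got shape {canvas.shape}")
    if ir == 1:
        return canvas.copy()
    h, w = canvas.shape
    if h % ir or w % ir:
        raise ValueError(f"canvas shape {canvas.shape} not divisible by ir={ir}")
    iy = _nn_down_indices(h // ir, ir, h)
    ix = _nn_down_indices(w // ir, ir, w)
    return canvas[np.ix_(iy, ix)]


def prepare_pair(
    slice_image: np.ndarray,
    mask: np.ndarray,
    config: InterpolationConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build aligned (image tile, mask tile) training pairs for one slice."""
    slice_image = np.asarray(slice_image)
    mask = np.asarray(mask)
    if slice_image.shape != mask.shape:
        raise ValueError(
            f"slice shape {slice_image.shape} != mask shape {mask.shape}"
        )
    img_up = upsample_image(slice_image, config.ir)
    msk_up = upsample_mask(mask, config.ir)
    img_ts = split_tiles(img_up, config.tile_size, ir=config.ir)
    msk_ts = split_tiles(msk_up, config.tile_size, ir=config.ir)
    return list(zip(img_ts.tiles, msk_ts.tiles))


def reconstruct_prediction(pred_tiles: TileSet, ir: int) -> np.ndarray:
    """Merge predicted probability tiles and down-sample to source resolution."""
    ir = _check_ir(ir)
    if pred_tiles.grid.ir != ir:
        raise ValueError(
            f"ir={ir} does not match the grid's ir={pred_tiles.grid.ir}"
        )
    for i, t in enumerate(pred_tiles.tiles):
        if np.min(t) < 0.0 or np.max(t) > 1.0:
            raise ValueError(f"tile {i} has values outside [0, 1]")
    canvas = merge_tiles(pred_tiles)
    return downsample_nn(canvas, ir)
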