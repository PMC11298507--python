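"""Bilinear interpolation primitives and resampling-artefact analyses.

Provides the four-corner bilinear estimator, the crop-then-upscale
comparator (up-scale each crop independently, reassemble in place), seam
discontinuity statistics, intensity profiles, and a diagonal-Laplacian
sharpness score with a paired t-test harness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tiling import TileGrid, upsample_image

__all__ = [
    "BilinearCell",
    "SeamReport",
    "SharpnessStudy",
    "bilinear_point",
    "crop_then_upscale",
    "intensity_profile",
    "seam_discontinuity",
    "diagonal_laplacian_sharpness",
    "paired_sharpness_study",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BilinearCell:
    """Four known corner samples and a query point inside their rectangle.

    ``f11`` sits at ``(x1, y1)``, ``f21`` at ``(x2, y1)``, ``f12`` at
    ``(x1, y2)`` and ``f22`` at ``(x2, y2)``; ``x`` is the lateral (column)
    and ``y`` the axial (row) coordinate of the query.
    """

    f11: float
    f21: float
    f12: float
    f22: float
    x1: float
    x2: float
    y1: float
    y2: float
    x: float
    y: float


def bilinear_point(cell: BilinearCell) -> float:
    """Evaluate the bilinear estimate at the cell's query point.

    Linear interpolation along x on each row of corners gives the two
    row-interpolants; a final linear interpolation along y combines them.
    Exact at corners, linear along each edge, and exact for any affine
    function of position.
    """
    if cell.x1 >= cell.x2 or cell.y1 >= cell.y2:
        raise ValueError(
            f"degenerate cell: x1={cell.x1}, x2={cell.x2}, y1={cell.y1}, y2={cell.y2}"
        )
    if not (cell.x1 <= cell.x <= cell.x2 and cell.y1 <= cell.y <= cell.y2):
        raise ValueError("query point lies outside the cell")
    dx = cell.x2 - cell.x1
    dy = cell.y2 - cell.y1
    f_c1 = (cell.x2 - cell.x) / dx * cell.f11 + (cell.x - cell.x1) / dx * cell.f21
    f_c2 = (cell.x2 - cell.x) / dx * cell.f12 + (cell.x - cell.x1) / dx * cell.f22
    return (cell.y2 - cell.y) / dy * f_c1 + (cell.y - cell.y1) / dy * f_c2


def crop_then_upscale(image: np.ndarray, block: int, ir: int) -> np.ndarray:
    """The comparator technique: crop first, then up-scale each crop.

    The image is partitioned into ``block x block`` crops, each crop is
    bilinearly up-scaled by ``ir`` independently (edges clamped per crop),
    and the results are reassembled in place.  Independent per-crop edge
    clamping is what creates seam discontinuities.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    h, w = image.shape
    if h % block or w % block:
        raise ValueError(f"image shape {image.shape} not divisible by block={block}")
    if ir == 1:
        return image.copy()
    out = np.empty((h * ir, w * ir), dtype=np.float64)
    B = block * ir
    for r in range(h // block):
        for c in range(w // block):
            crop = image[r * block : (r + 1) * block, c * block : (c + 1) * block]
            out[r * B : (r + 1) * B, c * B : (c + 1) * B] = upsample_image(crop, ir)
    return out


def intensity_profile(canvas: np.ndarray, axis: str, index: int) -> np.ndarray:
    """Extract one row (``axis='row'``) or column (``axis='column'``)."""
    canvas = np.asarray(canvas)
    if canvas.ndim != 2:
        raise ValueError(f"expected a 2D canvas, got shape {canvas.shape}")
    if axis == "row":
        if not 0 <= index < canvas.shape[0]:
            raise IndexError(f"row index {index} out of range for {canvas.shape}")
        return canvas[index, :].copy()
    if axis == "column":
        if not 0 <= index < canvas.shape[1]:
            raise IndexError(f"column index {index} out of range for {canvas.shape}")
        return canvas[:, index].copy()
    raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")


@dataclass(frozen=True)
class SeamReport:
    """Adjacent-pixel step statistics at and away from tile boundaries."""

    seam_step: float
    interior_step: float

    @property
    def discontinuity(self) -> float:
        return self.seam_step - self.interior_step

    def to_dict(self) -> dict:
        return {
            "seam_step": self.seam_step,
            "interior_step": self.interior_step,
            "discontinuity": self.discontinuity,
        }


def _seams_from_grid(grid: TileGrid, shape: tuple[int, int]) -> tuple[list[int], list[int]]:
    T = grid.tile_size
    rows = [r * T for r in range(1, grid.n_rows) if 0 < r * T < shape[0]]
    cols = [c * T for c in range(1, grid.n_cols) if 0 < c * T < shape[1]]
    return rows, cols


def seam_discontinuity(
    canvas: np.ndarray,
    seams: tuple[list[int], list[int]] | None = None,
    grid: TileGrid | None = None,
    exclude_border: int = 0,
) -> SeamReport:
    """Mean absolute adjacent-pixel step across seams vs. elsewhere.

    ``seams`` is ``(row_positions, col_positions)`` where position ``s``
    marks the boundary between index ``s-1`` and ``s``; alternatively pass
    the ``TileGrid`` of the split that produced the canvas.  A border margin
    of ``exclude_border`` pixels is dropped on every side before the
    statistic is taken — with half-pixel-centre resampling the outermost
    ``ir // 2`` pixels are edge-clamped and would otherwise bias the
    interior step of an up-sampled ramp.
    """
    canvas = np.asarray(canvas, dtype=np.float64)
    if canvas.ndim != 2:
        raise ValueError(f"expected a 2D canvas, got shape {canvas.shape}")
    if seams is None:
        if grid is None:
            raise ValueError("provide either seam positions or a TileGrid")
        seams = _seams_from_grid(grid, canvas.shape)
    row_seams, col_seams = (sorted(set(seams[0])), sorted(set(seams[1])))
    m = exclude_border
    sub = canvas[m : canvas.shape[0] - m or None, m : canvas.shape[1] - m or None]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("canvas too small after border exclusion")
    row_seams = [s - m for s in row_seams if 1 <= s - m <= sub.shape[0] - 1]
    col_seams = [s - m for s in col_seams if 1 <= s - m <= sub.shape[1] - 1]
    if not row_seams and not col_seams:
        raise ValueError("no seam position lies strictly inside the canvas")

    dr = np.abs(np.diff(sub, axis=0))  # dr[b-1] is the step across row boundary b
    dc = np.abs(np.diff(sub, axis=1))
    row_mask = np.zeros(dr.shape[0], dtype=bool)
    row_mask[[s - 1 for s in row_seams]] = True
    col_mask = np.zeros(dc.shape[1], dtype=bool)
    col_mask[[s - 1 for s in col_seams]] = True

    seam_vals = np.concatenate([dr[row_mask].ravel(), dc[:, col_mask].ravel()])
    interior_vals = np.concatenate([dr[~row_mask].ravel(), dc[:, ~col_mask].ravel()])
    seam_step = float(seam_vals.mean()) if seam_vals.size else 0.0
    interior_step = float(interior_vals.mean()) if interior_vals.size else 0.0
    return SeamReport(seam_step=seam_step, interior_step=interior_step)


def diagonal_laplacian_sharpness(image: np.ndarray) -> float:
    """Diagonal second-difference focus measure.

    Mean over interior pixels of
    ``|2*I(r,c) - I(r-1,c-1) - I(r+1,c+1)| + |2*I(r,c) - I(r-1,c+1) - I(r+1,c-1)|``.
    Zero iff both diagonal second differences vanish everywhere; translation
    invariant; scales linearly with contrast.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got shape {image.shape}")
    c = image[1:-1, 1:-1]
    d_main = np.abs(2.0 * c - image[:-2, :-2] - image[2:, 2:])
    d_anti = np.abs(2.0 * c - image[:-2, 2:] - image[2:, :-2])
    return float((d_main + d_anti).mean())


@dataclass(frozen=True)
class SharpnessStudy:
    """Paired sharpness comparison between two sub-image production routes."""

    existing_sharpness: np.ndarray
    interpsplit_sharpness: np.ndarray
    existing_mean: float
    existing_sd: float
    interpsplit_mean: float
    interpsplit_sd: float
    mean_difference: float
    sd_difference: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "existing_mean": self.existing_mean,
            "existing_sd": self.existing_sd,
            "interpsplit_mean": self.interpsplit_mean,
            "interpsplit_sd": self.interpsplit_sd,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def paired_sharpness_study(pairs) -> SharpnessStudy:
    """Paired t-test on diagonal-Laplacian sharpness.

    ``pairs`` is a sequence of ``(existing sub-image, interpolation-split
    sub-image)``; differences are interpolation-split minus existing.  The
    p-value is two-sided with ``n - 1`` degrees of freedom.  All-zero
    differences are reported as degenerate (t undefined); zero spread with a
    nonzero mean is reported as infinite t with p = 0.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(pairs)}")
    s_exist = np.array([diagonal_laplacian_sharpness(a) for a, _ in pairs])
    s_split = np.array([diagonal_laplacian_sharpness(b) for _, b in pairs])
    d = s_split - s_exist
    n = len(d)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    degenerate = False
    if sd_d == 0.0:
        if mean_d == 0.0:
            t_stat, p_val, degenerate = math.nan, math.nan, True
            log.warning("all paired differences are zero; t statistic is undefined")
        else:
            t_stat = math.inf if mean_d > 0 else -math.inf
            p_val = 0.0
    else:
        t_stat = mean_d / (sd_d / math.sqrt(n))
        p_val = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return SharpnessStudy(
        existing_sharpness=s_exist,
        interpsplit_sharpness=s_split,
        existing_mean=float(s_exist.mean()),
        existing_sd=float(s_exist.std(ddof=1)),
        interpsplit_mean=float(s_split.mean()),
        interpsplit_sd=float(s_split.std(ddof=1)),
        mean_difference=mean_d,
        sd_difference=sd_d,
        t_statistic=t_stat,
        p_value=p_val,
        n=n,
        degenerate=degenerate,
    )
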