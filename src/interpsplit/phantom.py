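"""Synthetic HRCT-like airway-tree phantoms with exact ground truth.

A seeded recursive binary tree of tubular branches is rasterized into a 3D
HU grid: dark lumina of generation-wise shrinking calibre, brighter wall
shells, parenchyma background, then additive Gaussian noise and a Gaussian
point-spread blur.  The lumen mask is taken before noise and blur, so the
ground truth is exact.  Also provides the small affine-ramp test images used
by the interpolation analyses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "Branch",
    "PhantomVolume",
    "generate_tree",
    "rasterize",
    "generate_phantom",
    "gradient_image",
    "affine_image",
    "write_fixture",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and corruption parameters of one phantom.

    Default intensities keep lumen (air), parenchyma (aerated lung) and wall
    (soft tissue) in distinct bands after a W=1500 / L=-500 lung window.
    """

    grid_shape: tuple[int, int, int] = (64, 96, 96)  # (z, y, x) voxels
    generations: int = 3
    root_radius: float = 4.0
    radius_decay: float = 0.6
    length_root: float = 24.0
    length_decay: float = 0.75
    branch_half_angle: float = 35.0  # degrees
    angle_jitter: float = 5.0  # degrees
    wall_thickness: float = 1.5
    hu_lumen: float = -1000.0
    hu_wall: float = -100.0
    hu_parenchyma: float = -850.0
    noise_sigma: float = 0.0
    psf_sigma: float = 0.0
    min_radius: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 4 voxels, got {self.grid_shape}")
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if not 0.0 < self.radius_decay < 1.0:
            raise ValueError(f"radius_decay must lie in (0, 1), got {self.radius_decay}")
        if not 0.0 < self.length_decay <= 1.0:
            raise ValueError(f"length_decay must lie in (0, 1], got {self.length_decay}")
        if self.min_radius <= 0.0:
            raise ValueError(f"min_radius must be > 0, got {self.min_radius}")
        if self.root_radius < self.min_radius:
            raise ValueError(
                f"root_radius ({self.root_radius}) must be >= min_radius ({self.min_radius})"
            )
        if not self.hu_lumen < self.hu_parenchyma < self.hu_wall:
            raise ValueError(
                "intensity ordering violated: require hu_lumen < hu_parenchyma < hu_wall, "
                f"got {self.hu_lumen}, {self.hu_parenchyma}, {self.hu_wall}"
            )
        if self.wall_thickness < 0:
            raise ValueError(f"wall_thickness must be >= 0, got {self.wall_thickness}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.psf_sigma < 0:
            raise ValueError(f"psf_sigma must be >= 0, got {self.psf_sigma}")
        if self.length_root <= 0:
            raise ValueError(f"length_root must be > 0, got {self.length_root}")


@dataclass
class Branch:
    """One tubular segment of the tree, in (z, y, x) voxel coordinates."""

    generation: int
    start: np.ndarray
    end: np.ndarray
    radius: float
    parent: "Branch | None" = None

    def to_dict(self) -> dict:
        return {
            "generation": self.generation,
            "start": [float(v) for v in self.start],
            "end": [float(v) for v in self.end],
            "radius": self.radius,
        }


@dataclass
class PhantomVolume:
    image: np.ndarray  # 3D HU grid (z, y, x)
    lumen_mask: np.ndarray  # 3D uint8, pre-noise pre-blur lumen
    branches: list[Branch]
    spec: PhantomSpec | None = None


def _rotation_about_axis(axis: int, angle_rad: float) -> np.ndarray:
    """Rotation matrix about one of the (z, y, x) grid axes."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
    return m


def _inside(point: np.ndarray, margin: float, shape: tuple[int, int, int]) -> bool:
    return all(margin <= p <= s - 1 - margin for p, s in zip(point, shape))


def generate_tree(spec: PhantomSpec) -> list[Branch]:
    """Grow a seeded recursive binary tree of branches.

    The root runs along +z from near the top face centre.  Each branch
    spawns two children deflected by +/- the half angle (with seeded jitter)
    from the parent direction; the deflection plane alternates between the
    two orthogonal planes containing the parent axis per generation, which
    fills space without a collision solver.  Recursion stops at the last
    generation or when a child radius would fall below ``min_radius``;
    children leaving the grid are dropped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    gz, gy, gx = spec.grid_shape
    root_start = np.array([2.0, gy / 2.0, gx / 2.0])
    root_dir = np.array([1.0, 0.0, 0.0])  # +z
    root_end = root_start + spec.length_root * root_dir
    branches: list[Branch] = []

    def grow(start: np.ndarray, end: np.ndarray, direction: np.ndarray,
             gen: int, radius: float, parent: Branch | None) -> None:
        margin = radius + spec.wall_thickness
        if not (_inside(start, 0.0, spec.grid_shape) and _inside(end, margin, spec.grid_shape)):
            log.warning("dropping out-of-grid branch at generation %d", gen)
            return
        branch = Branch(generation=gen, start=start.copy(), end=end.copy(),
                        radius=radius, parent=parent)
        branches.append(branch)
        if gen + 1 >= spec.generations:
            return
        child_radius = radius * spec.radius_decay
        if child_radius < spec.min_radius:
            return
        child_length = spec.length_root * spec.length_decay ** (gen + 1)
        # deflection plane alternates: rotate about the x axis on even
        # generations, about the y axis on odd ones
        rot_axis = 2 if gen % 2 == 0 else 1
        for sign in (+1.0, -1.0):
            jitter = rng.uniform(-spec.angle_jitter, spec.angle_jitter)
            angle = math.radians(sign * (spec.branch_half_angle + jitter))
            child_dir = _rotation_about_axis(rot_axis, angle) @ direction
            child_dir = child_dir / np.linalg.norm(child_dir)
            child_end = end + child_length * child_dir
            grow(end, child_end, child_dir, gen + 1, child_radius, branch)

    grow(root_start, root_end, root_dir, 0, spec.root_radius, None)
    if not branches:
        raise ValueError("no branch fits inside the grid; enlarge grid_shape")
    return branches


def _segment_distance_field(
    shape: tuple[int, int, int], start: np.ndarray, end: np.ndarray, reach: float
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Distance to a segment over its inflated bounding box only."""
    lo = np.maximum(np.floor(np.minimum(start, end) - reach), 0).astype(int)
    hi = np.minimum(np.ceil(np.maximum(start, end) + reach) + 1, shape).astype(int)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    coords = np.stack(
        np.meshgrid(*[np.arange(a, b, dtype=np.float64) for a, b in zip(lo, hi)],
                    indexing="ij"),
        axis=-1,
    )
    d = end - start
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        dist = np.linalg.norm(coords - start, axis=-1)
    else:
        t = np.clip(((coords - start) @ d) / seg_len2, 0.0, 1.0)
        nearest = start + t[..., None] * d
        dist = np.linalg.norm(coords - nearest, axis=-1)
    return sl, dist


def rasterize(branches: list[Branch], spec: PhantomSpec) -> PhantomVolume:
    """Voxelize a branch list into image + exact lumen mask.

    Lumen: distance-to-axis <= radius.  Wall: radius < d <= radius +
    wall_thickness, never overwriting any branch's lumen.  Noise and blur
    are applied after the mask is taken.
    """
    if not branches:
        raise ValueError("empty branch list")
    shape = spec.grid_shape
    lumen = np.zeros(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)
    for b in branches:
        reach = b.radius + spec.wall_thickness + 1.0
        sl, dist = _segment_distance_field(shape, b.start, b.end, reach)
        lumen[sl] |= dist <= b.radius
        wall[sl] |= (dist > b.radius) & (dist <= b.radius + spec.wall_thickness)
    wall &= ~lumen
    image = np.full(shape, spec.hu_parenchyma, dtype=np.float64)
    image[wall] = spec.hu_wall
    image[lumen] = spec.hu_lumen
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    if spec.psf_sigma > 0:
        image = gaussian_filter(image, sigma=spec.psf_sigma)
    return PhantomVolume(
        image=image, lumen_mask=lumen.astype(np.uint8), branches=branches, spec=spec
    )


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Convenience: ``rasterize(generate_tree(spec), spec)``."""
    return rasterize(generate_tree(spec), spec)


def gradient_image(n: int, orientation: str = "row") -> np.ndarray:
    """An ``n x n`` unit ramp along one axis: value = row (or column) index.

    Affine images are the exactness class of bilinear interpolation, which
    makes these the canonical inputs for the resampling analyses.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if orientation == "row":
        return affine_image(n, a=1.0, b=0.0, c=0.0)
    if orientation == "column":
        return affine_image(n, a=0.0, b=1.0, c=0.0)
    raise ValueError(f"orientation must be 'row' or 'column', got {orientation!r}")


def affine_image(n: int, a: float, b: float, c: float) -> np.ndarray:
    """``n x n`` image with ``value = a*row + b*col + c``."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rows = np.arange(n, dtype=np.float64)[:, None]
    cols = np.arange(n, dtype=np.float64)[None, :]
    return a * rows + b * cols + c


_FIXTURE_FORMATS = ("nifti", "tiff")


def write_fixture(
    volume: PhantomVolume, path: str | Path, format: str = "nifti"
) -> dict[str, Path]:
    """Write image + mask (+ JSON sidecar with spec and branch table).

    ``nifti`` writes ``image.nii.gz`` / ``mask.nii.gz``; ``tiff`` writes one
    16-bit image file per axial slice plus a multi-page mask stack.
    Integer-typed data round-trips bit-exactly through ``io.read_volume``.
    """
    if format not in _FIXTURE_FORMATS:
        raise ValueError(f"unsupported format {format!r}; supported: {_FIXTURE_FORMATS}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if format == "nifti":
        import nibabel as nib

        affine = np.eye(4)
        img_path = path / "image.nii.gz"
        mask_path = path / "mask.nii.gz"
        nib.save(nib.Nifti1Image(volume.image.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(volume.lumen_mask.astype(np.uint8), affine), mask_path)
        written["image"] = img_path
        written["mask"] = mask_path
    else:
        import tifffile

        # HU shifted to an unsigned 16-bit range; offset recorded in the sidecar
        offset = 2048.0
        for k in range(volume.image.shape[0]):
            sl = np.clip(volume.image[k] + offset, 0, 65535).astype(np.uint16)
            f = path / f"image_{k:04d}.tif"
            tifffile.imwrite(f, sl)
            written[f"image_{k:04d}"] = f
        mask_path = path / "mask.tif"
        tifffile.imwrite(mask_path, volume.lumen_mask.astype(np.uint8),
                         photometric="minisblack")
        written["mask"] = mask_path
    sidecar = path / "phantom.json"
    payload = {
        "format": format,
        "spec": asdict(volume.spec) if volume.spec is not None else None,
        "branches": [b.to_dict() for b in volume.branches],
    }
    if format == "tiff":
        payload["intensity_offset"] = 2048.0
    sidecar.write_text(json.dumps(payload, indent=2))
    written["sidecar"] = sidecar
    return written
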