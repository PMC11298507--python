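"""Volume I/O and intensity normalisation.

Readers for NIfTI, TIFF stacks (directory of per-slice files or one
multi-page file) and DICOM series (requires the optional ``pydicom``
dependency), plus the lung-window normalisation used throughout the
pipeline: W = 1500 HU, L = -500 HU, rescaled to [0, 255].

Arrays are ordered (axial, row, column); the axial axis defaults to axis 0
and is overridable.  Normalized intensities stay in floating point —
quantisation to 8 bit happens only at TIFF export, avoiding double-rounding
drift through the interpolation pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Volume",
    "WindowLevel",
    "DEFAULT_WINDOW",
    "read_volume",
    "write_volume",
    "window_level_normalize",
    "extract_slices",
    "stack_slices",
    "binarize_mask",
    "unsharp_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowLevel:
    """Window width / level in HU; display range is [L - W/2, L + W/2]."""

    W: float = 1500.0
    L: float = -500.0

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError(f"window width W must be > 0, got {self.W}")


DEFAULT_WINDOW = WindowLevel(W=1500.0, L=-500.0)


@dataclass
class Volume:
    """A 3D intensity grid with spacing and an axial slicing convention."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axial_axis: int = 0
    dtype_note: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not 0 <= self.axial_axis <= 2:
            raise ValueError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.axial_axis]


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if path.is_dir():
        if list(path.glob("*.tif")) or list(path.glob("*.tiff")):
            return "tiff"
        if list(path.glob("*.dcm")) or list(path.glob("*.DCM")):
            return "dicom"
    raise ValueError(f"cannot infer format of {path}; pass format explicitly")


def read_volume(path: str | Path, format: str | None = None, axial_axis: int = 0) -> Volume:
    """Read a volume from NIfTI, a TIFF stack, or a DICOM series directory.

    DICOM intensities are mapped to HU via rescale slope/intercept; other
    formats return raw stored values.  Slices are ordered ascending along
    the axial axis (filename order for TIFF, position/instance order for
    DICOM).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, axial_axis)
    if fmt == "tiff":
        return _read_tiff(path, axial_axis)
    if fmt == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unsupported format {fmt!r}; supported: nifti, tiff, dicom")


def _read_nifti(path: Path, axial_axis: int) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return Volume(data=np.asarray(data), spacing=tuple(float(z) for z in zooms),
                  axial_axis=axial_axis, dtype_note="raw")


def _read_tiff(path: Path, axial_axis: int) -> Volume:
    import tifffile

    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {shapes}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
    return Volume(data=data, axial_axis=axial_axis, dtype_note="raw")


def _read_dicom(path: Path) -> Volume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM series requires the optional 'pydicom' dependency "
            "(pip install interpsplit[dicom])"
        ) from exc
    files = sorted(path.glob("*.dcm")) or sorted(path.glob("*.DCM")) or sorted(
        p for p in path.iterdir() if p.is_file()
    )
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if not datasets:
        raise FileNotFoundError(f"no DICOM files in {path}")
    orientations = {tuple(getattr(d, "ImageOrientationPatient", ())) for d in datasets}
    if len(orientations) > 1:
        raise ValueError(f"mixed-orientation DICOM series in {path}")

    def sort_key(d):
        ipp = getattr(d, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return int(getattr(d, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=0)
    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    st = float(getattr(datasets[0], "SliceThickness", 1.0))
    return Volume(data=data, spacing=(st, float(ps[0]), float(ps[1])),
                  axial_axis=0, dtype_note="HU")


def write_volume(volume: Volume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as NIfTI or multi-page TIFF (inferred from the suffix)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(volume.data, np.eye(4)), str(path))
    elif fmt == "tiff":
        import tifffile

        data = volume.data
        if volume.dtype_note.startswith("normalized"):
            # round-half-even 8-bit quantisation happens only here
            data = np.rint(np.clip(data, 0, 255)).astype(np.uint8)
        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported format {fmt!r}; supported: nifti, tiff")
    return path


def window_level_normalize(volume: Volume, wl: WindowLevel = DEFAULT_WINDOW) -> Volume:
    """Map HU to [0, 255]: ``clamp((I - (L - W/2)) / W, 0, 1) * 255``.

    Monotone non-decreasing in the input; kept in floating point.
    """
    lo = wl.L - wl.W / 2.0
    g = np.clip((volume.data.astype(np.float64) - lo) / wl.W, 0.0, 1.0) * 255.0
    return replace(volume, data=g, dtype_note="normalized-0-255")


def extract_slices(volume: Volume) -> list[np.ndarray]:
    """One 2D image per axial index, order preserved."""
    return [np.take(volume.data, k, axis=volume.axial_axis)
            for k in range(volume.n_slices)]


def stack_slices(slices: list[np.ndarray], like: Volume | None = None) -> np.ndarray:
    """Inverse of :func:`extract_slices` (axial axis restored from ``like``)."""
    axis = like.axial_axis if like is not None else 0
    return np.stack(slices, axis=axis)


def binarize_mask(mask_volume: np.ndarray | Volume, positive_rule=None) -> np.ndarray:
    """Binarize a numeric mask; default rule is ``value > 0``."""
    data = mask_volume.data if isinstance(mask_volume, Volume) else np.asarray(mask_volume)
    if not np.issubdtype(data.dtype, np.number) and data.dtype != bool:
        raise TypeError(f"mask must be numeric, got dtype {data.dtype}")
    rule = positive_rule or (lambda a: a > 0)
    out = rule(data).astype(np.uint8)
    if not out.any():
        log.warning("binarized mask is empty")
    return out


def unsharp_mask(
    image: np.ndarray,
    amount: float,
    radius: float,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Generic unsharp mask: ``image + amount * (image - blur(image))``.

    Output is clamped to ``value_range``.  ``amount = 0`` is the identity;
    constant images are unchanged for any amount.
    """
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    image = np.asarray(image, dtype=np.float64)
    sharp = image + amount * (image - gaussian_filter(image, sigma=radius))
    return np.clip(sharp, *value_range)
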