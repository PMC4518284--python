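"""Volume, ROI and line-profile containers plus readers/writers.

Conventions used throughout the package:

* Arrays are indexed ``[x, y, z]`` with ``z`` the rostro-caudal axis
  (positive z = rostral).  TIFF stacks store one transverse (x, y) page
  per z slice.
* Coordinates are 0-based voxel indices; the physical position of a
  voxel is ``index * spacing`` (voxel-centre convention), in micrometres.
* Binary masks on disk are 8-bit TIFF with 0 = background, 255 = vessel.
* NIfTI orientation metadata beyond the voxel spacing is ignored: the
  pipeline is scanner-free and carries no anatomical orientation matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Volume3D:
    """A 3D grayscale volume with per-axis voxel spacing in micrometres."""

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (3.7, 3.7, 3.7)
    axis_labels: tuple[str, str, str] = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing_um, self.axis_labels)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned voxel box, half-open on every axis: ``[lo, hi)``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("ROI lo/hi must have 3 entries")
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"ROI must satisfy lo < hi per axis, got {self.lo}..{self.hi}")
        if any(l < 0 for l in self.lo):
            raise ValueError("ROI lower bounds must be >= 0")

    @staticmethod
    def full(shape: tuple[int, int, int]) -> "ROI":
        return ROI((0, 0, 0), tuple(int(s) for s in shape))

    def validate_within(self, shape: tuple[int, int, int]) -> None:
        if any(h > s for h, s in zip(self.hi, shape)):
            raise ValueError(f"ROI {self.lo}..{self.hi} exceeds volume shape {shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))

    def physical_volume_um3(self, spacing_um) -> float:
        return self.n_voxels() * float(np.prod(spacing_um))

    def contains(self, idx) -> bool:
        return all(l <= i < h for i, l, h in zip(idx, self.lo, self.hi))


@dataclass
class LineProfile:
    """Intensity samples along a straight line in a 2D image.

    ``positions_px``/``positions_um`` are distances from the start point;
    ``iod`` is the integral optical density: the line integral of gray
    values along the profile (trapezoidal rule over the samples).
    """

    positions_px: np.ndarray
    positions_um: np.ndarray
    intensities: np.ndarray
    iod: float

    def __post_init__(self) -> None:
        if len(self.positions_px) < 2:
            raise ValueError("a line profile needs at least 2 samples")
        if not np.all(np.diff(self.positions_px) > 0):
            raise ValueError("sample positions must be strictly increasing")

    def peak_count(self, threshold: float) -> int:
        """Number of contiguous runs of samples above ``threshold``."""
        above = self.intensities > threshold
        return int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))


# ---------------------------------------------------------------------------
# Volume readers / writers
# ---------------------------------------------------------------------------

_RAW_SIDECAR_SUFFIX = ".json"


def _tiff_spacing(path: Path) -> tuple[float, float, float] | None:
    try:
        with tifffile.TiffFile(str(path)) as tf:
            meta = tf.imagej_metadata or {}
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            # ImageJ convention: resolution in pixels per unit; spacing = 1/res
            if xres is not None and meta:
                num, den = xres.value
                sx = den / num if num else None
                sz = meta.get("spacing")
                if sx and sz:
                    return (float(sx), float(sx), float(sz))
    except Exception:
        return None
    return None


def read_volume(path, spacing_override=None) -> Volume3D:
    """Read a TIFF stack, NIfTI file or raw binary + JSON sidecar.

    ``spacing_override`` (per-axis micrometres) wins over any header value;
    if neither is available the default 3.7 um isotropic is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    name = path.name.lower()
    spacing = None
    if name.endswith((".tif", ".tiff")):
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ValueError(f"TIFF stack in {path} is not a stack of 2D slices")
        # pages axis = z, each page (x, y) -> array indexed [x, y, z]
        data = np.moveaxis(pages, 0, -1)
        spacing = _tiff_spacing(path)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
    elif name.endswith(".raw"):
        sidecar = path.with_suffix(_RAW_SIDECAR_SUFFIX)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"raw volume {path} requires a JSON sidecar at {sidecar} "
                "with keys 'shape', 'dtype' and optionally 'spacing_um'"
            )
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(str(path), dtype=np.dtype(meta["dtype"]))
        data = data.reshape(tuple(meta["shape"]))
        if "spacing_um" in meta:
            spacing = tuple(float(s) for s in meta["spacing_um"])
    else:
        raise ValueError(f"unrecognised volume format: {path}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        spacing = (3.7, 3.7, 3.7)
    return Volume3D(data, spacing)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume losslessly (integer grids round-trip bit-exactly)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".tif", ".tiff")):
        pages = np.moveaxis(vol.data, -1, 0)
        sx, sy, sz = vol.spacing_um
        tifffile.imwrite(
            str(path),
            pages,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um"},
        )
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(vol.data), affine=np.diag(list(vol.spacing_um) + [1.0]))
        img.header.set_zooms(vol.spacing_um)
        nib.save(img, str(path))
    elif name.endswith(".raw"):
        vol.data.tofile(str(path))
        sidecar = path.with_suffix(_RAW_SIDECAR_SUFFIX)
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(vol.data.shape),
                    "dtype": vol.data.dtype.str,
                    "spacing_um": list(vol.spacing_um),
                },
                indent=2,
            )
        )
    else:
        raise ValueError(f"unrecognised volume format: {path}")


def write_mask(mask_data: np.ndarray, spacing_um, path) -> None:
    """Write a boolean mask as 8-bit (0 = background, 255 = vessel)."""
    vol = Volume3D((np.asarray(mask_data, bool) * np.uint8(255)), spacing_um)
    write_volume(vol, path)


def read_mask(path) -> Volume3D:
    vol = read_volume(path)
    vol.data = vol.data > 0
    return vol


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------


def extract_line_profile(image: np.ndarray, p0, p1, n_samples: int = 100,
                         pixel_size_um: float = 3.7) -> LineProfile:
    """Sample a 2D image along the segment p0 -> p1 with bilinear interpolation.

    Points are (row, col) pixel coordinates.  Also reports the IOD
    (sum of samples x physical sample step).
    """
    from scipy.ndimage import map_coordinates

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("line profiles are extracted from 2D images")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if np.allclose(p0, p1):
        raise ValueError("line profile endpoints must differ")
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > np.array(image.shape) - 1):
            raise ValueError(f"endpoint {tuple(p)} lies outside the image")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    values = map_coordinates(image, coords, order=1, mode="nearest")
    length_px = float(np.linalg.norm(p1 - p0))
    positions_px = t * length_px
    step_um = (length_px / (n_samples - 1)) * pixel_size_um
    # trapezoidal rule: exact (= c x line length) on a constant image
    iod = float(np.trapezoid(values, dx=step_um))
    return LineProfile(positions_px, positions_px * pixel_size_um, values, iod)
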