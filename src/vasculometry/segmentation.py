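"""Vessel segmentation: iterative gray-level thresholding and size filtering.

The binarisation follows the classic Ridler-Calvard (isodata) iteration:
starting from the global mean, the threshold is repeatedly replaced by the
midpoint of the means of the two classes it induces,

    T_{k+1} = ( mean(I <= T_k) + mean(I > T_k) ) / 2,

until the update falls below a tolerance.  The resulting binary vasculature
is cleaned with a 3D size filter that removes isolated foreground islands
and fills isolated background holes smaller than a minimum voxel count
(default 3; components of exactly 3 voxels survive).  Foreground components
use 26-connectivity and background components 6-connectivity, the standard
dual pairing that avoids topological paradoxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_io import Volume3D


@dataclass
class ThresholdResult:
    threshold: float
    iterations: int
    history: list[float] = field(default_factory=list)


@dataclass
class BinaryMask:
    """Boolean vessel/background grid with voxel spacing in micrometres."""

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (3.7, 3.7, 3.7)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_foreground(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.spacing_um)


_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def isodata_threshold(vol: Volume3D, tol: float | None = None,
                      max_iter: int = 200) -> ThresholdResult:
    """Ridler-Calvard iterative threshold of a grayscale volume.

    ``tol`` defaults to 0.5 gray value for integer volumes and
    1e-4 x intensity range for float volumes, which guarantees
    termination on quantised data.
    """
    data = np.asarray(vol.data)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("no threshold exists: the volume is constant")
    if tol is None:
        tol = 0.5 if np.issubdtype(data.dtype, np.integer) else 1e-4 * (hi - lo)
    flat = data.ravel().astype(np.float64)
    t = float(flat.mean())
    history = [t]
    for k in range(max_iter):
        below = flat <= t
        mean_low = flat[below].mean() if below.any() else lo
        mean_high = flat[~below].mean() if (~below).any() else hi
        t_new = 0.5 * (mean_low + mean_high)
        history.append(float(t_new))
        if abs(t_new - t) < tol:
            return ThresholdResult(float(t_new), k + 1, history)
        t = t_new
    raise RuntimeError(
        f"isodata did not converge in {max_iter} iterations; history={history}"
    )


def binarize(vol: Volume3D, threshold: float) -> BinaryMask:
    """Foreground iff intensity is strictly greater than ``threshold``."""
    return BinaryMask(np.asarray(vol.data) > threshold, vol.spacing_um)


def connected_components(mask: BinaryMask | np.ndarray, connectivity: int = 26):
    """Label connected components in raster-scan order.

    Returns ``(labels, sizes)`` where ``sizes[i]`` is the voxel count of
    label ``i + 1``; sizes sum to the foreground voxel count.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labels, n = ndi.label(data, structure=_STRUCTS[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def size_filter(mask: BinaryMask, min_voxels: int = 3,
                fg_connectivity: int = 26, bg_connectivity: int = 6) -> BinaryMask:
    """Remove foreground components and fill background holes < ``min_voxels``.

    "Smaller than" is read strictly: components of exactly ``min_voxels``
    voxels survive.  Foreground is cleaned first, then background holes
    are filled.  The operation is idempotent.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    data = mask.data.copy()
    labels, sizes = connected_components(data, fg_connectivity)
    small = np.flatnonzero(sizes < min_voxels) + 1
    if small.size:
        data[np.isin(labels, small)] = False
    bg_labels, bg_sizes = connected_components(~data, bg_connectivity)
    small_bg = np.flatnonzero(bg_sizes < min_voxels) + 1
    if small_bg.size:
        data[np.isin(bg_labels, small_bg)] = True
    return BinaryMask(data, mask.spacing_um)


def segment_vessels(vol: Volume3D, threshold: float | None = None,
                    min_voxels: int = 3) -> tuple[BinaryMask, ThresholdResult | None]:
    """Full segmentation stage: isodata threshold (unless given) + size filter."""
    result = None
    if threshold is None:
        result = isodata_threshold(vol)
        threshold = result.threshold
    mask = binarize(vol, threshold)
    return size_filter(mask, min_voxels=min_voxels), result
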