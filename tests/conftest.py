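"""Shared fixtures: small geometric masks and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from vasculometry.segmentation import BinaryMask

SPACING = (3.7, 3.7, 3.7)


def cylinder_mask(shape=(24, 24, 50), center=(12, 12), radius=5.0,
                  spacing=(1.0, 1.0, 1.0), z_range=None):
    """Axial cylinder; flat caps at the z limits (or the volume border)."""
    x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    m = (x - center[0]) ** 2 + (y - center[1]) ** 2 < radius**2
    if z_range is not None:
        m &= (z >= z_range[0]) & (z < z_range[1])
    return BinaryMask(m, spacing)


def y_tube_mask(shape=(48, 48, 48), radius=2.0):
    """Three straight arms meeting at the centre (a thick 'Y')."""
    c = np.array([24, 24, 24], float)
    arms = [np.array(d, float) for d in
            [(0, 0, -1), (0.8, 0, 0.6), (-0.8, 0, 0.6)]]
    pts = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3).astype(float)
    m = np.zeros(int(np.prod(shape)), bool)
    for d in arms:
        rel = pts - c
        t = np.clip(rel @ d, 0, 18)
        m |= np.linalg.norm(rel - t[:, None] * d, axis=1) < radius
    return BinaryMask(m.reshape(shape), (1.0, 1.0, 1.0))


def torus_mask(shape=(40, 40, 16), major=12.0, minor=3.5):
    """Solid torus around the z axis through the volume centre."""
    x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cx, cy, cz = (shape[0] - 1) / 2, (shape[1] - 1) / 2, (shape[2] - 1) / 2
    rho = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    m = (rho - major) ** 2 + (z - cz) ** 2 < minor**2
    return BinaryMask(m, (1.0, 1.0, 1.0))


def brute_force_edm(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """O(n^2) nearest-background search: the independent distance oracle."""
    from scipy.spatial.distance import cdist

    mask = np.asarray(mask, bool)
    sp = np.asarray(spacing, float)
    fg = np.argwhere(mask) * sp
    bg = np.argwhere(~mask) * sp
    out = np.zeros(mask.shape)
    if len(fg) == 0 or len(bg) == 0:
        return out
    d = cdist(fg, bg).min(axis=1)
    out[mask] = d
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> int:
    """Independent component counter: explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    seen = np.zeros_like(mask)
    n = 0
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for o in offsets:
                nb = (cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)) \
                        and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
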