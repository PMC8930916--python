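"""Exact direct-evaluation non-uniform DFT along radial k-space lines.

Conventions: image coordinates r = (x, y) in units of the field of view,
spanning [-1/2, 1/2); k-space positions in cycles/FOV.  With 2x readout
oversampling a line of ``n_samples = 2 * grid_n`` samples has spacing
dk = 1/2 cycle/FOV and spans +/- grid_n/2 (the grid Nyquist radius).
The forward transform of a line at azimuth theta is

    y[s] = sum_v img[v] * exp(-2j*pi * k_s * (x_v cos(theta) + y_v sin(theta)))

and the adjoint is the exact conjugate transpose.  Because the samples along
a line are uniformly spaced, each line's transform matrix is built by a
geometric recursion (one complex exponential per voxel, then cumulative
products), which keeps the direct evaluation fast at the package's target
matrix sizes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grid_coords", "line_kpositions", "line_matrix", "LineTransformCache", "ramp_dcf"]


def grid_coords(grid_n: int):
    """Pixel-center coordinates in FOV units, both axes, 'ij' meshgrid."""
    c = (np.arange(grid_n) - grid_n // 2) / grid_n
    y, x = np.meshgrid(c, c, indexing="ij")
    return x, y


def line_kpositions(grid_n: int, oversample: int = 2) -> np.ndarray:
    """Signed radial k positions (cycles/FOV) of one readout line."""
    n_samples = oversample * grid_n
    s = np.arange(n_samples) - n_samples // 2
    dk = 1.0 / oversample
    return s * dk


def line_matrix(angle_deg: float, x: np.ndarray, y: np.ndarray,
                grid_n: int, oversample: int = 2) -> np.ndarray:
    """(n_samples, n_voxels) forward NUDFT matrix for one radial line.

    ``x``/``y`` are flat voxel coordinates in FOV units (possibly a support
    subset of the grid).
    """
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    k = line_kpositions(grid_n, oversample)
    n_samples = k.size
    dk = k[1] - k[0]
    step = np.exp(-2j * np.pi * dk * u)           # ratio between adjacent samples
    row0 = np.exp(-2j * np.pi * k[0] * u)
    out = np.empty((n_samples, u.size), dtype=np.complex128)
    out[0] = row0
    for s in range(1, n_samples):
        out[s] = out[s - 1] * step
    return out


class LineTransformCache:
    """Caches per-angle line matrices (training lines reuse the 0-deg matrix)."""

    def __init__(self, x: np.ndarray, y: np.ndarray, grid_n: int, oversample: int = 2,
                 max_entries: int = 16):
        self.x = x
        self.y = y
        self.grid_n = grid_n
        self.oversample = oversample
        self._cache: dict[float, np.ndarray] = {}
        self._max = max_entries

    def get(self, angle_deg: float) -> np.ndarray:
        key = round(float(angle_deg) % 360.0, 6)
        mat = self._cache.get(key)
        if mat is None:
            mat = line_matrix(key, self.x, self.y, self.grid_n, self.oversample)
            if len(self._cache) < self._max:
                self._cache[key] = mat
        return mat


def ramp_dcf(grid_n: int, oversample: int = 2) -> np.ndarray:
    """Ramp (|k|) density compensation for gridding previews; center clamped."""
    k = np.abs(line_kpositions(grid_n, oversample))
    k[k == 0] = k[k > 0].min() / 2
    return k
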