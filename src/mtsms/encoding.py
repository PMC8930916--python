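"""Golden-angle radial trajectory, 3-band CAIPIRINHA phase modulation, and the
SMS forward/adjoint encoding operator, plus coil-sensitivity estimation.

Slice/band convention (fixed): index 0 = apical (kz = -1, phase increment
-2*pi/3), index 1 = mid (kz = 0, no modulation), index 2 = basal (kz = +1,
+2*pi/3).  The phase step advances by one per imaging line, cycling mod 3,
so the three phasor patterns over steps j = 0, 1, 2 form a 3-point DFT
across the discrete kz dimension.  Training lines carry no modulation
(kz = 0, a through-slice projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .nufft import LineTransformCache, grid_coords, line_kpositions, ramp_dcf
from .sequence import GOLDEN_ANGLE_DEG, SequenceSchedule

SLICE_LABELS = ("apical", "mid", "basal")
SLICE_KZ = np.array([-1, 0, 1])

__all__ = [
    "SLICE_LABELS",
    "SLICE_KZ",
    "Trajectory",
    "radial_angles",
    "band_phases",
    "SMSRadialOperator",
    "make_operator",
    "power_method_norm",
    "estimate_coils",
]


def radial_angles(schedule: SequenceSchedule) -> np.ndarray:
    """Per-line azimuth: imaging line m gets (m * 111.24) mod 360; training 0."""
    angles = np.zeros(schedule.n_lines)
    img = ~schedule.is_training
    m = np.arange(img.sum())
    angles[img] = (m * GOLDEN_ANGLE_DEG) % 360.0
    return angles


def band_phases(schedule: SequenceSchedule, n_bands: int = 3) -> np.ndarray:
    """(n_lines, n_bands) unit phasors exp(i * j_l * kz_b * 2pi/3)."""
    if n_bands != 3:
        raise NotImplementedError("only the 3-band CAIPIRINHA scheme is supported")
    inc = SLICE_KZ * (2.0 * np.pi / 3.0)
    return np.exp(1j * np.outer(schedule.phase_step, inc))


@dataclass
class Trajectory:
    """Per-line sampling geometry of the executed scan."""

    angle_deg: np.ndarray
    phase_step: np.ndarray
    is_training: np.ndarray
    grid_n: int
    oversample: int = 2

    @property
    def k_positions(self) -> np.ndarray:
        return line_kpositions(self.grid_n, self.oversample)

    @property
    def dcf(self) -> np.ndarray:
        return ramp_dcf(self.grid_n, self.oversample)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "angle_deg": self.angle_deg,
                "phase_step": self.phase_step,
                "role": np.where(self.is_training, "training", "imaging"),
            }
        )

    @classmethod
    def from_schedule(cls, schedule: SequenceSchedule, grid_n: int, oversample: int = 2):
        return cls(
            angle_deg=schedule.radial_angle_deg.copy(),
            phase_step=schedule.phase_step.copy(),
            is_training=schedule.is_training.copy(),
            grid_n=grid_n,
            oversample=oversample,
        )


class SMSRadialOperator:
    """Forward/adjoint multislice radial encoding  E : images -> line samples.

    forward: per-slice coil weighting -> per-band CAIPIRINHA phasor -> band
    summation -> non-uniform in-plane Fourier evaluation along each line.
    The adjoint is the exact conjugate transpose (density compensation is
    never used inside the pair).

    Parameters
    ----------
    angles, phase_steps : per-line azimuth (deg) and CAIPIRINHA step.
    coils : (n_slices, n_coils, ny, nx) complex sensitivities.
    support : optional (ny, nx) bool mask restricting the voxel domain.
    """

    def __init__(self, angles, phase_steps, coils, grid_n: int, oversample: int = 2,
                 support=None, dtype=np.complex128):
        self.dtype = np.dtype(dtype)
        self._rdtype = np.float32 if self.dtype == np.complex64 else np.float64
        self.angles = np.asarray(angles, dtype=float)
        self.phase_steps = np.asarray(phase_steps, dtype=np.int64)
        coils = np.asarray(coils, dtype=np.complex128)
        if coils.ndim != 4:
            raise ValueError("coils must be (n_slices, n_coils, ny, nx)")
        self.n_slices, self.n_coils, ny, nx = coils.shape
        if ny != grid_n or nx != grid_n:
            raise ValueError("coil map grid does not match grid_n")
        if self.n_slices != 3:
            raise ValueError("3-band operator requires 3 slices")
        if self.angles.shape != self.phase_steps.shape:
            raise ValueError("angles/phase_steps length mismatch")
        self.grid_n = grid_n
        self.oversample = oversample
        self.n_samples = oversample * grid_n

        x, y = grid_coords(grid_n)
        if support is None:
            support = np.ones((grid_n, grid_n), dtype=bool)
        self.support = support
        self._xs = x[support].astype(self._rdtype)
        self._ys = y[support].astype(self._rdtype)
        self.n_vox = self._xs.size
        self.coils_flat = coils[:, :, support].astype(self.dtype)
        inc = SLICE_KZ * (2.0 * np.pi / 3.0)
        self.phasors = np.exp(1j * np.outer(self.phase_steps, inc)).astype(self.dtype)
        self._cache = LineTransformCache(self._xs, self._ys, grid_n, oversample)

    @property
    def n_lines(self) -> int:
        return self.angles.size

    def _line_matrices(self, line_sel: np.ndarray) -> np.ndarray:
        """(B, n_samples, n_vox) forward matrices for a chunk of lines.

        Built by geometric recursion from k = 0 outward; the negative-k half
        is the complex conjugate of the positive half mirrored (u is real),
        which halves the dominant cost.
        """
        from .nufft import line_kpositions

        th = np.deg2rad(self.angles[line_sel]).astype(self._rdtype)
        u = np.cos(th)[:, None] * self._xs + np.sin(th)[:, None] * self._ys  # (B, V)
        k = line_kpositions(self.grid_n, self.oversample)
        dk = k[1] - k[0]
        n_s = k.size
        half = n_s // 2            # index of k = 0
        w = np.exp((-2j * np.pi * dk) * u).astype(self.dtype)
        out = np.empty((u.shape[0], n_s, u.shape[1]), dtype=self.dtype)
        out[:, half] = 1.0
        for s in range(half + 1, n_s):
            out[:, s] = out[:, s - 1] * w
        out[:, 1:half] = out[:, n_s - 1:half:-1].conj()
        out[:, 0] = (out[:, n_s - 1] * w).conj()
        return out

    # -- flat <-> image helpers -------------------------------------------
    def embed(self, flat: np.ndarray) -> np.ndarray:
        """(n_slices, n_vox, ...) -> (n_slices, ny, nx, ...) zero outside support."""
        shape = (self.n_slices, self.grid_n, self.grid_n) + flat.shape[2:]
        out = np.zeros(shape, dtype=flat.dtype)
        out[:, self.support] = flat
        return out

    def extract(self, imgs: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(imgs[:, self.support])

    def _chunks(self):
        per_line = self.n_samples * self.n_vox * self.dtype.itemsize
        b = max(1, int(1.5e8 / per_line))
        for start in range(0, self.n_lines, b):
            yield np.arange(start, min(start + b, self.n_lines))

    def _mix(self, xb: np.ndarray, sel: np.ndarray) -> np.ndarray:
        """Coil-weight, band-phase and band-sum: (B, n_slices, V) -> (B, V, C)."""
        tmp = self.phasors[sel][:, :, None] * xb.astype(self.dtype, copy=False)
        return np.einsum("nbv,bcv->nvc", tmp, self.coils_flat)

    def _unmix(self, g: np.ndarray, sel: np.ndarray) -> np.ndarray:
        """Adjoint of _mix: (B, V, C) -> (B, n_slices, V)."""
        back = np.einsum("nvc,bcv->nbv", g, self.coils_flat.conj())
        return back * self.phasors[sel].conj()[:, :, None]

    @staticmethod
    def _adj_matmul(a: np.ndarray, r: np.ndarray) -> np.ndarray:
        """A^H r per chunk without materializing conj(A): (B,S,V),(B,S,C)->(B,V,C)."""
        return np.matmul(r.conj().transpose(0, 2, 1), a).conj().transpose(0, 2, 1)

    # -- static-image pair -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n_slices, ny, nx) or (n_slices, n_vox) -> (n_lines, n_samples, n_coils)."""
        xf = self.extract(x) if x.ndim == 3 else np.asarray(x)
        out = np.empty((self.n_lines, self.n_samples, self.n_coils), dtype=np.complex128)
        for sel in self._chunks():
            a = self._line_matrices(sel)
            img = self._mix(np.broadcast_to(xf, (sel.size,) + xf.shape), sel)
            out[sel] = a @ img
        return out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """y: (n_lines, n_samples, n_coils) -> (n_slices, n_vox)."""
        y = np.asarray(y)
        acc = np.zeros((self.n_slices, self.n_vox), dtype=np.complex128)
        for sel in self._chunks():
            a = self._line_matrices(sel)
            g = self._adj_matmul(a, y[sel].astype(self.dtype, copy=False))
            acc += self._unmix(g, sel).sum(axis=0)
        return acc

    # -- temporally weighted pair (subspace reconstructions) ---------------
    def forward_weighted(self, u: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """E(U phi_l) per line.  u: (n_slices, n_vox, L); phi: (n_lines, L)."""
        out = np.empty((phi.shape[0], self.n_samples, self.n_coils), dtype=np.complex128)
        for sel in self._chunks():
            a = self._line_matrices(sel)
            xb = np.tensordot(phi[sel], u, axes=([1], [2]))  # (B, n_slices, V)
            out[sel] = a @ self._mix(xb, sel)
        return out

    def adjoint_weighted(self, y: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Gradient-shaped adjoint: sum_l E_l^H y_l phi_l^H -> (n_slices, n_vox, L)."""
        acc = np.zeros((self.n_slices, self.n_vox, phi.shape[1]), dtype=np.complex128)
        for sel in self._chunks():
            a = self._line_matrices(sel)
            g = self._adj_matmul(a, y[sel].astype(self.dtype, copy=False))
            back = self._unmix(g, sel)                       # (B, n_slices, V)
            acc += np.einsum("nbv,nl->bvl", back, phi[sel].conj())
        return acc

    def gradient_weighted(self, u: np.ndarray, phi: np.ndarray,
                          d: np.ndarray | None = None,
                          sample_weight: np.ndarray | None = None):
        """Fused sweep: (E^H(E u phi - d) phi^H, 0.5*||E u phi - d||^2).

        Builds each line's transform matrix once per sweep (the golden-angle
        trajectory never repeats an azimuth, so caching across sweeps is
        useless); with ``d=None`` this is the normal operator applied to u.
        """
        acc = np.zeros_like(u)
        obj = 0.0
        for sel in self._chunks():
            a = self._line_matrices(sel)
            xb = np.tensordot(phi[sel], u, axes=([1], [2]))
            r = a @ self._mix(xb, sel)
            if d is not None:
                r = r - d[sel].astype(self.dtype, copy=False)
            if sample_weight is not None:
                r = r * sample_weight
                obj += 0.5 * float(np.vdot(r / sample_weight, r).real)
            else:
                obj += 0.5 * float(np.vdot(r, r).real)
            g = self._adj_matmul(a, r)
            back = self._unmix(g, sel)
            acc += np.einsum("nbv,nl->bvl", back, phi[sel].conj())
        return acc, obj


def make_operator(trajectory: Trajectory, coils, band_table=None,
                  support=None, line_mask=None) -> SMSRadialOperator:
    """Bind a trajectory (or a line subset of it) and coils into an operator."""
    angles = trajectory.angle_deg
    steps = trajectory.phase_step
    if line_mask is not None:
        angles = angles[line_mask]
        steps = steps[line_mask]
    return SMSRadialOperator(angles, steps, coils, trajectory.grid_n,
                             trajectory.oversample, support=support)


def power_method_norm(op: SMSRadialOperator, n_iter: int = 8, seed: int = 0) -> float:
    """Largest singular value of E by power iteration on E^H E."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((op.n_slices, op.n_vox)) \
        + 1j * rng.standard_normal((op.n_slices, op.n_vox))
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(n_iter):
        z = op.adjoint(op.forward(x))
        lam = np.linalg.norm(z)
        x = z / lam
    return float(np.sqrt(lam))


def estimate_coils(raw, smooth_sigma: float = 2.0, use_truth: bool = False):
    """Coil sensitivities from the imaging data (or the truth bypass).

    Time-averaged ramp-compensated gridding per CAIPIRINHA step gives three
    kz-bucket composite images; a per-voxel 3-point inverse DFT separates the
    slices; sensitivities are per-coil images over the root-sum-of-squares,
    lightly smoothed.
    """
    if use_truth:
        return raw.coils.copy()
    schedule = raw.schedule
    grid_n = raw.grid_n
    img_lines = np.asarray(raw.imaging_lines)
    if img_lines.size < 3 * grid_n or img_lines.size > raw.imaging.shape[0]:
        raise ValueError("too few imaging lines for coil estimation")
    x, y = grid_coords(grid_n)
    cache = LineTransformCache(x.ravel(), y.ravel(), grid_n, raw.oversample)
    dcf = ramp_dcf(grid_n, raw.oversample)
    n_coils = raw.imaging.shape[2]
    buckets = np.zeros((3, n_coils, grid_n * grid_n), dtype=np.complex128)
    counts = np.zeros(3)
    for j, l in enumerate(img_lines):
        step = schedule.phase_step[l] % 3
        a = cache.get(schedule.radial_angle_deg[l])
        buckets[step] += (a.conj().T @ (dcf[:, None] * raw.imaging[j])).T
        counts[step] += 1
    buckets /= counts[:, None, None]
    # bucket j = sum_b exp(i j kz_b 2pi/3) S_b rho_b  ->  invert the 3x3 DFT
    m = np.exp(1j * np.outer(np.arange(3), SLICE_KZ * 2 * np.pi / 3))
    minv = np.linalg.inv(m)
    per_slice = np.einsum("bj,jcv->bcv", minv, buckets).reshape(3, n_coils, grid_n, grid_n)
    if smooth_sigma > 0:
        # smooth before the ratio: anatomy structure then divides out cleanly
        per_slice = gaussian_filter(per_slice.real,
                                    sigma=(0, 0, smooth_sigma, smooth_sigma)) \
            + 1j * gaussian_filter(per_slice.imag,
                                   sigma=(0, 0, smooth_sigma, smooth_sigma))
    rss = np.sqrt((np.abs(per_slice) ** 2).sum(axis=1, keepdims=True))
    rss[rss == 0] = rss.max() * 1e-9
    return per_slice / rss
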