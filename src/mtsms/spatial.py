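"""Spatial-factor recovery: fit the known temporal tensor Phi to the imaging
data by accelerated proximal gradient with wavelet soft-thresholding.

Each imaging line carries an (n, combo) pair from the schedule and inherits
its (cardiac, respiratory) bin from the temporally nearest training line
(at most one TR away thanks to the 1:1 interleave).  The objective is

    || d - Omega(Phi x1 F S U_x) ||_2^2  +  lambda_w || W U_x ||_1

with W an orthogonal wavelet transform applied per spatial basis image,
solved by monotone FISTA (the candidate is kept only if the objective does
not rise; momentum restarts otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .lrt import Phi

__all__ = ["SpatialFactor", "solve_spatial", "imaging_line_weights"]


@dataclass
class SpatialFactor:
    """Complex spatial basis images (flat over the operator support)."""

    u_x: np.ndarray               # (n_slices, n_vox, L)
    operator: object
    residual: float
    objective_trace: list = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.u_x.shape[-1]

    def images(self) -> np.ndarray:
        """(n_slices, ny, nx, L) embedded basis images."""
        return self.operator.embed(self.u_x)

    def export_rendered_nifti(self, phi, out_dir, c_star: int, r_star: int,
                              voxel_mm=(1.0, 1.0, 8.0), prefix="contrast_stack"):
        """Write the rendered (x, y, n, combo) magnitude stack at one fixed
        motion state, one NIfTI file per slice."""
        import os

        import nibabel as nib

        from .mapping import extract_curves

        os.makedirs(out_dir, exist_ok=True)
        curves = extract_curves(self.u_x, phi, c_star, r_star)
        n_n = phi.n_grid.size
        n_k = curves.shape[-1] // n_n
        aff = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])
        paths = []
        for s in range(curves.shape[0]):
            img = np.zeros(self.operator.support.shape + (n_n, n_k), np.float32)
            stack = np.abs(curves[s]).reshape(self.operator.n_vox, n_k, n_n)
            img[self.operator.support] = stack.transpose(0, 2, 1)
            p = os.path.join(out_dir, f"{prefix}_slice{s}.nii")
            nib.save(nib.Nifti1Image(img, aff), p)
            paths.append(p)
        return paths


def imaging_line_weights(raw, phi: Phi, bins) -> np.ndarray:
    """Per-imaging-line temporal weight vectors (n_img, L1)."""
    sched = raw.schedule
    lines = raw.imaging_lines
    t_img = sched.time_ms[lines]
    c_bin, r_bin = bins.labels_for_times(t_img)
    return phi.weights(sched.n_index[lines], sched.combo_index[lines], c_bin, r_bin)


def _wavelet_prox(u_img: np.ndarray, thresh: float, wavelet: str, levels: int) -> np.ndarray:
    """Soft-threshold detail coefficients of each (slice, basis) image."""
    out = np.empty_like(u_img)
    n_slices = u_img.shape[0]
    n_basis = u_img.shape[-1]
    for s in range(n_slices):
        for j in range(n_basis):
            for part, target in (("real", 0), ("imag", 1)):
                img = getattr(u_img[s, :, :, j], part)
                coeffs = pywt.wavedec2(img, wavelet, level=levels, mode="periodization")
                new = [coeffs[0]]
                for detail in coeffs[1:]:
                    new.append(tuple(pywt.threshold(d, thresh, mode="soft")
                                     for d in detail))
                rec = pywt.waverec2(new, wavelet, mode="periodization")
                if part == "real":
                    out[s, :, :, j] = rec
                else:
                    out[s, :, :, j] = out[s, :, :, j].real + 1j * rec
    return out


def _wavelet_l1(u_img: np.ndarray, wavelet: str, levels: int) -> float:
    tot = 0.0
    for s in range(u_img.shape[0]):
        for j in range(u_img.shape[-1]):
            for part in ("real", "imag"):
                img = getattr(u_img[s, :, :, j], part)
                coeffs = pywt.wavedec2(img, wavelet, level=levels, mode="periodization")
                for detail in coeffs[1:]:
                    tot += sum(np.abs(d).sum() for d in detail)
    return tot


def _solve_cg(op, phi_lines: np.ndarray, d: np.ndarray, iters: int,
              ridge: float = 1e-3) -> SpatialFactor:
    """CG on the normal equations with temporal Jacobi scaling and a ridge.

    The temporal components span orders of magnitude in signal content, so
    the unknowns are rescaled by the column norms of the per-line weight
    matrix (Jacobi preconditioning); a small Tikhonov term (``ridge`` times
    the estimated largest normal-operator eigenvalue) keeps the weakly
    observed directions from amplifying subspace-truncation error.  The
    quadratic objective is non-increasing over CG iterates.
    """
    scale = np.linalg.norm(phi_lines, axis=0)
    scale[scale == 0] = 1.0
    phi_s = phi_lines / scale

    b = op.adjoint_weighted(d, phi_s)
    d_norm2 = float(np.vdot(d, d).real)

    mu = 0.0
    if ridge > 0:
        # crude largest-eigenvalue estimate from two power steps
        z = b / np.linalg.norm(b)
        z2, _ = op.gradient_weighted(z, phi_s)
        mu = ridge * float(np.linalg.norm(z2))

    def normal(u):
        return op.gradient_weighted(u, phi_s)[0] + mu * u

    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    # f(x) = 0.5||Ex - d||^2 + 0.5 mu ||x||^2 (up to the constant 0.5 d'd)
    trace = [0.5 * d_norm2]
    for _ in range(iters):
        ap = normal(p)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        # objective bookkeeping without an extra sweep:
        # f_{k+1} = f_k - alpha Re<r_k, p> - 0.5 alpha^2 <p, Ap>  with grad = -r
        trace.append(trace[-1] - alpha * rs + 0.5 * alpha ** 2 * denom)
        rs_new = float(np.vdot(r, r).real)
        if rs_new < 1e-16 * rs:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    resid = float(np.linalg.norm(op.forward_weighted(x, phi_s) - d)
                  / np.sqrt(d_norm2))
    return SpatialFactor(u_x=x / scale, operator=op, residual=resid,
                         objective_trace=trace)


def solve_spatial(raw, phi: Phi, operator, bins, lam_w: float = 0.0,
                  iters: int = 25, wavelet: str = "db4", levels: int = 3,
                  power_iters: int = 5, seed: int = 0, ridge: float = 1e-4,
                  phi_lines: np.ndarray | None = None) -> SpatialFactor:
    """Monotone FISTA for the spatial factor.

    ``lam_w`` is relative: the absolute threshold is ``lam_w`` times the
    largest wavelet-coefficient magnitude of the initial iterate.
    """
    if lam_w < 0:
        raise ValueError("lam_w must be non-negative")
    if phi_lines is None:
        phi_lines = imaging_line_weights(raw, phi, bins)
    d = raw.imaging
    rank = phi_lines.shape[1]
    op = operator

    if lam_w == 0:
        # pure least squares: conjugate gradients on the normal equations
        # (far fewer operator sweeps than proximal gradient; the quadratic
        # objective is non-increasing over CG iterates)
        return _solve_cg(op, phi_lines, d, iters, ridge=ridge)

    # Lipschitz constant of the data term by power iteration
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((op.n_slices, op.n_vox, rank)) \
        + 1j * rng.standard_normal((op.n_slices, op.n_vox, rank))
    x /= np.linalg.norm(x)
    lam_max = 0.0
    for _ in range(power_iters):
        z, _ = op.gradient_weighted(x, phi_lines)
        lam_max = np.linalg.norm(z)
        if lam_max == 0:
            raise RuntimeError("Lipschitz estimation failed: zero operator")
        x = z / lam_max
    lip = lam_max * 1.05

    def fwd(u):
        return op.forward_weighted(u, phi_lines)

    u = op.adjoint_weighted(d, phi_lines) / lip
    d_norm = np.linalg.norm(d)

    thresh0 = 0.0
    if lam_w > 0:
        img0 = op.embed(u)
        coeffs = pywt.wavedec2(np.abs(img0[..., 0]), wavelet, level=levels,
                               mode="periodization")
        thresh0 = lam_w * max(np.abs(d).max() for det in coeffs[1:] for d in det)

    def objective(uu):
        r = fwd(uu) - d
        obj = 0.5 * np.linalg.norm(r) ** 2
        if lam_w > 0:
            obj += thresh0 * lip * _wavelet_l1(op.embed(uu), wavelet, levels)
        return float(obj), float(np.linalg.norm(r) / d_norm)

    def prox(uu):
        if lam_w <= 0:
            return uu
        img = op.embed(uu)
        img = _wavelet_prox(img, thresh0, wavelet, levels)
        return img[:, op.support, :]

    obj, resid = objective(u)
    trace = [obj]
    y = u.copy()
    t_mom = 1.0
    for _ in range(iters):
        grad, _ = op.gradient_weighted(y, phi_lines, d)
        cand = prox(y - grad / lip)
        obj_c, resid_c = objective(cand)
        if obj_c <= obj * (1 + 1e-12):
            t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom ** 2))
            y = cand + ((t_mom - 1) / t_new) * (cand - u)
            u, obj, resid = cand, obj_c, resid_c
            t_mom = t_new
        else:
            # restart momentum from the best iterate
            y = u.copy()
            t_mom = 1.0
        trace.append(obj)

    return SpatialFactor(u_x=u, operator=op, residual=resid, objective_trace=trace)
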