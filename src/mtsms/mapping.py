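"""Two-step voxelwise multiparametric fitting from rendered recovery curves.

Curves are rendered at one fixed motion state (end-expiration, diastole by
default).  Step 1 matches each voxel's full dual-flip-angle curve against the
signal dictionary and refines (A, B, beta, T2) by nonlinear least squares
(T1 is free during refinement but discarded).  Step 2 re-fits T1 from the
low-flip-angle (3 deg) recovery periods only — where the Look-Locker readout
perturbation is smallest — with (B, beta, T2) held at their step-1 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .lrt import Phi
from .sequence import SignalDictionary, signal_curve_grid

__all__ = ["ParameterMaps", "extract_curves", "fit_step1", "fit_step2", "map_volume"]


@dataclass
class ParameterMaps:
    """Per-slice parameter maps on the image grid plus fit diagnostics."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    amp: np.ndarray
    eff: np.ndarray
    b1: np.ndarray
    fitted: np.ndarray            # bool mask of fitted voxels
    residual: np.ndarray          # relative fit residual per voxel
    c_star: int = 0
    r_star: int = 0

    def to_nifti(self, out_dir, voxel_mm=(1.0, 1.0, 8.0), prefix="map"):
        import os

        import nibabel as nib

        os.makedirs(out_dir, exist_ok=True)
        aff = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])
        paths = []
        for name in ("t1_ms", "t2_ms", "amp", "eff", "b1"):
            arr = getattr(self, name)
            for s in range(arr.shape[0]):
                img = nib.Nifti1Image(arr[s].astype(np.float32)[:, :, None], aff)
                p = os.path.join(out_dir, f"{prefix}_{name}_slice{s}.nii")
                nib.save(img, p)
                paths.append(p)
        return paths


class _CurveModel:
    """Vectorized closed-form curve evaluator in dictionary row order.

    Row-wise constants (tau, alpha_k, alpha_{k-1}, n) are precomputed so one
    call is a single numpy expression — the inner loop of the voxelwise fits.
    """

    def __init__(self, dictionary: SignalDictionary, combo_subset=None):
        tau, ak, ap, nn = [], [], [], []
        ng = dictionary.n_grid.astype(float)
        for p in dictionary.periods:
            if combo_subset is not None and p.combo_index not in combo_subset:
                continue
            tau.append(np.full(ng.size, p.prep_ms))
            ak.append(np.full(ng.size, p.flip_deg))
            ap.append(np.full(ng.size, p.prev_flip_deg))
            nn.append(ng)
        self.tau = np.concatenate(tau)
        self.ak = np.concatenate(ak)
        self.ap = np.concatenate(ap)
        self.n = np.concatenate(nn)
        self.tr = dictionary.tr_ms

    def __call__(self, amp, eff, b1, t1_ms, t2_ms):
        e1 = np.exp(-self.tr / t1_ms)
        ca = np.cos(np.deg2rad(b1 * self.ak))
        sa = np.sin(np.deg2rad(b1 * self.ak))
        cap = np.cos(np.deg2rad(b1 * self.ap))
        q = (1.0 - e1 * ca) / (1.0 - e1 * cap)
        prep = eff * q * np.exp(-self.tau / t2_ms)
        ss = amp * (1.0 - e1) / (1.0 - e1 * ca)
        return ss * (1.0 + (prep - 1.0) * (e1 * ca) ** self.n) * sa


def model_curve(amp, eff, b1, t1_ms, t2_ms, dictionary: SignalDictionary,
                combo_subset=None) -> np.ndarray:
    """Closed-form curve in dictionary row order (optionally a combo subset)."""
    return _CurveModel(dictionary, combo_subset)(amp, eff, b1, t1_ms, t2_ms)


def extract_curves(u_x, phi: Phi, c_star: int, r_star: int) -> np.ndarray:
    """Render the (n x combo) recovery curves per voxel at a fixed motion state.

    Returns (..., n_rows) with rows ordered combo-major to match the
    dictionary layout.  ``u_x``: (..., L1).
    """
    if not (0 <= c_star < phi.n_card) or not (0 <= r_star < phi.n_resp):
        raise IndexError("empty/invalid bin requested")
    n_grid = phi.n_grid
    n_combo = phi.subspaces.u_ta.shape[0]
    ns = np.tile(n_grid, n_combo)
    ks = np.repeat(np.arange(n_combo), n_grid.size)
    w = phi.weights(ns, ks, c_star, r_star)        # (rows, L1)
    return np.tensordot(u_x, w, axes=([-1], [1]))


def signed_magnitude(curves: np.ndarray, rows_per_combo: int | None = None) -> np.ndarray:
    """Phase-correct each voxel by its late-n (steady-state) phase and keep
    the real part.

    With combo-major row ordering the reference is the mean over the final
    quarter of the n-grid of every combo (steady-state approach, positive in
    the signal model); without ``rows_per_combo`` the last rows overall.
    """
    rows = curves.shape[-1]
    if rows_per_combo:
        tail = max(rows_per_combo // 4, 1)
        idx = np.concatenate([
            np.arange(start + rows_per_combo - tail, start + rows_per_combo)
            for start in range(0, rows, rows_per_combo)])
    else:
        idx = np.arange(rows - max(rows // 4, 1), rows)
    ref = curves[..., idx].mean(axis=-1)
    ph = np.exp(-1j * np.angle(ref))
    return (curves * ph[..., None]).real


@dataclass
class _Step1Result:
    amp: np.ndarray
    eff: np.ndarray
    b1: np.ndarray
    t2_ms: np.ndarray
    t1_seed_ms: np.ndarray
    residual: np.ndarray
    fitted: np.ndarray


def fit_step1(curves: np.ndarray, dictionary: SignalDictionary,
              refine: bool = True, zero_tol: float = 1e-6) -> _Step1Result:
    """Dictionary matching + local refinement of (A, B, beta, T2).

    ``curves``: (n_vox, n_rows) real (already signed-magnitude).  Matching
    maximizes the inner product with the L2-normalized atoms (amplitudes are
    positive); refinement is bounded nonlinear least squares with T1 free.
    """
    curves = np.atleast_2d(curves)
    n_vox = curves.shape[0]
    norms = np.linalg.norm(curves, axis=1)
    fitted = norms > zero_tol * max(norms.max(), 1e-300)

    out = _Step1Result(
        amp=np.zeros(n_vox), eff=np.full(n_vox, -1.0), b1=np.ones(n_vox),
        t2_ms=np.full(n_vox, np.nan), t1_seed_ms=np.full(n_vox, np.nan),
        residual=np.full(n_vox, np.nan), fitted=fitted,
    )
    if not fitted.any():
        return out

    x = curves[fitted] / norms[fitted][:, None]
    scores = x @ dictionary.atoms_norm            # (n_fit, n_atoms)
    best = scores.argmax(axis=1)
    model = _CurveModel(dictionary)

    t1 = np.empty(best.size)
    t2 = np.empty(best.size)
    b1 = np.empty(best.size)
    eff = np.empty(best.size)
    amp = np.empty(best.size)
    resid = np.empty(best.size)
    atom_norms = np.linalg.norm(dictionary.atoms, axis=0)
    for i, col in enumerate(best):
        t1_i, t2_i, b1_i, eff_i = dictionary.params_of(col)
        scale = norms[fitted][i] * scores[i, col] / atom_norms[col] \
            if atom_norms[col] > 0 else norms[fitted][i]
        if not np.isfinite(scale) or scale <= 0:
            scale = norms[fitted][i]
        # clamp the seed strictly inside the refinement bounds
        p0 = np.array([max(scale, 1e-6),
                       np.clip(eff_i, -1.04, -0.51),
                       np.clip(b1_i, 0.01, 1.59),
                       np.clip(t2_i, 5.1, 3400.0),
                       np.clip(t1_i, 51.0, 3400.0)])
        yv = curves[fitted][i]
        if refine:
            def res(p):
                # p = (amp, eff, b1, t2, t1); model takes (amp, eff, b1, t1, t2)
                return model(p[0], p[1], p[2], p[4], p[3]) - yv

            sol = least_squares(
                res, p0,
                bounds=([0.0, -1.05, 0.0, 5.0, 50.0],
                        [np.inf, -0.5, 1.6, 3500.0, 3500.0]),
                method="trf", xtol=1e-10, ftol=1e-10, max_nfev=200,
            )
            amp[i], eff[i], b1[i], t2[i], t1[i] = sol.x
            resid[i] = np.linalg.norm(sol.fun) / max(np.linalg.norm(yv), 1e-300)
        else:
            amp[i], eff[i], b1[i], t2[i], t1[i] = p0
            resid[i] = np.linalg.norm(
                model(p0[0], p0[1], p0[2], p0[4], p0[3]) - yv
            ) / max(np.linalg.norm(yv), 1e-300)

    out.amp[fitted] = amp
    out.eff[fitted] = eff
    out.b1[fitted] = b1
    out.t2_ms[fitted] = t2
    out.t1_seed_ms[fitted] = t1
    out.residual[fitted] = resid
    return out


def fit_step2(curves: np.ndarray, step1: _Step1Result,
              dictionary: SignalDictionary) -> np.ndarray:
    """T1 from the low-flip-angle recovery periods only, (B, beta, T2) fixed.

    ``curves``: same layout as step 1; the rows belonging to the smaller of
    the two flip angles are selected internally.
    """
    periods = dictionary.periods
    flips = sorted({p.flip_deg for p in periods})
    if len(flips) < 2:
        raise ValueError("no low-flip-angle combos in schedule")
    low = flips[0]
    low_combos = {p.combo_index for p in periods if p.flip_deg == low}
    nrows = dictionary.n_grid.size
    row_mask = np.concatenate([
        np.full(nrows, p.flip_deg == low) for p in periods
    ])

    model = _CurveModel(dictionary, combo_subset=low_combos)
    curves = np.atleast_2d(curves)
    t1_out = np.full(curves.shape[0], np.nan)
    for i in range(curves.shape[0]):
        if not step1.fitted[i]:
            continue
        yv = curves[i][row_mask]
        eff_i, b1_i, t2_i = step1.eff[i], step1.b1[i], step1.t2_ms[i]
        t1_0 = step1.t1_seed_ms[i]
        if not np.isfinite(t1_0):
            t1_0 = 1000.0

        def res(p):
            return model(p[0], eff_i, b1_i, p[1], t2_i) - yv

        sol = least_squares(
            res, np.array([max(step1.amp[i], 1e-6), np.clip(t1_0, 100.0, 3000.0)]),
            bounds=([0.0, 100.0], [np.inf, 3000.0]),
            method="trf", xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        t1_out[i] = sol.x[1]
    return t1_out


def map_volume(u_x, phi: Phi, dictionary: SignalDictionary,
               c_star: int, r_star: int, operator=None,
               support_threshold: float = 0.05) -> ParameterMaps:
    """Orchestrate extract -> step 1 -> step 2 over all voxels of a slice stack.

    ``u_x``: (n_slices, n_vox, L1) flat spatial factor; ``operator`` (if
    given) provides the support embedding back to image grids.
    """
    curves_c = extract_curves(u_x, phi, c_star, r_star)   # (n_slices, n_vox, rows)
    n_slices, n_vox, rows = curves_c.shape
    flat = signed_magnitude(curves_c.reshape(-1, rows),
                            rows_per_combo=phi.n_grid.size)
    energy = np.linalg.norm(flat, axis=1)
    # background voxels (below support_threshold of peak energy) are not fitted
    weak = energy < support_threshold * energy.max()
    flat[weak] = 0.0
    step1 = fit_step1(flat, dictionary, zero_tol=1e-12)
    step1.fitted &= ~weak
    t1 = fit_step2(flat, step1, dictionary)

    def shape_map(v, fill=np.nan):
        arr = np.where(step1.fitted, v, fill).reshape(n_slices, n_vox)
        if operator is not None:
            out = np.full((n_slices,) + operator.support.shape, fill)
            for s in range(n_slices):
                out[s][operator.support] = arr[s]
            return out
        return arr

    return ParameterMaps(
        t1_ms=shape_map(t1),
        t2_ms=shape_map(step1.t2_ms),
        amp=shape_map(step1.amp, fill=0.0),
        eff=shape_map(step1.eff),
        b1=shape_map(step1.b1),
        fitted=shape_map(step1.fitted.astype(float), fill=0.0) > 0.5,
        residual=shape_map(step1.residual),
        c_star=c_star, r_star=r_star,
    )
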