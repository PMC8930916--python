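"""Low-rank tensor engine: sampled 5-way training tensor, completion with
nuclear-norm + temporal-TV regularization under fixed relaxation subspaces,
HOSVD factor extraction, and the combined temporal factor tensor Phi.

Tensor axis order throughout: (feature, n, combo, cardiac bin, resp bin) =
modes 1..5.  Modes 2 and 3 are constrained to the ranges of the dictionary
subspaces U_T1 and U_ta; nuclear-norm penalties act on the unfoldings of
modes 1, 4 and 5; total variation is cyclic along the cardiac-bin axis
(phase is periodic) and non-cyclic along the respiratory axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import RelaxSubspaces

__all__ = [
    "SampledTrainingTensor",
    "FactorSet",
    "Phi",
    "unfold",
    "fold",
    "mode_product",
    "assemble_training_tensor",
    "complete_tensor",
    "hosvd_factors",
    "build_phi",
    "render",
]


# ---------------------------------------------------------------- utilities
def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-i unfolding (0-based): rows indexed by mode, columns by the rest."""
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def fold(m: np.ndarray, mode: int, shape) -> np.ndarray:
    shape = list(shape)
    full = [shape[mode]] + shape[:mode] + shape[mode + 1:]
    return np.moveaxis(m.reshape(full), 0, mode)


def mode_product(t: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """t x_mode mat  (mat: (new_dim, old_dim))."""
    return fold(mat @ unfold(t, mode), mode,
                t.shape[:mode] + (mat.shape[0],) + t.shape[mode + 1:])


def _svt(m: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft thresholding, Gram trick when one side is small."""
    rows, cols = m.shape
    if rows <= cols:
        g = m @ m.conj().T
        w, u = np.linalg.eigh(g)
        w = np.clip(w, 0, None)
        s = np.sqrt(w)
        keep = s > tau
        if not keep.any():
            return np.zeros_like(m)
        u = u[:, keep]
        s = s[keep]
        # V^H rows = (1/s) u^H m ; thresholded recon = u diag(s - tau) V^H
        return (u * ((s - tau) / s)) @ (u.conj().T @ m)
    return _svt(m.conj().T, tau).conj().T


def _nuclear(m: np.ndarray) -> float:
    rows, cols = m.shape
    if rows > cols:
        m = m.conj().T
    w = np.linalg.eigvalsh(m @ m.conj().T)
    return float(np.sqrt(np.clip(w, 0, None)).sum())


def _diff(t: np.ndarray, axis: int, cyclic: bool) -> np.ndarray:
    d = np.roll(t, -1, axis=axis) - t
    if not cyclic:
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(0, t.shape[axis] - 1)
        d = d[tuple(sl)]
    return d


def _tv_prox(v: np.ndarray, axis: int, w: float, cyclic: bool, n_iter: int = 40) -> np.ndarray:
    """prox of w * ||first differences along axis||_1 (complex soft clipping),
    by dual projected gradient."""
    if w <= 0 or v.shape[axis] < 2:
        return v.copy()
    x = np.moveaxis(v, axis, 0)
    m = x.shape[0]
    md = m if cyclic else m - 1
    p = np.zeros((md,) + x.shape[1:], dtype=v.dtype)

    def dt_p(p):  # D^T p
        out = np.zeros_like(x)
        if cyclic:
            out -= p
            out += np.roll(p, 1, axis=0)
        else:
            out[:-1] -= p
            out[1:] += p
        return out

    step = 0.25
    for _ in range(n_iter):
        z = x - dt_p(p)
        if cyclic:
            g = np.roll(z, -1, axis=0) - z
        else:
            g = z[1:] - z[:-1]
        p = p + step * g
        mag = np.abs(p)
        over = mag > w
        p[over] *= w / mag[over]
    return np.moveaxis(x - dt_p(p), 0, axis)


# ---------------------------------------------------------------- containers
@dataclass
class SampledTrainingTensor:
    """Observed training-tensor cells: averaged line features + sampling mask."""

    data: np.ndarray      # (F, Nn, K, C, R) complex, zero where unobserved
    mask: np.ndarray      # (Nn, K, C, R) bool
    counts: np.ndarray    # (Nn, K, C, R) int
    n_grid: np.ndarray    # intra-period excitation indices of the Nn axis

    @property
    def shape(self):
        return self.data.shape


@dataclass
class FactorSet:
    """HOSVD core + orthonormal factor matrices of the completed tensor."""

    core: np.ndarray
    u_feat: np.ndarray
    u_t1: np.ndarray
    u_ta: np.ndarray
    u_c: np.ndarray
    u_r: np.ndarray
    ranks: tuple

    def factors(self):
        return (self.u_feat, self.u_t1, self.u_ta, self.u_c, self.u_r)

    def reconstruct(self) -> np.ndarray:
        t = self.core
        for i, u in enumerate(self.factors()):
            t = mode_product(t, u, i)
        return t


@dataclass
class Phi:
    """Combined temporal factor tensor Phi = G x2 U_T1 x3 U_ta x4 U_c x5 U_r,
    stored in factored form and queried lazily by (n, k, c, r)."""

    core: np.ndarray          # (L1, L2, L3, L4, L5)
    subspaces: RelaxSubspaces
    u_c: np.ndarray
    u_r: np.ndarray
    n_grid: np.ndarray

    @property
    def rank(self) -> int:
        return self.core.shape[0]

    @property
    def n_card(self) -> int:
        return self.u_c.shape[0]

    @property
    def n_resp(self) -> int:
        return self.u_r.shape[0]

    def weights(self, n_values, k_idx, c_idx, r_idx) -> np.ndarray:
        """(n_queries, L1) temporal weight vectors; n interpolated off-grid."""
        n_values = np.atleast_1d(np.asarray(n_values, dtype=float))
        k_idx = np.broadcast_to(np.atleast_1d(k_idx), n_values.shape)
        c_idx = np.broadcast_to(np.atleast_1d(c_idx), n_values.shape)
        r_idx = np.broadcast_to(np.atleast_1d(r_idx), n_values.shape)
        if (np.any(k_idx < 0) or np.any(k_idx >= self.subspaces.u_ta.shape[0])
                or np.any(c_idx < 0) or np.any(c_idx >= self.n_card)
                or np.any(r_idx < 0) or np.any(r_idx >= self.n_resp)):
            raise IndexError("query outside tensor index ranges")
        a = self.subspaces.u_t1_at(n_values)          # (q, L2)
        b = self.subspaces.u_ta[np.asarray(k_idx)]    # (q, L3)
        c = self.u_c[np.asarray(c_idx)]
        d = self.u_r[np.asarray(r_idx)]
        return np.einsum("iabcd,qa,qb,qc,qd->qi", self.core, a, b, c, d, optimize=True)

    def full(self) -> np.ndarray:
        """Materialize Phi on the full (n_grid, K, C, R) grid (small cases/tests)."""
        t = self.core
        t = mode_product(t, self.subspaces.u_t1, 1)
        t = mode_product(t, self.subspaces.u_ta, 2)
        t = mode_product(t, self.u_c, 3)
        t = mode_product(t, self.u_r, 4)
        return t


# ---------------------------------------------------------------- operations
def assemble_training_tensor(raw, bins, schedule, subspaces: RelaxSubspaces,
                             features: np.ndarray | None = None,
                             contrast_correct: bool = True) -> SampledTrainingTensor:
    """Deposit per-training-line feature vectors at (n, combo, cardiac, resp).

    ``features``: optional (n_training, F) override (e.g. coil-compressed);
    defaults to the flattened raw training samples.  Lines mapping to the
    same cell are averaged; the n-axis is decimated to the subspace grid
    (nearest grid point).  With ``contrast_correct`` each line's relaxation
    sweep is shifted from its own n to the cell's grid n through the
    dictionary subspace before averaging, so cells hold point samples of the
    recovery curve rather than short-window averages (the early inversion
    recovery would otherwise be blurred).
    """
    lines = raw.training_lines
    if features is None:
        features = raw.training.reshape(len(lines), -1)
    n_grid = subspaces.n_grid
    combos = schedule.combo_index[lines]
    n_idx = schedule.n_index[lines]
    grid_pos = np.abs(n_idx[:, None] - n_grid[None, :]).argmin(axis=1)

    if contrast_correct:
        a_line = subspaces.u_t1_at(n_idx)
        a_grid = subspaces.u_t1_at(n_grid[grid_pos])
        b_line = subspaces.u_ta[combos]
        w_line = (a_line[:, :, None] * b_line[:, None, :]).reshape(len(lines), -1)
        w_grid = (a_grid[:, :, None] * b_line[:, None, :]).reshape(len(lines), -1)
        coef, *_ = np.linalg.lstsq(w_line, features, rcond=None)
        features = features + (w_grid - w_line) @ coef

    n_card = bins.n_card
    n_resp = bins.n_resp
    shape = (features.shape[1], n_grid.size, int(combos.max()) + 1, n_card, n_resp)
    data = np.zeros(shape, dtype=np.complex128)
    counts = np.zeros(shape[1:], dtype=np.int64)
    np.add.at(counts, (grid_pos, combos, bins.cardiac_bin, bins.resp_bin), 1)
    np.add.at(data.transpose(1, 2, 3, 4, 0),
              (grid_pos, combos, bins.cardiac_bin, bins.resp_bin), features)
    mask = counts > 0
    data[:, mask] /= counts[mask]
    return SampledTrainingTensor(data=data, mask=mask, counts=counts, n_grid=n_grid)


def nn_fill(st: SampledTrainingTensor) -> np.ndarray:
    """Nearest-neighbor fill of unobserved cells (view-sharing initialization).

    Missing motion states borrow the closest observed cell along the cardiac
    axis (cyclic), then respiratory, then the n and combo axes.  This is only
    an initialization: the completion solver refines it under the low-rank
    and subspace constraints.
    """
    d = st.data.copy()
    filled = st.mask.copy()
    for axis, cyclic in ((2, True), (3, False), (0, False), (1, False)):
        n_ax = st.mask.shape[axis]
        for shift in range(1, n_ax):
            for sgn in (1, -1):
                if filled.all():
                    return d
                src = np.roll(filled, sgn * shift, axis=axis)
                src_d = np.roll(d, sgn * shift, axis=axis + 1)
                if not cyclic:
                    sl = [slice(None)] * 4
                    sl[axis] = slice(0, shift) if sgn == 1 else slice(n_ax - shift, n_ax)
                    src = src.copy()
                    src[tuple(sl)] = False
                take = (~filled) & src
                d[:, take] = src_d[:, take]
                filled |= take
    return d


def adaptive_ranks(st: SampledTrainingTensor, max_ranks, energy: float = 0.9999,
                   feature_energy: float = 0.999999):
    """Cap multilinear ranks by the energy spectrum of the view-shared tensor.

    For the motion modes (4: cardiac, 5: respiratory) the rank is the
    smallest capturing ``energy`` of the squared singular values of the
    NN-filled tensor's unfolding, never above the configured maximum — a
    static scan thus collapses the motion modes to rank ~1 instead of
    letting the completion invent bin-to-bin variation.  The feature mode
    (1) uses the much tighter ``feature_energy`` since it doubles as the
    spatial rank of the reconstruction.
    """
    d0 = nn_fill(st)
    ranks = list(max_ranks)
    for mode, thr in ((0, feature_energy), (3, energy), (4, energy)):
        s = np.linalg.svd(unfold(d0, mode), compute_uv=False)
        frac = np.cumsum(s ** 2) / max((s ** 2).sum(), 1e-300)
        ranks[mode] = int(min(max_ranks[mode], np.searchsorted(frac, thr) + 1))
    return tuple(ranks)


def _objective(d, st, proj2, proj3, lam, lam_c, lam_r):
    resid = 0.5 * np.linalg.norm((d - st.data)[:, st.mask]) ** 2
    obj = resid
    if lam > 0:
        for mode in (0, 3, 4):
            obj += lam * _nuclear(unfold(d, mode))
    if lam_c > 0:
        obj += lam_c * np.abs(_diff(d, 3, cyclic=True)).sum()
    if lam_r > 0:
        obj += lam_r * np.abs(_diff(d, 4, cyclic=False)).sum()
    return float(obj)


def complete_tensor(st: SampledTrainingTensor, subspaces: RelaxSubspaces,
                    lam: float | None = None, lam_c: float | None = None,
                    lam_r: float | None = None, iters: int = 60,
                    continuation: bool = True, polish_ranks=None,
                    polish_iters: int = 30, init: str = "nn",
                    verbose: bool = False):
    """Complete the sampled training tensor (data consistency + mode-1/4/5
    nuclear norms + cardiac/respiratory TV) subject to mode-2/3 subspace
    membership, by a monotone proximal alternating scheme.

    Returns ``(d_hat, trace)`` where ``trace`` is a list of per-iteration
    dicts (iteration, lam, objective, accepted step).  Raises on sustained
    objective increase (non-convergence guard).
    """
    u2 = subspaces.u_t1
    u3 = subspaces.u_ta
    proj2 = u2 @ u2.conj().T
    proj3 = u3 @ u3.conj().T

    def project_subspaces(d):
        d = mode_product(d, proj2, 1)
        return mode_product(d, proj3, 2)

    d0 = nn_fill(st) if init == "nn" else st.data.copy()
    d = project_subspaces(d0)
    sigma_max = np.linalg.svd(unfold(d, 0), compute_uv=False)[0]
    if lam is None:
        lam = 0.01 * sigma_max
    if lam_c is None:
        lam_c = 0.02 * lam
    if lam_r is None:
        lam_r = 0.02 * lam

    lam_stages = [lam]
    if continuation:
        lam_stages = [lam * 16, lam * 4, lam]
        iters_per = max(iters // len(lam_stages), 1)
    else:
        iters_per = iters

    trace = []
    rise_streak = 0
    it_total = 0
    for lam_k in lam_stages:
        scale = lam_k / lam if lam > 0 else 1.0
        lc = lam_c * scale
        lr = lam_r * scale
        obj = _objective(d, st, proj2, proj3, lam_k, lc, lr)
        step = 1.0
        for it in range(iters_per):
            cand = d.copy()
            cand[:, st.mask] -= step * (cand - st.data)[:, st.mask]
            cand = project_subspaces(cand)
            cand = fold(_svt(unfold(cand, 0), step * lam_k), 0, cand.shape)
            cand = fold(_svt(unfold(cand, 3), step * lam_k), 3, cand.shape)
            cand = _tv_prox(cand, 3, step * lc, cyclic=True)
            cand = fold(_svt(unfold(cand, 4), step * lam_k), 4, cand.shape)
            cand = _tv_prox(cand, 4, step * lr, cyclic=False)
            cand = project_subspaces(cand)
            obj_c = _objective(cand, st, proj2, proj3, lam_k, lc, lr)
            if obj_c <= obj * (1 + 1e-12) + 1e-15:
                accepted = True
                if obj_c > obj * (1 + 1e-6):
                    rise_streak += 1
                    if rise_streak >= 10:
                        raise RuntimeError(
                            "tensor completion failed to converge "
                            f"(objective rising for {rise_streak} iterations); trace={trace[-12:]}")
                else:
                    rise_streak = 0
                d = cand
                obj = obj_c
            else:
                accepted = False
                step *= 0.5
            trace.append({"iter": it_total, "lam": lam_k, "objective": obj,
                          "step": step, "accepted": accepted})
            it_total += 1
            if step < 1e-8:
                break

    if polish_ranks is not None:
        # alternate exact data consistency with hard multilinear-rank
        # truncation; the iteration is not strictly monotone, so the best
        # iterate (lowest data-consistency objective) is tracked and returned
        best = d
        best_obj = _objective(d, st, proj2, proj3, 0.0, 0.0, 0.0)
        cur = d
        for it in range(polish_iters):
            cand = cur.copy()
            cand[:, st.mask] = st.data[:, st.mask]
            fs = hosvd_factors(cand, polish_ranks, subspaces=subspaces)
            cur = fs.reconstruct()
            obj_c = _objective(cur, st, proj2, proj3, 0.0, 0.0, 0.0)
            improved = obj_c <= best_obj * (1 + 1e-12) + 1e-15
            if improved:
                best, best_obj = cur, obj_c
            trace.append({"iter": it_total, "lam": 0.0, "objective": best_obj,
                          "step": 1.0, "accepted": improved})
            it_total += 1
        d = best
    return d, trace


def _top_left_singular(m: np.ndarray, rank: int) -> np.ndarray:
    rows, cols = m.shape
    if rows <= cols:
        w, u = np.linalg.eigh(m @ m.conj().T)
        order = np.argsort(w)[::-1][:rank]
        return u[:, order]
    u, _, _ = np.linalg.svd(m, full_matrices=False)
    return u[:, :rank]


def hosvd_factors(d_hat: np.ndarray, ranks, subspaces: RelaxSubspaces | None = None) -> FactorSet:
    """Truncated HOSVD; modes 2/3 use the fixed relaxation subspaces when given."""
    ranks = tuple(int(r) for r in ranks)
    if any(r > s for r, s in zip(ranks, d_hat.shape)):
        raise ValueError("ranks exceed tensor dimensions")
    factors = []
    for mode in range(5):
        if subspaces is not None and mode == 1:
            u = subspaces.u_t1[:, :ranks[1]].astype(d_hat.dtype)
        elif subspaces is not None and mode == 2:
            u = subspaces.u_ta[:, :ranks[2]].astype(d_hat.dtype)
        else:
            u = _top_left_singular(unfold(d_hat, mode), ranks[mode])
        factors.append(u)
    core = d_hat
    for mode, u in enumerate(factors):
        core = mode_product(core, u.conj().T, mode)
    return FactorSet(core=core, u_feat=factors[0], u_t1=factors[1], u_ta=factors[2],
                     u_c=factors[3], u_r=factors[4], ranks=ranks)


def build_phi(fs: FactorSet, subspaces: RelaxSubspaces) -> Phi:
    """Combined temporal tensor; the stored subspaces provide off-grid n lookup."""
    l2 = fs.u_t1.shape[1]
    eval_table = subspaces.eval_table
    if eval_table is not None:
        eval_table = eval_table[:, :l2]
    sub = RelaxSubspaces(
        u_t1=np.real_if_close(fs.u_t1) if np.isrealobj(subspaces.u_t1) else fs.u_t1,
        u_ta=np.real_if_close(fs.u_ta) if np.isrealobj(subspaces.u_ta) else fs.u_ta,
        n_grid=subspaces.n_grid,
        sv_t1=subspaces.sv_t1, sv_ta=subspaces.sv_ta,
        recon_error=subspaces.recon_error,
        eval_table=eval_table, eval_grid=subspaces.eval_grid,
    )
    return Phi(core=fs.core, subspaces=sub, u_c=fs.u_c, u_r=fs.u_r,
               n_grid=subspaces.n_grid)


def render(u_x: np.ndarray, phi: Phi, n_values, k_idx, c_idx, r_idx) -> np.ndarray:
    """Images at arbitrary (n, k, c, r) tuples: (..., n_queries) = u_x @ weights^T.

    ``u_x``: (..., L1) spatial basis; never materializes the full 5-way array.
    """
    w = phi.weights(n_values, k_idx, c_idx, r_idx)  # (q, L1)
    return np.tensordot(u_x, w, axes=([-1], [1]))
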