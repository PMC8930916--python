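"""Tensor utilities, completion solver, HOSVD extraction and lazy rendering."""

import numpy as np
import pytest

from mtsms.lrt import (Phi, SampledTrainingTensor, _svt, _tv_prox, build_phi,
                       complete_tensor, fold, hosvd_factors, mode_product,
                       render, unfold)
from mtsms.sequence import RelaxSubspaces


def _random_orthonormal(rng, n, r):
    q, _ = np.linalg.qr(rng.standard_normal((n, r)) + 1j * rng.standard_normal((n, r)))
    return q[:, :r]


def _random_lowrank_tensor(rng, dims, ranks):
    core = rng.standard_normal(ranks) + 1j * rng.standard_normal(ranks)
    factors = [_random_orthonormal(rng, n, r) for n, r in zip(dims, ranks)]
    t = core
    for i, u in enumerate(factors):
        t = mode_product(t, u, i)
    return t, core, factors


def _subspaces_from(factors, dims):
    n_grid = np.arange(1, dims[1] + 1)
    return RelaxSubspaces(u_t1=factors[1], u_ta=factors[2], n_grid=n_grid,
                          sv_t1=np.ones(factors[1].shape[1]),
                          sv_ta=np.ones(factors[2].shape[1]), recon_error=0.0)


class TestTensorAlgebra:
    def test_unfold_fold_roundtrip(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 4, 5, 2, 3))
        for mode in range(5):
            assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_svt_matches_direct_svd_thresholding(self):
        rng = np.random.default_rng(1)
        for shape in [(6, 40), (40, 6)]:
            m = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            tau = 2.0
            u, s, vh = np.linalg.svd(m, full_matrices=False)
            direct = (u * np.clip(s - tau, 0, None)) @ vh
            assert np.allclose(_svt(m, tau), direct, atol=1e-10)

    def test_tv_prox_against_dual_qp_oracle(self):
        # prox_{w||Dx||_1}(v) = v - D^T p*,  p* = argmin_{|p|<=w} ||v - D^T p||^2:
        # a box-constrained least-squares problem solved exactly by lsq_linear
        from scipy.optimize import lsq_linear

        rng = np.random.default_rng(2)
        v = rng.standard_normal(8)
        w = 0.3
        for cyclic in (False, True):
            n = v.size
            m = n if cyclic else n - 1
            dmat = np.zeros((m, n))
            for i in range(m):
                dmat[i, i] = -1.0
                dmat[i, (i + 1) % n] = 1.0
            sol = lsq_linear(dmat.T, v, bounds=(-w, w), tol=1e-14)
            ref = v - dmat.T @ sol.x
            got = _tv_prox(v.astype(complex), 0, w, cyclic, n_iter=5000).real
            assert np.allclose(got, ref, atol=1e-6)


class TestHosvd:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        dims, ranks = (8, 6, 5, 7, 4), (3, 2, 2, 3, 2)
        t, _, _ = _random_lowrank_tensor(rng, dims, ranks)
        fs = hosvd_factors(t, ranks)
        err = np.linalg.norm(fs.reconstruct() - t) / np.linalg.norm(t)
        assert err < 1e-10

    def test_rank_one_core_is_product_of_norms(self):
        rng = np.random.default_rng(4)
        vecs = [rng.standard_normal(n) for n in (5, 4, 3, 4, 2)]
        t = vecs[0][:, None, None, None, None]
        for i, v in enumerate(vecs[1:], start=1):
            shape = [1] * 5
            shape[i] = v.size
            t = t * v.reshape(shape)
        fs = hosvd_factors(t.astype(complex), (1, 1, 1, 1, 1))
        expected = np.prod([np.linalg.norm(v) for v in vecs])
        assert abs(fs.core).item() == pytest.approx(expected, rel=1e-10)

    def test_factor_orthonormality_and_ranks(self):
        rng = np.random.default_rng(5)
        t = rng.standard_normal((6, 5, 4, 7, 3)) + 1j * rng.standard_normal((6, 5, 4, 7, 3))
        fs = hosvd_factors(t, (3, 2, 2, 3, 2))
        for u in fs.factors():
            g = u.conj().T @ u
            assert np.abs(g - np.eye(g.shape[0])).max() < 1e-8

    def test_rank_exceeding_dims_raises(self):
        t = np.zeros((3, 3, 3, 3, 3))
        with pytest.raises(ValueError):
            hosvd_factors(t, (4, 1, 1, 1, 1))


class TestCompletion:
    def test_fully_observed_zero_lambda_is_projection(self):
        rng = np.random.default_rng(6)
        dims, ranks = (6, 5, 4, 4, 3), (3, 2, 2, 2, 2)
        t, _, factors = _random_lowrank_tensor(rng, dims, ranks)
        sub = _subspaces_from(factors, dims)
        st = SampledTrainingTensor(
            data=t, mask=np.ones(dims[1:], bool),
            counts=np.ones(dims[1:], np.int64), n_grid=np.arange(1, dims[1] + 1))
        d, _ = complete_tensor(st, sub, lam=0.0, lam_c=0.0, lam_r=0.0, iters=3,
                               continuation=False)
        # t already lies in the subspaces, so projection is a no-op
        assert np.linalg.norm(d - t) / np.linalg.norm(t) < 1e-10

    def test_seeded_lowrank_recovery_from_30pct_mask(self):
        rng = np.random.default_rng(7)
        dims, ranks = (12, 10, 8, 8, 6), (4, 3, 3, 3, 2)
        t, _, factors = _random_lowrank_tensor(rng, dims, ranks)
        sub = _subspaces_from(factors, dims)
        mask = rng.uniform(size=dims[1:]) < 0.30
        data = np.where(mask[None], t, 0)
        st = SampledTrainingTensor(data=data, mask=mask,
                                   counts=mask.astype(np.int64),
                                   n_grid=np.arange(1, dims[1] + 1))
        d, trace = complete_tensor(st, sub, iters=60, continuation=True,
                                   polish_ranks=ranks, polish_iters=60)
        err = np.linalg.norm(d - t) / np.linalg.norm(t)
        assert err < 1e-3

    def test_objective_non_increasing_within_stages(self):
        rng = np.random.default_rng(8)
        dims, ranks = (8, 6, 5, 6, 4), (3, 2, 2, 2, 2)
        t, _, factors = _random_lowrank_tensor(rng, dims, ranks)
        sub = _subspaces_from(factors, dims)
        mask = rng.uniform(size=dims[1:]) < 0.5
        st = SampledTrainingTensor(data=np.where(mask[None], t, 0), mask=mask,
                                   counts=mask.astype(np.int64),
                                   n_grid=np.arange(1, dims[1] + 1))
        _, trace = complete_tensor(st, sub, iters=30, continuation=True)
        by_stage = {}
        for rec in trace:
            if rec["accepted"]:
                by_stage.setdefault(rec["lam"], []).append(rec["objective"])
        for objs in by_stage.values():
            diffs = np.diff(objs)
            assert np.all(diffs <= 1e-9 * max(abs(objs[0]), 1.0))


class TestPhiRender:
    @pytest.fixture()
    def tiny_phi(self):
        rng = np.random.default_rng(9)
        dims, ranks = (8, 4, 2, 2, 2), (3, 2, 2, 2, 2)
        t, core, factors = _random_lowrank_tensor(rng, dims, ranks)
        sub = _subspaces_from(factors, dims)
        fs = hosvd_factors(t, ranks, subspaces=sub)
        return build_phi(fs, sub), t, fs

    def test_render_matches_brute_force_contraction(self, tiny_phi):
        phi, t, fs = tiny_phi
        u_x = fs.u_feat  # treat the feature factor as the spatial factor
        full = t
        for n_i, n in enumerate(phi.n_grid):
            for k in range(2):
                for c in range(2):
                    for r in range(2):
                        got = render(u_x, phi, [n], [k], [c], [r])[:, 0]
                        assert np.allclose(got, full[:, n_i, k, c, r], atol=1e-8)

    def test_identity_core_returns_spatial_columns(self):
        L = 3
        core = np.zeros((L, 1, 1, 1, 1), complex)
        sub = RelaxSubspaces(u_t1=np.ones((1, 1)), u_ta=np.ones((1, 1)),
                             n_grid=np.array([1]), sv_t1=np.ones(1),
                             sv_ta=np.ones(1), recon_error=0.0)
        phi = Phi(core=core, subspaces=sub, u_c=np.ones((1, 1)),
                  u_r=np.ones((1, 1)), n_grid=np.array([1]))
        rng = np.random.default_rng(10)
        u_x = rng.standard_normal((5, L))
        for j in range(L):
            core[:] = 0
            core[j, 0, 0, 0, 0] = 1.0
            got = render(u_x, phi, [1], [0], [0], [0])[:, 0]
            assert np.allclose(got, u_x[:, j])

    def test_render_linear_in_spatial_factor(self, tiny_phi):
        phi, _, fs = tiny_phi
        rng = np.random.default_rng(11)
        a = rng.standard_normal(fs.u_feat.shape) + 1j * rng.standard_normal(fs.u_feat.shape)
        b = rng.standard_normal(fs.u_feat.shape)
        q = (phi.n_grid[[1]], [1], [0], [1])
        assert np.allclose(render(2 * a + 3 * b, phi, *q),
                           2 * render(a, phi, *q) + 3 * render(b, phi, *q))

    def test_out_of_range_query_raises(self, tiny_phi):
        phi, _, _ = tiny_phi
        with pytest.raises(IndexError):
            phi.weights([1], [5], [0], [0])

    def test_factored_full_equals_contraction(self, tiny_phi):
        phi, t, fs = tiny_phi
        full = phi.full()
        t_temporal = mode_product(t, fs.u_feat.conj().T, 0)
        assert np.allclose(full, t_temporal, atol=1e-8)
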