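"""Schedule construction, the T2prep-IR FLASH closed form, the per-TR Bloch
recursion oracle, and the dictionary/subspace machinery."""

import numpy as np
import pytest

from mtsms.sequence import (GOLDEN_ANGLE_DEG, PeriodSpec, SequenceConfig,
                            TissueParams, bloch_oracle, build_dictionary,
                            build_schedule, default_grids, fit_subspaces,
                            q_factor, signal_curve)


class TestSchedule:
    def test_cycle_has_ten_distinct_combos(self):
        cfg = SequenceConfig(prep_ms=(0, 30, 40, 50, 60), flip_deg=(3, 10))
        cycle = cfg.combo_cycle()
        assert len(cycle) == 10
        assert len(set(cycle)) == 10
        # every prep duration is visited with both flip angles
        for tau in cfg.prep_ms:
            assert {a for t, a in cycle if t == tau} == {3.0, 10.0}

    def test_readouts_per_period(self):
        cfg = SequenceConfig(recovery_ms=2500.0, tr_ms=3.5)
        assert cfg.n_readouts_per_period == 714

    def test_one_full_cycle_covers_all_combos(self):
        sch = build_schedule(SequenceConfig(n_periods=10, recovery_ms=100.0))
        assert sorted(p.combo_index for p in sch.periods) == list(range(10))

    def test_period_combo_index_cycles_mod_ten(self):
        sch = build_schedule(SequenceConfig(n_periods=23, recovery_ms=100.0))
        for p_idx, p in enumerate(sch.periods):
            assert p.combo_index == p_idx % 10

    def test_roles_alternate_one_to_one(self, small_schedule):
        per_line = small_schedule.is_training.astype(int)
        n = small_schedule.config.n_readouts_per_period
        first_period = per_line[:n]
        assert np.array_equal(first_period[::2], np.ones(len(first_period[::2]), int))
        assert np.array_equal(first_period[1::2], np.zeros(len(first_period[1::2]), int))

    def test_training_lines_zero_angle_zero_step(self, small_schedule):
        tr = small_schedule.is_training
        assert np.all(small_schedule.radial_angle_deg[tr] == 0)
        assert np.all(small_schedule.phase_step[tr] == 0)

    def test_imaging_lines_golden_angle_increment(self, small_schedule):
        ang = small_schedule.radial_angle_deg[~small_schedule.is_training]
        inc = np.diff(ang) % 360.0
        assert np.allclose(inc, GOLDEN_ANGLE_DEG)

    def test_period_too_short_raises(self):
        with pytest.raises(ValueError, match="period too short"):
            build_schedule(SequenceConfig(recovery_ms=5.0, tr_ms=3.5))

    def test_table_roundtrip(self, small_schedule):
        tab = small_schedule.to_table()
        assert len(tab) == small_schedule.n_lines
        assert set(tab.columns) == {"period", "n", "role", "angle_deg",
                                    "phase_step", "time_ms"}


class TestQFactor:
    def test_equal_angles_give_unity(self):
        for t1 in (100.0, 1200.0, 3000.0):
            assert q_factor(t1, 0.9, 7.0, 7.0, 3.5) == pytest.approx(1.0)

    def test_worked_value(self):
        # E1 = exp(-3.5/1200); (1 - E1 cos3)/(1 - E1 cos10)
        assert q_factor(1200.0, 1.0, 3.0, 10.0, 3.5) == pytest.approx(0.23692, abs=2e-4)

    def test_fast_relaxation_limit(self):
        # TR/T1 -> inf means E1 -> 0 and the steady states coincide
        assert q_factor(1e-6, 1.0, 3.0, 10.0, 3.5) == pytest.approx(1.0, abs=1e-9)

    def test_continuous_in_t1(self):
        t1 = np.linspace(100, 3000, 20001)
        q = q_factor(t1, 1.0, 3.0, 10.0, 3.5)
        assert np.all(np.isfinite(q))
        # steps shrink proportionally with the grid: no jumps
        assert np.abs(np.diff(q)).max() < 5e-4


class TestSignalCurve:
    period = PeriodSpec(0, 30.0, 3.0, 10.0, 714)

    def test_worked_value_first_readout(self):
        t = TissueParams(amp=1, eff=-1, b1=1, t1_ms=1200, t2_ms=50)
        s = signal_curve(t, self.period, 1, tr_ms=3.5)
        assert s[0] == pytest.approx(-0.00446, abs=5e-6)

    def test_unit_bracket_gives_constant_steady_state(self):
        # choose eff so that B*Q*exp(-tau/T2) = 1 -> flat curve
        t1, t2, b1 = 1200.0, 50.0, 1.0
        q = q_factor(t1, b1, 3.0, 10.0, 3.5)
        eff = 1.0 / (q * np.exp(-30.0 / t2))
        t = TissueParams(amp=1, eff=eff, b1=b1, t1_ms=t1, t2_ms=t2)
        s = signal_curve(t, self.period, 100, tr_ms=3.5)
        e1 = np.exp(-3.5 / t1)
        ss = (1 - e1) / (1 - e1 * np.cos(np.deg2rad(3))) * np.sin(np.deg2rad(3))
        assert np.allclose(s, ss, rtol=1e-12)

    def test_large_n_approaches_steady_state(self):
        t = TissueParams(t1_ms=300.0, t2_ms=50.0, eff=-1.0)
        s = signal_curve(t, self.period, 5000, tr_ms=3.5)
        e1 = np.exp(-3.5 / 300.0)
        ss = (1 - e1) * np.sin(np.deg2rad(3)) / (1 - e1 * np.cos(np.deg2rad(3)))
        assert s[-1] == pytest.approx(ss, rel=1e-10)

    def test_approach_to_steady_state_strictly_decreasing(self):
        t = TissueParams(t1_ms=800.0, t2_ms=40.0)
        s = signal_curve(t, self.period, 400, tr_ms=3.5)
        e1 = np.exp(-3.5 / 800.0)
        ss = (1 - e1) * np.sin(np.deg2rad(3)) / (1 - e1 * np.cos(np.deg2rad(3)))
        gap = np.abs(s - ss)
        assert np.all(np.diff(gap) < 0)


class TestBlochOracle:
    @pytest.fixture(scope="class")
    def steady_schedule(self):
        # recovery long enough that every period truly ends in steady state,
        # the premise of the closed form's Q factor
        return build_schedule(SequenceConfig(recovery_ms=80000.0, n_periods=10))

    def test_closed_form_matches_recursion_randomized(self, steady_schedule):
        rng = np.random.default_rng(42)
        n = steady_schedule.config.n_readouts_per_period
        for _ in range(100):
            t = TissueParams(
                amp=rng.uniform(0.5, 2.0), eff=-rng.uniform(0.7, 1.0),
                b1=rng.uniform(0.5, 1.4), t1_ms=rng.uniform(100, 3000),
                t2_ms=rng.uniform(10, 300))
            sb = bloch_oracle(t, steady_schedule)
            for pi, per in enumerate(steady_schedule.periods):
                sc = signal_curve(t, per, n, tr_ms=3.5)
                err = np.abs(sb[pi * n:(pi + 1) * n] - sc).max() / np.abs(sc).max()
                assert err < 1e-9

    def test_saturation_recovery_when_prep_annihilates(self):
        sch = build_schedule(SequenceConfig(recovery_ms=350.0, n_periods=1))
        t = TissueParams(eff=0.0, t1_ms=500.0, t2_ms=50.0)
        s = bloch_oracle(t, sch)
        # magnetization grows from zero toward steady state, all same sign
        assert s[0] > 0 and np.all(np.diff(s) > 0)

    def test_zero_b1_gives_zero_signal(self, small_schedule):
        t = TissueParams(b1=0.0, t1_ms=900.0, t2_ms=45.0)
        assert np.all(bloch_oracle(t, small_schedule) == 0)


class TestDictionary:
    @pytest.fixture(scope="class")
    def dict_small(self, small_schedule):
        grids = default_grids(5, 4, 3, 2)
        return build_dictionary(small_schedule, grids)

    def test_default_grid_sizes_and_endpoints(self, small_schedule):
        d = build_dictionary(small_schedule)
        assert d.n_atoms == 21 * 21 * 7 * 7 == 21609
        assert d.t1_grid[0] == pytest.approx(100.0)
        assert d.t1_grid[-1] == pytest.approx(3000.0)
        assert d.t2_grid[0] == pytest.approx(10.0)
        assert d.t2_grid[-1] == pytest.approx(3000.0)
        assert d.b1_grid[0] == 0.0 and d.b1_grid[-1] == 1.5

    def test_column_reproducible_from_grid_entry(self, dict_small, small_schedule):
        col = 17
        t1, t2, b1, eff = dict_small.params_of(col)
        t = TissueParams(amp=1.0, eff=eff, b1=b1, t1_ms=t1, t2_ms=t2)
        curve = np.concatenate([
            signal_curve(t, p, 0, tr_ms=3.5, n_values=dict_small.n_grid)
            for p in dict_small.periods])
        assert np.allclose(curve, dict_small.atoms[:, col], rtol=1e-12)

    def test_empty_grid_raises(self, small_schedule):
        with pytest.raises(ValueError, match="empty"):
            build_dictionary(small_schedule, (np.array([]), np.array([1.0]),
                                              np.array([1.0]), np.array([-1.0])))


class TestSubspaces:
    @pytest.fixture(scope="class")
    def dict_small(self, small_schedule):
        return build_dictionary(small_schedule, default_grids(6, 5, 3, 2))

    def test_full_rank_reconstruction_error_zero(self, dict_small):
        n_n = dict_small.n_grid.size
        sub = fit_subspaces(dict_small, n_n, 10)
        assert sub.recon_error < 1e-10

    def test_error_non_increasing_in_rank(self, dict_small):
        errs = [fit_subspaces(dict_small, L, 4).recon_error for L in (1, 2, 4, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_orthonormal_columns(self, dict_small):
        sub = fit_subspaces(dict_small, 5, 6)
        assert np.abs(sub.u_t1.T @ sub.u_t1 - np.eye(5)).max() < 1e-10
        assert np.abs(sub.u_ta.T @ sub.u_ta - np.eye(6)).max() < 1e-10

    def test_single_atom_captured_at_combo_rank(self, small_schedule):
        # one atom's (n x combo) curve matrix has rank <= n_combos, so the
        # subspace pair (L_T1 = n_combos, L_ta = n_combos) captures it exactly
        d = build_dictionary(small_schedule, (np.array([800.0]), np.array([50.0]),
                                              np.array([1.0]), np.array([-1.0])))
        sub = fit_subspaces(d, min(10, d.n_grid.size), 10)
        assert sub.recon_error < 1e-10

    def test_rank_beyond_dimension_raises(self, dict_small):
        with pytest.raises(ValueError):
            fit_subspaces(dict_small, 5, 11)
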