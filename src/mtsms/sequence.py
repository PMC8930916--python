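"""Pulse-sequence schedule, T2prep-IR FLASH signal model, dictionary and relaxation subspaces.

The sequence interleaves five T2-preparation durations (0 ms = plain inversion)
with two FLASH excitation flip angles, producing a repeating cycle of ten
(tau, alpha) recovery periods.  Within each 2.5 s recovery period a continuous
FLASH readout train alternates 1:1 between training lines (fixed 0 deg radial
angle) and imaging lines (golden-angle increments).

The closed-form recovery signal for period k is

    s(n) = A * (1 - E1) / (1 - E1*cos(b*a_k))
           * [1 + (B * Q_k * exp(-tau/T2) - 1) * (E1*cos(b*a_k))**n]
           * sin(b*a_k),            E1 = exp(-TR/T1),

with amplitude A, inversion efficiency B (signed, -1 ideal), B1+ scale b,
and Q_k = (1 - E1*cos(b*a_k)) / (1 - E1*cos(b*a_{k-1})) absorbing the
steady state of the previous period's flip angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GOLDEN_ANGLE_DEG = 111.24

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "SequenceConfig",
    "PeriodSpec",
    "SequenceSchedule",
    "TissueParams",
    "SignalDictionary",
    "RelaxSubspaces",
    "build_schedule",
    "q_factor",
    "signal_curve",
    "bloch_oracle",
    "default_grids",
    "build_dictionary",
    "fit_subspaces",
]


@dataclass(frozen=True)
class SequenceConfig:
    """Scan-timing parameters of the T2prep-IR dual-flip-angle FLASH sequence."""

    tr_ms: float = 3.5
    te_ms: float = 1.6
    flip_deg: tuple[float, float] = (3.0, 10.0)
    prep_ms: tuple[float, ...] = (0.0, 30.0, 40.0, 50.0, 60.0)
    recovery_ms: float = 2500.0
    n_periods: int = 20
    train_first: bool = True
    # whether the golden-angle counter also advances on training lines
    # (training lines stay at 0 deg either way)
    golden_counter_all_lines: bool = False

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.recovery_ms < self.tr_ms:
            raise ValueError("recovery_ms must be at least one TR")
        if len(self.flip_deg) != 2:
            raise ValueError("exactly two flip angles required")
        if any(p < 0 for p in self.prep_ms):
            raise ValueError("prep_ms must be non-negative")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def n_readouts_per_period(self) -> int:
        return int(math.floor(self.recovery_ms / self.tr_ms))

    def combo_cycle(self) -> list[tuple[float, float]]:
        """The 10-long cycle of (tau, alpha) combinations.

        Each prep duration is visited with the flip angle toggling every
        period, so after one pass through the preps the toggle parity has
        flipped (5 preps, 2 flips are coprime) and the second pass pairs each
        prep with the other flip angle: a cycle of 10 distinct combinations.
        """
        a0, a1 = self.flip_deg
        cycle = []
        for j in range(2 * len(self.prep_ms)):
            tau = self.prep_ms[j % len(self.prep_ms)]
            alpha = a0 if j % 2 == 0 else a1
            cycle.append((tau, alpha))
        return cycle


@dataclass(frozen=True)
class PeriodSpec:
    """One recovery period: which (tau, alpha) combo it runs and what preceded it."""

    combo_index: int
    prep_ms: float
    flip_deg: float
    prev_flip_deg: float
    n_readouts: int


@dataclass
class SequenceSchedule:
    """Flat per-readout timetable of the executed scan.

    ``readouts`` columns: period, n (1-based excitation index within the
    period), role ('training'/'imaging'), radial_angle_deg, phase_step (0..2),
    time_ms.
    """

    config: SequenceConfig
    periods: list[PeriodSpec]
    period_idx: np.ndarray      # (n_lines,) int
    n_index: np.ndarray         # (n_lines,) int, 1..N
    is_training: np.ndarray     # (n_lines,) bool
    radial_angle_deg: np.ndarray
    phase_step: np.ndarray      # (n_lines,) int in {0,1,2}
    time_ms: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.period_idx.size

    @property
    def combo_index(self) -> np.ndarray:
        """Per-line combo index in 0..9."""
        combos = np.array([p.combo_index for p in self.periods])
        return combos[self.period_idx]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "period": self.period_idx,
                "n": self.n_index,
                "role": np.where(self.is_training, "training", "imaging"),
                "angle_deg": self.radial_angle_deg,
                "phase_step": self.phase_step,
                "time_ms": self.time_ms,
            }
        )


def build_schedule(cfg: SequenceConfig) -> SequenceSchedule:
    """Expand a :class:`SequenceConfig` into the per-readout timetable.

    Period p runs combo ``p mod 10``; the golden-angle counter and the
    CAIPIRINHA phase step advance only on imaging lines; training lines sit
    at 0 deg with phase step 0.
    """
    if cfg.recovery_ms < 2 * cfg.tr_ms:
        raise ValueError("period too short: recovery_ms < 2*tr_ms")
    cycle = cfg.combo_cycle()
    ncombo = len(cycle)
    n_per = cfg.n_readouts_per_period

    periods = []
    for p in range(cfg.n_periods):
        k = p % ncombo
        tau, alpha = cycle[k]
        # period 0 is preceded (in steady state) by the nominal cycle's last combo
        prev_alpha = cycle[(k - 1) % ncombo][1]
        periods.append(PeriodSpec(k, tau, alpha, prev_alpha, n_per))

    n_lines = cfg.n_periods * n_per
    period_idx = np.repeat(np.arange(cfg.n_periods), n_per)
    n_index = np.tile(np.arange(1, n_per + 1), cfg.n_periods)
    if cfg.train_first:
        is_training = (n_index - 1) % 2 == 0
    else:
        is_training = (n_index - 1) % 2 == 1

    angles = np.zeros(n_lines)
    phase_step = np.zeros(n_lines, dtype=np.int64)
    img = ~is_training
    if cfg.golden_counter_all_lines:
        m = np.arange(n_lines)[img]
    else:
        m = np.arange(img.sum())
    angles[img] = (m * GOLDEN_ANGLE_DEG) % 360.0
    phase_step[img] = m % 3

    # absolute time: each period occupies prep + recovery; excitation n at
    # prep + n*TR from period start
    prep_arr = np.array([p.prep_ms for p in periods])
    period_start = np.concatenate([[0.0], np.cumsum(prep_arr + cfg.recovery_ms)[:-1]])
    time_ms = period_start[period_idx] + prep_arr[period_idx] + n_index * cfg.tr_ms

    return SequenceSchedule(
        config=cfg,
        periods=periods,
        period_idx=period_idx,
        n_index=n_index,
        is_training=is_training,
        radial_angle_deg=angles,
        phase_step=phase_step,
        time_ms=time_ms,
    )


@dataclass(frozen=True)
class TissueParams:
    """Voxel/tissue signal parameters: amplitude A, prep efficiency B (signed),
    B1+ scale beta, and relaxation times in ms."""

    amp: float = 1.0
    eff: float = -1.0
    b1: float = 1.0
    t1_ms: float = 1200.0
    t2_ms: float = 42.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.b1 < 0:
            raise ValueError("b1 must be non-negative")


def q_factor(t1_ms, b1, alpha_k_deg, alpha_prev_deg, tr_ms):
    """Ratio of FLASH steady states Mss(alpha_{k-1})/Mss(alpha_k).

    Q_k = (1 - E1 cos(b*a_k)) / (1 - E1 cos(b*a_{k-1})), E1 = exp(-TR/T1).
    Vectorized in all arguments.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    e1 = np.exp(-tr_ms / t1_ms)
    num = 1.0 - e1 * np.cos(np.deg2rad(np.asarray(b1) * alpha_k_deg))
    den = 1.0 - e1 * np.cos(np.deg2rad(np.asarray(b1) * alpha_prev_deg))
    if np.any(np.abs(den) < 1e-15):
        raise ZeroDivisionError("degenerate angle: previous-period steady state undefined")
    return num / den


def signal_curve(tissue: TissueParams, period: PeriodSpec, n_points: int,
                 tr_ms: float | None = None, n_values=None) -> np.ndarray:
    """Closed-form recovery signal s(n), n = 1..n_points, for one period.

    ``n_values`` overrides the default 1..n_points grid (used for decimated
    dictionaries and for evaluating at arbitrary excitation indices).
    """
    if tr_ms is None:
        tr_ms = 3.5
    if n_values is None:
        n_values = np.arange(1, n_points + 1)
    n_values = np.asarray(n_values, dtype=float)
    e1 = math.exp(-tr_ms / tissue.t1_ms)
    ca = math.cos(math.radians(tissue.b1 * period.flip_deg))
    sa = math.sin(math.radians(tissue.b1 * period.flip_deg))
    q = q_factor(tissue.t1_ms, tissue.b1, period.flip_deg, period.prev_flip_deg, tr_ms)
    prep = tissue.eff * q * math.exp(-period.prep_ms / tissue.t2_ms)
    ss = tissue.amp * (1.0 - e1) / (1.0 - e1 * ca)
    return ss * (1.0 + (prep - 1.0) * (e1 * ca) ** n_values) * sa


def signal_curve_grid(amp, eff, b1, t1_ms, t2_ms, period: PeriodSpec,
                      tr_ms: float, n_values) -> np.ndarray:
    """Vectorized closed form over parameter arrays; returns (len(n_values), n_atoms)."""
    amp, eff, b1, t1_ms, t2_ms = np.broadcast_arrays(
        *[np.asarray(a, dtype=float) for a in (amp, eff, b1, t1_ms, t2_ms)]
    )
    n_values = np.asarray(n_values, dtype=float)[:, None]
    e1 = np.exp(-tr_ms / t1_ms)
    ca = np.cos(np.deg2rad(b1 * period.flip_deg))
    sa = np.sin(np.deg2rad(b1 * period.flip_deg))
    q = q_factor(t1_ms, b1, period.flip_deg, period.prev_flip_deg, tr_ms)
    prep = eff * q * np.exp(-period.prep_ms / t2_ms)
    ss = amp * (1.0 - e1) / (1.0 - e1 * ca)
    return ss * (1.0 + (prep - 1.0) * (e1 * ca) ** n_values) * sa


def bloch_oracle(tissue: TissueParams, schedule: SequenceSchedule) -> np.ndarray:
    """Per-TR Bloch recursion over the whole executed schedule.

    Longitudinal magnetization is initialized at the FLASH steady state of the
    flip angle that (nominally) precedes period 0.  At each period start the
    preparation maps Mz -> B * Mz * exp(-tau/T2); the excitation slot
    immediately following the preparation is the (unrecorded) n = 0 slot, so
    the first recorded readout n = 1 already carries one cos-rotation and one
    TR of T1 recovery, matching the closed form's (E1 cos)^n exponent.
    """
    cfg = schedule.config
    tr = cfg.tr_ms
    m0 = tissue.amp
    e1 = math.exp(-tr / tissue.t1_ms)
    prev_alpha = schedule.periods[0].prev_flip_deg
    ca_prev = math.cos(math.radians(tissue.b1 * prev_alpha))
    mz = m0 * (1.0 - e1) / (1.0 - e1 * ca_prev)  # steady state just before excitation

    out = np.empty(schedule.n_lines)
    pos = 0
    for period in schedule.periods:
        ca = math.cos(math.radians(tissue.b1 * period.flip_deg))
        sa = math.sin(math.radians(tissue.b1 * period.flip_deg))
        mz = tissue.eff * mz * math.exp(-period.prep_ms / tissue.t2_ms)
        for _ in range(period.n_readouts):
            mz = m0 * (1.0 - e1) + e1 * ca * mz
            out[pos] = mz * sa
            pos += 1
    return out


@dataclass
class SignalDictionary:
    """Dictionary of feasible recovery curves over a (T1, T2, b1, eff) grid.

    ``atoms``: (n_rows, n_atoms) raw curves, rows ordered by (combo, n) with
    n on ``n_grid``; ``atoms_norm``: L2-normalized copies; ``grid``: the four
    1-D parameter grids; ``index``: (n_atoms, 4) grid indices per column.
    """

    atoms: np.ndarray
    atoms_norm: np.ndarray
    t1_grid: np.ndarray
    t2_grid: np.ndarray
    b1_grid: np.ndarray
    eff_grid: np.ndarray
    index: np.ndarray
    n_grid: np.ndarray
    periods: list[PeriodSpec]
    tr_ms: float
    n_full: np.ndarray = None   # all training-line n positions (full resolution)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def n_combos(self) -> int:
        return len(self.periods)

    def params_of(self, col: int) -> tuple[float, float, float, float]:
        i, j, k, l = self.index[col]
        return (self.t1_grid[i], self.t2_grid[j], self.b1_grid[k], self.eff_grid[l])


def default_grids(n_t1: int = 21, n_t2: int = 21, n_b1: int = 7, n_eff: int = 7):
    """Default dictionary grids: log-spaced T1 in [100, 3000] ms and T2 in
    [10, 3000] ms, linear b1 in [0, 1.5], linear signed inversion efficiency
    in [-1, -0.7]."""
    return (
        np.geomspace(100.0, 3000.0, n_t1),
        np.geomspace(10.0, 3000.0, n_t2),
        np.linspace(0.0, 1.5, n_b1),
        np.linspace(-1.0, -0.7, n_eff),
    )


def _cycle_periods(cfg: SequenceConfig) -> list[PeriodSpec]:
    cycle = cfg.combo_cycle()
    return [
        PeriodSpec(k, cycle[k][0], cycle[k][1], cycle[(k - 1) % len(cycle)][1],
                   cfg.n_readouts_per_period)
        for k in range(len(cycle))
    ]


def build_dictionary(schedule: SequenceSchedule, grids=None, n_decim: int = 8) -> SignalDictionary:
    """Evaluate the closed form over the parameter grids at a decimated n-grid.

    Rows are the 10 combos' curves concatenated; the n-grid keeps every
    ``n_decim``-th training-line position (full resolution when N <= 256).
    """
    cfg = schedule.config
    if grids is None:
        grids = default_grids()
    t1g, t2g, b1g, effg = (np.asarray(g, dtype=float) for g in grids)
    if any(g.size == 0 for g in (t1g, t2g, b1g, effg)):
        raise ValueError("empty parameter grid")

    n_per = cfg.n_readouts_per_period
    # n-grid restricted to training-line excitation indices
    train_n = np.unique(schedule.n_index[schedule.is_training])
    if n_per <= 256:
        n_grid = train_n
    else:
        n_grid = train_n[::n_decim]

    idx = np.stack(np.meshgrid(
        np.arange(t1g.size), np.arange(t2g.size), np.arange(b1g.size),
        np.arange(effg.size), indexing="ij"), axis=-1).reshape(-1, 4)
    t1 = t1g[idx[:, 0]]
    t2 = t2g[idx[:, 1]]
    b1 = b1g[idx[:, 2]]
    eff = effg[idx[:, 3]]

    periods = _cycle_periods(cfg)
    blocks = [
        signal_curve_grid(1.0, eff, b1, t1, t2, p, cfg.tr_ms, n_grid)
        for p in periods
    ]
    atoms = np.concatenate(blocks, axis=0)
    norms = np.linalg.norm(atoms, axis=0)
    norms[norms == 0] = 1.0
    return SignalDictionary(
        atoms=atoms,
        atoms_norm=atoms / norms,
        t1_grid=t1g, t2_grid=t2g, b1_grid=b1g, eff_grid=effg,
        index=idx, n_grid=n_grid, periods=periods, tr_ms=cfg.tr_ms,
        n_full=train_n,
    )


@dataclass
class RelaxSubspaces:
    """Orthonormal relaxation subspaces from the dictionary SVD.

    ``u_t1``: (len(n_grid), L_T1) orthonormal basis over the decimated
    tensor n-grid; ``u_ta``: (n_combos, L_ta) basis over the (tau, alpha)
    combos.  Off-grid excitation indices are evaluated through
    ``eval_table`` — the full-temporal-resolution n-mode basis expressed in
    the same coordinates as ``u_t1`` (so ``u_t1_at(n_grid) == u_t1``
    exactly) — rather than by coarse interpolation of ``u_t1`` itself.
    ``recon_error``: relative Frobenius error of the dictionary under the
    two truncated subspaces.
    """

    u_t1: np.ndarray
    u_ta: np.ndarray
    n_grid: np.ndarray
    sv_t1: np.ndarray
    sv_ta: np.ndarray
    recon_error: float
    eval_table: np.ndarray = None   # (len(eval_grid), L_T1)
    eval_grid: np.ndarray = None

    def u_t1_at(self, n_values) -> np.ndarray:
        """n-mode basis rows at arbitrary excitation indices."""
        if self.eval_table is None:
            table, grid = self.u_t1, self.n_grid
        else:
            table, grid = self.eval_table, self.eval_grid
        n_values = np.asarray(n_values, dtype=float)
        out = np.empty((n_values.size, table.shape[1]), dtype=table.dtype)
        grid = grid.astype(float)
        for j in range(table.shape[1]):
            col = table[:, j]
            if np.iscomplexobj(col):
                out[:, j] = np.interp(n_values, grid, col.real) \
                    + 1j * np.interp(n_values, grid, col.imag)
            else:
                out[:, j] = np.interp(n_values, grid, col)
        return out


def fit_subspaces(dictionary: SignalDictionary, l_t1: int, l_ta: int,
                  chunk: int = 2048) -> RelaxSubspaces:
    """Relaxation subspaces from the dictionary, n-mode at full resolution.

    The n-mode Gram matrix is accumulated over all atoms at every
    training-line excitation index (not just the decimated tensor grid), so
    the basis is exact at any n.  The orthonormal tensor-grid basis ``u_t1``
    is the QR factor of the full-resolution basis sampled on the grid, and
    ``eval_table`` carries the compatible full-resolution rows.
    """
    n_c = dictionary.n_combos
    n_full = dictionary.n_full if dictionary.n_full is not None else dictionary.n_grid
    n_f = n_full.size
    if l_t1 > n_f or l_ta > n_c:
        raise ValueError("requested rank exceeds unfolding dimension")
    if l_t1 > dictionary.n_grid.size:
        raise ValueError("l_t1 exceeds the tensor n-grid size")

    idx = dictionary.index
    t1 = dictionary.t1_grid[idx[:, 0]]
    t2 = dictionary.t2_grid[idx[:, 1]]
    b1 = dictionary.b1_grid[idx[:, 2]]
    eff = dictionary.eff_grid[idx[:, 3]]

    gram_n = np.zeros((n_f, n_f))
    gram_c = np.zeros((n_c, n_c))
    for start in range(0, dictionary.n_atoms, chunk):
        sl = slice(start, min(start + chunk, dictionary.n_atoms))
        blocks = np.stack([
            signal_curve_grid(1.0, eff[sl], b1[sl], t1[sl], t2[sl], p,
                              dictionary.tr_ms, n_full)
            for p in dictionary.periods])                       # (combo, n, atoms)
        for c in range(n_c):
            gram_n += blocks[c] @ blocks[c].T
        flat = blocks.reshape(n_c, -1)
        gram_c += flat @ flat.T

    w_n, v_n = np.linalg.eigh(gram_n)
    order = np.argsort(w_n)[::-1]
    u_full = v_n[:, order[:l_t1]]
    sv_n = np.sqrt(np.clip(w_n[order], 0, None))
    w_c, v_c = np.linalg.eigh(gram_c)
    order_c = np.argsort(w_c)[::-1]
    u_ta = v_c[:, order_c[:l_ta]]
    sv_c = np.sqrt(np.clip(w_c[order_c], 0, None))

    # orthonormal basis on the decimated tensor grid, consistent with u_full
    grid_rows = np.searchsorted(n_full, dictionary.n_grid)
    sampled = u_full[grid_rows]
    q, r = np.linalg.qr(sampled)
    eval_table = u_full @ np.linalg.inv(r)

    # relative error of the decimated dictionary under both subspaces
    n_n = dictionary.n_grid.size
    tens = dictionary.atoms.reshape(n_c, n_n, dictionary.n_atoms)
    unf_n = np.transpose(tens, (1, 0, 2)).reshape(n_n, -1)
    p1 = q @ (q.T @ unf_n)
    t_proj = p1.reshape(n_n, n_c, -1).transpose(1, 0, 2).reshape(n_c, -1)
    t_proj = u_ta @ (u_ta.T @ t_proj)
    err = np.linalg.norm(t_proj - tens.reshape(n_c, -1)) / np.linalg.norm(tens)

    return RelaxSubspaces(u_t1=q, u_ta=u_ta, n_grid=dictionary.n_grid,
                          sv_t1=sv_n, sv_ta=sv_c, recon_error=float(err),
                          eval_table=eval_table, eval_grid=n_full)
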