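"""Real-time (ungated) reconstruction and cardiac/respiratory self-gating.

Training lines (the repeated 0-deg projections) are acquired every other TR,
i.e. at ~143 Hz for TR = 3.5 ms — far above both respiratory (~0.2-0.4 Hz)
and cardiac (~1-2 Hz) bands.  Binning removes the T1/T2prep contrast sweep
from the training features by regressing them onto the dictionary-predicted
relaxation subspace at each line's (combo, n), then reads motion off the
principal components of the residual: a low-passed component clustered by
k-means gives respiratory bins; the analytic-signal phase of a band-passed
component gives cardiac phase bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt, welch
from sklearn.cluster import KMeans

from .sequence import RelaxSubspaces, SequenceSchedule

__all__ = ["BinAssignment", "RealTimeSeries", "realtime_reconstruct", "assign_bins"]


@dataclass
class BinAssignment:
    """Per-training-line motion-state labels plus diagnostics."""

    cardiac_bin: np.ndarray       # (n_training,) int in [0, n_card)
    resp_bin: np.ndarray          # (n_training,) int in [0, n_resp)
    n_card: int
    n_resp: int
    time_ms: np.ndarray
    resp_trace: np.ndarray        # low-passed respiratory feature (ordered as input)
    cardiac_phase: np.ndarray     # analytic phase in [0, 1)
    end_expiration_bin: int = 0
    card_occupancy: np.ndarray = field(default=None)
    resp_occupancy: np.ndarray = field(default=None)

    def __post_init__(self):
        self.card_occupancy = np.bincount(self.cardiac_bin, minlength=self.n_card)
        self.resp_occupancy = np.bincount(self.resp_bin, minlength=self.n_resp)
        if (self.resp_occupancy[: max(self.resp_bin) + 1] == 0).any():
            raise ValueError("empty respiratory bin")
        if (self.card_occupancy == 0).any():
            warnings.warn("empty cardiac bin(s)", stacklevel=2)

    def labels_for_times(self, times_ms) -> tuple[np.ndarray, np.ndarray]:
        """(cardiac, resp) labels inherited from the nearest-in-time training line."""
        order = np.argsort(self.time_ms)
        t_sorted = self.time_ms[order]
        pos = np.searchsorted(t_sorted, times_ms)
        pos = np.clip(pos, 1, t_sorted.size - 1)
        left = np.abs(np.asarray(times_ms) - t_sorted[pos - 1])
        right = np.abs(t_sorted[pos] - np.asarray(times_ms))
        nearest = np.where(left <= right, pos - 1, pos)
        idx = order[nearest]
        return self.cardiac_bin[idx], self.resp_bin[idx]

    def to_table(self, truth=None):
        import pandas as pd

        cols = {"time_ms": self.time_ms, "card_bin": self.cardiac_bin,
                "resp_bin": self.resp_bin, "cardiac_phase": self.cardiac_phase,
                "resp_trace": self.resp_trace}
        if truth is not None:
            cols["truth_card_phase"] = truth["card"]
            cols["truth_resp_phase"] = truth["resp"]
        return pd.DataFrame(cols)


@dataclass
class RealTimeSeries:
    """Low-rank real-time image series: render any training timestamp."""

    u: np.ndarray                # (n_slices, n_vox, L)
    basis: np.ndarray            # (n_training, L) temporal weights
    time_ms: np.ndarray
    operator: object             # the SMSRadialOperator used (holds support)
    residual: float

    def frame(self, idx: int) -> np.ndarray:
        flat = self.u @ self.basis[idx]
        return self.operator.embed(flat)


def _training_features(raw):
    feats = raw.training.reshape(raw.training.shape[0], -1)
    # canonical global-phase alignment (assignments must not depend on an
    # overall complex phase of the data)
    tot = feats.sum()
    if np.abs(tot) < 1e-12 * np.abs(feats).sum():
        tot = feats.ravel()[np.abs(feats).argmax()]
    return feats * np.exp(-1j * np.angle(tot))


def realtime_reconstruct(raw, operator, l_rt: int = 8, reg: float = 1e-3,
                         n_iter: int = 15) -> RealTimeSeries:
    """Subspace real-time reconstruction.

    Temporal basis = top right singular vectors of the training (feature x
    time) matrix; spatial coefficients solved from the imaging lines by
    conjugate gradients on the Tikhonov-regularized normal equations, the
    per-line temporal weight taken from the nearest-in-time training line.
    """
    feats = _training_features(raw)                    # (n_tr, F)
    n_tr = feats.shape[0]
    if l_rt > n_tr:
        raise ValueError("l_rt exceeds number of training lines")
    u_svd, s, vh = np.linalg.svd(feats.T, full_matrices=False)  # feature x time
    good = s > s[0] * 1e-10
    if good.sum() < l_rt:
        warnings.warn(f"rank-deficient training data: reducing l_rt to {int(good.sum())}",
                      stacklevel=2)
        l_rt = int(good.sum())
    basis = (vh[:l_rt].conj().T) * s[:l_rt]            # (n_tr, L) weighted
    basis /= np.linalg.norm(basis, axis=0, keepdims=True).max()

    sched = raw.schedule
    t_train = sched.time_ms[raw.training_lines]
    t_img = sched.time_ms[raw.imaging_lines]
    nearest = np.abs(t_img[:, None] - t_train[None, :]).argmin(axis=1) \
        if t_img.size * t_train.size < 5e7 else np.searchsorted(t_train, t_img).clip(0, n_tr - 1)
    phi = basis[nearest]                               # (n_img, L)

    from .spatial import _solve_cg

    sf = _solve_cg(operator, phi, raw.imaging, iters=n_iter, ridge=reg)
    return RealTimeSeries(u=sf.u_x, basis=basis, time_ms=t_train,
                          operator=operator, residual=sf.residual)


def _contrast_residual(feats, subspaces: RelaxSubspaces, n_idx, combos):
    """Remove the dictionary-predicted contrast sweep from training features."""
    a = subspaces.u_t1_at(n_idx)           # (n_tr, L2)
    b = subspaces.u_ta[combos]             # (n_tr, L3)
    w = (a[:, :, None] * b[:, None, :]).reshape(len(n_idx), -1)  # (n_tr, L2*L3)
    coef, *_ = np.linalg.lstsq(w, feats, rcond=None)
    return feats - w @ coef


def assign_bins(raw, subspaces: RelaxSubspaces, schedule: SequenceSchedule,
                n_card: int = 20, n_resp: int = 6, seed: int = 0,
                resp_cutoff_hz: float = 0.7, card_band_hz: tuple = (0.5, 2.5),
                n_pcs: int = 6, kmeans_restarts: int = 50,
                center_fraction: float = 0.35) -> BinAssignment:
    """Assign every training line to one of ``n_card`` x ``n_resp`` motion bins.

    Gating features are restricted to the central ``center_fraction`` of each
    readout (motion information concentrates at low |k| while thermal noise
    is white across samples) and the contrast-removed residuals are smoothed
    with a short moving average well above the cardiac band, both purely to
    raise the motion-signal SNR.
    """
    from scipy.ndimage import uniform_filter1d

    lines = raw.training_lines
    t = schedule.time_ms[lines]
    order = np.argsort(t, kind="stable")   # time-explicit: line order irrelevant
    inv = np.argsort(order, kind="stable")
    t_sorted = t[order]
    feats_full = _training_features(raw)
    n_samples = raw.training.shape[1]
    n_coils = raw.training.shape[2]
    if 0 < center_fraction < 1:
        half = max(int(n_samples * center_fraction / 2), 4)
        c0 = n_samples // 2
        feats_full = feats_full.reshape(-1, n_samples, n_coils)[
            :, c0 - half:c0 + half, :].reshape(len(lines), -1)
    feats = feats_full[order]
    n_idx = schedule.n_index[lines][order]
    combos = schedule.combo_index[lines][order]

    dt = np.median(np.diff(t_sorted)) / 1000.0
    fs = 1.0 / dt
    if fs / 2.0 <= card_band_hz[1]:
        raise ValueError(
            f"training sampling rate {fs:.1f} Hz cannot resolve the cardiac band "
            f"(Nyquist {fs/2:.1f} Hz <= {card_band_hz[1]} Hz)")

    resid_raw = _contrast_residual(feats, subspaces, n_idx, combos)
    smooth_w = max(int(fs / (6.0 * card_band_hz[1])), 1)
    if smooth_w > 1:
        resid = uniform_filter1d(resid_raw.real, smooth_w, axis=0) \
            + 1j * uniform_filter1d(resid_raw.imag, smooth_w, axis=0)
    else:
        resid = resid_raw
    rr_raw = np.concatenate([resid_raw.real, resid_raw.imag], axis=1)
    rr_raw = rr_raw - rr_raw.mean(axis=0, keepdims=True)
    rr = np.concatenate([resid.real, resid.imag], axis=1)
    rr = rr - rr.mean(axis=0, keepdims=True)
    u_p, s_p, v_p = np.linalg.svd(rr, full_matrices=False)
    pcs = u_p[:, :n_pcs] * s_p[:n_pcs]
    # unsmoothed projections: the white-noise floor reference for detection
    pcs_raw = rr_raw @ v_p[:n_pcs].T
    # canonical sign: largest-magnitude element of each PC positive
    for j in range(pcs.shape[1]):
        k = np.abs(pcs[:, j]).argmax()
        if pcs[k, j] < 0:
            pcs[:, j] = -pcs[:, j]

    # ---------------- respiratory ----------------
    sos_lo = butter(4, resp_cutoff_hz / (fs / 2.0), btype="low", output="sos")
    low = sosfiltfilt(sos_lo, pcs, axis=0)
    # detect absence of respiratory signal: compare the low band of the
    # first (unsmoothed) component's spectrum against its high-frequency
    # noise floor
    f_w, pxx = welch(pcs_raw[:, 0], fs=fs, nperseg=min(4096, pcs.shape[0]))
    lo_band = (f_w > 0.05) & (f_w < resp_cutoff_hz)
    noise_band = f_w > fs / 4.0
    lo_p = pxx[lo_band].mean() if lo_band.any() else 0.0
    noise_p = pxx[noise_band].mean() if noise_band.any() else 0.0
    if lo_p <= 5.0 * noise_p or np.std(low[:, 0]) < 1e-12:
        resp_bin_sorted = np.zeros(len(t_sorted), dtype=np.int64)
        resp_trace = low[:, 0]
        end_exp = 0
    else:
        km = KMeans(n_clusters=n_resp, n_init=kmeans_restarts, random_state=seed)
        lab = km.fit_predict(low[:, :3])
        # order bins by the mean of the first low-passed component
        means = np.array([low[lab == j, 0].mean() for j in range(n_resp)])
        remap = np.empty(n_resp, dtype=np.int64)
        remap[np.argsort(means, kind="stable")] = np.arange(n_resp)
        resp_bin_sorted = remap[lab]
        resp_trace = low[:, 0]
        end_exp = int(np.bincount(resp_bin_sorted, minlength=n_resp).argmax())

    # ---------------- cardiac ----------------
    # The heartbeat is a narrow contraction pulse, so its spectrum carries
    # strong harmonics; score candidate rates by fundamental + 2nd harmonic
    # prominence across the leading components, then isolate the fundamental
    # with a narrow band-pass before taking the analytic-signal phase (the
    # broadband pulse itself has no clean instantaneous phase).
    best_score, f0, lead = -np.inf, None, 0
    for j in range(pcs.shape[1]):
        f_w2, pxx2 = welch(pcs[:, j], fs=fs, nperseg=min(4096, pcs.shape[0]))
        # respiration-dominated components (and their drift-smeared harmonics)
        # must not be mistaken for the heartbeat
        resp_frac = pxx2[f_w2 < resp_cutoff_hz].sum() / max(pxx2.sum(), 1e-300)
        if resp_frac > 0.5:
            continue
        band = (f_w2 >= max(card_band_hz[0], 0.6)) & (f_w2 <= card_band_hz[1])
        if not band.any():
            continue
        med = np.median(pxx2[(f_w2 >= card_band_hz[0]) & (f_w2 <= 2 * card_band_hz[1])])
        med = max(med, 1e-300)
        for fi, pf in zip(f_w2[band], pxx2[band]):
            p2 = np.interp(2 * fi, f_w2, pxx2) if 2 * fi < f_w2[-1] else 0.0
            score = (pf + p2) / med
            if score > best_score:
                best_score, f0, lead = score, fi, j
    if f0 is None:
        raise ValueError("no cardiac-band content found")
    nb_lo = max(0.72 * f0, 0.9 * card_band_hz[0]) / (fs / 2)
    nb_hi = min(1.35 * f0, card_band_hz[1]) / (fs / 2)
    sos_nb = butter(2, [nb_lo, nb_hi], btype="band", output="sos")
    bp = sosfiltfilt(sos_nb, pcs, axis=0)
    analytic = hilbert(bp[:, lead])
    phase = np.angle(analytic) / (2 * np.pi) % 1.0
    # uniform phase partition refined by k-means on the unit circle
    z = np.stack([np.cos(2 * np.pi * phase), np.sin(2 * np.pi * phase)], axis=1)
    centers0 = np.stack([np.cos(2 * np.pi * (np.arange(n_card) + 0.5) / n_card),
                         np.sin(2 * np.pi * (np.arange(n_card) + 0.5) / n_card)], axis=1)
    km_c = KMeans(n_clusters=n_card, init=centers0, n_init=1, random_state=seed)
    lab_c = km_c.fit_predict(z)
    centers = km_c.cluster_centers_
    center_phase = np.angle(centers[:, 0] + 1j * centers[:, 1]) / (2 * np.pi) % 1.0
    # anchor bin 0 at the contraction extremum (peak of the band-passed trace)
    anchor = phase[bp[:, lead].argmax()]
    remap_c = np.empty(n_card, dtype=np.int64)
    remap_c[np.argsort((center_phase - anchor) % 1.0, kind="stable")] = np.arange(n_card)
    card_bin_sorted = remap_c[lab_c]

    return BinAssignment(
        cardiac_bin=card_bin_sorted[inv],
        resp_bin=resp_bin_sorted[inv],
        n_card=n_card,
        n_resp=n_resp,
        time_ms=t,
        resp_trace=resp_trace[inv],
        cardiac_phase=phase[inv],
        end_expiration_bin=end_exp,
    )
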