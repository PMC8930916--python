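"""End-to-end orchestration: simulate -> reconstruct -> fit -> evaluate.

Reconstruction follows the staged design: (1) optional real-time preview
reconstruction, (2) dictionary + relaxation subspaces, (3) cardiac and
respiratory binning of the training lines, (4) training-tensor completion
and HOSVD factor extraction into the combined temporal tensor Phi, and
(5) the spatial-factor solve against the imaging lines.
"""

from __future__ import annotations

import dataclasses
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .encoding import SMSRadialOperator, estimate_coils
from .gating import BinAssignment, assign_bins, realtime_reconstruct
from .lrt import (Phi, assemble_training_tensor, build_phi, complete_tensor,
                  hosvd_factors)
from .mapping import ParameterMaps, map_volume
from .phantom import CLASS_ORDER, DynamicPhantom, PhantomConfig, RawData, make_phantom, simulate_scan
from .sequence import (SequenceConfig, build_dictionary, build_schedule,
                       default_grids, fit_subspaces)
from .spatial import solve_spatial

__all__ = ["ReconResult", "sequence_config", "phantom_config", "run_simulate",
           "compress_coils", "run_reconstruct", "choose_motion_state", "run_fit",
           "evaluate_against_truth", "evaluate_scan_rescan"]


def _log(cfg: RunConfig, stage: str, t0: float, **scalars):
    if cfg.verbosity > 0:
        extras = " ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                          for k, v in scalars.items())
        print(f"[mtsms] {stage}: {time.time() - t0:.1f}s {extras}", flush=True)


def sequence_config(cfg: RunConfig) -> SequenceConfig:
    s = cfg.sequence
    return SequenceConfig(tr_ms=s.tr_ms, te_ms=s.te_ms, flip_deg=tuple(s.flip_deg),
                          prep_ms=tuple(s.prep_ms), recovery_ms=s.recovery_ms,
                          n_periods=s.n_periods, train_first=s.train_first)


def phantom_config(cfg: RunConfig, **overrides) -> PhantomConfig:
    p = cfg.phantom
    kw = dict(grid_n=p.grid_n, fov_mm=p.fov_mm, cardiac_period_ms=p.cardiac_period_ms,
              resp_period_ms=p.resp_period_ms, resp_amp_mm=p.resp_amp_mm,
              contraction=p.contraction, n_coils=p.n_coils, noise_rel=p.noise_rel,
              resp_drift=p.resp_drift, supersample=p.supersample,
              partial_volume=p.partial_volume, oversample=cfg.encoding.oversample,
              outer_radius_mm=tuple(p.outer_radius_mm), wall_mm=tuple(p.wall_mm),
              heart_center_mm=tuple(p.heart_center_mm), liver_top_mm=p.liver_top_mm,
              seed=cfg.seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


def run_simulate(cfg: RunConfig, out_path: str | None = None) -> RawData:
    t0 = time.time()
    schedule = build_schedule(sequence_config(cfg))
    phantom = make_phantom(phantom_config(cfg))
    raw = simulate_scan(phantom, schedule)
    _log(cfg, "simulate", t0, lines=schedule.n_lines, noise_sigma=raw.noise_sigma)
    if out_path:
        from .io import save_raw

        os.makedirs(os.path.dirname(out_path) or ".", exist_ok=True)
        save_raw(out_path, raw)
        with open(out_path + ".config.yaml", "w") as fh:
            fh.write(cfg.resolved_yaml())
    return raw


def compress_coils(raw: RawData, n_virtual: int) -> RawData:
    """SVD coil compression applied consistently to data and sensitivity maps."""
    if n_virtual >= raw.n_coils:
        return raw
    stack = np.concatenate([raw.imaging.reshape(-1, raw.n_coils),
                            raw.training.reshape(-1, raw.n_coils)], axis=0)
    # right singular vectors of the (samples x coils) matrix
    _, _, vh = np.linalg.svd(stack[:: max(1, stack.shape[0] // 20000)], full_matrices=False)
    v = vh.conj().T[:, :n_virtual]          # (n_coils, n_virtual) right singular vectors
    # rows of the data live in the span of the v_i^H: compressed data = d @ V,
    # and the sensitivity model transforms identically (S'_j = sum_c V_cj S_c)
    imaging = raw.imaging @ v
    training = raw.training @ v
    coils = np.einsum("scyx,cj->sjyx", raw.coils, v)
    return dataclasses.replace(raw, imaging=imaging, training=training, coils=coils)


@dataclass
class ReconResult:
    phi: Phi
    u_x: np.ndarray
    operator: SMSRadialOperator
    bins: BinAssignment
    subspaces: object
    dictionary: object
    residual: float
    completion_trace: list = field(default_factory=list)
    realtime: object = None
    raw: RawData = None


def _support_mask(raw: RawData, cfg: RunConfig):
    if "support" in raw.truth:
        return np.asarray(raw.truth["support"], dtype=bool)
    # data-driven fallback: thresholded RSS of slice-separated gridded recon
    sens = estimate_coils(raw, smooth_sigma=cfg.encoding.coil_smooth_sigma)
    rss = np.sqrt((np.abs(sens) ** 2).sum(axis=(0, 1)))
    return rss > 0.1 * rss.max()


def run_reconstruct(raw: RawData, cfg: RunConfig, out_path: str | None = None) -> ReconResult:
    t0 = time.time()
    raw_c = compress_coils(raw, cfg.encoding.n_virtual_coils)
    schedule = raw_c.schedule

    if cfg.encoding.use_truth_coils:
        coils = raw_c.coils
    else:
        coils = estimate_coils(raw_c, smooth_sigma=cfg.encoding.coil_smooth_sigma)
    support = _support_mask(raw_c, cfg)

    lines = raw_c.imaging_lines
    operator = SMSRadialOperator(
        schedule.radial_angle_deg[lines], schedule.phase_step[lines], coils,
        raw_c.grid_n, raw_c.oversample, support=support,
        dtype=np.dtype(cfg.encoding.solver_dtype))
    _log(cfg, "operator", t0, n_vox=operator.n_vox, n_coils=operator.n_coils)

    # step 2: dictionary and relaxation subspaces
    t1 = time.time()
    grids = default_grids(cfg.lrt.n_t1, cfg.lrt.n_t2, cfg.lrt.n_b1, cfg.lrt.n_eff)
    dictionary = build_dictionary(schedule, grids, n_decim=cfg.lrt.dict_n_decim)
    subspaces = fit_subspaces(dictionary, cfg.lrt.l_t1, cfg.lrt.l_ta)
    _log(cfg, "dictionary", t1, atoms=dictionary.n_atoms,
         n_grid=dictionary.n_grid.size, sub_err=subspaces.recon_error)

    # step 1 (optional): real-time preview reconstruction
    realtime = None
    if cfg.gating.realtime:
        t1 = time.time()
        realtime = realtime_reconstruct(raw_c, operator, l_rt=cfg.gating.l_rt)
        _log(cfg, "realtime", t1, residual=realtime.residual)

    # step 3: self-gated binning
    t1 = time.time()
    bins = assign_bins(raw_c, subspaces, schedule, n_card=cfg.gating.n_card,
                       n_resp=cfg.gating.n_resp, seed=cfg.seed,
                       resp_cutoff_hz=cfg.gating.resp_cutoff_hz,
                       card_band_hz=tuple(cfg.gating.card_band_hz),
                       n_pcs=cfg.gating.n_pcs,
                       kmeans_restarts=cfg.gating.kmeans_restarts)
    _log(cfg, "binning", t1, resp_bins=int(bins.resp_occupancy.max()),
         end_exp=bins.end_expiration_bin)

    # step 4: training tensor completion + HOSVD -> Phi
    t1 = time.time()
    feats = raw_c.training.reshape(raw_c.training.shape[0], -1)
    fr = cfg.lrt.feature_rank
    if fr and fr < feats.shape[1]:
        u_f, s_f, _ = np.linalg.svd(feats.T, full_matrices=False)
        feats = feats @ u_f[:, :fr].conj()
    st = assemble_training_tensor(raw_c, bins, schedule, subspaces, features=feats)
    from .lrt import adaptive_ranks

    max_ranks = (min(cfg.lrt.l_x, st.shape[0]), cfg.lrt.l_t1, cfg.lrt.l_ta,
                 min(cfg.lrt.l_c, cfg.gating.n_card), min(cfg.lrt.l_r, cfg.gating.n_resp))
    ranks = adaptive_ranks(st, max_ranks)
    d_hat, trace = complete_tensor(
        st, subspaces, iters=cfg.lrt.iters, continuation=cfg.lrt.continuation,
        polish_ranks=ranks if cfg.lrt.polish else None,
        polish_iters=cfg.lrt.polish_iters)
    fs = hosvd_factors(d_hat, ranks, subspaces=subspaces)
    phi = build_phi(fs, subspaces)
    _log(cfg, "tensor", t1, mask_density=float(st.mask.mean()),
         final_obj=trace[-1]["objective"])

    # step 5: spatial factor
    t1 = time.time()
    sf = solve_spatial(raw_c, phi, operator, bins, lam_w=cfg.spatial.lam_w,
                       iters=cfg.spatial.iters, wavelet=cfg.spatial.wavelet,
                       levels=cfg.spatial.levels, power_iters=cfg.spatial.power_iters,
                       seed=cfg.seed, ridge=cfg.spatial.ridge)
    _log(cfg, "spatial", t1, residual=sf.residual, rank=sf.rank)

    if out_path:
        import pandas as pd

        from .io import save_bins, save_factors, save_subspaces

        save_subspaces(out_path, phi.subspaces)
        save_bins(out_path, bins)
        save_factors(out_path, phi, u_x=sf.u_x, support=support, trace=trace)
        pd.DataFrame(trace).to_csv(out_path + ".completion_trace.csv", index=False)

    _log(cfg, "reconstruct-total", t0, residual=sf.residual)
    return ReconResult(phi=phi, u_x=sf.u_x, operator=operator, bins=bins,
                       subspaces=subspaces, dictionary=dictionary,
                       residual=sf.residual, completion_trace=trace, realtime=realtime,
                       raw=raw_c)


def choose_motion_state(recon: ReconResult, cfg: RunConfig) -> tuple[int, int]:
    """(c*, r*): diastolic cardiac bin and end-expiration respiratory bin.

    In simulation, diastole is the cardiac bin whose training lines have the
    lowest mean truth contraction; without truth it falls back to the most
    occupied cardiac bin (diastole dominates the cycle).
    """
    r_star = cfg.fit.r_star
    if r_star is None:
        r_star = recon.bins.end_expiration_bin
    c_star = cfg.fit.c_star
    if c_star is None:
        raw = recon.raw
        if raw is not None and "card_phase" in raw.truth:
            phantom = make_phantom(raw.truth["phantom_config"]) \
                if "phantom_config" in raw.truth else None
            ph_lines = raw.truth["card_phase"][raw.training_lines]
            if phantom is not None:
                w = phantom.contraction_wave(ph_lines)
            else:
                w = np.cos(2 * np.pi * ph_lines)
            means = np.array([
                w[recon.bins.cardiac_bin == c].mean()
                if (recon.bins.cardiac_bin == c).any() else np.inf
                for c in range(recon.bins.n_card)])
            c_star = int(np.argmin(means))
        else:
            c_star = int(np.argmax(recon.bins.card_occupancy))
    return int(c_star), int(r_star)


def run_fit(recon: ReconResult, cfg: RunConfig, out_dir: str | None = None) -> ParameterMaps:
    t0 = time.time()
    c_star, r_star = choose_motion_state(recon, cfg)
    maps = map_volume(recon.u_x, recon.phi, recon.dictionary, c_star, r_star,
                      operator=recon.operator,
                      support_threshold=cfg.fit.support_threshold)
    _log(cfg, "fit", t0, c_star=c_star, r_star=r_star,
         fitted=int(maps.fitted.sum()))
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        vox = cfg.phantom.fov_mm / cfg.phantom.grid_n
        maps.to_nifti(out_dir, voxel_mm=(vox, vox, 8.0))
        import json

        with open(os.path.join(out_dir, "fit_settings.json"), "w") as fh:
            json.dump({"c_star": c_star, "r_star": r_star,
                       "support_threshold": cfg.fit.support_threshold,
                       "seed": cfg.seed}, fh, indent=2)
        if recon.raw is not None and "phantom_config" in recon.raw.truth:
            try:
                from .stats import aha16_labels, segment_table

                frames, _ = truth_masks_at_state(recon, maps)
                levels = ["apical", "mid", "basal"]
                for name in ("t1_ms", "t2_ms"):
                    stack = {}
                    for s, level in enumerate(levels):
                        mask = frames[s]["myo_mask"]
                        labels = aha16_labels(
                            mask, rv_insertion_deg=cfg.metrics.rv_insertion_deg,
                            slice_level=level)
                        stack[level] = (getattr(maps, name)[s], labels)
                    segment_table(stack).to_csv(
                        os.path.join(out_dir, f"segments_{name}.csv"), index=False)
            except ValueError:
                pass  # mask too thin for AHA sectors at this scale
    return maps


def truth_masks_at_state(recon: ReconResult, maps: ParameterMaps):
    """Truth parameter maps and interior myocardial masks at the fitted motion
    state (mean truth phases of the lines in the chosen bins)."""
    from scipy.ndimage import binary_erosion

    raw = recon.raw
    phantom = make_phantom(raw.truth["phantom_config"])
    sel = (recon.bins.cardiac_bin == maps.c_star) & (recon.bins.resp_bin == maps.r_star)
    lines = raw.training_lines[sel]
    card = float(np.median(raw.truth["card_phase"][lines]))
    dy = float(np.median(raw.truth["resp_dy_mm"][lines]))
    out = []
    myo_idx = CLASS_ORDER.index("myocardium")
    for s in range(len(phantom.cfg.slices)):
        fr = phantom.class_fractions_at(card, dy, s)
        params = {"fractions": fr}
        pure = fr[myo_idx] > 0.999
        interior = binary_erosion(pure)
        if interior.sum() < 10:
            interior = pure
        params["myo_mask"] = interior
        out.append(params)
    return out, phantom


def evaluate_against_truth(recon: ReconResult, maps: ParameterMaps, cfg: RunConfig) -> dict:
    """Median myocardial T1/T2 recovery errors against the phantom truth."""
    truth_frames, phantom = truth_masks_at_state(recon, maps)
    t1_true = phantom.cfg.tissues["myocardium"].t1_ms
    t2_true = phantom.cfg.tissues["myocardium"].t2_ms
    t1_vals, t2_vals = [], []
    for s, frame in enumerate(truth_frames):
        m = frame["myo_mask"] & maps.fitted[s]
        t1_vals.append(maps.t1_ms[s][m])
        t2_vals.append(maps.t2_ms[s][m])
    t1_vals = np.concatenate(t1_vals)
    t2_vals = np.concatenate(t2_vals)
    return {
        "n_myo_voxels": int(t1_vals.size),
        "t1_true_ms": t1_true,
        "t2_true_ms": t2_true,
        "t1_median_ms": float(np.median(t1_vals)),
        "t2_median_ms": float(np.median(t2_vals)),
        "t1_median_err_pct": float(abs(np.median(t1_vals) - t1_true) / t1_true * 100),
        "t2_median_err_pct": float(abs(np.median(t2_vals) - t2_true) / t2_true * 100),
    }


def evaluate_scan_rescan(maps1: ParameterMaps, maps2: ParameterMaps,
                         myo_masks, cfg: RunConfig) -> dict:
    """Two-run repeatability: global CoV, Bland-Altman and ICC on segment means."""
    from .stats import SLICE_SEGMENTS, aha16_labels, bland_altman, cov_rms, icc_two_way

    levels = ["apical", "mid", "basal"]
    seg1, seg2 = {}, {}
    for s, level in enumerate(levels):
        mask = myo_masks[s]
        labels = aha16_labels(mask, rv_insertion_deg=cfg.metrics.rv_insertion_deg,
                              slice_level=level)
        start, n_seg = SLICE_SEGMENTS[level]
        for seg in range(start, start + n_seg):
            m = labels == seg
            if m.sum() == 0:
                continue
            seg1[seg] = float(np.nanmedian(maps1.t1_ms[s][m]))
            seg2[seg] = float(np.nanmedian(maps2.t1_ms[s][m]))
    common = sorted(set(seg1) & set(seg2))
    a = np.array([[seg1[k] for k in common]])
    b = np.array([[seg2[k] for k in common]])
    bias, lo, hi = bland_altman(a.ravel(), b.ravel())
    return {
        "segments": common,
        "cov_global_pct": cov_rms(a, b, mode="global"),
        "cov_segmentwise_pct": cov_rms(a, b, mode="segmentwise"),
        "bland_altman_bias": bias, "loa_low": lo, "loa_high": hi,
        "icc": icc_two_way(a.ravel(), b.ravel()) if len(common) >= 3 else np.nan,
    }
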