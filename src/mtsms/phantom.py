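"""Dynamic 3-slice left-ventricle digital phantom and the exact forward simulator.

The phantom is a geometric short-axis torso: an elliptical body, a liver block
whose dome serves as the respiratory navigator structure, and a left-ventricle
myocardial annulus with a blood pool, at three slice levels (apical, mid,
basal).  Cardiac contraction periodically narrows the annulus; respiration
rigidly translates the whole frame along y with an asymmetric waveform
(longer end-expiration dwell).  Multicoil SMS radial k-space is produced
through the exact forward model: closed-form T2prep-IR FLASH contrast per
readout, coil sensitivities, per-band CAIPIRINHA phasors, band summation,
non-uniform Fourier transform along each line, complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import SLICE_KZ, SLICE_LABELS
from .nufft import LineTransformCache, grid_coords
from .sequence import SequenceSchedule, TissueParams

__all__ = [
    "PhantomConfig",
    "DynamicPhantom",
    "RawData",
    "make_phantom",
    "simulate_scan",
]

CLASS_ORDER = ("background", "body", "liver", "myocardium", "blood")


def _default_tissues() -> dict[str, TissueParams]:
    return {
        "background": TissueParams(amp=0.0, eff=-0.95, b1=1.0, t1_ms=1000.0, t2_ms=100.0),
        "body": TissueParams(amp=0.7, eff=-0.95, b1=1.0, t1_ms=350.0, t2_ms=120.0),
        "liver": TissueParams(amp=0.9, eff=-0.95, b1=1.0, t1_ms=800.0, t2_ms=34.0),
        "myocardium": TissueParams(amp=1.0, eff=-0.95, b1=1.0, t1_ms=1200.0, t2_ms=42.0),
        "blood": TissueParams(amp=1.0, eff=-0.95, b1=1.0, t1_ms=1900.0, t2_ms=250.0),
    }


@dataclass
class PhantomConfig:
    grid_n: int = 48
    fov_mm: float = 270.0
    slices: tuple[str, ...] = SLICE_LABELS
    tissues: dict[str, TissueParams] = field(default_factory=_default_tissues)
    cardiac_period_ms: float = 900.0
    resp_period_ms: float = 4000.0
    resp_amp_mm: float = 10.0
    contraction: float = 0.35          # fractional systolic narrowing of the inner radius
    b1_range: tuple[float, float] = (0.7, 1.3)
    n_coils: int = 8
    oversample: int = 2
    supersample: int = 2               # partial-volume anti-aliasing factor
    partial_volume: bool = True
    n_card_states: int = 32            # motion-state quantization for frame caching
    n_resp_states: int = 16
    resp_drift: bool = True            # +/-10% slow drift in respiratory rate/amplitude
    noise_rel: float = 0.02            # noise sd relative to peak training-line magnitude
    seed: int = 0

    # geometry (mm): heart center, per-slice outer radii and wall thickness
    heart_center_mm: tuple[float, float] = (0.0, 12.0)
    outer_radius_mm: tuple[float, float, float] = (20.0, 26.0, 30.0)   # apical, mid, basal
    wall_mm: tuple[float, float, float] = (8.0, 9.0, 10.0)
    body_semiaxes_mm: tuple[float, float] = (110.0, 85.0)
    liver_top_mm: float = -32.0
    liver_x_mm: tuple[float, float] = (-70.0, 30.0)

    def __post_init__(self) -> None:
        if self.grid_n < 32:
            raise ValueError("grid_n must be >= 32")
        if self.cardiac_period_ms <= 0 or self.resp_period_ms <= 0:
            raise ValueError("motion periods must be positive")


class DynamicPhantom:
    """Geometry + motion law + field maps; frames rendered (and cached) on demand."""

    def __init__(self, cfg: PhantomConfig):
        self.cfg = cfg
        cx, cy = cfg.heart_center_mm
        for r in cfg.outer_radius_mm:
            a, b = cfg.body_semiaxes_mm
            if (cx / a) ** 2 + ((cy + r) / b) ** 2 > 1 or (cy - r) < cfg.liver_top_mm:
                raise ValueError("overlapping geometry: heart leaves the body or hits the liver")
        self._frame_cache: dict[tuple, np.ndarray] = {}
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        self._b1_coeffs = rng.standard_normal(5)
        self._coil_rng_state = np.random.SeedSequence([cfg.seed, 13])
        self._drift_phases = rng.uniform(0, 2 * np.pi, size=2)
        self._b1_maps = None
        self._coil_maps = None

    # -- motion law --------------------------------------------------------
    def contraction_wave(self, card_phase) -> np.ndarray:
        """Smooth periodic systolic pulse in [0, 1], peaking at phase 0.35."""
        p = np.asarray(card_phase, dtype=float)
        return np.exp(8.0 * (np.cos(2 * np.pi * (p - 0.35)) - 1.0))

    def resp_wave(self, resp_phase) -> np.ndarray:
        """Asymmetric inhale/exhale displacement profile in [0, 1]; long
        end-expiration plateau around phase 0."""
        p = np.asarray(resp_phase, dtype=float)
        warped = p + 0.15 * np.sin(2 * np.pi * p) / (2 * np.pi)
        return np.sin(np.pi * warped) ** 4

    def resp_displacement_mm(self, resp_phase, amp_scale=1.0) -> np.ndarray:
        return self.cfg.resp_amp_mm * amp_scale * self.resp_wave(resp_phase)

    def inner_radius_mm(self, slice_idx: int, card_phase) -> np.ndarray:
        r0 = self.cfg.outer_radius_mm[slice_idx] - self.cfg.wall_mm[slice_idx]
        return r0 * (1.0 - self.cfg.contraction * self.contraction_wave(card_phase))

    def outer_radius_mm(self, slice_idx: int, card_phase) -> np.ndarray:
        r0 = self.cfg.outer_radius_mm[slice_idx]
        return r0 * (1.0 - 0.35 * self.cfg.contraction * self.contraction_wave(card_phase))

    # -- rasterization -----------------------------------------------------
    def _coords_mm(self, factor: int = 1):
        n = self.cfg.grid_n * factor
        c = (np.arange(n) - n // 2) / n * self.cfg.fov_mm
        y, x = np.meshgrid(c, c, indexing="ij")
        return x, y

    def class_fractions(self, card_phase: float, resp_phase: float, slice_idx: int,
                        amp_scale: float = 1.0) -> np.ndarray:
        dy = float(self.resp_displacement_mm(resp_phase, amp_scale))
        return self.class_fractions_at(card_phase, dy, slice_idx)

    def class_fractions_at(self, card_phase: float, dy_mm: float,
                           slice_idx: int) -> np.ndarray:
        """(n_classes, grid_n, grid_n) area-weighted occupancy fractions at a
        cardiac phase and an explicit respiratory displacement."""
        cfg = self.cfg
        ss = cfg.supersample if cfg.partial_volume else 1
        x, y = self._coords_mm(ss)
        yy = y - dy_mm  # frame translated along +y by dy
        cx, cy = cfg.heart_center_mm
        a, b = cfg.body_semiaxes_mm

        body = (x / a) ** 2 + (yy / b) ** 2 <= 1.0
        liver = body & (yy <= cfg.liver_top_mm) & (x >= cfg.liver_x_mm[0]) & (x <= cfg.liver_x_mm[1])
        r2 = (x - cx) ** 2 + (yy - cy) ** 2
        r_in = float(self.inner_radius_mm(slice_idx, card_phase))
        r_out = float(self.outer_radius_mm(slice_idx, card_phase))
        myo = body & (r2 <= r_out ** 2) & (r2 > r_in ** 2)
        blood = body & (r2 <= r_in ** 2)

        labels = np.zeros(x.shape, dtype=np.int8)
        labels[body] = 1
        labels[liver] = 2
        labels[myo] = 3
        labels[blood] = 4

        n = cfg.grid_n
        fracs = np.empty((len(CLASS_ORDER), n, n))
        for ci in range(len(CLASS_ORDER)):
            m = (labels == ci).astype(np.float64)
            fracs[ci] = m.reshape(n, ss, n, ss).mean(axis=(1, 3))
        return fracs

    def cached_fractions_at(self, qc: int, qdy: int, slice_idx: int) -> np.ndarray:
        """Frame cache keyed by quantized cardiac phase and quantized
        respiratory displacement (index on a uniform grid up to 1.1x the
        nominal amplitude, covering drift)."""
        key = (qc, qdy, slice_idx)
        out = self._frame_cache.get(key)
        if out is None:
            dy = qdy * self.dy_quantum_mm()
            out = self.class_fractions_at(qc / self.cfg.n_card_states, dy, slice_idx)
            self._frame_cache[key] = out
        return out

    def dy_quantum_mm(self) -> float:
        dy_max = 1.1 * self.cfg.resp_amp_mm
        return dy_max / max(self.cfg.n_resp_states, 1) if dy_max > 0 else 1.0

    def frame_params(self, card_phase: float, resp_phase: float, slice_idx: int) -> dict:
        """Rasterized per-voxel parameter images (majority class; fractional amp)."""
        fr = self.class_fractions(card_phase, resp_phase, slice_idx)
        maj = fr.argmax(axis=0)
        t1 = np.empty(maj.shape)
        t2 = np.empty(maj.shape)
        eff = np.empty(maj.shape)
        amp = np.zeros(maj.shape)
        for ci, name in enumerate(CLASS_ORDER):
            tp = self.cfg.tissues[name]
            sel = maj == ci
            t1[sel] = tp.t1_ms
            t2[sel] = tp.t2_ms
            eff[sel] = tp.eff
            amp += fr[ci] * tp.amp
        return {"t1_ms": t1, "t2_ms": t2, "eff": eff, "amp": amp,
                "class_label": maj, "fractions": fr}

    # -- field maps --------------------------------------------------------
    def b1_maps(self) -> np.ndarray:
        """(n_slices, grid_n, grid_n) smooth multiplicative B1+ maps in b1_range."""
        if self._b1_maps is None:
            cfg = self.cfg
            x, y = self._coords_mm()
            xn, yn = x / cfg.fov_mm, y / cfg.fov_mm
            c = self._b1_coeffs
            g = c[0] * xn + c[1] * yn + c[2] * (xn ** 2 - yn ** 2) + c[3] * xn * yn \
                + c[4] * (xn ** 2 + yn ** 2)
            g = g / np.abs(g).max()
            lo, hi = cfg.b1_range
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
            maps = []
            for s in range(len(cfg.slices)):
                maps.append(np.clip(mid + half * g * (1.0 - 0.06 * s), lo, hi))
            self._b1_maps = np.stack(maps)
        return self._b1_maps

    def coil_maps(self) -> np.ndarray:
        """(n_slices, n_coils, grid_n, grid_n) smooth complex sensitivities,
        loop-like magnitudes with low-order phase, RSS ~ 1 inside the FOV."""
        if self._coil_maps is None:
            cfg = self.cfg
            rng = np.random.default_rng(self._coil_rng_state)
            x, y = self._coords_mm()
            xn, yn = x / cfg.fov_mm, y / cfg.fov_mm
            n_s = len(cfg.slices)
            maps = np.empty((n_s, cfg.n_coils, cfg.grid_n, cfg.grid_n), dtype=np.complex128)
            angles = 2 * np.pi * np.arange(cfg.n_coils) / cfg.n_coils \
                + rng.uniform(-0.1, 0.1, cfg.n_coils)
            radius = 0.55
            widths = rng.uniform(0.40, 0.50, cfg.n_coils)
            ph_lin = rng.uniform(-1.5, 1.5, (cfg.n_coils, 2))
            ph_off = rng.uniform(0, 2 * np.pi, cfg.n_coils)
            for c in range(cfg.n_coils):
                px, py = radius * np.cos(angles[c]), radius * np.sin(angles[c])
                d2 = (xn - px) ** 2 + (yn - py) ** 2
                mag = np.exp(-d2 / (2 * widths[c] ** 2))
                phase = ph_off[c] + ph_lin[c, 0] * xn + ph_lin[c, 1] * yn
                base = mag * np.exp(1j * phase)
                for s in range(n_s):
                    maps[s, c] = base * (1.0 + 0.04 * s * (xn + yn))
            rss = np.sqrt((np.abs(maps) ** 2).sum(axis=1, keepdims=True))
            maps /= rss.mean()
            self._coil_maps = maps
        return self._coil_maps

    def support_mask(self, margin_px: int = 1) -> np.ndarray:
        """Union of body masks over the respiratory range, slightly dilated."""
        cfg = self.cfg
        x, y = self._coords_mm()
        a, b = cfg.body_semiaxes_mm
        amax = cfg.resp_amp_mm * (1.1 if cfg.resp_drift else 1.0)
        m = np.zeros((cfg.grid_n, cfg.grid_n), dtype=bool)
        for dy in np.linspace(0, amax, 5):
            m |= (x / a) ** 2 + ((y - dy) / b) ** 2 <= 1.0
        from scipy.ndimage import binary_dilation

        return binary_dilation(m, iterations=margin_px)


def make_phantom(cfg: PhantomConfig) -> DynamicPhantom:
    return DynamicPhantom(cfg)


@dataclass
class RawData:
    """Simulated (or externally supplied) SMS radial k-space plus truth sidecar."""

    imaging: np.ndarray          # (n_imaging, n_samples, n_coils)
    training: np.ndarray         # (n_training, n_samples, n_coils)
    imaging_lines: np.ndarray    # indices into the schedule
    training_lines: np.ndarray
    coils: np.ndarray            # (n_slices, n_coils, grid_n, grid_n)
    schedule: SequenceSchedule
    grid_n: int
    oversample: int
    noise_sigma: float
    seed: int
    truth: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.imaging.shape[2]


def _contrast_cache(phantom: DynamicPhantom, schedule: SequenceSchedule, support):
    """Per (slice, class, combo): arrays over support voxels so that the
    per-line signal is  ss * (1 + coeff * exp(n * logterm)) * sa."""
    from .sequence import q_factor

    cfg = phantom.cfg
    tr = schedule.config.tr_ms
    b1 = phantom.b1_maps()
    periods = {p.combo_index: p for p in schedule.periods}
    cache = {}
    for s in range(len(cfg.slices)):
        beta = b1[s][support]
        for ci, name in enumerate(CLASS_ORDER):
            tp = cfg.tissues[name]
            if tp.amp == 0:
                continue
            e1 = np.exp(-tr / tp.t1_ms)
            for k, p in periods.items():
                ca = np.cos(np.deg2rad(beta * p.flip_deg))
                sa = np.sin(np.deg2rad(beta * p.flip_deg))
                q = q_factor(tp.t1_ms, beta, p.flip_deg, p.prev_flip_deg, tr)
                prep = tp.eff * q * np.exp(-p.prep_ms / tp.t2_ms)
                ss = tp.amp * (1.0 - e1) / (1.0 - e1 * ca)
                cache[(s, ci, k)] = (ss * sa, (prep - 1.0), np.log(e1 * ca))
    return cache


def simulate_scan(phantom: DynamicPhantom, schedule: SequenceSchedule,
                  noise_sigma: float | None = None, seed: int | None = None) -> RawData:
    """Run the exact forward model over the full schedule.

    Deterministic given the phantom seed (or an explicit ``seed``); the noise
    level defaults to ``noise_rel`` times the peak training-line magnitude.
    """
    cfg = phantom.cfg
    if seed is None:
        seed = cfg.seed
    coils = phantom.coil_maps()
    if coils.shape[-1] != cfg.grid_n:
        raise ValueError("schedule/phantom grid mismatch")
    support = phantom.support_mask()
    x, y = grid_coords(cfg.grid_n)
    xs, ys = x[support], y[support]
    cache = LineTransformCache(xs, ys, cfg.grid_n, cfg.oversample)
    coils_flat = coils[:, :, support]
    n_s, n_c, _, _ = coils.shape
    contrast = _contrast_cache(phantom, schedule, support)
    support_fracs = {}  # (qc, qr, s, amp_scale) -> fractions over support voxels

    n_lines = schedule.n_lines
    n_samples = cfg.oversample * cfg.grid_n
    combos = schedule.combo_index
    inc = SLICE_KZ * (2.0 * np.pi / 3.0)
    phasors = np.exp(1j * np.outer(schedule.phase_step, inc))

    t = schedule.time_ms
    card_phase = (t / cfg.cardiac_period_ms) % 1.0
    if cfg.resp_drift:
        # slow (+/-10%, seeded) drift of respiratory timing and amplitude
        ph0, ph1 = phantom._drift_phases
        slow = 2 * np.pi * t / 45000.0
        resp_phase = (t / cfg.resp_period_ms + 0.10 * np.sin(slow + ph0)) % 1.0
        amp_scale = 1.0 + 0.10 * np.sin(slow + ph1)
    else:
        resp_phase = (t / cfg.resp_period_ms) % 1.0
        amp_scale = np.ones(n_lines)

    qc = np.floor(card_phase * cfg.n_card_states).astype(int) % cfg.n_card_states
    dy_line = phantom.resp_displacement_mm(resp_phase, 1.0) * np.asarray(amp_scale)
    qdy = np.rint(dy_line / phantom.dy_quantum_mm()).astype(int)

    data = np.empty((n_lines, n_samples, n_c), dtype=np.complex128)
    n_idx = schedule.n_index
    for l in range(n_lines):
        imgs = np.zeros((n_s, xs.size))
        for s in range(n_s):
            key = (qc[l], qdy[l], s)
            fr = support_fracs.get(key)
            if fr is None:
                fr = phantom.cached_fractions_at(qc[l], qdy[l], s)[:, support]
                support_fracs[key] = fr
            for ci in range(len(CLASS_ORDER)):
                ent = contrast.get((s, ci, combos[l]))
                if ent is None:
                    continue
                ssa, coeff, logterm = ent
                imgs[s] += fr[ci] * ssa * (1.0 + coeff * np.exp(n_idx[l] * logterm))
        a = cache.get(schedule.radial_angle_deg[l])
        comp = np.einsum("b,bcv,bv->vc", phasors[l], coils_flat, imgs, optimize=True)
        data[l] = a @ comp

    if noise_sigma is None:
        train_peak = np.abs(data[schedule.is_training]).max()
        noise_sigma = cfg.noise_rel * float(train_peak)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if noise_sigma > 0:
        data = data + noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    tr_mask = schedule.is_training
    truth = {
        "card_phase": card_phase,
        "resp_phase": resp_phase,
        "resp_dy_mm": dy_line,
        "resp_amp_scale": amp_scale if np.ndim(amp_scale) else np.full(n_lines, amp_scale),
        "b1_maps": phantom.b1_maps(),
        "phantom_config": cfg,
        "reference_params": [
            phantom.frame_params(0.85, 0.0, s) for s in range(n_s)
        ],
        "support": support,
    }
    return RawData(
        imaging=data[~tr_mask],
        training=data[tr_mask],
        imaging_lines=np.where(~tr_mask)[0],
        training_lines=np.where(tr_mask)[0],
        coils=coils,
        schedule=schedule,
        grid_n=cfg.grid_n,
        oversample=cfg.oversample,
        noise_sigma=float(noise_sigma),
        seed=seed,
        truth=truth,
    )
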