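"""AHA 16-segment labelling and agreement/repeatability statistics.

Implements the statistics surface used to characterize quantitative cardiac
maps: two-way mixed-effects absolute-agreement single-measure ICC,
Bland-Altman bias and 95% limits of agreement, scan-rescan coefficients of
variation with RMS aggregation across subjects/segments, segment-wise SNR
and SNR efficiency, and ordinary least-squares regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "aha16_labels",
    "segment_table",
    "icc_two_way",
    "bland_altman",
    "cov_rms",
    "snr_stats",
    "linear_fit",
    "paired_ttest",
]

SLICE_SEGMENTS = {"basal": (1, 6), "mid": (7, 6), "apical": (13, 4)}


def aha16_labels(myo_mask: np.ndarray, centroid=None, rv_insertion_deg: float = 60.0,
                 slice_level: str = "mid") -> np.ndarray:
    """Angular-sector segment labels for one short-axis slice.

    Sectors run counter-clockwise from the anterior RV insertion: 6 x 60 deg
    at the basal and mid levels (segments 1-6 and 7-12), 4 x 90 deg at the
    apical level (13-16).  Returns an int image, 0 outside the mask.
    """
    if slice_level not in SLICE_SEGMENTS:
        raise ValueError(f"unknown slice level {slice_level!r}")
    mask = np.asarray(myo_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myocardial mask")
    yy, xx = np.nonzero(mask)
    if centroid is None:
        centroid = (xx.mean(), yy.mean())
    cx, cy = centroid
    if mask[int(round(cy)), int(round(cx))]:
        raise ValueError("mask is not annular: centroid lies inside the mask")
    start, n_seg = SLICE_SEGMENTS[slice_level]
    width = 360.0 / n_seg
    ang = (np.degrees(np.arctan2(yy - cy, xx - cx)) - rv_insertion_deg) % 360.0
    labels = np.zeros(mask.shape, dtype=np.int64)
    labels[yy, xx] = start + (ang // width).astype(np.int64)
    return labels


def segment_table(stack: dict):
    """Per-segment mean/sd/count table over a {level: (map, labels)} stack."""
    import pandas as pd

    rows = []
    for level, (img, labels) in stack.items():
        start, n_seg = SLICE_SEGMENTS[level]
        for seg in range(start, start + n_seg):
            vals = np.asarray(img)[labels == seg]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append({"segment": seg, "slice": level, "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                         "count": vals.size})
    return pd.DataFrame(rows).sort_values("segment").reset_index(drop=True)


def icc_two_way(x, y) -> float:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC.

    From the mean-squares decomposition with n targets and k = 2 raters:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or ss_tot == 0:
        if np.allclose(x, y):
            return 1.0
        raise ZeroDivisionError("zero total variance with unequal raters")
    return float((msr - mse) / denom)


def bland_altman(x, y) -> tuple[float, float, float]:
    """(bias, lower LoA, upper LoA); LoA = bias +/- 1.96 sd(x - y), sample sd."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    bias = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    return float(bias), float(bias - 1.96 * sd), float(bias + 1.96 * sd)


def cov_rms(scan1, scan2, mode: str = "global") -> float:
    """Scan-rescan coefficient of variation (%), RMS-aggregated over subjects.

    global: per-subject CoV = |m1 - m2| / sqrt(2) / mean(m1, m2) from the two
    global myocardial means, then RMS over subjects.
    segmentwise: inputs (n_subjects, n_segments); per subject the two-point
    per-segment sd is RMS-aggregated over segments and divided by the subject
    mean, then RMS over subjects.
    """
    a = np.atleast_2d(np.asarray(scan1, dtype=float))
    b = np.atleast_2d(np.asarray(scan2, dtype=float))
    if a.shape != b.shape:
        raise ValueError("mismatched segment sets between scans")
    if np.isnan(a).any() or np.isnan(b).any():
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            raise ValueError("mismatched segment sets between scans")
    if mode == "global":
        m1 = np.nanmean(a, axis=1) if a.shape[1] > 1 else a[:, 0]
        m2 = np.nanmean(b, axis=1) if b.shape[1] > 1 else b[:, 0]
        cov = (np.abs(m1 - m2) / np.sqrt(2.0)) / ((m1 + m2) / 2.0)
    elif mode == "segmentwise":
        sd_seg = np.abs(a - b) / np.sqrt(2.0)                 # two-point sd per segment
        rms_seg = np.sqrt(np.nanmean(sd_seg ** 2, axis=1))    # RMS over segments
        subj_mean = np.nanmean((a + b) / 2.0, axis=1)
        cov = rms_seg / subj_mean
    else:
        raise ValueError("mode must be 'global' or 'segmentwise'")
    return float(np.sqrt(np.mean(cov ** 2)) * 100.0)


def snr_stats(seg_means, seg_sds, scan_minutes: float):
    """Segment SNR = mean/sd; SNR efficiency = SNR / sqrt(scan minutes).

    Accepts per-segment mean and sd arrays (or a precomputed SNR array with
    ``seg_sds=None``).  Segments with zero sd are flagged and excluded from
    the aggregate (mean over segments).
    """
    means = np.asarray(seg_means, dtype=float)
    if seg_sds is None:
        snr = means
        flagged = ~np.isfinite(snr)
    else:
        sds = np.asarray(seg_sds, dtype=float)
        flagged = sds == 0
        if flagged.any():
            warnings.warn(f"{int(flagged.sum())} segment(s) with zero sd excluded",
                          stacklevel=2)
        snr = np.where(flagged, np.nan, means / np.where(flagged, 1.0, sds))
    eff = snr / np.sqrt(scan_minutes)
    return {
        "snr": snr,
        "efficiency": eff,
        "flagged": flagged,
        "snr_mean": float(np.nanmean(snr)),
        "efficiency_mean": float(np.nanmean(eff)),
    }


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares (slope, intercept, r^2)."""
    from scipy.stats import linregress

    res = linregress(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def paired_ttest(x, y) -> tuple[float, float]:
    """Thin wrapper: paired t statistic and two-sided p-value."""
    from scipy.stats import ttest_rel

    res = ttest_rel(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(res.statistic), float(res.pvalue)


def bullseye_png(segment_values: dict, path: str, title: str = "", cmap="viridis"):
    """Optional 16-segment bull's-eye rendering (lazy matplotlib import)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    rings = [("basal", 1.0), ("mid", 0.66), ("apical", 0.33)]
    vals = [v for v in segment_values.values() if np.isfinite(v)]
    vmin, vmax = (min(vals), max(vals)) if vals else (0, 1)
    sm = plt.cm.ScalarMappable(cmap=cmap)
    sm.set_clim(vmin, vmax)
    for level, r_out in rings:
        start, n_seg = SLICE_SEGMENTS[level]
        width = 2 * np.pi / n_seg
        for j in range(n_seg):
            seg = start + j
            v = segment_values.get(seg, np.nan)
            color = sm.to_rgba(v) if np.isfinite(v) else (0.8, 0.8, 0.8, 1)
            ax.bar(j * width + width / 2, 0.33, width=width, bottom=r_out - 0.33,
                   color=color, edgecolor="w")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(sm, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
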