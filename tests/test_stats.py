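"""Agreement/repeatability statistics against closed-form and library oracles."""

import numpy as np
import pytest

from mtsms.stats import (aha16_labels, bland_altman, cov_rms, icc_two_way,
                         linear_fit, segment_table, snr_stats)


class TestAha16:
    @staticmethod
    def _ring(n=64, r_in=10, r_out=20):
        y, x = np.mgrid[:n, :n]
        r2 = (x - n / 2) ** 2 + (y - n / 2) ** 2
        return (r2 >= r_in ** 2) & (r2 <= r_out ** 2)

    def test_basal_ring_six_equal_segments(self):
        mask = self._ring()
        labels = aha16_labels(mask, rv_insertion_deg=0.0, slice_level="basal")
        counts = [np.sum(labels == s) for s in range(1, 7)]
        assert labels.max() == 6 and labels[~mask].max() == 0
        assert max(counts) - min(counts) <= 0.15 * min(counts)  # pixelization only

    def test_rotating_insertion_by_60_permutes_cyclically(self):
        mask = self._ring()
        l0 = aha16_labels(mask, rv_insertion_deg=0.0, slice_level="basal")
        l60 = aha16_labels(mask, rv_insertion_deg=60.0, slice_level="basal")
        inner = self._ring(r_in=12, r_out=18)  # away from boundary pixels
        m = inner & (l0 > 0)
        assert np.all((l60[m] - 1) % 6 == (l0[m] - 2) % 6)

    def test_apical_has_four_quadrants(self):
        labels = aha16_labels(self._ring(), slice_level="apical")
        assert set(np.unique(labels)) == {0, 13, 14, 15, 16}

    def test_wedge_lands_in_predicted_segment(self):
        n = 64
        mask = self._ring()
        y, x = np.mgrid[:n, :n]
        ang = np.degrees(np.arctan2(y - n / 2, x - n / 2)) % 360.0
        labels = aha16_labels(mask, rv_insertion_deg=0.0, slice_level="mid")
        wedge = mask & (ang > 70) & (ang < 110)  # second 60-deg sector
        assert np.all(labels[wedge] == 8)

    def test_filled_disk_rejected(self):
        y, x = np.mgrid[:32, :32]
        disk = (x - 16) ** 2 + (y - 16) ** 2 <= 100
        with pytest.raises(ValueError, match="annular"):
            aha16_labels(disk, slice_level="mid")


class TestIcc:
    def test_identity_gives_one(self):
        x = np.array([900.0, 1000.0, 1100.0, 1200.0])
        assert icc_two_way(x, x) == pytest.approx(1.0)

    def test_constant_offset_penalized_vs_consistency(self):
        x = np.array([900.0, 1000.0, 1100.0, 1200.0])
        y = x + 300.0
        icc_abs = icc_two_way(x, y)
        # consistency ICC of a pure offset is 1; absolute agreement must be lower
        assert icc_abs < 0.99

    def test_worked_table_against_mean_squares_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.4, 1.9, 3.2, 4.3])
        data = np.stack([x, y], 1)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((data - data.mean(1, keepdims=True) - data.mean(0)
                 + grand) ** 2).sum()) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert icc_two_way(x, y) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        x = rng.normal(1000, 100, 8)
        y = x + rng.normal(0, 30, 8)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(8), 2),
            "raters": np.repeat(["a", "b"], 8),
            "scores": np.concatenate([x, y]),
        })
        tab = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in tab.index else "ICC2"
        assert icc_two_way(x, y) == pytest.approx(float(tab.loc[key, "ICC"]), abs=1e-10)

    def test_degenerate_inputs(self):
        x = np.full(5, 3.0)
        # identical constant raters: perfect agreement by definition
        assert icc_two_way(x, x.copy()) == 1.0
        # constant raters with a pure offset: zero agreement
        assert icc_two_way(x, x + 1.0) == pytest.approx(0.0)


class TestBlandAltman:
    def test_identical_inputs(self):
        x = np.arange(5.0)
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_plus_minus_one_differences(self):
        x = np.array([1.0, 1.0])
        y = np.array([2.0, 0.0])
        bias, lo, hi = bland_altman(x, y)
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_swap_negates_bias(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        assert bland_altman(x, y)[0] == pytest.approx(-bland_altman(y, x)[0])


class TestCov:
    def test_identical_scans_zero(self):
        a = np.array([[1000.0, 1100.0]])
        assert cov_rms(a, a, mode="global") == 0.0
        assert cov_rms(a, a, mode="segmentwise") == 0.0

    def test_two_point_worked_example(self):
        # means 1000 and 1100: sd = 100/sqrt(2) = 70.71, mean 1050 -> 6.73%
        got = cov_rms(np.array([[1000.0]]), np.array([[1100.0]]), mode="global")
        assert got == pytest.approx(70.71067 / 1050 * 100, abs=5e-3)
        assert round(got, 2) == 6.73

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(900, 1300, (10, 16))
        b = a + rng.normal(0, 40, a.shape)
        for mode in ("global", "segmentwise"):
            assert cov_rms(a, b, mode) == pytest.approx(cov_rms(2 * a, 2 * b, mode))

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(900, 1300, (6, 16))
        b = a + rng.normal(0, 40, a.shape)
        perm = rng.permutation(6)
        for mode in ("global", "segmentwise"):
            assert cov_rms(a[perm], b[perm], mode) == pytest.approx(cov_rms(a, b, mode))

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError):
            cov_rms(np.ones((2, 16)), np.ones((2, 15)), mode="segmentwise")


class TestSnr:
    def test_printed_efficiency_values(self):
        # SNR 11.9 over a 3-minute scan and SNR 6.0 over 4.5 minutes
        sms = snr_stats(np.array([11.9]), None, scan_minutes=3.0)
        ss = snr_stats(np.array([6.0]), None, scan_minutes=4.5)
        assert round(sms["efficiency_mean"], 1) == 6.9
        assert round(ss["efficiency_mean"], 1) == 2.8

    def test_segmentwise_mean_over_sd(self):
        means = np.array([1200.0, 1000.0])
        sds = np.array([100.0, 200.0])
        out = snr_stats(means, sds, scan_minutes=4.0)
        assert np.allclose(out["snr"], [12.0, 5.0])
        assert np.allclose(out["efficiency"], [6.0, 2.5])
        assert out["snr_mean"] == pytest.approx(8.5)

    def test_zero_sd_segment_flagged_and_excluded(self):
        with pytest.warns(UserWarning):
            out = snr_stats(np.array([10.0, 12.0]), np.array([1.0, 0.0]), 4.0)
        assert out["flagged"][1]
        assert out["snr_mean"] == pytest.approx(10.0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(6.0)
        slope, intercept, r2 = linear_fit(x, 3 * x - 2)
        assert (slope, intercept, r2) == pytest.approx((3.0, -2.0, 1.0))

    def test_r2_invariant_to_axis_scaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(0, 0.3, 12)
        assert linear_fit(x, y)[2] == pytest.approx(linear_fit(10 * x, 0.1 * y)[2])

    def test_five_point_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.3])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = sxy ** 2 / (sxx * ((y - y.mean()) ** 2).sum())
        got = linear_fit(x, y)
        assert got == pytest.approx((slope, intercept, r2), rel=1e-12)


def test_segment_table_counts_and_slices():
    y, x = np.mgrid[:64, :64]
    r2 = (x - 32) ** 2 + (y - 32) ** 2
    ring = (r2 >= 100) & (r2 <= 400)
    img = np.where(ring, 1200.0, np.nan)
    rows = {}
    for level in ("basal", "mid", "apical"):
        labels = aha16_labels(ring, slice_level=level)
        rows[level] = (img, labels)
    tab = segment_table(rows)
    assert list(tab["segment"]) == list(range(1, 17))
    assert np.allclose(tab["mean"], 1200.0)
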