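"""Guided-breathing analysis: amplitude maps, activation, C.V., trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eitlung.errors import (
    DegenerateRegressionError,
    InvalidFrequencyError,
    TooShortError,
    UndefinedCVError,
    UndefinedNormalizationError,
)
from eitlung.guided import (
    LongitudinalSeries,
    activated_and_total,
    amplitude_map,
    longitudinal_trend,
    regional_cv,
    spectrum,
    subject_normalize,
)
from eitlung.reconstruct import ImageSeries
from eitlung.waveform import ConductivityCurve

from test_indicators import two_ellipse_map


def sine_series(gain, f=0.2, fps=10.0, duration=60.0, mask=None):
    """ImageSeries of voxelwise sines with per-voxel amplitude ``gain``."""
    t = np.arange(0, duration + 1 / fps, 1 / fps)
    if mask is None:
        mask = gain > 0
    vals = np.zeros((t.size, 32, 32))
    vals[:, mask] = np.outer(np.sin(2 * np.pi * f * t), gain[mask])
    return ImageSeries(vals, mask, fps, t)


class TestAmplitudeMap:
    def test_bin_aligned_sine_amplitude_calibrated(self):
        """Hann-corrected DFT returns the sine amplitude itself."""
        gain, _, _ = two_ellipse_map(0.7, 1.3)
        imgs = sine_series(gain, f=0.2, fps=10.0, duration=60.0)
        amp = amplitude_map(imgs, 0.2)
        sel = gain > 0
        np.testing.assert_allclose(amp[sel], gain[sel], rtol=0.02)

    def test_all_zero_series(self):
        mask = np.ones((32, 32), dtype=bool)
        imgs = ImageSeries(np.zeros((200, 32, 32)), mask, 10.0, np.arange(200) / 10.0)
        assert np.all(amplitude_map(imgs, 0.2) == 0)

    def test_p2p_method(self):
        gain, _, _ = two_ellipse_map()
        imgs = sine_series(gain, f=0.2, fps=10.0, duration=60.0)
        amp = amplitude_map(imgs, 0.2, method="p2p")
        sel = gain > 0
        np.testing.assert_allclose(amp[sel], 2.0 * gain[sel], rtol=0.05)

    def test_above_nyquist_rejected(self):
        gain, _, _ = two_ellipse_map()
        imgs = sine_series(gain, fps=10.0)
        with pytest.raises(InvalidFrequencyError):
            amplitude_map(imgs, 6.0)

    def test_too_few_cycles_rejected(self):
        gain, _, _ = two_ellipse_map()
        imgs = sine_series(gain, f=0.2, fps=10.0, duration=10.0)
        with pytest.raises(TooShortError):
            amplitude_map(imgs, 0.2)

    def test_linear_in_breathing_depth(self):
        gain, _, _ = two_ellipse_map()
        a1 = amplitude_map(sine_series(gain), 0.2)
        a3 = amplitude_map(sine_series(3 * gain), 0.2)
        np.testing.assert_allclose(a3, 3 * a1, rtol=1e-9, atol=1e-12)


class TestActivation:
    def test_uniform_map_all_roi_voxels_activated(self):
        amp, left, right = two_ellipse_map(1.0, 1.0)
        labels_src, _, _ = two_ellipse_map()
        from eitlung.indicators import segment_rois

        labels = segment_rois(labels_src)
        out = activated_and_total(amp, labels)
        assert out["L"]["activated_count"] == int(np.isin(labels, ("AL", "PL")).sum())
        assert out["R"]["activated_count"] == int(np.isin(labels, ("AR", "PR")).sum())

    def test_asymmetric_lungs_right_exceeds_left(self):
        """Right lung 20% larger: more activated voxels and higher total."""
        from eitlung.indicators import segment_rois

        r, c = np.mgrid[0:32, 0:32]
        x = -1 + (c + 0.5) / 16
        y = 1 - (r + 0.5) / 16
        amp = np.zeros((32, 32))
        amp[((x - 0.4) / 0.22) ** 2 + ((y + 0.1) / 0.3) ** 2 <= 1] = 1.0
        amp[((x + 0.4) / (0.22 * 1.1)) ** 2 + ((y + 0.1) / (0.3 * 1.1)) ** 2 <= 1] = 1.0
        labels = segment_rois(amp)
        out = activated_and_total(amp, labels)
        assert out["R"]["activated_count"] > out["L"]["activated_count"]
        assert out["R"]["total_amplitude"] > out["L"]["total_amplitude"]

    def test_depth_invariant_counts_scaled_totals(self):
        from eitlung.indicators import segment_rois

        amp, _, _ = two_ellipse_map(0.6, 1.0)
        labels = segment_rois(amp)
        shallow = activated_and_total(amp, labels)
        deep = activated_and_total(3 * amp, labels)
        for reg in ("L", "R"):
            assert deep[reg]["activated_count"] == shallow[reg]["activated_count"]
            assert deep[reg]["total_amplitude"] == pytest.approx(
                3 * shallow[reg]["total_amplitude"], rel=1e-12
            )


class TestRegionalCV:
    def labels(self):
        from eitlung.indicators import segment_rois

        amp, _, _ = two_ellipse_map()
        return amp, segment_rois(amp)

    def test_uniform_cv_zero(self):
        amp, labels = self.labels()
        assert regional_cv(amp, labels, "L") == pytest.approx(0.0, abs=1e-12)

    def test_two_value_hand_arithmetic(self):
        """Amplitudes {1, 3}: mean 2, population SD 1, CV 0.5."""
        amp, labels = self.labels()
        sel = np.flatnonzero((labels == "AL").ravel())[:2]
        amp = np.zeros_like(amp)
        amp.ravel()[sel] = [1.0, 3.0]
        labels2 = np.full((32, 32), "none", dtype="<U4")
        labels2.ravel()[sel] = "AL"
        assert regional_cv(amp, labels2, "AL") == pytest.approx(0.5, rel=1e-12)

    @given(scale=st.floats(0.01, 1000))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        amp, labels = self.labels()
        rng = np.random.default_rng(4)
        amp = amp * rng.uniform(0.5, 1.5, amp.shape)
        base = regional_cv(amp, labels, "R")
        assert regional_cv(scale * amp, labels, "R") == pytest.approx(base, rel=1e-9)

    def test_undefined_cases(self):
        labels = np.full((32, 32), "none", dtype="<U4")
        labels[0, 0] = "AL"
        with pytest.raises(UndefinedCVError):
            regional_cv(np.ones((32, 32)), labels, "AL")


class TestSpectrum:
    def test_guided_cosine_peaks_at_0p2_hz(self):
        t = np.arange(0, 60 + 0.1, 0.1)
        c = ConductivityCurve(t, 0.75 * (1 - np.cos(2 * np.pi * 0.2 * t)), 10.0)
        freqs, mag = spectrum(c)
        assert freqs[np.argmax(mag)] == pytest.approx(0.2, abs=1 / 60)

    def test_two_tone_magnitude_ratio(self):
        t = np.arange(0, 60, 0.1)
        x = 2.0 * np.sin(2 * np.pi * 0.2 * t) + 0.8 * np.sin(2 * np.pi * 0.4 * t)
        freqs, mag = spectrum(ConductivityCurve(t, x, 10.0))
        k1 = np.argmin(np.abs(freqs - 0.2))
        k2 = np.argmin(np.abs(freqs - 0.4))
        assert mag[k1] / mag[k2] == pytest.approx(2.0 / 0.8, rel=0.01)

    def test_constant_signal_no_spectral_content(self):
        t = np.arange(0, 60, 0.1)
        freqs, mag = spectrum(ConductivityCurve(t, np.full(t.size, 5.0), 10.0))
        assert np.all(mag[freqs > 0] < 1e-9)

    def test_too_short_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(TooShortError):
            spectrum(ConductivityCurve(t, np.sin(t), 10.0))


class TestLongitudinalTrend:
    def test_exact_line(self):
        days = np.arange(10.0)
        series = LongitudinalSeries(days, 0.5 - 0.01 * days)
        res = longitudinal_trend(series)
        assert res.slope == pytest.approx(-0.01, rel=1e-9)
        assert res.pvalue < 1e-12
        assert res.pcc == pytest.approx(-1.0, abs=1e-9)

    def test_type_one_error_rate(self):
        """Null series: slope significant at 5% in about 5% of replicates."""
        rng = np.random.default_rng(12)
        days = np.arange(10.0)
        hits = sum(
            longitudinal_trend(LongitudinalSeries(days, rng.normal(0.5, 0.05, 10))).pvalue < 0.05
            for _ in range(400)
        )
        assert 0.02 < hits / 400 < 0.09

    def test_outlier_leverage_flagged(self):
        days = np.append(np.arange(9.0), 60.0)
        res = longitudinal_trend(LongitudinalSeries(days, 0.4 + 0.001 * days))
        assert 9 in res.outlier_sessions
        assert len(res.outlier_sessions) <= 2

    def test_identical_times_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            longitudinal_trend(LongitudinalSeries(np.ones(5), np.arange(5.0)))


class TestSubjectNormalize:
    def test_basic_and_idempotent(self):
        out = subject_normalize({"a": [2.0, 4.0]})
        np.testing.assert_allclose(out["a"], [0.5, 1.0])
        again = subject_normalize(out)
        np.testing.assert_allclose(again["a"], out["a"])

    def test_deep_shallow_ratio(self):
        out = subject_normalize({"s": [6.0, 2.0]})
        np.testing.assert_allclose(out["s"], [1.0, 1 / 3], rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            subject_normalize({"z": [0.0, 0.0]})
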