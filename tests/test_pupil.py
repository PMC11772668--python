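"""Pupil preprocessing: margin masking, cubic fill, downsampling, SSA, high-pass."""

import numpy as np
import pytest

from pupilbands.core import SampledSignal
from pupilbands.pupil import (downsample, fill_gaps_shape_preserving_cubic,
                              highpass, mask_invalid_with_margin,
                              preprocess_pupil, trim_invalid_edges)
from pupilbands.ssa import SSAConfig, iterative_ssa_clean, ssa_decompose


def signal_with_invalid(n=5000, fs=500.0, spans=()):
    mask = np.ones(n, dtype=bool)
    for a, b in spans:
        mask[int(a * fs):int(b * fs)] = False
    return SampledSignal(np.sin(np.arange(n) / 300.0) + 3.0, fs,
                         valid_mask=mask)


class TestMarginMask:
    def test_no_invalid_no_change(self):
        sig = signal_with_invalid()
        out = mask_invalid_with_margin(sig, 100.0)
        assert out.valid_mask.all()

    def test_margin_covers_100ms_each_side(self):
        sig = signal_with_invalid(spans=[(2.0, 2.1)])
        out = mask_invalid_with_margin(sig, 100.0)
        t = sig.times
        must_be_masked = (t >= 1.905) & (t <= 2.195)
        assert not out.valid_mask[must_be_masked].any()
        assert out.valid_mask[t < 1.85].all()
        assert out.valid_mask[t > 2.25].all()

    def test_nearby_spans_merge(self):
        """Two invalid spans 150 ms apart merge under a 100 ms margin."""
        sig = signal_with_invalid(spans=[(2.0, 2.05), (2.2, 2.25)])
        out = mask_invalid_with_margin(sig, 100.0)
        t = sig.times
        between = (t > 2.05) & (t < 2.2)
        assert not out.valid_mask[between].any()

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            mask_invalid_with_margin(signal_with_invalid(), -1.0)


class TestCubicFill:
    def test_linear_ramp_restored_exactly(self):
        mask = np.ones(100, dtype=bool)
        mask[40:50] = False
        ramp = np.linspace(0, 9.9, 100)
        sig = SampledSignal(ramp.copy(), 10.0, valid_mask=mask)
        sig.values[~mask] = -99.0
        out = fill_gaps_shape_preserving_cubic(sig)
        np.testing.assert_allclose(out.values, ramp, atol=1e-9)

    def test_monotone_gap_no_overshoot(self):
        mask = np.ones(60, dtype=bool)
        mask[20:35] = False
        vals = np.tanh(np.linspace(-3, 3, 60)) * 2 + 5
        sig = SampledSignal(vals.copy(), 10.0, valid_mask=mask)
        out = fill_gaps_shape_preserving_cubic(sig)
        assert out.values[20:35].min() >= vals[19] - 1e-12
        assert out.values[20:35].max() <= vals[35] + 1e-12

    def test_no_gap_identity(self):
        sig = SampledSignal(np.random.default_rng(0).normal(size=50), 10.0)
        out = fill_gaps_shape_preserving_cubic(sig)
        np.testing.assert_array_equal(out.values, sig.values)

    def test_edge_invalid_rejected_until_trimmed(self):
        mask = np.ones(50, dtype=bool)
        mask[:5] = False
        sig = SampledSignal(np.ones(50), 10.0, valid_mask=mask)
        with pytest.raises(ValueError, match="trim"):
            fill_gaps_shape_preserving_cubic(sig)
        trimmed = trim_invalid_edges(sig)
        assert len(trimmed) == 45
        assert trimmed.t0 == pytest.approx(0.5)


class TestDownsample:
    def test_dc_preserved(self):
        sig = SampledSignal(np.full(50000, 2.5), 500.0)
        out = downsample(sig, 8.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-9)
        assert out.fs == 8.0

    def test_slow_sinusoid_amplitude_preserved(self):
        t = np.arange(0, 100, 1 / 500)
        sig = SampledSignal(np.sin(2 * np.pi * 0.2 * t), 500.0)
        out = downsample(sig, 8.0)
        mid = slice(40, -40)
        assert out.values[mid].std() == pytest.approx(
            sig.values.std(), rel=0.02)

    def test_above_nyquist_content_suppressed(self):
        t = np.arange(0, 100, 1 / 500)
        sig = SampledSignal(np.sin(2 * np.pi * 10.0 * t), 500.0)
        out = downsample(sig, 8.0)
        assert np.sqrt(np.mean(out.values ** 2)) < 0.05 * np.sqrt(
            np.mean(sig.values ** 2))

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(SampledSignal(np.zeros(100), 8.0), 16.0)


class TestHighpass:
    def test_oscillation_preserved(self):
        t = np.arange(4800) / 8.0
        sig = SampledSignal(np.sin(2 * np.pi * 0.1 * t), 8.0)
        out = highpass(sig)
        mid = slice(400, -400)
        assert out.values[mid].std() == pytest.approx(
            sig.values[mid].std(), rel=0.02)

    def test_dc_rejected(self):
        sig = SampledSignal(np.full(4800, 5.0), 8.0)
        out = highpass(sig)
        assert abs(out.values.mean()) < 1e-6 * 5.0

    def test_linear_drift_mostly_removed(self):
        t = np.arange(4800) / 8.0
        sig = SampledSignal(0.01 * t, 8.0)
        out = highpass(sig)
        assert out.values.var() < 0.10 * sig.values.var()


class TestSSA:
    def test_decomposition_complete(self, rng):
        x = np.sin(2 * np.pi * 0.2 * np.arange(300) / 8) \
            + 0.2 * rng.standard_normal(300)
        comps = ssa_decompose(x, 50)
        recon = np.sum(comps, axis=0)
        assert np.max(np.abs(recon - x)) < 1e-8 * max(np.max(np.abs(x)), 1)

    def test_sinusoid_captured_by_leading_pair(self):
        x = np.sin(2 * np.pi * 0.2 * np.arange(400) / 8)
        comps = ssa_decompose(x, 60)
        recon2 = comps[0] + comps[1]
        assert np.var(recon2) / np.var(x) > 0.95

    def test_constant_series_first_component(self):
        comps = ssa_decompose(np.full(100, 7.0), 20)
        assert np.var(comps[0] - 7.0) < 1e-9
        assert sum(np.abs(c).max() for c in comps[1:]) < 1e-6

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            ssa_decompose(np.ones(20), 15)

    def test_clean_no_flags_identity(self):
        sig = SampledSignal(np.sin(np.arange(200) / 5), 8.0)
        out, status = iterative_ssa_clean(sig, SSAConfig(window_len=40))
        np.testing.assert_array_equal(out.values, sig.values)
        assert status["n_iter"] == 0

    def test_corrupted_sinusoid_repaired(self, rng):
        n = 1600
        clean = np.sin(2 * np.pi * 0.2 * np.arange(n) / 8)
        flags = rng.random(n) < 0.05
        x = clean.copy()
        x[flags] += rng.normal(0, 1, flags.sum())
        out, status = iterative_ssa_clean(
            SampledSignal(x, 8.0), SSAConfig(window_len=240), flags=flags)
        rmse = np.sqrt(np.mean((out.values[flags] - clean[flags]) ** 2))
        assert rmse < 0.05  # < 5% of unit amplitude
        assert status["converged"]

    def test_infinite_tolerance_single_iteration(self):
        sig = SampledSignal(np.sin(np.arange(400) / 5), 8.0)
        flags = np.zeros(400, dtype=bool)
        flags[100:104] = True
        _, status = iterative_ssa_clean(
            sig, SSAConfig(window_len=60, tol=np.inf), flags=flags)
        assert status["n_iter"] == 1


class TestFullChain:
    def test_clean_signal_roundtrip_within_3pct(self, rng):
        """On an artifact-free signal whose values stay inside the Tukey
        fences, the chain reduces to the band-pass: output equals the
        band-passed input within 3% RMS."""
        fs = 500.0
        t = np.arange(int(600 * fs)) / fs
        vals = (3.5 + 0.10 * np.sin(2 * np.pi * 0.20 * t)
                + 0.05 * np.sin(2 * np.pi * 0.35 * t))
        raw = SampledSignal(vals, fs)
        clean, report = preprocess_pupil(raw)
        reference = highpass(downsample(raw, 8.0))
        n = min(len(clean), len(reference))
        mid = slice(200, n - 200)
        err = clean.values[mid] - reference.values[mid]
        assert np.sqrt(np.mean(err ** 2)) < 0.03 * reference.values[mid].std()
        assert report["n_filled"] == 0

    def test_stage_order_matters(self):
        """Swapping margin-masking and gap-filling changes the output:
        filling first would interpolate through still-unmasked samples."""
        sig = signal_with_invalid(n=20000, spans=[(10.0, 10.3)])
        sig.values[~sig.valid_mask] = 0.0
        proper, _ = preprocess_pupil(sig)
        # improper order: fill gaps, then mask (mask now has nothing to do)
        filled = fill_gaps_shape_preserving_cubic(trim_invalid_edges(sig))
        swapped = mask_invalid_with_margin(filled, 100.0)
        improper = downsample(swapped, 8.0)
        n = min(len(proper), len(improper))
        assert not np.allclose(proper.values[:n], improper.values[:n] -
                               np.mean(improper.values[:n]), atol=1e-3)

    def test_report_counts(self):
        sig = signal_with_invalid(n=100000, spans=[(20.0, 20.2), (50.0, 50.15)])
        _, report = preprocess_pupil(sig)
        assert report["n_invalid_in"] == int(0.2 * 500) + int(0.15 * 500)
        assert report["n_masked_with_margin"] > report["n_invalid_in"]
        assert report["fs_out"] == 8.0
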