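"""Band-combination enumeration, feature extraction and per-run correlations."""

import numpy as np
import pytest
from scipy import stats

from pupilbands.core import SampledSignal
from pupilbands.sweep import (FeatureSeries, align_signals,
                              combination_indices, combo_correlations_at_edges,
                              enumerate_combinations, grid_edges,
                              hrv_feature_series, per_run_correlation,
                              pupil_cumpower_matrix)


class TestEnumeration:
    @pytest.mark.parametrize("step,f_max,expected", [
        (0.25, 1.0, 10),      # C(5,3)
        (0.5, 1.0, 1),
        (0.1, 1.0, 165),      # C(11,3)
        (0.01, 1.0, 166650),  # C(101,3)
    ])
    def test_counts(self, step, f_max, expected):
        i, j, k = combination_indices(step, f_max)
        assert i.size == expected

    def test_lexicographic_order_and_invariants(self):
        combos = enumerate_combinations(0.25, 1.0)
        assert combos == sorted(combos)
        for c in combos:
            assert 0 <= c.lf_lo < c.split < c.hf_hi <= 1.0

    def test_non_integral_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations(0.03, 1.0)

    def test_edges(self):
        np.testing.assert_allclose(grid_edges(0.25, 1.0),
                                   [0, 0.25, 0.5, 0.75, 1.0])


def _toy_signal(duration=400.0, seed=0, freq=None):
    rng = np.random.default_rng(seed)
    n = int(duration * 8)
    x = rng.standard_normal(n)
    if freq:
        x = x * 0.05 + np.sin(2 * np.pi * freq * np.arange(n) / 8)
    return SampledSignal(x, 8.0)


class TestHRVFeatures:
    def test_lf_dominant_signal(self):
        feats = hrv_feature_series(_toy_signal(seed=1, freq=0.1))
        assert np.median(feats.ratio) > 5

    def test_hf_dominant_signal(self):
        feats = hrv_feature_series(_toy_signal(seed=2, freq=0.3))
        assert np.median(feats.ratio) < 0.5

    def test_white_noise_ratio_near_bandwidth_ratio(self):
        """Flat spectrum: LF/HF ~ 0.11/0.25 on average."""
        ratios = []
        for seed in range(5):
            feats = hrv_feature_series(_toy_signal(duration=400, seed=seed))
            ratios.append(np.mean(feats.ratio))
        assert np.mean(ratios) == pytest.approx(0.11 / 0.25, rel=0.25)

    def test_one_triplet_per_window(self):
        feats = hrv_feature_series(_toy_signal(duration=200.0))
        assert feats.n_windows == (200 - 180) * 8 // 8 + 1
        assert feats.lf.shape == feats.hf.shape == feats.ratio.shape


class TestCumPowerMatrix:
    def test_monotone_rows_and_reconstruction(self):
        from pupilbands.spectral import sliding_windows, window_psd, band_power
        sig = _toy_signal(duration=250.0, seed=3)
        edges = grid_edges(0.1, 1.0)
        mat, starts = pupil_cumpower_matrix(sig, edges)
        assert np.all(np.diff(mat, axis=1) >= 0)
        # reconstruction equals direct band_power
        wins = sliding_windows(sig)
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.integers(len(wins))
            i, j = sorted(rng.choice(len(edges), 2, replace=False))
            psd = window_psd(wins[w], 8.0)
            direct = band_power(psd, edges[i], edges[j])
            assert mat[w, j] - mat[w, i] == pytest.approx(direct, rel=1e-10)

    def test_edges_beyond_psd_coverage_rejected(self):
        sig = _toy_signal(duration=200.0)
        with pytest.raises(ValueError):
            pupil_cumpower_matrix(sig, [0.0, 5.0])


def _fake_hrv(n, rng):
    lf = rng.random(n) + 0.5
    hf = rng.random(n) + 0.5
    return FeatureSeries(lf, hf, lf / hf, np.arange(n, dtype=float))


class TestPerRunCorrelation:
    def test_self_correlation_is_one(self, rng):
        n, edges = 50, np.array([0.0, 0.2, 0.5, 1.0])
        hrv = _fake_hrv(n, rng)
        # craft cum matrix so that band powers equal the HRV features
        cum = np.zeros((n, 4))
        cum[:, 1] = hrv.lf
        cum[:, 2] = hrv.lf + hrv.hf
        cum[:, 3] = hrv.lf + hrv.hf + 1.0
        rc = per_run_correlation(cum, edges, hrv,
                                 (np.array([0]), np.array([1]), np.array([2])))
        assert rc.r_lf[0] == pytest.approx(1.0)
        assert rc.r_hf[0] == pytest.approx(1.0)
        assert rc.r_ratio[0] == pytest.approx(1.0)
        assert rc.p_lf[0] < 1e-10

    def test_negated_series(self, rng):
        n, edges = 40, np.array([0.0, 0.5, 0.8, 1.0])
        hrv = _fake_hrv(n, rng)
        cum = np.zeros((n, 4))
        cum[:, 1] = 10 - hrv.lf          # anti-correlated LF power
        cum[:, 2] = cum[:, 1] + hrv.hf
        cum[:, 3] = cum[:, 2] + 1
        rc = per_run_correlation(cum, edges, hrv,
                                 (np.array([0]), np.array([1]), np.array([2])))
        assert rc.r_lf[0] == pytest.approx(-1.0)

    def test_null_calibration(self):
        """Independent white-noise feature pairs: mean r ~ 0 and ~5% of
        p-values below 0.05 (1000 replicates, n = 400)."""
        rng = np.random.default_rng(99)
        n, reps = 400, 1000
        rs = np.empty(reps)
        ps = np.empty(reps)
        edges = np.array([0.0, 0.5, 0.75, 1.0])
        for b in range(reps):
            hrv = _fake_hrv(n, rng)
            cum = np.zeros((n, 4))
            cum[:, 1] = rng.random(n) + 0.5
            cum[:, 2] = cum[:, 1] + rng.random(n) + 0.5
            cum[:, 3] = cum[:, 2] + 1
            rc = per_run_correlation(cum, edges, hrv,
                                     (np.array([0]), np.array([1]),
                                      np.array([2])))
            rs[b], ps[b] = rc.r_lf[0], rc.p_lf[0]
        assert abs(rs.mean()) < 0.01
        assert 0.03 <= (ps < 0.05).mean() <= 0.07

    def test_spearman_monotone_invariance(self, rng):
        n, edges = 60, np.array([0.0, 0.4, 0.7, 1.0])
        hrv = _fake_hrv(n, rng)
        cum = np.zeros((n, 4))
        base = rng.random(n) + 0.5
        cum[:, 1] = base
        cum[:, 2] = base + rng.random(n) + 0.5
        cum[:, 3] = cum[:, 2] + 1
        idx = (np.array([0]), np.array([1]), np.array([2]))
        r1 = per_run_correlation(cum, edges, hrv, idx, method="spearman")
        # strictly monotone transform of the LF band power
        cum2 = cum.copy()
        cum2[:, 1] = np.exp(base)
        cum2[:, 2] = cum2[:, 1] + (cum[:, 2] - cum[:, 1])
        cum2[:, 3] = cum2[:, 2] + 1
        r2 = per_run_correlation(cum2, edges, hrv, idx, method="spearman")
        assert r1.r_lf[0] == pytest.approx(r2.r_lf[0], abs=1e-12)

    def test_sweep_matches_bruteforce_on_coarse_grid(self):
        """Cumulative-matrix sweep equals per-combo recomputation."""
        sig = _toy_signal(duration=220.0, seed=5)
        hrv_sig = _toy_signal(duration=220.0, seed=6)
        edges = grid_edges(0.1, 1.0)
        cidx = combination_indices(0.1, 1.0)
        hrv = hrv_feature_series(hrv_sig)
        cum, _ = pupil_cumpower_matrix(sig, edges)
        rc = per_run_correlation(cum, edges, hrv, cidx)
        i, j, k = cidx
        rng = np.random.default_rng(1)
        for c in rng.choice(i.size, 15, replace=False):
            lf_pow = cum[:, j[c]] - cum[:, i[c]]
            hf_pow = cum[:, k[c]] - cum[:, j[c]]
            r_lf = stats.pearsonr(lf_pow, hrv.lf)
            r_ratio = stats.pearsonr(lf_pow / hf_pow, hrv.ratio)
            assert rc.r_lf[c] == pytest.approx(r_lf.statistic, abs=1e-10)
            assert rc.p_lf[c] == pytest.approx(r_lf.pvalue, rel=1e-6)
            assert rc.r_ratio[c] == pytest.approx(r_ratio.statistic, abs=1e-10)

    def test_explicit_combo_evaluation_matches_lattice(self):
        sig = _toy_signal(duration=220.0, seed=7)
        hrv_sig = _toy_signal(duration=220.0, seed=8)
        edges = grid_edges(0.1, 1.0)
        cidx = combination_indices(0.1, 1.0)
        hrv = hrv_feature_series(hrv_sig)
        cum, _ = pupil_cumpower_matrix(sig, edges)
        full = per_run_correlation(cum, edges, hrv, cidx)
        sub = combo_correlations_at_edges(cum, edges, hrv,
                                          [(0.1, 0.3, 0.6)])
        i, j, k = cidx
        pos = np.nonzero((edges[i] == 0.1) & (edges[j] == 0.3)
                         & (edges[k] == 0.6))[0][0]
        assert sub.r_lf[0] == pytest.approx(full.r_lf[pos])
        assert sub.r_ratio[0] == pytest.approx(full.r_ratio[pos])


class TestAlign:
    def test_overlap_cropping(self):
        a = SampledSignal(np.arange(80, dtype=float), 8.0, t0=0.0)
        b = SampledSignal(np.arange(80, dtype=float), 8.0, t0=2.0)
        ca, cb = align_signals(a, b)
        assert ca.t0 == pytest.approx(2.0)
        assert cb.t0 == pytest.approx(2.0)
        assert len(ca) == len(cb)

    def test_rate_mismatch_rejected(self):
        a = SampledSignal(np.zeros(10), 8.0)
        b = SampledSignal(np.zeros(10), 4.0)
        with pytest.raises(ValueError):
            align_signals(a, b)
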