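"""Exhaustive LF/HF band-limit sweep and per-run feature correlations.

A band combination is a triple (lf_lo, split, hf_hi) on a regular frequency
grid: LF = [lf_lo, split), HF = [split, hf_hi), no overlap by construction.
For each 180 s window the pupil PSD's cumulative power is sampled once at
every grid edge; the power of *any* band is then a difference of two stored
values (exact, by additivity of the cumulative integral), which makes the
full sweep over C(101, 3) = 166,650 combinations tractable.

HRV features use the canonical bands (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz).
Per run, each pupil combination's LF/HF/ratio window series is correlated
feature-to-feature against the HRV series (Pearson by default, Spearman as
a robustness variant) with two-sided p-values from the t transform of r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .core import SampledSignal
from .spectral import (DEFAULT_AR_ORDER, DEFAULT_N_GRID, DEFAULT_STEP_S,
                       DEFAULT_WINDOW_S, sliding_windows, window_psd)

HRV_LF_BAND = (0.04, 0.15)
HRV_HF_BAND = (0.15, 0.40)

DEFAULT_GRID_STEP = 0.01
DEFAULT_F_MAX = 1.0


class BandCombination(NamedTuple):
    lf_lo: float
    split: float
    hf_hi: float


def _n_edges(step: float, f_max: float) -> int:
    ratio = f_max / step
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"f_max={f_max} is not an integer multiple of step={step}")
    return int(round(ratio)) + 1


def grid_edges(step: float = DEFAULT_GRID_STEP,
               f_max: float = DEFAULT_F_MAX) -> np.ndarray:
    """The band-edge grid 0, step, 2*step, ..., f_max."""
    return np.round(np.arange(_n_edges(step, f_max)) * step, 10)


def combination_indices(step: float = DEFAULT_GRID_STEP,
                        f_max: float = DEFAULT_F_MAX):
    """All combinations as index triples (i < j < k) into the edge grid."""
    n = _n_edges(step, f_max)
    tri = np.array(np.triu_indices(n, 1)).T          # all i < j pairs
    i_idx, j_idx, k_idx = [], [], []
    for i, j in tri:
        ks = np.arange(j + 1, n)
        i_idx.append(np.full(ks.size, i))
        j_idx.append(np.full(ks.size, j))
        k_idx.append(ks)
    return (np.concatenate(i_idx), np.concatenate(j_idx), np.concatenate(k_idx))


def enumerate_combinations(step: float = DEFAULT_GRID_STEP,
                           f_max: float = DEFAULT_F_MAX
                           ) -> list[BandCombination]:
    """Every grid-aligned non-overlapping triple, lexicographically ordered."""
    edges = grid_edges(step, f_max)
    i, j, k = combination_indices(step, f_max)
    return [BandCombination(edges[a], edges[b], edges[c])
            for a, b, c in zip(i, j, k)]


@dataclass
class FeatureSeries:
    """Windowed LF/HF/ratio series for one signal under fixed bands."""

    lf: np.ndarray
    hf: np.ndarray
    ratio: np.ndarray
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.lf.size


def hrv_feature_series(signal: SampledSignal,
                       win: float = DEFAULT_WINDOW_S,
                       step: float = DEFAULT_STEP_S,
                       order: int = DEFAULT_AR_ORDER,
                       n_grid: int = DEFAULT_N_GRID) -> FeatureSeries:
    """Canonical-band HRV features, one triplet per sliding window.

    Windows with zero HF power would make the ratio undefined; they are
    marked NaN and dropped pairwise by the correlation step.
    """
    windows = sliding_windows(signal, win, step)
    lf = np.empty(len(windows))
    hf = np.empty(len(windows))
    for idx, w in enumerate(windows):
        psd = window_psd(w, signal.fs, order, n_grid)
        c = np.interp([HRV_LF_BAND[0], HRV_LF_BAND[1], HRV_HF_BAND[1]],
                      psd.freqs, psd.cum_power)
        lf[idx] = c[1] - c[0]
        hf[idx] = c[2] - c[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hf > 0, lf / hf, np.nan)
    starts = np.array([w.start for w in windows])
    return FeatureSeries(lf, hf, ratio, starts)


def pupil_cumpower_matrix(signal: SampledSignal, edges,
                          win: float = DEFAULT_WINDOW_S,
                          step: float = DEFAULT_STEP_S,
                          order: int = DEFAULT_AR_ORDER,
                          n_grid: int = DEFAULT_N_GRID):
    """Per-window cumulative power sampled at the band-edge grid.

    Returns ``(matrix, window_starts)`` with matrix shape
    (n_windows, n_edges); band power of any combination is an exact
    difference of two columns.
    """
    edges = np.asarray(edges, dtype=float)
    windows = sliding_windows(signal, win, step)
    mat = np.empty((len(windows), edges.size))
    for idx, w in enumerate(windows):
        psd = window_psd(w, signal.fs, order, n_grid)
        if edges[-1] > psd.freqs[-1] + 1e-9:
            raise ValueError("edge grid extends beyond the PSD coverage")
        mat[idx] = np.interp(edges, psd.freqs, psd.cum_power)
    starts = np.array([w.start for w in windows])
    return mat, starts


@dataclass
class RunCorrelations:
    """Per-combination correlations of one run against the HRV features."""

    combo_idx: tuple[np.ndarray, np.ndarray, np.ndarray]
    edges: np.ndarray
    r_lf: np.ndarray
    p_lf: np.ndarray
    r_hf: np.ndarray
    p_hf: np.ndarray
    r_ratio: np.ndarray
    p_ratio: np.ndarray
    n: int
    n_ratio: int
    method: str

    @property
    def n_combos(self) -> int:
        return self.r_lf.size

    def combos(self) -> list[BandCombination]:
        i, j, k = self.combo_idx
        return [BandCombination(self.edges[a], self.edges[b], self.edges[c])
                for a, b, c in zip(i, j, k)]


def _corr_columns(target: np.ndarray, mat: np.ndarray):
    """Pearson r of ``target`` against every column, plus the t-test p."""
    n = target.size
    if n < 3:
        raise ValueError("need at least 3 aligned windows")
    tc = target - target.mean()
    mc = mat - mat.mean(axis=0)
    t_norm = np.sqrt(tc @ tc)
    m_norm = np.sqrt(np.einsum("ij,ij->j", mc, mc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc.T @ tc) / (m_norm * t_norm)
    r = np.where((m_norm == 0) | (t_norm == 0), np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t_stat), n - 2))
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def per_run_correlation(cum_matrix: np.ndarray, edges, hrv: FeatureSeries,
                        combo_idx, method: str = "pearson",
                        chunk: int = 40000) -> RunCorrelations:
    """Correlate every band combination's features against the HRV features.

    LF depends only on the (lf_lo, split) edge pair and HF only on
    (split, hf_hi), so correlations are computed once per unique pair and
    broadcast to combinations; the ratio is combination-specific and
    processed in chunks.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    edges = np.asarray(edges, dtype=float)
    n_windows, n_edges = cum_matrix.shape
    if hrv.n_windows != n_windows:
        raise ValueError("HRV and pupil window counts differ; align runs first")
    i_idx, j_idx, k_idx = combo_idx

    band = lambda a, b: cum_matrix[:, b] - cum_matrix[:, a]

    def prep(v):
        return _rank(v) if method == "spearman" else v

    # unique-band correlations for LF and HF
    def pair_corr(first, second, target):
        pid = first.astype(np.int64) * n_edges + second
        uniq, inv = np.unique(pid, return_inverse=True)
        powers = cum_matrix[:, uniq % n_edges] - cum_matrix[:, uniq // n_edges]
        r_u, p_u = _corr_columns(prep(target), prep(powers))
        return r_u[inv], p_u[inv]

    finite = np.isfinite(hrv.ratio)
    r_lf, p_lf = pair_corr(i_idx, j_idx, hrv.lf)
    r_hf, p_hf = pair_corr(j_idx, k_idx, hrv.hf)

    n_combos = i_idx.size
    r_ratio = np.empty(n_combos)
    p_ratio = np.empty(n_combos)
    h_ratio = hrv.ratio[finite]
    for s in range(0, n_combos, chunk):
        sl = slice(s, min(s + chunk, n_combos))
        lf_pow = band(i_idx[sl], j_idx[sl])
        hf_pow = band(j_idx[sl], k_idx[sl])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(hf_pow > 0, lf_pow / hf_pow, np.nan)
        ratio = ratio[finite]
        col_ok = np.all(np.isfinite(ratio), axis=0)
        r_c = np.full(ratio.shape[1], np.nan)
        p_c = np.full(ratio.shape[1], np.nan)
        if col_ok.any():
            r_c[col_ok], p_c[col_ok] = _corr_columns(prep(h_ratio),
                                                     prep(ratio[:, col_ok]))
        if (~col_ok).any():
            # windows with undefined pupil ratio dropped pairwise, per combo
            for c in np.nonzero(~col_ok)[0]:
                ok = np.isfinite(ratio[:, c])
                if ok.sum() >= 3:
                    r_c[c:c + 1], p_c[c:c + 1] = _corr_columns(
                        prep(h_ratio[ok]), prep(ratio[ok, c:c + 1]))
        r_ratio[sl], p_ratio[sl] = r_c, p_c
    return RunCorrelations((i_idx, j_idx, k_idx), edges, r_lf, p_lf,
                           r_hf, p_hf, r_ratio, p_ratio,
                           n=n_windows, n_ratio=int(finite.sum()),
                           method=method)


def combo_correlations_at_edges(cum_matrix: np.ndarray, edges,
                                hrv: FeatureSeries, combos,
                                method: str = "pearson") -> RunCorrelations:
    """Correlations for an explicit list of combinations.

    Every combination limit must be present in ``edges`` (which need not be
    a regular grid) — this is how band definitions off the sweep lattice,
    such as the canonical literature bands on a coarse grid, are evaluated
    on exactly the same windows as the sweep itself.
    """
    edges = np.asarray(edges, dtype=float)
    idx = []
    for combo in combos:
        pos = []
        for v in combo:
            hits = np.nonzero(np.isclose(edges, v, atol=1e-9))[0]
            if hits.size == 0:
                raise ValueError(f"edge {v} Hz not in the stored edge set")
            pos.append(int(hits[0]))
        idx.append(pos)
    arr = np.asarray(idx, dtype=np.int64)
    return per_run_correlation(cum_matrix, edges, hrv,
                               (arr[:, 0], arr[:, 1], arr[:, 2]),
                               method=method)


def align_signals(a: SampledSignal, b: SampledSignal
                  ) -> tuple[SampledSignal, SampledSignal]:
    """Crop two signals to their overlapping time span.

    Window starts downstream then coincide, which the correlation step
    requires.  Sampling rates must match.
    """
    if a.fs != b.fs:
        raise ValueError("signals must share a sampling rate")
    t0 = max(a.t0, b.t0)
    t1 = min(a.t0 + a.span, b.t0 + b.span)
    if t1 <= t0:
        raise ValueError("signals do not overlap in time")

    def crop(s: SampledSignal) -> SampledSignal:
        i0 = int(np.ceil(round((t0 - s.t0) * s.fs, 6)))
        i1 = int(np.floor(round((t1 - s.t0) * s.fs, 6))) + 1
        return SampledSignal(s.values[i0:i1], s.fs, s.t0 + i0 / s.fs,
                             s.valid_mask[i0:i1])

    ca, cb = crop(a), crop(b)
    n = min(len(ca), len(cb))
    ca.values, ca.valid_mask = ca.values[:n], ca.valid_mask[:n]
    cb.values, cb.valid_mask = cb.values[:n], cb.valid_mask[:n]
    return ca, cb
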