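"""Autoregressive (Burg) spectral estimation and band-power integration.

The pipeline estimates each 180 s window's PSD with Burg's method: AR
coefficients from forward+backward prediction-error minimization via the
Levinson-style reflection-coefficient recursion, then the AR transfer
function evaluated on a fine frequency grid.  Band powers come from the
cumulative integrated power, so adjacent half-open bands [lo, hi) partition
power exactly.

Convention: the density is the two-sided AR spectrum evaluated on
[0, fs/2], i.e. density(f) = sigma^2 / (fs * |A(e^{-i 2 pi f / fs})|^2);
its integral over [0, fs/2] is sigma^2/2 for white noise.  The convention
scales every band power equally and cancels in all ratios and correlations
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SampledSignal

# 32 poles: enough to resolve a slow-drift remnant, two oscillatory bands
# and a 1/f background on a 1440-sample window; fewer poles smear each
# band's resonance skirt across its neighbors and bias band powers.
DEFAULT_AR_ORDER = 32
DEFAULT_N_GRID = 2049
DEFAULT_WINDOW_S = 180.0
DEFAULT_STEP_S = 1.0


@dataclass
class ARModel:
    """AR(p) model ``x_t + sum_k a_k x_{t-k} = e_t``, e_t white with
    variance ``noise_variance``."""

    order: int
    coefficients: np.ndarray      # a_1 .. a_p
    noise_variance: float
    reflection: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order < 1 or self.coefficients.size != self.order:
            raise ValueError("order must be >= 1 and match coefficients")
        if not self.noise_variance > 0:
            raise ValueError("noise_variance must be > 0")

    def is_stable(self) -> bool:
        roots = np.roots(np.concatenate([[1.0], self.coefficients]))
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class PSDEstimate:
    """Frequency grid, power density and cumulative integrated power."""

    freqs: np.ndarray
    density: np.ndarray
    cum_power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.cum_power = np.asarray(self.cum_power, dtype=float)

    @property
    def total_power(self) -> float:
        return float(self.cum_power[-1])


@dataclass
class AnalysisWindow:
    start: float
    length: float
    samples: np.ndarray


def burg_fit(x, order: int) -> ARModel:
    """Burg's recursion.

    Minimizes the summed forward and backward prediction-error power at each
    stage; reflection coefficients are guaranteed in (-1, 1), so the model
    is stable by construction.  A constant series has zero prediction error
    and is rejected.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if not n > 2 * order:
        raise ValueError(f"series length {n} must exceed 2*order={2 * order}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant series: zero prediction error")

    f = x.copy()
    b = x.copy()
    a = np.zeros(0)
    refl = np.zeros(order)
    energy = float(x @ x) / n
    for m in range(order):
        fp = f[1:]
        bp = b[:-1]
        den = float(fp @ fp + bp @ bp)
        if den <= 0:
            raise ValueError("prediction error vanished before reaching order")
        k = -2.0 * float(fp @ bp) / den
        refl[m] = k
        a = np.concatenate([a + k * a[::-1], [k]]) if a.size else np.array([k])
        f, b = fp + k * bp, bp + k * fp
        energy *= (1.0 - k * k)
    return ARModel(order, a, energy, refl)


def ar_psd(model: ARModel, fs: float, n_grid: int = DEFAULT_N_GRID,
           ) -> PSDEstimate:
    """AR spectrum on a uniform grid over [0, fs/2], with cumulative power."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if not model.is_stable():
        raise ValueError("unstable AR model")
    nfft = 2 * (n_grid - 1)
    poly = np.concatenate([[1.0], model.coefficients])
    a_f = np.fft.rfft(poly, nfft)
    density = model.noise_variance / (fs * np.abs(a_f) ** 2)
    freqs = np.linspace(0.0, fs / 2.0, n_grid)
    df = freqs[1] - freqs[0]
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * df)])
    return PSDEstimate(freqs, density, cum)


def band_power(psd: PSDEstimate, f_lo: float, f_hi: float) -> float:
    """Integrated power in the half-open band [f_lo, f_hi)."""
    if not 0 <= f_lo < f_hi <= psd.freqs[-1] + 1e-12:
        raise ValueError(f"invalid band [{f_lo}, {f_hi})")
    c_hi, c_lo = np.interp([f_hi, f_lo], psd.freqs, psd.cum_power)
    return float(c_hi - c_lo)


def sliding_windows(signal: SampledSignal, win: float = DEFAULT_WINDOW_S,
                    step: float = DEFAULT_STEP_S) -> list[AnalysisWindow]:
    """Windows of exactly win*fs samples, advanced by step*fs samples.

    Windows are views into the underlying series, not copies.
    """
    n_win = int(round(win * signal.fs))
    n_step = int(round(step * signal.fs))
    n = len(signal)
    if n < n_win:
        raise ValueError(f"signal ({n} samples) shorter than window ({n_win})")
    count = (n - n_win) // n_step + 1
    return [AnalysisWindow(signal.t0 + i * n_step / signal.fs, win,
                           signal.values[i * n_step:i * n_step + n_win])
            for i in range(count)]


def power_percentile_freq(psd: PSDEstimate, q: float) -> float:
    """Smallest grid frequency at which cumulative power reaches q * total."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    target = q * psd.total_power
    idx = int(np.searchsorted(psd.cum_power, target))
    return float(psd.freqs[min(idx, psd.freqs.size - 1)])


def window_psd(window: AnalysisWindow, fs: float,
               order: int = DEFAULT_AR_ORDER,
               n_grid: int = DEFAULT_N_GRID) -> PSDEstimate:
    """PSD of one analysis window: detrend, Burg fit, AR spectrum.

    A linear trend is removed first: Burg on non-zero-mean or trending data
    biases the low frequencies that carry all the structure of interest
    here (within a 3-minute window, residual slow baseline wander looks
    like a trend and would otherwise soak up model poles).
    """
    x = window.samples
    t = np.arange(x.size, dtype=float)
    t -= t.mean()
    slope = (t @ x) / (t @ t)
    x = x - x.mean() - slope * t
    return ar_psd(burg_fit(x, order), fs, n_grid)
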