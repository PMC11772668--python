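"""Synthetic coupled RR / pupil-diameter runs with planted spectral structure.

The generator emulates the physiological premise of the analysis: heart-rate
variability and pupil diameter are driven by the same sympathetic and
parasympathetic outflow.  Each autonomic drive (one per band, LF and HF) is
a frequency-wandering oscillation with a slowly fluctuating amplitude; both
the wander trajectory and the amplitude envelope are shared between the two
signals, while the frequency range in which the drive is expressed differs:

* the RR series is modulated inside the canonical HRV bands
  (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz);
* the pupil signal expresses the same drives inside *planted* bands (by
  default LF [0.06, 0.29) Hz, HF [0.29, 0.49) Hz), superposed on a slow
  baseline drift and a 1/f^beta background with its own independent
  amplitude envelope, with blink stretches flagged invalid and isolated
  spike outliers left valid for the outlier filter to find.

Because trajectory and envelope are shared, windowed band powers of the two
signals co-fluctuate — coherently even at the sub-band level — which is
exactly the structure the band sweep downstream is designed to detect.
Planted band limits are recorded as ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import RRSeries, SampledSignal

RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0

# Envelope of the shared autonomic drive: slow amplitude fluctuations.
# The timescale must sit below the 180 s analysis window so that windowed
# band powers vary across a run, yet slow enough that the sidebands it
# convolves onto a carrier stay well under one band-grid step (support
# <= 1/60 Hz).  The depth sets how strongly band power co-fluctuates
# between the two signals (moderate coupling).  The 1/f background carries
# its own independent envelope: physiological noise is heteroscedastic,
# and a background whose band power never fluctuates would make planted
# band edges unidentifiable in principle.
ENVELOPE_TIMESCALE_S = 60.0
ENVELOPE_DEPTH = 0.5
# Measurement and residual-artifact noise in pupillometry is itself
# heteroscedastic (gaze position, partial occlusions, setup drift), so the
# background carries an amplitude envelope of the same depth.
BACKGROUND_ENVELOPE_DEPTH = 0.5


@dataclass(frozen=True)
class ModulatorSpec:
    """Band-limited stochastic oscillator: center, width and gain.

    ``gain`` is dimensionless for RR modulation (fractional RR change per
    unit modulator) and in diameter units for the pupil.
    """

    center_freq: float
    bandwidth: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.center_freq > 0:
            raise ValueError("center_freq must be > 0")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")
        if self.center_freq - self.bandwidth / 2 < 0:
            raise ValueError("band lower edge must be >= 0")

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2,
                self.center_freq + self.bandwidth / 2)


def _spec_for_band(lo: float, hi: float, gain: float) -> ModulatorSpec:
    return ModulatorSpec((lo + hi) / 2, hi - lo, gain)


@dataclass
class SyntheticRunConfig:
    """One run of the virtual experiment.

    Defaults reproduce the recording conditions the pipeline targets: a
    600 s task, RR around 850 ms modulated in the canonical HRV bands, a
    500 Hz pupil stream with planted LF/HF bands, 1/f background, ~15
    blinks/min of ~200 ms and occasional spike outliers.
    """

    duration: float = 600.0
    rr_mean: float = 850.0
    rr_lf: ModulatorSpec = field(
        default_factory=lambda: _spec_for_band(0.04, 0.15, 0.06))
    rr_hf: ModulatorSpec = field(
        default_factory=lambda: _spec_for_band(0.15, 0.40, 0.04))
    pupil_lf: ModulatorSpec = field(
        default_factory=lambda: _spec_for_band(0.06, 0.29, 0.08))
    pupil_hf: ModulatorSpec = field(
        default_factory=lambda: _spec_for_band(0.29, 0.49, 0.05))
    pupil_baseline: float = 3.5
    drift_sd: float = 0.30          # slow baseline wander, < 0.01 Hz
    pink_noise_sd: float = 0.10
    pink_exponent: float = 1.0
    blink_rate: float = 15.0            # events / min
    blink_duration_mean: float = 200.0  # ms
    spike_outlier_rate: float = 2.0     # events / min
    pupil_fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 360.0:
            raise ValueError("duration must be >= 360 s (two analysis windows)")
        if self.pupil_fs < 16.0:
            raise ValueError("pupil_fs must be >= 16 Hz")
        for name in ("blink_rate", "blink_duration_mean", "spike_outlier_rate",
                     "pink_noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: the pupil LF/HF bands and the shared envelopes."""

    planted_lf_band: tuple[float, float]
    planted_hf_band: tuple[float, float]
    realizations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lf, hf = self.planted_lf_band, self.planted_hf_band
        if not (0 <= lf[0] < lf[1] <= hf[0] < hf[1] <= 1.0):
            raise ValueError("planted bands must be disjoint within [0, 1] Hz")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# timescale of the oscillator's frequency wander within its band
WANDER_TIMESCALE_S = 60.0


def _slow_gaussian(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian with spectral support (0, 1/wander-timescale]."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs > 0) & (freqs <= 1.0 / WANDER_TIMESCALE_S)
    if not band.any():
        raise ValueError("series too short for the wander timescale")
    coef = np.zeros(freqs.size, dtype=complex)
    coef[band] = rng.standard_normal(band.sum()) \
        + 1j * rng.standard_normal(band.sum())
    s = np.fft.irfft(coef, n)
    return (s - s.mean()) / (s.std() or 1.0)


def make_band_limited_modulator(spec: ModulatorSpec, duration: float,
                                fs: float, seed: int) -> SampledSignal:
    """Zero-mean unit-variance oscillation confined to the band.

    Modeled as a frequency-wandering tone: the instantaneous frequency
    follows a slow trajectory with uniform marginal over
    [center - bw/2, center + bw/2), so the long-run spectrum fills the
    band and is, up to slow-FM sidebands of width ~1/60 Hz, zero outside
    it.  This mirrors how autonomic rhythms behave physiologically —
    Mayer waves and respiration-coupled oscillations wander in frequency
    rather than humming at a fixed line — and keeps the planted
    ground-truth band edges sharp; a damped resonator driven by white
    noise would smear Lorentzian tails well into the neighboring bands.

    The wander trajectory depends only on ``seed`` and is mapped affinely
    onto the band, so two modulators built from the same seed but
    different bands are one underlying oscillation expressed in two
    frequency ranges with coherent time structure — the construction by
    which a single autonomic drive appears in the canonical HRV band of
    the RR series and in a shifted planted band of the pupil at once.
    Deterministic for a fixed seed.
    """
    from scipy.special import ndtr

    f_lo, f_hi = spec.band
    if not fs > 2 * f_hi:
        raise ValueError(
            f"fs={fs} violates Nyquist for band upper edge {f_hi} Hz")
    n = int(round(duration * fs))
    if n < 8:
        raise ValueError("duration too short")
    rng = _rng(seed)
    u = ndtr(_slow_gaussian(n, fs, rng))
    freq = f_lo + (f_hi - f_lo) * u
    phase = rng.uniform(0.0, 2.0 * np.pi) + 2.0 * np.pi * np.cumsum(freq) / fs
    x = np.cos(phase)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate modulator realization")
    return SampledSignal(x / sd, fs=fs)


def _slow_envelope(duration: float, fs: float, seed: int, *key: int,
                   depth: float = ENVELOPE_DEPTH) -> np.ndarray:
    """Slow amplitude envelope, unit mean square.

    1 + depth * s with s a strictly band-limited slow noise (support
    (0, 1/timescale] Hz).  The modulation is kept exactly linear in s — no
    floor or clipping — so the modulated component's spectrum is confined
    to its carrier band widened by at most 1/timescale Hz; any static
    nonlinearity would scatter harmonics of s across the spectrum and blur
    the planted band edges.  The envelope may rarely dip below zero
    (|s| > 1/depth, under 1% of samples), which amounts to a momentary
    phase slip of the carrier rather than an artifact.
    """
    n = int(round(duration * fs))
    cutoff = 1.0 / ENVELOPE_TIMESCALE_S
    rng = _rng(seed, *key)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs > 0) & (freqs <= cutoff)
    coef = np.zeros(freqs.size, dtype=complex)
    coef[band] = rng.standard_normal(band.sum()) + 1j * rng.standard_normal(band.sum())
    s = np.fft.irfft(coef, n)
    s = (s - s.mean()) / (s.std() or 1.0)
    env = 1.0 + depth * s
    return env / np.sqrt(np.mean(env ** 2))


_MOD_FS = 8.0  # internal rate for modulators/envelopes; all bands are < 1 Hz

# spawn-key layout for the per-run seed; one carrier per band, shared
# between the RR and pupil expressions of that band's autonomic drive
_KEY_CARRIER_LF, _KEY_CARRIER_HF = 1, 2
_KEY_PINK, _KEY_BLINK, _KEY_SPIKE, _KEY_DRIFT = 5, 6, 7, 8
_KEY_ENV_LF, _KEY_ENV_HF, _KEY_ENV_BG = 101, 102, 103

DRIFT_MAX_HZ = 0.01


def _baseline_drift(duration: float, fs: float, sd: float, seed: int) -> np.ndarray:
    """Slow pupil baseline wander: 1/f-weighted noise below 0.01 Hz.

    Real pupil diameter drifts by a few tenths of a millimeter over minutes
    (the preprocessing's very-low-frequency high-pass exists to strip it);
    without it the run's value distribution is unrealistically tight and the
    boxplot fences clip genuine oscillation peaks.
    """
    n = int(round(duration * fs))
    rng = _rng(seed, _KEY_DRIFT)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs > 0) & (freqs <= DRIFT_MAX_HZ)
    coef = np.zeros(freqs.size, dtype=complex)
    amp = freqs[band] ** -0.5
    coef[band] = amp * (rng.standard_normal(band.sum())
                        + 1j * rng.standard_normal(band.sum()))
    x = np.fft.irfft(coef, n)
    x = x - x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_components(cfg: SyntheticRunConfig):
    """Shared envelopes and the four standardized band components at 8 Hz.

    Each autonomic drive (LF, HF) is one carrier seed plus one envelope:
    the RR and pupil components of a band are frequency-warped expressions
    of the same underlying oscillation, amplitude-modulated by the same
    slow envelope.
    """
    d, s = cfg.duration, cfg.seed
    env_lf = _slow_envelope(d, _MOD_FS, s, _KEY_ENV_LF)
    env_hf = _slow_envelope(d, _MOD_FS, s, _KEY_ENV_HF)
    seed_lf = int(_rng(s, _KEY_CARRIER_LF).integers(2 ** 31))
    seed_hf = int(_rng(s, _KEY_CARRIER_HF).integers(2 ** 31))

    def component(spec: ModulatorSpec, carrier_seed: int,
                  env: np.ndarray) -> np.ndarray:
        carrier = make_band_limited_modulator(spec, d, _MOD_FS, carrier_seed)
        x = env * carrier.values
        return (x - x.mean()) / x.std()

    comps = {
        "rr_lf": component(cfg.rr_lf, seed_lf, env_lf),
        "rr_hf": component(cfg.rr_hf, seed_hf, env_hf),
        "pupil_lf": component(cfg.pupil_lf, seed_lf, env_lf),
        "pupil_hf": component(cfg.pupil_hf, seed_hf, env_hf),
    }
    return comps, {"env_lf": env_lf, "env_hf": env_hf}


def synthesize_rr(cfg: SyntheticRunConfig) -> RRSeries:
    """Beat times by integrating the instantaneous RR trajectory.

    RR(t) = rr_mean * (1 + g_lf*s_lf(t) + g_hf*s_hf(t)); a beat is placed,
    then the clock advances by the local RR.  Configurations whose RR
    trajectory leaves [300, 2000] ms are rejected.
    """
    comps, _ = _band_components(cfg)
    t_grid = np.arange(comps["rr_lf"].size) / _MOD_FS
    rr_inst = cfg.rr_mean * (1.0
                             + cfg.rr_lf.gain * comps["rr_lf"]
                             + cfg.rr_hf.gain * comps["rr_hf"])
    if rr_inst.min() < RR_MIN_MS or rr_inst.max() > RR_MAX_MS:
        raise ValueError(
            f"modulation drives RR outside [{RR_MIN_MS}, {RR_MAX_MS}] ms "
            f"(realized range [{rr_inst.min():.0f}, {rr_inst.max():.0f}])")
    beats = [0.0]
    t = 0.0
    while True:
        rr_t = np.interp(t, t_grid, rr_inst) / 1000.0
        t = t + rr_t
        if t > cfg.duration:
            break
        beats.append(t)
    beat_times = np.asarray(beats)
    intervals = np.diff(beat_times) * 1000.0
    return RRSeries(beat_times, intervals)


def synthesize_pupil(cfg: SyntheticRunConfig) -> SampledSignal:
    """Pupil-diameter stream at ``cfg.pupil_fs`` with a validity mask.

    diameter = baseline + planted-band modulators + 1/f^beta noise; blink
    stretches are zeroed and flagged invalid; spike outliers are isolated
    large deviations left valid (the outlier filter's job downstream).
    """
    comps, _ = _band_components(cfg)
    n = int(round(cfg.duration * cfg.pupil_fs))
    t = np.arange(n) / cfg.pupil_fs
    t8 = np.arange(comps["pupil_lf"].size) / _MOD_FS

    x = np.full(n, cfg.pupil_baseline)
    if cfg.drift_sd > 0:
        x += _baseline_drift(cfg.duration, cfg.pupil_fs, cfg.drift_sd, cfg.seed)
    x += cfg.pupil_lf.gain * np.interp(t, t8, comps["pupil_lf"])
    x += cfg.pupil_hf.gain * np.interp(t, t8, comps["pupil_hf"])
    if cfg.pink_noise_sd > 0:
        background = pink_noise(n, cfg.pink_exponent, cfg.pink_noise_sd,
                                _rng(cfg.seed, _KEY_PINK))
        env_bg = _slow_envelope(cfg.duration, cfg.pupil_fs, cfg.seed,
                                _KEY_ENV_BG,
                                depth=BACKGROUND_ENVELOPE_DEPTH)[:n]
        x += background * env_bg

    mask = np.ones(n, dtype=bool)
    rng_b = _rng(cfg.seed, _KEY_BLINK)
    n_blinks = rng_b.poisson(cfg.blink_rate * cfg.duration / 60.0)
    if n_blinks:
        onsets = np.sort(rng_b.uniform(0, cfg.duration, n_blinks))
        mu = np.log(cfg.blink_duration_mean) - 0.3 ** 2 / 2
        durs = rng_b.lognormal(mu, 0.3, n_blinks) / 1000.0
        for on, du in zip(onsets, durs):
            i0 = int(np.floor(on * cfg.pupil_fs))
            i1 = min(int(np.ceil((on + du) * cfg.pupil_fs)), n)
            mask[i0:i1] = False
            x[i0:i1] = 0.0  # tracker reports no pupil during a blink

    rng_s = _rng(cfg.seed, _KEY_SPIKE)
    n_spikes = rng_s.poisson(cfg.spike_outlier_rate * cfg.duration / 60.0)
    if n_spikes:
        idx = rng_s.integers(0, n, n_spikes)
        scale = cfg.pink_noise_sd if cfg.pink_noise_sd > 0 else 0.2 * cfg.pupil_baseline
        amp = rng_s.uniform(6.0, 10.0, n_spikes) * scale
        x[idx] += np.where(rng_s.random(n_spikes) < 0.5, -amp, amp)

    return SampledSignal(x, fs=cfg.pupil_fs, valid_mask=mask)


def pink_noise(n: int, beta: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^beta noise via spectral shaping of white noise, scaled to ``sd``."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x = x - x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


@dataclass
class SyntheticRun:
    subject: int
    run: int
    config: SyntheticRunConfig
    rr: RRSeries
    pupil: SampledSignal


def run_seed(master_seed: int, subject: int, run: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(subject, run))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_subjects: int, runs_per_subject: int,
                     cfg_template: SyntheticRunConfig | None = None,
                     seed: int = 0) -> tuple[list[SyntheticRun], GroundTruth]:
    """Independent seeded runs for a cohort, plus the planted ground truth."""
    if n_subjects < 1 or runs_per_subject < 1:
        raise ValueError("counts must be >= 1")
    template = cfg_template or SyntheticRunConfig()
    runs = []
    for s in range(n_subjects):
        for r in range(runs_per_subject):
            cfg = dataclasses.replace(template, seed=run_seed(seed, s, r))
            runs.append(SyntheticRun(s, r, cfg,
                                     synthesize_rr(cfg),
                                     synthesize_pupil(cfg)))
    truth = GroundTruth(template.pupil_lf.band, template.pupil_hf.band,
                        realizations={"template": template, "master_seed": seed})
    return runs, truth


# ---------------------------------------------------------------------------
# plain-text export

def write_run(run: SyntheticRun, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"sub{run.subject:02d}_run{run.run:02d}"
    beat_path = out / f"{tag}_beats.csv"
    pupil_path = out / f"{tag}_pupil.csv"
    pd.DataFrame({"beat_time_s": run.rr.beat_times}).to_csv(beat_path, index=False)
    pd.DataFrame({
        "time_s": run.pupil.times,
        "diameter": run.pupil.values,
        "valid": run.pupil.valid_mask.astype(int),
    }).to_csv(pupil_path, index=False, float_format="%.6f")
    return {"subject": run.subject, "run": run.run,
            "beats": beat_path.name, "pupil": pupil_path.name}


def write_dataset(runs: list[SyntheticRun], truth: GroundTruth,
                  out_dir: str | Path) -> Path:
    """Write every run as CSV plus a sidecar JSON with config + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = [write_run(r, out) for r in runs]
    template = truth.realizations.get("template")
    sidecar = {
        "planted_lf_band": list(truth.planted_lf_band),
        "planted_hf_band": list(truth.planted_hf_band),
        "master_seed": truth.realizations.get("master_seed"),
        "config": dataclasses.asdict(template) if template else None,
        "runs": entries,
    }
    path = out / "dataset.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path
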