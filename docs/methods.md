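# Methods

This note documents the models, algorithms and design choices behind
`pupilbands`: a pipeline that searches for the pupillography frequency-band
limits (LF, HF) whose spectral power features correlate maximally with the
canonical heart-rate-variability (HRV) features.

## The question and the approach

HRV frequency features are well standardized: power in LF (0.04–0.15 Hz)
and HF (0.15–0.40 Hz) and their ratio index the sympathovagal balance of
the autonomic nervous system. Pupil diameter is driven by the same
sympathetic/parasympathetic outflow, but the literature disagrees on which
pupil frequency bands carry that information. The pipeline treats HRV as
ground truth and sweeps *all* non-overlapping (LF, HF) band pairs on a
regular frequency grid over 0–1 Hz, scoring each combination by how well
its windowed pupil band powers track the canonical HRV features across a
cohort of recordings.

The full chain is: preprocessing of both signals to clean 8 Hz series →
Burg autoregressive spectra on 180 s sliding windows (1 s step) → band
powers for every combination (LF, HF, LF/HF) → per-run Pearson (or
Spearman) correlations against the HRV features → Fisher-Z aggregation
across runs → cluster-based permutation correction over the combination
lattice → ranking by the geometric mean of the three group correlations.

## Synthetic cohort generator

Real recordings are not required anywhere: the `synthetic` module
generates coupled RR/pupil runs with a *planted* pupil band structure, so
every downstream stage can be tested against known ground truth.

**Autonomic drives.** Each band (LF, HF) has one underlying drive,
realized as a frequency-wandering tone: the instantaneous frequency
follows a slow trajectory (spectral support ≤ 1/60 Hz) with uniform
marginal over the band, and the amplitude is modulated by a slow envelope
`1 + 0.5·s(t)` with `s` strictly band-limited below 1/60 Hz. Both the
wander trajectory and the envelope are *shared* between the RR and pupil
expressions of a drive; only the frequency range differs (RR: canonical
HRV bands; pupil: planted bands, by default LF [0.06, 0.29) Hz and HF
[0.29, 0.49) Hz). Physiologically this mirrors how Mayer waves and
respiration-coupled oscillations wander in frequency rather than humming
at fixed lines; statistically it makes windowed band powers — including
sub-band powers — co-fluctuate coherently between the two signals, which
is the structure the sweep detects. The modulation is kept exactly linear
in `s` (no clipping): any static nonlinearity scatters harmonics of the
envelope across the spectrum and blurs the planted band edges.

Two properties of this construction matter for interpretation:

* spectral support is sharp at the band edges (up to slow-FM sidebands of
  ~1/60 Hz), unlike a damped-resonator model whose Lorentzian tails would
  leak the drive into neighboring bands and make the planted limits
  unrecoverable in principle;
* the amplitude envelope's timescale (60 s) sits below the 180 s analysis
  window, so band powers genuinely vary within a 600 s run — but window
  smoothing still leaves only a handful of independent power fluctuations
  per run, which is the dominant noise source at cohort level.

**RR series.** Instantaneous RR(t) = rr_mean·(1 + g_lf·s_lf + g_hf·s_hf)
with defaults rr_mean = 850 ms (a typical young adult under cognitive
load; the ~1.2 Hz beat rate comfortably Nyquist-samples the 0.4 Hz HF
drive), g_lf = 0.06, g_hf = 0.04. Beats are placed by direct integration
(each beat advances the clock by the local RR); configurations whose RR
leaves [300, 2000] ms are rejected.

**Pupil stream.** diameter = 3.5 mm baseline + slow drift (1/f-weighted
noise below 0.01 Hz, sd 0.3 mm — real pupil baselines wander over
minutes, which is also why the preprocessing includes a very-low-frequency
high-pass) + planted drives (gains 0.08 / 0.05 mm) + 1/f background
(sd 0.10 mm) carrying its own independent slow amplitude envelope
(measurement and residual-artifact noise is heteroscedastic). Blinks are a
homogeneous Poisson process (15/min) with log-normal durations (mean
200 ms, σ = 0.3 log-units), flagged invalid with the sample values zeroed
as an eye tracker would; spike outliers (2/min) are isolated large
deviations left *valid* for the boxplot stage to find. Native rate 500 Hz.

**What the generator does not emulate.** Luminance responses, gaze-angle
artifacts, left/right-eye differences, ectopic beats, and any
nonstationarity of the drives beyond amplitude/frequency wander. Passing
tests therefore show that the pipeline recovers band structure under
realistic artifact load and noise — not that it would survive, e.g.,
luminance confounds in real recordings.

## Preprocessing

**HRV.** Beat times → RR intervals (ms, stamped at the terminating beat)
→ Tukey boxplot outlier removal (fences Q1 − 1.5·IQR, Q3 + 1.5·IQR; a
zero-IQR series flags nothing) → linear interpolation onto a uniform 8 Hz
grid → zero-phase 4th-order Butterworth low-pass at 1 Hz.

**Pupil.** Invalid samples are extended by a 100 ms margin on each side
(the lid partially occludes the pupil while moving); boxplot outliers
among the remaining valid samples are flagged; leading/trailing invalid
stretches are trimmed (extrapolated cubic tails are unreliable); interior
gaps are filled with a shape-preserving piecewise cubic (PCHIP); the
signal is low-passed at 3.2 Hz (8th-order Butterworth, zero-phase) and
resampled to 8 Hz; invalid *stretches* mapped to the 8 Hz grid are then
repaired by iterative SSA; finally a zero-phase 2nd-order Butterworth
high-pass at 4×10⁻⁴ Hz removes slow nonstationarity (a higher order is
numerically fragile at that cutoff; the filter is applied with full-length
reflection padding because its transient exceeds the record length).

**Iterative SSA.** The series (centered — a DC baseline would otherwise
own the leading singular triple) is embedded in an L×K Hankel matrix with
L = 30 s × 8 Hz = 240; the factorization runs on the L×L lag-covariance
matrix, and anti-diagonal averaging of each rank-one term is computed as a
full convolution, so no trajectory matrix is materialized. The series is
repeatedly reconstructed from the leading components (the smallest set
explaining 90% of squared singular values) and only flagged samples are
overwritten, until the largest relative change at flagged positions drops
below 10⁻³ or 20 iterations. Non-convergence is reported, not raised.

Only blink stretches are SSA-flagged. Isolated boxplot outliers are
single samples at 500 Hz: after cubic filling and the anti-alias low-pass
they are already repaired, and replacing them with a low-rank
reconstruction would inject signal-proportional broadband error (measured
as an order-of-magnitude increase in out-of-band power).

A caveat worth knowing: on the generator's strongly amplitude-modulated
(hence leptokurtic) signals, the Tukey fences clip 2–6% of genuine
oscillation peaks. That is faithful behavior of the boxplot stage, and the
slow baseline drift keeps it modest, but it means the chain is exactly
transparent only for signals whose values stay inside the fences.

## Spectral estimation

Each 180 s window (1440 samples) is linearly detrended (Burg on trending
data biases the low frequencies; within 3 minutes the residual baseline
drift looks like a trend) and fitted with Burg's method: AR coefficients
minimizing summed forward/backward prediction error via the
reflection-coefficient recursion, stable by construction. The default
order is 32 — enough poles for a drift remnant, two oscillatory bands and
a 1/f background; fewer poles smear each band's resonance skirt across
its neighbors and bias band powers. The order is a configuration knob and
is recorded in outputs.

The density is the two-sided AR spectrum evaluated on [0, fs/2]:
`S(f) = σ²/(fs·|A(e^{-i2πf/fs})|²)` on a 2049-point grid (step ≈ 0.002 Hz,
five times finer than the 0.01 Hz band grid), so white noise integrates to
σ²/2. The convention scales every band equally and cancels in all ratios
and correlations. Band power over [lo, hi) is a difference of the
trapezoid-cumulative power, making adjacent bands partition power exactly;
the sweep stores each window's cumulative power at the grid edges once and
reconstructs any combination's bands as column differences.

## Sweep and statistics

Combinations are all grid-aligned triples 0 ≤ lf_lo < split < hf_hi ≤ 1 Hz
(166,650 at the default 0.01 Hz step). Per run, each combination's
LF/HF/ratio window series is correlated feature-to-feature against the HRV
series; p-values use the t transform of r with n − 2 degrees of freedom.
The 180 s/1 s sliding windows make consecutive feature values strongly
autocorrelated, so per-run p-values are anti-conservative; this is a
property of the windowing design itself and is deliberately not corrected
— group-level inference rests on the permutation test instead. Windows
with an undefined ratio (zero HF power) are dropped pairwise.

Across runs, correlations are averaged on the Fisher-Z scale with weights
nᵢ − 3 (inverse variance for independent samples; runs differ in window
count) and mapped back with tanh. Family-wise error over the lattice is
controlled by cluster-based permutation: combinations are adjacent iff
they differ by one grid step in exactly one limit; supra-threshold
combinations (|group z| above the two-sided α = 0.05 quantile) form
connected clusters whose mass is the summed |z|; the null of the maximum
mass is built from random sign flips of each run's z vector (exchangeable
under zero correlation); every member of a cluster inherits the cluster's
corrected p, and sub-threshold combinations get p = 1.

Combinations are scored by the geometric mean of the three group
correlations, defined only when all three are positive — a combination
whose features do not all correlate in the same direction cannot serve as
an HRV surrogate and is left unranked. Ties are broken deterministically
(descending r_ratio, r_lf, r_hf, then lexicographic limits).

## Numerical and degenerate-input choices

* Boxplot filter requires ≥ 4 values and errors if it would remove all.
* `fisher_z` rejects |r| ≥ 1; group tables clip |r| at 1 − 10⁻¹².
* Correlations of zero-variance series are recorded as missing.
* The permutation count must be ≥ 100; corrected p uses the
  (1 + exceedances)/(B + 1) estimator, so p is never 0.
* All randomness flows through `numpy` `SeedSequence` spawning, keyed per
  run and per noise source; identical seeds give byte-identical outputs.

## Scale of the shipped experiments

The recovery experiment used by the tests and the acceptance script runs
10 subjects × 2 runs of 600 s on a 0.02 Hz sweep grid with 300
permutations (≈ half a minute on one core); the study-scale 0.01 Hz grid
with thousands of permutations is supported by the same code paths. At
this cohort size the top-ranked HF upper limit still wanders by one or two
grid steps around the planted value across cohort realizations — window
smoothing leaves only ~3 independent power fluctuations per run, so the
outer-edge contrast is shallow — while the LF lower limit and the
LF/HF split recover exactly on every cohort tried.

## Known limitations

* Per-run p-values inherit the sliding-window autocorrelation (above).
* The geometric mean's positivity requirement discards combinations with
  mixed-sign correlations rather than modeling direction explicitly.
* The cluster statistic (summed |z|) weights broad weak clusters and
  narrow strong ones equally per unit mass; other mass definitions exist.
* The generator's coupling is strong enough that group correlations reach
  ~0.9 on clean synthetic cohorts; empirical pupil–HRV coupling is far
  weaker, so real-data correlations will be much smaller even if the band
  structure is recovered.
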