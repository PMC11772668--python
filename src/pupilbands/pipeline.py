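"""End-to-end orchestration: manifest -> preprocessing -> sweep -> ranking.

The pipeline consumes a manifest of per-run beat and pupil CSV files,
cleans both signals, sweeps LF/HF band combinations on the configured
grid, aggregates across the cohort with cluster-permutation correction,
and writes the group table, the top-k ranking and the literature-band
comparison as CSV, plus a provenance JSON carrying the configuration and
its hash.  A secondary analysis contrasts feature values between task
conditions (e.g. low vs high code complexity) with a Mann-Whitney U test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import group as grp
from . import hrv as hrvmod
from . import pupil as pupmod
from . import sweep as swp
from .core import SampledSignal
from .spectral import DEFAULT_AR_ORDER, DEFAULT_N_GRID, sliding_windows, window_psd
from .ssa import SSAConfig

log = logging.getLogger("pupilbands")


@dataclass
class RunManifest:
    """One run's inputs: file paths, optional task span and condition labels.

    ``condition_segments`` is a list of ``[start_s, end_s, label]`` triples
    used only by the condition-contrast analysis.
    """

    subject: int
    run: int
    beats: str
    pupil: str
    task_span: tuple[float, float] | None = None
    condition_segments: list | None = None


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, validated on construction."""

    fs: float = 8.0
    hrv_lowpass_hz: float = 1.0
    fence_k: float = 1.5
    margin_ms: float = 100.0
    highpass_hz: float = 4e-4
    ssa_window_s: float = 30.0
    ssa_max_iter: int = 20
    ssa_tol: float = 1e-3
    ar_order: int = DEFAULT_AR_ORDER
    n_grid: int = DEFAULT_N_GRID
    window_s: float = 180.0
    step_s: float = 1.0
    grid_step: float = 0.01
    f_max: float = 1.0
    method: str = "pearson"
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.window_s * self.fs < 2 * self.ar_order + 1:
            raise ValueError("window too short for the AR order")
        swp.grid_edges(self.grid_step, self.f_max)  # validates divisibility

    def pupil_config(self) -> pupmod.PupilPreprocessConfig:
        return pupmod.PupilPreprocessConfig(
            margin_ms=self.margin_ms, fence_k=self.fence_k,
            target_fs=self.fs,
            ssa=SSAConfig(window_len=int(round(self.ssa_window_s * self.fs)),
                          max_iter=self.ssa_max_iter, tol=self.ssa_tol),
            highpass_hz=self.highpass_hz)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_manifest(path: str | Path) -> list[RunManifest]:
    entries = json.loads(Path(path).read_text())
    base = Path(path).parent
    out = []
    for e in entries["runs"] if isinstance(entries, dict) else entries:
        out.append(RunManifest(
            subject=int(e["subject"]), run=int(e["run"]),
            beats=str(base / e["beats"]), pupil=str(base / e["pupil"]),
            task_span=tuple(e["task_span"]) if e.get("task_span") else None,
            condition_segments=e.get("condition_segments")))
    return out


def _crop_to_span(sig: SampledSignal, span) -> SampledSignal:
    if span is None:
        return sig
    t0, t1 = span
    i0 = max(int(np.ceil((t0 - sig.t0) * sig.fs)), 0)
    i1 = min(int(np.floor((t1 - sig.t0) * sig.fs)) + 1, len(sig))
    if i1 - i0 < 2:
        raise ValueError("task span leaves no samples")
    return SampledSignal(sig.values[i0:i1], sig.fs, sig.t0 + i0 / sig.fs,
                         sig.valid_mask[i0:i1])


def process_run(hrv_rr, pupil_sig: SampledSignal, config: PipelineConfig,
                edges, combo_idx) -> tuple[swp.RunCorrelations, dict]:
    """One run through the full per-run chain."""
    hrv_sig, hrv_report = hrvmod.preprocess_rr(
        hrv_rr, fs=config.fs, lowpass_hz=config.hrv_lowpass_hz,
        fence_k=config.fence_k)
    pup_sig, pup_report = pupmod.preprocess_pupil(pupil_sig,
                                                  config.pupil_config())
    ha, pa = swp.align_signals(hrv_sig, pup_sig)
    hrv_feats = swp.hrv_feature_series(ha, config.window_s, config.step_s,
                                       config.ar_order, config.n_grid)
    cum, starts = swp.pupil_cumpower_matrix(pa, edges, config.window_s,
                                            config.step_s, config.ar_order,
                                            config.n_grid)
    rc = swp.per_run_correlation(cum, edges, hrv_feats, combo_idx,
                                 method=config.method)
    report = {"hrv": hrv_report, "pupil": pup_report,
              "n_windows": int(rc.n)}
    return rc, report


def run_pipeline(manifest: list[RunManifest], config: PipelineConfig,
                 out_dir: str | Path) -> dict:
    """Execute the whole analysis and write all result tables.

    Runs failing preprocessing are skipped with a logged reason; the
    pipeline errors out only if fewer than 2 runs survive.
    """
    if len(manifest) < 2:
        raise ValueError("pipeline needs at least 2 runs")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = swp.grid_edges(config.grid_step, config.f_max)
    combo_idx = swp.combination_indices(config.grid_step, config.f_max)

    results, reports = [], {}
    for m in manifest:
        tag = f"sub{m.subject:02d}_run{m.run:02d}"
        try:
            rr = hrvmod.read_beats_csv(m.beats)
            pup = pupmod.read_pupil_csv(m.pupil)
            pup = _crop_to_span(pup, m.task_span)
            rc, report = process_run(rr, pup, config, edges, combo_idx)
        except (ValueError, OSError, KeyError) as exc:
            log.warning("skipping %s: %s", tag, exc)
            reports[tag] = {"skipped": str(exc)}
            continue
        results.append(rc)
        reports[tag] = report
    if len(results) < 2:
        raise ValueError(f"only {len(results)} runs survived preprocessing")

    rng = np.random.default_rng(config.seed)
    cluster_cfg = grp.ClusterCorrectionConfig(alpha=config.cluster_alpha,
                                              n_permutations=config.n_permutations)
    table = grp.group_table(results, cluster_cfg, rng)
    top = grp.rank_top(table, 10)
    table.insert(0, "config_hash", config.config_hash)
    top.insert(0, "config_hash", config.config_hash)
    table.to_csv(out / "group_table.csv", index=False)
    top.to_csv(out / "top10.csv", index=False)

    lit = literature_comparison(results, edges)
    lit.insert(0, "config_hash", config.config_hash)
    lit.to_csv(out / "literature_combos.csv", index=False)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "n_runs_in": len(manifest),
        "n_runs_used": len(results),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "cleaning_reports.json").write_text(json.dumps(reports, indent=2,
                                                          default=str))
    return {"table": table, "top": top, "literature": lit,
            "reports": reports, "out_dir": str(out)}


def literature_comparison(results: list[swp.RunCorrelations], edges,
                          combos=grp.LITERATURE_COMBOS) -> pd.DataFrame:
    """The literature band combinations' group metrics on this cohort.

    Combinations whose edges are on the sweep grid are looked up exactly;
    for the others the nearest grid-aligned combination is reported with
    its rounded limits (flagged in the ``snapped`` column).
    """
    edges = np.asarray(edges)
    i, j, k = results[0].combo_idx
    rows = []
    for combo in combos:
        snapped = [float(edges[np.argmin(np.abs(edges - v))]) for v in combo]
        pos = np.nonzero((edges[i] == snapped[0]) & (edges[j] == snapped[1])
                         & (edges[k] == snapped[2]))[0]
        if pos.size == 0:
            raise ValueError(f"combination {combo} not on the sweep lattice")
        p = int(pos[0])
        row = {"lf_lo": combo[0], "split": combo[1], "hf_hi": combo[2],
               "snapped": bool(tuple(snapped) != tuple(combo))}
        for feat in grp.FEATURES:
            rs = np.array([getattr(r, f"r_{feat}")[p] for r in results])
            ns = np.array([r.n_ratio if feat == "ratio" else r.n
                           for r in results])
            ps = np.array([getattr(r, f"p_{feat}")[p] for r in results])
            r_g, p_g = grp.aggregate_runs(rs, ns)
            row[f"r_{feat}"] = r_g
            row[f"p_{feat}_uncorrected"] = p_g
            row[f"pct_{feat}"] = grp.pct_significant_runs(ps)
        row["geo_mean"] = grp.geometric_mean_score(
            row["r_lf"], row["r_hf"], row["r_ratio"])
        rows.append(row)
    return pd.DataFrame(rows)


def condition_contrast(values, labels) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U between two condition groups.

    Returns ``(median_low, median_high, p)`` where "low"/"high" are the two
    label values in sorted order.  Both groups must be non-empty.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {names}")
    a = values[labels == names[0]]
    b = values[labels == names[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both condition groups must be non-empty")
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(p)


def label_windows_by_majority(window_starts, window_s, segments) -> np.ndarray:
    """Condition label per window by majority time overlap.

    ``segments`` are ``[start, end, label]``; windows with no overlapping
    labeled time get the empty string.
    """
    labels = []
    for w0 in np.asarray(window_starts, dtype=float):
        w1 = w0 + window_s
        overlap: dict[str, float] = {}
        for s0, s1, lab in segments:
            o = min(w1, s1) - max(w0, s0)
            if o > 0:
                overlap[lab] = overlap.get(lab, 0.0) + o
        labels.append(max(overlap, key=overlap.get) if overlap else "")
    return np.asarray(labels)


def cumulative_power_report(psds, percentiles=(0.90, 0.95, 0.975, 0.99)
                            ) -> dict:
    """Average normalized PSD across windows and its percentile crossings.

    Mirrors the diagnostic used to justify restricting the band sweep to
    0-1 Hz: with a 1/f-type spectrum nearly all pupil power sits well below
    the Nyquist frequency.
    """
    psds = list(psds)
    if not psds:
        raise ValueError("need at least one PSD")
    freqs = psds[0].freqs
    avg = np.zeros_like(freqs)
    for ps in psds:
        total = ps.total_power
        if total <= 0:
            continue
        avg += ps.density / total
    avg /= len(psds)
    df = freqs[1] - freqs[0]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (avg[1:] + avg[:-1]) * df)])
    cum = cum / cum[-1]
    crossings = {q: float(freqs[int(np.searchsorted(cum, q))])
                 for q in percentiles}
    return {"freqs": freqs, "avg_density": avg, "cum_fraction": cum,
            "crossings": crossings}


def window_psds_for_signal(sig: SampledSignal, window_s: float = 180.0,
                           step_s: float = 1.0, order: int = DEFAULT_AR_ORDER,
                           n_grid: int = DEFAULT_N_GRID):
    """All sliding-window PSDs of one signal (helper for the power report)."""
    return [window_psd(w, sig.fs, order, n_grid)
            for w in sliding_windows(sig, window_s, step_s)]
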