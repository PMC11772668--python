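#!/usr/bin/env python
"""Per-run band sweep: correlate every pupil band combination with HRV.

Sweeps each cohort run on a 0.02 Hz grid and writes, per run, the
combination with the highest within-run geometric mean of the three
feature correlations — illustrating how variable single-run optima are
before group aggregation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pupilbands.hrv import preprocess_rr, read_beats_csv
from pupilbands.pipeline import load_manifest
from pupilbands.pupil import preprocess_pupil, read_pupil_csv
from pupilbands.sweep import (align_signals, combination_indices, grid_edges,
                              hrv_feature_series, per_run_correlation,
                              pupil_cumpower_matrix)

ROOT = Path(__file__).resolve().parents[1]
STEP = 0.02


def main() -> None:
    manifest = load_manifest(ROOT / "scratch" / "cohort" / "dataset.json")
    edges = grid_edges(STEP, 1.0)
    cidx = combination_indices(STEP, 1.0)
    i, j, k = cidx
    rows = []
    for m in manifest:
        hrv_sig, _ = preprocess_rr(read_beats_csv(m.beats))
        pup_sig, _ = preprocess_pupil(read_pupil_csv(m.pupil))
        ha, pa = align_signals(hrv_sig, pup_sig)
        feats = hrv_feature_series(ha)
        cum, _ = pupil_cumpower_matrix(pa, edges)
        rc = per_run_correlation(cum, edges, feats, cidx)
        with np.errstate(invalid="ignore"):
            geo = np.where(
                (rc.r_lf > 0) & (rc.r_hf > 0) & (rc.r_ratio > 0),
                np.cbrt(rc.r_lf * rc.r_hf * rc.r_ratio), np.nan)
        best = np.nanargmax(geo)
        rows.append({
            "subject": m.subject, "run": m.run, "n_windows": rc.n,
            "best_lf_lo": edges[i[best]], "best_split": edges[j[best]],
            "best_hf_hi": edges[k[best]], "best_geo_mean": geo[best],
        })
    df = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df.to_csv(results / "per_run_best_combos.csv", index=False)
    print(df.to_string(index=False))
    print("\nsingle-run optima scatter widely (sd of lf_lo: "
          f"{df.best_lf_lo.std():.3f} Hz) -> group aggregation is essential")


if __name__ == "__main__":
    main()
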