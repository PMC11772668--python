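"""Cohort-level aggregation of the band sweep.

Per-run correlation coefficients are variance-stabilized with Fisher's Z,
averaged across runs with weights n_i - 3 (runs differ in window count),
and mapped back with the inverse transform.  Family-wise error over the
combination lattice is controlled with a cluster-based permutation test:
adjacent supra-threshold combinations form clusters, cluster mass is the
summed |group z-score|, and the null of the maximum mass is built by
randomly sign-flipping each run's z vector (exchangeable when the true
correlation is zero).  Combinations are finally scored by the geometric
mean of the three group correlations (LF, HF, LF/HF) and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .sweep import RunCorrelations

FEATURES = ("lf", "hf", "ratio")

# The two LF/HF band definitions most pupillography studies borrow from the
# HRV literature, evaluated alongside the sweep's top combinations.
LITERATURE_COMBOS = ((0.04, 0.15, 0.40), (0.05, 0.15, 0.45))


def fisher_z(r):
    """z = atanh(r); rejects |r| >= 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    return np.arctanh(r)


def fisher_z_inv(z):
    return np.tanh(np.asarray(z, dtype=float))


def aggregate_runs(rs, ns) -> tuple[float, float]:
    """Weighted Fisher-Z mean across runs and its two-sided normal p.

    Weights are n_i - 3, the inverse variance of z_i for independent
    samples; the group statistic is z_bar * sqrt(sum of weights) ~ N(0, 1).
    """
    rs = np.asarray(rs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    ok = np.isfinite(rs)
    rs, ns = rs[ok], ns[ok]
    if rs.size < 2:
        raise ValueError("need >= 2 runs with a defined correlation")
    if np.any(ns < 4):
        raise ValueError("every run must contribute at least 4 windows")
    w = ns - 3.0
    z_bar = float((w * fisher_z(rs)).sum() / w.sum())
    stat = z_bar * np.sqrt(w.sum())
    p = 2.0 * stats.norm.sf(abs(stat))
    return float(fisher_z_inv(z_bar)), float(p)


def pct_significant_runs(ps, alpha: float = 0.05) -> float:
    """Percentage of runs whose per-run p-value is below alpha."""
    ps = np.asarray(ps, dtype=float)
    ps = ps[np.isfinite(ps)]
    if ps.size == 0:
        return float("nan")
    return 100.0 * float((ps < alpha).sum()) / ps.size


def geometric_mean_score(r_lf: float, r_hf: float, r_ratio: float) -> float:
    """Cube root of the product of the three group correlations.

    Defined only when all three are positive: a combination whose features
    do not all correlate in the same (positive) direction cannot be ranked.
    """
    vals = np.array([r_lf, r_hf, r_ratio], dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        return float("nan")
    return float(np.cbrt(vals.prod()))


@dataclass
class ClusterCorrectionConfig:
    alpha: float = 0.05
    n_permutations: int = 1000
    adjacency: str = "lattice-1step"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


def lattice_edges(combo_idx, n_edges: int) -> np.ndarray:
    """Adjacency edges of the combination lattice.

    Two combinations are neighbors iff they differ by exactly one grid step
    in exactly one of the three limits.  Returns an (m, 2) array of
    positions into the combination list (each pair once).
    """
    i, j, k = (np.asarray(a, dtype=np.int64) for a in combo_idx)
    codes = (i * n_edges + j) * n_edges + k     # lexicographic, ascending
    pairs = []
    for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        ni, nj, nk = i + di, j + dj, k + dk
        valid = (ni < nj) & (nj < nk) & (nk < n_edges)
        target = (ni[valid] * n_edges + nj[valid]) * n_edges + nk[valid]
        pos = np.searchsorted(codes, target)
        found = (pos < codes.size) & (codes[np.minimum(pos, codes.size - 1)]
                                      == target)
        pairs.append(np.column_stack([np.nonzero(valid)[0][found],
                                      pos[found]]))
    return np.concatenate(pairs, axis=0)


def _cluster_masses(stat: np.ndarray, supra: np.ndarray,
                    edges: np.ndarray):
    """Connected clusters of supra-threshold combos and their |stat| mass."""
    idx = np.nonzero(supra)[0]
    if idx.size == 0:
        return np.full(stat.size, -1), np.array([])
    relabel = np.full(stat.size, -1)
    relabel[idx] = np.arange(idx.size)
    both = supra[edges[:, 0]] & supra[edges[:, 1]]
    e = edges[both]
    graph = sparse.coo_matrix(
        (np.ones(e.shape[0]), (relabel[e[:, 0]], relabel[e[:, 1]])),
        shape=(idx.size, idx.size))
    n_clusters, labels = connected_components(graph, directed=False)
    masses = np.bincount(labels, weights=np.abs(stat[idx]),
                         minlength=n_clusters)
    cluster_of = np.full(stat.size, -1)
    cluster_of[idx] = labels
    return cluster_of, masses


def cluster_permutation_correct(z_runs: np.ndarray, weights,
                                combo_idx, n_edges: int,
                                cfg: ClusterCorrectionConfig | None = None,
                                rng: np.random.Generator | None = None):
    """Cluster-corrected p-values over the combination lattice.

    ``z_runs``: (n_runs, n_combos) Fisher-z values, one row per run;
    ``weights``: per-run aggregation weights (n_i - 3).  Returns
    ``(p_corrected, stat)``: combinations in the same cluster share one
    corrected p; sub-threshold or unclustered combinations get p = 1.
    """
    cfg = cfg or ClusterCorrectionConfig()
    rng = rng or np.random.default_rng()
    z_runs = np.asarray(z_runs, dtype=float)
    if z_runs.ndim != 2 or z_runs.shape[0] < 2:
        raise ValueError("need z vectors from at least 2 runs")
    w = np.asarray(weights, dtype=float)
    sqrt_w = np.sqrt(w.sum())

    def group_stat(z):
        return (w @ z) / w.sum() * sqrt_w

    stat = group_stat(z_runs)
    z_crit = stats.norm.isf(cfg.alpha / 2.0)
    edges = lattice_edges(combo_idx, n_edges)
    cluster_of, masses = _cluster_masses(stat, np.abs(stat) > z_crit, edges)

    n_runs = z_runs.shape[0]
    null_max = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_runs)
        s = group_stat(signs[:, None] * z_runs)
        _, m = _cluster_masses(s, np.abs(s) > z_crit, edges)
        null_max[b] = m.max() if m.size else 0.0

    p_corr = np.ones(stat.size)
    for c, mass in enumerate(masses):
        p_c = (1.0 + float((null_max >= mass).sum())) / (cfg.n_permutations + 1.0)
        p_corr[cluster_of == c] = p_c
    return p_corr, stat


def group_table(run_results: list[RunCorrelations],
                cluster_cfg: ClusterCorrectionConfig | None = None,
                rng: np.random.Generator | None = None,
                alpha_run: float = 0.05) -> pd.DataFrame:
    """Full cohort table: one row per band combination.

    Columns: the three band limits; per feature the group correlation,
    cluster-corrected p and % of runs with a significant per-run
    correlation; and the geometric-mean score.
    """
    if len(run_results) < 2:
        raise ValueError("group analysis needs at least 2 runs")
    first = run_results[0]
    n_edges = first.edges.size
    for rr in run_results[1:]:
        if rr.n_combos != first.n_combos or rr.edges.size != n_edges:
            raise ValueError("runs were swept on different grids")

    i, j, k = first.combo_idx
    df = pd.DataFrame({"lf_lo": first.edges[i], "split": first.edges[j],
                       "hf_hi": first.edges[k]})
    eps = 1e-12
    for feat in FEATURES:
        r_mat = np.vstack([getattr(rr, f"r_{feat}") for rr in run_results])
        p_mat = np.vstack([getattr(rr, f"p_{feat}") for rr in run_results])
        ns = np.array([rr.n_ratio if feat == "ratio" else rr.n
                       for rr in run_results], dtype=float)
        keep = np.all(np.isfinite(r_mat), axis=1) & (ns >= 4)
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 usable runs for feature {feat}")
        r_mat, p_mat, ns = r_mat[keep], p_mat[keep], ns[keep]
        z_mat = np.arctanh(np.clip(r_mat, -1 + eps, 1 - eps))
        w = ns - 3.0
        z_bar = (w @ z_mat) / w.sum()
        df[f"r_{feat}"] = np.tanh(z_bar)
        p_corr, _ = cluster_permutation_correct(
            z_mat, w, first.combo_idx, n_edges, cluster_cfg, rng)
        df[f"p_{feat}"] = p_corr
        df[f"pct_{feat}"] = 100.0 * (p_mat < alpha_run).mean(axis=0)
    df["geo_mean"] = [
        geometric_mean_score(a, b, c)
        for a, b, c in zip(df["r_lf"], df["r_hf"], df["r_ratio"])]
    return df


def rank_top(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k combinations by geometric mean, deterministically tie-broken.

    Ties descend through (r_ratio, r_lf, r_hf) and finally the combination
    limits in lexicographic order, so reruns produce identical tables.
    """
    scored = df[np.isfinite(df["geo_mean"])].copy()
    if scored.empty:
        return scored
    scored = scored.sort_values(
        by=["geo_mean", "r_ratio", "r_lf", "r_hf", "lf_lo", "split", "hf_hi"],
        ascending=[False, False, False, False, True, True, True],
        kind="mergesort")
    return scored.head(k).reset_index(drop=True)


def evaluate_named_combos(df: pd.DataFrame, combos=LITERATURE_COMBOS,
                          step: float | None = None) -> pd.DataFrame:
    """Look up specific band combinations in the sweep table.

    Combinations must be aligned to the sweep grid; an off-grid request is
    an error, not a nearest-neighbor lookup.
    """
    rows = []
    for lf_lo, split, hf_hi in combos:
        if step is not None:
            for v in (lf_lo, split, hf_hi):
                if abs(v / step - round(v / step)) > 1e-6:
                    raise ValueError(f"{v} Hz is not on the {step} Hz grid")
        match = df[(np.isclose(df["lf_lo"], lf_lo))
                   & (np.isclose(df["split"], split))
                   & (np.isclose(df["hf_hi"], hf_hi))]
        if match.empty:
            raise ValueError(
                f"combination ({lf_lo}, {split}, {hf_hi}) not in the sweep")
        rows.append(match.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)
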