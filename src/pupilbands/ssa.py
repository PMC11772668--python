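"""Singular spectrum analysis and iterative artifact repair.

SSA embeds a series into an L x K Hankel trajectory matrix, factorizes it,
and maps each singular triple back to a series by anti-diagonal averaging.
The iterative cleaner repeatedly reconstructs the series from its leading
components and overwrites only the artifact-flagged samples with the
reconstruction, so blink-contaminated stretches are replaced by the smooth
oscillatory structure carried by the rest of the run.

The factorization runs on the L x L lag-covariance matrix (eigendecomposition
of X X^T) rather than a full SVD of X, which is much cheaper for the long
series this pipeline sees; anti-diagonal averaging of a rank-one term
u w^T is exactly the full convolution of u and w divided by the diagonal
lengths, so no trajectory matrix is ever materialized for reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import SampledSignal


@dataclass
class SSAConfig:
    """Embedding length L, kept components, and iteration control.

    ``n_components=None`` keeps the smallest leading set explaining
    ``energy_frac`` of the squared singular values.
    """

    window_len: int | None = None      # default: 30 s of samples, set by caller
    n_components: int | None = None
    max_iter: int = 20
    tol: float = 1e-3
    energy_frac: float = 0.90


def _check_window(n: int, window_len: int) -> None:
    if not 2 <= window_len <= n // 2:
        raise ValueError(
            f"window_len must be in [2, n//2] = [2, {n // 2}], got {window_len}")


def _ssa_factor(x: np.ndarray, window_len: int):
    """Singular values (descending), left vectors U, and scores W = U^T X."""
    n = x.size
    _check_window(n, window_len)
    traj = sliding_window_view(x, window_len).T      # L x K, no copy
    cov = traj @ traj.T
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    sing = np.sqrt(np.clip(eigval[order], 0.0, None))
    u = eigvec[:, order]
    w = u.T @ traj                                    # r x K
    return sing, u, w


def _diag_average(u: np.ndarray, w: np.ndarray, counts: np.ndarray) -> np.ndarray:
    # anti-diagonal sums of the outer product u w^T = full convolution
    return np.convolve(u, w) / counts


def _diag_counts(window_len: int, k: int) -> np.ndarray:
    n = window_len + k - 1
    idx = np.arange(n)
    return np.minimum(np.minimum(idx + 1, n - idx), min(window_len, k)).astype(float)


def ssa_decompose(x, window_len: int) -> list[np.ndarray]:
    """Elementary reconstructed series, ordered by decreasing singular value.

    Their sum reconstructs ``x`` exactly (to numerical precision).
    """
    x = np.asarray(x, dtype=float)
    sing, u, w = _ssa_factor(x, window_len)
    counts = _diag_counts(window_len, x.size - window_len + 1)
    return [_diag_average(u[:, i], w[i], counts) for i in range(sing.size)]


def ssa_singular_values(x, window_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return _ssa_factor(x, window_len)[0]


def _n_from_energy(sing: np.ndarray, frac: float) -> int:
    energy = sing ** 2
    total = energy.sum()
    if total == 0:
        return 1
    return int(np.searchsorted(np.cumsum(energy) / total, frac) + 1)


def ssa_reconstruct(x, window_len: int, n_components: int | None,
                    energy_frac: float = 0.90) -> np.ndarray:
    """Series rebuilt from the leading components only."""
    x = np.asarray(x, dtype=float)
    sing, u, w = _ssa_factor(x, window_len)
    m = n_components if n_components is not None else _n_from_energy(sing, energy_frac)
    m = min(m, sing.size)
    counts = _diag_counts(window_len, x.size - window_len + 1)
    recon = np.zeros(x.size)
    for i in range(m):
        recon += _diag_average(u[:, i], w[i], counts)
    return recon


def iterative_ssa_clean(signal: SampledSignal, cfg: SSAConfig | None = None,
                        flags=None) -> tuple[SampledSignal, dict]:
    """Replace artifact-flagged samples with the low-rank SSA reconstruction.

    ``flags`` marks corrupted positions (defaults to the signal's invalid
    mask, inverted).  Iterates reconstruction/replacement until the largest
    relative change at flagged positions drops below ``cfg.tol`` or
    ``cfg.max_iter`` is hit; unflagged samples always keep their original
    values.  Non-convergence is reported in the status dict, not raised.
    """
    cfg = cfg or SSAConfig()
    flags = np.asarray(~signal.valid_mask if flags is None else flags, dtype=bool)
    if flags.shape != signal.values.shape:
        raise ValueError("flags length must match the signal")
    x = signal.values.copy()
    window_len = cfg.window_len or max(int(round(30.0 * signal.fs)), 2)
    window_len = min(window_len, x.size // 2)
    if not flags.any():
        out = signal.copy()
        out.valid_mask[:] = True
        return out, {"n_iter": 0, "converged": True, "n_flagged": 0}

    scale = np.ptp(x[~flags]) if (~flags).any() else np.ptp(x)
    scale = scale if scale > 0 else 1.0
    # factorize the centered series: a large DC offset would otherwise own
    # the leading singular triple and defeat the energy-based rank choice
    offset = x.mean()
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        recon = offset + ssa_reconstruct(x - offset, window_len,
                                         cfg.n_components, cfg.energy_frac)
        delta = np.max(np.abs(recon[flags] - x[flags])) / scale
        x[flags] = recon[flags]
        if delta < cfg.tol:
            converged = True
            break
    out = SampledSignal(x, signal.fs, signal.t0,
                        np.ones(x.size, dtype=bool))
    return out, {"n_iter": it, "converged": converged,
                 "n_flagged": int(flags.sum())}
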