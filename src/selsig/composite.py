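"""Combining per-SNP selection statistics into DCMS scores and q-values.

The decorrelated composite of multiple signals (DCMS) turns K aligned
per-SNP statistics into one score per locus.  Each statistic is first
converted to a right-tailed p-value from its fractional rank,
p = 1 - (rank - 0.5)/n, which keeps p strictly inside (0, 1).  The
composite at locus l is

    DCMS_l = sum_t  w_t * log((1 - p_lt) / p_lt),   w_t = 1 / sum_i |r_it|,

where r is the Pearson correlation matrix between the (absolute-valued)
statistics, the self term included.  Duplicated or strongly correlated
statistics therefore share weight instead of double counting.  Raw DCMS
scores are calibrated against a normal with the empirical mean and SD,
and the resulting p-values are Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "running_median",
    "rank_pvalues",
    "signal_correlation",
    "dcms_score",
    "empirical_pvalues",
    "bh_fdr",
]


def running_median(values: np.ndarray, k: int = 1001) -> np.ndarray:
    """Centered running median with symmetric shrinking windows at the ends.

    Within k//2 of either end the window shrinks to k' = 2*min(i, n-1-i)+1
    so it stays centered; NaNs are excluded from each window (a window of
    only NaNs yields NaN).  Output length equals input length.
    """
    if k % 2 == 0:
        raise ValueError("window size k must be odd")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k > n:
        raise ValueError("window size exceeds track length")
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        window = values[i - h:i + h + 1]
        out[i] = np.nanmedian(window) if not np.all(np.isnan(window)) else np.nan
    return out


def rank_pvalues(values: np.ndarray) -> np.ndarray:
    """Right-tailed p-values from ascending fractional ranks.

    p_l = 1 - (rank_l - 0.5)/n with average ranks for ties; the largest
    statistic receives the smallest p.  NaN inputs yield NaN outputs and
    are excluded from n.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = finite.sum()
    if n == 0:
        raise ValueError("all values are missing")
    out = np.full(len(values), np.nan)
    ranks = stats.rankdata(values[finite], method="average")
    out[finite] = 1.0 - (ranks - 0.5) / n
    return out


def signal_correlation(tracks: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Pearson correlation matrix between absolute-valued statistic tracks.

    Each pair uses its pairwise-complete observations.  A track with zero
    variance on the complete observations raises, naming the track.
    """
    if isinstance(tracks, dict):
        names = list(tracks)
        mats = [np.abs(np.asarray(tracks[t], dtype=float)) for t in names]
    else:
        names = [f"track{i}" for i in range(len(tracks))]
        mats = [np.abs(np.asarray(t, dtype=float)) for t in tracks]
    k = len(mats)
    if k < 2:
        raise ValueError("need at least two tracks")
    r = np.eye(k)
    for a in range(k):
        if np.nanstd(mats[a]) == 0:
            raise ValueError(f"track {names[a]!r} has zero variance")
    for a in range(k):
        for b in range(a + 1, k):
            ok = np.isfinite(mats[a]) & np.isfinite(mats[b])
            if ok.sum() < 2:
                raise ValueError(f"tracks {names[a]!r}/{names[b]!r} share <2 sites")
            r[a, b] = r[b, a] = np.corrcoef(mats[a][ok], mats[b][ok])[0, 1]
    return r


def dcms_score(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Raw DCMS per locus from an (L, K) p-value matrix and (K, K) r matrix.

    Weights are 1 / sum_i |r_it| (self term included).  Loci with any
    missing p are emitted as NaN (complete-case).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    r = np.atleast_2d(np.asarray(r, dtype=float))
    k = p.shape[1]
    if r.shape != (k, k):
        raise ValueError("correlation matrix shape does not match track count")
    finite = np.isfinite(p)
    if np.any((p <= 0) | (p >= 1), where=finite):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    w = 1.0 / np.abs(r).sum(axis=0)
    out = np.where(
        finite.all(axis=1),
        np.nansum(np.log((1.0 - p) / p) * w, axis=1),
        np.nan,
    )
    return out


def empirical_pvalues(dcms: np.ndarray) -> np.ndarray:
    """Upper-tail normal p-values using the empirical mean and SD."""
    dcms = np.asarray(dcms, dtype=float)
    finite = np.isfinite(dcms)
    if finite.sum() < 2:
        raise ValueError("need at least two non-missing DCMS values")
    mu = dcms[finite].mean()
    sd = dcms[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("DCMS values have zero standard deviation")
    out = np.full(len(dcms), np.nan)
    out[finite] = stats.norm.sf((dcms[finite] - mu) / sd)
    return out


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and significance flags (q < alpha).

    NaN p-values are excluded from the adjustment and flagged False.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("empty p-value vector")
    q = np.full(len(p), np.nan)
    _, q_fin, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
    q[finite] = q_fin
    flags = np.zeros(len(p), dtype=bool)
    flags[finite] = q[finite] < alpha
    return q, flags
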