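"""Hartigan-style dip statistic for multimodality.

The dip measures how far an empirical CDF is from the closest unimodal CDF.
Here it is computed by the greatest-convex-minorant / least-concave-majorant
construction: for every candidate mode index m, the best convex fit to the
midpoint ECDF left of m is its greatest convex minorant (GCM) and the best
concave fit right of m is its least concave majorant (LCM); the deviation at
mode m is the larger of the two maximal gaps, and the dip is half the
minimum deviation over modes.  Larger values indicate stronger departure
from unimodality (e.g. a second mode of outlying beta values at a probe).

The p-value is calibrated by Monte Carlo against Uniform(0, 1) samples of
the same size — the canonical least-favourable unimodal null — so it is
valid for the statistic exactly as defined here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _prefix_hull_gaps(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Max gap between points and the lower convex hull of every prefix.

    Returns g where g[m] = max_{i<=m} (y_i - gcm_m(x_i)) for the greatest
    convex minorant gcm_m of the first m+1 points.  Incremental monotone
    chain; when appending a point replaces hull segments, only gaps inside
    the new final segment change, so the running maximum stays correct.
    """
    n = len(x)
    hull: list[int] = []
    gaps = np.empty(n)
    runmax = 0.0
    for m_i in range(n):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on or above chord a->m (non-convex turn)
            if (x[b] - x[a]) * (y[m_i] - y[a]) - (x[m_i] - x[a]) * (y[b] - y[a]) <= 0:
                hull.pop()
            else:
                break
        hull.append(m_i)
        if len(hull) >= 2:
            a = hull[-2]
            if x[m_i] > x[a]:
                inner = slice(a + 1, m_i)
                t = (x[inner] - x[a]) / (x[m_i] - x[a])
                line = y[a] + t * (y[m_i] - y[a])
                if line.size:
                    runmax = max(runmax, float(np.max(y[inner] - line)))
        gaps[m_i] = runmax
    return gaps


def dip_statistic(values: np.ndarray) -> float:
    """Dip of a sample: half the minimax ECDF deviation from unimodality."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("dip requires at least 4 observations")
    y = (np.arange(1, n + 1) - 0.5) / n
    d_left = _prefix_hull_gaps(x, y)
    d_right = _prefix_hull_gaps(-x[::-1], -y[::-1])[::-1]
    return 0.5 * float(np.min(np.maximum(d_left, d_right)))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_test(values: np.ndarray, n_mc: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dip statistic with a Monte-Carlo p-value against the uniform null.

    ``p > 0.05`` suggests the distribution is unimodal.  The null dip
    distribution depends only on the sample size, so replicates are cached
    per (n, n_mc, seed).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("dip_test requires at least 4 observations")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    d = dip_statistic(x)
    key = (n, n_mc, seed)
    null = _NULL_CACHE.get(key)
    if null is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        null = np.array([dip_statistic(rng.random(n)) for _ in range(n_mc)])
        _NULL_CACHE[key] = null
    p = (1.0 + np.count_nonzero(null >= d)) / (n_mc + 1.0)
    return d, float(p)
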