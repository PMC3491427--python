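"""Embedding-parameter estimation: FNN dimension, auto-MI delay,
over-embedding and timestamp realignment.

The pattern dimension ``d`` is estimated per channel with the false
nearest neighbours (FNN) criterion of Kennel et al., the delay ``tau``
from the first local minimum of the binned auto-mutual-information.
Across channels the dimension estimates are aggregated by their mode and
the delays by their rounded mean.  For symbolization the dimension is
deliberately over-embedded to ``d_hat = 2d + 2``, which suppresses chance
symbol matches and copes with non-stationarity.  Because a pattern spans
``span = (d_hat - 1) * tau`` samples, pattern timestamps are realigned to
the window centre, ``t* = t + span / 2``.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .symbolize import _embed

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingParams",
    "fnn_fraction",
    "estimate_dimension",
    "mutual_information",
    "estimate_delay",
    "aggregate_params",
    "realign_times",
    "estimate_set_params",
]

#: Kennel false-neighbour criteria: relative distance growth and absolute
#: growth in units of the series' standard deviation.
FNN_RTOL = 10.0
FNN_ATOL = 2.0
#: Fraction of false neighbours below which a dimension is accepted.
#: A 1% cutoff is sometimes quoted, but on short (~10^3 sample) series the
#: FNN fraction of a clean low-dimensional attractor plateaus at a few
#: percent, so 10% is used as the practical default.
FNN_THRESHOLD = 0.10
DEFAULT_BINS = 100


@dataclass
class EmbeddingParams:
    """Per-channel and aggregated embedding parameters."""

    per_channel_d: list[int]
    per_channel_tau: list[int]
    d: int
    tau: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("aggregated dimension must be >= 2")
        if self.tau < 1:
            raise ValueError("aggregated delay must be >= 1")

    @property
    def d_hat(self) -> int:
        """Over-embedded dimension 2d + 2."""
        return 2 * self.d + 2

    @property
    def span(self) -> int:
        """Samples covered by one over-embedded pattern: (d_hat - 1) * tau."""
        return (self.d_hat - 1) * self.tau


def fnn_fraction(
    u,
    d: int,
    tau: int,
    rtol: float = FNN_RTOL,
    atol: float = FNN_ATOL,
    theiler: int | None = None,
) -> float:
    """Fraction of false nearest neighbours in a ``d``-dimensional delay
    embedding of ``u``.

    A point's nearest neighbour (Euclidean metric, temporal neighbours
    within a Theiler window of one delay excluded) is "false" when adding
    the ``(d+1)``-th delay coordinate grows the distance by more than
    ``rtol`` relatively, or past ``atol`` standard deviations absolutely.
    """
    u = np.asarray(u, dtype=float)
    if theiler is None:
        theiler = tau
    n_pts = u.size - d * tau
    if n_pts < 10:
        raise ValueError(
            f"series of length {u.size} too short for FNN at d={d}, tau={tau}: "
            f"needs more than {d * tau + 9} samples"
        )
    emb = _embed(u, d, tau)[:n_pts]
    nxt = u[d * tau : d * tau + n_pts]
    sigma = u.std()
    if sigma == 0:
        return 0.0
    tree = cKDTree(emb)
    k = min(n_pts, 2 * theiler + 5)
    dist, idx = tree.query(emb, k=k)
    n_false = 0
    n_total = 0
    for i in range(n_pts):
        r_d = None
        for kk in range(1, k):
            j = int(idx[i, kk])
            if abs(j - i) > theiler:
                r_d, j_nn = dist[i, kk], j
                break
        if r_d is None:
            # all k candidates inside the Theiler window: brute-force fallback
            dists = np.linalg.norm(emb - emb[i], axis=1)
            dists[max(0, i - theiler) : i + theiler + 1] = np.inf
            j_nn = int(np.argmin(dists))
            r_d = dists[j_nn]
            if not np.isfinite(r_d):
                continue
        growth = abs(nxt[i] - nxt[j_nn])
        n_total += 1
        if (r_d > 0 and growth / r_d > rtol) or np.hypot(r_d, growth) / sigma > atol:
            n_false += 1
    if n_total == 0:
        raise ValueError("no valid neighbour pairs outside the Theiler window")
    return n_false / n_total


def estimate_dimension(
    u,
    tau: int,
    max_d: int = 8,
    threshold: float = FNN_THRESHOLD,
    **fnn_kwargs,
) -> tuple[int, bool]:
    """Smallest dimension ``d`` in ``2..max_d`` whose FNN fraction drops to
    ``threshold`` or below.

    Returns ``(d, converged)``; when no dimension qualifies, ``max_d`` is
    returned with ``converged=False``.
    """
    if max_d < 2:
        raise ValueError("max_d must be >= 2")
    for d in range(2, max_d + 1):
        if fnn_fraction(u, d, tau, **fnn_kwargs) <= threshold:
            return d, True
    logger.warning("FNN fraction never dropped to %.3g up to d=%d", threshold, max_d)
    return max_d, False


def mutual_information(u, lag: int, n_bins: int = DEFAULT_BINS) -> float:
    """Histogram estimate (bits) of the mutual information between ``u(t)``
    and ``u(t + lag)``, using ``n_bins`` equal-width bins per marginal."""
    u = np.asarray(u, dtype=float)
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if lag >= u.size:
        raise ValueError(f"lag {lag} leaves no overlap on a series of length {u.size}")
    a = u[: u.size - lag] if lag else u
    b = u[lag:] if lag else u
    if a.max() == a.min() or b.max() == b.min():
        warnings.warn("constant series: histogram degenerate, MI set to 0")
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / np.outer(px, py)[nz])).sum())


def mi_profile(u, max_lag: int, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Auto-MI at lags ``0..max_lag`` (index = lag)."""
    return np.array([mutual_information(u, lag, n_bins) for lag in range(max_lag + 1)])


def estimate_delay(u, max_lag: int = 60, n_bins: int = DEFAULT_BINS) -> int:
    """Delay at the first local minimum of the auto-MI profile.

    The first lag ``l`` in ``[2, max_lag-1]`` with ``MI(l) < MI(l-1)`` and
    ``MI(l) <= MI(l+1)`` is returned; if no local minimum exists the global
    arg-min over ``1..max_lag`` is returned with a warning.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    mi = mi_profile(u, max_lag, n_bins)
    for lag in range(2, max_lag):
        if mi[lag] < mi[lag - 1] and mi[lag] <= mi[lag + 1]:
            return lag
    warnings.warn("no local MI minimum up to max_lag; returning global arg-min")
    return int(np.argmin(mi[1:]) + 1)


def aggregate_params(per_channel_d, per_channel_tau, converged: bool = True) -> EmbeddingParams:
    """Aggregate per-channel estimates: mode of dimensions (ties broken
    toward the smaller value), mean of delays rounded half away from zero."""
    ds = [int(d) for d in per_channel_d]
    taus = [int(t) for t in per_channel_tau]
    if not ds or not taus:
        raise ValueError("need at least one channel estimate")
    counts = Counter(ds)
    top = max(counts.values())
    candidates = sorted(d for d, c in counts.items() if c == top)
    if len(candidates) > 1:
        logger.info("dimension mode tie among %s; choosing %d", candidates, candidates[0])
    d = candidates[0]
    mean_tau = float(np.mean(taus))
    tau = int(np.sign(mean_tau) * np.floor(abs(mean_tau) + 0.5))
    return EmbeddingParams(ds, taus, d=d, tau=tau, converged=converged)


def realign_times(t, d_hat: int, tau: int, sampling_rate: float | None = None):
    """Window-centre realignment ``t* = t + (d_hat - 1) * tau / 2``.

    ``t`` may be a scalar or array of raw pattern anchor indices (samples).
    The result is fractional, in samples; if ``sampling_rate`` (Hz) is
    given, it is converted to milliseconds.
    """
    t_star = np.asarray(t, dtype=float) + (d_hat - 1) * tau / 2.0
    if sampling_rate is not None:
        t_star = t_star / sampling_rate * 1000.0
    if t_star.ndim == 0:
        return float(t_star)
    return t_star


def estimate_set_params(
    ts,
    max_d: int = 8,
    max_lag: int = 60,
    n_bins: int = DEFAULT_BINS,
    threshold: float = FNN_THRESHOLD,
) -> EmbeddingParams:
    """Estimate (d, tau) for every channel of a TimeSeriesSet and aggregate.

    Each channel's delay is estimated first (auto-MI first minimum) and
    used as that channel's FNN delay.
    """
    dims, delays = [], []
    all_converged = True
    for label, row in zip(ts.labels, ts.values):
        tau_i = estimate_delay(row, max_lag=max_lag, n_bins=n_bins)
        d_i, ok = estimate_dimension(row, tau_i, max_d=max_d, threshold=threshold)
        if not ok:
            logger.warning("channel %r: FNN did not converge by d=%d", label, max_d)
            all_converged = False
        dims.append(d_i)
        delays.append(tau_i)
    return aggregate_params(dims, delays, converged=all_converged)
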