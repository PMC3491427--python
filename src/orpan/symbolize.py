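"""Order-pattern symbolization of real-valued time series.

A signal ``u(t)`` is coarse-grained by the permutation describing the
relative ranks of the ``d`` values ``u(t), u(t+tau), ..., u(t+(d-1)tau)``.
With ties ignored there are ``d!`` possible patterns; each pattern is
encoded as its lexicographic rank (Lehmer code), giving an integer symbol
in ``[0, d!-1]``.  The encoding depends only on the order structure of the
signal, so it is exactly invariant under any strictly increasing amplitude
transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSet",
    "SymbolSequence",
    "rank_pattern",
    "pattern_index",
    "pattern_unrank",
    "symbolize_series",
    "symbolize_set",
]


@dataclass
class TimeSeriesSet:
    """Labelled multichannel time series (rows = channels).

    Parameters
    ----------
    labels
        Unique channel identifiers, one per row.
    values
        ``N x T`` real matrix, channel-major.
    sampling_rate
        Samples per second; optional, used only to express realigned
        pattern times in milliseconds.
    """

    labels: list[str]
    values: np.ndarray
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D channel-by-time matrix")
        n, t = self.values.shape
        if n < 1 or t < 2:
            raise ValueError(f"need N >= 1 channels and T >= 2 samples, got {n} x {t}")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} channels")
        if len(set(self.labels)) != n:
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SymbolSequence:
    """Integer order-pattern series for one channel.

    ``symbols[k]`` encodes the pattern anchored at sample ``start_index + k``;
    the window it describes extends ``(d-1)*tau`` samples to the right.
    """

    symbols: np.ndarray
    d: int
    tau: int
    start_index: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise ValueError("symbols must be a nonempty 1-D integer array")
        hi = factorial(self.d)
        if self.symbols.min() < 0 or self.symbols.max() >= hi:
            raise ValueError(f"symbols out of range [0, {hi - 1}] for d={self.d}")

    def __len__(self) -> int:
        return self.symbols.size


def _check_window(window: np.ndarray) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("pattern window needs at least 2 values")
    if not np.all(np.isfinite(w)):
        raise ValueError("pattern window contains non-finite values")
    return w


def rank_pattern(window) -> tuple[int, ...]:
    """Rank of each position in a window of ``d`` values (1 = smallest).

    Ties are broken by position: the earlier sample receives the smaller
    rank (stable sort), so quantized inputs behave reproducibly.
    """
    w = _check_window(window)
    order = np.argsort(w, kind="stable")
    ranks = np.empty(w.size, dtype=int)
    ranks[order] = np.arange(1, w.size + 1)
    return tuple(int(r) for r in ranks)


def pattern_index(label) -> int:
    """Lexicographic rank of a permutation of ``1..d`` (Lehmer code).

    Accepts a sequence of integers or a string of digits like ``"132"``.
    Bijective over the ``d!`` permutations: ``"12...d"`` maps to 0,
    ``"d...21"`` to ``d!-1``.
    """
    if isinstance(label, str):
        perm = [int(c) for c in label]
    else:
        perm = [int(x) for x in label]
    d = len(perm)
    if d < 1 or sorted(perm) != list(range(1, d + 1)):
        raise ValueError(f"{label!r} is not a permutation of 1..{d}")
    idx = 0
    for i in range(d - 1):
        smaller_right = sum(1 for j in range(i + 1, d) if perm[j] < perm[i])
        idx += smaller_right * factorial(d - 1 - i)
    return idx


def pattern_unrank(index: int, d: int) -> tuple[int, ...]:
    """Inverse of :func:`pattern_index`: permutation of ``1..d`` at a
    given lexicographic rank."""
    if not 0 <= index < factorial(d):
        raise ValueError(f"index {index} out of range for d={d}")
    avail = list(range(1, d + 1))
    perm = []
    for i in range(d):
        f = factorial(d - 1 - i)
        q, index = divmod(index, f)
        perm.append(avail.pop(q))
    return tuple(perm)


def _embed(u: np.ndarray, d: int, tau: int) -> np.ndarray:
    """Delay-embedding matrix, one window per row; shape (T-(d-1)tau, d)."""
    length = u.size - (d - 1) * tau
    return np.stack([u[j * tau : j * tau + length] for j in range(d)], axis=1)


def _encode_windows(windows: np.ndarray) -> np.ndarray:
    """Vectorized Lehmer encoding of rank patterns, row-wise."""
    n, d = windows.shape
    order = np.argsort(windows, axis=1, kind="stable")
    ranks = np.empty_like(order)
    ranks[np.arange(n)[:, None], order] = np.arange(d)[None, :]
    codes = np.zeros(n, dtype=np.int64)
    for i in range(d - 1):
        smaller_right = (ranks[:, i + 1 :] < ranks[:, [i]]).sum(axis=1)
        codes += smaller_right * factorial(d - 1 - i)
    return codes


def symbolize_series(u, d: int, tau: int, label: str | None = None) -> SymbolSequence:
    """Encode a series into order-pattern symbols.

    Parameters
    ----------
    u
        Real series of length ``T``; must satisfy ``T > (d-1)*tau``.
    d
        Pattern dimension (number of samples per pattern), ``>= 2``.
    tau
        Delay between pattern samples, in samples, ``>= 1``.

    Returns
    -------
    SymbolSequence of length ``T - (d-1)*tau``.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("series must be 1-D")
    if d < 2:
        raise ValueError("pattern dimension d must be >= 2")
    if int(tau) != tau or tau < 1:
        raise ValueError("delay tau must be a positive integer")
    tau = int(tau)
    min_len = (d - 1) * tau + 1
    if u.size < min_len:
        raise ValueError(
            f"series of length {u.size} too short for d={d}, tau={tau}: "
            f"need at least {min_len} samples"
        )
    if not np.all(np.isfinite(u)):
        raise ValueError("series contains non-finite values")
    windows = _embed(u, d, tau)
    ties = int(np.any(np.diff(np.sort(windows, axis=1), axis=1) == 0, axis=1).sum())
    if ties:
        logger.warning(
            "%d of %d pattern windows contain tied values; ties broken by "
            "position (earlier sample ranks lower)",
            ties,
            windows.shape[0],
        )
    return SymbolSequence(_encode_windows(windows), d=d, tau=tau, start_index=0, label=label)


def symbolize_set(ts: TimeSeriesSet, d: int, tau: int) -> list[SymbolSequence]:
    """Symbolize every channel of a :class:`TimeSeriesSet` with shared
    parameters; all returned sequences share d, tau, start_index and length."""
    out = []
    for label, row in zip(ts.labels, ts.values):
        try:
            out.append(symbolize_series(row, d, tau, label=label))
        except ValueError as exc:
            raise ValueError(f"channel {label!r}: {exc}") from exc
    return out
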