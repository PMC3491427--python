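"""Sliding paired permutation test for condition differences.

At each time point the cross-subject values of a graph metric under two
conditions are compared with a two-sided paired sign-flip permutation
test: the statistic is the absolute mean within-subject difference, and
the null distribution is obtained by randomly flipping the sign of each
subject's difference.  When all ``2^n`` sign patterns number no more than
the requested permutations, the test enumerates them exhaustively;
otherwise a seeded Monte-Carlo sample with the add-one estimator
``p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1)`` is used, so p never
reaches 0.  No multiple-testing correction is applied across time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "ConditionPanel",
    "PermutationTestResult",
    "permutation_test_scalar",
    "sliding_permutation_test",
]


@dataclass
class ConditionPanel:
    """Subjects x time matrix of a metric for one condition."""

    values: np.ndarray
    times: np.ndarray
    subjects: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be subjects x time")
        if self.times.size != self.values.shape[1]:
            raise ValueError("one timestamp per column required")
        if self.subjects is not None and len(self.subjects) != self.values.shape[0]:
            raise ValueError("one subject id per row required")


@dataclass
class PermutationTestResult:
    times: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int | None
    statistic: str = "abs mean paired difference"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.times.shape != self.p_values.shape:
            raise ValueError("times and p_values must align")


def _sign_flip_p(diffs: np.ndarray, n_perm: int, rng: np.random.Generator) -> tuple[float, int]:
    """Two-sided sign-flip p for paired differences; returns (p, n_used)."""
    n = diffs.size
    observed = abs(diffs.mean())
    if observed == 0:
        return 1.0, n_perm
    if 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        stats = np.abs(signs @ diffs) / n
        # exhaustive: exact p over all 2^n equally likely sign patterns
        return float((stats >= observed - 1e-12).mean()), 2**n
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    stats = np.abs(signs @ diffs) / n
    exceed = int((stats >= observed - 1e-12).sum())
    return (1 + exceed) / (n_perm + 1), n_perm


def permutation_test_scalar(a, b, n_perm: int = 2000, seed: int | None = None) -> float:
    """Two-sided paired sign-flip permutation p-value for samples ``a``, ``b``.

    ``a`` and ``b`` are per-subject values of the two conditions (paired by
    position).  Statistic: ``|mean(a - b)|``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D paired samples")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    p, _ = _sign_flip_p(a - b, n_perm, rng)
    return p


def sliding_permutation_test(
    panel_a: ConditionPanel,
    panel_b: ConditionPanel,
    n_perm: int = 2000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Paired sign-flip test at every time point of two aligned panels.

    One seeded generator drives all time points, so the full p series is
    reproducible from ``seed``.
    """
    if panel_a.values.shape != panel_b.values.shape:
        raise ValueError("panels must have identical subjects x time shape")
    if not np.array_equal(panel_a.times, panel_b.times):
        raise ValueError("panels must share the time axis")
    if panel_a.subjects is not None and panel_b.subjects is not None:
        if panel_a.subjects != panel_b.subjects:
            raise ValueError("panels must list the same subjects in the same order")
    rng = np.random.default_rng(seed)
    diffs = panel_a.values - panel_b.values
    p_values = np.empty(diffs.shape[1])
    n_used = n_perm
    for t in range(diffs.shape[1]):
        p_values[t], n_used = _sign_flip_p(diffs[:, t], n_perm, rng)
    return PermutationTestResult(
        times=panel_a.times, p_values=p_values, n_permutations=n_used, seed=seed
    )
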