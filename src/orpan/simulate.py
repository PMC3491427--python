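"""Synthetic benchmarks: coupled Lorenz oscillators and multichannel
ensembles with planted synchronization epochs.

The Lorenz benchmark couples two chaotic Lorenz systems diffusively
through their first components with strength ``g`` (``g = 0``: independent
attractors; ``g = 5``: complete synchronization).  The link-detection
experiment symbolizes the first components of both systems and counts the
fraction of time points with identical order patterns, against a windowed
absolute-Pearson-correlation baseline whose window matches the pattern
span ``w = (d - 1) * tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .symbolize import TimeSeriesSet, symbolize_series

__all__ = [
    "LorenzConfig",
    "DetectionResult",
    "simulate_coupled_lorenz",
    "orpan_detection_rate",
    "correlation_detection_rate",
    "run_lorenz_benchmark",
    "benchmark_frame",
    "GroundTruth",
    "generate_synthetic_ensemble",
]

#: Base initial states of the two Lorenz systems.
X0 = (-1.0, 3.0, 4.0)
Y0 = (-8.0, 8.0, 27.0)


@dataclass
class LorenzConfig:
    """Protocol of the coupled-Lorenz link-detection benchmark.

    Integration at step ``dt``, down-sampling by keeping every
    ``downsample``-th point, then discarding ``transient`` points and
    retaining ``length`` points of the first components.  Initial states
    are the base states jittered uniformly on ``[-jitter, jitter]``.
    """

    g: float = 0.0
    dt: float = 0.001
    downsample: int = 5
    transient: int = 10_000
    length: int = 1_000
    x0: tuple[float, float, float] = X0
    y0: tuple[float, float, float] = Y0
    jitter: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.length < 1 or self.downsample < 1:
            raise ValueError("dt > 0, length >= 1, downsample >= 1 required")


@dataclass
class DetectionResult:
    """Mean link-detection rate of one method at one coupling/dimension."""

    method: str          # "orpan" | "correlation"
    coupling: str        # "coupled" | "uncoupled"
    dimension: int
    rates: np.ndarray    # per-realization detection rates
    n_realizations: int
    seed: int | None

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))


def _lorenz_rhs(t, s, g):
    x1, x2, x3, y1, y2, y3 = s
    return (
        10.0 * (x2 - x1) + g * (y1 - x1),
        x1 * (28.0 - x3) - x2,
        x1 * x2 - 8.0 / 3.0 * x3,
        10.0 * (y2 - y1) + g * (x1 - y1),
        y1 * (28.0 - y3) - y2,
        y1 * y2 - 8.0 / 3.0 * y3,
    )


def simulate_coupled_lorenz(
    cfg: LorenzConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First components ``(x1, y1)`` of two coupled Lorenz systems.

    Integrated with an adaptive embedded Runge-Kutta 4(5) (Dormand-Prince)
    scheme sampled at ``cfg.dt``, down-sampled, transient discarded.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    s0 = np.array(cfg.x0 + cfg.y0, dtype=float)
    s0 += rng.uniform(-cfg.jitter, cfg.jitter, size=6)
    n_keep = cfg.transient + cfg.length
    n_fine = n_keep * cfg.downsample
    t_eval = np.arange(n_fine) * cfg.dt
    sol = solve_ivp(
        _lorenz_rhs,
        (0.0, t_eval[-1]),
        s0,
        method="RK45",
        t_eval=t_eval,
        args=(cfg.g,),
        rtol=1e-6,
        atol=1e-9,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"Lorenz integration failed: {sol.message}")
    x1 = sol.y[0, :: cfg.downsample][cfg.transient : cfg.transient + cfg.length]
    y1 = sol.y[3, :: cfg.downsample][cfg.transient : cfg.transient + cfg.length]
    return x1.copy(), y1.copy()


def orpan_detection_rate(x1, y1, d: int, tau: int) -> float:
    """Fraction of pattern time points at which the two series carry the
    same order-pattern symbol."""
    sx = symbolize_series(x1, d, tau)
    sy = symbolize_series(y1, d, tau)
    return float(np.mean(sx.symbols == sy.symbols))


def correlation_detection_rate(x1, y1, d: int, tau: int) -> float:
    """Windowed absolute Pearson correlation, window ``w = (d - 1) * tau``,
    averaged over consecutive non-overlapping windows."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    w = (d - 1) * tau
    if x1.size != y1.size:
        raise ValueError("series must have equal length")
    if x1.size < w:
        raise ValueError(f"series shorter than one window of {w} samples")
    n_win = x1.size // w
    rs = np.empty(n_win)
    for k in range(n_win):
        a = x1[k * w : (k + 1) * w]
        b = y1[k * w : (k + 1) * w]
        if a.std() == 0 or b.std() == 0:
            import warnings

            warnings.warn(f"zero-variance window {k}: correlation set to 0")
            rs[k] = 0.0
        else:
            rs[k] = abs(np.corrcoef(a, b)[0, 1])
    return float(rs.mean())


def run_lorenz_benchmark(
    n_realizations: int = 100,
    seed: int | None = None,
    tau: int = 30,
    d: int = 2,
    d_hat: int = 6,
    base_cfg: LorenzConfig | None = None,
) -> list[DetectionResult]:
    """Full link-detection grid: {coupled, uncoupled} x {d, d_hat} x
    {order patterns, windowed correlation}.

    Every realization draws fresh jittered initial conditions from one
    seeded generator and is integrated at both couplings.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if base_cfg is None:
        base_cfg = LorenzConfig()
    rng = np.random.default_rng(seed)
    grid = {
        (method, coupling, dim): []
        for method in ("orpan", "correlation")
        for coupling in ("coupled", "uncoupled")
        for dim in (d, d_hat)
    }
    for _ in range(n_realizations):
        for coupling, g in (("coupled", 5.0), ("uncoupled", 0.0)):
            x1, y1 = simulate_coupled_lorenz(replace(base_cfg, g=g), rng=rng)
            for dim in (d, d_hat):
                grid[("orpan", coupling, dim)].append(
                    orpan_detection_rate(x1, y1, dim, tau)
                )
                grid[("correlation", coupling, dim)].append(
                    correlation_detection_rate(x1, y1, dim, tau)
                )
    return [
        DetectionResult(
            method=method,
            coupling=coupling,
            dimension=dim,
            rates=np.array(rates),
            n_realizations=n_realizations,
            seed=seed,
        )
        for (method, coupling, dim), rates in grid.items()
    ]


def benchmark_frame(results: list[DetectionResult]) -> pd.DataFrame:
    """Tidy frame of a detection-rate grid (one row per cell)."""
    return pd.DataFrame(
        {
            "method": [r.method for r in results],
            "coupling": [r.coupling for r in results],
            "dimension": [r.dimension for r in results],
            "mean_rate": [r.mean_rate for r in results],
            "n_realizations": [r.n_realizations for r in results],
        }
    )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic ensemble.

    ``groups`` maps a group name to its channel indices, ``epochs`` to the
    half-open sample interval ``[t0, t1)`` during which those channels share
    one waveform (each seen through a channel-specific strictly increasing
    distortion, so their order patterns agree exactly).
    """

    n_channels: int
    n_samples: int
    groups: dict[str, list[int]]
    epochs: dict[str, tuple[int, int]]

    def active_anchor_range(self, name: str, d: int, tau: int) -> tuple[int, int]:
        """Half-open range of pattern anchors whose whole window lies inside
        the group's epoch."""
        t0, t1 = self.epochs[name]
        return t0, max(t0, t1 - (d - 1) * tau)

    def expected_components(self, d: int, tau: int) -> np.ndarray:
        """Expected component count at every pattern anchor, ignoring
        chance symbol collisions between independent channels."""
        n_anchors = self.n_samples - (d - 1) * tau
        counts = np.full(n_anchors, self.n_channels, dtype=float)
        for name, members in self.groups.items():
            a0, a1 = self.active_anchor_range(name, d, tau)
            a1 = min(a1, n_anchors)
            if a1 > a0:
                counts[a0:a1] -= len(members) - 1
        return counts


def _monotone_distortion(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Channel-specific strictly increasing amplitude distortion."""
    offset = rng.normal(scale=2.0)
    slope = rng.uniform(0.5, 2.0)
    cubic = rng.uniform(0.0, 0.5)
    return offset + slope * u + cubic * u**3


def _smooth_noise(n: int, rng: np.random.Generator, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(rng.normal(size=n + width), kernel, mode="same")[:n]


def generate_synthetic_ensemble(
    n_channels: int,
    n_samples: int,
    groups: dict[str, list[int]] | None = None,
    epochs: dict[str, tuple[int, int]] | None = None,
    noise_sd: float = 1.0,
    seed: int | None = None,
    sampling_rate: float | None = None,
) -> tuple[TimeSeriesSet, GroundTruth]:
    """Multichannel ensemble with planted synchronization epochs.

    During its epoch every channel of a group renders one shared smooth
    waveform through its own strictly increasing distortion — identical
    order patterns, different amplitudes.  Outside epochs (and on
    ungrouped channels) samples are independent smooth noise, so channels
    are functionally disconnected up to chance pattern collisions.
    """
    groups = groups or {}
    epochs = epochs or {}
    if set(groups) != set(epochs):
        raise ValueError("groups and epochs must list the same names")
    claimed: dict[int, list[str]] = {}
    for name, members in groups.items():
        t0, t1 = epochs[name]
        if not (0 <= t0 < t1 <= n_samples):
            raise ValueError(f"epoch {name!r} = [{t0}, {t1}) outside [0, {n_samples}]")
        for ch in members:
            if not 0 <= ch < n_channels:
                raise ValueError(f"group {name!r}: channel {ch} out of range")
            for other in claimed.get(ch, []):
                if _overlaps(epochs[other], epochs[name]):
                    raise ValueError(
                        f"channel {ch} assigned to overlapping groups "
                        f"{other!r} and {name!r}"
                    )
            claimed.setdefault(ch, []).append(name)
    rng = np.random.default_rng(seed)
    values = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        values[ch] = noise_sd * _smooth_noise(n_samples, rng)
    for name, members in groups.items():
        t0, t1 = epochs[name]
        waveform = _smooth_noise(t1 - t0, rng)
        for ch in members:
            values[ch, t0:t1] = _monotone_distortion(waveform, rng)
    labels = [f"ch{idx}" for idx in range(n_channels)]
    ts = TimeSeriesSet(labels=labels, values=values, sampling_rate=sampling_rate)
    truth = GroundTruth(
        n_channels=n_channels, n_samples=n_samples, groups=dict(groups), epochs=dict(epochs)
    )
    return ts, truth


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]
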