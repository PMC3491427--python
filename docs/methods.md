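# Methods

## Model

A real-valued series *u(t)*, *t = 1…T*, is encoded by order patterns: the
symbol at *t* is the permutation of ranks of the window
*(u(t), u(t+τ), …, u(t+(d−1)τ))*, with rank 1 the smallest value. For
*d = 2* this reduces to increase/decrease; in general there are *d*!
patterns and the symbol series has length *T − (d−1)τ*. Symbols are stored
as the lexicographic rank of the permutation (Lehmer code), a bijection
over the *d*! patterns; any bijection would do for connectivity, but one
must be pinned for serialization, and lexicographic rank makes
"12…d" ↦ 0 and "d…21" ↦ d!−1.

Two channels *i, j* are functionally connected at *t* iff their symbols at
*t* are equal. The resulting graph at every *t* is a disjoint union of
cliques — one clique per symbol value in use — so the number of connected
components equals the number of distinct symbols present, every defined
(degree ≥ 2) node clustering is exactly 1, and pairwise graph distances
are 0, 1 or ∞. These are asserted as hard invariants in the tests.

**Ties.** Tied window values are rare in continuous-valued data. They are
broken deterministically by position (earlier sample gets the smaller rank,
via a stable sort) and a warning counts affected windows, so quantized
inputs behave reproducibly rather than erroring or desynchronizing.
Non-finite samples are rejected outright: silently skipping them would
desynchronize channels.

## Parameter estimation

- **Delay τ**: first local minimum of the auto-mutual-information, MI
  between *u(t)* and *u(t+ℓ)*, estimated on a joint histogram with
  equal-width bins (default 100 per marginal; zero cells contribute zero;
  MI in bits). The first ℓ with MI(ℓ) < MI(ℓ−1) and MI(ℓ) ≤ MI(ℓ+1) is
  taken; when the profile has no local minimum in range, the global
  arg-min is returned with a warning. Too few bins flatten the profile and
  inflate the estimate (tested as a directional property); on signals whose
  MI profile has a broad shallow basin the three-point rule is sensitive to
  estimator jitter, which is why estimates are aggregated across channels.
- **Dimension d**: Kennel false-nearest-neighbour criterion, Euclidean
  metric, relative growth threshold rtol = 10, absolute growth threshold
  atol = 2 standard deviations, Theiler window of one delay to exclude
  temporal neighbours. The smallest *d* in 2…max_d whose FNN fraction is at
  or below the acceptance threshold is returned; if none qualifies, max_d
  with a non-convergence flag (white noise behaves this way by design).
  The acceptance threshold defaults to **0.10**: on short series
  (~10³ points) the FNN fraction of a clean low-dimensional attractor
  plateaus at a few percent because nearest-neighbour distances are large,
  so a 1% cutoff systematically overshoots the dimension; 10% is the
  practical cutoff at these lengths and is what the Lorenz benchmark
  resolves to d = 2 with.
- **Aggregation** across channels: mode of the dimension estimates (ties
  broken toward the smaller, cheaper dimension — it is over-embedded
  afterwards anyway) and arithmetic mean of the delays rounded half away
  from zero. The aggregated τ is rounded once, before the span Δt is
  derived from it.
- **Over-embedding**: symbolization uses d̂ = 2d + 2. Longer patterns make
  chance matches between independent channels vanishingly rare and buffer
  non-stationarity; the Lorenz experiment quantifies the effect (uncoupled
  false-positive rate 0.5 at d=2 vs ~0.01 at d̂=6).
- **Realignment**: a pattern anchored at *t* spans Δt = (d̂−1)τ samples, so
  network timestamps are shifted to the window centre, t* = t + Δt/2
  (fractional samples; milliseconds when a sampling rate is supplied).

## Graph measures

Density ρ = Σ_{i≠j} A_ij / (N(N−1)) counts ordered pairs, so ρ ∈ [0, 1]
with the complete graph at 1. Node clustering C_i = 2E_i/(k_i(k_i−1)) with
E_i the links among i's neighbours; **nodes of degree < 2 enter the network
average with C_i = 0** rather than being excluded — in clique-union graphs
averaging only defined nodes would make C ≡ 1 identically, whereas the
zero convention lets C grow with density while the normalized C′ = C/ρ
falls, which is the diagnostic behaviour of interest. C′ is reported as
missing (NaN) for empty graphs, and infinite distances are serialized as
missing values, never as a large sentinel number.

Implementations are dense numpy/scipy (csgraph for components, BFS for
distances); networkx serves as an independent oracle in the tests on
general random graphs, not just clique unions.

## Permutation test

Condition comparisons use a two-sided paired sign-flip test per time
point: statistic |mean(a_s − b_s)| over subjects s, null generated by
flipping each subject's difference sign. When 2ⁿ ≤ n_perm (default 2000)
all sign patterns are enumerated and the p-value is exact; otherwise a
seeded Monte-Carlo sample with the add-one estimator
p = (1 + #exceedances)/(n_perm + 1), bounded below by 1/(n_perm+1). One
generator drives the whole sliding series, so results are reproducible
from the recorded seed. No multiple-testing correction is applied across
time; 0.05/0.01 are reference levels only.

## Lorenz benchmark

Two Lorenz systems (σ=10, r=28, b=8/3) coupled diffusively through their
first components with strength g; the coupling term in the ẏ₁ equation is
g(x₁−y₁), symmetric with the x-equation. Integration uses scipy's RK45
(Dormand–Prince 4(5), adaptive) sampled at dt = 0.001, rtol 1e-6 / atol
1e-9; the solution is down-sampled by keeping every 5th point, the first
10 000 retained points are discarded as transient and the next 1000 kept.
The transient is counted after down-sampling so the analysis window sits
long after synchronization (g=5) or decorrelation (g=0) is complete.
Initial states are (−1,3,4) and (−8,8,27) jittered independently and
uniformly on [−0.5, 0.5] per realization.

Detection rate per realization: fraction of time points with identical
symbols (order patterns, τ=30; d=2 and d̂=6), or the mean over consecutive
non-overlapping windows of length w = (d−1)τ of the **absolute** Pearson
correlation — signed correlation would average toward zero on uncoupled
data and misrepresent the baseline's false-positive behaviour. Windows
with zero variance contribute 0 with a warning. The experiment grid is
averaged over 100 seeded realizations (both in the test suite and in
`scripts/acceptance.py`), which puts Monte-Carlo error on the grid means
near 0.01 while keeping the full run under a minute.

## Synthetic multichannel generator

Channels are independent smooth noise (white Gaussian convolved with a
5-sample boxcar, so the decorrelation time is ~5 samples). During a planted
epoch, the channels of a group render one shared smooth waveform, each
through its own strictly increasing distortion
(offset + positive-slope linear + positive cubic term) — their order
patterns agree exactly while their amplitudes differ, which is precisely
the invariance the method exploits. The ground truth object reports, for
any (d, τ), the anchor range whose whole pattern window lies inside the
epoch and the expected component count ignoring chance collisions.

What the generator does **not** emulate: volume conduction / shared
reference artifacts, 1/f spectra, oscillatory rhythms, trial-to-trial
variability, or graded (non-identical) coupling. Passing tests therefore
demonstrate correct mechanics of symbolization, network construction and
epoch recovery, not performance on real electrophysiological recordings.
Because patterns of smoothed noise are serially correlated, chance symbol
collisions between independent channels exceed the uniform 1/d! rate when
τ is shorter than the noise decorrelation time; analyses (and tests) use
τ at or above that time, which is also what the MI criterion would select.

## Numerical and design choices

- Symbol encoding is int64; d ≤ 20 stays within range, far beyond practical
  pattern dimensions (d̂ = 8 is typical).
- FNN nearest neighbours come from a k-d tree query of 2·(Theiler)+5
  candidates with a brute-force fallback when all candidates are temporal
  neighbours.
- The delay estimator keeps the raw three-point first-local-minimum
  definition rather than smoothing the MI profile; robustness is obtained
  by aggregating across channels, not by altering the criterion.
- Edge lists (realigned time, source, target) are the canonical network
  interchange format; reading one back, together with the run manifest's
  time axis and labels, reconstructs every adjacency matrix exactly
  (components are recovered by union-find; in clique-union graphs
  connectivity determines adjacency).
- Degenerate inputs: constant series yield MI 0 with a degenerate-histogram
  warning; all-zero difference panels yield p = 1; empty network sequences
  refuse to serialize rather than writing partial output.

## Known limitations

- The identity criterion makes connectivity binary; graded similarity
  between patterns (e.g. edit-distance weighting) is out of scope.
- FNN and MI estimates on very short or strongly non-stationary channels
  are noisy; the mode/mean aggregation assumes the channels are broadly
  comparable.
- The permutation test treats time points independently; clusters of
  significance across time are not corrected for.
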