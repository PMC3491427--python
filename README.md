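# orpan

Time-evolving functional connectivity from order-pattern symbolic dynamics.

Most connectivity measures (correlation, coherence, Granger causality) need
long, stationary records, which stimulus-locked electrophysiology rarely
provides. `orpan` instead coarse-grains each channel of a multivariate time
series into **order patterns**: the symbol at time *t* is the permutation
describing the relative ranks of the *d* values
*u(t), u(t+τ), …, u(t+(d−1)τ)*, one of *d*! possibilities. Two channels are
declared functionally connected at *t* exactly when their symbols are
identical — no similarity threshold is needed, and the encoding is exactly
invariant under any strictly increasing amplitude distortion (gain
differences, drifts, monotone sensor nonlinearities).

From *N* channels of length *T* this yields a sequence of
*T − (d−1)τ* binary *N×N* networks, each a disjoint union of cliques
(one clique per symbol in use). The package provides:

- **symbolization** — rank patterns, lexicographic (Lehmer) integer
  encoding, per-channel and whole-set symbolization;
- **parameter estimation** — embedding delay τ from the first local minimum
  of the binned auto-mutual-information, dimension *d* from false nearest
  neighbours, aggregation across channels (mode of *d*, mean τ),
  over-embedding *d̂ = 2d + 2*, and window-centre time realignment
  *t\* = t + (d̂−1)τ/2*;
- **network construction** — adjacency sequences with realigned timestamps,
  edge-list/GraphML export;
- **graph metrics over time** — link density ρ, clustering coefficient C,
  normalized clustering C′ = C/ρ, connected components, shortest paths;
- **statistics** — a sliding two-sided paired sign-flip permutation test
  (exhaustive when 2ⁿ permutations fit the budget, seeded Monte-Carlo
  otherwise) for cross-subject condition comparisons;
- **synthetic benchmarks** — two diffusively coupled Lorenz systems
  (`ẋ₁ = 10(x₂−x₁) + g(y₁−x₁)`, …) for the link-detection experiment, and a
  multichannel generator with planted synchronization epochs and monotone
  per-channel distortions.

## Worked example

Detecting coupling between two Lorenz oscillators
(`examples/lorenz_benchmark.py`, 10 realizations):

```
     method  coupling  dimension  mean_rate  n_realizations
      orpan   coupled          2   0.998763              10
      orpan   coupled          6   0.984353              10
      orpan uncoupled          2   0.497320              10
      orpan uncoupled          6   0.011882              10
correlation   coupled          2   0.999629              10
correlation   coupled          6   0.999727              10
correlation uncoupled          2   0.864245              10
correlation uncoupled          6   0.529407              10
```

Each row is a mean link-detection rate: the fraction of time points at
which the two oscillators' first components carry the same order pattern
(method `orpan`), or the mean windowed absolute Pearson correlation with
window *(d−1)τ* (method `correlation`). Coupled (g=5) systems synchronize
completely, so both methods report ≈1. Uncoupled (g=0), the rates are false
positives: order patterns at the estimated dimension d=2 match by chance
half the time, but over-embedding to d̂=6 collapses the false-positive rate
to ≈0.01, while windowed correlation stays at 0.86 (w=30) and 0.53 (w=150).

The full pipeline on synthetic multichannel data
(`examples/synthetic_pipeline.py`):

```
networks built: 582 (= 600 - (4-1)*6)
components inside epoch:  6.21
components outside epoch: 8.23
density inside epoch:     0.168
density outside epoch:    0.043
```

The four channels sharing a waveform during the planted epoch merge into
one clique, visible as a dip in the component count and a rise in link
density exactly over the (realigned) epoch.

There is also a thin CLI: `orpan estimate-params`, `orpan symbolize`,
`orpan build-networks`, `orpan metrics`, `orpan permtest`,
`orpan lorenz-benchmark`, `orpan synth` and `orpan run-all` (estimate →
symbolize → networks → metrics). Inputs are CSV/TSV matrices with rows =
channels (a flag accepts the transposed layout); outputs are edge-list and
tidy-metric TSVs plus a JSON run manifest.

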