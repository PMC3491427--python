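"""Link detection between two Lorenz oscillators: order patterns vs correlation.

Runs a reduced detection-rate grid (10 realizations) of the coupled
(g=5, fully synchronized) and uncoupled (g=0) two-oscillator benchmark.
Rates are the fraction of time points at which the two first components
carry identical order patterns (or, for the baseline, the mean windowed
absolute Pearson correlation with window (d-1)*tau).
"""

from orpan import run_lorenz_benchmark, benchmark_frame

results = run_lorenz_benchmark(n_realizations=10, seed=1)
print(benchmark_frame(results).to_string(index=False))

# Coupled rates are ~1 for both methods.  Uncoupled, the order-pattern
# false-positive rate collapses from ~0.5 at d=2 to ~0.02 at the
# over-embedded d=6, while windowed correlation stays at ~0.85 (w=30) and
# ~0.55 (w=150): over-embedding suppresses chance matches, correlation
# cannot tell short-window coincidence from coupling.
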