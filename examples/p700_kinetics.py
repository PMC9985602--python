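"""Physiology arithmetic: chlorophyll a, qPCR fold change, P700 kinetics.

Simulates a far-red P700+ re-reduction trace (rate constant k = 0.5 /s,
instrument noise), normalizes it to the pre-light-off maximum, and extracts
the initial re-reduction rate — the cyclic-electron-flow index.
"""

from hypermut import (
    AbsorbancePair,
    ExpressionMeasurement,
    chlorophyll_a,
    fold_expression,
    initial_rereduction_rate,
    normalize_p700,
    simulate_trace,
)

chl = chlorophyll_a(AbsorbancePair(A665=0.5, A720=0.1))
print(f"chlorophyll a: {chl:.5f} ug/mL  (12.9447 x (A665 - A720))")

fold = fold_expression(ExpressionMeasurement(20, 15, 24, 15))
print(f"qPCR fold change: {fold:.0f}x  (ddCt = -4 -> 2^4)")

trace = simulate_trace(k=0.5, noise_sd=0.002, seed=3)
norm = normalize_p700(trace, "FR-rereduction")
k_hat = initial_rereduction_rate(norm)
print(f"P700+ re-reduction initial rate: {k_hat:.3f} /s (true k = 0.5)")

# The initial slope after the far-red light turns off indexes cyclic
# electron flow around photosystem I; the fit uses the longest window
# within 0.3 s that keeps R^2 >= 0.99.
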