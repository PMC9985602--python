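"""Estimate a mutation-rate fold change from simulated plating counts.

Simulates a rifampicin-resistance plating assay: a hypermutator at 130x the
wild-type resistant-cell frequency (1e-8), 3 replicates of 2e9 plated
cells against 12 wild-type replicates, then recovers the fold change.
"""

from hypermut import PlatingSimSpec, relative_rate, simulate_plating, survival_rate

wt = simulate_plating(PlatingSimSpec(1e-8, n_replicates=12, strain_id="WT", seed=1))
mutator = simulate_plating(PlatingSimSpec(130e-8, n_replicates=3, strain_id="HS84", seed=2))

res = relative_rate(mutator, wt)
print(f"mean frequency:  {res.mean_frequency:.3e} +/- {res.sd_frequency:.1e}")
print(f"fold change:     {res.fold_change:.1f}x wild type (truth: 130x)")
print(f"t-test p-value:  {res.p_value:.2e}  (n = {res.n} replicates)")

s, l = survival_rate(1000, 10_000)
print(f"mutagen survival example: {s:.0%} survival = {l:.0%} lethality")

# The fold change is the ratio of mean resistant-cell frequencies; Poisson
# counting noise at ~20 colonies/plate for the reference dominates the error.
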