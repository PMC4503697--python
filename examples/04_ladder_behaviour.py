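"""Inspect the tempering ladder: alive counts per chain and swap health.

The Dirichlet concentration decreases along the ladder from 30 (all
components merged and alive) to 0.5**30 (unsupported components
emptied).  Alive counts should fall monotonically in expectation and
stabilise over the last several chains; adjacent-pair swap acceptance
should be positive everywhere.
"""

import overmix as om

y, _ = om.sample_mixture(om.sim_spec(2, n=200, seed=7))
draws = om.run_zmix(
    y, om.SamplerConfig(K=10, n_iter=5_000, burn_in=1_500, seed=3)
)

alive = draws.alive_counts_all.mean(axis=0)
rates = draws.swap_acceptance_rates()
print(f"{'chain':>5} {'alpha':>12} {'mean alive':>11} {'swap acc (j,j+1)':>17}")
for j, (a, m) in enumerate(zip(draws.ladder.alphas, alive), start=1):
    acc = f"{rates[j]:.2f}" if j < draws.ladder.J else "-"
    print(f"{j:>5} {a:>12.3e} {m:>11.2f} {acc:>17}")

# High-alpha chains keep all K components alive; the count decays past
# the d/2 = 1 threshold and flattens at the true order in the deepest
# chains, which is what makes the target chain's count an order estimate.
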