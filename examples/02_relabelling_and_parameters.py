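"""Resolve label switching and summarise the fitted parameters.

Runs the overlapping three-component design, aligns the target-chain
draws per configuration with the allocation-matching relabeller, and
prints posterior means with 95% credible intervals for each group.
"""

import overmix as om
from overmix.postprocess import configuration_probabilities, parameter_summaries

y, labels = om.sample_mixture(om.sim_spec(2, n=200, seed=7))
draws = om.run_zmix(
    y, om.SamplerConfig(K=10, n_iter=6_000, burn_in=2_000, seed=1)
)

results = om.zswitch_run(draws, m=0.5)
probs = configuration_probabilities(results)

for k0, result in sorted(results.items()):
    frac = result.phase_fractions()
    print(f"\nconfiguration k0 = {k0}: p = {probs[k0]:.3f} "
          f"(phase 1 resolved {frac['phase1']:.0%} of iterations)")
    print(parameter_summaries(result).to_string(index=False))

# Each block is one candidate model order.  After relabelling, the
# per-group marginals are unimodal and the means/intervals are directly
# interpretable; without it every group's marginal would look identical.
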