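"""Date one simulated alignment with the independent-rates relaxed clock.

A single mixed-rates replicate is simulated and re-dated under full
calibration (soft bounds on I-VI plus the 180-220 Ma root).  The posterior
summary shows the error-shift signature on a single replicate: the
calibrated low-rate clades I and III are held near 33 Ma while the
uncalibrated placental crown (truth 80 Ma) is pulled markedly older.
Chain lengths here are desk-scale for a quick demonstration.
"""

import numpy as np

from errorshift import (
    CalibrationScheme,
    DatingModel,
    McmcSettings,
    RateScheme,
    build_calibrations,
    build_simulation_tree,
    draw_branch_rates,
    run_mcmc,
    simulate_alignment,
    summarize,
)

tree = build_simulation_tree()
rng = np.random.default_rng(7)
rates = draw_branch_rates(tree, RateScheme.mixed(tree), rng)
aln = simulate_alignment(tree, rates, length=20_000, seed=rng)

model = DatingModel(
    calibrations=build_calibrations(tree, CalibrationScheme.full()),
    rate_prior=(1.0, 7.51),    # mean rate 1/7.51 per 100 Ma (mixed-rates arithmetic)
    sigma2_prior=(1.0, 2.0),   # mean log-rate variance 0.5
)
sample = run_mcmc(aln, tree, model, McmcSettings(generations=6_000, sample_every=5, burnin=1_500, seed=1, chains=1))
summary = summarize(sample)
print(summary[["mean", "ci_lower", "ci_upper", "true_age", "ess"]].round(2))
print("\nposterior mean rate mu: %.4f subs/site per 100 Ma" % sample.mu.mean())
print("posterior log-rate variance sigma2: %.3f (simulated truth 0.274^2 = 0.075;"
      " inflation of sigma2 is how the clock absorbs the parallel deceleration)"
      % sample.sigma2.mean())
if sample.warnings:
    print("warnings:", "; ".join(sample.warnings))
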