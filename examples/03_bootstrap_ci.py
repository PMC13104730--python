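"""Bootstrap confidence intervals for the break-point of one clone.

Resamples growth observations within each concentration stratum (1000
iterations), refits the plateau model each time, and prints percentile
95% CIs for the ILL, plateau elevation and TFL.
"""

from illfit import (BootstrapConfig, CloneSpec, ExperimentDesign,
                    bootstrap_growth_fit, generate_dataset)

truth = CloneSpec("demo", g_slope=1.16, g_breakpoint=0.7,
                  survival_prob=1.0, g_noise_sd=0.03)
records = generate_dataset(ExperimentDesign(seed=11), [truth])

boot = bootstrap_growth_fit(records, BootstrapConfig(n_resamples=1000, seed=1))
for tag in ("ill", "plateau", "tfl"):
    dist, ci = boot[tag]
    print(f"{tag:8s} 95% CI [{ci.lower:.4f}, {ci.upper:.4f}] "
          f"({dist.n_failed} failed refits)")
print("\nEach interval is the 2.5-97.5 percentile range of the statistic "
      "over stratified resamples; the ILL interval should cover the "
      "generating truth of 0.7 mg C/L.")
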