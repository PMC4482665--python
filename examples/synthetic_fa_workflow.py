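"""Fatty-acid mode end to end on a synthetic consumer-resource library.

Generates feeding-trial profiles for three phytoplankton groups (26 FA
tracers), classifies the monoculture profiles, then resolves a mixed
80/10/10 diet -- the many-tracer case where the mixing problem is
well determined.
"""

import numpy as np

from fatracer import (
    MCMCConfig,
    fit_many,
    generate_library,
    simulate_mixed_fa,
    summarize,
    zscore_diagnostic,
)
from fatracer.synthetic import within_group_r2

profiles, lib = generate_library(seed=0)
r2 = within_group_r2(profiles, lib).mean()
z = zscore_diagnostic(profiles)
print(f"Library: {lib.n_groups} groups x {lib.n_tracers} FA tracers, "
      f"{len(profiles)} feeding-trial profiles")
print(f"Within-group profile-vs-mean r^2: {r2:.2f}")
print(f"Dominant-FA z-scores: pooled SD {z.pooled_sd:.2f}, median {z.pooled_median:.2f} "
      f"(approximately standard normal supports the Gaussian likelihood)")

cfg = MCMCConfig.fast(seed=0)
posts, _ = fit_many(profiles, lib, None, cfg)
medians = [np.median(p.draws[:, lib.group_index(c.label)]) for p, c in zip(posts, profiles)]
print(f"\nMonoculture classification: true-group posterior median "
      f"min {min(medians):.3f}, mean {np.mean(medians):.3f} over {len(profiles)} cases")

consumers = simulate_mixed_fa([0.8, 0.1, 0.1], lib.raw_profiles, n=50, seed=1)
_, pooled = fit_many(consumers, lib, None, cfg)
print("\nPooled posterior for the 80/10/10 mixed diet:")
print(summarize(pooled).round(3).to_string())
print(
    "\nWith 26 group-diagnostic tracers the mixed diet is recovered"
    "\naccurately and precisely -- unlike the two-isotope case, where the"
    "\nsame scenario pulls halfway to the generalist prior."
)
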