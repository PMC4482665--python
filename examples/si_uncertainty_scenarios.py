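"""Full-uncertainty stable-isotope scenario: prior pull in action.

Simulates consumers on a known 80/10/10 diet with full source and
fractionation uncertainty, fits each independently, and pools the
posteriors.  With only two tracers the pooled medians land roughly halfway
between the truth and the generalist prior (1/3 each) -- the underdetermined
constraint.
"""

import numpy as np

from fatracer import (
    MCMCConfig,
    builtin_si_table1,
    fit_many,
    simulate_mixed_si,
    summarize,
)

lib, frac = builtin_si_table1()
truth = [0.8, 0.1, 0.1]

consumers = simulate_mixed_si(truth, lib, frac, n=50, seed=0)
vals = np.array([c.values for c in consumers])
print(f"Simulated {len(consumers)} consumers: d13C {vals[:,0].mean():.2f} ± "
      f"{vals[:,0].std(ddof=1):.2f} permil, d15N {vals[:,1].mean():.2f} ± "
      f"{vals[:,1].std(ddof=1):.2f} permil")

_, pooled = fit_many(consumers, lib, frac, MCMCConfig(seed=0))
print("\nPooled posterior (true diet: 0.80 diatoms, 0.10, 0.10):")
print(summarize(pooled).round(3).to_string())

med = np.median(pooled.draws[:, 0])
print(
    f"\nThe pooled diatom median ({med:.2f}) sits between the generalist"
    f"\nprior (0.33) and the truth (0.80), and the 95% intervals span most"
    f"\nof [0, 1]: two isotopes cannot pin down three uncertain sources."
)
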