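"""Fixed-scenario operating characteristics for all four approaches.

Simulates the global-null scenario and one heterogeneous scenario (all
existing baskets effective, new basket null) at 500 replicates, analysing
every dataset under all four approaches with the published robust cut-offs,
and prints per-basket rejection percentages.
"""

import numpy as np

from baskex import (
    DEFAULT_STRUCTURE,
    ExnexConfig,
    StudyDesign,
    fixed_scenarios,
    reference_cutoffs,
    run_fixed_study,
)

config = ExnexConfig()
cutoffs = {a: reference_cutoffs(a, "rcap") for a in ("IND", "UNPL", "PL1a", "PL2a")}
design = StudyDesign(
    structure=DEFAULT_STRUCTURE,
    scenarios=fixed_scenarios((1, 3)),
    cutoffs=cutoffs,
    reps=500,
    seed=7,
)
result = run_fixed_study(design, config)

for scen in ("scenario_1", "scenario_3"):
    p = result[("IND", scen)].p_true
    print(f"\n{scen}  (true rates {p.tolist()}): % reject per basket")
    for a in ("IND", "UNPL", "PL1a", "PL2a"):
        oc = result[(a, scen)]
        cells = "  ".join(f"{100 * v:5.1f}" for v in oc.pct_reject)
        print(f"  {a:5s} {cells}   FWER {100 * oc.fwer:5.1f}" if np.isfinite(oc.fwer)
              else f"  {a:5s} {cells}")

print(
    "\nBaskets at the 20% null rate should reject near or below 10%; "
    "baskets at the 40% target rate show power.  In scenario 3 the "
    "borrowing approaches inflate the null new basket's error rate above "
    "the nominal level, while IND holds it by construction."
)
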