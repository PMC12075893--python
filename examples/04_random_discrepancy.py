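"""Pairwise decision discrepancies when the new basket's rate is random.

Existing baskets are fixed at the null rate while the new basket's true
response rate is drawn uniformly from an interval in every replicate.
Whenever two approaches disagree on a basket decision, exactly one of them
is right; the table reports how often each side wins.
"""

from baskex import (
    DEFAULT_STRUCTURE,
    ExnexConfig,
    MCMCSettings,
    RandomScenarioSpec,
    StudyDesign,
    reference_cutoffs,
    run_random_study,
)

config = ExnexConfig()
cutoffs = {a: reference_cutoffs(a, "rcap") for a in ("IND", "UNPL", "PL1a", "PL2a")}
design = StudyDesign(
    structure=DEFAULT_STRUCTURE, scenarios=(), cutoffs=cutoffs, reps=1, seed=5
)

for interval, label in [((0.4, 0.5), "effective"), ((0.1, 0.2), "null")]:
    spec = RandomScenarioSpec(
        fixed_p_existing=[0.2] * 4, new_interval=interval, n_draws=500, seed=5
    )
    res = run_random_study(spec, design, config, MCMCSettings(2, 750, 6000))
    print(f"\nnew basket {label} (p5 ~ U{interval}), existing baskets null:")
    print(res.table.to_string(index=False))

print(
    "\ndiff_prop_correct > 0 favours the row approach.  With a truly "
    "effective new basket the independent analysis wins most disagreements "
    "(borrowing from null baskets drags the new basket down); with a null "
    "new basket the borrowing analysis wins (shrinkage suppresses false "
    "rejections)."
)
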