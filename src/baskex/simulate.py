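"""Operating-characteristic studies for the basket-addition approaches.

Two study types are provided.  The *fixed-scenario* study simulates many
trials at fixed true response-rate vectors and reports, per approach and
basket, the proportion of datasets rejecting the null (type I error where
the basket is truly null, power where it is truly effective), plus
family-wise error, all-correct rates and estimation summaries.  The
*random-scenario* study draws the new basket's true rate uniformly from an
interval in every replicate and tabulates pairwise decision discrepancies
between approaches — replicates where one approach rejects a basket and
another does not — and which side of each discrepancy was correct.

All approaches analyse the *same* simulated datasets within a replicate
(common random numbers), so differences between approaches are not diluted
by simulation noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .calibration import Scenario, _derive_seed, _scenario_key, generate_batch, _TAG_MCMC
from .decisions import APPROACHES, CutoffSet, TrialStructure, normalise_approach
from .model import (
    SIM_MCMC,
    BatchPosterior,
    ExnexConfig,
    MCMCSettings,
    fit_exnex_batch,
    fit_independent_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "OperatingCharacteristics",
    "FixedStudyResult",
    "RandomScenarioSpec",
    "DiscrepancyResult",
    "run_fixed_study",
    "summarise_vs_nominal",
    "run_random_study",
]

# model tags for MCMC seed derivation, disjoint per fitted model shape
_FIT_TAGS = {"exnex_existing": 31, "exnex_all": 32, "indep_new": 33}


@dataclass(frozen=True)
class StudyDesign:
    """A fixed-scenario study: scenarios, per-approach cut-offs, replicates."""

    structure: TrialStructure
    scenarios: tuple[Scenario, ...]
    cutoffs: dict[str, CutoffSet]
    reps: int = 1000
    seed: int = 0
    approaches: tuple[str, ...] = APPROACHES
    q0: float = 0.2
    q1: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(
            self, "approaches", tuple(normalise_approach(a) for a in self.approaches)
        )
        object.__setattr__(
            self,
            "cutoffs",
            {normalise_approach(a): c for a, c in self.cutoffs.items()},
        )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        missing = [a for a in self.approaches if a not in self.cutoffs]
        if missing:
            raise ValueError(f"missing cut-offs for approaches: {missing}")


@dataclass
class OperatingCharacteristics:
    """Per-basket simulation metrics for one (approach, scenario) cell."""

    approach: str
    scenario: str
    p_true: np.ndarray
    reps: int
    pct_reject: np.ndarray
    type1: np.ndarray  # NaN where the basket is not truly null
    power: np.ndarray  # NaN where the basket is not truly at the target rate
    fwer: float  # NaN when no basket is truly null
    all_correct: float
    est_mean: np.ndarray
    est_sd: np.ndarray
    mc_se: np.ndarray


@dataclass
class FixedStudyResult:
    """Results of :func:`run_fixed_study`, indexable by (approach, scenario)."""

    cells: dict[tuple[str, str], OperatingCharacteristics]
    design: StudyDesign

    def __getitem__(self, key: tuple[str, str]) -> OperatingCharacteristics:
        approach, scenario = key
        return self.cells[(normalise_approach(approach), scenario)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: approach, scenario, basket, metric, value, mc_se."""
        rows = []
        for (approach, scen), oc in self.cells.items():
            for k in range(oc.pct_reject.size):
                rows.append(
                    {
                        "approach": approach,
                        "scenario": scen,
                        "basket": k + 1,
                        "metric": "pct_reject",
                        "value": oc.pct_reject[k],
                        "mc_se": oc.mc_se[k],
                    }
                )
                rows.append(
                    {
                        "approach": approach,
                        "scenario": scen,
                        "basket": k + 1,
                        "metric": "est_mean",
                        "value": oc.est_mean[k],
                        "mc_se": oc.est_sd[k] / np.sqrt(oc.reps),
                    }
                )
            for metric, value in (("fwer", oc.fwer), ("all_correct", oc.all_correct)):
                rows.append(
                    {
                        "approach": approach,
                        "scenario": scen,
                        "basket": 0,
                        "metric": metric,
                        "value": value,
                        "mc_se": np.sqrt(max(value * (1 - value), 0.0) / oc.reps)
                        if np.isfinite(value)
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _fit_shared_models(
    Y: np.ndarray,
    structure: TrialStructure,
    approaches: tuple[str, ...],
    config: ExnexConfig,
    mcmc: MCMCSettings,
    master_seed: int,
    key: int,
) -> dict[str, BatchPosterior]:
    """Fit only the models the requested approaches need, once each."""
    K0 = structure.K0
    fits: dict[str, BatchPosterior] = {}
    need_k0 = any(a in ("IND", "PL2a") for a in approaches)
    need_all = any(a in ("UNPL", "PL1a", "PL2a") for a in approaches) and structure.K_new
    need_ind = "IND" in approaches and structure.K_new
    if not structure.K_new:
        need_all = any(a in ("UNPL", "PL1a") for a in approaches)

    def seed_for(tag: str) -> int:
        return _derive_seed(master_seed, key, _TAG_MCMC, _FIT_TAGS[tag])

    if need_k0:
        fits["exnex_existing"] = fit_exnex_batch(
            Y[:, :K0], structure.n_existing, config, replace(mcmc, seed=seed_for("exnex_existing"))
        )
    if need_all:
        fits["exnex_all"] = fit_exnex_batch(
            Y, structure.n, config, replace(mcmc, seed=seed_for("exnex_all"))
        )
    if need_ind:
        fits["indep_new"] = fit_independent_batch(
            Y[:, K0:], structure.n_new, config, replace(mcmc, seed=seed_for("indep_new"))
        )
    return fits


def _assemble(
    approach: str, fits: dict[str, BatchPosterior], K0: int, K_new: int
) -> tuple[np.ndarray, np.ndarray]:
    """(exceed_prob, post_mean) matrices for one approach from shared fits."""
    if approach in ("UNPL", "PL1a"):
        src = fits["exnex_all"] if K_new else fits.get("exnex_all") or fits["exnex_existing"]
        return src.exceed_prob, src.post_mean
    ex = fits["exnex_existing"]
    if not K_new:
        return ex.exceed_prob, ex.post_mean
    new = fits["indep_new"] if approach == "IND" else None
    if approach == "IND":
        prob = np.hstack([ex.exceed_prob, new.exceed_prob])
        mean = np.hstack([ex.post_mean, new.post_mean])
    else:  # PL2a
        alla = fits["exnex_all"]
        prob = np.hstack([ex.exceed_prob, alla.exceed_prob[:, K0:]])
        mean = np.hstack([ex.post_mean, alla.post_mean[:, K0:]])
    return prob, mean


def run_fixed_study(
    design: StudyDesign,
    config: ExnexConfig,
    mcmc: MCMCSettings = SIM_MCMC,
) -> FixedStudyResult:
    """Simulate every (scenario, approach) cell of a fixed-scenario study.

    Within a scenario all approaches see the same ``reps`` simulated
    datasets; each distinct analysis model is fitted once per scenario and
    shared among the approaches that use it.
    """
    structure = design.structure
    cells: dict[tuple[str, str], OperatingCharacteristics] = {}
    for idx, sc in enumerate(design.scenarios):
        if sc.K != structure.K:
            raise ValueError(
                f"scenario {sc.name or idx!r} has {sc.K} baskets, design expects {structure.K}"
            )
        key = _scenario_key(sc, idx)
        Y = generate_batch(sc, design.reps, design.seed, key)
        fits = _fit_shared_models(
            Y, structure, design.approaches, config, mcmc, design.seed, key
        )
        null_mask = sc.p == design.q0
        target_mask = sc.p == design.q1
        truth_reject = sc.p > design.q0
        for approach in design.approaches:
            prob, mean = _assemble(approach, fits, structure.K0, structure.K_new)
            delta = design.cutoffs[approach].delta
            reject = prob > delta[None, :]
            pct = reject.mean(axis=0)
            correct = reject == truth_reject[None, :]
            oc = OperatingCharacteristics(
                approach=approach,
                scenario=sc.name or f"scenario_{idx}",
                p_true=sc.p.copy(),
                reps=design.reps,
                pct_reject=pct,
                type1=np.where(null_mask, pct, np.nan),
                power=np.where(target_mask, pct, np.nan),
                fwer=float(reject[:, null_mask].any(axis=1).mean()) if null_mask.any() else np.nan,
                all_correct=float(correct.all(axis=1).mean()),
                est_mean=mean.mean(axis=0),
                est_sd=mean.std(axis=0, ddof=1),
                mc_se=np.sqrt(pct * (1 - pct) / design.reps),
            )
            cells[(approach, oc.scenario)] = oc
    return FixedStudyResult(cells=cells, design=design)


def summarise_vs_nominal(
    oc: OperatingCharacteristics,
    structure: TrialStructure,
    nominal_type1: float = 0.10,
    nominal_power: float = 0.80,
) -> dict:
    """Absolute gaps between observed rates and their nominal targets.

    Error/power rates are first averaged over the relevant existing baskets,
    then compared with the target; the new-basket gap is reported against
    whichever target applies to its true rate.  A gap with no applicable
    basket is ``None``, never zero.
    """
    K0 = structure.K0
    t1 = oc.type1[:K0]
    pw = oc.power[:K0]
    out: dict[str, float | None] = {
        "existing_error_gap": None,
        "existing_power_gap": None,
        "new_gap": None,
        "new_is_null": None,
    }
    if np.isfinite(t1).any():
        out["existing_error_gap"] = abs(float(np.nanmean(t1)) - nominal_type1)
    if np.isfinite(pw).any():
        out["existing_power_gap"] = abs(float(np.nanmean(pw)) - nominal_power)
    if oc.pct_reject.size > K0:
        new_rate = float(np.mean(oc.pct_reject[K0:]))
        new_null = bool(np.all(np.isfinite(oc.type1[K0:])))
        out["new_is_null"] = new_null
        out["new_gap"] = abs(new_rate - (nominal_type1 if new_null else nominal_power))
    return out


@dataclass(frozen=True)
class RandomScenarioSpec:
    """Random-scenario study: fixed existing rates, uniform new-basket rate."""

    fixed_p_existing: np.ndarray
    new_interval: tuple[float, float]
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.fixed_p_existing, dtype=float))
        object.__setattr__(self, "fixed_p_existing", p)
        lo, hi = self.new_interval
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("new-basket interval must satisfy 0 <= lo <= hi <= 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class DiscrepancyResult:
    """Pairwise decision disagreements and which side was correct.

    ``table`` has one row per approach pair with ``n_discrepant`` (count of
    basket-level decision disagreements) and ``diff_prop_correct`` (among
    those disagreements, proportion decided correctly by the row approach
    minus the column approach; positive favours the row approach).
    """

    table: pd.DataFrame
    spec: RandomScenarioSpec
    details: dict = field(default_factory=dict)

    def pair(self, a: str, b: str) -> pd.Series:
        a, b = normalise_approach(a), normalise_approach(b)
        t = self.table
        row = t[(t.approach_row == a) & (t.approach_col == b)]
        if row.empty:
            row = t[(t.approach_row == b) & (t.approach_col == a)]
            out = row.iloc[0].copy()
            out["approach_row"], out["approach_col"] = a, b
            out["diff_prop_correct"] = -out["diff_prop_correct"]
            return out
        return row.iloc[0]


def run_random_study(
    spec: RandomScenarioSpec,
    design: StudyDesign,
    config: ExnexConfig,
    mcmc: MCMCSettings = SIM_MCMC,
) -> DiscrepancyResult:
    """Simulate the random-scenario discrepancy study.

    One dataset is generated per drawn scenario; the new basket's true rate
    is drawn uniformly from the spec's interval.  Truth for basket ``k`` is
    "reject" iff its true rate exceeds ``q0``, so in a basket-level
    disagreement exactly one side is correct; replicates where both sides
    are wrong are excluded as a safeguard (a no-op under this labelling).
    """
    structure = design.structure
    if structure.K_new != 1:
        raise ValueError("the random-scenario study is defined for one new basket")
    if spec.fixed_p_existing.size != structure.K0:
        raise ValueError("fixed_p_existing must cover the existing baskets")
    lo, hi = spec.new_interval
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
    D = spec.n_draws
    if lo == hi:
        logger.info("degenerate interval: new-basket rate fixed at %g", lo)
        p_new = np.full(D, lo)
    else:
        p_new = rng.uniform(lo, hi, D)
    Y = np.empty((D, structure.K), dtype=np.int64)
    Y[:, : structure.K0] = rng.binomial(
        structure.n_existing[None, :], spec.fixed_p_existing[None, :], size=(D, structure.K0)
    )
    Y[:, structure.K0] = rng.binomial(int(structure.n_new[0]), p_new)

    fits = _fit_shared_models(
        Y, structure, design.approaches, config, mcmc, spec.seed, 0
    )
    p_true = np.broadcast_to(spec.fixed_p_existing, (D, structure.K0))
    p_true = np.hstack([p_true, p_new[:, None]])
    truth = p_true > design.q0

    rejects: dict[str, np.ndarray] = {}
    for approach in design.approaches:
        prob, _ = _assemble(approach, fits, structure.K0, structure.K_new)
        rejects[approach] = prob > design.cutoffs[approach].delta[None, :]

    rows = []
    for a, b in combinations(design.approaches, 2):
        ra, rb = rejects[a], rejects[b]
        disagree = ra != rb
        a_correct = disagree & (ra == truth)
        b_correct = disagree & (rb == truth)
        usable = a_correct | b_correct  # both-wrong exclusion (no-op here)
        n_disc = int(usable.sum())
        diff = (
            (int(a_correct.sum()) - int(b_correct.sum())) / n_disc if n_disc else np.nan
        )
        rows.append(
            {
                "approach_row": a,
                "approach_col": b,
                "n_discrepant": n_disc,
                "diff_prop_correct": diff,
            }
        )
    return DiscrepancyResult(
        table=pd.DataFrame(rows), spec=spec, details={"p_new": p_new, "rejects": rejects}
    )
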