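"""Cut-off calibration by simulation: global-null and robust (multi-scenario).

The efficacy cut-offs ``Delta_k`` are chosen so that the basket-wise type I
error rate is controlled at a nominal level ``alpha``.  Classically this is
done under the *global null* (every basket's true rate equals ``q0``): the
cut-off is the empirical ``(1 - alpha)``-quantile of the null exceedance
probabilities ``Q = P(p_k > q0 | data)`` over simulated datasets.

The robust calibration procedure generalises this to a weighted collection
of scenarios.  For each scenario ``m`` (true rate vector ``p_m``, sample
sizes ``n_m``, positive integer weight ``omega_m``), ``R`` datasets are
simulated and the model fitted; whenever a basket is truly null
(``p_mk == q0``), ``omega_m`` copies of its ``Q`` are appended to a pooled
store.  Stores of baskets sharing a sample size (under the same calibration
model) are pooled, and the cut-off for that sample-size class is the
empirical ``(1 - alpha)``-quantile of the pooled store — so the type I error
is controlled *on average* across the scenarios, and equal-sized baskets
receive identical cut-offs by construction.

The quantile is the order statistic at rank ``ceil((1 - alpha) * N)`` (no
interpolation): with the strict rejection rule ``Q > Delta`` at most
``alpha * N`` of the stored values would reject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .decisions import CutoffSet, TrialStructure, normalise_approach
from .model import (
    BasketData,
    ExnexConfig,
    MCMCSettings,
    fit_exnex_batch,
    fit_independent_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "CalibrationSpec",
    "generate_trial",
    "generate_batch",
    "rcap_calibrate",
    "calibrate_global_null",
    "match_cutoff_by_sample_size",
    "calibrate_approach",
    "global_null_spec",
]

# integer tags keeping the data-generation and MCMC seed substreams disjoint
_TAG_DATA = 11
_TAG_MCMC = 23
_MODEL_CODES = {"exnex": 1, "independent": 2}


@dataclass(frozen=True)
class Scenario:
    """A true response-rate vector with sample sizes and an integer weight.

    ``seed_key`` identifies the scenario's random substream; it defaults to
    the scenario's position in the list it is used from.  Giving two
    scenario entries the same key makes them reuse identical simulated
    datasets, which is how integer weights and repeated scenario entries are
    made exactly equivalent.
    """

    p: np.ndarray
    n: np.ndarray
    weight: int = 1
    name: str = ""
    seed_key: int | None = None

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        n = np.atleast_1d(np.asarray(self.n, dtype=np.int64))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "n", n)
        if p.shape != n.shape:
            raise ValueError("p and n must have equal length")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("true response rates must lie in [0, 1]")
        if np.any(n <= 0):
            raise ValueError("sample sizes must be positive")
        if int(self.weight) != self.weight or self.weight < 1:
            raise ValueError("weight must be a positive integer")

    @property
    def K(self) -> int:
        return int(self.p.size)


@dataclass(frozen=True)
class CalibrationSpec:
    """Everything one calibration run needs.

    ``model`` selects the analysis model fitted to each simulated dataset:
    ``"exnex"`` (borrowing across the scenario's baskets) or
    ``"independent"``.  ``metric`` is a hook for generalisation; only the
    basket-wise type I error metric is implemented.
    """

    scenarios: tuple[Scenario, ...]
    R: int
    alpha: float
    q0: float
    model: str = "exnex"
    metric: str = "type1"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        if len(self.scenarios) == 0:
            raise ValueError("need at least one scenario")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.model not in _MODEL_CODES:
            raise ValueError(f"unknown calibration model {self.model!r}")
        if self.metric != "type1":
            raise NotImplementedError("only the type I error metric is shipped")


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def generate_trial(scenario: Scenario, rng: np.random.Generator) -> BasketData:
    """Simulate one trial: ``y_k ~ Binomial(n_k, p_k)`` independently."""
    y = rng.binomial(scenario.n, scenario.p)
    return BasketData(y=y, n=scenario.n)


def generate_batch(scenario: Scenario, R: int, master_seed: int, key: int) -> np.ndarray:
    """Simulate ``R`` datasets as a (R, K) matrix, one recorded substream per
    (scenario key, replicate) so any single replicate can be regenerated."""
    base = np.random.SeedSequence([master_seed, key, _TAG_DATA])
    children = base.spawn(R)
    Y = np.empty((R, scenario.K), dtype=np.int64)
    for r, child in enumerate(children):
        Y[r] = np.random.default_rng(child).binomial(scenario.n, scenario.p)
    return Y


def _scenario_key(sc: Scenario, idx: int) -> int:
    return idx if sc.seed_key is None else int(sc.seed_key)


def _fit_batch(Y, n, model, config, mcmc):
    if model == "independent":
        return fit_independent_batch(Y, n, config, mcmc)
    return fit_exnex_batch(Y, n, config, mcmc)


def _order_stat_quantile(values: np.ndarray, alpha: float) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    N = v.size
    rank = int(np.ceil((1.0 - alpha) * N))
    rank = min(max(rank, 1), N)
    return float(v[rank - 1])


def _pooled_stores(
    spec: CalibrationSpec, config: ExnexConfig, mcmc: MCMCSettings
) -> dict[int, np.ndarray]:
    """Map sample-size class -> pooled, weight-replicated null Q values."""
    stores: dict[int, list[np.ndarray]] = {}
    for idx, sc in enumerate(spec.scenarios):
        null_mask = sc.p == spec.q0
        if not null_mask.any():
            logger.info(
                "scenario %r has no basket at q0=%g; it contributes nothing "
                "to type-I calibration and is skipped",
                sc.name or f"#{idx}",
                spec.q0,
            )
            continue
        key = _scenario_key(sc, idx)
        Y = generate_batch(sc, spec.R, spec.seed, key)
        run = replace(
            mcmc,
            seed=_derive_seed(spec.seed, key, _TAG_MCMC, _MODEL_CODES[spec.model], sc.K),
        )
        bp = _fit_batch(Y, sc.n, spec.model, config, run)
        for k in np.flatnonzero(null_mask):
            q = np.tile(bp.exceed_prob[:, k], int(sc.weight))
            stores.setdefault(int(sc.n[k]), []).append(q)
    return {nc: np.concatenate(chunks) for nc, chunks in stores.items()}


def rcap_calibrate(
    spec: CalibrationSpec,
    config: ExnexConfig,
    mcmc: MCMCSettings,
    structure: TrialStructure | None = None,
) -> CutoffSet:
    """Robust calibration across the spec's weighted scenarios.

    Per-basket cut-offs are read off the trial's sample sizes (the first
    scenario's ``n``); baskets sharing a sample size share one pooled store
    and hence receive bit-identical cut-offs.  When ``structure`` is given
    the resulting vector is split into existing/new entries, otherwise all
    baskets are reported as existing.
    """
    stores = _pooled_stores(spec, config, mcmc)
    if not stores:
        raise ValueError(
            "no scenario contains a basket at the null rate; type-I "
            "calibration is impossible"
        )
    class_delta = {nc: _order_stat_quantile(q, spec.alpha) for nc, q in stores.items()}
    n_trial = spec.scenarios[0].n
    delta = np.empty(n_trial.size)
    for k, nk in enumerate(n_trial):
        if int(nk) not in class_delta:
            raise ValueError(
                f"no scenario ever nulls a basket of sample size {int(nk)}; "
                "cannot calibrate that class"
            )
        delta[k] = class_delta[int(nk)]
    provenance = {
        "method": "rcap",
        "model": spec.model,
        "alpha": spec.alpha,
        "q0": spec.q0,
        "R": spec.R,
        "seed": spec.seed,
        "scenarios": [
            {"name": sc.name, "p": sc.p.tolist(), "n": sc.n.tolist(), "weight": sc.weight}
            for sc in spec.scenarios
        ],
        "class_delta": {str(k): v for k, v in class_delta.items()},
    }
    if structure is None:
        return CutoffSet(delta_existing=delta, delta_new=np.empty(0), provenance=provenance)
    K0 = structure.K0
    return CutoffSet(
        delta_existing=delta[:K0], delta_new=delta[K0:], provenance=provenance
    )


def global_null_spec(
    n: np.ndarray,
    R: int,
    alpha: float,
    q0: float,
    model: str = "exnex",
    seed: int = 0,
) -> CalibrationSpec:
    """Spec containing the single all-null scenario ``p = (q0, ..., q0)``."""
    sc = Scenario(p=np.full(np.asarray(n).size, q0), n=n, name="global_null", seed_key=0)
    return CalibrationSpec(
        scenarios=(sc,), R=R, alpha=alpha, q0=q0, model=model, seed=seed
    )


def calibrate_global_null(
    spec: CalibrationSpec,
    config: ExnexConfig,
    mcmc: MCMCSettings,
    structure: TrialStructure | None = None,
) -> CutoffSet:
    """Classical calibration under the global null: robust calibration with
    a single all-null scenario."""
    if len(spec.scenarios) != 1 or np.any(spec.scenarios[0].p != spec.q0):
        raise ValueError("global-null calibration needs exactly one all-null scenario")
    cut = rcap_calibrate(spec, config, mcmc, structure=structure)
    cut.provenance["method"] = "global_null"
    return cut


def match_cutoff_by_sample_size(
    delta_existing: np.ndarray, n_existing: np.ndarray, n_new: int
) -> float:
    """Inherit a new basket's cut-off from the existing basket whose sample
    size is nearest (ties broken toward the smallest basket index)."""
    delta_existing = np.atleast_1d(np.asarray(delta_existing, dtype=float))
    n_existing = np.atleast_1d(np.asarray(n_existing))
    if delta_existing.size == 0:
        raise ValueError("no existing cut-offs to match against")
    if delta_existing.size != n_existing.size:
        raise ValueError("delta_existing and n_existing must have equal length")
    i = int(np.argmin(np.abs(n_existing - int(n_new))))
    return float(delta_existing[i])


def _restrict(sc: Scenario, idx: int, keep: slice, K_expected: int) -> Scenario:
    if sc.K == K_expected:
        return replace(sc, seed_key=_scenario_key(sc, idx))
    p, n = sc.p[keep], sc.n[keep]
    if p.size != K_expected:
        raise ValueError(
            f"scenario {sc.name or idx!r} has {sc.K} baskets; cannot restrict "
            f"to {K_expected}"
        )
    return Scenario(
        p=p, n=n, weight=sc.weight, name=sc.name, seed_key=_scenario_key(sc, idx)
    )


def calibrate_approach(
    approach: str,
    structure: TrialStructure,
    scenarios: Sequence[Scenario] | None,
    weights: Sequence[int] | None,
    R: int,
    alpha: float,
    config: ExnexConfig,
    mcmc: MCMCSettings,
    method: str = "global_null",
    seed: int | None = None,
) -> CutoffSet:
    """Calibrate the cut-offs an approach needs, per its calibration models.

    ``method`` is ``"global_null"`` (scenarios ignored; the all-null scenario
    is built from the structure) or ``"rcap"`` (the given scenarios are
    used).  For the robust method, scenarios must cover the full trial
    (length K) for IND/PL1(a)/PL2(a); for UNPL they describe the existing
    baskets only (length K0; full-length scenarios are truncated).
    """
    approach = normalise_approach(approach)
    method = method.replace("-", "_")
    if method not in ("global_null", "rcap"):
        raise ValueError(f"unknown calibration method {method!r}")
    master = int(mcmc.seed if seed is None else seed)
    K0 = structure.K0
    q0 = config.q0

    def _spec(scen_list: Sequence[Scenario], model: str) -> CalibrationSpec:
        return CalibrationSpec(
            scenarios=tuple(scen_list), R=R, alpha=alpha, q0=q0, model=model, seed=master
        )

    def _scen(keep: slice, K_expected: int, n_sub: np.ndarray) -> list[Scenario]:
        if method == "global_null":
            return [Scenario(p=np.full(K_expected, q0), n=n_sub, name="global_null", seed_key=0)]
        if scenarios is None:
            raise ValueError("robust calibration requires a scenario list")
        out = [_restrict(sc, i, keep, K_expected) for i, sc in enumerate(scenarios)]
        if weights is not None:
            if len(weights) != len(out):
                raise ValueError("weights must match the scenario list length")
            out = [replace(sc, weight=int(w)) for sc, w in zip(out, weights)]
        return out

    existing_sl = slice(0, K0)
    new_sl = slice(K0, None)

    if approach == "PL1a":
        cut = rcap_calibrate(
            _spec(_scen(slice(None), structure.K, structure.n), "exnex"),
            config,
            mcmc,
            structure=structure,
        )
        prov = dict(cut.provenance, method=method, approach=approach)
        return CutoffSet(cut.delta_existing, cut.delta_new, prov)

    # all remaining approaches calibrate existing baskets on EXNEX-on-K0
    cut_ex = rcap_calibrate(
        _spec(_scen(existing_sl, K0, structure.n_existing), "exnex"), config, mcmc
    )
    delta_existing = cut_ex.delta_existing

    if approach == "IND":
        cut_new = rcap_calibrate(
            _spec(_scen(new_sl, structure.K_new, structure.n_new), "independent"),
            config,
            mcmc,
        ) if structure.K_new else None
        delta_new = cut_new.delta_existing if cut_new is not None else np.empty(0)
    elif approach == "UNPL":
        delta_new = np.array(
            [
                match_cutoff_by_sample_size(delta_existing, structure.n_existing, nk)
                for nk in structure.n_new
            ]
        )
    else:  # PL2a: new baskets calibrated on EXNEX-on-all-K
        cut_all = rcap_calibrate(
            _spec(_scen(slice(None), structure.K, structure.n), "exnex"),
            config,
            mcmc,
            structure=structure,
        ) if structure.K_new else None
        delta_new = cut_all.delta_new if cut_all is not None else np.empty(0)

    provenance = dict(cut_ex.provenance, method=method, approach=approach)
    return CutoffSet(delta_existing=delta_existing, delta_new=delta_new, provenance=provenance)
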