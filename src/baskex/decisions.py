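"""Efficacy decisions and the four analysis approaches for added baskets.

A trial has ``K0`` *existing* baskets (open from the start) and ``K'`` *new*
baskets added mid-study, typically with smaller sample sizes.  The treatment
is declared effective in basket ``k`` when the posterior exceedance
probability ``P(p_k > q0 | data)`` strictly exceeds a calibrated cut-off
``Delta_k``.  Four approaches differ in which model feeds each decision:

========  =============================  ==============================
Approach  Existing baskets               New baskets
========  =============================  ==============================
IND       EXNEX on the K0 existing       independent model per new basket
UNPL      EXNEX on all K                 EXNEX on all K (cut-off inherited
                                         from the existing-basket
                                         calibration by sample-size match)
PL1(a)    EXNEX on all K                 EXNEX on all K
PL2(a)    EXNEX on the K0 existing       EXNEX on all K
========  =============================  ==============================

UNPL and PL1(a) share the analysis model and differ only through their
calibrated cut-offs; IND and PL2(a) share the existing-basket model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BasketData,
    ExnexConfig,
    MCMCSettings,
    fit_exnex,
    fit_independent,
)

__all__ = [
    "APPROACHES",
    "TrialStructure",
    "CutoffSet",
    "Decision",
    "decide",
    "analyse_trial",
    "normalise_approach",
]

APPROACHES = ("IND", "UNPL", "PL1a", "PL2a")

_APPROACH_ALIASES = {
    "ind": "IND",
    "unpl": "UNPL",
    "pl1a": "PL1a",
    "pl1(a)": "PL1a",
    "pl2a": "PL2a",
    "pl2(a)": "PL2a",
}


def normalise_approach(approach: str) -> str:
    key = str(approach).strip().lower()
    if key not in _APPROACH_ALIASES:
        raise ValueError(
            f"unknown approach {approach!r}; expected one of {APPROACHES}"
        )
    return _APPROACH_ALIASES[key]


@dataclass(frozen=True)
class TrialStructure:
    """Existing/new split of the trial: sample sizes per basket group."""

    n_existing: np.ndarray
    n_new: np.ndarray

    def __post_init__(self) -> None:
        ne = np.atleast_1d(np.asarray(self.n_existing, dtype=np.int64))
        nn = np.asarray(self.n_new, dtype=np.int64).reshape(-1)
        object.__setattr__(self, "n_existing", ne)
        object.__setattr__(self, "n_new", nn)
        if ne.size < 1:
            raise ValueError("need at least one existing basket")
        if np.any(ne <= 0) or (nn.size and np.any(nn <= 0)):
            raise ValueError("sample sizes must be positive integers")

    @property
    def K0(self) -> int:
        return int(self.n_existing.size)

    @property
    def K_new(self) -> int:
        return int(self.n_new.size)

    @property
    def K(self) -> int:
        return self.K0 + self.K_new

    @property
    def n(self) -> np.ndarray:
        return np.concatenate([self.n_existing, self.n_new])


@dataclass(frozen=True)
class CutoffSet:
    """Calibrated cut-offs, split into existing- and new-basket entries."""

    delta_existing: np.ndarray
    delta_new: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        de = np.atleast_1d(np.asarray(self.delta_existing, dtype=float))
        dn = np.asarray(self.delta_new, dtype=float).reshape(-1)
        object.__setattr__(self, "delta_existing", de)
        object.__setattr__(self, "delta_new", dn)
        allv = np.concatenate([de, dn])
        ok = np.isnan(allv) | ((allv > 0.0) & (allv < 1.0))
        if not np.all(ok):
            raise ValueError("cut-offs must lie strictly inside (0, 1)")

    @property
    def delta(self) -> np.ndarray:
        return np.concatenate([self.delta_existing, self.delta_new])


@dataclass(frozen=True)
class Decision:
    """Per-basket efficacy decisions and the probabilities they compare."""

    reject: np.ndarray
    exceed_prob: np.ndarray
    details: dict = field(default_factory=dict)


def decide(exceed_prob: np.ndarray, cutoffs: CutoffSet) -> Decision:
    """Strict comparison ``P(p_k > q0 | D) > Delta_k`` per basket.

    Ties never reject.  A basket whose cut-off is missing (NaN) raises — a
    decision must never fall back to a default threshold.
    """
    prob = np.atleast_1d(np.asarray(exceed_prob, dtype=float))
    delta = cutoffs.delta
    if prob.size != delta.size:
        raise ValueError(
            f"{prob.size} exceedance probabilities vs {delta.size} cut-offs"
        )
    if np.any(np.isnan(delta)):
        raise ValueError("missing cut-off for at least one basket")
    return Decision(reject=prob > delta, exceed_prob=prob)


def analyse_trial(
    approach: str,
    data: BasketData,
    structure: TrialStructure,
    config: ExnexConfig,
    cutoffs: CutoffSet,
    mcmc: MCMCSettings,
) -> Decision:
    """Analyse one observed trial under the given approach and decide.

    All model fits use the same ``mcmc`` settings (and seed), so approaches
    that share a model produce identical exceedance probabilities: UNPL and
    PL1(a) always coincide, as do IND and PL2(a) on existing baskets.
    """
    approach = normalise_approach(approach)
    if data.K != structure.K:
        raise ValueError(f"data has {data.K} baskets, structure expects {structure.K}")
    K0 = structure.K0
    details: dict = {"approach": approach}

    existing = BasketData(y=data.y[:K0], n=data.n[:K0])

    if approach in ("UNPL", "PL1a"):
        fit_all = fit_exnex(data, config, mcmc)
        prob = fit_all.exceed_prob
        details["fit_all"] = fit_all
    elif approach == "IND":
        fit_ex = fit_exnex(existing, config, mcmc)
        prob = fit_ex.exceed_prob
        details["fit_existing"] = fit_ex
        if structure.K_new:
            # each new basket is its own one-basket model; the independent
            # fit has no cross-basket terms so a joint call is equivalent
            new = BasketData(y=data.y[K0:], n=data.n[K0:])
            fit_new = fit_independent(new, config, mcmc)
            prob = np.concatenate([prob, fit_new.exceed_prob])
            details["fit_new"] = fit_new
    elif approach == "PL2a":
        fit_ex = fit_exnex(existing, config, mcmc)
        prob = fit_ex.exceed_prob
        details["fit_existing"] = fit_ex
        if structure.K_new:
            fit_all = fit_exnex(data, config, mcmc)
            # existing-basket posteriors of the all-K fit are kept for
            # transparency but never feed the existing-basket decisions
            details["fit_all"] = fit_all
            prob = np.concatenate([prob, fit_all.exceed_prob[K0:]])
    else:  # pragma: no cover - normalise_approach already guards
        raise ValueError(approach)

    decision = decide(prob, cutoffs)
    return Decision(reject=decision.reject, exceed_prob=prob, details=details)
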