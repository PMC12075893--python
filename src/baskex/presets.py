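"""Preset design: the default 4+1 basket trial and its scenario tables.

The default study has four existing baskets of 24 patients, one new basket
of 14 patients, null rate ``q0 = 0.2`` and target rate ``q1 = 0.4`` (sample
sizes from a Simon two-stage design at 10% type I error / 80% power).  Ten
fixed scenarios mix null (0.2) and effective (0.4) rates; a separate
four-basket table covers every global/partial null of the existing baskets
and drives the robust calibration of the unplanned-addition approach.
"""

from __future__ import annotations

import numpy as np

from .calibration import Scenario
from .decisions import CutoffSet, TrialStructure

__all__ = [
    "DEFAULT_STRUCTURE",
    "Q0",
    "Q1",
    "FIXED_SCENARIO_TABLE",
    "RCAP_SCENARIO_IDS",
    "fixed_scenarios",
    "rcap_scenarios",
    "existing_rcap_scenarios",
    "reference_cutoffs",
]

Q0 = 0.2
Q1 = 0.4

DEFAULT_STRUCTURE = TrialStructure(n_existing=[24, 24, 24, 24], n_new=[14])

#: the ten fixed true-response-rate scenarios of the default design
FIXED_SCENARIO_TABLE: dict[int, tuple[float, ...]] = {
    1: (0.2, 0.2, 0.2, 0.2, 0.2),
    2: (0.4, 0.2, 0.2, 0.2, 0.2),
    3: (0.4, 0.4, 0.4, 0.4, 0.2),
    4: (0.4, 0.4, 0.4, 0.4, 0.4),
    5: (0.2, 0.2, 0.2, 0.2, 0.4),
    6: (0.4, 0.2, 0.2, 0.2, 0.4),
    7: (0.4, 0.4, 0.2, 0.2, 0.2),
    8: (0.4, 0.4, 0.4, 0.2, 0.2),
    9: (0.4, 0.4, 0.2, 0.2, 0.4),
    10: (0.4, 0.4, 0.4, 0.2, 0.4),
}

#: scenario ids used in the robust calibration of IND / PL1(a) / PL2(a)
RCAP_SCENARIO_IDS = (1, 2, 3, 7, 8)

#: existing-basket-only scenarios (every global/partial null of 4 equal-size
#: baskets) used in the robust calibration of the UNPL approach
_EXISTING_RCAP_TABLE: tuple[tuple[float, ...], ...] = (
    (0.2, 0.2, 0.2, 0.2),
    (0.4, 0.2, 0.2, 0.2),
    (0.4, 0.4, 0.2, 0.2),
    (0.4, 0.4, 0.4, 0.2),
)


def fixed_scenarios(
    ids: tuple[int, ...] | None = None,
    structure: TrialStructure = DEFAULT_STRUCTURE,
) -> list[Scenario]:
    """The fixed scenarios (all ten by default) as :class:`Scenario` objects."""
    ids = tuple(FIXED_SCENARIO_TABLE) if ids is None else ids
    return [
        Scenario(
            p=np.array(FIXED_SCENARIO_TABLE[i]),
            n=structure.n,
            name=f"scenario_{i}",
            seed_key=i,
        )
        for i in ids
    ]


def rcap_scenarios(structure: TrialStructure = DEFAULT_STRUCTURE) -> list[Scenario]:
    """Scenarios feeding the robust calibration of IND / PL1(a) / PL2(a)."""
    return fixed_scenarios(RCAP_SCENARIO_IDS, structure)


def existing_rcap_scenarios(
    structure: TrialStructure = DEFAULT_STRUCTURE,
) -> list[Scenario]:
    """Existing-basket scenarios feeding the UNPL robust calibration."""
    return [
        Scenario(p=np.array(p), n=structure.n_existing, name=f"existing_{i + 1}", seed_key=100 + i)
        for i, p in enumerate(_EXISTING_RCAP_TABLE)
    ]


#: calibrated cut-offs (Delta_existing, Delta_new) for the default design at
#: alpha = 0.10, as published for this design; used as fixed inputs when
#: analysing trials or reproducing operating characteristics without
#: re-running the calibration.
_REFERENCE_CUTOFFS: dict[str, dict[str, tuple[float, float]]] = {
    "global_null": {
        "IND": (0.860, 0.900),
        "UNPL": (0.860, 0.860),
        "PL1a": (0.857, 0.841),
        "PL2a": (0.860, 0.841),
    },
    "rcap": {
        "IND": (0.903, 0.890),
        "UNPL": (0.906, 0.906),
        "PL1a": (0.903, 0.902),
        "PL2a": (0.903, 0.902),
    },
}


def reference_cutoffs(
    approach: str, method: str = "rcap", structure: TrialStructure = DEFAULT_STRUCTURE
) -> CutoffSet:
    """Published calibrated cut-offs for the default 4+1 design."""
    from .decisions import normalise_approach

    method = method.replace("-", "_")
    approach = normalise_approach(approach)
    d0, dn = _REFERENCE_CUTOFFS[method][approach]
    return CutoffSet(
        delta_existing=np.full(structure.K0, d0),
        delta_new=np.full(structure.K_new, dn),
        provenance={"method": method, "approach": approach, "source": "reference"},
    )
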