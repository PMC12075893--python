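"""Configuration files, serialisation and packaged fixtures.

A run configuration is a single YAML document with a strict schema: unknown
keys are rejected with the offending field named, missing entries fall back
to the default design's values (``q0 = 0.2``, ``q1 = 0.4``, ``pi = 0.5``,
``rho = 0.3``, prior sd 10).  Every output file carries a provenance block
(package version, seed, configuration hash) so results can be traced to the
exact inputs that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .calibration import Scenario
from .decisions import APPROACHES, CutoffSet, Decision, TrialStructure
from .model import BasketData, ExnexConfig, MCMCSettings
from .simulate import FixedStudyResult

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "read_counts_csv",
    "read_scenarios_yaml",
    "write_cutoffs_json",
    "read_cutoffs_json",
    "write_oc_csv",
    "write_decision_json",
]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything a run needs."""

    structure: TrialStructure
    priors: ExnexConfig
    mcmc: MCMCSettings
    scenarios: tuple[Scenario, ...] = ()
    calibration: dict = field(
        default_factory=lambda: {"method": "rcap", "alpha": 0.10, "reps": 2000}
    )
    study: dict = field(default_factory=lambda: {"reps": 1000, "approaches": list(APPROACHES)})
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "structure": {
                "n_existing": self.structure.n_existing.tolist(),
                "n_new": self.structure.n_new.tolist(),
            },
            "priors": {
                "q0": self.priors.q0,
                "q1": self.priors.q1,
                "pi": np.atleast_1d(np.asarray(self.priors.pi)).tolist(),
                "rho": np.atleast_1d(np.asarray(self.priors.rho)).tolist(),
                "mu_prior_mean": self.priors.mu_prior_mean,
                "mu_prior_sd": self.priors.mu_prior_sd,
                "sigma_prior_scale": self.priors.sigma_prior_scale,
                "indep_prior_mean": self.priors.indep_prior_mean,
                "indep_prior_sd": self.priors.indep_prior_sd,
            },
            "mcmc": dataclasses.asdict(self.mcmc),
            "scenarios": [
                {
                    "name": sc.name,
                    "p": sc.p.tolist(),
                    "n": sc.n.tolist(),
                    "weight": sc.weight,
                    "seed_key": sc.seed_key,
                }
                for sc in self.scenarios
            ],
            "calibration": dict(self.calibration),
            "study": dict(self.study),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_scenario(entry, structure: TrialStructure, idx: int) -> Scenario:
    if isinstance(entry, int):
        # preset id into the default fixed-scenario table
        table = presets.FIXED_SCENARIO_TABLE
        if entry not in table:
            raise ValueError(f"unknown preset scenario id {entry}")
        return Scenario(
            p=np.array(table[entry]), n=structure.n, name=f"scenario_{entry}", seed_key=entry
        )
    _check_keys(dict(entry), {"name", "p", "n", "weight", "seed_key"}, f"scenarios[{idx}]")
    n = entry.get("n", None)
    p = np.asarray(entry["p"], dtype=float)
    if n is None:
        n = structure.n if p.size == structure.K else structure.n_existing
    return Scenario(
        p=p,
        n=np.asarray(n),
        weight=int(entry.get("weight", 1)),
        name=str(entry.get("name", f"scenario_{idx}")),
        seed_key=entry.get("seed_key", None),
    )


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(
        raw,
        {"structure", "priors", "mcmc", "scenarios", "calibration", "study", "seed", "log_level"},
        "config",
    )
    if "structure" not in raw:
        raise ValueError("config requires a 'structure' section")
    s = raw["structure"]
    _check_keys(s, {"n_existing", "n_new"}, "structure")
    structure = TrialStructure(
        n_existing=np.asarray(s["n_existing"]), n_new=np.asarray(s.get("n_new", []))
    )
    pr = dict(raw.get("priors", {}))
    _check_keys(
        pr,
        {
            "q0",
            "q1",
            "pi",
            "rho",
            "mu_prior_mean",
            "mu_prior_sd",
            "sigma_prior_scale",
            "indep_prior_mean",
            "indep_prior_sd",
        },
        "priors",
    )
    q0 = float(pr.get("q0", presets.Q0))
    q1 = float(pr.get("q1", presets.Q1))
    if q1 <= q0:
        raise ValueError(f"priors.q1 ({q1}) must exceed priors.q0 ({q0})")

    def _maybe_vec(x):
        return np.asarray(x, dtype=float) if isinstance(x, (list, tuple)) else float(x)

    priors = ExnexConfig(
        q0=q0,
        q1=q1,
        pi=_maybe_vec(pr.get("pi", 0.5)),
        rho=_maybe_vec(pr.get("rho", 0.3)),
        mu_prior_mean=pr.get("mu_prior_mean", None),
        mu_prior_sd=float(pr.get("mu_prior_sd", 10.0)),
        sigma_prior_scale=float(pr.get("sigma_prior_scale", 1.0)),
        indep_prior_mean=pr.get("indep_prior_mean", None),
        indep_prior_sd=float(pr.get("indep_prior_sd", 10.0)),
    )
    mc = dict(raw.get("mcmc", {}))
    _check_keys(mc, {"n_chains", "n_warmup", "n_samples", "seed", "thin"}, "mcmc")
    mc.setdefault("seed", int(raw.get("seed", 0)))
    mcmc = MCMCSettings(**mc)
    cal = dict(raw.get("calibration", {}))
    _check_keys(cal, {"method", "alpha", "reps"}, "calibration")
    cal = {"method": cal.get("method", "rcap"), "alpha": float(cal.get("alpha", 0.10)), "reps": int(cal.get("reps", 2000))}
    study = dict(raw.get("study", {}))
    _check_keys(study, {"reps", "approaches"}, "study")
    study = {
        "reps": int(study.get("reps", 1000)),
        "approaches": list(study.get("approaches", list(APPROACHES))),
    }
    scenarios = tuple(
        _parse_scenario(e, structure, i) for i, e in enumerate(raw.get("scenarios", []))
    )
    return RunConfig(
        structure=structure,
        priors=priors,
        mcmc=mcmc,
        scenarios=scenarios,
        calibration=cal,
        study=study,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config file must contain a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def make_fixture(name: str) -> tuple[RunConfig, list[Scenario]]:
    """Packaged fixtures: ``"default"`` (the 4+1 design with its scenario
    tables) or ``"tiny"`` (2+1 small baskets for fast tests)."""
    if name == "default":
        cfg = RunConfig(
            structure=presets.DEFAULT_STRUCTURE,
            priors=ExnexConfig(),
            mcmc=MCMCSettings(),
            scenarios=tuple(presets.fixed_scenarios()),
        )
        return cfg, presets.fixed_scenarios() + presets.existing_rcap_scenarios()
    if name == "tiny":
        structure = TrialStructure(n_existing=[8, 8], n_new=[6])
        scen = [
            Scenario(p=np.array(p), n=structure.n, name=f"tiny_{i + 1}", seed_key=i + 1)
            for i, p in enumerate([(0.2, 0.2, 0.2), (0.4, 0.2, 0.2), (0.4, 0.4, 0.2)])
        ]
        cfg = RunConfig(
            structure=structure,
            priors=ExnexConfig(),
            mcmc=MCMCSettings(n_chains=2, n_warmup=400, n_samples=800),
            scenarios=tuple(scen),
            calibration={"method": "rcap", "alpha": 0.10, "reps": 200},
            study={"reps": 200, "approaches": list(APPROACHES)},
        )
        return cfg, scen
    raise ValueError(f"unknown fixture {name!r}; expected 'default' or 'tiny'")


# ---------------------------------------------------------------------------
# flat-file formats
# ---------------------------------------------------------------------------


def read_counts_csv(path: str | Path) -> tuple[BasketData, TrialStructure]:
    """Read observed counts: columns ``basket,label,y,n,is_new``."""
    df = pd.read_csv(path, comment="#")
    required = {"basket", "y", "n", "is_new"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.sort_values(["is_new", "basket"], kind="stable")
    labels = tuple(df["label"].astype(str)) if "label" in df.columns else None
    data = BasketData(y=df["y"].to_numpy(), n=df["n"].to_numpy(), labels=labels)
    is_new = df["is_new"].astype(bool).to_numpy()
    structure = TrialStructure(
        n_existing=df["n"].to_numpy()[~is_new], n_new=df["n"].to_numpy()[is_new]
    )
    return data, structure


def read_scenarios_yaml(path: str | Path, structure: TrialStructure) -> list[Scenario]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["scenarios"] if isinstance(raw, dict) else raw
    return [_parse_scenario(e, structure, i) for i, e in enumerate(entries)]


def _provenance(seed: int | None = None, extra: dict | None = None) -> dict:
    block = {"package": f"baskex {_VERSION}"}
    if seed is not None:
        block["seed"] = seed
    if extra:
        block.update(extra)
    return block


def write_cutoffs_json(
    cutoffs: dict[str, CutoffSet] | CutoffSet, path: str | Path, seed: int | None = None
) -> None:
    if isinstance(cutoffs, CutoffSet):
        cutoffs = {"": cutoffs}
    doc = {"provenance": _provenance(seed), "cutoffs": {}}
    for approach, cut in cutoffs.items():
        doc["cutoffs"][approach] = {
            "delta_existing": cut.delta_existing.tolist(),
            "delta_new": cut.delta_new.tolist(),
            "provenance": cut.provenance,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)


def read_cutoffs_json(path: str | Path) -> dict[str, CutoffSet]:
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for approach, entry in doc["cutoffs"].items():
        out[approach] = CutoffSet(
            delta_existing=np.asarray(entry["delta_existing"], dtype=float),
            delta_new=np.asarray(entry["delta_new"], dtype=float),
            provenance=entry.get("provenance", {}),
        )
    return out


def write_oc_csv(
    result: FixedStudyResult, path: str | Path, config_hash: str | None = None
) -> None:
    """Tidy operating characteristics with a commented provenance header."""
    frame = result.to_frame()
    with open(path, "w") as fh:
        for key, val in _provenance(result.design.seed, {"config_hash": config_hash or ""}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def write_decision_json(
    decision: Decision,
    cutoffs: CutoffSet,
    path: str | Path,
    seed: int | None = None,
    labels: tuple[str, ...] | None = None,
) -> None:
    doc = {
        "provenance": _provenance(seed, {"approach": decision.details.get("approach", "")}),
        "baskets": [
            {
                "basket": k + 1,
                "label": labels[k] if labels else f"basket_{k + 1}",
                "exceed_prob": float(decision.exceed_prob[k]),
                "cutoff": float(cutoffs.delta[k]),
                "reject_null": bool(decision.reject[k]),
            }
            for k in range(decision.reject.size)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
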