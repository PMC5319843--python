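"""Scenario configuration: schema, validation, bundled figure scenarios.

A scenario JSON document has four blocks plus a name::

    {
      "name": "fig2b",
      "params": {"r1": 1, "r2": 10, "rs": 1000, "A": 1.001, "Kmax": null},
      "capacity_mode": "unbounded",
      "policy": {"mode": "fixed", "L1": 3, "L2": 4},
      "init": {"n1": 2, "n2": 2, "K": 5},
      "options": {"t_end": 100},
      "assumed": ["A"]
    }

Unknown keys are rejected; all violations are reported together with their
field paths.  ``policy.B`` may be the string ``"auto"`` to request the
corrected critical entry level derived from the model parameters.  The
``assumed`` list documents caption gaps filled by convention (e.g. the
shared Allee capacity 1.001 for scenarios whose caption omits it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np

from .engine import SimOptions, SwitchPolicy
from .model import ModelParams, SimState

__all__ = [
    "ConfigError",
    "ScenarioConfig",
    "load_config",
    "load_scenario",
    "available_scenarios",
]


class ConfigError(ValueError):
    """Raised with every violation found, each tagged by its field path."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid scenario configuration:\n  " + "\n  ".join(violations))


_PARAM_KEYS = {"r1", "r2", "rs", "A", "Kmax"}
_POLICY_KEYS = {"mode", "L1", "L2", "B"}
_INIT_KEYS = {"n1", "n2", "K"}
_OPTION_KEYS = {"t_end", "rtol", "atol", "max_step", "extinction_floor",
                "output_grid", "method"}
_TOP_KEYS = {"name", "params", "capacity_mode", "policy", "init", "options",
             "assumed"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: parameters, policy, initial state, run options."""

    name: str
    params: ModelParams
    policy: SwitchPolicy
    init: SimState
    options: SimOptions
    assumed: tuple[str, ...] = field(default_factory=tuple)

    @property
    def capacity_mode(self) -> str:
        return "bounded" if self.params.bounded else "unbounded"

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "params": {
                "r1": self.params.r1, "r2": self.params.r2,
                "rs": self.params.rs, "A": self.params.A,
                "Kmax": self.params.Kmax,
            },
            "capacity_mode": self.capacity_mode,
            "policy": {"mode": self.policy.mode},
            "init": {"n1": self.init.n1, "n2": self.init.n2, "K": self.init.K},
            "options": {
                "t_end": self.options.t_end, "rtol": self.options.rtol,
                "atol": self.options.atol,
                "extinction_floor": self.options.extinction_floor,
            },
        }
        for k in ("L1", "L2", "B"):
            v = getattr(self.policy, k)
            if v is not None:
                d["policy"][k] = v
        if self.policy.mode == "adaptive" and self.policy.B is None:
            d["policy"]["B"] = "auto"
        if self.options.max_step is not None:
            d["options"]["max_step"] = self.options.max_step
        if self.options.method != "RK45":
            d["options"]["method"] = self.options.method
        if self.assumed:
            d["assumed"] = list(self.assumed)
        return d

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "ScenarioConfig":
        errs: list[str] = []

        def unknown(block: dict, allowed: set, path: str) -> None:
            for k in block:
                if k not in allowed:
                    errs.append(f"{path}{k}: unknown key")

        if not isinstance(doc, dict):
            raise ConfigError(["document must be a JSON object"])
        unknown(doc, _TOP_KEYS, "")

        def num(block: dict, key: str, path: str, required=True, default=None):
            if key not in block:
                if required:
                    errs.append(f"{path}{key}: missing")
                return default
            v = block[key]
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                errs.append(f"{path}{key}: expected a number, got {v!r}")
                return default
            return float(v)

        pblock = doc.get("params", {})
        unknown(pblock, _PARAM_KEYS, "params.")
        r1 = num(pblock, "r1", "params.")
        r2 = num(pblock, "r2", "params.")
        rs = num(pblock, "rs", "params.", required=False, default=0.0)
        A = num(pblock, "A", "params.")
        Kmax = None
        if pblock.get("Kmax") is not None:
            Kmax = num(pblock, "Kmax", "params.", required=False)
        mode_declared = doc.get("capacity_mode")
        if mode_declared is not None:
            if mode_declared not in ("bounded", "unbounded"):
                errs.append(f"capacity_mode: must be 'bounded' or 'unbounded', got {mode_declared!r}")
            elif (mode_declared == "bounded") != (Kmax is not None):
                errs.append(
                    f"capacity_mode: {mode_declared!r} inconsistent with Kmax={Kmax!r}"
                )

        polblock = doc.get("policy", {"mode": "none"})
        unknown(polblock, _POLICY_KEYS, "policy.")
        pmode = polblock.get("mode", "none")
        L1 = num(polblock, "L1", "policy.", required=(pmode == "fixed"))
        L2 = num(polblock, "L2", "policy.", required=(pmode == "fixed"))
        B = None
        if polblock.get("B") not in (None, "auto"):
            B = num(polblock, "B", "policy.", required=False)
        if L1 is not None and L2 is not None and L1 > L2:
            errs.append(f"policy: switching levels must satisfy L1 <= L2, got {L1} > {L2}")

        iblock = doc.get("init", {})
        unknown(iblock, _INIT_KEYS, "init.")
        n1 = num(iblock, "n1", "init.")
        n2 = num(iblock, "n2", "init.")
        K0 = num(iblock, "K", "init.")

        oblock = doc.get("options", {})
        unknown(oblock, _OPTION_KEYS, "options.")
        okw: dict[str, Any] = {}
        for k in ("t_end", "rtol", "atol", "max_step", "extinction_floor"):
            v = num(oblock, k, "options.", required=False)
            if v is not None:
                okw[k] = v
        if "output_grid" in oblock and oblock["output_grid"] is not None:
            try:
                okw["output_grid"] = np.asarray(oblock["output_grid"], dtype=float)
            except (TypeError, ValueError):
                errs.append("options.output_grid: expected an array of times")
        if "method" in oblock:
            okw["method"] = str(oblock["method"])

        for key, val, path in (("r1", r1, "params.r1"), ("r2", r2, "params.r2"),
                               ("rs", rs, "params.rs"), ("A", A, "params.A")):
            if val is not None and key in ("r1", "r2") and val <= 0:
                errs.append(f"{path}: must be positive, got {val}")
            if val is not None and key == "rs" and val < 0:
                errs.append(f"{path}: must be non-negative, got {val}")
            if val is not None and key == "A" and val <= 0:
                errs.append(f"{path}: must be positive, got {val}")
        if Kmax is not None and Kmax <= 0:
            errs.append(f"params.Kmax: must be positive, got {Kmax}")
        if errs:
            raise ConfigError(errs)

        try:
            params = ModelParams(r1=r1, r2=r2, rs=rs, A=A, Kmax=Kmax)
            policy = SwitchPolicy(mode=pmode, L1=L1, L2=L2, B=B)
            init = SimState(t=0.0, n1=n1, n2=n2, K=K0)
            options = SimOptions(**okw)
        except ValueError as exc:
            raise ConfigError([str(exc)]) from exc

        return cls(
            name=str(doc.get("name", "scenario")),
            params=params, policy=policy, init=init, options=options,
            assumed=tuple(doc.get("assumed", ())),
        )


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a scenario JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError([f"not valid JSON: {exc}"]) from exc
    return ScenarioConfig.from_dict(doc)


def _scenario_dir():
    return resources.files("nomadcolony") / "scenarios"


def available_scenarios() -> list[str]:
    """Names of the bundled figure scenarios."""
    return sorted(
        p.name[:-5] for p in _scenario_dir().iterdir() if p.name.endswith(".json")
    )


def load_scenario(name: str) -> ScenarioConfig:
    """Load a bundled scenario (e.g. ``"fig2b"``) by name."""
    res = _scenario_dir() / f"{name}.json"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        ) from None
    return ScenarioConfig.from_dict(json.loads(text))
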