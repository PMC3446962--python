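"""YAML run configuration: validation, defaults, round-tripping.

A config has four blocks — ``population``, ``dynamics``, ``analysis``,
``output`` — each optional except ``population``.  Unknown keys are
rejected, every constraint is checked before any computation, and a
fully-resolved copy (all defaults expanded) is written alongside every
output directory so any result can be regenerated bit-exactly from the
files it ships with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import DEFAULT_GAP
from .dynamics import RunParams
from .population import InitialOpinionSpec, SubgroupSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class RunConfig:
    n: int
    spec: SubgroupSpec
    init: InitialOpinionSpec
    seed: int
    params: RunParams = field(default_factory=RunParams)
    gap: float = DEFAULT_GAP
    consensus_tol: float = 0.05
    fractions_grid: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10, 0.30)
    sizes_grid: tuple[int, ...] = (100, 200, 500, 1000)
    replicates: int = 20
    shared_initials: bool = True
    out_dir: str = "hkopinion-out"
    plots: bool = False

    def resolved(self) -> dict:
        """Plain-dict form with every default expanded (YAML-dumpable)."""
        init: dict = {"kind": self.init.kind}
        if self.init.kind == "uniform":
            init["interval"] = [float(v) for v in self.init.interval]
        else:
            init["values"] = [float(v) for v in self.init.values]
        if self.init.seed is not None:
            init["seed"] = int(self.init.seed)
        rm = self.params.record_mode
        return {
            "population": {
                "n": int(self.n),
                "levels": [
                    {"epsilon": float(e), "fraction": float(f)} for e, f in self.spec.levels
                ],
                "initial": init,
                "seed": int(self.seed),
            },
            "dynamics": {
                "t_max": int(self.params.t_max),
                "tol": float(self.params.tol),
                "record_mode": rm if isinstance(rm, str) else int(rm),
            },
            "analysis": {
                "gap": float(self.gap),
                "consensus_tol": float(self.consensus_tol),
                "fractions": [float(v) for v in self.fractions_grid],
                "sizes": [int(v) for v in self.sizes_grid],
                "replicates": int(self.replicates),
                "shared_initials": bool(self.shared_initials),
            },
            "output": {"directory": self.out_dir, "plots": bool(self.plots)},
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where!r} block")


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for {key!r}: {msg}")


def parse_config(doc: dict) -> RunConfig:
    """Validate a parsed YAML document into a :class:`RunConfig`."""
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(doc, {"population", "dynamics", "analysis", "output"}, "top-level")
    if "population" not in doc:
        raise ConfigError("missing required 'population' block")

    popb = doc["population"]
    _check_keys(popb, {"n", "levels", "initial", "seed"}, "population")
    _require("n" in popb, "population.n", "required")
    n = popb["n"]
    _require(isinstance(n, int) and n >= 1, "population.n", "must be a positive integer")
    _require("levels" in popb, "population.levels", "required")
    levels = []
    for i, lv in enumerate(popb["levels"]):
        _check_keys(lv, {"epsilon", "fraction"}, f"population.levels[{i}]")
        _require("epsilon" in lv, f"population.levels[{i}].epsilon", "required")
        levels.append((float(lv["epsilon"]), float(lv.get("fraction", 1.0))))
    try:
        spec = SubgroupSpec(levels)
    except ValueError as e:
        raise ConfigError(f"invalid value for 'population.levels': {e}") from e

    initb = popb.get("initial", {"kind": "uniform", "interval": [0.0, 1.0]})
    _check_keys(initb, {"kind", "interval", "values", "seed"}, "population.initial")
    try:
        init = InitialOpinionSpec(
            kind=initb.get("kind", "uniform"),
            interval=tuple(initb.get("interval", (0.0, 1.0))),
            values=tuple(initb["values"]) if "values" in initb else None,
            seed=initb.get("seed"),
        )
    except ValueError as e:
        raise ConfigError(f"invalid value for 'population.initial': {e}") from e
    seed = popb.get("seed", 0)
    _require(isinstance(seed, int) and seed >= 0, "population.seed", "must be a non-negative integer")

    dynb = doc.get("dynamics", {})
    _check_keys(dynb, {"t_max", "tol", "record_mode"}, "dynamics")
    try:
        params = RunParams(
            t_max=int(dynb.get("t_max", 10_000)),
            tol=float(dynb.get("tol", 1e-8)),
            record_mode=dynb.get("record_mode", "final"),
        )
    except ValueError as e:
        raise ConfigError(f"invalid value in 'dynamics' block: {e}") from e

    anab = doc.get("analysis", {})
    _check_keys(
        anab,
        {"gap", "consensus_tol", "fractions", "sizes", "replicates", "shared_initials"},
        "analysis",
    )
    gap = float(anab.get("gap", DEFAULT_GAP))
    _require(gap > 0, "analysis.gap", "must be positive")
    consensus_tol = float(anab.get("consensus_tol", 0.05))
    _require(consensus_tol >= 0, "analysis.consensus_tol", "must be non-negative")
    replicates = anab.get("replicates", 20)
    _require(
        isinstance(replicates, int) and replicates >= 1,
        "analysis.replicates",
        "must be a positive integer",
    )
    fractions_grid = tuple(float(v) for v in anab.get("fractions", (0.01, 0.02, 0.05, 0.10, 0.30)))
    for v in fractions_grid:
        _require(0.0 <= v < 1.0, "analysis.fractions", f"fraction {v} outside [0, 1)")
    sizes_grid = tuple(int(v) for v in anab.get("sizes", (100, 200, 500, 1000)))
    for v in sizes_grid:
        _require(v >= 1, "analysis.sizes", f"size {v} must be positive")

    outb = doc.get("output", {})
    _check_keys(outb, {"directory", "plots"}, "output")

    return RunConfig(
        n=n,
        spec=spec,
        init=init,
        seed=seed,
        params=params,
        gap=gap,
        consensus_tol=consensus_tol,
        fractions_grid=fractions_grid,
        sizes_grid=sizes_grid,
        replicates=replicates,
        shared_initials=bool(anab.get("shared_initials", True)),
        out_dir=str(outb.get("directory", "hkopinion-out")),
        plots=bool(outb.get("plots", False)),
    )


def load_config(path) -> RunConfig:
    """Read, parse and validate a YAML config file."""
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {p}: {e}") from e
    return parse_config(doc)
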