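"""Flat key-value run configuration: parsing, validation, round-tripping.

One dialect for every scenario:

    scenario = growth        # growth | membrane | cannibalistic | spherical
    seed = 1
    steps = 12000
    diag_every = 50
    dump_every = 0
    outdir = runs/demo
    c0 = 0.15                # scenario parameter override (reduced units)

All lengths are in reduced sigma, energies in epsilon, times in reduced LJ
time; concentrations are number densities 1/sigma^3.  Unknown keys are
rejected with the offending line number.  Writing a parsed config is
byte-identical to writing it again after a read (canonical sorted form).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .scenarios import SCENARIOS, ScenarioSpec

__all__ = ["RunConfig", "read_config", "write_config"]

_RUN_KEYS = {
    "scenario": str,
    "seed": int,
    "steps": int,
    "diag_every": int,
    "dump_every": int,
    "outdir": str,
}

_SCENARIO_PARAM_TYPES = (int, float)


@dataclass
class RunConfig:
    """Validated run configuration: run-control keys + scenario overrides."""

    scenario: str
    seed: int = 0
    steps: int = 0
    diag_every: int = 50
    dump_every: int = 0
    outdir: str = "run_output"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{sorted(SCENARIOS)}"
            )
        # scenario generators validate their own parameter values
        self.spec: ScenarioSpec = SCENARIOS[self.scenario](
            seed=self.seed, **self.params
        )

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(canonical_text(self).encode()).hexdigest()[:12]

    def build(self):
        return self.spec.build(
            steps=self.steps,
            diag_every=self.diag_every,
            dump_every=self.dump_every,
            outdir=self.outdir,
        )


def canonical_text(cfg: RunConfig) -> str:
    lines = [
        f"scenario = {cfg.scenario}",
        f"seed = {cfg.seed}",
        f"steps = {cfg.steps}",
        f"diag_every = {cfg.diag_every}",
        f"dump_every = {cfg.dump_every}",
        f"outdir = {cfg.outdir}",
    ]
    lines += [f"{k} = {cfg.params[k]:.10g}" for k in sorted(cfg.params)]
    return "\n".join(lines) + "\n"


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(canonical_text(cfg))


def read_config(path) -> RunConfig:
    run_kw: dict = {}
    params: dict = {}
    valid_params = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _RUN_KEYS:
            typ = _RUN_KEYS[key]
            try:
                run_kw[key] = typ(value)
            except ValueError:
                raise ConfigError(
                    f"{path}:{lineno}: key {key!r} expects {typ.__name__}, "
                    f"got {value!r}"
                )
        else:
            try:
                num = float(value)
            except ValueError:
                raise ConfigError(
                    f"{path}:{lineno}: unknown key {key!r} or non-numeric value"
                )
            params[key] = int(num) if num == int(num) and "." not in value else num
    if "scenario" not in run_kw:
        raise ConfigError(f"{path}: missing required key 'scenario'")
    # reject keys the scenario generator does not know
    from .scenarios import (
        CANNIBAL_DEFAULTS,
        GROWTH_DEFAULTS,
        MEMBRANE_DEFAULTS,
        SPHERICAL_DEFAULTS,
    )

    defaults = {
        "growth": GROWTH_DEFAULTS,
        "membrane": MEMBRANE_DEFAULTS,
        "cannibalistic": CANNIBAL_DEFAULTS,
        "spherical": SPHERICAL_DEFAULTS,
    }.get(run_kw["scenario"], {})
    for key in params:
        if key not in defaults:
            raise ConfigError(
                f"{path}: key {key!r} is not a parameter of scenario "
                f"{run_kw['scenario']!r} (valid: {sorted(defaults)})"
            )
    return RunConfig(params=params, **run_kw)
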