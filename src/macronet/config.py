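"""Configuration files for simulation runs.

A run is described by a flat YAML mapping; unknown keys, type errors and
constraint violations are all reported together.  Defaults follow the
figure-scale study conditions: N=10000 cells, k=4 links, omega=0.01,
random-regular topology, initial counts 9900 type A / 100 type C.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .abm import RunConfig
from .network import TOPOLOGIES, NetworkConfig
from .payoffs import InteractionMatrix, SelectionConfig

__all__ = ["DEFAULTS", "config_load", "config_save", "config_from_dict",
           "config_to_dict", "ConfigError"]

DEFAULTS: dict[str, Any] = {
    "N": 10_000,
    "omega": 0.01,
    "topology": "random-regular",
    "seed": 0,
    "n_A_initial": 9_900,
    "max_generations": 1_000,
    "generation_unit": "sweep",
    "record_every": 1,
    "count_vacated_link": True,
}

_REQUIRED = ("payoff", "k")
_KNOWN = set(DEFAULTS) | set(_REQUIRED)


class ConfigError(ValueError):
    """Raised with a list of every problem found in a config mapping."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    """Validate a config mapping and materialize all defaults."""
    problems: list[str] = []
    for key in raw:
        if key not in _KNOWN:
            problems.append(f"unknown key {key!r}")
    for key in _REQUIRED:
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    if problems:
        raise ConfigError(problems)

    merged = {**DEFAULTS, **raw}
    payoff = merged["payoff"]
    if not (isinstance(payoff, (list, tuple)) and len(payoff) == 4
            and all(isinstance(x, (int, float)) for x in payoff)):
        problems.append(f"payoff must be a list of four numbers [a, b, c, d], got {payoff!r}")
    for key, typ in (("N", int), ("k", int), ("n_A_initial", int),
                     ("max_generations", int), ("record_every", int),
                     ("seed", int)):
        if not isinstance(merged[key], typ) or isinstance(merged[key], bool):
            problems.append(f"{key} must be an integer, got {merged[key]!r}")
    if not isinstance(merged["omega"], (int, float)) or isinstance(merged["omega"], bool):
        problems.append(f"omega must be a number, got {merged['omega']!r}")
    elif not (0 <= merged["omega"] < 1):
        problems.append(f"omega must be in [0, 1), got {merged['omega']}")
    if merged["topology"] not in TOPOLOGIES:
        problems.append(f"topology must be one of {TOPOLOGIES}, got {merged['topology']!r}")
    if merged["generation_unit"] not in ("event", "sweep"):
        problems.append(f"generation_unit must be 'event' or 'sweep', got {merged['generation_unit']!r}")
    if not isinstance(merged["count_vacated_link"], bool):
        problems.append(f"count_vacated_link must be a boolean, got {merged['count_vacated_link']!r}")
    if problems:
        raise ConfigError(problems)

    # constraint validation of the nested dataclasses, reported together
    try:
        return RunConfig(
            network=NetworkConfig(
                N=merged["N"], k=merged["k"],
                topology=merged["topology"], seed=merged["seed"],
            ),
            payoff=InteractionMatrix(*(float(x) for x in payoff)),
            sel=SelectionConfig(float(merged["omega"])),
            n_A_initial=merged["n_A_initial"],
            max_generations=merged["max_generations"],
            generation_unit=merged["generation_unit"],
            record_every=merged["record_every"],
            seed=merged["seed"],
            count_vacated_link=merged["count_vacated_link"],
        )
    except ValueError as exc:
        raise ConfigError([str(exc)]) from exc


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Flat mapping representation; round-trips through config_from_dict."""
    return {
        "payoff": list(cfg.payoff.as_tuple()),
        "k": cfg.network.k,
        "N": cfg.network.N,
        "omega": cfg.sel.omega,
        "topology": cfg.network.topology,
        "seed": cfg.seed,
        "n_A_initial": cfg.n_A_initial,
        "max_generations": cfg.max_generations,
        "generation_unit": cfg.generation_unit,
        "record_every": cfg.record_every,
        "count_vacated_link": cfg.count_vacated_link,
    }


def config_load(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError([f"config file must contain a mapping, got {type(raw).__name__}"])
    return config_from_dict(raw)


def config_save(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
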