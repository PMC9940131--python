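"""Run configuration: validated key-value settings for the CLI.

A :class:`RunConfig` captures everything a run needs — subcommand, design
parameters, prior grammar strings, integration settings, seed and output
format — and round-trips losslessly through a plain mapping (YAML/JSON).
Unknown keys are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["RunConfig", "parse_config", "merge_config"]

_COMMANDS = {"design", "power", "ep", "ss", "compare", "fixtures"}


@dataclass
class RunConfig:
    command: str = "power"
    fixture: str | None = None
    kind: str | None = None          # pg | sw
    clusters: int | None = None      # C
    size: float | None = None        # n (per cluster, or per cluster-period)
    periods: int | None = None       # T
    delta: float | None = None
    sigma: float | None = None
    rho: float | None = None
    alpha: float | None = None
    beta: float = 0.1
    gamma: float | None = None
    icc_prior: str | None = None     # prior grammar string
    sd_prior: str | None = None
    icc_only: bool = False
    framework: str = "freq"          # freq | hybrid
    solve_for: str = "clusters"      # clusters | size
    allow_unequal: bool = False
    budget: float | None = None      # N, measurements per cluster (compare)
    effect: float | None = None      # standardized delta/sigma (compare)
    resolution: float = 0.025
    nodes: int = 129
    tol: float = 1e-6
    draws: int = 100_000
    seed: int = 20220901
    out: str | None = None
    fmt: str = "text"                # text | json | csv

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {sorted(_COMMANDS)}")
        if self.kind is not None and self.kind not in {"pg", "sw"}:
            raise ValueError(f"kind must be 'pg' or 'sw', got {self.kind!r}")
        if self.framework not in {"freq", "hybrid"}:
            raise ValueError(f"framework must be 'freq' or 'hybrid', got {self.framework!r}")
        if self.solve_for not in {"clusters", "size"}:
            raise ValueError(f"solve_for must be 'clusters' or 'size', got {self.solve_for!r}")
        if self.fmt not in {"text", "json", "csv"}:
            raise ValueError(f"fmt must be text, json or csv, got {self.fmt!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {sorted(unknown)}; accepted: {sorted(valid)}"
            )
        return cls(**data)


def parse_config(text: str) -> RunConfig:
    """Parse YAML (or JSON) key-value text into a validated RunConfig."""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping of key: value pairs")
    return RunConfig.from_dict(data)


def merge_config(base: RunConfig, overrides: dict[str, Any]) -> RunConfig:
    """Apply non-None overrides (CLI flags win over file values)."""
    data = base.to_dict()
    for key, val in overrides.items():
        if val is not None:
            data[key] = val
    return RunConfig.from_dict(data)
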