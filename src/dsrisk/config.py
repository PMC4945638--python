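"""Run configuration: a single declarative key/value file (YAML) mirrored by
CLI flags; CLI values override the file."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass(frozen=True)
class RunConfig:
    window_length: int = 400
    nmer_min: int = 19
    nmer_max: int = 23
    count_mode: str = "maximal_runs"          # or sliding_windows
    identity_mode: str = "all_columns"        # or exclude_terminal_gaps
    aggregator: str = "mean"                  # or min
    rounding: str = "half_away_from_zero"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.nmer_min < 1 or self.nmer_max < self.nmer_min:
            raise ValueError(f"invalid N-mer range [{self.nmer_min}, {self.nmer_max}]")
        if self.window_length < self.nmer_max:
            raise ValueError("window length must be >= the largest N-mer")
        if self.count_mode not in ("maximal_runs", "sliding_windows"):
            raise ValueError(f"unknown count mode {self.count_mode!r}")
        if self.identity_mode not in ("all_columns", "exclude_terminal_gaps"):
            raise ValueError(f"unknown identity mode {self.identity_mode!r}")
        if self.aggregator not in ("mean", "min"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.rounding != "half_away_from_zero":
            raise ValueError(f"unknown rounding mode {self.rounding!r}")


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file and apply non-None keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a key/value mapping")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
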