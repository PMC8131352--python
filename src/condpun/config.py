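"""Run configuration: a YAML-serializable bundle of model parameters, sweep
grid and output settings, with a loss-free round trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .experiments import SweepSpec
from .params import ModelParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one run or sweep needs, resolvable from a YAML file.

    Sections: ``model`` (every ModelParams field, including the behavioral
    switches), ``sweep`` (grid, replicates, root seed) and ``output``
    (directory, time-series stride, asymptotic tail fraction).
    """

    params: ModelParams = field(default_factory=ModelParams)
    w_values: tuple = (1.0, 0.5)
    inflicted_costs: tuple = (3.0, 0.9)
    replicates: int = 20
    root_seed: int = 0
    out_dir: str = "condpun_out"
    stride: int = 20
    tail_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction: must lie in (0, 1]")

    def sweep_spec(self) -> SweepSpec:
        return SweepSpec(
            base_params=self.params,
            w_values=tuple(self.w_values),
            inflicted_costs=tuple(self.inflicted_costs),
            replicates=self.replicates,
            root_seed=self.root_seed,
            tail_fraction=self.tail_fraction,
            stride=self.stride,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.params.to_dict(),
            "sweep": {
                "w_values": list(self.w_values),
                "inflicted_costs": list(self.inflicted_costs),
                "replicates": self.replicates,
                "root_seed": self.root_seed,
            },
            "output": {
                "out_dir": self.out_dir,
                "stride": self.stride,
                "tail_fraction": self.tail_fraction,
            },
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {"model", "sweep", "output"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        model = d.get("model", {}) or {}
        sweep = d.get("sweep", {}) or {}
        output = d.get("output", {}) or {}
        params = ModelParams.from_dict(model)
        kwargs: dict[str, Any] = {"params": params}
        for key in ("w_values", "inflicted_costs"):
            if key in sweep:
                kwargs[key] = tuple(sweep.pop(key))
        for key in ("replicates", "root_seed"):
            if key in sweep:
                kwargs[key] = sweep.pop(key)
        if sweep:
            raise ValueError(f"unknown sweep option(s): {sorted(sweep)}")
        for key in ("out_dir", "stride", "tail_fraction"):
            if key in output:
                kwargs[key] = output.pop(key)
        if output:
            raise ValueError(f"unknown output option(s): {sorted(output)}")
        return cls(**kwargs)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; an absent path or empty file yields full defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
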