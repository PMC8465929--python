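"""Run configuration: one document controlling a full run.

A run configuration can be written as a YAML file and/or overridden by
command-line flags (flags win over file values, file values over
defaults).  The resolved configuration is embedded in every output
summary so results are reproducible from their own provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .engine import SimulationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a full synth -> calibrate -> simulate run needs.

    Survey defaults (25 owners, 23 consumers) match the sample sizes the
    calibration procedure was designed around.
    """

    horizon: int = 60
    start_step: int = 3
    spacing: int = 2
    grid_resolution: int = 201
    kappa: float = 0.001
    gamma: float = 0.0
    s_ref: float = 100.0
    convenience: float = 5.0
    taste: float = 5.0
    healthiness: float = 5.0
    seed: int = 2021
    n_stores: int = 25
    n_consumers: int = 23
    missingness_rate: float = 0.1
    catalog_path: str | None = None
    owner_surveys_path: str | None = None
    consumer_surveys_path: str | None = None
    parameters_path: str | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must lie in [0, 1)")

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            horizon=self.horizon,
            start_step=self.start_step,
            spacing=self.spacing,
            grid_resolution=self.grid_resolution,
            kappa=self.kappa,
            gamma=self.gamma,
            s_ref=self.s_ref,
            convenience=self.convenience,
            taste=self.taste,
            healthiness=self.healthiness,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Overrides with value ``None`` are ignored, so command-line flags that
    were not given fall through to the file (or the defaults).
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config file must contain a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
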