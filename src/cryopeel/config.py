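"""Run configuration: a YAML file with one block per model component."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .afm import SensorParams
from .chain import SurfaceModel, TipModel
from .errors import InvalidParameterError

__all__ = ["AnalysisParams", "RunConfig", "default_config", "load_config", "save_config"]


@dataclass
class AnalysisParams:
    prominence: float = 2.0  # N/m, dip prominence for event detection
    n_min: int = 1
    n_max: int = 18
    grid_lo: float = 0.40
    grid_hi: float = 0.90
    grid_step: float = 0.005
    smoothing_window: float = 0.02  # nm
    force_floor: float = 0.05  # nN, detachment threshold

    def __post_init__(self) -> None:
        if self.prominence < 0 or self.smoothing_window <= 0:
            raise InvalidParameterError("invalid analysis parameters")
        if not (0 < self.grid_lo < self.grid_hi) or self.grid_step <= 0:
            raise InvalidParameterError("invalid b_cos_theta grid")


@dataclass
class RunConfig:
    """Everything a full simulate→convert→detect→fit run needs.

    The global ``seed`` propagates to every stochastic stage unless a stage
    block overrides it.
    """

    n_bases: int = 20
    b: float = 0.63
    bond_stiffness: float = 32.6
    seed: int = 1
    z_max: float = 13.5
    dz: float = 0.002
    jitter: float = 0.0
    sigma_k: float = 0.0
    rupture_force: float | None = None
    surface: SurfaceModel = field(default_factory=SurfaceModel)
    tip: TipModel = field(default_factory=TipModel)
    sensor: SensorParams = field(default_factory=SensorParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str = "cryopeel_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_bases < 2 or self.b <= 0 or self.z_max <= 0 or self.dz <= 0:
            raise InvalidParameterError("invalid chain/retraction parameters")


def default_config() -> RunConfig:
    return RunConfig()


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    for key, cls in (
        ("surface", SurfaceModel),
        ("tip", TipModel),
        ("sensor", SensorParams),
        ("analysis", AnalysisParams),
    ):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise InvalidParameterError(f"{path}: {exc}") from exc
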