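"""Simulation configuration: defaults, YAML loading, validation.

Every default lives in the dataclasses themselves (``ModelParameters``,
``SolverSettings``, ``Grid``); a configuration file is a *diff* against
those defaults, so an empty file reproduces the published default run.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import Grid
from .parameters import ModelParameters
from .solver import SolverSettings
from .strain import SyntheticStrainParams


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a run.

    Exactly one strain source applies: a displacement-deck path, a
    strain-field file, or the synthetic generator (the default).
    ``heaviside_conservative`` switches the catabolic-to-EPOR-active loss
    term to carry the same EPO gate as its matching gain (the literal
    equations gate only the gain).
    """

    grid: Grid = field(default_factory=Grid)
    horizon: float = 14.0
    snapshot_times: tuple[float, ...] = (0.0, 1.0, 7.0, 14.0)
    solver: SolverSettings = field(default_factory=SolverSettings)
    parameters: ModelParameters = field(default_factory=ModelParameters)
    heaviside_conservative: bool = False
    deck_path: str | None = None
    strain_file: str | None = None
    synthetic_strain: SyntheticStrainParams = field(
        default_factory=SyntheticStrainParams
    )
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for t in self.snapshot_times:
            if not (0.0 <= t <= self.horizon):
                raise ValueError(
                    f"snapshot time {t} outside [0, {self.horizon}]"
                )
        if self.deck_path is not None and self.strain_file is not None:
            raise ValueError("specify at most one of deck_path / strain_file")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def strain_field(self):
        """Build the strain field from the configured source."""
        from . import strain as sm

        if self.deck_path is not None:
            deck = sm.read_displacement_deck(self.deck_path)
            recs = sm.strain_from_displacement(deck)
            recs = sm.mirror_half_symmetry(recs)
            return sm.nearest_strain(recs, self.grid)
        if self.strain_file is not None:
            fld = sm.read_strain_field(self.strain_file)
            if fld.grid != self.grid:
                raise ValueError("strain file grid does not match config grid")
            return fld
        return sm.synthetic_strain_field(self.synthetic_strain, self.grid)

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "horizon": self.horizon,
            "snapshot_times": list(self.snapshot_times),
            "solver": dataclasses.asdict(self.solver),
            "parameters": dataclasses.asdict(self.parameters),
            "heaviside_conservative": self.heaviside_conservative,
            "deck_path": self.deck_path,
            "strain_file": self.strain_file,
            "synthetic_strain": dataclasses.asdict(self.synthetic_strain),
            "output_dir": self.output_dir,
        }


_SECTION_TYPES = {
    "grid": Grid,
    "solver": SolverSettings,
    "parameters": ModelParameters,
    "synthetic_strain": SyntheticStrainParams,
}
_SCALAR_KEYS = {
    "horizon",
    "snapshot_times",
    "heaviside_conservative",
    "deck_path",
    "strain_file",
    "output_dir",
}


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a configuration from a (possibly partial) nested dict.

    Top-level model-parameter names are also accepted flat, so a minimal
    file can say ``beta_13: 20`` without nesting.
    """
    data = dict(data or {})
    kwargs: dict = {}
    param_names = set(ModelParameters.field_names())
    flat_params = {}
    for key in list(data):
        if key in param_names:
            flat_params[key] = data.pop(key)
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(
                    f"unknown key(s) in {section!r}: {sorted(unknown)}"
                )
            kwargs[section] = cls(**sub)
    for key in list(data):
        if key in _SCALAR_KEYS:
            val = data.pop(key)
            if key == "snapshot_times":
                val = tuple(float(t) for t in val)
            kwargs[key] = val
    if data:
        raise ValueError(f"unknown config key(s): {sorted(data)}")
    if flat_params:
        base = kwargs.get("parameters", ModelParameters())
        kwargs["parameters"] = base.replace(**flat_params)
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML configuration file merged over the defaults."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the full effective configuration (for provenance); reloading
    it reproduces the identical run."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
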