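"""Run configuration: phantom, grid, noise, schedules and analysis options.

A single YAML file (or nested dict) configures a whole run; every section
is optional and defaults reproduce the standard setup — 150 s acquisition,
fourteen subsets (RL 4-30 s), six spheres at a nominal 10:1
sphere:background ratio, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .framing import DEFAULT_RLS_S, DEFAULT_TOTAL_S, FrameSchedule, make_schedule
from .geometry import ConfigurationError, GridSpec, PhantomGeometry, build_phantom_geometry
from .simulate import NoiseModel

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    phantom: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    seed: int = 0

    _SECTIONS = ("phantom", "grid", "noise", "schedule", "analysis", "io")
    _ANALYSIS_KEYS = {"target_rl_s", "alpha", "transforms", "supersample", "detection"}
    _SCHEDULE_KEYS = {"total_s", "rls_s"}
    _IO_KEYS = {"write_frames", "write_plots", "frames_dir"}

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, allowed in (
            ("analysis", self._ANALYSIS_KEYS),
            ("schedule", self._SCHEDULE_KEYS),
            ("io", self._IO_KEYS),
        ):
            extra = set(getattr(self, name)) - allowed
            if extra:
                raise ConfigurationError(f"unknown keys in [{name}]: {sorted(extra)}")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.target_rl_s <= 0:
            raise ConfigurationError("target_rl_s must be > 0")
        # building the objects validates the remaining sections
        self.build_geometry()
        self.build_grid()
        self.build_noise()
        self.build_schedules()

    # --- derived objects -------------------------------------------------
    def build_geometry(self) -> PhantomGeometry:
        return build_phantom_geometry(self.phantom)

    def build_grid(self) -> GridSpec:
        g = dict(self.grid)
        return GridSpec(
            shape=tuple(g.pop("shape", (144, 144, 48))),
            voxel_size_mm=float(g.pop("voxel_size_mm", 4.0)),
            origin_mm=tuple(g["origin_mm"]) if g.pop("origin_mm", None) else None,
        )

    def build_noise(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def build_schedules(self) -> list[FrameSchedule]:
        total = float(self.schedule.get("total_s", DEFAULT_TOTAL_S))
        rls = self.schedule.get("rls_s", DEFAULT_RLS_S)
        return [make_schedule(total, float(rl)) for rl in rls]

    # --- analysis options ------------------------------------------------
    @property
    def total_s(self) -> float:
        return float(self.schedule.get("total_s", DEFAULT_TOTAL_S))

    @property
    def target_rl_s(self) -> float:
        return float(self.analysis.get("target_rl_s", self.total_s))

    @property
    def alpha(self) -> float:
        return float(self.analysis.get("alpha", 0.05))

    @property
    def supersample(self) -> int:
        return int(self.analysis.get("supersample", 5))

    @property
    def detection(self) -> str:
        """'geometry' (use the phantom layout as hint) or 'auto'."""
        return str(self.analysis.get("detection", "geometry"))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig._SECTIONS) | {"seed"}
    extra = set(data) - known
    if extra:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(extra)}")
    return RunConfig(**data)
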