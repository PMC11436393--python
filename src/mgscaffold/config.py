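"""Study configuration: parsing, defaulting, and invariant checks.

A study config describes one synthetic time-course run: the scaffold design,
material model, degradation schedule, rendering parameters, and the single
seed governing every stochastic draw.  Validation errors name the offending
field path (e.g. ``schedule[1].time_months``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .geometry import ScaffoldDesign, DesignError, design_from_dict
from .phantom import MaterialModel, PhantomError

__all__ = [
    "ConfigError",
    "SchedulePoint",
    "RenderingParams",
    "StudyConfig",
    "validate_config",
]


class ConfigError(ValueError):
    """Schema violation; message carries the field path."""


@dataclass(frozen=True)
class SchedulePoint:
    time_months: float
    erosion_depth: float | None = None  # mm; default k * time from the model
    cut_fraction: float = 0.0
    dilation: float = 1.0  # radial remodeling factor applied to the design

    def check(self, path: str) -> None:
        if self.time_months <= 0:
            raise ConfigError(f"{path}.time_months: must be > 0, got {self.time_months}")
        if self.erosion_depth is not None and self.erosion_depth < 0:
            raise ConfigError(
                f"{path}.erosion_depth: must be >= 0, got {self.erosion_depth}"
            )
        if not (0.0 <= self.cut_fraction <= 1.0):
            raise ConfigError(
                f"{path}.cut_fraction: must be in [0, 1], got {self.cut_fraction}"
            )
        if self.dilation <= 0:
            raise ConfigError(f"{path}.dilation: must be > 0, got {self.dilation}")


@dataclass(frozen=True)
class RenderingParams:
    spacing: float = 0.02  # mm / voxel
    psf_sigma: float = 0.0  # voxels
    noise_sd: float = 0.0  # grayvalue units

    def check(self, path: str = "rendering") -> None:
        if self.spacing <= 0:
            raise ConfigError(f"{path}.spacing: must be > 0, got {self.spacing}")
        if self.psf_sigma < 0:
            raise ConfigError(f"{path}.psf_sigma: must be >= 0, got {self.psf_sigma}")
        if self.noise_sd < 0:
            raise ConfigError(f"{path}.noise_sd: must be >= 0, got {self.noise_sd}")


_DEFAULT_SCHEDULE = ({"time_months": 1.0}, {"time_months": 6.0},
                     {"time_months": 12.0}, {"time_months": 18.0},
                     {"time_months": 26.0})


@dataclass
class StudyConfig:
    design: ScaffoldDesign = field(default_factory=ScaffoldDesign)
    material: MaterialModel = field(default_factory=MaterialModel)
    schedule: tuple[SchedulePoint, ...] = ()
    rendering: RenderingParams = field(default_factory=RenderingParams)
    t_complete_months: float = 23.5  # sets the recession rate k
    substitution_fraction_dense: float = 0.5
    substitution_fraction_lucent: float = 0.3
    measurement_mode: str = "grayscale"  # "grayscale" | "labels"
    n_bins: int = 128
    mixture_k: "int | str" = "auto"
    seed: int = 0
    out_dir: str | None = None
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if not self.schedule:
            self.schedule = tuple(
                SchedulePoint(**p) for p in _DEFAULT_SCHEDULE
            )
        self.check()

    def check(self) -> None:
        for i, p in enumerate(self.schedule):
            p.check(f"schedule[{i}]")
        times = [p.time_months for p in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError(
                f"schedule: times must be strictly increasing, got {times}"
            )
        self.rendering.check()
        if self.t_complete_months <= 0:
            raise ConfigError(
                f"t_complete_months: must be > 0, got {self.t_complete_months}"
            )
        fd, fl = self.substitution_fraction_dense, self.substitution_fraction_lucent
        if fd < 0 or fl < 0 or fd + fl > 1:
            raise ConfigError(
                "substitution fractions must be >= 0 and sum <= 1 "
                f"(dense={fd}, lucent={fl})"
            )
        if self.measurement_mode not in ("grayscale", "labels"):
            raise ConfigError(
                f"measurement_mode: expected 'grayscale' or 'labels', "
                f"got {self.measurement_mode!r}"
            )
        if self.n_bins < 16:
            raise ConfigError(f"n_bins: must be >= 16, got {self.n_bins}")
        if int(self.seed) != self.seed:
            raise ConfigError(f"seed: must be an integer, got {self.seed!r}")

    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "design": self.design.to_dict(),
            "material": {
                "means": list(self.material.means),
                "spreads": list(self.material.spreads),
            },
            "schedule": [asdict(p) for p in self.schedule],
            "rendering": asdict(self.rendering),
            "t_complete_months": self.t_complete_months,
            "substitution_fraction_dense": self.substitution_fraction_dense,
            "substitution_fraction_lucent": self.substitution_fraction_lucent,
            "measurement_mode": self.measurement_mode,
            "n_bins": self.n_bins,
            "mixture_k": self.mixture_k,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "save_volumes": self.save_volumes,
        }
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw or {})
        known = {
            "design", "material", "schedule", "rendering", "t_complete_months",
            "substitution_fraction_dense", "substitution_fraction_lucent",
            "measurement_mode", "n_bins", "mixture_k", "seed", "out_dir",
            "save_volumes",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        try:
            if "design" in raw:
                kwargs["design"] = design_from_dict(raw["design"] or {})
        except DesignError as exc:
            raise ConfigError(f"design: {exc}") from exc
        try:
            if "material" in raw:
                m = raw["material"] or {}
                kwargs["material"] = MaterialModel(
                    means=tuple(m.get("means", MaterialModel().means)),
                    spreads=tuple(m.get("spreads", MaterialModel().spreads)),
                )
        except PhantomError as exc:
            raise ConfigError(f"material: {exc}") from exc
        if "schedule" in raw:
            pts = []
            for i, entry in enumerate(raw["schedule"] or []):
                if not isinstance(entry, dict) or "time_months" not in entry:
                    raise ConfigError(f"schedule[{i}]: needs a time_months field")
                extra = set(entry) - {
                    "time_months", "erosion_depth", "cut_fraction", "dilation"
                }
                if extra:
                    raise ConfigError(f"schedule[{i}]: unknown key(s) {sorted(extra)}")
                pts.append(SchedulePoint(**entry))
            kwargs["schedule"] = tuple(pts)
        if "rendering" in raw:
            r = raw["rendering"] or {}
            extra = set(r) - {"spacing", "psf_sigma", "noise_sd"}
            if extra:
                raise ConfigError(f"rendering: unknown key(s) {sorted(extra)}")
            kwargs["rendering"] = RenderingParams(**r)
        for key in known - {"design", "material", "schedule", "rendering"}:
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def validate_config(path: str | Path) -> StudyConfig:
    """Load, default, and invariant-check a YAML study config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return StudyConfig.from_dict(raw)
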