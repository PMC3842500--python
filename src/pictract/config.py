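"""Pipeline configuration: one nested, YAML-serialisable structure.

Defaults reproduce the printed protocol constants: a 61-direction
b = 1200 s/mm^2 scheme, 10,000 streamlines per seed voxel, 0.50 mm steps,
500 mm path limit, 180 degrees-per-voxel curvature limit, Poisson p = .05
individual threshold and 75% / 50% group-consistency criteria on 13
participants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PhantomConfig:
    preset: str = "two_arcs"
    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 1.0  # mm
    tube_radius: float = 2.0  # mm
    crossing_angle_deg: float = 90.0
    snr: float = 30.0
    S0: float = 1000.0
    lambda_parallel: float = 1.7e-3  # mm^2/s
    lambda_perp: float = 3e-4
    iso_diffusivity: float = 7e-4
    n_participants: int = 13
    #: bundle name -> per-participant presence; None = all present
    presence: dict[str, list[bool]] | None = None


@dataclass
class SchemeConfig:
    n_directions: int = 61
    b_value: float = 1200.0  # s/mm^2


@dataclass
class CSDConfig:
    lmax: int = 8
    tau: float = 0.1
    max_iter: int = 50
    response_axis_tol_deg: float = 10.0


@dataclass
class TrackingConfig:
    n_streamlines_per_voxel: int = 10_000
    step_size: float = 0.50
    max_path_length: float = 500.0
    curvature_limit_deg: float = 180.0
    fod_amplitude_threshold: float = 0.2


@dataclass
class ConnectivityConfig:
    seed_radius: float = 1.0  # mm; desk-scale stand-in for the 5 mm ROI
    n_distractor_regions: int = 12


@dataclass
class GroupConfig:
    alpha: float = 0.05
    strict_frac: float = 0.75
    relaxed_frac: float = 0.50


@dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    csd: CSDConfig = field(default_factory=CSDConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    group: GroupConfig = field(default_factory=GroupConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "phantom": PhantomConfig,
            "scheme": SchemeConfig,
            "csd": CSDConfig,
            "tracking": TrackingConfig,
            "connectivity": ConnectivityConfig,
            "group": GroupConfig,
        }
        kwargs: dict = {"seed": d.get("seed", 0)}
        for name, klass in sections.items():
            sub = dict(d.get(name, {}))
            if name == "phantom" and "shape" in sub:
                sub["shape"] = tuple(sub["shape"])
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        d["phantom"]["shape"] = list(d["phantom"]["shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
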