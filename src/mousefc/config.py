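"""Pipeline configuration: one flat dataclass, YAML-loadable."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from .netclass import DEFAULT_CUBES


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """All fixed constants of a pipeline run.

    Thresholds follow the study conventions: seed maps keep voxels with
    |r| >= ``r_threshold`` at ``alpha``; connectogram edges need
    r > ``connectogram_threshold``; predictor networks need
    p < ``predictor_alpha``.
    """

    outdir: str = "mousefc_out"
    seed: int = 0
    # synthetic cohort
    dims: tuple = (96, 48, 12)
    n_regions: int = 235
    T: int = 310
    tr_s: float = 1.0
    noise_sd: float = 1.0
    drift: bool = False
    motion: bool = False
    template: dict = field(default_factory=dict)  # TemplateParams overrides
    run_plan: dict | None = None
    # preprocessing (off by default: synthetic runs are born in atlas space)
    preprocess: bool = False
    # connectome thresholds
    r_threshold: float = 0.15
    alpha: float = 0.05
    connectogram_threshold: float = 0.2
    predictor_alpha: float = 0.001
    # classifier
    cubes: tuple = DEFAULT_CUBES
    seed_regions: tuple = ("ACAr", "CAr", "MDr")
    B: int = 200
    frac: float = 0.8
    lambda_strategy: str = "per-bootstrap"
    cv_folds: int = 2
    lam_grid_size: int = 3
    lasso_tol: float = 1e-3
    unit: str = "run"
    # outputs
    save_volumes: bool = False

    def __post_init__(self):
        self.dims = tuple(self.dims)
        self.cubes = tuple(tuple(c) for c in self.cubes)
        self.seed_regions = tuple(self.seed_regions)
        checks = [
            (0.0 <= self.r_threshold < 1.0, "r_threshold must be in [0, 1)"),
            (0.0 < self.alpha < 1.0, "alpha must be in (0, 1)"),
            (0.0 <= self.connectogram_threshold < 1.0,
             "connectogram_threshold must be in [0, 1)"),
            (0.0 < self.predictor_alpha < 1.0,
             "predictor_alpha must be in (0, 1)"),
            (self.B >= 1, "B must be >= 1"),
            (0.0 < self.frac <= 1.0, "frac must be in (0, 1]"),
            (self.unit in ("run", "subject"), "unit must be run|subject"),
            (self.T >= 4, "T must be >= 4"),
            (self.n_regions >= 2, "need at least 2 regions"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .io import load_yaml
        return cls.from_dict(load_yaml(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        d["cubes"] = [list(c) for c in self.cubes]
        d["seed_regions"] = list(self.seed_regions)
        return d
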