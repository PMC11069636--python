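"""Run configuration: one YAML file describing an end-to-end pipeline run.

Sections mirror the stage specs (dataset, split, models, skeleton, camera)
plus an output directory and a global seed that feeds every stochastic
stage.  Validation is fail-fast: a bad value raises before any work runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import UsageError
from .kinematics import SkeletonConfig
from .models import FAMILIES, ModelSpec, SplitSpec
from .simulator import CameraSpec, DatasetSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for :func:`thumbrot.pipeline.run_pipeline`."""

    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    models: tuple[ModelSpec, ...] = tuple(ModelSpec(f) for f in FAMILIES)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    camera: CameraSpec = field(default_factory=CameraSpec)
    output_dir: str = "thumbrot_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.models:
            raise UsageError("config lists no model families")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise UsageError(f"unknown log level {self.log_level!r}")

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every stochastic sub-spec."""
        from dataclasses import replace

        return replace(
            self,
            seed=seed,
            dataset=replace(self.dataset, seed=seed),
            split=replace(self.split, seed=seed + 1),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise UsageError("config root must be a mapping")
        known = {
            "dataset",
            "split",
            "models",
            "skeleton",
            "camera",
            "output_dir",
            "seed",
            "log_level",
        }
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config section(s): {sorted(unknown)}")
        try:
            kwargs: dict = {}
            if "dataset" in raw:
                ds = dict(raw["dataset"])
                for tup_key in ("angle_grid", "scale_range"):
                    if tup_key in ds:
                        ds[tup_key] = tuple(ds[tup_key])
                kwargs["dataset"] = DatasetSpec(**ds)
            if "split" in raw:
                kwargs["split"] = SplitSpec(**raw["split"])
            if "models" in raw:
                specs = []
                for m in raw["models"]:
                    if isinstance(m, str):
                        specs.append(ModelSpec(family=m))
                    else:
                        specs.append(ModelSpec(**m))
                kwargs["models"] = tuple(specs)
            if "skeleton" in raw:
                kwargs["skeleton"] = SkeletonConfig(**raw["skeleton"])
            if "camera" in raw:
                cam = dict(raw["camera"])
                for tup_key in ("position", "look_at", "up"):
                    if tup_key in cam:
                        cam[tup_key] = tuple(cam[tup_key])
                kwargs["camera"] = CameraSpec(**cam)
            for scalar in ("output_dir", "seed", "log_level"):
                if scalar in raw:
                    kwargs[scalar] = raw[scalar]
            return cls(**kwargs)
        except TypeError as exc:
            raise UsageError(f"invalid config: {exc}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = [
            {"family": m.family, "tuning_folds": m.tuning_folds} for m in self.models
        ]
        return d
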