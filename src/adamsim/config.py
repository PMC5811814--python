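"""Run configuration: defaults reproduce the study's simulation settings
(n = 90 per condition, kp = .04, series noise variance 10)."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

from .experiment import ALL_MODELS
from .model import AdamParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    n_per_condition: int = 90
    kp: float = 0.04
    noise_variance: float = 10.0
    normalization_constant: float = 10_000.0
    fixed_series: bool = False
    models: tuple[str, ...] = ALL_MODELS
    master_seed: int = 0
    output_dir: str = "runs"
    arima_method: str = "cls"
    ses_alpha: float | None = None
    comparator_noise: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.models, str):
            self.models = tuple(m.strip() for m in self.models.split(",") if m.strip())
        else:
            self.models = tuple(self.models)
        self.validate()

    def validate(self) -> None:
        """Raise ValueError naming the offending field."""
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition: must be >= 1")
        if self.kp < 0:
            raise ValueError("kp: must be >= 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance: must be >= 0")
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant: must be > 0")
        if not self.models:
            raise ValueError("models: must be non-empty")
        unknown = sorted(set(self.models) - set(ALL_MODELS))
        if unknown:
            raise ValueError(f"models: unknown name(s) {unknown}")
        if self.arima_method not in ("cls", "mle"):
            raise ValueError("arima_method: must be 'cls' or 'mle'")
        if self.ses_alpha is not None and not 0.0 < self.ses_alpha <= 1.0:
            raise ValueError("ses_alpha: must lie in (0, 1]")

    @property
    def adam_params(self) -> AdamParams:
        return AdamParams(
            kp=self.kp,
            normalization_constant=self.normalization_constant,
            static_stimulus=3500.0 / self.normalization_constant,
            static_anchor=3500.0,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"config: unknown key(s) {bad}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d
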