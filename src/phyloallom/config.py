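"""Run configuration: YAML parsing and defaults shared by the CLI commands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scaling import CATEGORIES, DEFAULT_METABOLIC_EXPONENTS, DEFAULT_TRAIT_CATEGORIES

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    categories: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRAIT_CATEGORIES))
    metabolic_exponents: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METABOLIC_EXPONENTS)
    )
    alpha: float = 0.05
    criterion: str = "REML"
    lambda_bounds: tuple[float, float] = (-2.0, 2.0)
    nsim: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for trait, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for trait {trait!r}")
        for hyp, m in self.metabolic_exponents.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"metabolic exponent for {hyp} must be in (0, 1), got {m}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing file or sections fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "categories" in raw:
        kwargs["categories"] = {str(k): str(v) for k, v in raw["categories"].items()}
    if "metabolic_exponents" in raw:
        kwargs["metabolic_exponents"] = {
            str(k): float(v) for k, v in raw["metabolic_exponents"].items()
        }
    for key in ("alpha", "criterion", "nsim", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "lambda_bounds" in raw:
        lo, hi = raw["lambda_bounds"]
        kwargs["lambda_bounds"] = (float(lo), float(hi))
    return RunConfig(**kwargs)
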