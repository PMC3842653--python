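"""Run configuration: a flat YAML file mirroring :class:`RunConfig`.

Exactly one of ``inputs`` (paths to the CSV tables) or ``synthetic`` (a
synthetic-generator block) must be present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .gam import ModelSpec, SmoothTerm, TensorTerm
from .synth import RegionConfig, SyntheticConfig, _DEFAULT_REGIONS

__all__ = ["RunConfig", "load_config", "default_model_spec"]


def default_model_spec(level: str = "subregion") -> ModelSpec:
    """Initial term roster handed to selection: fire-PM exposure as linear,
    all weekday indicators except the reference day, anthropogenic PM2.5 as a
    smooth, and the humidity/temperature tensor; the sub-region model adds
    the two spatial indicators and the demographic proportions."""
    indicators = ["is_monday", "is_tuesday", "is_wednesday", "is_thursday", "is_friday", "is_saturday"]
    linear = ["fire_pm"]
    if level == "subregion":
        indicators += ["is_sr3", "is_sr6"]
        linear += ["prop_income_gt50k", "prop_age_lt24"]
    elif level != "county":
        raise ValueError("level must be 'county' or 'subregion'")
    return ModelSpec(
        linear_terms=tuple(linear),
        indicator_terms=tuple(indicators),
        smooth_terms=(SmoothTerm("anthro_pm25", 10),),
        tensor_terms=(TensorTerm("mean_rh", "min_temp", 5, 5),),
    )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    level: str = "subregion"            # county | subregion
    alpha: float = 0.05
    kernel_sd: float = 1.0              # days
    kernel_lags: int = 3
    select: bool = True
    out_dir: str = "results/run"
    inputs: dict | None = None          # paths: counts, covariates, demographics
    synthetic: SyntheticConfig | None = None
    model_spec: ModelSpec | None = None # None -> default roster for the level

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.level not in ("county", "subregion"):
            raise ValueError("level must be 'county' or 'subregion'")
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' and 'synthetic' must be given")
        if self.kernel_sd < 0 or self.kernel_lags < 0:
            raise ValueError("kernel settings must be nonnegative")

    def spec(self) -> ModelSpec:
        return self.model_spec if self.model_spec is not None else default_model_spec(self.level)


def _parse_synthetic(block: dict) -> SyntheticConfig:
    kwargs = dict(block)
    regions = kwargs.pop("regions", None)
    if regions is not None:
        kwargs["regions"] = tuple(RegionConfig(**r) for r in regions)
    return SyntheticConfig(**kwargs)


def _parse_spec(block: dict) -> ModelSpec:
    return ModelSpec(
        linear_terms=tuple(block.get("linear_terms", ())),
        indicator_terms=tuple(block.get("indicator_terms", ())),
        smooth_terms=tuple(SmoothTerm(**s) for s in block.get("smooth_terms", ())),
        tensor_terms=tuple(TensorTerm(**t) for t in block.get("tensor_terms", ())),
    )


def load_config(path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "synthetic" in raw and raw["synthetic"] is not None and not isinstance(raw["synthetic"], SyntheticConfig):
        block = dict(raw["synthetic"])
        block.setdefault("seed", raw.get("seed", 0))
        raw["synthetic"] = _parse_synthetic(block)
    if "model_spec" in raw and raw["model_spec"] is not None and not isinstance(raw["model_spec"], ModelSpec):
        raw["model_spec"] = _parse_spec(raw["model_spec"])
    return RunConfig(**raw)
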