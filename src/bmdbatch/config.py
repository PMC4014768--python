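"""Run and decision-rule configuration.

All thresholds of the automated decision logic are parameterized here so the
exact rule set of a given workflow can be re-created by configuration rather
than code changes.  Defaults follow standard benchmark-dose practice: 10%
extra risk (dichotomous), 1 control-SD change (continuous), one-sided 95%
profile-likelihood BMDL, goodness-of-fit alpha 0.05, variance-test alpha 0.10,
BMD/BMDL ratio warning at 5 and failure at 20, low-dose extrapolation warning
at 3x below the lowest non-zero dose, and a 3-fold "sufficiently close" BMDL
spread for AIC-based selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


@dataclass
class RuleConfig:
    """Thresholds for fit classification and model selection."""

    gof_alpha: float = 0.05
    variance_alpha: float = 0.10
    ratio_warn: float = 5.0
    ratio_fail: float = 20.0
    extrap_factor: float = 3.0
    bmdl_close_factor: float = 3.0
    min_groups: int = 3
    aic_tie_tol: float = 1e-3
    #: treat a marginal mean-model fit (gof_alpha < p < 2*gof_alpha) as a
    #: non-fatal warning on otherwise Viable fits
    marginal_gof_warning: bool = True

    def __post_init__(self):
        for name in ("gof_alpha", "variance_alpha", "ratio_warn", "ratio_fail",
                     "extrap_factor", "bmdl_close_factor", "aic_tie_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_groups < 3:
            raise ValueError("min_groups must be >= 3")


@dataclass
class RunConfig:
    """Full configuration of a batch run."""

    rules: RuleConfig = field(default_factory=RuleConfig)
    bmr_dichotomous: float = 0.10
    bmr_continuous_sd: float = 1.0
    bmdl_level: float = 0.95
    restrictions: bool = True
    max_degree: int = 8
    #: optional subset of model family names to fit (None = full suite)
    models: Optional[Sequence[str]] = None
    variance_modes: Sequence[str] = ("constant", "modeled")
    optimizer_starts: int = 5
    optimizer_tol: float = 1e-8
    rho_bounds: Sequence[float] = (-18.0, 18.0)
    #: per-dataset adversity-direction override {dataset_id: +1 or -1}
    direction_override: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        # accept both nested and dotted-key styles for the common knobs
        rules = RuleConfig(**raw.pop("rules", {}))
        bmr = raw.pop("bmr", {})
        bmdl = raw.pop("bmdl", {})
        opt = raw.pop("optimizer", {})
        variance = raw.pop("variance", {})
        cfg = cls(rules=rules, **raw)
        if "dichotomous" in bmr:
            cfg.bmr_dichotomous = float(bmr["dichotomous"])
        if "continuous_sd" in bmr:
            cfg.bmr_continuous_sd = float(bmr["continuous_sd"])
        if "level" in bmdl:
            cfg.bmdl_level = float(bmdl["level"])
        if "starts" in opt:
            cfg.optimizer_starts = int(opt["starts"])
        if "tol" in opt:
            cfg.optimizer_tol = float(opt["tol"])
        if "rho_bounds" in variance:
            cfg.rho_bounds = tuple(variance["rho_bounds"])
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
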