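"""Simulation configuration for the synthetic threshold-assigned cohort.

The defaults describe a cohort entering HIV care with baseline CD4 counts on
0-350 cells/uL, an eligibility threshold at 200 cells/uL, fuzzy uptake of
antiretroviral therapy (ART) at the threshold, a mortality hazard that falls
with CD4 (confounding by indication), a truly protective conditional
treatment effect (hazard ratio 0.5), 6-monthly laboratory monitoring with
missed visits and absorbing disengagement from care, and 32 binary household
assets feeding a principal-component wealth index.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml

__all__ = ["SimConfig", "ConfigError"]

#: eligible share observed in the motivating cohort (2,751 of 4,435 below 200)
DEFAULT_ELIGIBLE_FRACTION = 2751.0 / 4435.0


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _is_prob(x: float) -> bool:
    return 0.0 <= x <= 1.0


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic-cohort generator.

    Times are in months; one discrete period is ``period_length`` months.
    ``true_log_hr`` is the conditional log hazard ratio of current ART,
    applied on the complementary log-log scale so it is a genuine log hazard
    ratio regardless of period length.
    """

    n_subjects: int = 4435
    seed: int = 0

    # assignment variable
    threshold: float = 200.0
    cd4_min: float = 0.0
    cd4_max: float = 350.0
    eligible_fraction: float = DEFAULT_ELIGIBLE_FRACTION

    # treatment uptake (fuzzy threshold rule)
    p_init_below: float = 0.85
    p_init_above: float = 0.05
    late_init_hazard: float = 0.03  # per-period hazard of deferred initiation

    # outcome model
    true_log_hr: float = math.log(0.5)
    true_log_hr_trend_per_year: float = 0.0
    hazard_scale: float = 0.018       # per-period event rate at CD4 = 0
    hazard_cd4_slope: float = -0.0075  # log-rate change per cell/uL

    # follow-up and monitoring
    n_periods: int = 48
    period_length: float = 1.0   # months per period
    lab_interval: int = 6        # months between scheduled lab visits
    p_lab_miss: float = 0.25
    lab_miss_cd4_slope: float = 0.0    # logit change per +100 cells/uL
    dropout_rate: float = 0.004        # per-period care-disengagement hazard
    dropout_cd4_slope: float = 0.0     # logit change per +100 cells/uL

    # CD4 trajectory (cells/uL per month)
    cd4_decline_rate: float = 4.0
    cd4_recovery_rate: float = 8.0

    # covariates
    n_assets: int = 32
    asset_missing_frac: float = 0.10
    residence_missing_frac: float = 0.10
    education_missing_frac: float = 0.02

    @property
    def cd4_range(self) -> tuple[float, float]:
        return (self.cd4_min, self.cd4_max)

    def validate(self) -> "SimConfig":
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be nonnegative")
        for name in (
            "p_init_below",
            "p_init_above",
            "late_init_hazard",
            "p_lab_miss",
            "dropout_rate",
            "eligible_fraction",
            "asset_missing_frac",
            "residence_missing_frac",
            "education_missing_frac",
        ):
            if not _is_prob(getattr(self, name)):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not (self.cd4_min <= self.threshold <= self.cd4_max):
            raise ConfigError(
                "cd4 range must bracket the threshold: "
                f"[{self.cd4_min}, {self.cd4_max}] vs {self.threshold}"
            )
        if self.cd4_min >= self.cd4_max:
            raise ConfigError("cd4_min must be below cd4_max")
        if self.p_init_below < self.p_init_above:
            raise ConfigError(
                "p_init_below < p_init_above would create defiers; "
                "monotonicity requires p_init_below >= p_init_above"
            )
        lo, hi = self._eligible_fraction_bounds()
        if not (lo - 1e-12 <= self.eligible_fraction <= hi + 1e-12):
            raise ConfigError(
                f"eligible_fraction must lie in [{lo:.4f}, {hi:.4f}] for this "
                "cd4 range/threshold (uniform-triangular mixture support)"
            )
        if self.hazard_scale <= 0:
            raise ConfigError("hazard_scale must be positive")
        if self.n_periods <= 0:
            raise ConfigError("n_periods must be positive")
        if self.period_length <= 0:
            raise ConfigError("period_length must be positive")
        if self.lab_interval <= 0:
            raise ConfigError("lab_interval must be positive")
        if self.n_assets < 2:
            raise ConfigError("n_assets must be at least 2")
        return self

    def _eligible_fraction_bounds(self) -> tuple[float, float]:
        """Feasible eligible fractions for the uniform/triangular CD4 mixture."""
        span = self.cd4_max - self.cd4_min
        p_unif = (self.threshold - self.cd4_min) / span
        p_tri = 1.0 - ((self.cd4_max - self.threshold) / span) ** 2
        return min(p_unif, p_tri), max(p_unif, p_tri)

    def mixture_weight(self) -> float:
        """Weight on the uniform component of the CD4 mixture."""
        span = self.cd4_max - self.cd4_min
        p_unif = (self.threshold - self.cd4_min) / span
        p_tri = 1.0 - ((self.cd4_max - self.threshold) / span) ** 2
        if abs(p_tri - p_unif) < 1e-12:
            return 1.0
        w = (p_tri - self.eligible_fraction) / (p_tri - p_unif)
        return float(min(max(w, 0.0), 1.0))

    # ------------------------------------------------------------------ io
    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
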