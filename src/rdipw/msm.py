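"""Stabilized inverse-probability weights and marginal structural
discrete-time hazard models.

Treatment here is absorbing (once on ART, always on ART). Baseline weights
target the time-invariant contrast "initiated within the grace period vs
not"; time-varying treatment weights target time-updated ART status; and
censoring weights correct informative lab-gap censoring. All weighted fits
use a subject-clustered sandwich variance, since weighting induces
within-subject dependence.

Missing covariate values enter every weight model as an explicit "missing"
category rather than being dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._glm import fit_binomial, wald_interval
from ._splines import period_basis

__all__ = [
    "WeightModelSpec",
    "WeightSet",
    "PositivityError",
    "BaselineIPTW",
    "TimeVaryingIPTW",
    "LabGapIPCW",
    "MarginalStructuralHazard",
    "fit_baseline_weights",
    "fit_timevarying_weights",
    "fit_censoring_weights",
    "fit_msm",
    "fit_msm_interaction",
    "weight_diagnostics",
]

DEFAULT_DENOMINATOR = (
    "age",
    "sex",
    "baseline_cd4",
    "education",
    "wealth_quintile",
    "distance_km",
    "residence",
)

_CATEGORICAL = ("sex", "education", "residence", "wealth_quintile")
_POSITIVITY_EPS = 1e-6


class PositivityError(RuntimeError):
    """Fitted treatment/censoring probabilities too close to 0 or 1."""


@dataclass(frozen=True)
class WeightModelSpec:
    """Covariate sets for the stabilized weight models.

    ``numerator_covariates`` must be a subset of ``denominator_covariates``;
    an empty numerator means marginal stabilization (time-invariant case).
    ``include_threshold_indicator`` adds a below-threshold dummy alongside
    linear baseline CD4, since treatment assignment follows a step rule in
    CD4. Optional symmetric percentile ``truncation`` (e.g. ``(1, 99)``)
    caps extreme weights; off by default.
    """

    denominator_covariates: tuple = DEFAULT_DENOMINATOR
    numerator_covariates: tuple = ()
    truncation: tuple | None = None
    include_threshold_indicator: bool = True
    threshold: float = 200.0
    #: whether the time-varying denominator models condition on the most
    #: recent recorded CD4 (switching this off makes numerator and
    #: denominator identical in the time-varying estimators)
    time_varying_cd4: bool = True

    def __post_init__(self):
        if not set(self.numerator_covariates) <= set(self.denominator_covariates):
            raise ValueError(
                "numerator covariates must be a subset of denominator covariates"
            )
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (0 <= lo < hi <= 100):
                raise ValueError("truncation percentiles must satisfy 0 <= lo < hi <= 100")


@dataclass
class WeightSet:
    """Row-aligned stabilized weights with diagnostics."""

    treatment: np.ndarray
    censoring: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def combined(self) -> np.ndarray:
        return self.treatment * self.censoring

    def validate(self) -> "WeightSet":
        for name, w in (("treatment", self.treatment), ("censoring", self.censoring)):
            if not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise ValueError(f"{name} weights must be positive and finite")
        return self


def _design(df: pd.DataFrame, covariates, spec: WeightModelSpec) -> pd.DataFrame:
    """Logistic design matrix with explicit missing categories."""
    X = {"const": np.ones(len(df))}
    for cov in covariates:
        v = df[cov]
        if cov in _CATEGORICAL:
            s = v.astype(object).where(~pd.isna(v), "missing").astype(str)
            levels = sorted(pd.unique(s))
            for level in levels[1:]:
                X[f"{cov}_{level}"] = (s == level).to_numpy(dtype=float)
        else:
            X[cov] = v.to_numpy(dtype=float)
            if cov == "baseline_cd4" and spec.include_threshold_indicator:
                X["below_threshold"] = (
                    v.to_numpy(dtype=float) < spec.threshold
                ).astype(float)
    return pd.DataFrame(X, index=df.index)


def _check_positivity(p: np.ndarray, df: pd.DataFrame, what: str) -> None:
    bad = (p < _POSITIVITY_EPS) | (p > 1 - _POSITIVITY_EPS)
    if np.any(bad):
        strata = df.loc[bad].head(5).to_dict("records")
        raise PositivityError(
            f"positivity violation in the {what} model: fitted probabilities "
            f"outside ({_POSITIVITY_EPS}, 1-{_POSITIVITY_EPS}) for "
            f"{int(bad.sum())} rows; first offending strata: {strata}"
        )


def _truncate(w: np.ndarray, truncation) -> np.ndarray:
    if truncation is None:
        return w
    lo, hi = np.percentile(w, truncation)
    return np.clip(w, lo, hi)


class BaselineIPTW(BaseEstimator):
    """Stabilized baseline inverse-probability-of-treatment weights.

    Denominator: logistic model for immediate initiation given baseline
    covariates; numerator: the marginal initiation probability (or a
    baseline-covariate model when ``spec.numerator_covariates`` is set).
    One weight per subject, constant over that subject's person-periods.
    """

    def __init__(self, spec: WeightModelSpec | None = None):
        self.spec = spec

    def fit(self, cohort: pd.DataFrame):
        spec = self.spec or WeightModelSpec()
        if "art_immediate" in cohort.columns:
            a = cohort["art_immediate"].to_numpy(dtype=float)
        else:
            from .prep import classify_immediate_art

            a = np.asarray(
                classify_immediate_art(
                    cohort["entry_time"].to_numpy(),
                    cohort["art_init_time"].to_numpy(dtype=float),
                ),
                dtype=float,
            )
        Xd = _design(cohort, spec.denominator_covariates, spec)
        pd_hat = fit_binomial(a, Xd, link="logit").predict(Xd)
        pd_hat = np.asarray(pd_hat)
        _check_positivity(pd_hat, cohort[list(spec.denominator_covariates)], "treatment denominator")
        if spec.numerator_covariates:
            Xn = _design(cohort, spec.numerator_covariates, spec)
            pn_hat = np.asarray(fit_binomial(a, Xn, link="logit").predict(Xn))
        else:
            pn_hat = np.full(len(cohort), a.mean())
        w = np.where(a == 1, pn_hat / pd_hat, (1 - pn_hat) / (1 - pd_hat))
        w = _truncate(w, spec.truncation)
        self.weights_ = pd.Series(w, index=cohort["subject_id"].to_numpy(), name="iptw")
        self.p_denominator_ = pd_hat
        self.p_numerator_ = pn_hat
        self.diagnostics_ = weight_diagnostics(w)
        return self

    def row_weights(self, pp: pd.DataFrame) -> np.ndarray:
        """Broadcast subject-level weights onto person-period rows."""
        return self.weights_.reindex(pp["subject_id"].to_numpy()).to_numpy()


def _lagged_art(pp: pd.DataFrame) -> np.ndarray:
    """Previous-period treatment status within subject (0 in period 0...
    unless treatment started at entry, in which case initiation is the
    period-0 event being modelled)."""
    a = pp["art_now"].to_numpy(dtype=float)
    first = ~pp["subject_id"].duplicated().to_numpy()
    lag = np.roll(a, 1)
    lag[first] = 0.0
    return lag


class TimeVaryingIPTW(BaseEstimator):
    """Stabilized time-varying treatment weights by cumulative product.

    At each period where the subject has not yet initiated, the contribution
    is P(observed status | baseline covariates) over P(observed status |
    baseline covariates + most recent recorded CD4); after initiation the
    treatment is deterministic (absorbing) and the contribution is one.
    Both models include smooth period effects.
    """

    def __init__(self, spec: WeightModelSpec | None = None):
        self.spec = spec

    def fit(self, pp: pd.DataFrame):
        spec = self.spec or WeightModelSpec(
            numerator_covariates=DEFAULT_DENOMINATOR,
        )
        a = pp["art_now"].to_numpy(dtype=float)
        lag = _lagged_art(pp)
        at_risk = lag == 0.0  # still untreated entering the period

        contrib = np.ones(len(pp))
        if at_risk.sum() > 0 and np.unique(a[at_risk]).size > 1:
            sub = pp[at_risk]
            y = a[at_risk]
            pb = period_basis(sub["period"].to_numpy())
            Xn = _design(sub, spec.numerator_covariates, spec)
            Xd = _design(sub, spec.denominator_covariates, spec)
            for k, v in pb.items():
                Xn[k] = v
                Xd[k] = v
            if spec.time_varying_cd4:
                Xd["current_cd4"] = sub["current_cd4"].to_numpy(dtype=float)
                if spec.include_threshold_indicator:
                    Xd["current_below"] = (
                        sub["current_cd4"].to_numpy(dtype=float) < spec.threshold
                    ).astype(float)
            pn = np.asarray(fit_binomial(y, Xn, link="logit").predict(Xn))
            pdn = np.asarray(fit_binomial(y, Xd, link="logit").predict(Xd))
            _check_positivity(pdn, sub[["current_cd4"]], "time-varying treatment")
            ratio = np.where(y == 1, pn / pdn, (1 - pn) / (1 - pdn))
            contrib[at_risk] = ratio
            self.p_num_ = pn
            self.p_den_ = pdn

        self.at_risk_ = at_risk
        self.contrib_ = contrib
        w = (
            pd.Series(contrib)
            .groupby(pp["subject_id"].to_numpy(), sort=False)
            .cumprod()
            .to_numpy()
        )
        w = _truncate(w, spec.truncation)
        self.weights_ = w
        self.diagnostics_ = weight_diagnostics(w)
        return self


class LabGapIPCW(BaseEstimator):
    """Stabilized inverse-probability-of-censoring weights for lab-gap
    censoring, cumulative within subject.

    Per period, the contribution is P(uncensored | baseline covariates) over
    P(uncensored | baseline covariates + most recent recorded CD4).
    """

    def __init__(self, spec: WeightModelSpec | None = None):
        self.spec = spec

    def fit(self, pp: pd.DataFrame):
        spec = self.spec or WeightModelSpec(
            numerator_covariates=DEFAULT_DENOMINATOR,
        )
        c = pp["censored_this_period"].to_numpy(dtype=float)
        contrib = np.ones(len(pp))
        if np.unique(c).size > 1:
            pb = period_basis(pp["period"].to_numpy())
            Xn = _design(pp, spec.numerator_covariates, spec)
            Xd = _design(pp, spec.denominator_covariates, spec)
            for k, v in pb.items():
                Xn[k] = v
                Xd[k] = v
            if spec.time_varying_cd4:
                Xd["current_cd4"] = pp["current_cd4"].to_numpy(dtype=float)
            pn = np.asarray(fit_binomial(c, Xn, link="logit").predict(Xn))
            pdn = np.asarray(fit_binomial(c, Xd, link="logit").predict(Xd))
            _check_positivity(1 - pdn, pp[["current_cd4"]], "censoring")
            contrib = (1 - pn) / (1 - pdn)
        self.contrib_ = contrib
        w = (
            pd.Series(contrib)
            .groupby(pp["subject_id"].to_numpy(), sort=False)
            .cumprod()
            .to_numpy()
        )
        w = _truncate(w, spec.truncation)
        self.weights_ = w
        self.diagnostics_ = weight_diagnostics(w)
        return self


class MarginalStructuralHazard(BaseEstimator):
    """Weighted discrete-time hazard model for the marginal structural
    contrast, with smooth period effects and a subject-clustered sandwich
    variance.

    ``treatment`` picks the exposure column (``art_immediate`` for the
    time-invariant contrast, ``art_now`` for time-updated status);
    ``covariates`` optionally conditions on baseline covariates (the
    time-varying MSM is conditional on its weight-numerator covariates);
    ``interaction=True`` adds treatment x years-since-entry, reported as a
    per-year multiplicative change in the hazard ratio.
    """

    def __init__(
        self,
        treatment: str = "art_immediate",
        covariates=(),
        interaction: bool = False,
        link: str = "cloglog",
        period_knots: int = 4,
        model_tag: str = "time-invariant",
    ):
        self.treatment = treatment
        self.covariates = covariates
        self.interaction = interaction
        self.link = link
        self.period_knots = period_knots
        self.model_tag = model_tag

    def fit(self, pp: pd.DataFrame, sample_weight=None):
        if pp["event"].sum() == 0:
            raise ValueError("no events in the person-period table")
        if sample_weight is not None and len(sample_weight) != len(pp):
            raise ValueError("weights are not aligned with the person-period rows")
        a = pp[self.treatment].to_numpy(dtype=float)
        X = {"const": np.ones(len(pp)), self.treatment: a}
        if self.interaction:
            years = (pp["period_start"].to_numpy(dtype=float)) / 12.0
            X[f"{self.treatment}_x_years"] = a * years
        X.update(period_basis(pp["period"].to_numpy(), n_knots=self.period_knots))
        Xdf = pd.DataFrame(X, index=pp.index)
        if self.covariates:
            spec = WeightModelSpec()
            cov = _design(pp, self.covariates, spec).drop(columns="const")
            Xdf = pd.concat([Xdf, cov], axis=1)
        res = fit_binomial(
            pp["event"],
            Xdf,
            link=self.link,
            weights=sample_weight,
            groups=pp["subject_id"],
        )
        self.results_ = res
        self.coef_ = res.params
        hr, lo, hi = wald_interval(res, self.treatment)
        self.hr_, self.ci95_ = hr, (lo, hi)
        if self.interaction:
            phr, plo, phi = wald_interval(res, f"{self.treatment}_x_years")
            self.per_year_hr_, self.per_year_ci95_ = phr, (plo, phi)
        self.n_subjects_ = int(pp["subject_id"].nunique())
        self.n_events_ = int(pp["event"].sum())
        self.model_tag_ = self.model_tag
        return self


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def fit_baseline_weights(cohort: pd.DataFrame, spec: WeightModelSpec | None = None) -> BaselineIPTW:
    return BaselineIPTW(spec=spec).fit(cohort)


def fit_timevarying_weights(pp: pd.DataFrame, spec: WeightModelSpec | None = None) -> TimeVaryingIPTW:
    return TimeVaryingIPTW(spec=spec).fit(pp)


def fit_censoring_weights(pp: pd.DataFrame, spec: WeightModelSpec | None = None) -> LabGapIPCW:
    return LabGapIPCW(spec=spec).fit(pp)


_MODEL_TAGS = {
    "time-invariant": dict(treatment="art_immediate", covariates=()),
    "time-varying": dict(treatment="art_now", covariates=DEFAULT_DENOMINATOR),
    "time-varying+censor-weights": dict(treatment="art_now", covariates=DEFAULT_DENOMINATOR),
    "interaction": dict(treatment="art_now", covariates=DEFAULT_DENOMINATOR, interaction=True),
}


def fit_msm(pp: pd.DataFrame, weights, model_tag: str = "time-invariant") -> MarginalStructuralHazard:
    """Fit the weighted marginal structural hazard model named by
    ``model_tag`` (see ``_MODEL_TAGS``); ``weights`` may be None, an array
    aligned to rows, or a :class:`WeightSet` (its combined weights are used)."""
    if model_tag not in _MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if isinstance(weights, WeightSet):
        weights = weights.combined
    kwargs = dict(_MODEL_TAGS[model_tag])
    return MarginalStructuralHazard(model_tag=model_tag, **kwargs).fit(
        pp, sample_weight=weights
    )


def fit_msm_interaction(pp: pd.DataFrame, weights) -> MarginalStructuralHazard:
    return fit_msm(pp, weights, model_tag="interaction")


def weight_diagnostics(w) -> dict:
    """Summary statistics with standard IPW red flags."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    diag = {
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=0)),
        "min": float(w.min()),
        "max": float(w.max()),
        "p1": float(np.percentile(w, 1)),
        "p99": float(np.percentile(w, 99)),
        "warnings": [],
    }
    if abs(diag["mean"] - 1.0) > 0.1:
        diag["warnings"].append("mean weight deviates from 1 by more than 0.1")
    if diag["max"] > 10.0:
        diag["warnings"].append("maximum weight exceeds 10")
    for msg in diag["warnings"]:
        warnings.warn(msg, stacklevel=2)
    return diag
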