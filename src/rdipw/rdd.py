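"""Fuzzy regression-discontinuity estimation on discrete-time survival data.

The assignment variable is baseline CD4 count; eligibility for immediate
treatment is assigned strictly below a threshold (200 cells/uL by default).
The intention-to-treat (ITT) effect of eligibility is the exponentiated
eligibility coefficient from a discrete-time hazards model with separate
CD4-gap slopes above and below the threshold. The complier average causal
effect (CACE) instruments actual treatment with eligibility, using the
ivprobit maximum-likelihood system (linear first stage, probit outcome,
correlated errors) with a two-stage residual-inclusion (2SRI) fallback.

Bandwidths restrict the analysis to an inclusive CD4 window around the
threshold; functional-form sensitivity adds a squared below-threshold term
or a restricted cubic spline with a knot at 125 cells/uL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._glm import SeparationError, fit_binomial, wald_interval
from ._splines import period_basis, rcs_basis
from .prep import BandwidthWindow, restrict_bandwidth

__all__ = [
    "RDDSpec",
    "DiscreteTimeRDD",
    "ARTUptakeFirstStage",
    "RDDCACE",
    "fit_itt",
    "fit_first_stage",
    "fit_cace",
    "wald_cace",
    "binned_summary",
    "density_continuity_check",
    "DensityCheck",
]

FORMS = ("linear-gap", "squared-below", "spline-knot-125")


@dataclass(frozen=True)
class RDDSpec:
    """Bandwidth, functional form and link for one RDD fit."""

    window: BandwidthWindow = field(default_factory=lambda: BandwidthWindow(0.0, 350.0))
    form: str = "linear-gap"
    covariates: tuple = ()
    link: str = "cloglog"
    threshold: float = 200.0
    knot: float = 125.0

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")


def _as_window(window) -> BandwidthWindow:
    if isinstance(window, BandwidthWindow):
        return window
    return BandwidthWindow(*window)


def _gap_design(
    pp: pd.DataFrame,
    threshold: float,
    form: str,
    knot: float,
    window: BandwidthWindow,
    covariates=(),
    period_knots: int = 4,
    include_eligible: bool = True,
) -> pd.DataFrame:
    """Design matrix shared by the ITT and CACE outcome models."""
    cd4 = pp["baseline_cd4"].to_numpy(dtype=float)
    below = (cd4 < threshold).astype(float)
    gap = cd4 - threshold
    X = {"const": np.ones(len(pp))}
    if include_eligible:
        X["eligible"] = below
    X["gap_below"] = gap * below
    X["gap_above"] = gap * (1.0 - below)
    if form == "squared-below":
        X["gap_below_sq"] = (gap * below) ** 2 / 100.0
    elif form == "spline-knot-125":
        lo = max(window.lower, float(np.min(cd4)))
        knots = sorted({lo, knot, threshold})
        if len(knots) >= 3:
            nl = rcs_basis(np.minimum(cd4, threshold), knots) * below[:, None]
            for j in range(nl.shape[1]):
                X[f"cd4_rcs{j + 1}"] = nl[:, j]
    for cov in covariates:
        v = pp[cov]
        if v.dtype == object:
            for level in sorted(pd.unique(v.astype(str)))[1:]:
                X[f"{cov}_{level}"] = (v.astype(str) == level).astype(float)
        else:
            X[cov] = v.to_numpy(dtype=float)
    X.update(period_basis(pp["period"].to_numpy(), n_knots=period_knots))
    return pd.DataFrame(X, index=pp.index)


def _check_events_both_sides(pp: pd.DataFrame) -> None:
    below = pp["eligible"].to_numpy() == 1
    ev = pp["event"].to_numpy() == 1
    for side, mask in (("below", below), ("above", ~below)):
        if mask.sum() == 0:
            raise ValueError(f"no subjects on the {side} side of the threshold")
        if (ev & mask).sum() == 0:
            raise ValueError(f"no events on the {side} side of the threshold")


class DiscreteTimeRDD(BaseEstimator):
    """Intention-to-treat RDD fit: discrete-time hazard of death regressed
    on eligibility, side-specific CD4-gap slopes and smooth period effects.

    Fitted attributes: ``hr_`` (eligibility hazard ratio), ``ci95_``,
    ``coef_``/``se_`` (pandas Series), ``n_subjects_``, ``n_events_``,
    ``results_`` (statsmodels results).
    """

    def __init__(
        self,
        window=(0.0, 350.0),
        form: str = "linear-gap",
        link: str = "cloglog",
        covariates=(),
        threshold: float = 200.0,
        knot: float = 125.0,
        period_knots: int = 4,
    ):
        self.window = window
        self.form = form
        self.link = link
        self.covariates = covariates
        self.threshold = threshold
        self.knot = knot
        self.period_knots = period_knots

    def fit(self, pp: pd.DataFrame):
        window = _as_window(self.window)
        sub = restrict_bandwidth(pp, window)
        if sub.empty:
            raise ValueError("no person-periods inside the bandwidth window")
        _check_events_both_sides(sub)
        X = _gap_design(
            sub,
            self.threshold,
            self.form,
            self.knot,
            window,
            covariates=self.covariates,
            period_knots=self.period_knots,
        )
        res = fit_binomial(
            sub["event"],
            X,
            link=self.link,
            groups=sub["subject_id"],
            advice="Consider a wider bandwidth.",
        )
        self.results_ = res
        self.coef_ = res.params
        self.se_ = res.bse
        hr, lo, hi = wald_interval(res, "eligible")
        self.hr_, self.ci95_ = hr, (lo, hi)
        self.n_subjects_ = int(sub["subject_id"].nunique())
        self.n_events_ = int(sub["event"].sum())
        return self


class ARTUptakeFirstStage(BaseEstimator):
    """Discontinuity at the threshold in the probability of treatment
    initiation within ``init_window_months`` of entry.

    Side-specific linear probability fits in the window, evaluated at the
    threshold; ``jump_`` is the below-minus-above difference with a Wald CI
    from heteroskedasticity-robust intercept variances.
    """

    def __init__(
        self,
        window=(0.0, 350.0),
        init_window_months: float = 6.0,
        threshold: float = 200.0,
        period_length: float = 1.0,
    ):
        self.window = window
        self.init_window_months = init_window_months
        self.threshold = threshold
        self.period_length = period_length

    def fit(self, cohort: pd.DataFrame):
        window = _as_window(self.window)
        sub = restrict_bandwidth(cohort, window)
        cd4 = sub["baseline_cd4"].to_numpy(dtype=float)
        init = sub["art_init_time"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            y = (~np.isnan(init)) & (
                init * self.period_length <= self.init_window_months
            )
        y = y.astype(float)
        below = cd4 < self.threshold

        est, var = {}, {}
        for side, mask in (("below", below), ("above", ~below)):
            if mask.sum() == 0:
                raise ValueError(f"no subjects on the {side} side of the threshold")
            Xs = np.column_stack([np.ones(mask.sum()), cd4[mask] - self.threshold])
            ys = y[mask]
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            resid = ys - Xs @ beta
            XtXi = np.linalg.pinv(Xs.T @ Xs)
            meat = Xs.T @ (Xs * resid[:, None] ** 2)
            V = XtXi @ meat @ XtXi  # HC0
            est[side], var[side] = beta[0], V[0, 0]

        self.p_below_, self.p_above_ = float(est["below"]), float(est["above"])
        self.jump_ = self.p_below_ - self.p_above_
        se = float(np.sqrt(var["below"] + var["above"]))
        z = norm.ppf(0.975)
        self.ci95_ = (self.jump_ - z * se, self.jump_ + z * se)
        self.se_ = se
        return self


# --------------------------------------------------------------------------
# CACE: ivprobit maximum likelihood with a 2SRI fallback
# --------------------------------------------------------------------------

def _ivprobit_negll_grad(theta, y, A, Xo, Z):
    k1, k2 = Xo.shape[1], Z.shape[1]
    beta = theta[:k1]
    lam = theta[k1]
    pi = theta[k1 + 1 : k1 + 1 + k2]
    lns, a = theta[-2], theta[-1]
    s = np.exp(lns)
    r = np.tanh(a)
    q = np.sqrt(1.0 - r * r)

    v = A - Z @ pi
    c = Xo @ beta + lam * A
    m = (c + (r / s) * v) / q

    logPhi = log_ndtr(m)
    logPhic = log_ndtr(-m)
    ll = (
        y * logPhi
        + (1.0 - y) * logPhic
        - 0.5 * (v / s) ** 2
        - lns
        - 0.5 * np.log(2.0 * np.pi)
    )

    logpdf = norm.logpdf(m)
    d = np.where(y == 1.0, np.exp(logpdf - logPhi), -np.exp(logpdf - logPhic))

    g = np.empty_like(theta)
    g[:k1] = Xo.T @ (d / q)
    g[k1] = (d / q) @ A
    g[k1 + 1 : k1 + 1 + k2] = Z.T @ (-(r / s) * d / q + v / s**2)
    g[-2] = np.sum(d * (-(r * v / s) / q) + (v / s) ** 2 - 1.0)
    dm_dr = (v / s) / q + m * r / (q * q)
    g[-1] = np.sum(d * dm_dr) * (1.0 - r * r)
    return -np.sum(ll), -g


def _numerical_hessian(grad_fn, x, eps: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        h = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


class RDDCACE(BaseEstimator):
    """Complier average causal effect via instrumented discrete-time hazards.

    The per-period event indicator is regressed on current treatment status,
    instrumenting treatment with the eligibility indicator and adjusting for
    the same CD4-gap and period terms as the ITT model. Estimation is by
    maximum likelihood of the ivprobit system (``method="ivprobit"``), by
    two-stage residual inclusion (``method="2sri"``), or ``method="auto"``
    (ML with 2SRI fallback on non-convergence). When treatment coincides
    with eligibility (sharp design) the instrumented model collapses to the
    ITT model and is fitted directly with the requested link.

    The probit coefficient is mapped to a hazard-ratio scale by the ratio of
    implied per-period event probabilities at the covariate means; this
    conversion is an approximation and is recorded in ``method_used_``.
    """

    def __init__(
        self,
        window=(0.0, 350.0),
        form: str = "linear-gap",
        link: str = "cloglog",
        method: str = "auto",
        covariates=(),
        threshold: float = 200.0,
        knot: float = 125.0,
        period_knots: int = 4,
    ):
        self.window = window
        self.form = form
        self.link = link
        self.method = method
        self.covariates = covariates
        self.threshold = threshold
        self.knot = knot
        self.period_knots = period_knots

    # -- helpers ----------------------------------------------------------
    def _first_stage_strength(self, sub: pd.DataFrame) -> None:
        subj = sub.drop_duplicates("subject_id")
        elig = subj["eligible"].to_numpy() == 1
        a = subj["art_immediate"].to_numpy(dtype=float)
        p1, p0 = a[elig].mean(), a[~elig].mean()
        n1, n0 = elig.sum(), (~elig).sum()
        se = np.sqrt(
            p1 * (1 - p1) / max(n1, 1) + p0 * (1 - p0) / max(n0, 1)
        )
        self.first_stage_jump_ = float(p1 - p0)
        z = norm.ppf(0.975)
        self.first_stage_ci95_ = (
            self.first_stage_jump_ - z * se,
            self.first_stage_jump_ + z * se,
        )
        self.weak_instrument_ = (
            self.first_stage_ci95_[0] <= 0.0 <= self.first_stage_ci95_[1]
        )
        if self.weak_instrument_:
            warnings.warn(
                "weak first stage: the eligibility jump in treatment uptake is "
                "not distinguishable from zero in this window",
                stacklevel=3,
            )

    def _fit_2sri(self, sub, A, Xo, Z, elig):
        pi, *_ = np.linalg.lstsq(Z.to_numpy(), A, rcond=None)
        resid = A - Z.to_numpy() @ pi
        X = Xo.copy()
        X.insert(1, "art_now", A)
        if np.abs(resid).max() > 1e-10:
            X["fs_resid"] = resid
        res = fit_binomial(
            sub["event"],
            X,
            link=self.link,
            groups=sub["subject_id"],
            advice="Consider a wider bandwidth.",
        )
        self.results_ = res
        self.coef_ = res.params
        hr, lo, hi = wald_interval(res, "art_now")
        return hr, (lo, hi)

    def _fit_ivprobit(self, sub, A, Xo, Z):
        y = sub["event"].to_numpy(dtype=float)
        Xo_np, Z_np = Xo.to_numpy(), Z.to_numpy()
        k1, k2 = Xo_np.shape[1], Z_np.shape[1]

        pi0, *_ = np.linalg.lstsq(Z_np, A, rcond=None)
        resid = A - Z_np @ pi0
        s0 = max(float(resid.std()), 1e-2)
        start_out = fit_binomial(
            y, pd.concat([Xo, pd.Series(A, index=Xo.index, name="art_now")], axis=1),
            link="probit",
        )
        theta0 = np.concatenate(
            [
                start_out.params[Xo.columns].to_numpy(),
                [float(start_out.params["art_now"])],
                pi0,
                [np.log(s0), 0.0],
            ]
        )
        res = optimize.minimize(
            _ivprobit_negll_grad,
            theta0,
            args=(y, A, Xo_np, Z_np),
            jac=True,
            method="BFGS",
            options={"maxiter": 300, "gtol": 1e-5},
        )
        grad_norm = float(np.max(np.abs(res.jac))) / max(len(y), 1)
        if not np.all(np.isfinite(res.x)) or grad_norm > 1e-4:
            raise SeparationError("ivprobit ML did not converge")
        theta = res.x
        beta, lam = theta[:k1], float(theta[k1])

        grad_only = lambda x: _ivprobit_negll_grad(x, y, A, Xo_np, Z_np)[1]
        H = _numerical_hessian(grad_only, theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        se_lam = float(np.sqrt(max(cov[k1, k1], 0.0)))

        cbar = float(np.mean(Xo_np @ beta))
        z = norm.ppf(0.975)

        def to_hr(l):
            return float(ndtr(cbar + l) / max(ndtr(cbar), 1e-300))

        self.coef_ = pd.Series(
            np.concatenate([beta, [lam]]), index=list(Xo.columns) + ["art_now"]
        )
        self.probit_coef_ = lam
        self.probit_se_ = se_lam
        self.rho_ = float(np.tanh(theta[-1]))
        return to_hr(lam), (to_hr(lam - z * se_lam), to_hr(lam + z * se_lam))

    # -- main entry -------------------------------------------------------
    def fit(self, pp: pd.DataFrame):
        window = _as_window(self.window)
        sub = restrict_bandwidth(pp, window)
        if sub.empty:
            raise ValueError("no person-periods inside the bandwidth window")
        _check_events_both_sides(sub)
        self._first_stage_strength(sub)

        elig = sub["eligible"].to_numpy(dtype=float)
        A = sub["art_now"].to_numpy(dtype=float)
        Xo = _gap_design(
            sub,
            self.threshold,
            self.form,
            self.knot,
            window,
            covariates=self.covariates,
            period_knots=self.period_knots,
            include_eligible=False,
        )
        Z = Xo.copy()
        Z["eligible"] = elig

        if np.array_equal(A, elig):
            # sharp design: treatment is the instrument; the instrumented
            # model reduces to the ITT model with the same regressor
            res = fit_binomial(
                sub["event"],
                Xo.assign(art_now=A)[["const", "art_now"] + [c for c in Xo.columns if c != "const"]],
                link=self.link,
                groups=sub["subject_id"],
                advice="Consider a wider bandwidth.",
            )
            self.results_ = res
            self.coef_ = res.params
            hr, lo, hi = wald_interval(res, "art_now")
            self.hr_, self.ci95_ = hr, (lo, hi)
            self.method_used_ = "sharp"
        elif self.method == "2sri":
            self.hr_, self.ci95_ = self._fit_2sri(sub, A, Xo, Z, elig)
            self.method_used_ = "2sri"
        elif self.method in ("ivprobit", "auto"):
            try:
                self.hr_, self.ci95_ = self._fit_ivprobit(sub, A, Xo, Z)
                self.method_used_ = "ivprobit-ml (probit-to-HR at covariate means)"
            except (SeparationError, np.linalg.LinAlgError) as exc:
                if self.method == "ivprobit":
                    raise
                warnings.warn(
                    f"ivprobit ML failed ({exc}); falling back to 2SRI",
                    stacklevel=2,
                )
                self.hr_, self.ci95_ = self._fit_2sri(sub, A, Xo, Z, elig)
                self.method_used_ = "2sri (ivprobit fallback)"
        else:
            raise ValueError(f"unknown CACE method {self.method!r}")

        self.n_subjects_ = int(sub["subject_id"].nunique())
        self.n_events_ = int(sub["event"].sum())
        return self


# --------------------------------------------------------------------------
# functional wrappers and diagnostics
# --------------------------------------------------------------------------

def fit_itt(pp: pd.DataFrame, spec: RDDSpec) -> DiscreteTimeRDD:
    return DiscreteTimeRDD(
        window=spec.window,
        form=spec.form,
        link=spec.link,
        covariates=spec.covariates,
        threshold=spec.threshold,
        knot=spec.knot,
    ).fit(pp)


def fit_first_stage(
    cohort: pd.DataFrame,
    window,
    init_window_months: float = 6.0,
    threshold: float = 200.0,
    period_length: float = 1.0,
) -> ARTUptakeFirstStage:
    return ARTUptakeFirstStage(
        window=window,
        init_window_months=init_window_months,
        threshold=threshold,
        period_length=period_length,
    ).fit(cohort)


def fit_cace(pp: pd.DataFrame, spec: RDDSpec, method: str = "auto") -> RDDCACE:
    return RDDCACE(
        window=spec.window,
        form=spec.form,
        link=spec.link,
        method=method,
        covariates=spec.covariates,
        threshold=spec.threshold,
        knot=spec.knot,
    ).fit(pp)


def wald_cace(itt_risk_diff: float, first_stage_jump: float) -> float:
    """Wald/instrumental-variable ratio: ITT risk difference scaled by the
    first-stage jump in uptake. Equals the ITT under perfect compliance."""
    if first_stage_jump == 0:
        raise ValueError("first-stage jump is zero; the Wald ratio is undefined")
    return itt_risk_diff / first_stage_jump


def binned_summary(
    cohort: pd.DataFrame,
    bin_width: float = 10.0,
    cd4_max: float = 350.0,
    init_window_months: float = 6.0,
    period_length: float = 1.0,
) -> pd.DataFrame:
    """Per-CD4-bin mortality hazard and 6-month treatment-uptake fraction.

    Bins are ``[0, bin_width), [bin_width, 2*bin_width), ...`` partitioning
    ``[0, cd4_max]``, with the upper endpoint folded into the last bin; a
    count at the threshold falls in the bin starting at the threshold.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cd4 = cohort["baseline_cd4"].to_numpy(dtype=float)
    n_bins = int(np.ceil(cd4_max / bin_width))
    idx = np.minimum((cd4 // bin_width).astype(int), n_bins - 1)

    months = (cohort["followup_end"].to_numpy(dtype=float) + 1.0) * period_length
    deaths = (~cohort["event_time"].isna()).to_numpy().astype(int)
    init = cohort["art_init_time"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        init6 = ((~np.isnan(init)) & (init * period_length <= init_window_months)).astype(
            float
        )

    rows = []
    for b in range(n_bins):
        mask = idx == b
        py = months[mask].sum() / 12.0
        d = int(deaths[mask].sum())
        rows.append(
            {
                "bin_left": b * bin_width,
                "bin_right": (b + 1) * bin_width,
                "n": int(mask.sum()),
                "deaths": d,
                "person_years": py,
                "hazard_per_100py": 100.0 * d / py if py > 0 else np.nan,
                "init_frac": init6[mask].mean() if mask.sum() else np.nan,
                "is_empty": int(mask.sum() == 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DensityCheck:
    ratio: float
    ci95: tuple
    n_below: int
    n_above: int
    flag: str  # "consistent" | "discontinuous" | "inconclusive"


def density_continuity_check(
    cohort: pd.DataFrame, threshold: float = 200.0, bin_width: float = 10.0
) -> DensityCheck:
    """Compare counts in the two bins adjacent to the threshold.

    Diagnostic for manipulation/heaping of the assignment variable: under a
    continuous density the ratio of the below-bin to above-bin count is near
    one. The CI is a Wilson binomial interval on the below-share, mapped to
    the ratio scale. An empty adjacent bin makes the check inconclusive.
    """
    from statsmodels.stats.proportion import proportion_confint

    cd4 = cohort["baseline_cd4"].to_numpy(dtype=float)
    n_below = int(((cd4 >= threshold - bin_width) & (cd4 < threshold)).sum())
    n_above = int(((cd4 >= threshold) & (cd4 < threshold + bin_width)).sum())
    if n_below == 0 or n_above == 0:
        return DensityCheck(np.nan, (np.nan, np.nan), n_below, n_above, "inconclusive")
    lo, hi = proportion_confint(n_below, n_below + n_above, method="wilson")
    ci = (lo / (1 - lo), hi / (1 - hi))
    ratio = n_below / n_above
    flag = "consistent" if ci[0] <= 1.0 <= ci[1] else "discontinuous"
    return DensityCheck(float(ratio), ci, n_below, n_above, flag)
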