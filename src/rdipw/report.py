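"""Presentation surfaces: balance table, estimate (forest) table,
unweighted reference fits, and figures.

Figures are presentation only; every number they show comes from
:func:`rdipw.rdd.binned_summary` or the estimate table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .msm import MarginalStructuralHazard
from .prep import classify_eligibility

__all__ = [
    "make_balance_table",
    "make_estimate_table",
    "fit_unadjusted_and_adjusted",
    "plot_binned_hazard",
    "plot_initiation",
    "plot_forest",
]

_CONTINUOUS = ("age", "baseline_cd4", "distance_km")
_CATEGORICAL = ("sex", "wealth_quintile", "residence", "education")

#: canonical presentation order of the fitted model families
MODEL_ORDER = (
    "rdd-itt",
    "rdd-cace",
    "ipw-time-invariant",
    "ipw-time-varying",
    "ipw-time-varying+censor-weights",
    "unadjusted",
    "adjusted",
)


def make_balance_table(cohort: pd.DataFrame, threshold: float = 200.0) -> pd.DataFrame:
    """Baseline characteristics stratified by eligibility.

    Continuous variables report median and IQR; categorical variables report
    counts and within-stratum percentages, with missing values as their own
    category. Stratum counts sum to the cohort size.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    eligible = classify_eligibility(cohort["baseline_cd4"].to_numpy(), threshold)
    rows = []
    strata = {"eligible": cohort[eligible], "ineligible": cohort[~eligible]}
    rows.append(
        {
            "variable": "n",
            "category": "",
            **{f"{s}_n": len(df) for s, df in strata.items()},
        }
    )
    for var in _CONTINUOUS:
        row = {"variable": var, "category": "median (IQR)"}
        for s, df in strata.items():
            if len(df):
                q1, q2, q3 = np.percentile(df[var].dropna(), [25, 50, 75])
                row[f"{s}_median"] = round(q2, 1)
                row[f"{s}_iqr"] = f"{q1:.1f}-{q3:.1f}"
            else:
                row[f"{s}_median"] = np.nan
                row[f"{s}_iqr"] = ""
        rows.append(row)
    for var in _CATEGORICAL:
        values = cohort[var]
        s_all = values.astype(object).where(~pd.isna(values), "missing").astype(str)
        for level in sorted(pd.unique(s_all)):
            row = {"variable": var, "category": level}
            for s, df in strata.items():
                sv = s_all[df.index]
                n = int((sv == level).sum())
                row[f"{s}_n"] = n
                row[f"{s}_pct"] = round(100.0 * n / len(df), 1) if len(df) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _fit_row(fit) -> dict:
    return {
        "model": getattr(fit, "model_tag_", fit.__class__.__name__),
        "hr": fit.hr_,
        "ci_low": fit.ci95_[0],
        "ci_high": fit.ci95_[1],
        "n_subjects": getattr(fit, "n_subjects_", np.nan),
        "n_events": getattr(fit, "n_events_", np.nan),
    }


def make_estimate_table(fits) -> pd.DataFrame:
    """Hazard-ratio table in canonical forest order.

    ``fits`` is a list of fitted estimators (each exposing ``hr_`` and
    ``ci95_``) or of dicts with keys model/hr/ci_low/ci_high.
    """
    if not len(fits):
        raise ValueError("need at least one fit")
    rows = [f if isinstance(f, dict) else _fit_row(f) for f in fits]
    df = pd.DataFrame(rows)

    def order_key(tag: str) -> int:
        for i, prefix in enumerate(MODEL_ORDER):
            if str(tag).startswith(prefix):
                return i
        return len(MODEL_ORDER)

    df["_order"] = df["model"].map(order_key)
    df = df.sort_values(["_order"], kind="stable").drop(columns="_order")
    return df.reset_index(drop=True)


def fit_unadjusted_and_adjusted(pp: pd.DataFrame):
    """Unweighted reference comparators for the estimate table.

    Returns the unadjusted discrete-time hazard fit of death on immediate
    initiation, and the same fit adjusted for baseline covariates.
    """
    from .msm import DEFAULT_DENOMINATOR

    unadj = MarginalStructuralHazard(
        treatment="art_immediate", covariates=(), model_tag="unadjusted"
    ).fit(pp)
    adj = MarginalStructuralHazard(
        treatment="art_immediate",
        covariates=DEFAULT_DENOMINATOR,
        model_tag="adjusted",
    ).fit(pp)
    return unadj, adj


# --------------------------------------------------------------------------
# figures (presentation only)
# --------------------------------------------------------------------------

def plot_binned_hazard(binned: pd.DataFrame, threshold: float = 200.0, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mid = (binned["bin_left"] + binned["bin_right"]) / 2
    ax.plot(mid, binned["hazard_per_100py"], "ko", ms=4)
    ax.axvline(threshold, ls="--", color="grey")
    ax.set_xlabel("baseline CD4 (cells/uL)")
    ax.set_ylabel("mortality (per 100 person-years)")
    return ax


def plot_initiation(binned: pd.DataFrame, threshold: float = 200.0, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mid = (binned["bin_left"] + binned["bin_right"]) / 2
    ax.plot(mid, binned["init_frac"], "ko", ms=4)
    ax.axvline(threshold, ls="--", color="grey")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("baseline CD4 (cells/uL)")
    ax.set_ylabel("P(ART initiation within 6 months)")
    return ax


def plot_forest(estimates: pd.DataFrame, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(estimates) + 1.5))
    ypos = np.arange(len(estimates))[::-1]
    ax.errorbar(
        estimates["hr"],
        ypos,
        xerr=[
            estimates["hr"] - estimates["ci_low"],
            estimates["ci_high"] - estimates["hr"],
        ],
        fmt="s",
        color="k",
        capsize=3,
    )
    ax.axvline(1.0, ls="--", color="grey")
    ax.set_yticks(ypos)
    ax.set_yticklabels(estimates["model"])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    return ax
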