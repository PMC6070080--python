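"""Cohort preparation: eligibility, grace period, person-period expansion,
lab-gap censoring, bandwidth restriction and incidence summaries.

All analyses in this package run on a person-period table: one row per
subject per discrete period at risk, with the per-period event indicator as
the regression outcome. Time is measured in months from the first CD4 count
(entry), and a period covers ``[t * period_length, (t + 1) * period_length)``
months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BandwidthWindow",
    "IncidenceSummary",
    "classify_eligibility",
    "classify_immediate_art",
    "expand_person_periods",
    "apply_lab_gap_censoring",
    "restrict_bandwidth",
    "incidence_rate",
    "person_time_months",
]

BASELINE_COVARIATES = (
    "baseline_cd4",
    "age",
    "sex",
    "education",
    "wealth_quintile",
    "distance_km",
    "residence",
)


@dataclass(frozen=True)
class BandwidthWindow:
    """Inclusive CD4 window around the threshold, in cells/uL."""

    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("window lower bound must not exceed upper bound")

    def contains(self, cd4) -> np.ndarray:
        cd4 = np.asarray(cd4, dtype=float)
        return (cd4 >= self.lower) & (cd4 <= self.upper)


@dataclass(frozen=True)
class IncidenceSummary:
    deaths: int
    person_years: float
    rate_per_100py: float


def classify_eligibility(baseline_cd4, threshold: float = 200.0):
    """Eligible iff CD4 strictly below the threshold ("dropped below 200").

    A count exactly at the threshold is ineligible; this boundary rule is
    configurable only through the threshold itself.
    """
    cd4 = np.asarray(baseline_cd4, dtype=float)
    if np.any(cd4 < 0):
        raise ValueError("negative CD4 count")
    out = cd4 < threshold
    return bool(out) if np.isscalar(baseline_cd4) else out


def classify_immediate_art(entry_time, art_init_time, grace_months: float = 3.0):
    """Immediate initiator iff ART started within the grace period of entry.

    ``art_init_time`` may be NaN/None (never initiated -> not immediate).
    """
    entry = np.asarray(entry_time, dtype=float)
    init = np.asarray(
        [np.nan if v is None else v for v in np.atleast_1d(art_init_time)], dtype=float
    ) if not isinstance(art_init_time, (np.ndarray, pd.Series)) else np.asarray(art_init_time, dtype=float)
    entry = np.broadcast_to(entry, init.shape)
    with np.errstate(invalid="ignore"):
        if np.any(init < entry):
            raise ValueError("ART initiation before entry into care")
    out = np.where(np.isnan(init), False, (init - entry) <= grace_months)
    return bool(out[0]) if out.size == 1 and np.isscalar(art_init_time) else out


def _parse_int_list(s) -> list[int]:
    if isinstance(s, (list, tuple, np.ndarray)):
        return [int(v) for v in s]
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return []
    return [int(float(tok)) for tok in str(s).split(";")]


def _parse_float_list(s) -> list[float]:
    if isinstance(s, (list, tuple, np.ndarray)):
        return [float(v) for v in s]
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return []
    return [float(tok) for tok in str(s).split(";")]


def expand_person_periods(
    cohort: pd.DataFrame,
    period_length: float = 1.0,
    grace_months: float = 3.0,
    threshold: float = 200.0,
) -> pd.DataFrame:
    """Expand a subject-level cohort into a person-period table.

    Person-time is conserved exactly: each subject contributes
    ``followup_end + 1`` rows of ``period_length`` months. ``art_now``
    switches on in the period containing the initiation time and stays on
    (treatment is absorbing); ``art_immediate`` is the baseline grace-period
    definition repeated on every row. ``current_cd4`` is the most recent
    recorded laboratory CD4 carried forward, ``last_lab_time`` its period.
    """
    if cohort.empty:
        raise ValueError("cannot expand an empty cohort")
    if period_length <= 0:
        raise ValueError("period_length must be positive")
    fe = cohort["followup_end"].to_numpy()
    if np.any(fe < 0):
        raise ValueError("negative follow-up duration")
    ev = cohort["event_time"].to_numpy(dtype=float)
    if np.any(ev[~np.isnan(ev)] > fe[~np.isnan(ev)]):
        raise ValueError("event after end of follow-up")

    n_rows = fe + 1
    idx = np.repeat(np.arange(len(cohort)), n_rows)
    period = np.concatenate([np.arange(k) for k in n_rows])

    init = cohort["art_init_time"].to_numpy(dtype=float)[idx]
    with np.errstate(invalid="ignore"):
        art_now = (~np.isnan(init)) & (period >= init)
    art_imm = classify_immediate_art(
        cohort["entry_time"].to_numpy(),
        cohort["art_init_time"].to_numpy(dtype=float),
        grace_months=grace_months / period_length,
    )

    event_row = np.zeros(idx.size, dtype=int)
    has_event = ~np.isnan(ev)
    event_row[(period == fe[idx]) & has_event[idx]] = 1

    # carry the most recent recorded lab forward
    lab_t_lists = [_parse_int_list(v) for v in cohort["lab_times"]]
    lab_v_lists = [_parse_float_list(v) for v in cohort["lab_cd4"]]
    sub_of_lab = np.concatenate(
        [np.full(len(ts), i) for i, ts in enumerate(lab_t_lists)]
    )
    lab_t = np.concatenate([np.asarray(ts, dtype=float) for ts in lab_t_lists])
    lab_v = np.concatenate([np.asarray(vs, dtype=float) for vs in lab_v_lists])
    big = float(max(int(fe.max()), int(lab_t.max()) if lab_t.size else 0) + 2)
    lab_key = sub_of_lab * big + lab_t
    row_key = idx * big + period
    order = np.argsort(lab_key, kind="stable")
    lab_key, lab_t, lab_v = lab_key[order], lab_t[order], lab_v[order]
    pos = np.searchsorted(lab_key, row_key, side="right") - 1
    # every subject has a baseline lab at period 0, so pos is always valid
    current_cd4 = lab_v[pos]
    last_lab = lab_t[pos]

    pp = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy()[idx],
            "period": period,
            "period_start": period * period_length,
            "period_stop": (period + 1) * period_length,
            "at_risk": 1,
            "event": event_row,
            "art_now": art_now.astype(int),
            "art_immediate": np.asarray(art_imm, dtype=int)[idx],
            "current_cd4": current_cd4,
            "last_lab_time": last_lab,
            "censored_this_period": 0,
        }
    )
    for col in BASELINE_COVARIATES:
        if col in cohort.columns:
            pp[col] = cohort[col].to_numpy()[idx]
    if "baseline_cd4" in pp.columns:
        pp["eligible"] = classify_eligibility(
            pp["baseline_cd4"].to_numpy(), threshold
        ).astype(int)
    return pp


def apply_lab_gap_censoring(pp: pd.DataFrame, gap_months: float = 12.0) -> pd.DataFrame:
    """Administratively censor follow-up at a long gap in lab measurements.

    A subject is censored at the first period whose start lies ``gap_months``
    or more after the most recent recorded lab measurement: rows from that
    period on are dropped (events there removed) and the last retained row is
    flagged ``censored_this_period``. Applying the rule twice is a no-op.
    """
    period_length = (pp["period_stop"] - pp["period_start"]).to_numpy()
    months_since_lab = (
        pp["period_start"].to_numpy() - pp["last_lab_time"].to_numpy() * period_length
    )
    hit = months_since_lab >= gap_months

    df = pp.copy()
    df["_hit"] = hit
    first_hit = (
        df[df["_hit"]].groupby("subject_id")["period"].min().rename("_censor_period")
    )
    df = df.merge(first_hit, on="subject_id", how="left")
    keep = df["_censor_period"].isna() | (df["period"] < df["_censor_period"])
    out = df[keep].copy()
    # flag last retained row of each newly censored subject
    censored_subjects = df.loc[~df["_censor_period"].isna(), "subject_id"].unique()
    if len(censored_subjects):
        last_rows = (
            out[out["subject_id"].isin(censored_subjects)]
            .groupby("subject_id")["period"]
            .idxmax()
        )
        out.loc[last_rows, "censored_this_period"] = 1
    return out.drop(columns=["_hit", "_censor_period"]).reset_index(drop=True)


def restrict_bandwidth(table: pd.DataFrame, window: BandwidthWindow) -> pd.DataFrame:
    """Subset rows with baseline CD4 inside the inclusive window."""
    mask = window.contains(table["baseline_cd4"].to_numpy())
    return table[mask].reset_index(drop=True)


def person_time_months(pp: pd.DataFrame) -> float:
    """Total person-time in a person-period table, in months."""
    return float((pp["period_stop"] - pp["period_start"]).sum())


def incidence_rate(deaths: int, person_years: float) -> IncidenceSummary:
    """Mortality incidence per 100 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return IncidenceSummary(
        deaths=int(deaths),
        person_years=float(person_years),
        rate_per_100py=100.0 * deaths / person_years,
    )
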