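"""Synthetic cohort generator with known ground truth.

Generates subject-level records with the statistical structure the two
causal pipelines assume: a continuously distributed assignment variable
(baseline CD4) whose density is continuous at the eligibility threshold, a
jump in treatment-initiation probability at the threshold (fuzzy
compliance, no defiers by construction), a mortality hazard that decreases
in CD4 so that unadjusted treated-vs-untreated comparisons are confounded
by indication, a truly protective conditional treatment effect, 6-monthly
laboratory monitoring with missed visits and absorbing disengagement from
care, and a binary asset battery summarised into a wealth quintile by
principal components analysis.

The potential-outcome hazard is a continuous function of CD4 everywhere;
the only discontinuity at the threshold is in treatment probability, so the
regression-discontinuity continuity assumption holds by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.decomposition import PCA

from .config import ConfigError, SimConfig

__all__ = [
    "generate_assets_and_wealth",
    "wealth_quintiles_from_assets",
    "assign_treatment",
    "simulate_outcomes",
    "generate_cohort",
    "baseline_hazard_rate",
]

EDUCATION_LEVELS = ("<=7", "8-12", ">12")
RESIDENCE_LEVELS = ("rural", "periurban", "urban")
MISSING = "missing"

_CD4_FLOOR = 1.0
_CD4_CEIL = 1200.0


# --------------------------------------------------------------------------
# assets and wealth index
# --------------------------------------------------------------------------

def _asset_params(n_assets: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-asset intercepts and wealth loadings.

    Deterministic so that cohorts drawn under different seeds share the same
    asset battery; prevalences span rare to common items and loadings span
    weakly to strongly wealth-related items.
    """
    alphas = np.linspace(-2.0, 2.0, n_assets)
    loadings = 0.5 + 1.0 * (np.arange(n_assets) % 5) / 4.0
    return alphas, loadings


def generate_assets_and_wealth(
    n_subjects: int,
    n_assets: int,
    rng: np.random.Generator,
    missing_frac: float = 0.0,
):
    """Draw a binary asset matrix and derive wealth quintiles from its PCA.

    The wealth quintile is the quintile bin of the first principal-component
    score of the asset matrix (sign-fixed so that higher score means more
    assets). A ``missing_frac`` share of subjects has the whole battery and
    the quintile set to missing (NaN).

    Returns
    -------
    assets : ndarray of shape (n_subjects, n_assets), float with NaN rows
    quintile : ndarray of shape (n_subjects,), values 1..5 or NaN
    """
    if n_assets < 2:
        raise ConfigError("n_assets must be at least 2")
    if n_subjects == 0:
        return np.empty((0, n_assets)), np.empty(0)
    alphas, loadings = _asset_params(n_assets)
    z = rng.normal(size=n_subjects)
    p = expit(alphas[None, :] + loadings[None, :] * z[:, None])
    assets = (rng.uniform(size=(n_subjects, n_assets)) < p).astype(float)
    missing = rng.uniform(size=n_subjects) < missing_frac
    assets[missing] = np.nan

    observed = ~missing
    quintile = np.full(n_subjects, np.nan)
    if observed.sum() > 0:
        quintile[observed] = wealth_quintiles_from_assets(assets[observed])
    return assets, quintile


def wealth_quintiles_from_assets(assets: np.ndarray) -> np.ndarray:
    """Quintile bins of the first principal-component score of a complete
    binary asset matrix (rows = subjects). The score is sign-fixed so that
    higher means owning more assets; tied scores share a bin, so fewer than
    five distinct quintiles can occur in degenerate batteries."""
    assets = np.asarray(assets, dtype=float)
    n = assets.shape[0]
    if n < 2:
        return np.ones(n)
    if np.allclose(assets.var(axis=0), 0.0):
        raise ValueError(
            "degenerate asset matrix: every asset column has zero variance"
        )
    score = PCA(n_components=1).fit_transform(assets)[:, 0]
    wealthier = assets.sum(axis=1) - assets.sum(axis=1).mean()
    if np.dot(score, wealthier) < 0:
        score = -score
    # quintile = ceil(5 * empirical CDF); ties share a bin monotonically
    from scipy.stats import rankdata

    cdf = rankdata(score, method="max") / n
    return np.ceil(5.0 * cdf - 1e-12).clip(1, 5)


# --------------------------------------------------------------------------
# treatment assignment
# --------------------------------------------------------------------------

def assign_treatment(
    baseline_cd4: np.ndarray,
    threshold: float,
    p_init_below: float,
    p_init_above: float,
    rng: np.random.Generator,
    late_init_hazard: float = 0.03,
    n_periods: int = 48,
):
    """Assign ART initiation times under the fuzzy threshold rule.

    Immediate initiation (period 0) occurs with probability ``p_init_below``
    if CD4 is strictly below the threshold, else ``p_init_above``. A shared
    uniform draw per subject determines the response under either assignment,
    so the compliance class is well defined and monotone (no defiers):
    ``always`` if the subject would initiate immediately on either side,
    ``complier`` if only when eligible, ``never`` otherwise. Subjects without
    immediate initiation defer and initiate later with a constant per-period
    hazard ``late_init_hazard`` (0 disables late initiation).

    Returns
    -------
    art_init_time : float ndarray, period index of initiation or NaN
    compliance : object ndarray in {"always", "complier", "never"}
    """
    if not (0.0 <= p_init_below <= 1.0 and 0.0 <= p_init_above <= 1.0):
        raise ConfigError("initiation probabilities must lie in [0, 1]")
    if p_init_below < p_init_above:
        raise ConfigError("p_init_below >= p_init_above required (no defiers)")
    cd4 = np.asarray(baseline_cd4, dtype=float)
    n = cd4.size
    u = rng.uniform(size=n)
    eligible = cd4 < threshold
    immediate = u < np.where(eligible, p_init_below, p_init_above)

    compliance = np.where(
        u < p_init_above, "always", np.where(u < p_init_below, "complier", "never")
    ).astype(object)

    init = np.where(immediate, 0.0, np.nan)
    if late_init_hazard > 0.0:
        late = rng.geometric(late_init_hazard, size=n).astype(float)  # >= 1
        late[late > n_periods - 1] = np.nan
        init = np.where(immediate, 0.0, late)
    return init, compliance


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def baseline_hazard_rate(cd4, config: SimConfig) -> np.ndarray:
    """Per-period baseline event rate at a given CD4, strictly decreasing
    in CD4 when ``hazard_cd4_slope`` is negative."""
    cd4 = np.asarray(cd4, dtype=float)
    rate = config.hazard_scale * np.exp(config.hazard_cd4_slope * cd4)
    bad = ~np.isfinite(rate) | (rate <= 0.0)
    if np.any(bad):
        offender = cd4[np.argmax(bad)]
        raise ValueError(
            f"per-period event probability outside (0, 1) at CD4 = {offender}"
        )
    return rate


def _cd4_trajectory(baseline_cd4, art_init_time, config: SimConfig) -> np.ndarray:
    """True CD4 per subject-period: linear decline off ART, recovery on ART."""
    n = baseline_cd4.size
    t = np.arange(config.n_periods, dtype=float)[None, :]
    t0 = np.where(np.isnan(art_init_time), np.inf, art_init_time)[:, None]
    months = t * config.period_length
    months0 = np.minimum(months, t0 * config.period_length)
    on_art_months = np.maximum(months - t0 * config.period_length, 0.0)
    cd4 = (
        baseline_cd4[:, None]
        - config.cd4_decline_rate * months0
        + config.cd4_recovery_rate * on_art_months
    )
    return np.clip(cd4, _CD4_FLOOR, _CD4_CEIL)


def simulate_outcomes(
    baseline_cd4: np.ndarray,
    art_init_time: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Simulate death times, lab-visit histories and care disengagement.

    The per-period event probability is the complementary log-log transform
    of the baseline rate (a decreasing function of the baseline CD4 count)
    times the treatment effect::

        p_t = 1 - exp(-rate(baseline_cd4) * exp(beta_t * A_t)),
        beta_t = true_log_hr + trend_per_year * years_t

    so ``true_log_hr`` is a discrete-time log hazard ratio. Lab visits follow
    the ``lab_interval`` schedule; each scheduled visit after baseline is
    skipped with probability ``p_lab_miss`` (optionally CD4-dependent) and
    stops permanently once the subject disengages from care (absorbing, with
    per-period hazard ``dropout_rate``, optionally CD4-dependent). Mortality
    follow-up continues to administrative end regardless of disengagement,
    mirroring population-surveillance outcome ascertainment.

    Returns a dict of per-subject arrays/lists: ``event_time``,
    ``followup_end``, ``lab_times``, ``lab_cd4``.
    """
    cd4_path = _cd4_trajectory(
        np.asarray(baseline_cd4, float), np.asarray(art_init_time, float), config
    )
    n, T = cd4_path.shape
    t = np.arange(T, dtype=float)[None, :]
    t0 = np.where(np.isnan(art_init_time), np.inf, art_init_time)[:, None]
    on_art = t >= t0

    # the mortality hazard is driven by the assignment variable (baseline
    # CD4) and current treatment; the CD4 *trajectory* below feeds only the
    # laboratory monitoring stream
    rate = baseline_hazard_rate(np.asarray(baseline_cd4, float), config)[:, None]
    rate = np.broadcast_to(rate, (n, T))
    years = t * config.period_length / 12.0
    beta = config.true_log_hr + config.true_log_hr_trend_per_year * years
    p_event = 1.0 - np.exp(-rate * np.exp(beta * on_art))

    ev_draw = rng.uniform(size=(n, T)) < p_event
    event_period = np.where(ev_draw.any(axis=1), ev_draw.argmax(axis=1), T)

    # care disengagement (stops labs only)
    if config.dropout_rate > 0.0:
        p_dis = expit(
            logit(config.dropout_rate)
            + config.dropout_cd4_slope * (cd4_path - config.threshold) / 100.0
        )
        dis_draw = rng.uniform(size=(n, T)) < p_dis
        dis_period = np.where(dis_draw.any(axis=1), dis_draw.argmax(axis=1), T)
    else:
        dis_period = np.full(n, T)

    event_time = np.where(event_period < T, event_period.astype(float), np.nan)
    followup_end = np.where(event_period < T, event_period, T - 1)

    # lab schedule (period indices); baseline visit always recorded
    sched_months = np.arange(0, config.n_periods * config.period_length, config.lab_interval)
    sched_periods = np.unique((sched_months / config.period_length).astype(int))
    sched_periods = sched_periods[sched_periods < T]
    p_miss = expit(
        logit(np.clip(config.p_lab_miss, 1e-9, 1 - 1e-9))
        + config.lab_miss_cd4_slope * (cd4_path[:, sched_periods] - config.threshold) / 100.0
    ) if config.p_lab_miss > 0.0 or config.lab_miss_cd4_slope != 0.0 else np.zeros((n, sched_periods.size))
    miss_draw = rng.uniform(size=(n, sched_periods.size)) < p_miss
    miss_draw[:, sched_periods == 0] = False

    lab_times: list[list[int]] = []
    lab_cd4: list[list[float]] = []
    for i in range(n):
        keep = (
            (sched_periods <= followup_end[i])
            & (sched_periods < dis_period[i])
            & ~miss_draw[i]
        )
        times = sched_periods[keep]
        if times.size == 0 or times[0] != 0:
            times = np.concatenate(([0], times))
        lab_times.append(times.tolist())
        lab_cd4.append(np.round(cd4_path[i, times], 1).tolist())

    return {
        "event_time": event_time,
        "followup_end": followup_end.astype(int),
        "lab_times": lab_times,
        "lab_cd4": lab_cd4,
    }


# --------------------------------------------------------------------------
# covariates and full cohort
# --------------------------------------------------------------------------

def _draw_cd4(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Mixture of a uniform core and a triangular component bunched away
    from the threshold (mode at cd4_min); density continuous everywhere."""
    w = config.mixture_weight()
    lo, hi = config.cd4_min, config.cd4_max
    span = hi - lo
    take_unif = rng.uniform(size=n) < w
    unif = lo + span * rng.uniform(size=n)
    tri = lo + span * (1.0 - np.sqrt(rng.uniform(size=n)))
    return np.where(take_unif, unif, tri)


def _draw_categorical(rng, n, levels, probs) -> np.ndarray:
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def _apply_missing(values, rng, frac) -> np.ndarray:
    out = values.copy()
    out[rng.uniform(size=out.size) < frac] = MISSING
    return out


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observable cohort table and a hidden truth table.

    The cohort table is what the estimators see (one row per subject); the
    truth table carries the compliance class and counterfactual hazard
    parameters used by recovery tests. Identical config (including seed)
    reproduces both tables bit-for-bit.
    """
    config.validate()
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)
    if n == 0:
        cohort = pd.DataFrame(
            columns=[
                "subject_id", "baseline_cd4", "age", "sex", "education",
                "wealth_quintile", "distance_km", "residence", "entry_time",
                "art_init_time", "lab_times", "lab_cd4", "event_time",
                "followup_end",
            ]
        )
        truth = pd.DataFrame(
            columns=["subject_id", "compliance_class", "baseline_rate", "true_log_hr"]
        )
        return cohort, truth

    # the recorded (0.1-cell) baseline CD4 is the assignment variable and
    # drives eligibility, uptake and hazard alike
    cd4 = np.round(_draw_cd4(config, rng, n), 1)

    # demographics loosely matched to the study's baseline table
    age = np.clip(rng.normal(34.5, 9.5, size=n), 16.0, 80.0)
    p_female = expit(0.92 + 0.0032 * (cd4 - config.threshold))
    sex = np.where(rng.uniform(size=n) < p_female, "female", "male").astype(object)
    education = _draw_categorical(rng, n, EDUCATION_LEVELS, (0.34, 0.57, 0.09))
    education = _apply_missing(education, rng, config.education_missing_frac)
    residence = _draw_categorical(rng, n, RESIDENCE_LEVELS, (0.52, 0.37, 0.11))
    residence = _apply_missing(residence, rng, config.residence_missing_frac)
    distance = rng.gamma(shape=2.0, scale=1.55, size=n)

    assets, quintile = generate_assets_and_wealth(
        n, config.n_assets, rng, missing_frac=config.asset_missing_frac
    )

    art_init, compliance = assign_treatment(
        cd4,
        config.threshold,
        config.p_init_below,
        config.p_init_above,
        rng,
        late_init_hazard=config.late_init_hazard,
        n_periods=config.n_periods,
    )
    out = simulate_outcomes(cd4, art_init, config, rng)

    cohort = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "baseline_cd4": cd4,
            "age": np.round(age, 1),
            "sex": sex,
            "education": education,
            "wealth_quintile": quintile,
            "distance_km": np.round(distance, 2),
            "residence": residence,
            "entry_time": 0,
            "art_init_time": art_init,
            "lab_times": [";".join(str(t) for t in ts) for ts in out["lab_times"]],
            "lab_cd4": [";".join(f"{v:g}" for v in vs) for vs in out["lab_cd4"]],
            "event_time": out["event_time"],
            "followup_end": out["followup_end"],
        }
    )
    for j in range(config.n_assets):
        cohort[f"asset_{j:02d}"] = assets[:, j]

    truth = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "compliance_class": compliance,
            "baseline_rate": baseline_hazard_rate(cd4, config),
            "true_log_hr": config.true_log_hr,
        }
    )
    return cohort, truth
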