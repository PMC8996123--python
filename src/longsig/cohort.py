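"""New-user cohort analyses of treatment effects.

The analysis population is the *new-user cohort*: participants with no
second-generation DMT exposure before enrolment.  Three layers sit on top:

* **primary** -- a stratified episode analysis: within strata defined by
  any first-generation use before second-generation initiation, outcomes
  while exposed to second-generation DMT are compared to outcomes while
  unexposed; follow-up is censored at second-generation cessation, and a
  participant contributes at most one unexposed then one exposed episode;
* **secondary** -- marginal structural models on the 6-month interval
  panel with four exposure parameterizations (current class; current class
  plus carryover of other classes in the past 6 months; cumulative months
  per class; exponentially decayed cumulative exposure);
* **tertiary** -- the carryover model extended with current-class x
  carryover interaction terms.

Outcome models are fitted either as pooled discrete-time log-linear
(Poisson) regressions with person-time offsets and cluster-robust
sandwich variance (the default, respecting weights and repeated intervals
per participant) or as time-varying Cox partial-likelihood fits (Efron
ties) via lifelines; the two agree closely on simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (
    DRUG_CLASS,
    MONTH_DAYS,
    DrugClass,
    PatientMonthPanel,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort selection and primary episodes
# ---------------------------------------------------------------------------

def select_new_user_cohort(participants: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Participants with no pre-enrolment second-generation DMT episode."""
    if episodes.empty:
        return participants.copy()
    ep = episodes.copy()
    ep["start_date"] = pd.to_datetime(ep["start_date"])
    parts = participants.copy()
    parts["enrolment_date"] = pd.to_datetime(parts["enrolment_date"])
    enrol = parts.set_index(parts["id"].astype(str))["enrolment_date"]
    ep_enrol = enrol.reindex(ep["participant_id"].astype(str)).to_numpy()
    is_2g = ep["drug"].map(lambda d: DRUG_CLASS.get(d)) == DrugClass.SECOND_GEN
    pre_2g = is_2g.to_numpy() & (ep["start_date"].to_numpy() < ep_enrol)
    excluded = set(ep.loc[pre_2g, "participant_id"].astype(str))
    return parts.loc[~parts["id"].astype(str).isin(excluded)].reset_index(drop=True)


def build_primary_episodes(
    cohort: pd.DataFrame,
    episodes: pd.DataFrame,
    panel: PatientMonthPanel,
    outcome_key,
    covariate_cols=(),
) -> pd.DataFrame:
    """Episode table for the primary stratified exposed/unexposed analysis.

    Per participant: an unexposed episode from enrolment to first
    second-generation initiation (or end of follow-up), and an exposed
    episode from initiation to second-generation cessation or censoring.
    Months after cessation do not contribute.  The stratum records any
    first-generation use prior to second-generation initiation (or to the
    end of follow-up when never initiated), pre-enrolment history included.
    Episodes are truncated at the first occurrence of ``outcome_key``.
    """
    f = panel.frame
    cohort_ids = set(cohort["id"].astype(str))
    f = f.loc[f["participant_id"].isin(cohort_ids)]
    ev_col = panel.event_col(outcome_key)

    # pre-enrolment first-gen history (panel cls only covers on-study months)
    pre_fg: set = set()
    if not episodes.empty:
        ep = episodes.copy()
        ep["start_date"] = pd.to_datetime(ep["start_date"])
        parts = cohort.set_index(cohort["id"].astype(str))
        enrol = pd.to_datetime(parts["enrolment_date"]).reindex(ep["participant_id"].astype(str))
        is_fg = ep["drug"].map(lambda d: DRUG_CLASS.get(d)) == DrugClass.FIRST_GEN
        pre = is_fg.to_numpy() & (ep["start_date"].to_numpy() < enrol.to_numpy())
        pre_fg = set(ep.loc[pre, "participant_id"].astype(str))

    rows = []
    for pid, sub in f.groupby("participant_id", sort=False):
        sub = sub.sort_values("month_index")
        months = sub["month_index"].to_numpy()
        cls = sub["cls"].to_numpy()
        ev = sub[ev_col].to_numpy()
        T = months[-1] + 1
        on2 = cls == DrugClass.SECOND_GEN.value
        if on2.any():
            t1 = int(months[np.argmax(on2)])
            after = months >= t1
            off = after & ~on2
            t2 = int(months[np.argmax(off)]) if off.any() else int(T)
        else:
            t1, t2 = int(T), int(T)
        fg_window = months < t1
        stratum = (
            "PRIOR_FIRST_GEN"
            if (pid in pre_fg or (cls[fg_window] == DrugClass.FIRST_GEN.value).any())
            else "NO_PRIOR_FIRST_GEN"
        )
        for exposed, a, b in ((0, 0, t1), (1, t1, t2)):
            if b <= a:
                continue
            span = (months >= a) & (months < b)
            ev_span = ev & span
            if ev_span.any():
                ev_month = int(months[np.argmax(ev_span)])
                stop, outcome = ev_month + 1, 1
            else:
                stop, outcome = b, 0
            row = {
                "participant_id": pid,
                "stratum": stratum,
                "exposed": exposed,
                "start_month": a,
                "stop_month": stop,
                "event": outcome,
            }
            start_row = sub.loc[months == a]
            for c in covariate_cols:
                row[c] = start_row[c].iloc[0] if len(start_row) else np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        empty = out["stop_month"] <= out["start_month"]
        if empty.any():
            logger.info("dropping %d zero-length episode(s)", int(empty.sum()))
            out = out.loc[~empty].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# secondary exposure parameterizations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureModelConfig:
    model: str = "A"  # A current / B carryover / C cumulative / D decayed
    carryover_window: int = 6
    decay_half_life: float = 6.0

    def __post_init__(self):
        if self.model not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown exposure model {self.model!r}")
        if self.carryover_window <= 0 or self.decay_half_life <= 0:
            raise ValueError("window and half-life must be positive")


def build_exposure_covariates(
    panel: PatientMonthPanel,
    config: ExposureModelConfig,
    interval_months: int = 6,
) -> pd.DataFrame:
    """Exposure covariate block per (participant, interval) under models A-D.

    A: current-class indicators.  B: A plus indicators of any *other*
    class in the past ``carryover_window`` months.  C: cumulative months
    of each active class up to the interval start.  D: as C but with each
    month's contribution decayed by 2^(-lag / half_life).
    """
    f = panel.frame.sort_values(["participant_id", "month_index"], kind="mergesort")
    rows = []
    for pid, sub in f.groupby("participant_id", sort=False):
        months = sub["month_index"].to_numpy()
        cls = sub["cls"].to_numpy()
        for t in months[months % interval_months == 0]:
            i = int(np.argmax(months == t))
            cur = cls[i]
            row = {"participant_id": pid, "interval": int(t) // interval_months,
                   "cur_FIRST_GEN": float(cur == "FIRST_GEN"),
                   "cur_SECOND_GEN": float(cur == "SECOND_GEN")}
            if config.model == "B":
                lo = t - config.carryover_window
                window = (months >= lo) & (months < t)
                for c in ("FIRST_GEN", "SECOND_GEN", "NONE"):
                    if c == cur:
                        row[f"carry_{c}"] = 0.0
                    else:
                        row[f"carry_{c}"] = float((cls[window] == c).any())
                row.pop("carry_NONE", None)  # carryover of no-treatment is not modelled
            elif config.model == "C":
                past = months <= t
                row["cum_FIRST_GEN"] = float((cls[past] == "FIRST_GEN").sum())
                row["cum_SECOND_GEN"] = float((cls[past] == "SECOND_GEN").sum())
            elif config.model == "D":
                past = months <= t
                lag = t - months[past]
                decay = np.power(2.0, -lag / config.decay_half_life)
                row["dec_FIRST_GEN"] = float(decay[(cls[past] == "FIRST_GEN")].sum())
                row["dec_SECOND_GEN"] = float(decay[(cls[past] == "SECOND_GEN")].sum())
            rows.append(row)
    return pd.DataFrame(rows)


def exposure_term_columns(config: ExposureModelConfig) -> list:
    base = ["cur_FIRST_GEN", "cur_SECOND_GEN"]
    if config.model == "A":
        return base
    if config.model == "B":
        return base + ["carry_FIRST_GEN", "carry_SECOND_GEN"]
    if config.model == "C":
        return ["cum_FIRST_GEN", "cum_SECOND_GEN"]
    return ["dec_FIRST_GEN", "dec_SECOND_GEN"]


# ---------------------------------------------------------------------------
# outcome models
# ---------------------------------------------------------------------------

def fit_outcome_model(
    data: pd.DataFrame,
    exposure_cols,
    outcome_col: str = "event",
    persontime_col: str = "persontime",
    weight_col: str | None = "weight",
    cluster_col: str = "participant_id",
    adjust_cols=(),
    method: str = "poisson",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Hazard-ratio estimates with cluster-robust sandwich variance.

    ``method='poisson'`` (default) fits the pooled discrete-time
    log-linear rate model: outcome counts on exposure terms with a
    log person-time offset, variance clustered on the participant.
    ``method='cox'`` fits a weighted time-varying Cox model via lifelines
    (requires ``start_month``/``stop_month`` columns) with robust variance.
    Returns one row per exposure term: hazard ratio, CI, SE.
    """
    import scipy.stats as st

    exposure_cols = list(exposure_cols)
    if data[outcome_col].sum() == 0:
        raise ValueError(f"no events for outcome column {outcome_col!r}")
    z = st.norm.ppf(0.5 + ci_level / 2.0)

    if method == "poisson":
        import statsmodels.api as sm

        X = sm.add_constant(data[exposure_cols + list(adjust_cols)].astype(float))
        w = data[weight_col].to_numpy(dtype=float) if weight_col and weight_col in data else None
        offset = np.log(data[persontime_col].to_numpy(dtype=float))
        model = sm.GLM(
            data[outcome_col].to_numpy(dtype=float), X,
            family=sm.families.Poisson(), offset=offset,
            var_weights=w if w is not None else None,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            # var_weights + sandwich covariance is exactly what we want here
            _warnings.filterwarnings("ignore", message="cov_type not fully supported")
            res = model.fit(
                cov_type="cluster", cov_kwds={"groups": data[cluster_col]}, maxiter=200,
            )
        rows = []
        for term in exposure_cols:
            b, se = res.params[term], res.bse[term]
            rows.append({
                "term": term, "coef": b, "hr": np.exp(b), "se": se,
                "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se),
                "n_events": float(data[outcome_col].sum()), "n_rows": len(data),
            })
        return pd.DataFrame(rows)

    if method == "cox":
        from lifelines import CoxTimeVaryingFitter

        df = data.copy()
        df["start"] = df["start_month"].astype(float)
        df["stop"] = df["stop_month"].astype(float)
        keep = ["start", "stop", outcome_col, cluster_col] + exposure_cols + list(adjust_cols)
        if weight_col and weight_col in df:
            keep.append(weight_col)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            df[keep], id_col=cluster_col, start_col="start", stop_col="stop",
            event_col=outcome_col,
            weights_col=weight_col if weight_col and weight_col in df else None,
        )
        rows = []
        for term in exposure_cols:
            b = ctv.params_[term]
            se = ctv.standard_errors_[term]
            rows.append({
                "term": term, "coef": b, "hr": np.exp(b), "se": se,
                "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se),
                "n_events": float(data[outcome_col].sum()), "n_rows": len(data),
            })
        return pd.DataFrame(rows)

    raise ValueError(f"unknown method {method!r}")


def interval_outcome_table(
    panel: PatientMonthPanel,
    outcome_key,
    interval_months: int = 6,
) -> pd.DataFrame:
    """Per-(participant, interval) incident event counts and person-time.

    Follow-up stops after the interval containing the first event
    (incident-event analysis); person-time within the event interval runs
    up to and including the event month.
    """
    from .panel import apply_incident_censoring

    censored = apply_incident_censoring(panel, outcome_key)
    f = censored.frame
    g = f.assign(interval=f["month_index"] // interval_months).groupby(
        ["participant_id", "interval"], sort=False
    )
    out = g.agg(
        event=(panel.event_col(outcome_key), "sum"),
        persontime=(panel.event_col(outcome_key), "size"),
    ).reset_index()
    out["event"] = out["event"].astype(float)
    return out


def secondary_msm(
    panel: PatientMonthPanel,
    exposure_config: ExposureModelConfig,
    outcome_key,
    weight_set=None,
    interval_months: int = 6,
    method: str = "poisson",
) -> pd.DataFrame:
    """Secondary MSM analysis: exposure model A-D, weighted pooled fit."""
    outcomes = interval_outcome_table(panel, outcome_key, interval_months)
    expo = build_exposure_covariates(panel, exposure_config, interval_months)
    df = outcomes.merge(expo, on=["participant_id", "interval"], how="left")
    if weight_set is not None:
        df = df.merge(
            weight_set.frame[["participant_id", "interval", "weight"]],
            on=["participant_id", "interval"], how="left",
        )
        df["weight"] = df["weight"].fillna(1.0)
    else:
        df["weight"] = 1.0
    terms = exposure_term_columns(exposure_config)
    df[terms] = df[terms].fillna(0.0)
    return fit_outcome_model(df, terms, method=method)


def tertiary_interaction(
    panel: PatientMonthPanel,
    outcome_key,
    weight_set=None,
    interval_months: int = 6,
) -> pd.DataFrame:
    """Carryover model (B) plus current-class x carryover interaction terms."""
    cfg = ExposureModelConfig(model="B")
    outcomes = interval_outcome_table(panel, outcome_key, interval_months)
    expo = build_exposure_covariates(panel, cfg, interval_months)
    df = outcomes.merge(expo, on=["participant_id", "interval"], how="left")
    if weight_set is not None:
        df = df.merge(
            weight_set.frame[["participant_id", "interval", "weight"]],
            on=["participant_id", "interval"], how="left",
        )
        df["weight"] = df["weight"].fillna(1.0)
    else:
        df["weight"] = 1.0
    terms = exposure_term_columns(cfg)
    df[terms] = df[terms].fillna(0.0)
    df["ix_cur2G_carry1G"] = df["cur_SECOND_GEN"] * df["carry_FIRST_GEN"]
    all_terms = terms + ["ix_cur2G_carry1G"]
    if df["ix_cur2G_carry1G"].sum() == 0:
        raise ValueError("interaction inestimable: no switchers with carryover under current "
                         "second-generation exposure")
    return fit_outcome_model(df, all_terms)
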