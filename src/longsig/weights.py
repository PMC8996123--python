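"""Confounder control by inverse-probability-of-treatment weighting.

Two constructions are provided:

* **Episode propensity weights** for the primary cohort analysis: each
  exposure episode is weighted by the inverse of the estimated probability
  of its observed exposure status, from a pooled logistic regression on
  covariates measured at episode start, fitted within stratum.

* **Stabilized time-varying IPTW** for the marginal structural analyses
  and the weighted signal-detection pathway: treatment class is modelled
  at 6-month intervals by multinomial logistic regression; the stabilized
  weight at interval t is the product over k <= t of

      Pr(A_k = a_k | A_{k-1}, baseline) / Pr(A_k = a_k | A_{k-1}, covariates_k)

  i.e. the probability of the participant's observed treatment history
  under the numerator model divided by that under the covariate-history
  model.  Weights are truncated at configurable percentiles (default
  1st/99th) against extreme-weight instability.

Positivity is enforced: a denominator probability at machine tolerance is
an error naming the offending stratum, not a silent large weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .disprop import ContingencyTable, tabulate
from .panel import PatientMonthPanel

logger = logging.getLogger(__name__)

CLASS_ORDER = ("NONE", "FIRST_GEN", "SECOND_GEN")


class PositivityError(RuntimeError):
    pass


def panel_to_intervals(
    panel: PatientMonthPanel,
    interval_months: int = 6,
    covariate_cols=None,
) -> pd.DataFrame:
    """Snapshot the panel at interval starts.

    Returns one row per (participant, interval) with the treatment class
    and covariate values at the interval's first month, the previous
    interval's class (``prev_cls``, NONE before enrolment), and the number
    of panel months the interval actually contains.
    """
    f = panel.frame
    cols = ["participant_id", "month_index", "cls"] + list(covariate_cols or [])
    snap = f.loc[f["month_index"] % interval_months == 0, cols].copy()
    snap["interval"] = snap["month_index"] // interval_months
    counts = (
        f.assign(interval=f["month_index"] // interval_months)
        .groupby(["participant_id", "interval"], sort=False)
        .size()
        .rename("n_months")
        .reset_index()
    )
    snap = snap.merge(counts, on=["participant_id", "interval"], how="left")
    snap = snap.sort_values(["participant_id", "interval"], kind="mergesort").reset_index(drop=True)
    prev = snap.groupby("participant_id", sort=False)["cls"].shift(1)
    snap["prev_cls"] = prev.fillna("NONE")
    return snap


@dataclass
class TreatmentModel:
    """Multinomial logistic model of interval treatment class."""

    covariate_cols: tuple
    include_prev: bool = True
    _clf: LogisticRegression | None = None
    _classes: tuple = ()

    def _design(self, intervals: pd.DataFrame) -> np.ndarray:
        blocks = []
        for c in self.covariate_cols:
            v = intervals[c]
            if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
                blocks.append(pd.get_dummies(v, prefix=c).reindex(
                    columns=getattr(self, f"_levels_{c}", None), fill_value=0
                ).to_numpy(dtype=float) if hasattr(self, f"_levels_{c}")
                    else pd.get_dummies(v, prefix=c).to_numpy(dtype=float))
            else:
                blocks.append(v.to_numpy(dtype=float)[:, None])
        if self.include_prev:
            for lvl in CLASS_ORDER[1:]:
                blocks.append((intervals["prev_cls"] == lvl).to_numpy(dtype=float)[:, None])
        if not blocks:
            return np.ones((len(intervals), 1))
        return np.hstack(blocks)

    def fit(self, intervals: pd.DataFrame) -> "TreatmentModel":
        # freeze categorical levels so predict uses the same design
        for c in self.covariate_cols:
            v = intervals[c]
            if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
                setattr(self, f"_levels_{c}", tuple(pd.get_dummies(v, prefix=c).columns))
        X = self._design(intervals)
        y = intervals["cls"].to_numpy()
        observed = set(np.unique(y))
        missing = [c for c in CLASS_ORDER if c not in observed]
        if missing:
            raise ValueError(f"treatment class(es) never observed: {missing}")
        clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
        clf.fit(X, y)
        if not np.all(np.isfinite(clf.coef_)):
            raise RuntimeError(
                "treatment model failed to converge; covariates: "
                f"{self.covariate_cols}"
            )
        self._clf = clf
        self._classes = tuple(clf.classes_)
        return self

    def predict_proba(self, intervals: pd.DataFrame) -> pd.DataFrame:
        """Per-interval probabilities for all three classes, columns in CLASS_ORDER."""
        if self._clf is None:
            raise RuntimeError("model not fitted")
        p = self._clf.predict_proba(self._design(intervals))
        out = pd.DataFrame(p, columns=self._classes, index=intervals.index)
        return out.reindex(columns=list(CLASS_ORDER))

    def prob_observed(self, intervals: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(intervals)
        idx = intervals["cls"].map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy()
        return p.to_numpy()[np.arange(len(intervals)), idx]


def fit_treatment_model(
    intervals: pd.DataFrame, covariate_spec, include_prev: bool = True
) -> TreatmentModel:
    """Fit the pooled multinomial assignment model on the interval panel."""
    return TreatmentModel(tuple(covariate_spec), include_prev=include_prev).fit(intervals)


@dataclass
class WeightSet:
    """Stabilized weights per (participant, interval) with diagnostics."""

    frame: pd.DataFrame  # participant_id, interval, weight, truncated
    diagnostics: dict = field(default_factory=dict)

    @property
    def mean_weight(self) -> float:
        return float(self.frame["weight"].mean())


def stabilized_iptw(
    model: TreatmentModel,
    intervals: pd.DataFrame,
    numerator_model: TreatmentModel | None = None,
    numerator_covariates=(),
    truncate: tuple | None = (0.01, 0.99),
) -> WeightSet:
    """Stabilized MSM weights from fitted assignment models.

    ``model`` is the denominator (covariate-history) model; the numerator
    model conditions only on previous class and any ``numerator_covariates``
    (baseline values), and is fitted here if not supplied.  Weights are the
    interval-wise cumulative product of numerator/denominator probabilities
    of the observed class.
    """
    intervals = intervals.sort_values(["participant_id", "interval"], kind="mergesort")
    if numerator_model is None:
        numerator_model = fit_treatment_model(intervals, numerator_covariates, include_prev=True)
    p_den = model.prob_observed(intervals)
    p_num = numerator_model.prob_observed(intervals)
    tiny = p_den <= 1e-12
    if tiny.any():
        bad = intervals.loc[tiny].iloc[0]
        raise PositivityError(
            "positivity violation: denominator probability ~0 for class "
            f"{bad['cls']} at interval {bad['interval']} (participant {bad['participant_id']})"
        )
    ratio = pd.Series(p_num / p_den, index=intervals.index)
    w = ratio.groupby(intervals["participant_id"], sort=False).cumprod().to_numpy()
    truncated = np.zeros(len(w), dtype=bool)
    bounds = None
    if truncate is not None:
        lo, hi = np.quantile(w, truncate)
        truncated = (w < lo) | (w > hi)
        if truncated.any():
            logger.info("truncating %d weight(s) to [%.4g, %.4g]", int(truncated.sum()), lo, hi)
        w = np.clip(w, lo, hi)
        bounds = (float(lo), float(hi))
    frame = pd.DataFrame({
        "participant_id": intervals["participant_id"].to_numpy(),
        "interval": intervals["interval"].to_numpy(),
        "weight": w,
        "truncated": truncated,
    })
    diags = {
        "mean": float(np.mean(w)),
        "max": float(np.max(w)),
        "min": float(np.min(w)),
        "truncation_bounds": bounds,
        "n_truncated": int(truncated.sum()),
    }
    return WeightSet(frame=frame, diagnostics=diags)


def weighted_cells(
    panel: PatientMonthPanel,
    weight_set: WeightSet,
    drug_key,
    event_key,
    interval_months: int = 6,
) -> ContingencyTable:
    """Contingency cells with each patient-month weighted by its interval weight."""
    merged = apply_weights(panel, weight_set, interval_months)
    return tabulate(merged, drug_key, event_key)


def apply_weights(
    panel: PatientMonthPanel, weight_set: WeightSet, interval_months: int = 6
) -> PatientMonthPanel:
    """Return a panel whose ``weight`` column carries the interval IPT weights."""
    out = panel.copy()
    f = out.frame
    f["interval"] = f["month_index"] // interval_months
    merged = f.merge(
        weight_set.frame[["participant_id", "interval", "weight"]],
        on=["participant_id", "interval"],
        how="left",
        suffixes=("_unit", ""),
    )
    if merged["weight"].isna().any():
        n_bad = int(merged["weight"].isna().sum())
        raise ValueError(f"{n_bad} patient-month(s) have no matching interval weight")
    merged = merged.drop(columns=["interval", "weight_unit"])
    out.frame = merged
    return out


def episode_propensity_weights(
    episode_table: pd.DataFrame,
    covariate_cols,
    stratum_col: str = "stratum",
    exposure_col: str = "exposed",
) -> pd.DataFrame:
    """Inverse-propensity weights for the primary episode analysis.

    Fits a logistic regression of exposure status on the episode-start
    covariates separately within each stratum; each episode's weight is
    1 / Pr(observed exposure | covariates).
    """
    out = episode_table.copy()
    out["weight"] = np.nan
    for stratum, sub in out.groupby(stratum_col):
        X = sub[list(covariate_cols)].to_numpy(dtype=float)
        y = sub[exposure_col].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            out.loc[sub.index, "weight"] = 1.0
            logger.warning("stratum %s has a single exposure level; unit weights used", stratum)
            continue
        clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
        clf.fit(X, y)
        p1 = clf.predict_proba(X)[:, 1]
        p_obs = np.where(y == 1, p1, 1.0 - p1)
        if (p_obs <= 1e-12).any():
            raise PositivityError(f"propensity ~0 in stratum {stratum}")
        out.loc[sub.index, "weight"] = 1.0 / p_obs
    return out


def balance_diagnostics(
    model: TreatmentModel,
    intervals: pd.DataFrame,
    covariate_cols,
) -> pd.DataFrame:
    """Weighted vs unweighted covariate balance across current treatment class.

    The balance check reweights each interval by marginal class frequency /
    fitted assignment probability, which makes current class independent of
    the full covariate history in the pseudo-population (the stabilized
    analysis weights themselves deliberately retain the previous-class
    association, so they are not the right weights for this diagnostic).
    Returns one row per covariate with max pairwise SMD before/after.
    """
    cls = intervals["cls"].to_numpy()
    marg = intervals["cls"].value_counts(normalize=True)
    w = marg.reindex(cls).to_numpy() / model.prob_observed(intervals)
    rows = []
    for c in covariate_cols:
        v = intervals[c].to_numpy(dtype=float)
        rows.append({
            "covariate": c,
            "smd_unweighted": standardized_mean_difference(v, cls),
            "smd_weighted": standardized_mean_difference(v, cls, w),
        })
    return pd.DataFrame(rows)


def standardized_mean_difference(
    values: np.ndarray, group: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Maximum pairwise absolute SMD of ``values`` across treatment groups."""
    if weights is None:
        weights = np.ones(len(values), dtype=float)
    stats = {}
    for g in np.unique(group):
        m = group == g
        w = weights[m]
        v = values[m]
        mu = np.average(v, weights=w)
        var = np.average((v - mu) ** 2, weights=w)
        stats[g] = (mu, var)
    groups = list(stats)
    worst = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            (m1, v1), (m2, v2) = stats[groups[i]], stats[groups[j]]
            pooled = np.sqrt((v1 + v2) / 2.0)
            if pooled > 0:
                worst = max(worst, abs(m1 - m2) / pooled)
    return float(worst)
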