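"""The three-level signal generation procedure.

For each drug (or drug pair) and event category, under one exposure
definition at a time:

* **Level 1** -- the minimum-report list: the incident event must occur in
  at least 3 exposed participants for second-generation drugs, 5 for
  first-generation drugs (2 in the pediatric analysis).
* **Level 2** -- the disproportionality screen: the lower 95% confidence
  bound of the ROR (equivalently the IRR) strictly exceeds 1.  In the
  subgrouped pathway this must hold in at least one subgroup.
* **Level 3** -- shrinkage + sequence filtering: the per-signal FDR
  estimate (posterior null probability of the shrunk information
  component) is strictly below 5% and the protopathic-bias filter does not
  discard the signal.  The weighted pathway applies the same machinery to
  IPTW-weighted cells.

Three parallel pathways (crude, subgrouped, IPTW-weighted) are pooled into
ranked Level-2 and Level-3 lists keyed on the number of pathways flagging
each signal.  Levels nest: every Level-3 signal is Level-2, every Level-2
signal Level-1.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bcpnn, disprop, leopard as leopard_mod, weights as weights_mod
from .panel import (
    DRUG_CLASS,
    DrugClass,
    ExposureDefinition,
    PatientMonthPanel,
    apply_incident_censoring,
    build_panel,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    min_participants_second_gen: int = 3
    min_participants_first_gen: int = 5
    min_participants_pediatric: int = 2
    fdr_threshold: float = 0.05
    ci_level: float = 0.95

    def minimum_for(self, drug_key, pediatric: bool = False) -> int:
        if pediatric:
            return self.min_participants_pediatric
        classes = set()
        for d in drug_key if isinstance(drug_key, tuple) else (drug_key,):
            if d in (c.value for c in DrugClass):
                classes.add(DrugClass(d))
            else:
                classes.add(DRUG_CLASS.get(d, DrugClass.SECOND_GEN))
        if classes == {DrugClass.FIRST_GEN}:
            return self.min_participants_first_gen
        return self.min_participants_second_gen


def _key_str(key) -> str:
    return "+".join(key) if isinstance(key, tuple) else str(key)


# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------

def level1_list(
    panel: PatientMonthPanel,
    thresholds: ThresholdConfig | None = None,
    drug_keys=None,
    event_keys=None,
    pediatric: bool = False,
) -> list:
    """(drug, event) pairs whose incident event occurs in enough exposed participants.

    The counting unit is the number of distinct participants whose *first*
    occurrence of the event falls in a patient-month exposed to the drug
    under the panel's active exposure definition.
    """
    thresholds = thresholds or ThresholdConfig()
    drug_keys = list(drug_keys) if drug_keys is not None else list(panel.drugs)
    event_keys = list(event_keys) if event_keys is not None else list(panel.event_keys)
    out = []
    for event_key in event_keys:
        censored = apply_incident_censoring(panel, event_key)
        ev = censored.event_vector(event_key)
        if not ev.any():
            continue
        pids = censored.frame["participant_id"].to_numpy()
        for drug_key in drug_keys:
            exposed = censored.exposure_vector(drug_key)
            n_affected = len(np.unique(pids[ev & exposed]))
            if n_affected >= thresholds.minimum_for(drug_key, pediatric):
                out.append((drug_key, event_key))
    return out


def level2_screen(records: pd.DataFrame) -> pd.DataFrame:
    """Flag records whose disproportionality lower confidence bound exceeds 1."""
    out = records.copy()
    out["level2"] = out["ror_defined"].fillna(False).astype(bool) & (out["ci_low"] > 1.0)
    return out


def level3_screen(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Flag Level-2 records with FDR strictly below threshold, not discarded by LEOPARD."""
    out = records.copy()
    out["level3"] = (
        out["level2"]
        & (out["fdr"] < fdr_threshold)
        & ~out["leopard_discard"].fillna(False).astype(bool)
    )
    return out


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def default_subgroups(panel: PatientMonthPanel, min_patient_months: int = 200) -> pd.Series:
    """Default subgroup labels: sex x age band (<40/>=40) x prior-first-gen.

    Subgroups with fewer than ``min_patient_months`` patient-months are
    merged into a single OTHER stratum (logged).
    """
    f = panel.frame
    parts = []
    if "sex" in f.columns:
        parts.append(f["sex"].astype(str))
    if "age_years" in f.columns:
        parts.append(np.where(f["age_years"] < 40, "age<40", "age>=40"))
    if "prior_first_gen" in f.columns:
        parts.append(np.where(f["prior_first_gen"].astype(float) > 0, "priorFG", "noFG"))
    if not parts:
        return pd.Series(["ALL"] * len(f), index=f.index)
    lab = parts[0].astype(str)
    for p in parts[1:]:
        lab = lab + "|" + pd.Series(p, index=f.index).astype(str)
    counts = lab.value_counts()
    small = counts.index[counts < min_patient_months]
    if len(small):
        logger.info("merging %d small subgroup(s) into OTHER", len(small))
        lab = lab.where(~lab.isin(small), "OTHER")
    return lab


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _measure_row(table, ci_level):
    r = disprop.ror(table, ci_level)
    p = disprop.prr(table, ci_level)
    q = disprop.rrr(table, ci_level)
    return {
        "n00": table.n00, "n01": table.n01, "n10": table.n10, "n11": table.n11,
        "ror": r.point, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "ror_defined": r.defined,
        "prr": p.point, "prr_ci_low": p.ci_low, "prr_ci_high": p.ci_high,
        "rrr": q.point, "rrr_ci_low": q.ci_low, "rrr_ci_high": q.ci_high,
    }


def scan_pairs(
    panel: PatientMonthPanel,
    pairs,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    pathway: str = "CRUDE",
    weight_set=None,
    subgrouper=None,
    thresholds: ThresholdConfig | None = None,
    seed: int = 0,
    bcpnn_draws: int = 100_000,
    leopard_window_months: int = 1,
) -> pd.DataFrame:
    """Full statistics for each (drug, event) pair in one pathway.

    Returns one summary row per pair (subgrouped pathway: flags are
    satisfied-in-at-least-one-subgroup; the per-subgroup detail is in the
    ``subgroup_detail`` mapping on the function attribute of the result).
    """
    thresholds = thresholds or ThresholdConfig()
    work_panel = panel
    if pathway == "WEIGHTED":
        if weight_set is None:
            raise ValueError("weighted pathway requires a WeightSet")
        work_panel = weights_mod.apply_weights(panel, weight_set)
    rows = []
    detail_rows = []
    for i, (drug_key, event_key) in enumerate(pairs):
        censored = apply_incident_censoring(work_panel, event_key)
        rng = np.random.default_rng((seed, 7, i))
        lb, la = leopard_mod.count_initiations(
            episodes, events, drug_key, event_key,
            window_months=leopard_window_months, participants=participants,
        )
        lres = leopard_mod.leopard_test(lb, la)
        base = {
            "drug": _key_str(drug_key), "event": _key_str(event_key),
            "pathway": pathway, "exposure_def": panel.exposure_def.value,
            "leopard_before": lres.n_before, "leopard_after": lres.n_after,
            "leopard_p": lres.p_value, "leopard_discard": lres.discard,
            "leopard_testable": lres.testable,
        }
        if pathway == "SUBGROUP":
            labels = (subgrouper or default_subgroups)(censored)
            any_l2 = False
            any_l3_stats = False
            best = None
            for g in sorted(pd.unique(labels)):
                sub = censored.copy()
                sub.frame = censored.frame.loc[labels == g]
                if sub.frame.empty:
                    continue
                table = disprop.tabulate(sub, drug_key, event_key)
                m = _measure_row(table, thresholds.ci_level)
                ic = bcpnn.ic_posterior(
                    disprop.ContingencyTable(m["n00"], m["n01"], m["n10"], m["n11"]),
                    draws=bcpnn_draws, rng=rng,
                )
                l2 = bool(m["ror_defined"] and m["ci_low"] > 1.0)
                l3s = l2 and ic.p_null < thresholds.fdr_threshold
                any_l2 |= l2
                any_l3_stats |= l3s
                detail_rows.append({**base, "subgroup": g, **m,
                                    "ic_mean": ic.ic_mean, "fdr": ic.p_null,
                                    "level2": l2})
                if best is None or (m["ror_defined"] and (
                        not best["ror_defined"] or m["ror"] > best["ror"])):
                    best = {**m, "ic_mean": ic.ic_mean, "ic_sd": ic.ic_sd,
                            "ic_q025": ic.ic_q025, "ic_q975": ic.ic_q975,
                            "fdr": ic.p_null}
            row = {**base, **(best or {"ror_defined": False, "ci_low": np.nan, "fdr": np.nan}),
                   "level2": any_l2}
            row["level3"] = bool(any_l3_stats and not lres.discard)
            rows.append(row)
            continue

        table = disprop.tabulate(censored, drug_key, event_key)
        m = _measure_row(table, thresholds.ci_level)
        if pathway == "WEIGHTED":
            irr = disprop.irr_from_panel(censored, drug_key, event_key,
                                         ci_level=thresholds.ci_level)
            m["ror"], m["ci_low"], m["ci_high"] = irr.point, irr.ci_low, irr.ci_high
            m["ror_defined"] = irr.defined
        ic = bcpnn.ic_posterior(table, draws=bcpnn_draws, rng=rng)
        row = {**base, **m,
               "ic_mean": ic.ic_mean, "ic_sd": ic.ic_sd,
               "ic_q025": ic.ic_q025, "ic_q975": ic.ic_q975,
               "fdr": ic.p_null}
        row["level2"] = bool(m["ror_defined"] and m["ci_low"] > 1.0)
        row["level3"] = bool(row["level2"] and ic.p_null < thresholds.fdr_threshold
                             and not lres.discard)
        rows.append(row)
    result = pd.DataFrame(rows)
    result.attrs["subgroup_detail"] = pd.DataFrame(detail_rows)
    return result


def pool_and_rank(records: pd.DataFrame) -> dict:
    """Pooled ranked Level-2 and Level-3 lists across pathways.

    Primary sort: number of pathways flagging the signal (descending);
    secondary: best disproportionality statistic (Level 2) or lowest FDR
    (Level 3); ties broken lexicographically on (drug, event).
    """
    if records.empty:
        empty = pd.DataFrame(columns=["drug", "event", "n_pathways", "best_stat"])
        return {"level2": empty, "level3": empty.rename(columns={"best_stat": "best_fdr"})}
    out = {}
    for level, statcol, best in (("level2", "ror", "max"), ("level3", "fdr", "min")):
        flagged = records.loc[records[level].fillna(False).astype(bool)]
        if flagged.empty:
            out[level] = pd.DataFrame(columns=["drug", "event", "n_pathways",
                                               "best_stat" if level == "level2" else "best_fdr"])
            continue
        grp = flagged.groupby(["drug", "event"]).agg(
            n_pathways=("pathway", "nunique"),
            stat=(statcol, best),
        ).reset_index()
        ascending = [False, level == "level3", True, True]
        grp = grp.sort_values(["n_pathways", "stat", "drug", "event"],
                              ascending=ascending, kind="mergesort").reset_index(drop=True)
        grp = grp.rename(columns={"stat": "best_stat" if level == "level2" else "best_fdr"})
        out[level] = grp
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pathways(
    participants: pd.DataFrame,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    monthly_covariates: pd.DataFrame | None = None,
    exposure_def=ExposureDefinition.E1_CURRENT_OR_PREVIOUS_MONTH,
    thresholds: ThresholdConfig | None = None,
    pathways=("CRUDE", "SUBGROUP", "WEIGHTED"),
    drug_keys=None,
    event_keys=None,
    tv_covariate_cols=("severity",),
    seed: int = 0,
    bcpnn_draws: int = 100_000,
    pediatric: bool = False,
) -> dict:
    """Execute the full signal-generation procedure for one exposure definition.

    Returns ``{"signals": per-pathway records, "pooled_level2": ...,
    "pooled_level3": ..., "panel": ...}``.  The weighted pathway is skipped
    with a warning when interval weights cannot be estimated.
    """
    thresholds = thresholds or ThresholdConfig()
    panel = build_panel(
        participants, episodes, events, labs,
        exposure_def=exposure_def, monthly_covariates=monthly_covariates,
    )
    if pediatric:
        keep = panel.frame["age_years"] < 18.0
        panel = panel.copy()
        panel.frame = panel.frame.loc[keep].reset_index(drop=True)
        pathways = ("CRUDE",)
    pairs = level1_list(panel, thresholds, drug_keys=drug_keys,
                        event_keys=event_keys, pediatric=pediatric)

    weight_set = None
    if "WEIGHTED" in pathways:
        try:
            tv = [c for c in tv_covariate_cols if c in panel.frame.columns]
            intervals = weights_mod.panel_to_intervals(panel, covariate_cols=tv)
            model = weights_mod.fit_treatment_model(intervals, tv)
            weight_set = weights_mod.stabilized_iptw(model, intervals)
        except Exception as exc:  # noqa: BLE001 - any failure downgrades the run
            warnings.warn(f"weighted pathway skipped: {exc}", stacklevel=2)
            pathways = tuple(p for p in pathways if p != "WEIGHTED")

    frames = []
    for pathway in pathways:
        frames.append(scan_pairs(
            panel, pairs, episodes, events, participants=participants,
            pathway=pathway, weight_set=weight_set,
            thresholds=thresholds, seed=seed, bcpnn_draws=bcpnn_draws,
        ))
    details = [f.attrs.pop("subgroup_detail", None) for f in frames]
    for f in frames:
        f.attrs = {}
    signals = pd.concat([f for f in frames if not f.empty], ignore_index=True) \
        if any(not f.empty for f in frames) else pd.DataFrame()
    pooled = pool_and_rank(signals) if not signals.empty else pool_and_rank(pd.DataFrame())
    detail_frames = [d for d in details if d is not None and not d.empty]
    return {
        "signals": signals,
        "subgroup_detail": (pd.concat(detail_frames, ignore_index=True)
                            if detail_frames else pd.DataFrame()),
        "pooled_level2": pooled["level2"],
        "pooled_level3": pooled["level3"],
        "panel": panel,
        "weight_set": weight_set,
        "level1_pairs": pairs,
    }


def drug_drug_event_scan(
    panel: PatientMonthPanel,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    thresholds: ThresholdConfig | None = None,
    event_keys=None,
    seed: int = 0,
    bcpnn_draws: int = 100_000,
) -> pd.DataFrame:
    """Level 1-3 scan over drug pairs: exposure = months qualifying for both drugs."""
    thresholds = thresholds or ThresholdConfig()
    pair_keys = []
    for a, b in itertools.combinations(sorted(panel.drugs), 2):
        co = panel.exposure_vector((a, b))
        if co.any():
            pair_keys.append((a, b))
    pairs = level1_list(panel, thresholds, drug_keys=pair_keys, event_keys=event_keys)
    return scan_pairs(panel, pairs, episodes, events, participants=participants,
                      pathway="CRUDE", thresholds=thresholds, seed=seed,
                      bcpnn_draws=bcpnn_draws)


def interim_run(
    participants: pd.DataFrame,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    exposure_def=ExposureDefinition.E1_CURRENT_OR_PREVIOUS_MONTH,
    thresholds: ThresholdConfig | None = None,
    seed: int = 0,
    bcpnn_draws: int = 50_000,
) -> dict:
    """Annual interim report: crude single-drug scan + constant-hazard any-SAE rates.

    The any-SAE model is an unadjusted constant-hazard rate comparison by
    *current* treatment class: events per patient-month per class, with
    rate ratios vs the untreated class and Wald CIs.  Subgrouped and
    weighted pathways are deliberately excluded.
    """
    thresholds = thresholds or ThresholdConfig()
    res = run_pathways(
        participants, episodes, events, labs,
        exposure_def=exposure_def, thresholds=thresholds,
        pathways=("CRUDE",), seed=seed, bcpnn_draws=bcpnn_draws,
    )
    panel = res["panel"]
    f = panel.frame
    ev_cols = [panel.event_col(k) for k in panel.event_keys]
    any_sae = f[ev_cols].any(axis=1).astype(float)
    rows = []
    base_rate = None
    for cls in ("NONE", "FIRST_GEN", "SECOND_GEN"):
        m = (f["cls"] == cls).to_numpy()
        months = float(m.sum())
        evn = float(any_sae[m].sum())
        rate = evn / months if months else np.nan
        if cls == "NONE":
            base_rate = rate
            base_ev = evn
        rows.append({"cls": cls, "events": evn, "patient_months": months, "rate": rate})
    table = pd.DataFrame(rows)
    rr, lo, hi = [], [], []
    for _, r in table.iterrows():
        if r["cls"] == "NONE" or not base_rate or r["events"] == 0:
            rr.append(1.0 if r["cls"] == "NONE" else np.nan)
            lo.append(np.nan)
            hi.append(np.nan)
            continue
        ratio = r["rate"] / base_rate
        se = np.sqrt(1.0 / r["events"] + 1.0 / base_ev)
        rr.append(ratio)
        lo.append(ratio * np.exp(-1.959963984540054 * se))
        hi.append(ratio * np.exp(1.959963984540054 * se))
    table["rate_ratio"] = rr
    table["ci_low"] = lo
    table["ci_high"] = hi
    return {"signals": res["signals"], "any_sae_rates": table, "panel": panel}
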