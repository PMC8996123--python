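"""Patient-month panel construction and clinical outcome derivation.

The unit of observation throughout the package is the *patient-month*: a
fixed 30-day bin of one participant's follow-up, classified by drug
exposure (under one of three exposure definitions) and by incident adverse
event occurrence.  This module owns the domain vocabulary (drug classes,
event categories), panel assembly from raw tabular records, incident-event
censoring, and the clinical outcome derivations (lymphopenia grades, liver
function classes, disability progression).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Length of one analysis month, in days.  Months are fixed 30-day bins
#: anchored at each participant's enrolment date, not calendar months.
MONTH_DAYS = 30


class DrugClass(str, Enum):
    NONE = "NONE"
    FIRST_GEN = "FIRST_GEN"
    SECOND_GEN = "SECOND_GEN"


FIRST_GEN_DRUGS = frozenset({
    "GLATIRAMER_ACETATE",
    "INTERFERON_BETA_1A_IM",
    "INTERFERON_BETA_1A_SC",
    "PEG_INTERFERON_BETA_1A",
    "INTERFERON_BETA_1B",
})

SECOND_GEN_DRUGS = frozenset({
    "ALEMTUZUMAB",
    "CLADRIBINE",
    "DACLIZUMAB",
    "DIMETHYL_FUMARATE",
    "FINGOLIMOD",
    "NATALIZUMAB",
    "OCRELIZUMAB",
    "OFATUMUMAB",
    "RITUXIMAB",
    "SIPONIMOD",
    "TERIFLUNOMIDE",
})

DRUG_CLASS: dict[str, DrugClass] = {
    **{d: DrugClass.FIRST_GEN for d in FIRST_GEN_DRUGS},
    **{d: DrugClass.SECOND_GEN for d in SECOND_GEN_DRUGS},
}

#: Adverse event categories.  RELAPSE is recorded but excluded from signal
#: detection (relapses are an efficacy outcome, not an SAE signal target).
EVENT_CATEGORIES = (
    "INFECTION",
    "OPPORTUNISTIC_INFECTION",
    "MALIGNANCY_TREATMENT_RELATED",
    "DEATH",
    "COVID19",
    "RELAPSE",
    "OTHER_SAE",
)

SIGNAL_CATEGORIES = tuple(c for c in EVENT_CATEGORIES if c != "RELAPSE")


class ExposureDefinition(str, Enum):
    """The three parallel exposure-attribution windows.

    E1: exposure within the month of interest or the previous month.
    E2: exposure within the month of interest or the preceding 6 months.
    E3: exposure at any prior time in the participant's history.

    The definitions nest: E1 implies E2 implies E3 for every month.
    """

    E1_CURRENT_OR_PREVIOUS_MONTH = "E1"
    E2_PRECEDING_6_MONTHS = "E2"
    E3_EVER = "E3"


def drug_class_of(drug_key: str) -> DrugClass:
    """Class of a drug code; class names map to themselves."""
    if drug_key in DRUG_CLASS:
        return DRUG_CLASS[drug_key]
    try:
        return DrugClass(drug_key)
    except ValueError:
        raise KeyError(f"unknown drug or class code: {drug_key!r}") from None


# ---------------------------------------------------------------------------
# clinical outcome derivations
# ---------------------------------------------------------------------------

def grade_lymphopenia(alc_value: float, lower_limit_normal: float = 1000.0) -> int:
    """Lymphopenia grade 0-4 from an absolute lymphocyte count (cells/mm3).

    Grade 0 at/above the lower limit of normal, then grades 1-4 at the
    800 / 500 / 200 cells/mm3 boundaries.  Boundary values are assigned to
    the less severe grade (lower-inclusive half-open bins).
    """
    if alc_value < 0:
        raise ValueError(f"ALC must be nonnegative, got {alc_value}")
    if lower_limit_normal <= 800:
        raise ValueError("lower limit of normal must exceed 800/mm3")
    if alc_value >= lower_limit_normal:
        return 0
    if alc_value >= 800:
        return 1
    if alc_value >= 500:
        return 2
    if alc_value >= 200:
        return 3
    return 4


def classify_liver(value: float, upper_limit_normal: float) -> str:
    """Transaminase elevation class: NORMAL, MODERATE (>2.5x ULN) or SEVERE (>5x ULN)."""
    if upper_limit_normal <= 0:
        raise ValueError("upper limit of normal must be positive")
    if value < 0:
        raise ValueError(f"lab value must be nonnegative, got {value}")
    if value > 5.0 * upper_limit_normal:
        return "SEVERE"
    if value > 2.5 * upper_limit_normal:
        return "MODERATE"
    return "NORMAL"


def detect_edss_progression(edss_series) -> list:
    """Dates of disability progression events in an EDSS series.

    A progression event is a measurement scoring at least 1.0 point higher
    than the immediately preceding measurement (the most recent one at or
    after baseline).  Input: iterable of (date, score), date-sorted.
    """
    series = list(edss_series)
    dates = [d for d, _ in series]
    if any(dates[i] > dates[i + 1] for i in range(len(dates) - 1)):
        raise ValueError("EDSS series must be sorted by date")
    out = []
    for (_, prev), (date, cur) in zip(series, series[1:]):
        if cur - prev >= 1.0:
            out.append(date)
    return out


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def _exp_col(drug: str) -> str:
    return f"exp__{drug}"


def _ev_col(event_key) -> str:
    if isinstance(event_key, tuple):
        return f"ev__{event_key[0]}__{event_key[1]}"
    return f"ev__{event_key}"


@dataclass
class PatientMonthPanel:
    """One row per participant per on-study 30-day month.

    ``frame`` columns: ``participant_id``, ``month_index``, ``cls``
    (current-month treatment class), one boolean ``exp__<drug>`` column per
    drug (under ``exposure_def``), one boolean ``ev__<category>`` column per
    event key, covariate columns, and a positive ``weight`` (default 1).
    """

    frame: pd.DataFrame
    exposure_def: ExposureDefinition
    drugs: tuple = ()
    event_keys: tuple = ()
    covariate_cols: tuple = ()
    schema_version: str = "1"

    def exposure_col(self, drug: str) -> str:
        return _exp_col(drug)

    def event_col(self, event_key) -> str:
        return _ev_col(event_key)

    def exposure_vector(self, drug_key) -> np.ndarray:
        """Boolean exposure indicator for a drug, a class, or a drug pair.

        A tuple key means simultaneous qualification for both drugs
        (drug-drug-event scans); a class key is the union of its member
        drugs' columns present in the panel.
        """
        if isinstance(drug_key, tuple):
            v = self.exposure_vector(drug_key[0])
            for k in drug_key[1:]:
                v = v & self.exposure_vector(k)
            return v
        if drug_key in (c.value for c in DrugClass):
            members = [d for d in self.drugs if DRUG_CLASS.get(d) == DrugClass(drug_key)]
            if not members:
                return np.zeros(len(self.frame), dtype=bool)
            v = np.zeros(len(self.frame), dtype=bool)
            for d in members:
                v |= self.frame[_exp_col(d)].to_numpy()
            return v
        col = _exp_col(drug_key)
        if col not in self.frame.columns:
            return np.zeros(len(self.frame), dtype=bool)
        return self.frame[col].to_numpy()

    def event_vector(self, event_key) -> np.ndarray:
        return self.frame[_ev_col(event_key)].to_numpy()

    def copy(self) -> "PatientMonthPanel":
        return replace(self, frame=self.frame.copy())

    def n_rows(self) -> int:
        return len(self.frame)


def _month_of(dates: pd.Series, enrolment: pd.Series) -> np.ndarray:
    """30-day-bin index of each date relative to its participant's enrolment."""
    delta = (pd.to_datetime(dates).to_numpy() - pd.to_datetime(enrolment).to_numpy())
    days = delta.astype("timedelta64[D]").astype(np.int64)
    return np.floor_divide(days, MONTH_DAYS)


def normalize_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Resolve overlapping exposure episodes per participant.

    Episodes are half-open date intervals.  Overlaps between different
    drugs are resolved by truncating the earlier episode at the later one's
    start (switch semantics, logged).  Episodes that end up empty are
    dropped.  Remaining overlaps (identical starts) are rejected.
    """
    if episodes.empty:
        return episodes.copy()
    ep = episodes.copy()
    ep["start_date"] = pd.to_datetime(ep["start_date"])
    ep["end_date"] = pd.to_datetime(ep["end_date"])
    if (ep["end_date"] <= ep["start_date"]).any():
        raise ValueError("episode end_date must be after start_date")
    ep = ep.sort_values(["participant_id", "start_date"], kind="mergesort").reset_index(drop=True)
    if ep.duplicated(subset=["participant_id", "start_date"]).any():
        bad = ep.loc[ep.duplicated(subset=["participant_id", "start_date"]), "participant_id"]
        raise ValueError(
            "episodes with identical start dates for the same participant "
            "cannot be normalized: " + ", ".join(map(str, bad.unique()[:5]))
        )
    pid = ep["participant_id"].to_numpy()
    start = ep["start_date"].to_numpy()
    end = ep["end_date"].to_numpy().copy()
    same = pid[:-1] == pid[1:]
    has_end = ~pd.isna(end[:-1])
    overlap = same & ((end[:-1] > start[1:]) | ~has_end)
    if overlap.any():
        logger.warning("truncating %d overlapping episode(s) at the successor's start",
                       int(overlap.sum()))
        end[:-1][overlap] = start[1:][overlap]
    ep["end_date"] = end
    return ep


def build_panel(
    participants: pd.DataFrame,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    exposure_def: ExposureDefinition = ExposureDefinition.E1_CURRENT_OR_PREVIOUS_MONTH,
    censor_rules: dict | None = None,
    monthly_covariates: pd.DataFrame | None = None,
    derive_lab_events: bool = False,
) -> PatientMonthPanel:
    """Assemble the patient-month panel from raw record tables.

    Parameters
    ----------
    participants
        Columns ``id``, ``sex``, ``birth_date``, ``enrolment_date``, an
        optional ``end_date``, plus arbitrary baseline covariate columns.
    episodes
        Columns ``participant_id``, ``drug``, ``drug_class``,
        ``start_date``, ``end_date`` (half-open; NaT end = open).
    events
        Columns ``participant_id``, ``category``, optional ``subtype``,
        ``event_date``.  Pre-enrolment events are excluded with a warning.
    labs
        Optional lab results; when ``derive_lab_events`` is true, incident
        lymphopenia (grade >= 3) and moderate/severe liver elevation are
        derived as additional event columns.
    exposure_def
        Active exposure attribution window (exactly one per run).
    censor_rules
        Optional ``{"study_end": date}``; follow-up per participant ends at
        the earliest of their ``end_date``, first DEATH event, and the
        study end.  Defaults to the latest date seen in the inputs.
    monthly_covariates
        Optional long table (``participant_id``, ``month_index``, value
        columns), carried forward within participant to every panel month.
    """
    exposure_def = ExposureDefinition(exposure_def)
    if participants.empty:
        raise ValueError("participants table is empty")
    parts = participants.reset_index(drop=True).copy()
    parts["enrolment_date"] = pd.to_datetime(parts["enrolment_date"])
    if "birth_date" in parts.columns:
        parts["birth_date"] = pd.to_datetime(parts["birth_date"])
        if (parts["birth_date"] >= parts["enrolment_date"]).any():
            raise ValueError("birth_date must precede enrolment_date")
    n = len(parts)
    pid_index = pd.Series(np.arange(n), index=parts["id"].astype(str))

    episodes = normalize_episodes(episodes) if not episodes.empty else episodes.copy()
    events = events.copy()
    if not events.empty:
        events["event_date"] = pd.to_datetime(events["event_date"])

    # --- follow-up length (complete-or-partial 30-day bins) ---------------
    candidates = [parts["enrolment_date"].max() + pd.Timedelta(days=MONTH_DAYS)]
    if "end_date" in parts.columns:
        candidates.append(pd.to_datetime(parts["end_date"]).max())
    for df, col in ((episodes, "end_date"), (episodes, "start_date"), (events, "event_date")):
        if df is not None and not df.empty and col in df.columns:
            v = pd.to_datetime(df[col]).dropna()
            if len(v):
                candidates.append(v.max())
    study_end = pd.to_datetime((censor_rules or {}).get("study_end", max(candidates)))

    end = pd.Series([study_end] * n)
    if "end_date" in parts.columns:
        own = pd.to_datetime(parts["end_date"])
        end = pd.concat([end, own], axis=1).min(axis=1)
    fu_days = (end - parts["enrolment_date"]).dt.days.to_numpy()
    if (fu_days <= 0).any():
        raise ValueError("participants with nonpositive follow-up")
    T = ((fu_days - 1) // MONTH_DAYS + 1).astype(np.int64)  # months on study

    # deaths censor follow-up at the death month (inclusive)
    if not events.empty and (events["category"] == "DEATH").any():
        dd = events.loc[events["category"] == "DEATH"]
        idx = pid_index.reindex(dd["participant_id"].astype(str)).to_numpy()
        ok = ~np.isnan(idx)
        midx = _month_of(dd["event_date"], parts["enrolment_date"].to_numpy()[idx[ok].astype(int)])
        for i, m in zip(idx[ok].astype(int), midx):
            if m >= 0:
                T[i] = min(T[i], m + 1)
    Tmax = int(T.max())

    # --- current-month exposure coverage per drug -------------------------
    drugs: list[str] = []
    cur: dict[str, np.ndarray] = {}
    ever_pre: dict[str, np.ndarray] = {}
    if not episodes.empty:
        ep = episodes
        unknown = ~ep["participant_id"].astype(str).isin(pid_index.index)
        if unknown.any():
            raise ValueError("episodes reference unknown participants")
        eidx = pid_index.reindex(ep["participant_id"].astype(str)).to_numpy().astype(int)
        enrol = parts["enrolment_date"].to_numpy()[eidx]
        s_day = (ep["start_date"].to_numpy() - enrol).astype("timedelta64[D]").astype(np.int64)
        e_raw = ep["end_date"].to_numpy()
        open_end = pd.isna(e_raw)
        e_day = np.where(
            open_end,
            (T[eidx] * MONTH_DAYS).astype(np.int64),
            (e_raw - enrol).astype("timedelta64[D]").astype("float64"),
        ).astype(np.int64)
        s_m = np.floor_divide(s_day, MONTH_DAYS)
        e_m = np.floor_divide(e_day - 1, MONTH_DAYS)
        for j, drug in enumerate(ep["drug"].to_numpy()):
            if drug not in cur:
                cur[drug] = np.zeros((n, Tmax), dtype=bool)
                ever_pre[drug] = np.zeros(n, dtype=bool)
                drugs.append(drug)
            a, b = s_m[j], e_m[j]
            if b < 0:
                ever_pre[drug][eidx[j]] = True  # wholly pre-enrolment
                continue
            a2 = max(a, 0)
            b2 = min(b, T[eidx[j]] - 1)
            if a < 0:
                ever_pre[drug][eidx[j]] = True
            if b2 >= a2:
                cur[drug][eidx[j], a2 : b2 + 1] = True
    drugs = sorted(drugs)

    # class per month from current coverage
    cls = np.full((n, Tmax), DrugClass.NONE.value, dtype=object)
    for drug in drugs:
        dc = DRUG_CLASS.get(drug)
        if dc is DrugClass.FIRST_GEN:
            cls[cur[drug] & (cls == DrugClass.NONE.value)] = DrugClass.FIRST_GEN.value
    for drug in drugs:
        if DRUG_CLASS.get(drug) is DrugClass.SECOND_GEN:
            cls[cur[drug]] = DrugClass.SECOND_GEN.value

    # exposure definition windows
    def windowed(c: np.ndarray, pre: np.ndarray) -> np.ndarray:
        if exposure_def is ExposureDefinition.E1_CURRENT_OR_PREVIOUS_MONTH:
            out = c.copy()
            out[:, 1:] |= c[:, :-1]
            return out
        if exposure_def is ExposureDefinition.E2_PRECEDING_6_MONTHS:
            out = c.copy()
            for lag in range(1, 7):
                out[:, lag:] |= c[:, :-lag]
            return out
        out = np.logical_or.accumulate(c, axis=1)
        out[pre, :] = True
        return out

    flags = {d: windowed(cur[d], ever_pre[d]) for d in drugs}

    # --- events -----------------------------------------------------------
    event_keys = list(SIGNAL_CATEGORIES)
    ev: dict[str, np.ndarray] = {k: np.zeros((n, Tmax), dtype=bool) for k in event_keys}
    if not events.empty:
        evd = events.loc[events["category"] != "RELAPSE"]
        unknown = ~evd["participant_id"].astype(str).isin(pid_index.index)
        if unknown.any():
            raise ValueError("events reference unknown participants")
        vidx = pid_index.reindex(evd["participant_id"].astype(str)).to_numpy().astype(int)
        enrol = parts["enrolment_date"].to_numpy()[vidx]
        m = ((evd["event_date"].to_numpy() - enrol).astype("timedelta64[D]").astype(np.int64)) // MONTH_DAYS
        pre = m < 0
        if pre.any():
            warnings.warn(f"excluding {int(pre.sum())} pre-enrolment event(s); retrospective "
                          "history enters only as covariates", stacklevel=2)
        for i, mm, cat in zip(vidx, m, evd["category"].to_numpy()):
            if 0 <= mm < T[i] and cat in ev:
                ev[cat][i, mm] = True

    if derive_lab_events and labs is not None and not labs.empty:
        lab_ev = derive_lab_event_records(labs)
        for key, sub in lab_ev.groupby("category"):
            if key not in ev:
                ev[key] = np.zeros((n, Tmax), dtype=bool)
                event_keys.append(key)
            lidx = pid_index.reindex(sub["participant_id"].astype(str)).to_numpy().astype(int)
            enrol = parts["enrolment_date"].to_numpy()[lidx]
            m = ((pd.to_datetime(sub["event_date"]).to_numpy() - enrol)
                 .astype("timedelta64[D]").astype(np.int64)) // MONTH_DAYS
            for i, mm in zip(lidx, m):
                if 0 <= mm < T[i]:
                    ev[key][i, mm] = True

    # --- flatten to the long frame ---------------------------------------
    on = np.zeros((n, Tmax), dtype=bool)
    for i in range(n):
        on[i, : T[i]] = True
    flat = on.ravel()
    row_pid = np.repeat(parts["id"].astype(str).to_numpy(), Tmax)[flat]
    row_month = np.tile(np.arange(Tmax), n)[flat]
    data = {
        "participant_id": row_pid,
        "month_index": row_month,
        "cls": cls.ravel()[flat],
    }
    for d in drugs:
        data[_exp_col(d)] = flags[d].ravel()[flat]
    for k in event_keys:
        data[_ev_col(k)] = ev[k].ravel()[flat]

    covariate_cols: list[str] = []
    reserved = {"id", "sex", "birth_date", "enrolment_date", "end_date"}
    if "sex" in parts.columns:
        data["sex"] = np.repeat(parts["sex"].to_numpy(), Tmax)[flat]
        covariate_cols.append("sex")
    if "birth_date" in parts.columns:
        age0 = (parts["enrolment_date"] - parts["birth_date"]).dt.days.to_numpy() / 365.25
        data["age_years"] = (np.repeat(age0, Tmax)[flat]
                             + row_month * MONTH_DAYS / 365.25)
        covariate_cols.append("age_years")
    for col in parts.columns:
        if col in reserved or col in covariate_cols:
            continue
        data[col] = np.repeat(parts[col].to_numpy(), Tmax)[flat]
        covariate_cols.append(col)
    frame = pd.DataFrame(data)
    frame["weight"] = 1.0

    if monthly_covariates is not None and not monthly_covariates.empty:
        mc = monthly_covariates.copy()
        mc["participant_id"] = mc["participant_id"].astype(str)
        val_cols = [c for c in mc.columns if c not in ("participant_id", "month_index")]
        frame = frame.merge(mc, on=["participant_id", "month_index"], how="left")
        frame[val_cols] = frame.groupby("participant_id", sort=False)[val_cols].ffill()
        covariate_cols.extend(val_cols)

    frame = frame.sort_values(["participant_id", "month_index"], kind="mergesort").reset_index(drop=True)
    return PatientMonthPanel(
        frame=frame,
        exposure_def=exposure_def,
        drugs=tuple(drugs),
        event_keys=tuple(event_keys),
        covariate_cols=tuple(covariate_cols),
    )


def derive_lab_event_records(labs: pd.DataFrame) -> pd.DataFrame:
    """Event-like records derived from lab results.

    Emits LYMPHOPENIA_G3PLUS for ALC at grade >= 3 and LIVER_MODERATE /
    LIVER_SEVERE for transaminase elevations.
    """
    labs = labs.copy()
    out = []
    alc = labs.loc[labs["analyte"] == "ALC"]
    for _, r in alc.iterrows():
        if grade_lymphopenia(float(r["value"]), float(r["lln"])) >= 3:
            out.append((r["participant_id"], "LYMPHOPENIA_G3PLUS", r["date"]))
    liv = labs.loc[labs["analyte"].isin(["ALT", "AST"])]
    for _, r in liv.iterrows():
        cl = classify_liver(float(r["value"]), float(r["uln"]))
        if cl != "NORMAL":
            out.append((r["participant_id"], f"LIVER_{cl}", r["date"]))
    return pd.DataFrame(out, columns=["participant_id", "category", "event_date"])


def apply_incident_censoring(panel: PatientMonthPanel, event_key) -> PatientMonthPanel:
    """Keep only the at-risk months for an incident-event analysis.

    For each participant, months after the first occurrence of
    ``event_key`` are removed; the event indicator is true only at that
    first month.  Participants with no occurrence are unchanged.
    """
    col = panel.event_col(event_key)
    f = panel.frame
    ev = f[col].to_numpy()
    if not ev.any():
        return panel.copy()
    # cumulative count of events so far (within participant); keep rows up
    # to and including the first event month
    grp = f.groupby("participant_id", sort=False)[col]
    cum = grp.cumsum().to_numpy()
    keep = (cum == 0) | ((cum == 1) & ev)
    out = f.loc[keep].copy()
    return replace(panel, frame=out.reset_index(drop=True))
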