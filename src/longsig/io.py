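"""Reading and writing the delimited file schemas.

All inputs are UTF-8 CSV with a header row and ISO-8601 dates:

* ``participants.csv`` -- id, sex, birth_date, enrolment_date, optional
  end_date, plus baseline covariate columns.
* ``exposures.csv`` -- participant_id, drug, drug_class, start_date,
  end_date (empty = open).
* ``events.csv`` -- participant_id, category, subtype, event_date.
* ``labs.csv`` -- participant_id, date, analyte, value, lln, uln.
* ``monthly.csv`` (optional) -- participant_id, month_index, time-varying
  covariate columns.

The panel writer emits one row per patient-month in the same dialect with
a ``schema_version`` comment-free column set.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .panel import PatientMonthPanel, ExposureDefinition

_DATE_COLS = {
    "participants": ["birth_date", "enrolment_date", "end_date"],
    "exposures": ["start_date", "end_date"],
    "events": ["event_date"],
    "labs": ["date"],
}


def _read(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _DATE_COLS.get(kind, []):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def read_participants(path) -> pd.DataFrame:
    return _read(path, "participants")


def read_exposures(path) -> pd.DataFrame:
    return _read(path, "exposures")


def read_events(path) -> pd.DataFrame:
    return _read(path, "events")


def read_labs(path) -> pd.DataFrame:
    return _read(path, "labs")


def read_monthly(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_cohort_dir(directory) -> dict:
    """Read the standard file set from a directory; missing optional files are None."""
    d = Path(directory)
    out = {
        "participants": read_participants(d / "participants.csv"),
        "exposures": read_exposures(d / "exposures.csv"),
        "events": read_events(d / "events.csv"),
    }
    out["labs"] = read_labs(d / "labs.csv") if (d / "labs.csv").exists() else None
    out["monthly"] = read_monthly(d / "monthly.csv") if (d / "monthly.csv").exists() else None
    return out


def write_panel(panel: PatientMonthPanel, path) -> None:
    frame = panel.frame.copy()
    frame.insert(0, "schema_version", panel.schema_version)
    frame.insert(1, "exposure_def", panel.exposure_def.value)
    frame.to_csv(path, index=False)


def read_panel(path) -> PatientMonthPanel:
    frame = pd.read_csv(path)
    exposure_def = ExposureDefinition(frame["exposure_def"].iloc[0])
    version = str(frame["schema_version"].iloc[0])
    frame = frame.drop(columns=["schema_version", "exposure_def"])
    drugs = tuple(sorted(c[len("exp__"):] for c in frame.columns if c.startswith("exp__")))
    event_keys = tuple(c[len("ev__"):] for c in frame.columns if c.startswith("ev__"))
    reserved = {"participant_id", "month_index", "cls", "weight"}
    covariates = tuple(
        c for c in frame.columns
        if c not in reserved and not c.startswith(("exp__", "ev__"))
    )
    return PatientMonthPanel(
        frame=frame, exposure_def=exposure_def, drugs=drugs,
        event_keys=event_keys, covariate_cols=covariates,
        schema_version=version,
    )
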