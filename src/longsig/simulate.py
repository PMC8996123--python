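"""Synthetic longitudinal cohort generator with known ground truth.

Produces participants / exposure episodes / adverse events / lab results in
the panel module's file schemas, from a discrete-time model operating on
the same fixed 30-day months used by the analyses:

* a latent disease-severity covariate follows a stationary AR(1) process;
* treatment class (none / first-generation / second-generation DMT) is
  redrawn at regular decision months from a multinomial logit on current
  severity and the previous class (persistence), so confounding strength
  and switching are configurable;
* adverse events are Bernoulli draws per patient-month with hazard
  base x RR(exposure, category) x exp(beta x severity), with optional
  carryover-interaction and protopathic mechanisms;
* in the protopathic scenario the hazard of the target category is
  multiplied in the ``lead_months`` bins ending at (and including) the
  initiation month, and events landing in the initiation month are dated
  before the initiation day -- the event precedes the prescription.

Ground truth (the realized config plus the true per-decision assignment
probabilities) is returned for estimator-recovery testing.  All randomness
flows through one seeded generator; identical seeds give identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MONTH_DAYS, DrugClass

CLASS_CODES = (DrugClass.NONE.value, DrugClass.FIRST_GEN.value, DrugClass.SECOND_GEN.value)

DEFAULT_DRUG_MAP = {
    DrugClass.FIRST_GEN.value: "INTERFERON_BETA_1A_SC",
    DrugClass.SECOND_GEN.value: "NATALIZUMAB",
}


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    horizon_months: int = 60
    seed: int = 0

    # treatment assignment (multinomial logit, redrawn at decision months)
    intercept_first_gen: float = -0.5
    intercept_second_gen: float = -0.5
    confounding_gamma: float = 0.0        # severity -> second-gen logit
    confounding_gamma_first: float = 0.0  # severity -> first-gen logit
    persistence: float = 2.5              # stay-in-current-class logit bonus
    decision_interval_months: int = 6

    # covariate dynamics
    severity_rho: float = 0.85

    # event model: monthly hazards per category and true rate ratios per
    # (drug or class, category) pair
    base_hazards: dict = field(default_factory=lambda: {"INFECTION": 0.01, "OTHER_SAE": 0.008})
    rate_ratios: dict = field(default_factory=dict)
    severity_beta: float = 0.0            # hazard multiplier exp(beta * severity)

    # carryover interaction: hazard multiplier for `carryover_category`
    # applied while on second-gen with first-gen exposure in the past 6 months
    carryover_interaction: float = 1.0
    carryover_category: str = "INFECTION"

    # protopathic scenario: {"category", "multiplier", "lead_months"},
    # targeting the first second-generation initiation
    protopathic: dict | None = None

    drug_map: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_MAP))
    prior_first_gen_prob: float = 0.3
    age_range: tuple = (20.0, 60.0)
    base_date: str = "2020-01-01"
    lab_every_months: int = 6

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for k, v in self.rate_ratios.items():
            if v <= 0:
                raise ValueError(f"rate ratio for {k} must be positive")


@dataclass
class SyntheticTruth:
    """Realized config plus the true assignment probabilities per decision month."""

    config: SimulationConfig
    assignment_probs: pd.DataFrame  # participant_id, month_index, p_NONE, p_FIRST_GEN, p_SECOND_GEN, cls
    n_hazard_clipped: int = 0


@dataclass
class SimulationResult:
    participants: pd.DataFrame
    exposures: pd.DataFrame
    events: pd.DataFrame
    labs: pd.DataFrame
    monthly: pd.DataFrame  # participant_id, month_index, severity
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.exposures.to_csv(out / "exposures.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.labs.to_csv(out / "labs.csv", index=False)
        self.monthly.to_csv(out / "monthly.csv", index=False)
        self.truth.assignment_probs.to_csv(out / "truth_probs.csv", index=False)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_cohort(config: SimulationConfig) -> SimulationResult:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_patients, config.horizon_months
    base = pd.Timestamp(config.base_date)

    # --- covariates -------------------------------------------------------
    rho = config.severity_rho
    sev = np.empty((n, T))
    sev[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        sev[:, t] = rho * sev[:, t - 1] + innov_sd * rng.standard_normal(n)

    prior_fg = rng.random(n) < config.prior_first_gen_prob
    age0 = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < 0.7, "F", "M")
    baseline_edss = np.round(np.clip(rng.normal(2.5, 1.5, n), 0, 9.5) * 2) / 2
    disease_duration = np.round(rng.exponential(5.0, n), 1)
    comorbidity = rng.poisson(0.8, n)

    # --- treatment path ---------------------------------------------------
    cls = np.zeros((n, T), dtype=np.int8)
    prev = np.zeros(n, dtype=np.int8)
    prob_rows = []
    k = config.decision_interval_months
    for t in range(T):
        if t % k == 0:
            logits = np.zeros((n, 3))
            logits[:, 0] = config.persistence * (prev == 0)
            logits[:, 1] = (config.intercept_first_gen
                            + config.confounding_gamma_first * sev[:, t]
                            + config.persistence * (prev == 1))
            logits[:, 2] = (config.intercept_second_gen
                            + config.confounding_gamma * sev[:, t]
                            + config.persistence * (prev == 2))
            p = _softmax(logits)
            u = rng.random(n)
            draw = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1).astype(np.int8)
            prob_rows.append((t, p, draw.copy()))
            prev = draw
        cls[:, t] = prev

    # --- event draws ------------------------------------------------------
    day_off = rng.integers(0, MONTH_DAYS, size=(n, T))  # initiation day within month

    # first second-gen initiation month (for the protopathic mechanism)
    on2 = cls == 2
    any2 = on2.any(axis=1)
    first2 = np.where(any2, on2.argmax(axis=1), -1)

    carry_mult = np.ones((n, T))
    if config.carryover_interaction != 1.0:
        past_fg = np.zeros((n, T), dtype=bool)
        was_fg = cls == 1
        for lag in range(1, 7):
            past_fg[:, lag:] |= was_fg[:, :-lag]
        carry_mult[(cls == 2) & past_fg] = config.carryover_interaction

    proto_mult = np.ones((n, T))
    if config.protopathic is not None:
        lead = int(config.protopathic.get("lead_months", 1))
        mult = float(config.protopathic["multiplier"])
        for i in np.flatnonzero(first2 >= 0):
            a = max(0, first2[i] - lead + 1)
            proto_mult[i, a : first2[i] + 1] = mult

    sev_mult = np.exp(config.severity_beta * sev) if config.severity_beta else np.ones((n, T))

    n_clipped = 0
    event_rows = []
    for cat, h0 in config.base_hazards.items():
        rrm = np.ones(3)
        for ci, cname in enumerate(CLASS_CODES):
            rrm[ci] = config.rate_ratios.get(
                (cname, cat), config.rate_ratios.get((config.drug_map.get(cname), cat), 1.0)
            )
        h = h0 * rrm[cls] * sev_mult * carry_mult
        if config.protopathic is not None and cat == config.protopathic["category"]:
            h = h * proto_mult
        clipped = h > 0.95
        if clipped.any():
            n_clipped += int(clipped.sum())
            h = np.clip(h, 0.0, 0.95)
        hits = rng.random((n, T)) < h
        ii, tt = np.nonzero(hits)
        if len(ii) == 0:
            continue
        days = rng.integers(0, MONTH_DAYS, size=len(ii))
        if config.protopathic is not None and cat == config.protopathic["category"]:
            at_init = first2[ii] == tt
            if at_init.any():
                # event precedes (or ties with) the initiation day in that month
                init_days = day_off[ii[at_init], tt[at_init]]
                days[at_init] = (rng.random(at_init.sum()) * (init_days + 1)).astype(np.int64)
        for j in range(len(ii)):
            event_rows.append((ii[j], cat, tt[j] * MONTH_DAYS + days[j]))
    if n_clipped:
        warnings.warn(f"{n_clipped} patient-month hazard(s) clipped to 0.95", stacklevel=2)

    # --- assemble output tables ------------------------------------------
    pids = np.array([f"P{i:06d}" for i in range(n)])
    enrol = base  # common enrolment date; months are participant-anchored anyway
    participants = pd.DataFrame({
        "id": pids,
        "sex": sex,
        "birth_date": (enrol - pd.to_timedelta((age0 * 365.25).astype(int), unit="D")),
        "enrolment_date": enrol,
        "end_date": enrol + pd.Timedelta(days=T * MONTH_DAYS),
        "prior_first_gen": prior_fg.astype(int),
        "baseline_edss": baseline_edss,
        "disease_duration": disease_duration,
        "comorbidity_count": comorbidity,
    })

    ep_rows = []
    fg_drug = config.drug_map[DrugClass.FIRST_GEN.value]
    sg_drug = config.drug_map[DrugClass.SECOND_GEN.value]
    for i in np.flatnonzero(prior_fg):
        ep_rows.append((pids[i], fg_drug, DrugClass.FIRST_GEN.value,
                        enrol - pd.Timedelta(days=400), enrol - pd.Timedelta(days=100)))
    change = np.diff(cls, axis=1, prepend=np.full((n, 1), -1, dtype=np.int8))
    for i in range(n):
        starts = np.flatnonzero(change[i] != 0)
        bounds = np.append(starts, T)
        for a, b in zip(bounds[:-1], bounds[1:]):
            c = cls[i, a]
            if c == 0:
                continue
            drug = fg_drug if c == 1 else sg_drug
            start = enrol + pd.Timedelta(days=int(a) * MONTH_DAYS + int(day_off[i, a]))
            stop = enrol + pd.Timedelta(days=int(b) * MONTH_DAYS)
            ep_rows.append((pids[i], drug, CLASS_CODES[c], start, stop))
    exposures = pd.DataFrame(
        ep_rows, columns=["participant_id", "drug", "drug_class", "start_date", "end_date"]
    )

    events = pd.DataFrame(
        [(pids[i], cat, "", enrol + pd.Timedelta(days=int(d))) for i, cat, d in event_rows],
        columns=["participant_id", "category", "subtype", "event_date"],
    )

    lab_parts = []
    for t in range(0, T, config.lab_every_months):
        alc = np.exp(rng.normal(np.log(1800.0) - 0.35 * (cls[:, t] == 2), 0.35, n))
        alt = np.exp(rng.normal(np.log(22.0) + 0.15 * (cls[:, t] == 2), 0.45, n))
        date = enrol + pd.Timedelta(days=t * MONTH_DAYS)
        lab_parts.append(pd.DataFrame({
            "participant_id": pids, "date": date, "analyte": "ALC",
            "value": np.round(alc, 1), "lln": 1000.0, "uln": 4800.0,
        }))
        lab_parts.append(pd.DataFrame({
            "participant_id": pids, "date": date, "analyte": "ALT",
            "value": np.round(alt, 1), "lln": 5.0, "uln": 40.0,
        }))
    labs = pd.concat(lab_parts, ignore_index=True)

    monthly = pd.DataFrame({
        "participant_id": np.repeat(pids, T),
        "month_index": np.tile(np.arange(T), n),
        "severity": sev.ravel(),
    })

    tp = []
    for t, p, draw in prob_rows:
        tp.append(pd.DataFrame({
            "participant_id": pids,
            "month_index": t,
            "p_NONE": p[:, 0],
            "p_FIRST_GEN": p[:, 1],
            "p_SECOND_GEN": p[:, 2],
            "cls": np.array(CLASS_CODES)[draw],
        }))
    truth = SyntheticTruth(
        config=config,
        assignment_probs=pd.concat(tp, ignore_index=True),
        n_hazard_clipped=n_clipped,
    )
    return SimulationResult(participants, exposures, events, labs, monthly, truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("null", "planted_signal", "confounded", "protopathic", "switching_carryover")


def scenario_presets(name: str, **overrides) -> SimulationConfig:
    """Fixed, documented configurations for the acceptance experiments.

    null
        All rate ratios 1, no confounding: every signal is a false one.
    planted_signal
        RR(second-gen drug, INFECTION) = 3, no confounding.
    confounded
        Severity drives both second-gen selection and event hazard;
        true RR(second-gen, INFECTION) = 2.  Crude estimates are biased
        upward, correctly weighted ones are not.
    protopathic
        All RR = 1, but infection hazard is multiplied in the month leading
        up to (and including) second-gen initiation: a spurious
        disproportionality signal that the initiation-sequence filter
        should discard.
    switching_carryover
        Infection hazard elevated only while on second-gen with first-gen
        exposure in the preceding 6 months (an interaction, not a main
        effect).
    """
    common = dict(
        base_hazards={"INFECTION": 0.01, "COVID19": 0.008, "OTHER_SAE": 0.008},
    )
    if name == "null":
        cfg = SimulationConfig(**common)
    elif name == "planted_signal":
        cfg = SimulationConfig(
            **common,
            rate_ratios={(DEFAULT_DRUG_MAP["SECOND_GEN"], "INFECTION"): 3.0},
        )
    elif name == "confounded":
        cfg = SimulationConfig(
            base_hazards={"INFECTION": 0.0025, "OTHER_SAE": 0.004},
            rate_ratios={(DrugClass.SECOND_GEN.value, "INFECTION"): 2.0},
            confounding_gamma=1.2,
            severity_beta=0.8,
        )
    elif name == "protopathic":
        cfg = SimulationConfig(
            base_hazards={"INFECTION": 0.02, "COVID19": 0.008, "OTHER_SAE": 0.008},
            protopathic={"category": "INFECTION", "multiplier": 3.0, "lead_months": 1},
            persistence=1.5,
            decision_interval_months=3,
        )
    elif name == "switching_carryover":
        cfg = SimulationConfig(
            **common,
            carryover_interaction=3.0,
            carryover_category="INFECTION",
            persistence=1.5,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    return cfg
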