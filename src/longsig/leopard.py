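"""Protopathic-bias filter (initiation-sequence test).

A signal is suspect when treatment initiation tends to *follow* the event
rather than precede it (the drug was started in response to the prodrome
that also produced the event).  The filter counts, over participants with
an incident event, first initiations of the drug in a symmetric window
before vs after the event date and applies a one-sided binomial test of
H0: initiation equally likely on either side, against the alternative that
initiation is more likely after.  The test is carried out at the 50%
significance level; rejected signals are discarded.

Window length (default one 30-day month on each side) and the same-day tie
rule (counts as "after", favoring discard) are package decisions; the same
window must be used on both sides for the fair-coin null to hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .panel import MONTH_DAYS, DRUG_CLASS, DrugClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeopardResult:
    n_before: int
    n_after: int
    p_value: float
    discard: bool
    testable: bool


def leopard_test(n_before: int, n_after: int, alpha: float = 0.5) -> LeopardResult:
    """One-sided binomial test of the before/after initiation split.

    p = Pr(X >= n_after) for X ~ Binomial(n_before + n_after, 1/2);
    discard when p < alpha (default 0.5).  Both counts zero: untestable,
    the signal is retained with a flag.
    """
    if n_before < 0 or n_after < 0:
        raise ValueError("counts must be nonnegative")
    n = n_before + n_after
    if n == 0:
        return LeopardResult(0, 0, float("nan"), False, False)
    p = float(binom.sf(n_after - 1, n, 0.5))
    # strict p < alpha with a guard against float noise at the exact-0.5 ties
    return LeopardResult(int(n_before), int(n_after), p, bool(p < alpha - 1e-9), True)


def null_rejection_mass(total: int, alpha: float = 0.5) -> float:
    """Exact null probability of discard at a given before+after total.

    Because the test statistic is discrete, the realized rejection rate
    under the fair-coin null is below the nominal level; this computes it
    exactly for calibration checks.
    """
    if total <= 0:
        return 0.0
    k = np.arange(total + 1)
    pvals = binom.sf(k - 1, total, 0.5)
    return float(binom.pmf(k, total, 0.5)[pvals < alpha - 1e-9].sum())


def count_initiations(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    drug_key,
    event_key,
    window_months: int = 1,
    participants: pd.DataFrame | None = None,
) -> tuple[int, int]:
    """Before/after counts of first drug initiations around incident events.

    For each participant with an incident (first) occurrence of
    ``event_key``, the *first* initiation of ``drug_key`` counts as "after"
    if it falls in (event, event + window] (same-day ties included) and as
    "before" if in [event - window, event).  When ``participants`` (with
    ``enrolment_date`` and optional ``end_date``) is given, participants
    whose window extends outside their follow-up contribute to neither
    count.
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    wdays = pd.Timedelta(days=window_months * MONTH_DAYS)

    ev = events.copy()
    if isinstance(event_key, tuple):
        ev = ev.loc[(ev["category"] == event_key[0]) & (ev.get("subtype") == event_key[1])]
    else:
        ev = ev.loc[ev["category"] == event_key]
    if ev.empty:
        return (0, 0)
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    first_event = ev.groupby("participant_id")["event_date"].min()

    ep = episodes.copy()
    ep["start_date"] = pd.to_datetime(ep["start_date"])
    if isinstance(drug_key, tuple):
        # pair initiation: the moment the combination is completed, i.e. the
        # later of the two drugs' first initiations (both must be present)
        firsts = []
        for d in drug_key:
            sub = ep.loc[ep["drug"] == d]
            if sub.empty:
                return (0, 0)
            firsts.append(sub.groupby("participant_id")["start_date"].min())
        first_init = pd.concat(firsts, axis=1).dropna().max(axis=1)
        if first_init.empty:
            return (0, 0)
    else:
        if drug_key in (c.value for c in DrugClass):
            keep = ep["drug"].map(lambda d: DRUG_CLASS.get(d)) == DrugClass(drug_key)
        else:
            keep = ep["drug"] == drug_key
        ep = ep.loc[keep]
        if ep.empty:
            return (0, 0)
        first_init = ep.groupby("participant_id")["start_date"].min()

    both = pd.concat([first_event.rename("event"), first_init.rename("init")], axis=1).dropna()
    if both.empty:
        return (0, 0)

    if participants is not None:
        parts = participants.set_index(participants["id"].astype(str))
        enrol = pd.to_datetime(parts["enrolment_date"]).reindex(both.index.astype(str))
        lo_ok = (both["event"].to_numpy() - wdays) >= enrol.to_numpy()
        if "end_date" in parts.columns:
            end = pd.to_datetime(parts["end_date"]).reindex(both.index.astype(str))
            hi_ok = (both["event"].to_numpy() + wdays) <= end.to_numpy()
        else:
            hi_ok = np.ones(len(both), dtype=bool)
        dropped = ~(lo_ok & hi_ok)
        if dropped.any():
            logger.info("leopard: %d participant(s) with window outside follow-up excluded",
                        int(dropped.sum()))
        both = both.loc[lo_ok & hi_ok]

    delta = both["init"] - both["event"]
    after = (delta >= pd.Timedelta(0)) & (delta <= wdays)
    before = (delta < pd.Timedelta(0)) & (delta >= -wdays)
    return (int(before.sum()), int(after.sum()))
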