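"""Contingency tabulation and simple disproportionality measures.

Patient-months are cross-classified by drug exposure and event occurrence
into a 2x2 table with cells

    n00  unexposed, no event        n01  unexposed, event
    n10  exposed,  no event         n11  exposed,  event

from which the reporting odds ratio (ROR), proportional reporting ratio
(PRR), relative reporting ratio (RRR) and incidence rate ratio (IRR) are
computed.  Cells may be real-valued (weighted pathway).  In the
patient-month formulation the PRR and the IRR are the same number; both
routes are implemented and must agree to numerical precision.

Confidence intervals are delta-method (Woolf-type) intervals on the log
scale; no published CI formula exists for these measures in this setting,
so the choice is a package decision.  Tables with a zero cell yield a
flagged *undefined* estimate rather than a continuity-corrected one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PatientMonthPanel


@dataclass(frozen=True)
class ContingencyTable:
    """The four patient-month counts (real-valued when weighted)."""

    n00: float
    n01: float
    n10: float
    n11: float

    def __post_init__(self):
        for name in ("n00", "n01", "n10", "n11"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be nonnegative")

    @property
    def n0_(self) -> float:  # unexposed margin
        return self.n00 + self.n01

    @property
    def n1_(self) -> float:  # exposed margin
        return self.n10 + self.n11

    @property
    def n_0(self) -> float:  # no-event margin
        return self.n00 + self.n10

    @property
    def n_1(self) -> float:  # event margin
        return self.n01 + self.n11

    @property
    def n__(self) -> float:
        return self.n00 + self.n01 + self.n10 + self.n11

    def scaled(self, k: float) -> "ContingencyTable":
        return ContingencyTable(self.n00 * k, self.n01 * k, self.n10 * k, self.n11 * k)


@dataclass(frozen=True)
class MeasureEstimate:
    measure: str
    point: float
    ci_low: float
    ci_high: float
    log_se: float
    defined: bool = True
    note: str = ""

    @property
    def is_signal(self) -> bool:
        """Lower confidence bound strictly exceeds 1 (and the estimate exists)."""
        return bool(self.defined and self.ci_low > 1.0)


def _undefined(measure: str, note: str) -> MeasureEstimate:
    nan = float("nan")
    return MeasureEstimate(measure, nan, nan, nan, nan, defined=False, note=note)


def _log_ci(measure: str, point: float, log_se: float, ci_level: float) -> MeasureEstimate:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo = point * np.exp(-z * log_se)
    hi = point * np.exp(z * log_se)
    return MeasureEstimate(measure, float(point), float(lo), float(hi), float(log_se))


def tabulate(panel: PatientMonthPanel, drug_key, event_key) -> ContingencyTable:
    """Weighted patient-month counts, cross-classified exposure x event.

    The panel should already be incident-censored for ``event_key``; every
    row contributes its ``weight`` (1 when unweighted) to exactly one cell.
    """
    if panel.frame.empty:
        raise ValueError("cannot tabulate an empty panel")
    e = panel.exposure_vector(drug_key)
    y = panel.event_vector(event_key)
    w = panel.frame["weight"].to_numpy()
    n11 = float(w[e & y].sum())
    n10 = float(w[e & ~y].sum())
    n01 = float(w[~e & y].sum())
    n00 = float(w[~e & ~y].sum())
    return ContingencyTable(n00=n00, n01=n01, n10=n10, n11=n11)


def ror(table: ContingencyTable, ci_level: float = 0.95) -> MeasureEstimate:
    """Reporting odds ratio n11*n00 / (n01*n10) with a Woolf log-scale CI."""
    if min(table.n00, table.n01, table.n10, table.n11) <= 0:
        return _undefined("ROR", "zero cell")
    point = table.n11 * table.n00 / (table.n01 * table.n10)
    se = np.sqrt(1 / table.n00 + 1 / table.n01 + 1 / table.n10 + 1 / table.n11)
    return _log_ci("ROR", point, se, ci_level)


def prr(table: ContingencyTable, ci_level: float = 0.95) -> MeasureEstimate:
    """Proportional reporting ratio (n11/n1.)/(n01/n0.): risk in exposed vs unexposed months."""
    if table.n11 <= 0 or table.n01 <= 0 or table.n1_ <= 0 or table.n0_ <= 0:
        return _undefined("PRR", "zero cell or margin")
    point = (table.n11 / table.n1_) / (table.n01 / table.n0_)
    se = np.sqrt(1 / table.n11 - 1 / table.n1_ + 1 / table.n01 - 1 / table.n0_)
    return _log_ci("PRR", point, se, ci_level)


def rrr(table: ContingencyTable, ci_level: float = 0.95) -> MeasureEstimate:
    """Relative reporting ratio n11*n.. / (n.1*n1.): risk in exposed vs all months."""
    if table.n11 <= 0 or table.n_1 <= 0 or table.n1_ <= 0:
        return _undefined("RRR", "zero cell or margin")
    point = table.n11 * table.n__ / (table.n_1 * table.n1_)
    se = np.sqrt(max(1 / table.n11 - 1 / table.n1_ + 1 / table.n_1 - 1 / table.n__, 0.0))
    return _log_ci("RRR", point, se, ci_level)


def _sandwich_log_irr_se(y: np.ndarray, e: np.ndarray, w: np.ndarray) -> float:
    """Robust (HC0 sandwich) SE of log IRR from the weighted saturated rate model.

    For the two-group weighted Poisson rate model the sandwich variance of
    each log rate is sum(w^2 (y - rate)^2) / (sum(w) * rate)^2 per group.
    With unit weights this reduces to the PRR delta-method SE.
    """
    se2 = 0.0
    for grp in (e, ~e):
        wg, yg = w[grp], y[grp]
        sw = wg.sum()
        rate = (wg * yg).sum() / sw
        se2 += ((wg**2 * (yg - rate) ** 2).sum()) / (sw * rate) ** 2
    return float(np.sqrt(se2))


def irr_from_panel(
    panel: PatientMonthPanel,
    drug_key,
    event_key,
    method: str = "rates",
    ci_level: float = 0.95,
) -> MeasureEstimate:
    """Incidence rate ratio: events per patient-month, exposed vs unexposed.

    ``method='rates'`` computes the rate quotient directly (identical to
    the PRR of the tabulated cells); ``method='glm'`` fits a log-linear
    event-rate model and exponentiates the exposure coefficient.  Both use
    the panel ``weight`` column; variance is a robust sandwich estimate.
    """
    e = panel.exposure_vector(drug_key)
    y = panel.event_vector(event_key).astype(float)
    w = panel.frame["weight"].to_numpy().astype(float)
    if not e.any() or e.all():
        return _undefined("IRR", "no exposed or no unexposed patient-months")
    ev_exp = float((w * y)[e].sum())
    ev_un = float((w * y)[~e].sum())
    pt_exp = float(w[e].sum())
    pt_un = float(w[~e].sum())
    if ev_un <= 0:
        return _undefined("IRR", "no unexposed events")
    if ev_exp <= 0:
        return _undefined("IRR", "no exposed events")
    if method == "rates":
        point = (ev_exp / pt_exp) / (ev_un / pt_un)
    elif method == "glm":
        import statsmodels.api as sm

        X = np.column_stack([np.ones_like(w), e.astype(float)])
        model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
        res = model.fit(tol=1e-14, maxiter=200)
        point = float(np.exp(res.params[1]))
    else:
        raise ValueError(f"unknown method {method!r}")
    se = _sandwich_log_irr_se(y, e, w)
    return _log_ci("IRR", point, se, ci_level)
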