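"""Bayesian shrinkage of the relative reporting ratio (BCPNN).

The Information Component IC = log2 P(drug, event) / (P(drug) P(event)) is
the base-2 logarithm of the RRR.  Under the conjugate model the marginal
exposure and event probabilities carry Beta(1, 1) priors and the joint
probability a Beta prior whose strength is set so that the prior
expectation of the IC is zero (independence-favoring shrinkage).  With
large cells the posterior IC mean converges to log2(RRR); with sparse
cells it is pulled toward 0.

Posterior location comes from the moment (ratio-of-posterior-means)
approximation; tail quantities -- the 95% credible interval and the null
probability Pr(IC <= 0 | data) used as the per-signal FDR statistic -- are
computed by seeded Monte Carlo from the conjugate posteriors, which is the
authoritative route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .disprop import ContingencyTable

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the conjugate model.

    ``marginal_a``/``marginal_b`` parameterize the Beta priors on the drug
    and event marginal probabilities; ``joint_strength`` is the prior
    pseudo-count on the joint cell, with the complementary parameter chosen
    so that the prior joint mean equals the product of the posterior
    marginal means (prior IC expectation zero).
    """

    marginal_a: float = 1.0
    marginal_b: float = 1.0
    joint_strength: float = 1.0


@dataclass(frozen=True)
class ICPosterior:
    ic_mean: float
    ic_sd: float
    ic_q025: float
    ic_q975: float
    p_null: float
    draws: int

    @property
    def fdr(self) -> float:
        """Per-signal FDR statistic: posterior probability of no association."""
        return self.p_null


def _posterior_params(table: ContingencyTable, prior: PriorSpec):
    N = table.n__
    a_q = prior.marginal_a + table.n1_
    b_q = prior.marginal_b + N - table.n1_
    a_p = prior.marginal_a + table.n_1
    b_p = prior.marginal_b + N - table.n_1
    e_q = a_q / (a_q + b_q)
    e_p = a_p / (a_p + b_p)
    gamma = prior.joint_strength / (e_p * e_q)
    a_r = prior.joint_strength + table.n11
    b_r = gamma - prior.joint_strength + N - table.n11
    return (a_r, b_r), (a_p, b_p), (a_q, b_q)


def ic_posterior(
    table: ContingencyTable,
    prior: PriorSpec | None = None,
    draws: int = 100_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ICPosterior:
    """Posterior of the Information Component for one drug-event table.

    Accepts real-valued (weighted) cells, interpreted as effective counts;
    the weighted pathway plugs weighted cells into the same posterior
    (documented approximation).
    """
    if min(table.n00, table.n01, table.n10, table.n11) < 0:
        raise ValueError("negative cells")
    prior = prior or PriorSpec()
    (a_r, b_r), (a_p, b_p), (a_q, b_q) = _posterior_params(table, prior)

    e_r = a_r / (a_r + b_r)
    e_p = a_p / (a_p + b_p)
    e_q = a_q / (a_q + b_q)
    ic_mean = float(np.log2(e_r / (e_p * e_q)))
    var_log = 0.0
    for a, b in ((a_r, b_r), (a_p, b_p), (a_q, b_q)):
        var_log += polygamma(1, a) - polygamma(1, a + b)
    ic_sd = float(np.sqrt(max(var_log, 0.0)) / _LN2)

    if rng is None:
        rng = np.random.default_rng(seed)
    r = rng.beta(a_r, b_r, size=draws)
    p = rng.beta(a_p, b_p, size=draws)
    q = rng.beta(a_q, b_q, size=draws)
    ic = np.log2(r / (p * q))
    q025, q975 = np.quantile(ic, [0.025, 0.975])
    p_null = float(np.mean(ic <= 0.0))
    return ICPosterior(
        ic_mean=ic_mean,
        ic_sd=ic_sd,
        ic_q025=float(q025),
        ic_q975=float(q975),
        p_null=p_null,
        draws=draws,
    )


def fdr_for_list(posteriors) -> pd.DataFrame:
    """Per-signal and ranked running FDR for a list of IC posteriors.

    Each signal's FDR statistic is its posterior null probability; the
    running FDR of the ranked list is the cumulative mean of the null
    probabilities over signals sorted ascending (Bayesian FDR of calling
    everything up to that rank a signal).  The Level-3 gate consumes the
    per-signal value.
    """
    items = list(posteriors)
    if not items:
        raise ValueError("empty signal list")
    p_null = np.array([p.p_null if isinstance(p, ICPosterior) else float(p) for p in items])
    order = np.argsort(p_null, kind="stable")
    running_sorted = np.cumsum(p_null[order]) / np.arange(1, len(p_null) + 1)
    running = np.empty_like(running_sorted)
    running[order] = running_sorted
    return pd.DataFrame({"fdr": p_null, "running_fdr": running})
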