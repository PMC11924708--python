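"""Posterior updating and the noninferiority decision rule.

Beta-mixture priors are conjugate to binomial data: each component updates
as (a, b) -> (a + y, b + n - y) and component weights are reweighted by the
beta-binomial marginal likelihood of the observed counts.  The posterior
probability of noninferiority

    p = Pr(theta_t - theta_c < M | D_c, D_t)

is evaluated by one-dimensional quadrature of the test-arm posterior CDF
against the control-arm posterior density.  Interim decisions compare p to
the futility/efficacy thresholds of the group-sequential design with strict
inequalities; values exactly on a threshold continue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import integrate, special

from .design import GSDesign
from .mixture import BetaMixture

__all__ = [
    "ArmPosterior",
    "Decision",
    "update_mixture_posterior",
    "prob_noninferiority",
    "interim_decision",
]

Outcome = Literal[
    "stop_futility", "stop_efficacy", "continue", "final_noninferior", "final_inferior"
]


@dataclass(frozen=True)
class ArmPosterior:
    """Posterior of one arm's event rate plus the counts it has absorbed."""

    mixture: BetaMixture
    n_obs: int = 0
    y_obs: int = 0

    def __post_init__(self):
        if not (0 <= self.y_obs <= self.n_obs):
            raise ValueError("need 0 <= y_obs <= n_obs")

    def update(self, y: int, n: int) -> "ArmPosterior":
        return ArmPosterior(
            mixture=update_mixture_posterior(self.mixture, y, n),
            n_obs=self.n_obs + n,
            y_obs=self.y_obs + y,
        )


@dataclass(frozen=True)
class Decision:
    outcome: Outcome
    posterior_prob_h1: float
    analysis_index: int


def update_mixture_posterior(prior: BetaMixture, y: int, n: int) -> BetaMixture:
    """Conjugate beta-mixture update with y events in n trials.

    Posterior weights are proportional to prior weight times the
    beta-binomial marginal likelihood
    m_k = C(n, y) B(a_k + y, b_k + n - y) / B(a_k, b_k), computed in log
    space (the binomial coefficient is common and drops out).
    """
    if not (0 <= y <= n):
        raise ValueError("need 0 <= y <= n")
    if n == 0:
        return prior
    a = np.array([c[0] for c in prior.components])
    b = np.array([c[1] for c in prior.components])
    w = np.array(prior.weights)
    log_m = special.betaln(a + y, b + n - y) - special.betaln(a, b)
    with np.errstate(divide="ignore"):
        log_w = np.log(w) + log_m
    log_w -= special.logsumexp(log_w)
    return BetaMixture(list(zip(a + y, b + n - y)), np.exp(log_w))


def prob_noninferiority(test: ArmPosterior, control: ArmPosterior, margin_m: float) -> float:
    """Posterior probability that theta_t - theta_c < M.

    p = integral of F_t(theta_c + M) f_c(theta_c) d theta_c, with the
    test CDF argument clamped to [0, 1]; adaptive quadrature to absolute
    tolerance 1e-6.
    """
    f_c = control.mixture
    F_t = test.mixture

    def integrand(th: float) -> float:
        return float(F_t.cdf(min(th + margin_m, 1.0))) * float(f_c.pdf(np.array([th]))[0])

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-6, epsrel=1e-8)
    return float(min(max(val, 0.0), 1.0))


def interim_decision(p: float, design: GSDesign, analysis_index: int) -> Decision:
    """Apply the stopping rule at ``analysis_index`` (0-based).

    Interim looks: p < futility threshold stops for futility, p > efficacy
    threshold stops for efficacy, ties continue.  The final look declares
    noninferiority iff p exceeds the final efficacy threshold.
    """
    k = design.n_analyses
    if not (0 <= analysis_index < k):
        raise IndexError(f"analysis index {analysis_index} outside design with {k} looks")
    c_fut = design.prob_lower[analysis_index]
    c_eff = design.prob_upper[analysis_index]
    if analysis_index == k - 1:
        outcome: Outcome = "final_noninferior" if p > c_eff else "final_inferior"
    elif p < c_fut:
        outcome = "stop_futility"
    elif p > c_eff:
        outcome = "stop_efficacy"
    else:
        outcome = "continue"
    return Decision(outcome=outcome, posterior_prob_h1=float(p), analysis_index=analysis_index)
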