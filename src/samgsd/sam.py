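"""Self-adapting mixture (SAM) prior: congruence weighting and assembly.

The SAM prior for the control rate is a two-part mixture

    Pr(theta) = w * Pr(theta)_informative + (1 - w) * Pr(theta)_weak

whose weight w is recomputed from the current control data each time it is
used.  Congruence between current and historical control rates is judged
against a clinically significant margin Delta: the weight is the posterior
odds transform w = R / (1 + R) of the likelihood-ratio

    R = L(D_c | theta_c = theta_h) / max over s in {+1,-1} of
        L(D_c | theta_c = theta_h + s * Delta),

with the binomial likelihood evaluated at the historical point estimate and
at the two incongruence points one margin away (binomial coefficients
cancel).  Strong agreement of the observed control rate with theta_h drives
w toward 1 (borrow); a discrepancy of Delta or more drives w toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixture import BetaMixture

__all__ = ["CongruenceSpec", "ControlData", "sam_weight", "weak_prior", "build_sam_prior"]


@dataclass(frozen=True)
class CongruenceSpec:
    """Historical point estimate and congruence margin Delta.

    Both likelihood evaluation points ``theta_h_hat +- delta`` must lie
    inside (0, 1).
    """

    theta_h_hat: float
    delta: float

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("congruence margin delta must be positive")
        if not (0 < self.theta_h_hat - self.delta and self.theta_h_hat + self.delta < 1):
            raise ValueError("theta_h_hat +- delta must lie inside (0, 1)")


@dataclass(frozen=True)
class ControlData:
    """Current-trial control arm counts."""

    n: int
    y: int

    def __post_init__(self):
        if not (0 <= self.y <= self.n):
            raise ValueError("need 0 <= y <= n")


def _binom_loglik(p: float, y: int, n: int) -> float:
    # log p^y (1-p)^(n-y); the binomial coefficient cancels in the ratio
    ll = 0.0
    if y > 0:
        ll += y * np.log(p)
    if n - y > 0:
        ll += (n - y) * np.log1p(-p)
    return ll


def sam_weight(data: ControlData, spec: CongruenceSpec) -> float:
    """Adaptive weight of the informative component, w = R/(1+R) in [0, 1].

    With no current control data (n = 0) there is no evidence either way
    and the weight is 1/2.
    """
    if data.n == 0:
        return 0.5
    th, d = spec.theta_h_hat, spec.delta
    log_num = _binom_loglik(th, data.y, data.n)
    log_den = max(
        _binom_loglik(th + d, data.y, data.n),
        _binom_loglik(th - d, data.y, data.n),
    )
    log_r = log_num - log_den
    # w = R/(1+R) = sigmoid(log R), stable in both tails
    if log_r >= 0:
        return float(1.0 / (1.0 + np.exp(-log_r)))
    return float(np.exp(log_r) / (1.0 + np.exp(log_r)))


def weak_prior(theta_h_hat: float, ess_weak: float = 1.0) -> BetaMixture:
    """Weakly informative beta prior mean-matched to the historical estimate.

    ``Beta(theta * ess, (1 - theta) * ess)`` carries ``ess_weak`` patients of
    information (its ELIR effective sample size equals ``ess_weak``) centred
    at ``theta_h_hat``.
    """
    if ess_weak <= 0:
        raise ValueError("ess_weak must be positive")
    if not (0 < theta_h_hat < 1):
        raise ValueError("theta_h_hat must lie in (0, 1)")
    return BetaMixture([(theta_h_hat * ess_weak, (1 - theta_h_hat) * ess_weak)], [1.0])


def build_sam_prior(w: float, informative: BetaMixture, weak: BetaMixture) -> BetaMixture:
    """Assemble the SAM mixture: informative components scaled by w, weak
    components by 1 - w; negligible components (< 1e-8) dropped."""
    if not (0 <= w <= 1):
        raise ValueError("w must lie in [0, 1]")
    comps = list(informative.components) + list(weak.components)
    weights = np.concatenate(
        [w * np.asarray(informative.weights), (1 - w) * np.asarray(weak.weights)]
    )
    keep = weights >= 1e-8
    if not np.any(keep):  # pragma: no cover - w in [0,1] guarantees mass
        raise AssertionError
    comps = [c for c, k in zip(comps, keep) if k]
    weights = weights[keep]
    return BetaMixture(comps, weights / weights.sum())
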