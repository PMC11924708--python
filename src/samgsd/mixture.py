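"""Weighted mixtures of beta densities.

A beta mixture is the universal prior/posterior representation in this
package: the MAP prior approximated by EM is a beta mixture, the SAM prior
is a beta mixture, and conjugacy with binomial data keeps every posterior a
beta mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = ["BetaMixture"]

_WEIGHT_TOL = 1e-10


def _beta_logpdf(x, a, b):
    # direct formula; avoids scipy.stats dispatch overhead in hot loops
    with np.errstate(divide="ignore", invalid="ignore"):
        out = special.xlogy(a - 1.0, x) + special.xlog1py(b - 1.0, -x) - special.betaln(a, b)
    return np.where((x < 0) | (x > 1), -np.inf, out)


def _beta_pdf(x, a, b):
    return np.exp(_beta_logpdf(x, a, b))


@dataclass(frozen=True)
class BetaMixture:
    """Finite mixture of Beta(alpha_k, beta_k) densities on (0, 1).

    Parameters
    ----------
    components
        Sequence of ``(alpha, beta)`` pairs, both strictly positive.
    weights
        Mixture weights in ``[0, 1]`` summing to 1 (renormalised on
        construction if they are within 1e-10 of 1).
    """

    components: tuple[tuple[float, float], ...]
    weights: tuple[float, ...]

    def __init__(self, components: Sequence[Sequence[float]], weights: Sequence[float]):
        comps = tuple((float(a), float(b)) for a, b in components)
        w = np.asarray(weights, dtype=float)
        if len(comps) == 0:
            raise ValueError("mixture needs at least one component")
        if len(comps) != len(w):
            raise ValueError("components and weights length mismatch")
        if any(a <= 0 or b <= 0 for a, b in comps):
            raise ValueError("alpha and beta must be strictly positive")
        if np.any(w < -_WEIGHT_TOL) or np.any(w > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")
        total = w.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        w = np.clip(w / total, 0.0, 1.0)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    # -- basic properties -------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.components)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.array([c[0] for c in self.components])
        b = np.array([c[1] for c in self.components])
        w = np.array(self.weights)
        return a, b, w

    @property
    def mean(self) -> float:
        """Mixture mean: sum of w_k * alpha_k / (alpha_k + beta_k)."""
        a, b, w = self._arrays()
        return float(np.sum(w * a / (a + b)))

    @property
    def variance(self) -> float:
        a, b, w = self._arrays()
        m_k = a / (a + b)
        v_k = a * b / ((a + b) ** 2 * (a + b + 1))
        m = np.sum(w * m_k)
        return float(np.sum(w * (v_k + m_k**2)) - m**2)

    # -- density / distribution -------------------------------------------

    def pdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        a, b, w = self._arrays()
        xv = np.atleast_1d(x)
        out = np.sum(w[:, None] * _beta_pdf(xv[None, :], a[:, None], b[:, None]), axis=0)
        return out.reshape(x.shape) if x.ndim else float(out[0])

    def logpdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        a, b, w = self._arrays()
        xv = np.atleast_1d(x)
        with np.errstate(divide="ignore"):
            lp = _beta_logpdf(xv[None, :], a[:, None], b[:, None])
            out = special.logsumexp(lp + np.log(w)[:, None], axis=0)
        return out.reshape(x.shape) if x.ndim else float(out[0])

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, 0.0, 1.0)
        a, b, w = self._arrays()
        out = np.sum(w[:, None] * special.betainc(a[:, None], b[:, None], np.atleast_1d(xc)[None, :]), axis=0)
        out = out.reshape(x.shape) if x.ndim else float(out[0])
        return out

    def ppf(self, q, tol: float = 1e-10) -> np.ndarray | float:
        """Quantile function by bisection on the mixture CDF."""
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((qs <= 0) | (qs >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        out = np.empty_like(qs)
        for i, p in enumerate(qs):
            out[i] = optimize.brentq(lambda x: self.cdf(x) - p, 0.0, 1.0, xtol=tol)
        return out if np.asarray(q).ndim else float(out[0])

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        a, b, w = self._arrays()
        idx = rng.choice(len(w), size=size, p=w)
        return rng.beta(a[idx], b[idx])

    # -- structural operations --------------------------------------------

    def prune(self, min_weight: float = 1e-8) -> "BetaMixture":
        """Drop components whose weight falls below ``min_weight``."""
        a, b, w = self._arrays()
        keep = w >= min_weight
        if not np.any(keep):
            keep = w == w.max()
        return BetaMixture(list(zip(a[keep], b[keep])), w[keep] / w[keep].sum())

    def sorted_by_weight(self) -> "BetaMixture":
        order = np.argsort(self.weights)[::-1]
        comps = [self.components[i] for i in order]
        return BetaMixture(comps, [self.weights[i] for i in order])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "components": [{"alpha": a, "beta": b} for a, b in self.components],
            "weights": list(self.weights),
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "BetaMixture":
        comps = [(c["alpha"], c["beta"]) for c in d["components"]]
        return cls(comps, d["weights"])

    @classmethod
    def from_json(cls, source: str) -> "BetaMixture":
        """Parse from a JSON string or a path to a JSON file."""
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source, encoding="utf-8") as fh:
                d = json.load(fh)
        return cls.from_dict(d)
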