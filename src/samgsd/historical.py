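"""Meta-analytic-predictive (MAP) prior elicitation from historical studies.

Aggregated historical control arms (n_j, y_j) enter a binomial hierarchical
model with a logit-normal random effect,

    y_j ~ Binomial(n_j, theta_j),   logit(theta_j) = mu + tau * z_j,
    z_j ~ N(0, 1),  mu ~ N(0, sd_mu^2),  tau ~ Half-Normal(sd_tau),

and the MAP prior is the posterior predictive distribution of the control
rate in a new exchangeable trial, theta_new = expit(mu + tau * z_new).  The
posterior is sampled by ensemble MCMC; the resulting draws are then
approximated as a parametric beta mixture by an EM algorithm so that all
downstream computation (congruence weighting, conjugate updating, effective
sample size) is analytic.

Between-study heterogeneity is summarised by Cochran's Q and the I^2
statistic on either the logit or the raw proportion scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

from .mixture import BetaMixture

__all__ = [
    "HistoricalStudy",
    "PosteriorSamples",
    "HeterogeneityResult",
    "McmcSettings",
    "ConvergenceError",
    "read_historical_csv",
    "fit_map_hierarchical",
    "heterogeneity_i2",
    "fit_beta_mixture_em",
    "mixture_summary",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistoricalStudy:
    """One historical control arm: patients enrolled and events observed."""

    n_patients: int
    n_events: int

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0 <= self.n_events <= self.n_patients):
            raise ValueError("need 0 <= n_events <= n_patients")

    @property
    def proportion(self) -> float:
        return self.n_events / self.n_patients


@dataclass(frozen=True)
class PosteriorSamples:
    """Predictive draws of the historical control rate with MCMC diagnostics."""

    draws: np.ndarray
    n_chains: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.draws, dtype=float)
        if np.any((d <= 0) | (d >= 1)):
            raise ValueError("all draws must lie strictly inside (0, 1)")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        object.__setattr__(self, "draws", d)


@dataclass(frozen=True)
class HeterogeneityResult:
    q_statistic: float
    df: int
    i_squared: float
    p_value: float
    scale: str
    continuity_corrected: bool = False


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-MCMC configuration (walkers are grouped into chains for
    split-R-hat diagnostics)."""

    n_chains: int = 4
    n_tune: int = 2000
    n_draws: int = 2500
    walkers_per_chain: int = 16
    thin: int = 8
    sd_mu: float = 2.0
    sd_tau: float = 1.0
    max_rhat: float = 1.01
    tau_fixed: float | None = None  # pooling limit for testing


class ConvergenceError(RuntimeError):
    """MCMC failed its convergence diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def read_historical_csv(path) -> list[HistoricalStudy]:
    """Read studies from a CSV with header ``study_id,n_patients,n_events``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"study_id", "n_patients", "n_events"}
    if not required.issubset(df.columns):
        raise ValueError(f"historical CSV must have columns {sorted(required)}")
    return [
        HistoricalStudy(int(r.n_patients), int(r.n_events))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------


def heterogeneity_i2(
    studies: Sequence[HistoricalStudy], scale: Literal["logit", "raw"] = "logit"
) -> HeterogeneityResult:
    """Cochran's Q and I^2 with inverse-variance fixed-effect weights.

    On the logit scale a 0.5 continuity correction is applied (and flagged)
    to any study with a zero cell.  ``i_squared = max(0, (Q - df) / Q)``.
    """
    if len(studies) < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    y = np.array([s.n_events for s in studies], dtype=float)
    n = np.array([s.n_patients for s in studies], dtype=float)
    corrected = False
    if scale == "logit":
        zero = (y == 0) | (y == n)
        if np.any(zero):
            corrected = True
            y = y + 0.5 * zero
            n = n + 1.0 * zero
        eff = np.log(y / (n - y))
        var = 1.0 / y + 1.0 / (n - y)
    elif scale == "raw":
        p = y / n
        eff = p
        var = p * (1 - p) / n
        if np.any(var == 0):
            raise ValueError("degenerate study proportion (0 or 1) on raw scale")
    else:
        raise ValueError("scale must be 'logit' or 'raw'")
    w = 1.0 / var
    pooled = np.sum(w * eff) / np.sum(w)
    q = float(np.sum(w * (eff - pooled) ** 2))
    df = len(studies) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    p_val = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q, df, i2, p_val, scale, corrected)


# ---------------------------------------------------------------------------
# hierarchical MAP fit
# ---------------------------------------------------------------------------


def _log_posterior(params: np.ndarray, y: np.ndarray, n: np.ndarray, s: McmcSettings) -> float:
    """Unnormalised log posterior over (mu, log tau, z_1..z_J)."""
    mu, log_tau = params[0], params[1]
    z = params[2:]
    if not np.all(np.isfinite(params)) or abs(log_tau) > 12:
        return -np.inf
    tau = np.exp(log_tau)
    if s.tau_fixed is not None:
        tau = s.tau_fixed
    lp = stats.norm.logpdf(mu, 0.0, s.sd_mu)
    if s.tau_fixed is None:
        # half-normal on tau with log-scale Jacobian
        lp += stats.halfnorm.logpdf(tau, scale=s.sd_tau) + log_tau
    else:
        # dummy proper prior keeps the unused coordinate well behaved
        lp += stats.norm.logpdf(log_tau)
    lp += float(np.sum(stats.norm.logpdf(z)))
    eta = mu + tau * z
    # binomial log-likelihood, coefficient omitted
    lp += float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
    return lp


def fit_map_hierarchical(
    studies: Sequence[HistoricalStudy],
    mcmc_settings: McmcSettings | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Fit the binomial/logit-normal hierarchical model and return
    posterior-predictive draws of the control rate for a new trial.

    Sampling uses an affine-invariant ensemble sampler whose walkers are
    grouped into ``n_chains`` chains; split-R-hat must stay below the
    configured limit or a :class:`ConvergenceError` is raised.
    """
    import emcee

    if len(studies) == 0:
        raise ValueError("need at least one historical study")
    s = mcmc_settings or McmcSettings()
    y = np.array([st.n_events for st in studies], dtype=float)
    n = np.array([st.n_patients for st in studies], dtype=float)
    ndim = 2 + len(studies)
    n_walkers = max(s.walkers_per_chain, 2 * ndim + 2)
    n_walkers += n_walkers % 2
    rng = np.random.default_rng(seed)

    p_hat = (y + 0.5) / (n + 1.0)
    mu0 = float(np.mean(special.logit(p_hat)))

    # one fully independent ensemble per chain; walkers flattened and
    # thinned within chain to tame ensemble autocorrelation
    chains = []
    for c in range(s.n_chains):
        crng = np.random.default_rng((seed, c))
        p0 = np.column_stack(
            [
                mu0 + 0.5 * crng.standard_normal(n_walkers),
                np.log(0.5) + 0.3 * crng.standard_normal(n_walkers),
                *(0.3 * crng.standard_normal((len(studies), n_walkers))),
            ]
        )
        sampler = emcee.EnsembleSampler(n_walkers, ndim, _log_posterior, args=(y, n, s))
        sampler.random_state = np.random.RandomState(
            int(crng.integers(2**31))
        ).get_state()
        state = sampler.run_mcmc(p0, s.n_tune, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, s.n_draws, progress=False)
        ch = sampler.get_chain(thin=s.thin)  # (draws/thin, walkers, ndim)
        chains.append(ch.reshape(-1, ndim))

    grouped = np.stack(chains)  # (n_chains, draws_per_chain, ndim)
    diagnostics = _diagnostics(grouped, s)
    if diagnostics["max_rhat"] >= s.max_rhat:
        raise ConvergenceError(
            f"split-R-hat {diagnostics['max_rhat']:.4f} >= {s.max_rhat}", diagnostics
        )

    flat = grouped.reshape(-1, ndim)
    mu = flat[:, 0]
    tau = np.exp(flat[:, 1]) if s.tau_fixed is None else np.full(len(flat), s.tau_fixed)
    z_new = rng.standard_normal(len(flat))
    theta_new = special.expit(mu + tau * z_new)
    theta_new = np.clip(theta_new, 1e-12, 1 - 1e-12)
    return PosteriorSamples(draws=theta_new, n_chains=s.n_chains, diagnostics=diagnostics)


def _diagnostics(grouped: np.ndarray, s: McmcSettings) -> dict:
    import arviz as az

    _, n_per_chain, ndim = grouped.shape
    names = ["mu", "log_tau"] + [f"z_{j}" for j in range(ndim - 2)]
    ds = az.convert_to_dataset({k: grouped[:, :, i] for i, k in enumerate(names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    rhats = {k: float(rhat[k].values) for k in names}
    return {
        "rhat": rhats,
        "max_rhat": max(rhats.values()),
        "ess_bulk": {k: float(ess[k].values) for k in names},
        "n_chains": s.n_chains,
        "draws_per_chain": n_per_chain,
    }


# ---------------------------------------------------------------------------
# EM approximation of the MCMC sample by a beta mixture
# ---------------------------------------------------------------------------


def _beta_mom(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments beta parameters, used to initialise EM."""
    wsum = w.sum()
    m = float(np.sum(w * x) / wsum)
    v = float(np.sum(w * (x - m) ** 2) / wsum)
    v = max(v, 1e-8)
    common = max(m * (1 - m) / v - 1.0, 0.1)
    return max(m * common, 1e-3), max((1 - m) * common, 1e-3)


def _weighted_beta_mle(
    x: np.ndarray, w: np.ndarray, init: tuple[float, float]
) -> tuple[float, float]:
    """Weighted maximum-likelihood Beta(a, b) fit via sufficient statistics."""
    wsum = w.sum()
    s_log = float(np.sum(w * np.log(x)) / wsum)
    s_log1m = float(np.sum(w * np.log1p(-x)) / wsum)

    def neg_ll(params):
        a, b = np.exp(params)
        return -(
            (a - 1) * s_log + (b - 1) * s_log1m - special.betaln(a, b)
        )

    res = optimize.minimize(neg_ll, np.log(init), method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_beta_mixture_em(
    samples: PosteriorSamples | np.ndarray,
    n_components: int = 2,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> BetaMixture:
    """Maximum-likelihood beta-mixture approximation of posterior draws by EM.

    Initialised by method-of-moments on a k-means split of the draws; the
    log-likelihood is non-decreasing across iterations (asserted).
    Components whose weight collapses below 1e-4 are dropped and the fit is
    restarted with fewer components (with a warning).  The returned mixture
    is ordered by descending weight.
    """
    x = samples.draws if isinstance(samples, PosteriorSamples) else np.asarray(samples, float)
    if x.size < 1000:
        raise ValueError("need at least 1000 draws for a stable EM fit")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = np.clip(x, 1e-12, 1 - 1e-12)

    # k-means-style 1-D split by quantile seeding for initialisation
    order = np.argsort(x)
    splits = np.array_split(order, n_components)
    comps = []
    for idx in splits:
        comps.append(_beta_mom(x[idx], np.ones(len(idx))))
    weights = np.array([len(idx) for idx in splits], dtype=float)
    weights /= weights.sum()

    prev_ll = -np.inf
    for it in range(max_iter):
        a = np.array([c[0] for c in comps])[:, None]
        b = np.array([c[1] for c in comps])[:, None]
        logf = stats.beta.logpdf(x[None, :], a, b) + np.log(weights)[:, None]
        ll = float(np.sum(special.logsumexp(logf, axis=0)))
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(logf - special.logsumexp(logf, axis=0, keepdims=True))
        new_w = resp.sum(axis=1) / x.size
        if np.any(new_w < 1e-4) and n_components > 1:
            warnings.warn(
                f"degenerate EM component at iteration {it}; refitting with "
                f"{n_components - 1} components",
                RuntimeWarning,
                stacklevel=2,
            )
            return fit_beta_mixture_em(x, n_components - 1, seed=seed, tol=tol)
        comps = [
            _weighted_beta_mle(x, resp[k], comps[k]) for k in range(n_components)
        ]
        weights = new_w
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll

    return BetaMixture(comps, weights).sorted_by_weight()


def fit_beta_mixture_auto(
    samples: PosteriorSamples | np.ndarray,
    max_components: int = 4,
    seed: int = 0,
) -> BetaMixture:
    """Choose the number of EM components by AIC (1..max_components)."""
    x = samples.draws if isinstance(samples, PosteriorSamples) else np.asarray(samples, float)
    best, best_aic = None, np.inf
    for k in range(1, max_components + 1):
        mix = fit_beta_mixture_em(x, k, seed=seed)
        ll = float(np.sum(mix.logpdf(np.clip(x, 1e-12, 1 - 1e-12))))
        aic = 2 * (3 * mix.n_components - 1) - 2 * ll
        if aic < best_aic:
            best, best_aic = mix, aic
    return best


def mixture_summary(mix: BetaMixture, probs: Sequence[float] = (0.025, 0.5, 0.975)) -> dict:
    """Mean and quantiles of a beta mixture.

    The mean is the weight-averaged component mean; quantiles come from
    numerically inverting the mixture CDF.
    """
    probs = list(probs)
    if any(not (0 < p < 1) for p in probs):
        raise ValueError("quantile levels must lie in (0, 1)")
    q = mix.ppf(np.array(probs), tol=1e-8)
    return {"mean": mix.mean, "quantiles": dict(zip(probs, np.atleast_1d(q).tolist()))}
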