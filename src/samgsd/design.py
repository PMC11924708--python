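"""Group-sequential scaffold: error-spending boundaries and sample size.

The design machinery is entirely frequentist: Hwang-Shih-DeCani (HSD) error
spending allocates the one-sided type-I error alpha across the planned
analyses (efficacy/upper bounds) and the type-II error beta across the
interim analyses (futility/lower bounds, computed under the design
alternative).  Boundary crossing probabilities for the sequence of
standardised test statistics Z_1..Z_K — jointly normal with
Corr(Z_i, Z_j) = sqrt(t_i / t_j) — are evaluated by the canonical recursive
numerical integration over the continuation regions on the score scale,
where the increments are independent.

The resulting Z-bounds are then mapped to thresholds on the posterior
probability of the alternative via the standard-normal CDF, giving the
Bayesian stopping rules used by the trial engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DesignConfig",
    "GSDesign",
    "hsd_spending",
    "one_stage_sample_size",
    "build_gs_design",
    "z_to_probability_bounds",
]

_Z_RANGE = 8.0  # truncation of integration grids, in SDs of the score


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """All constants needed to build the group-sequential scaffold.

    Parameters
    ----------
    alpha
        One-sided type-I error level.
    beta_err
        Type-II error level (1 - power).
    margin_m
        Noninferiority margin on the risk-difference scale (> 0).
    theta_control
        Assumed control event rate used for sample-size variance.
    n_analyses
        Number of analyses including the final one (>= 1).
    info_fractions
        Increasing information fractions in (0, 1], last equal to 1.
        Defaults to equally spaced.
    gamma_alpha, gamma_beta
        HSD spending parameters for the alpha- (efficacy) and beta-
        (futility) spending functions.
    binding
        If True the futility bounds constrain the efficacy-bound
        computation (binding futility, the default — it reproduces the
        worked example's boundaries and maximum sample size).
    sample_size_rule
        ``"rounded_rate"`` rounds the control rate to 2 decimals before the
        variance term (the convention that reproduces the worked example);
        ``"exact_rate"`` uses ``theta_control`` as given.
    """

    alpha: float = 0.05
    beta_err: float = 0.2
    margin_m: float = 0.04
    theta_control: float = 0.179
    n_analyses: int = 3
    info_fractions: tuple[float, ...] | None = None
    gamma_alpha: float = -4.0
    gamma_beta: float = -2.0
    binding: bool = True
    sample_size_rule: Literal["rounded_rate", "exact_rate"] = "rounded_rate"

    def __post_init__(self):
        if not (0 < self.alpha < 0.5 and 0 < self.beta_err < 0.5):
            raise ValueError("alpha and beta_err must lie in (0, 0.5)")
        if self.margin_m <= 0:
            raise ValueError("noninferiority margin must be positive")
        if not (0 < self.theta_control < 1):
            raise ValueError("theta_control must lie in (0, 1)")
        if self.n_analyses < 1:
            raise ValueError("need at least one analysis")
        t = self.fractions()
        if len(t) != self.n_analyses:
            raise ValueError("info_fractions length must equal n_analyses")
        if np.any(np.diff(np.concatenate([[0.0], t])) <= 0) or abs(t[-1] - 1.0) > 1e-12:
            raise ValueError("info_fractions must be strictly increasing and end at 1")

    def fractions(self) -> np.ndarray:
        if self.info_fractions is None:
            k = self.n_analyses
            return np.arange(1, k + 1) / k
        return np.asarray(self.info_fractions, dtype=float)


@dataclass(frozen=True)
class GSDesign:
    """A fully solved group-sequential design."""

    z_lower: tuple[float, ...]
    z_upper: tuple[float, ...]
    prob_lower: tuple[float, ...]
    prob_upper: tuple[float, ...]
    info_fractions: tuple[float, ...]
    n_fixed: int
    n_max: int
    per_look_n: tuple[int, ...]
    inflation: float
    drift: float
    config: DesignConfig = field(repr=False)

    @property
    def n_analyses(self) -> int:
        return len(self.z_upper)

    def to_dict(self) -> dict:
        return {
            "z_lower": list(self.z_lower),
            "z_upper": list(self.z_upper),
            "prob_lower": list(self.prob_lower),
            "prob_upper": list(self.prob_upper),
            "info_fractions": list(self.info_fractions),
            "n_fixed": self.n_fixed,
            "n_max": self.n_max,
            "per_look_n": list(self.per_look_n),
            "inflation": self.inflation,
            "drift": self.drift,
        }

    def boundary_table(self) -> str:
        """Human-readable decision table on the posterior-probability scale."""
        lines = ["Analysis  Futility stopping   Continuation region        Efficacy stopping"]
        k = self.n_analyses
        for i in range(k):
            lo, hi = self.prob_lower[i], self.prob_upper[i]
            if i < k - 1:
                lines.append(
                    f"{i + 1:>8}  Pr(H1) < {lo:.3f}     {lo:.3f} <= Pr(H1) <= {hi:.3f}   Pr(H1) > {hi:.3f}"
                )
            else:
                lines.append(f"{'f':>8}  {'--':<17}   {'--':<24}   Pr(H1) > {hi:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spending functions
# ---------------------------------------------------------------------------


def hsd_spending(level: float, gamma: float, t: float | np.ndarray) -> float | np.ndarray:
    """Cumulative Hwang-Shih-DeCani error spent at information fraction t.

    ``level * (1 - exp(-gamma * t)) / (1 - exp(-gamma))``; the gamma -> 0
    limit is linear spending ``level * t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("information fraction must lie in [0, 1]")
    if abs(gamma) < 1e-12:
        out = level * t
    else:
        out = level * (1.0 - np.exp(-gamma * t)) / (1.0 - np.exp(-gamma))
    return out if out.ndim else float(out)


def z_to_probability_bounds(
    z_lower: Sequence[float], z_upper: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Map Z-scale bounds to posterior-probability thresholds Phi(Z)."""
    zl = np.asarray(z_lower, dtype=float)
    zu = np.asarray(z_upper, dtype=float)
    if not (np.all(np.isfinite(zl)) and np.all(np.isfinite(zu))):
        raise ValueError("bounds must be finite")
    return stats.norm.cdf(zl), stats.norm.cdf(zu)


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------


def one_stage_sample_size(cfg: DesignConfig) -> int:
    """Total one-stage (fixed) sample size for 1:1 noninferiority on a
    risk difference, unpooled normal approximation.

    Per-arm n = (z_{1-alpha} + z_{1-beta})^2 * 2 * theta (1 - theta) / M^2,
    rounded up per arm.
    """
    theta = cfg.theta_control
    if cfg.sample_size_rule == "rounded_rate":
        theta = round(theta, 2)
    z_a = stats.norm.ppf(1 - cfg.alpha)
    z_b = stats.norm.ppf(1 - cfg.beta_err)
    per_arm = (z_a + z_b) ** 2 * 2.0 * theta * (1 - theta) / cfg.margin_m**2
    return 2 * int(np.ceil(per_arm - 1e-9))


# ---------------------------------------------------------------------------
# recursive integration over continuation regions
# ---------------------------------------------------------------------------


class _ScoreGrid:
    """Subdensity of the score statistic S_k = Z_k * sqrt(t_k) restricted to
    the event 'no boundary crossed before analysis k'.

    Increments S_k - S_{k-1} are independent N(drift * dt, dt), which makes
    the restriction a one-dimensional convolution evaluated on Gauss-Legendre
    nodes over each continuation interval.
    """

    def __init__(self, n_nodes: int = 281):
        self.n_nodes = n_nodes
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        self._gl_x = x
        self._gl_w = w

    def nodes(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        return mid + half * self._gl_x, half * self._gl_w

    def start(self, lo: float, hi: float, mean: float, sd: float):
        x, w = self.nodes(lo, hi)
        dens = stats.norm.pdf(x, loc=mean, scale=sd)
        return x, w, dens

    def step(self, x_prev, w_prev, dens_prev, lo, hi, dmean, dsd):
        """Propagate the subdensity through one independent increment."""
        x, w = self.nodes(lo, hi)
        kern = stats.norm.pdf(x[:, None] - x_prev[None, :], loc=dmean, scale=dsd)
        dens = kern @ (w_prev * dens_prev)
        return x, w, dens

    @staticmethod
    def mass_above(x_prev, w_prev, dens_prev, cut, dmean, dsd) -> float:
        """P(next score >= cut, no earlier crossing)."""
        sf = stats.norm.sf((cut - x_prev - dmean) / dsd)
        return float(np.sum(w_prev * dens_prev * sf))

    @staticmethod
    def mass_below(x_prev, w_prev, dens_prev, cut, dmean, dsd) -> float:
        cdf = stats.norm.cdf((cut - x_prev - dmean) / dsd)
        return float(np.sum(w_prev * dens_prev * cdf))


def _solve_upper_bounds(
    t: np.ndarray,
    spend: np.ndarray,
    drift: float = 0.0,
    lower_scores: np.ndarray | None = None,
    grid: _ScoreGrid | None = None,
) -> np.ndarray:
    """Sequentially solve Z-scale efficacy bounds matching cumulative
    alpha-spend ``spend`` under the given drift.

    ``lower_scores`` (score scale) bound the continuation region from below
    (binding futility); when None the region is truncated at -8 SD
    (non-binding).
    """
    grid = grid or _ScoreGrid()
    k = len(t)
    z = np.empty(k)
    state = None  # (x, w, dens) at previous look
    for i in range(k):
        dt = t[i] - (t[i - 1] if i else 0.0)
        dmean, dsd = drift * dt, np.sqrt(dt)
        incr = spend[i] - (spend[i - 1] if i else 0.0)
        incr = max(incr, 1e-12)
        if i == 0:
            # marginal: P(S_1 >= c) = incr with S_1 ~ N(drift*t1, sqrt(t1))
            c = dmean + dsd * stats.norm.isf(incr)
        else:
            x_p, w_p, d_p = state

            def excess(cc):
                return _ScoreGrid.mass_above(x_p, w_p, d_p, cc, dmean, dsd) - incr

            lo_c = x_p.min() + dmean - _Z_RANGE * dsd
            hi_c = x_p.max() + dmean + _Z_RANGE * dsd
            c = optimize.brentq(excess, lo_c, hi_c, xtol=1e-12)
        z[i] = c / np.sqrt(t[i])
        if i < k - 1:
            lo = (
                lower_scores[i]
                if lower_scores is not None
                else (drift * t[i] - _Z_RANGE * np.sqrt(t[i]))
            )
            if lo >= c:
                raise ValueError(f"bounds crossed at look {i + 1}")
            if i == 0:
                state = grid.start(lo, c, dmean, dsd)
            else:
                x_p, w_p, d_p = state
                state = grid.step(x_p, w_p, d_p, lo, c, dmean, dsd)
    return z


def _solve_lower_bounds(
    t: np.ndarray,
    beta_spend: np.ndarray,
    upper_scores: np.ndarray,
    drift: float,
    grid: _ScoreGrid | None = None,
) -> tuple[np.ndarray, float]:
    """Solve futility bounds under the design alternative (``drift``) so the
    incremental probability of a lower crossing matches the beta-spend at
    each interim; returns interim lower Z-bounds and the probability of
    accepting the null at the final look (score below the final efficacy
    bound with no earlier stop).
    """
    grid = grid or _ScoreGrid()
    k = len(t)
    z = np.empty(k - 1) if k > 1 else np.empty(0)
    state = None
    for i in range(k):
        dt = t[i] - (t[i - 1] if i else 0.0)
        dmean, dsd = drift * dt, np.sqrt(dt)
        if i == k - 1:
            if k == 1:
                return z, float(stats.norm.cdf((upper_scores[0] - dmean) / dsd))
            x_p, w_p, d_p = state
            final_accept = _ScoreGrid.mass_below(x_p, w_p, d_p, upper_scores[i], dmean, dsd)
            return z, float(final_accept)
        incr = beta_spend[i] - (beta_spend[i - 1] if i else 0.0)
        incr = max(incr, 1e-12)
        if i == 0:
            c = dmean + dsd * stats.norm.ppf(incr)
        else:
            x_p, w_p, d_p = state

            def deficit(cc):
                return _ScoreGrid.mass_below(x_p, w_p, d_p, cc, dmean, dsd) - incr

            lo_c = x_p.min() + dmean - _Z_RANGE * dsd
            hi_c = x_p.max() + dmean + _Z_RANGE * dsd
            c = optimize.brentq(deficit, lo_c, hi_c, xtol=1e-12)
        if c >= upper_scores[i]:
            raise ValueError(f"bounds crossed at look {i + 1}")
        z[i] = c / np.sqrt(t[i])
        if i == 0:
            state = grid.start(c, upper_scores[i], dmean, dsd)
        else:
            x_p, w_p, d_p = state
            state = grid.step(x_p, w_p, d_p, c, upper_scores[i], dmean, dsd)
    raise AssertionError("unreachable")


def build_gs_design(cfg: DesignConfig) -> GSDesign:
    """Solve the full group-sequential design for ``cfg``.

    Efficacy (upper) Z-bounds satisfy the cumulative HSD alpha-spend under
    the null; futility (lower) bounds satisfy the HSD beta-spend under the
    design alternative, whose drift is inflated until the two boundaries
    meet at the final analysis with total type-II error ``beta_err``.
    ``n_max = ceil(n_fixed * inflation)`` where the inflation factor is
    ``(drift / drift_fixed)^2``.
    """
    t = cfg.fractions()
    k = cfg.n_analyses
    grid = _ScoreGrid()
    alpha_spend = np.asarray(hsd_spending(cfg.alpha, cfg.gamma_alpha, t), dtype=float).reshape(-1)
    n_fixed = one_stage_sample_size(cfg)
    z_a = stats.norm.ppf(1 - cfg.alpha)
    z_b = stats.norm.ppf(1 - cfg.beta_err)
    drift_fixed = z_a + z_b

    if k == 1:
        z_up = np.array([z_a])
        z_lo = np.array([z_a])
        drift = drift_fixed
        inflation = 1.0
    else:
        beta_spend = np.asarray(hsd_spending(cfg.beta_err, cfg.gamma_beta, t), dtype=float).reshape(-1)

        def upper_for(drift: float, lower_z: np.ndarray | None) -> np.ndarray:
            lower_scores = None
            if cfg.binding and lower_z is not None:
                lower_scores = lower_z * np.sqrt(t[:-1])
            return _solve_upper_bounds(t, alpha_spend, 0.0, lower_scores, grid)

        def total_beta(drift: float) -> tuple[float, np.ndarray, np.ndarray]:
            z_up = upper_for(drift, None)
            if cfg.binding:
                # futility bounds feed back into the alpha recursion
                z_lo_i = None
                for _ in range(20):
                    z_lo_i, accept = _solve_lower_bounds(
                        t, beta_spend, z_up * np.sqrt(t), drift, grid
                    )
                    z_new = upper_for(drift, z_lo_i)
                    if np.max(np.abs(z_new - z_up)) < 1e-10:
                        z_up = z_new
                        break
                    z_up = z_new
                z_lo_i, accept = _solve_lower_bounds(t, beta_spend, z_up * np.sqrt(t), drift, grid)
                return accept, z_up, z_lo_i
            z_lo_i, accept = _solve_lower_bounds(t, beta_spend, z_up * np.sqrt(t), drift, grid)
            return accept, z_up, z_lo_i

        # interim looks spend beta_spend[:-1]; the rest is accepted at the end
        target_final = cfg.beta_err - beta_spend[-2]

        def resid(drift: float) -> float:
            accept, _, _ = total_beta(drift)
            return accept - target_final

        try:
            lo_d, hi_d = drift_fixed * 0.95, drift_fixed * 1.05
            while resid(hi_d) > 0 and hi_d < drift_fixed * 1.6:
                hi_d *= 1.05
            drift = optimize.brentq(resid, lo_d, hi_d, xtol=1e-10)
        except ValueError as exc:
            raise ValueError(
                "spending configuration yields no solvable design: bounds cross "
                "before the final look or the drift search failed to bracket"
            ) from exc
        _, z_up, z_lo_interim = total_beta(drift)
        z_lo = np.concatenate([z_lo_interim, [z_up[-1]]])
        inflation = (drift / drift_fixed) ** 2

    n_max = int(np.ceil(n_fixed * inflation))
    if n_max % 2:
        n_max += 1  # keep 1:1 allocation possible
    per_look = tuple(int(np.ceil(n_max * ti)) for ti in t)
    per_look = per_look[:-1] + (n_max,)
    prob_lo, prob_up = z_to_probability_bounds(z_lo, z_up)
    return GSDesign(
        z_lower=tuple(float(x) for x in z_lo),
        z_upper=tuple(float(x) for x in z_up),
        prob_lower=tuple(float(x) for x in prob_lo),
        prob_upper=tuple(float(x) for x in prob_up),
        info_fractions=tuple(float(x) for x in t),
        n_fixed=n_fixed,
        n_max=n_max,
        per_look_n=per_look,
        inflation=float(inflation),
        drift=float(drift),
        config=cfg,
    )
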