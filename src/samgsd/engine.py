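"""Monte-Carlo trial engine for the group-sequential SAM-borrowing design.

Each simulated trial follows the interim algorithm: enrol the first stage
1:1, test the posterior probability of noninferiority against the
group-sequential thresholds, and — if the trial continues — recompute the
congruence weight w from the cumulative control data, assemble the SAM
prior, measure its ELIR effective sample size, and enrol the next stage
reduced by that ESS with the control-assignment probability tilted so that
borrowed information replaces control patients.

Operating characteristics (rejection rate, enrolment, ESS, stopping
pattern, weight traces) are aggregated over the eight-scenario grid that
crosses congruent/incongruent control rates with the null and alternative
noninferiority hypotheses.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .design import GSDesign
from .ess import elir_ess
from .inference import ArmPosterior, Decision, interim_decision, prob_noninferiority
from .mixture import BetaMixture
from .sam import CongruenceSpec, ControlData, build_sam_prior, sam_weight, weak_prior

__all__ = [
    "Scenario",
    "TrialConfig",
    "LookRecord",
    "TrialResult",
    "OperatingCharacteristics",
    "allocation_probability",
    "default_scenarios",
    "simulate_trial",
    "run_scenarios",
]


# ---------------------------------------------------------------------------
# scenario grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """True parameter settings for one simulation scenario."""

    id: str
    theta_h: float
    theta_c: float
    theta_t: float
    delta: float
    margin_m: float
    hypothesis: Literal["H0", "H1"]
    congruent: bool

    def __post_init__(self):
        for name in ("theta_h", "theta_c", "theta_t"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


def default_scenarios(theta_h: float, delta: float, margin_m: float) -> list[Scenario]:
    """The standard eight-scenario grid: current control rate offset from
    the historical rate by {0, -delta, -3 delta/2, -2 delta}, each crossed
    with the null (theta_t = theta_c + M) and alternative
    (theta_t = theta_c) hypotheses."""
    if theta_h - 2 * delta <= 0:
        raise ValueError("theta_h - 2*delta must stay positive")
    offsets = [0.0, -delta, -1.5 * delta, -2.0 * delta]
    out: list[Scenario] = []
    for i, off in enumerate(offsets):
        theta_c = theta_h + off
        for hyp in ("H0", "H1"):
            sid = str(2 * i + 1 + (hyp == "H1"))
            theta_t = theta_c + margin_m if hyp == "H0" else theta_c
            out.append(
                Scenario(
                    id=sid,
                    theta_h=theta_h,
                    theta_c=theta_c,
                    theta_t=theta_t,
                    delta=delta,
                    margin_m=margin_m,
                    hypothesis=hyp,
                    congruent=off == 0.0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# trial configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialConfig:
    """Everything the simulator needs besides the scenario truth.

    ``weight_mode="sam_adaptive"`` recomputes w from cumulative control
    data at each interim (design version a); ``"fixed"`` freezes w at
    ``fixed_weight`` (version b, default 0.5).
    """

    design: GSDesign
    map_em: BetaMixture
    theta_h_hat: float
    delta: float
    margin_m: float
    weight_mode: Literal["sam_adaptive", "fixed"] = "sam_adaptive"
    fixed_weight: float | None = None
    # uniform keeps the ELIR integral of the SAM mixture finite; the
    # mean-matched variant has alpha < 1 for low rates and no usable ESS
    weak_prior_kind: Literal["uniform", "mean_matched"] = "uniform"
    ess_weak: float = 1.0
    test_prior: BetaMixture = field(
        default_factory=lambda: BetaMixture([(1.0, 1.0)], [1.0])
    )
    borrow_first_stage: bool = False

    def __post_init__(self):
        if self.weight_mode == "fixed" and self.fixed_weight is None:
            raise ValueError("weight_mode='fixed' requires fixed_weight")
        if self.fixed_weight is not None and not (0 <= self.fixed_weight <= 1):
            raise ValueError("fixed_weight must lie in [0, 1]")


@dataclass(frozen=True)
class LookRecord:
    analysis: int
    w: float | None
    ess: float | None
    p: float
    n_control: int
    n_test: int


@dataclass(frozen=True)
class TrialResult:
    decision: Decision
    total_enrolled: int
    stop_look: int
    per_look: tuple[LookRecord, ...]

    @property
    def rejected_h0(self) -> bool:
        return self.decision.outcome in ("stop_efficacy", "final_noninferior")


@dataclass(frozen=True)
class OperatingCharacteristics:
    scenario_id: str
    hypothesis: str
    rejection_rate: float
    mean_enrolled: float
    enrolled_iqr: tuple[float, float]
    mean_ess: float
    ess_iqr: tuple[float, float]
    pct_stop_by_look: tuple[float, ...]
    mean_w_by_look: tuple[float, ...]
    w_iqr_by_look: tuple[tuple[float, float], ...]
    n_sims: int

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario_id,
            "hypothesis": self.hypothesis,
            "rejection_rate": self.rejection_rate,
            "enrolled_mean": self.mean_enrolled,
            "enrolled_q1": self.enrolled_iqr[0],
            "enrolled_q3": self.enrolled_iqr[1],
            "ess_mean": self.mean_ess,
            "ess_q1": self.ess_iqr[0],
            "ess_q3": self.ess_iqr[1],
            "n_sims": self.n_sims,
        }
        for i, pct in enumerate(self.pct_stop_by_look[:-1], start=1):
            row[f"pct_stop_{i}"] = pct
        for i, (m, iqr) in enumerate(
            zip(self.mean_w_by_look, self.w_iqr_by_look), start=1
        ):
            row[f"w{i}_mean"] = m
            row[f"w{i}_q1"] = iqr[0]
            row[f"w{i}_q3"] = iqr[1]
        return row


# ---------------------------------------------------------------------------
# allocation
# ---------------------------------------------------------------------------


def allocation_probability(n_c_planned: float, n_t_planned: float, ess: float) -> float:
    """Probability of assigning a new patient to the control arm when the
    prior already contributes ``ess`` patients of control information:
    r = max(n_c_planned - ess, 0) / n_t_planned; returns r / (r + 1)."""
    if n_c_planned <= 0 or n_t_planned <= 0:
        raise ValueError("planned per-arm counts must be positive")
    if ess < 0:
        raise ValueError("ess must be non-negative")
    r = max(n_c_planned - ess, 0.0) / n_t_planned
    return r / (r + 1.0)


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    cfg: TrialConfig, scenario: Scenario, rng: np.random.Generator
) -> TrialResult:
    """Run one trial under ``scenario`` and return its full per-look trace."""
    design = cfg.design
    k = design.n_analyses
    spec = CongruenceSpec(cfg.theta_h_hat, cfg.delta)
    if cfg.weak_prior_kind == "uniform":
        weak = BetaMixture([(1.0, 1.0)], [1.0])
    else:
        weak = weak_prior(cfg.theta_h_hat, cfg.ess_weak)

    n_c = y_c = n_t = y_t = 0
    records: list[LookRecord] = []
    control_prior = (
        build_sam_prior(0.5, cfg.map_em, weak) if cfg.borrow_first_stage else weak
    )
    w_current: float | None = None
    ess_current: float | None = None

    for i in range(k):
        prev_total = design.per_look_n[i - 1] if i else 0
        increment = design.per_look_n[i] - prev_total
        if i == 0 or ess_current is None:
            new_total, p_control = increment, 0.5
        else:
            new_total = max(increment - int(round(ess_current)), 0)
            per_arm_planned = increment / 2.0
            p_control = allocation_probability(
                per_arm_planned, per_arm_planned, ess_current
            )
            # keep the test arm on schedule even when ESS swallows the stage
            new_total = max(new_total, int(np.ceil(per_arm_planned)))
        assign_control = rng.random(new_total) < p_control
        add_c = int(assign_control.sum())
        add_t = new_total - add_c
        y_c += int(rng.binomial(add_c, scenario.theta_c)) if add_c else 0
        y_t += int(rng.binomial(add_t, scenario.theta_t)) if add_t else 0
        n_c += add_c
        n_t += add_t

        control_post = ArmPosterior(control_prior).update(y_c, n_c)
        test_post = ArmPosterior(cfg.test_prior).update(y_t, n_t)
        p = prob_noninferiority(test_post, control_post, cfg.margin_m)
        decision = interim_decision(p, design, i)
        records.append(
            LookRecord(analysis=i + 1, w=w_current, ess=ess_current, p=p, n_control=n_c, n_test=n_t)
        )
        if decision.outcome != "continue":
            return TrialResult(
                decision=decision,
                total_enrolled=n_c + n_t,
                stop_look=i + 1,
                per_look=tuple(records),
            )

        # continuing: refresh the SAM prior from cumulative control data
        if cfg.weight_mode == "sam_adaptive":
            w_current = sam_weight(ControlData(n_c, y_c), spec)
        else:
            w_current = float(cfg.fixed_weight)
        sam_prior = build_sam_prior(w_current, cfg.map_em, weak)
        ess_current = elir_ess(sam_prior).ess
        control_prior = sam_prior

    raise AssertionError("unreachable: final look always decides")


# ---------------------------------------------------------------------------
# scenario aggregation
# ---------------------------------------------------------------------------


def _iqr(x: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def run_scenarios(
    cfg: TrialConfig,
    scenarios: Sequence[Scenario],
    n_sims: int = 1000,
    seed: int = 0,
) -> list[OperatingCharacteristics]:
    """Simulate ``n_sims`` independent trials per scenario and aggregate.

    Each trial gets its own counter-based substream keyed by
    ``(seed, scenario id, trial index)`` so any scenario is reproducible in
    isolation.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    k = cfg.design.n_analyses
    out: list[OperatingCharacteristics] = []
    for sc in scenarios:
        sc_key = zlib.crc32(sc.id.encode()) & 0x7FFFFFFF
        results = []
        for j in range(n_sims):
            rng = np.random.default_rng((seed, sc_key, j))
            results.append(simulate_trial(cfg, sc, rng))
        rej = np.array([r.rejected_h0 for r in results], dtype=float)
        enrolled = np.array([r.total_enrolled for r in results], dtype=float)
        # SAM-prior ESS at the first interim, over trials that computed one
        # (trials stopped at the first look never assemble a SAM prior)
        ess_list = [
            next((rec.ess for rec in r.per_look if rec.ess is not None), None)
            for r in results
        ]
        ess_vals = np.array([e for e in ess_list if e is not None], dtype=float)
        if ess_vals.size == 0:
            ess_vals = np.array([np.nan])
        stops = np.array([r.stop_look for r in results])
        pct_stop = tuple(float(np.mean(stops == i + 1) * 100) for i in range(k))
        w_means, w_iqrs = [], []
        for look in range(1, k):  # w defined from the 2nd analysis onward
            ws = np.array(
                [
                    r.per_look[look].w
                    for r in results
                    if len(r.per_look) > look and r.per_look[look].w is not None
                ]
            )
            if ws.size:
                w_means.append(float(ws.mean()))
                w_iqrs.append(_iqr(ws))
            else:
                w_means.append(float("nan"))
                w_iqrs.append((float("nan"), float("nan")))
        out.append(
            OperatingCharacteristics(
                scenario_id=sc.id,
                hypothesis=sc.hypothesis,
                rejection_rate=float(rej.mean()),
                mean_enrolled=float(enrolled.mean()),
                enrolled_iqr=_iqr(enrolled),
                mean_ess=float(ess_vals.mean()),
                ess_iqr=_iqr(ess_vals),
                pct_stop_by_look=pct_stop,
                mean_w_by_look=tuple(w_means),
                w_iqr_by_look=tuple(w_iqrs),
                n_sims=n_sims,
            )
        )
    return out


def characteristics_table(ocs: Sequence[OperatingCharacteristics]) -> pd.DataFrame:
    """Operating characteristics as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame([oc.to_row() for oc in ocs])
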