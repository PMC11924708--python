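import numpy as np
import pytest
from scipy import stats

from samgsd.design import (
    DesignConfig,
    build_gs_design,
    hsd_spending,
    one_stage_sample_size,
    z_to_probability_bounds,
)


class TestHsdSpending:
    def test_full_spend_at_one(self):
        assert hsd_spending(0.05, -4, 1.0) == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "level,gamma,t,expected",
        [(0.05, -4, 1 / 3, 0.0026061), (0.2, -2, 1 / 3, 0.029667)],
    )
    def test_direct_formula_values(self, level, gamma, t, expected):
        assert hsd_spending(level, gamma, t) == pytest.approx(expected, abs=5e-7)

    def test_gamma_zero_limit_linear(self):
        assert hsd_spending(0.1, 0.0, 0.4) == pytest.approx(0.04)

    def test_rejects_fraction_outside_unit(self):
        with pytest.raises(ValueError):
            hsd_spending(0.05, -4, 1.2)


class TestOneStageSampleSize:
    def test_worked_example_total(self):
        assert one_stage_sample_size(DesignConfig()) == 2282

    def test_hand_arithmetic_small(self):
        cfg = DesignConfig(theta_control=0.5, margin_m=0.5, sample_size_rule="exact_rate")
        # (1.6449 + 0.8416)^2 * 2 * 0.25 / 0.25 = 12.37 -> 13 per arm
        assert one_stage_sample_size(cfg) == 26

    def test_margin_scaling_quarters_n(self):
        base = DesignConfig(margin_m=0.02, sample_size_rule="exact_rate")
        wide = DesignConfig(margin_m=0.04, sample_size_rule="exact_rate")
        ratio = one_stage_sample_size(base) / one_stage_sample_size(wide)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(margin_m=0.0)


class TestBoundarySolve:
    def test_single_look_degenerate(self):
        d = build_gs_design(DesignConfig(n_analyses=1, info_fractions=(1.0,)))
        assert d.z_upper[0] == pytest.approx(stats.norm.ppf(0.95), abs=1e-6)
        assert d.inflation == pytest.approx(1.0)

    def test_inflation_exceeds_one_for_multiple_looks(self):
        for k in (2, 3, 4):
            d = build_gs_design(DesignConfig(n_analyses=k))
            assert d.inflation > 1.0

    def test_bounds_meet_only_at_final(self, example_design):
        z_lo, z_up = np.array(example_design.z_lower), np.array(example_design.z_upper)
        assert np.all(z_lo[:-1] < z_up[:-1])
        assert z_lo[-1] == pytest.approx(z_up[-1], abs=1e-9)

    def test_four_analysis_design_solves(self):
        d = build_gs_design(DesignConfig(n_analyses=4))
        assert d.n_analyses == 4
        assert d.per_look_n[-1] == d.n_max
        assert np.all(np.diff(d.per_look_n) > 0)

    def test_alpha_spent_matches_total(self, example_design):
        """Total null crossing probability of the upper bounds (with binding
        futility) equals alpha by MC simulation."""
        rej, _ = _mc_crossing(example_design, drift=0.0, n=400_000, seed=5)
        se = np.sqrt(0.05 * 0.95 / 400_000)
        assert rej == pytest.approx(0.05, abs=3.5 * se)

    def test_beta_spent_matches_total_at_alternative(self, example_design):
        """Acceptance probability at the design alternative equals beta."""
        _, acc = _mc_crossing(example_design, drift=example_design.drift, n=400_000, seed=6)
        se = np.sqrt(0.2 * 0.8 / 400_000)
        assert acc == pytest.approx(0.2, abs=3.5 * se)

    def test_two_look_engine_vs_bivariate_mc(self):
        """Per-look crossing probabilities vs brute-force correlated-normal
        simulation."""
        cfg = DesignConfig(n_analyses=2)
        d = build_gs_design(cfg)
        t = np.array(d.info_fractions)
        rng = np.random.default_rng(11)
        n = 1_000_000
        # Brownian construction: S_i = sum of independent increments
        s1 = rng.normal(0, np.sqrt(t[0]), n)
        s2 = s1 + rng.normal(0, np.sqrt(t[1] - t[0]), n)
        z1, z2 = s1 / np.sqrt(t[0]), s2 / np.sqrt(t[1])
        spend = hsd_spending(cfg.alpha, cfg.gamma_alpha, t)
        p1 = np.mean(z1 >= d.z_upper[0])
        se1 = np.sqrt(spend[0] * (1 - spend[0]) / n)
        assert p1 == pytest.approx(spend[0], abs=3 * se1)
        cont = (z1 > d.z_lower[0]) & (z1 < d.z_upper[0])
        p2 = np.mean(cont & (z2 >= d.z_upper[1]))
        incr = spend[1] - spend[0]
        se2 = np.sqrt(incr * (1 - incr) / n)
        assert p2 == pytest.approx(incr, abs=3 * se2)

    def test_unsolvable_spending_raises(self):
        # spending nearly all beta at the first looks leaves no solvable design
        with pytest.raises(ValueError, match="bounds cross|look"):
            build_gs_design(DesignConfig(beta_err=0.45, gamma_beta=20.0, alpha=0.049))


class TestProbabilityBounds:
    def test_phi_mapping_examples(self):
        lo, up = z_to_probability_bounds([-0.42, 0.64, 1.64], [2.79, 2.29, 1.64])
        assert np.round(lo, 3).tolist() == [0.337, 0.739, 0.949]
        assert np.round(up[:2], 3).tolist() == [0.997, 0.989]

    def test_zero_maps_to_half(self):
        lo, _ = z_to_probability_bounds([0.0], [1.0])
        assert lo[0] == pytest.approx(0.5)

    def test_preserves_ordering(self, example_design):
        assert np.all(np.diff(example_design.prob_lower) > -1e-12)
        assert np.all(np.array(example_design.prob_lower) <= np.array(example_design.prob_upper) + 1e-12)

    def test_rejects_infinite(self):
        with pytest.raises(ValueError):
            z_to_probability_bounds([np.inf], [1.0])


def _mc_crossing(design, drift, n, seed):
    """MC estimate of (efficacy crossing, acceptance) probabilities."""
    rng = np.random.default_rng(seed)
    t = np.array(design.info_fractions)
    k = len(t)
    dt = np.diff(np.concatenate([[0.0], t]))
    s = np.cumsum(
        rng.normal(drift * dt, np.sqrt(dt), size=(n, k)), axis=1
    )
    z = s / np.sqrt(t)
    alive = np.ones(n, dtype=bool)
    rejected = np.zeros(n, dtype=bool)
    accepted = np.zeros(n, dtype=bool)
    for i in range(k):
        up = z[:, i] > np.array(design.z_upper)[i]
        lo = z[:, i] < np.array(design.z_lower)[i]
        if i < k - 1:
            rejected |= alive & up
            accepted |= alive & lo
            alive &= ~(up | lo)
        else:
            rejected |= alive & up
            accepted |= alive & ~up
    return float(np.mean(rejected)), float(np.mean(accepted))
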