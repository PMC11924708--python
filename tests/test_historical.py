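import numpy as np
import pytest
from scipy import special, stats

from samgsd.historical import (
    ConvergenceError,
    HistoricalStudy,
    McmcSettings,
    PosteriorSamples,
    fit_beta_mixture_em,
    fit_map_hierarchical,
    heterogeneity_i2,
    mixture_summary,
    read_historical_csv,
)
from samgsd.mixture import BetaMixture

FAST_MCMC = McmcSettings(n_tune=800, n_draws=800, thin=4, max_rhat=1.02)


class TestHistoricalStudy:
    def test_invariants(self):
        with pytest.raises(ValueError):
            HistoricalStudy(0, 0)
        with pytest.raises(ValueError):
            HistoricalStudy(10, 11)
        assert HistoricalStudy(204, 30).proportion == pytest.approx(30 / 204)

    def test_csv_roundtrip(self, tmp_path, four_studies):
        p = tmp_path / "hist.csv"
        p.write_text(
            "study_id,n_patients,n_events\n"
            + "\n".join(f"S{i},{s.n_patients},{s.n_events}" for i, s in enumerate(four_studies))
        )
        assert read_historical_csv(p) == four_studies


class TestHeterogeneity:
    def test_homogeneous_studies_give_zero(self):
        studies = [HistoricalStudy(100, 20), HistoricalStudy(100, 20)]
        res = heterogeneity_i2(studies)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.i_squared == 0.0

    def test_worked_example_matches_reported_value(self, four_studies):
        # substantial heterogeneity across the four historical arms
        res = heterogeneity_i2(four_studies, scale="logit")
        assert res.i_squared == pytest.approx(0.92, abs=0.015)
        assert res.p_value < 0.001
        raw = heterogeneity_i2(four_studies, scale="raw")
        assert raw.i_squared == pytest.approx(0.92, abs=0.015)

    def test_hand_computed_extreme_case(self):
        # proportions 0.1 / 0.5 / 0.9 with n=100: direct Q arithmetic
        studies = [HistoricalStudy(100, 10), HistoricalStudy(100, 50), HistoricalStudy(100, 90)]
        y = np.array([10.0, 50.0, 90.0])
        n = np.array([100.0] * 3)
        eff = np.log(y / (n - y))
        w = 1.0 / (1.0 / y + 1.0 / (n - y))
        pooled = np.sum(w * eff) / np.sum(w)
        q = float(np.sum(w * (eff - pooled) ** 2))
        res = heterogeneity_i2(studies)
        assert res.q_statistic == pytest.approx(q)
        assert res.i_squared > 0.9

    def test_relabeling_invariance(self, four_studies):
        shuffled = [four_studies[i] for i in (2, 0, 3, 1)]
        assert heterogeneity_i2(shuffled).i_squared == pytest.approx(
            heterogeneity_i2(four_studies).i_squared
        )

    def test_zero_cell_continuity_correction_flagged(self):
        studies = [HistoricalStudy(50, 0), HistoricalStudy(60, 10)]
        res = heterogeneity_i2(studies)
        assert res.continuity_corrected

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_i2([HistoricalStudy(10, 2)])


def _grid_oracle_predictive_mean(studies, sd_mu=2.0, sd_tau=1.0):
    """Brute-force posterior over (mu, tau): Gauss-Hermite integration of
    each study's random effect, trapezoid over a (mu, tau) grid."""
    zh, wh = np.polynomial.hermite_e.hermegauss(64)
    wh = wh / wh.sum()
    mus = np.linspace(-6, 2, 241)
    taus = np.linspace(1e-4, 4, 161)
    y = np.array([s.n_events for s in studies], dtype=float)
    n = np.array([s.n_patients for s in studies], dtype=float)
    # log-lik per (mu, tau): sum_j log E_z[Bin(y_j | n_j, expit(mu + tau z))]
    logpost = np.empty((len(mus), len(taus)))
    for i, mu in enumerate(mus):
        for j, tau in enumerate(taus):
            eta = mu + tau * zh  # (64,)
            ll_z = (
                y[:, None] * eta[None, :]
                - n[:, None] * np.logaddexp(0.0, eta)[None, :]
            )
            ll = special.logsumexp(ll_z + np.log(wh)[None, :], axis=1).sum()
            logpost[i, j] = (
                ll
                + stats.norm.logpdf(mu, 0, sd_mu)
                + stats.halfnorm.logpdf(tau, scale=sd_tau)
            )
    post = np.exp(logpost - logpost.max())
    post /= post.sum()
    pred = special.expit(mus[:, None, None] + taus[None, :, None] * zh[None, None, :])
    pred_mean_cell = np.sum(pred * wh[None, None, :], axis=2)
    return float(np.sum(post * pred_mean_cell))


class TestHierarchicalFit:
    def test_pooling_limit_single_balanced_study(self):
        # tau pinned near zero: predictive collapses to the pooled posterior
        s = McmcSettings(n_tune=500, n_draws=500, thin=2, tau_fixed=1e-4, max_rhat=1.02)
        ps = fit_map_hierarchical([HistoricalStudy(100, 50)], s, seed=7)
        assert float(np.mean(ps.draws)) == pytest.approx(0.5, abs=0.02)

    def test_two_identical_studies_match_grid_oracle(self):
        studies = [HistoricalStudy(100, 20), HistoricalStudy(100, 20)]
        oracle = _grid_oracle_predictive_mean(studies)
        ps = fit_map_hierarchical(studies, FAST_MCMC, seed=11)
        assert float(np.mean(ps.draws)) == pytest.approx(oracle, abs=0.02)

    def test_four_studies_match_grid_oracle_and_stay_in_range(self, four_studies):
        oracle = _grid_oracle_predictive_mean(four_studies)
        ps = fit_map_hierarchical(four_studies, FAST_MCMC, seed=13)
        mean = float(np.mean(ps.draws))
        assert mean == pytest.approx(oracle, abs=0.025)
        props = [s.proportion for s in four_studies]
        assert min(props) < mean < max(props)
        assert ps.diagnostics["max_rhat"] < FAST_MCMC.max_rhat

    def test_nonconvergence_raises_with_diagnostics(self, four_studies):
        s = McmcSettings(n_tune=2, n_draws=20, thin=1, max_rhat=1.0001)
        with pytest.raises(ConvergenceError) as exc:
            fit_map_hierarchical(four_studies, s, seed=1)
        assert "rhat" in exc.value.diagnostics

    def test_zero_event_study_is_valid(self):
        s = McmcSettings(n_tune=400, n_draws=400, thin=2, max_rhat=1.05)
        ps = fit_map_hierarchical([HistoricalStudy(50, 0)], s, seed=3)
        assert 0 < float(np.mean(ps.draws)) < 0.2


class TestBetaMixtureEM:
    def test_single_component_parameter_recovery(self, rng):
        draws = rng.beta(10, 50, size=10_000)
        mix = fit_beta_mixture_em(draws, n_components=1, seed=0)
        a, b = mix.components[0]
        assert a == pytest.approx(10, rel=0.10)
        assert b == pytest.approx(50, rel=0.10)

    def test_two_component_weight_recovery(self, rng):
        comp = rng.random(20_000) < 0.5
        draws = np.where(comp, rng.beta(2, 38, 20_000), rng.beta(30, 70, 20_000))
        mix = fit_beta_mixture_em(draws, n_components=2, seed=0)
        assert max(mix.weights) == pytest.approx(0.5, abs=0.05)

    def test_fitted_mean_matches_sample_mean(self, rng):
        draws = np.concatenate([rng.beta(3, 20, 6000), rng.beta(8, 30, 6000)])
        mix = fit_beta_mixture_em(draws, n_components=2, seed=0)
        assert mix.mean == pytest.approx(float(draws.mean()), abs=0.005)

    def test_components_sorted_by_weight(self, rng):
        draws = np.where(rng.random(12_000) < 0.8, rng.beta(5, 45, 12_000), rng.beta(40, 60, 12_000))
        mix = fit_beta_mixture_em(draws, n_components=2, seed=0)
        assert mix.weights[0] >= mix.weights[1]

    def test_requires_enough_draws(self, rng):
        with pytest.raises(ValueError):
            fit_beta_mixture_em(rng.beta(2, 2, 100), 1)

    def test_overparameterised_fit_stays_valid(self, rng):
        # unimodal draws with too many components: the fit must stay a
        # proper mixture and reproduce the sample mean
        draws = rng.beta(10, 50, size=5_000)
        mix = fit_beta_mixture_em(draws, n_components=4, seed=0)
        assert sum(mix.weights) == pytest.approx(1.0, abs=1e-9)
        assert mix.mean == pytest.approx(float(draws.mean()), abs=0.005)


class TestMixtureSummary:
    def test_published_mixture_mean(self, map_em):
        s = mixture_summary(map_em)
        assert s["mean"] == pytest.approx(0.179, abs=5e-4)

    def test_published_mixture_lower_quantile(self, map_em):
        s = mixture_summary(map_em, [0.025])
        assert s["quantiles"][0.025] == pytest.approx(0.08, abs=5e-3)

    def test_uniform_summary(self, uniform):
        s = mixture_summary(uniform, [0.5])
        assert s["mean"] == 0.5
        assert s["quantiles"][0.5] == pytest.approx(0.5, abs=1e-8)

    def test_rejects_bad_levels(self, uniform):
        with pytest.raises(ValueError):
            mixture_summary(uniform, [0.0, 0.5])


def test_posterior_samples_invariants():
    with pytest.raises(ValueError):
        PosteriorSamples(np.array([0.2, 1.0]), 4)
    with pytest.raises(ValueError):
        PosteriorSamples(np.array([0.2, 0.4]), 1)
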