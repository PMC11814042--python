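"""Monte Carlo risk: fitting, propagation, exceedance, shares."""

import numpy as np
import pytest
from scipy import stats

from soilrisk import hra
from soilrisk.hra import CHILD, DEFAULT_TOXICITY, ToxicityValues
from soilrisk.mc_risk import (
    ConcentrationDistribution,
    McConfig,
    contribution_shares,
    fit_concentration_distribution,
    monte_carlo_risk,
)


class TestFitDistribution:
    def test_moment_match_is_exact_in_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 0.9, 200)
        d = fit_concentration_distribution(x, method="moments")
        mean = np.exp(d.params["mu"] + d.params["sigma"] ** 2 / 2)
        sd = mean * np.sqrt(np.expm1(d.params["sigma"] ** 2))
        assert mean == pytest.approx(x.mean(), rel=1e-12)
        assert sd == pytest.approx(x.std(ddof=1), rel=1e-12)

    def test_mle_recovers_parameters_within_3_se(self):
        mu, sigma, n = 2.0, 0.7, 20000
        x = np.random.default_rng(1).lognormal(mu, sigma, n)
        d = fit_concentration_distribution(x, method="mle")
        assert abs(d.params["mu"] - mu) < 3 * sigma / np.sqrt(n)
        assert abs(d.params["sigma"] - sigma) < 3 * sigma / np.sqrt(2 * n)

    def test_constant_sample_degenerate(self):
        d = fit_concentration_distribution(np.full(10, 4.0))
        assert d.family == "degenerate"
        draws = d.sample(np.random.default_rng(0), 50)
        np.testing.assert_array_equal(draws, 4.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_concentration_distribution(np.ones(4) + np.arange(4))

    def test_nonpositive_rejected_for_lognormal(self):
        with pytest.raises(ValueError):
            fit_concentration_distribution(np.array([1.0, 2.0, 0.0, 3.0, 4.0]))


class TestMonteCarloRisk:
    def test_zero_variance_equals_deterministic_exactly(self):
        c = 85.0
        # power-of-two iteration count keeps the float mean of identical
        # draws exact, so equality can be asserted without tolerance
        dists = {"As": ConcentrationDistribution("degenerate", {"value": c})}
        cfg = McConfig(n_iter=256, seed=0)
        mc = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, cfg, "HI")
        det = hra.hazard_quotients(c, CHILD, DEFAULT_TOXICITY["As"]).total
        assert mc.mean == det
        assert mc.percentile == det

    def test_exceedance_zero_when_all_draws_below_threshold(self):
        dists = {"As": ConcentrationDistribution("degenerate", {"value": 1.0})}
        mc = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, McConfig(seed=1), "HI")
        assert mc.exceedance(1.0) == 0.0

    def test_exceedance_matches_analytic_lognormal_tail(self):
        """Single element, ingestion-only: HI is a linear map of a
        lognormal, so P(HI > 1) has a closed form."""
        mu, sigma = 4.0, 0.8
        dists = {"X": ConcentrationDistribution("lognormal", {"mu": mu, "sigma": sigma})}
        tox = {"X": ToxicityValues("X", RfDo=3e-4, RBA=1.0, ABSd=0.0)}
        n_iter = 10**4
        mc = monte_carlo_risk(dists, CHILD, tox, McConfig(n_iter=n_iter, seed=2), "HI")
        slope = hra.hazard_quotients(1.0, CHILD, tox["X"]).total
        # HI > 1  <=>  C > 1/slope
        p_true = 1 - stats.lognorm.cdf(1.0 / slope, sigma, scale=np.exp(mu))
        se = np.sqrt(p_true * (1 - p_true) / n_iter)
        assert abs(mc.exceedance(1.0) - p_true) < 3 * se

    def test_mc_mean_converges_to_deterministic_at_mean(self):
        mu, sigma = 3.0, 0.5
        dists = {"As": ConcentrationDistribution("lognormal", {"mu": mu, "sigma": sigma})}
        mc = monte_carlo_risk(
            dists, CHILD, DEFAULT_TOXICITY, McConfig(n_iter=10**5, seed=3), "HI"
        )
        det = hra.hazard_quotients(dists["As"].mean, CHILD, DEFAULT_TOXICITY["As"]).total
        assert mc.mean == pytest.approx(det, rel=0.005)

    def test_seed_reproducibility(self):
        dists = {"As": ConcentrationDistribution("lognormal", {"mu": 3, "sigma": 1})}
        cfg = McConfig(n_iter=500, seed=9)
        a = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, cfg, "HI")
        b = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, cfg, "HI")
        np.testing.assert_array_equal(a.total_draws, b.total_draws)

    def test_exceedance_monotone_in_threshold(self):
        dists = {"As": ConcentrationDistribution("lognormal", {"mu": 3, "sigma": 1})}
        mc = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, McConfig(seed=4), "HI")
        thresholds = np.linspace(0, 10, 25)
        probs = [mc.exceedance(t) for t in thresholds]
        assert np.all(np.diff(probs) <= 0)

    def test_tcr_skips_non_carcinogens(self):
        dists = {
            "As": ConcentrationDistribution("degenerate", {"value": 50.0}),
            "Sb": ConcentrationDistribution("degenerate", {"value": 5.0}),
        }
        mc = monte_carlo_risk(dists, hra.AGE_ADJUSTED, DEFAULT_TOXICITY,
                              McConfig(seed=5), "TCR")
        assert list(mc.element_draws.columns) == ["As"]

    def test_band_probabilities_partition(self):
        dists = {"As": ConcentrationDistribution("lognormal", {"mu": 3, "sigma": 1.5})}
        mc = monte_carlo_risk(dists, hra.AGE_ADJUSTED, DEFAULT_TOXICITY,
                              McConfig(n_iter=2000, seed=6), "TCR")
        bands = mc.band_probabilities()
        assert sum(bands.values()) == pytest.approx(1.0)
        assert all(0 <= p <= 1 for p in bands.values())


class TestContributionShares:
    def test_single_element_is_100(self):
        import pandas as pd

        shares = contribution_shares(pd.DataFrame({"As": [1.0, 2.0, 3.0]}))
        assert shares["As"] == pytest.approx(100.0)

    def test_identical_elements_split_50_50(self):
        dists = {
            "A": ConcentrationDistribution("lognormal", {"mu": 2, "sigma": 0.5}),
            "B": ConcentrationDistribution("lognormal", {"mu": 2, "sigma": 0.5}),
        }
        tox = {
            "A": ToxicityValues("A", RfDo=3e-4, RBA=1.0),
            "B": ToxicityValues("B", RfDo=3e-4, RBA=1.0),
        }
        mc = monte_carlo_risk(dists, CHILD, tox, McConfig(n_iter=20000, seed=7), "HI")
        shares = mc.contribution_pct()
        assert shares["A"] == pytest.approx(50.0, abs=1.5)

    def test_shares_sum_to_100_same_draws(self):
        dists = {
            "As": ConcentrationDistribution("lognormal", {"mu": 4, "sigma": 1}),
            "Pb": ConcentrationDistribution("lognormal", {"mu": 5, "sigma": 1}),
            "Sb": ConcentrationDistribution("lognormal", {"mu": 1, "sigma": 1}),
        }
        mc = monte_carlo_risk(dists, CHILD, DEFAULT_TOXICITY, McConfig(seed=8), "HI")
        assert mc.contribution_pct().sum() == pytest.approx(100.0, rel=1e-12)

    def test_zero_total_risk_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            contribution_shares(pd.DataFrame({"As": [0.0, 0.0]}))
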