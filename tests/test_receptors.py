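"""PCA/varimax and weighted PMF: recovery, monotonicity, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from soilrisk.receptors import (
    UncertaintySpec,
    match_factors,
    pca_varimax,
    pmf_diagnostics,
    pmf_fit,
    q_scan,
    uncertainty_matrix,
)
from tests.conftest import make_table


def uniform_mu(X: pd.DataFrame, value: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(value, index=X.index, columns=X.columns)


class TestPcaVarimax:
    def test_two_latent_factors_recovered(self):
        rng = np.random.default_rng(0)
        n = 300
        f = rng.normal(size=(n, 2))
        true_loadings = np.array(
            [
                [0.9, 0.0], [0.85, 0.1], [0.8, 0.05],
                [0.0, 0.9], [0.1, 0.85], [0.05, 0.8],
            ]
        )
        X = f @ true_loadings.T + rng.normal(scale=0.3, size=(n, 6))
        res = pca_varimax(make_table(X + 10.0))
        assert res.loadings.shape[1] == 2
        # Tucker congruence after optimal matching
        _, cos = match_factors(res.loadings.to_numpy().T, true_loadings.T)
        assert (np.abs(cos) > 0.95).all()

    def test_null_data_warns_about_unstable_retention(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 6)) + 5.0
        with pytest.warns(UserWarning, match="retention is unstable"):
            pca_varimax(make_table(X), n_components=2)

    def test_rotation_preserves_communalities(self, study_table):
        _, table, _, _ = study_table
        res = pca_varimax(table, n_components=4)
        Z = (table.conc - table.conc.mean()) / table.conc.std(ddof=1)
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1][:4]
        unrotated = eigvec[:, order] * np.sqrt(eigval[order])[None, :]
        np.testing.assert_allclose(
            (res.loadings.to_numpy() ** 2).sum(axis=1),
            (unrotated**2).sum(axis=1),
            atol=1e-8,
        )

    def test_retained_variance_totals_match(self, study_table):
        _, table, _, _ = study_table
        res = pca_varimax(table, n_components=4)
        Z = (table.conc - table.conc.mean()) / table.conc.std(ddof=1)
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        eigval = np.sort(np.linalg.eigvalsh(R))[::-1]
        expected_total = 100 * eigval[:4].sum() / len(table.elements)
        assert res.variance_pct.sum() == pytest.approx(expected_total, rel=1e-8)

    def test_constant_column_rejected(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10.0)
        X[:, 1] = np.arange(10.0) ** 2
        with pytest.raises(ValueError):
            pca_varimax(make_table(X))


class TestUncertaintyMatrix:
    def test_error_propagation_above_mdl(self):
        conc = pd.DataFrame({"As": [10.0]})
        spec = UncertaintySpec(sigma={"As": 0.1}, mdl={"As": 1.0})
        mu = uncertainty_matrix(conc, spec)
        assert mu.iloc[0, 0] == pytest.approx(np.sqrt(1.25))

    def test_five_sixths_rule_below_mdl(self):
        conc = pd.DataFrame({"As": [0.5]})
        spec = UncertaintySpec(sigma={"As": 0.1}, mdl={"As": 1.0})
        mu = uncertainty_matrix(conc, spec)
        assert mu.iloc[0, 0] == pytest.approx(5.0 / 6.0)

    def test_degenerate_mdl_zero(self):
        conc = pd.DataFrame({"As": [50.0]})
        spec = UncertaintySpec(sigma={"As": 0.2}, mdl={"As": 0.0})
        mu = uncertainty_matrix(conc, spec)
        assert mu.iloc[0, 0] == pytest.approx(10.0)

    def test_literal_dialect_uses_printed_trigger(self):
        # propagated = sqrt(1 + 0.25) > MDL = 1 -> literal dialect fires 5/6 rule
        conc = pd.DataFrame({"As": [10.0]})
        spec = UncertaintySpec(sigma={"As": 0.1}, mdl={"As": 1.0})
        mu = uncertainty_matrix(conc, spec, dialect="literal")
        assert mu.iloc[0, 0] == pytest.approx(5.0 / 6.0)

    def test_negative_concentration_rejected(self):
        conc = pd.DataFrame({"As": [-1.0]})
        spec = UncertaintySpec(sigma={"As": 0.1}, mdl={"As": 1.0})
        with pytest.raises(ValueError):
            uncertainty_matrix(conc, spec)


class TestPmfFit:
    def make_rank3(self, n=60, m=8, seed=0):
        """Rank-3 system with marker elements (block support in F): each
        source has elements no other source emits, which makes the
        non-negative factorisation identifiable for recovery assertions."""
        rng = np.random.default_rng(seed)
        G = rng.uniform(0.5, 2.0, size=(n, 3))
        G[:3] = 2.0 * np.eye(3)  # pure samples pin the mixing cone
        F = np.zeros((3, m))
        F[0, :3] = rng.uniform(1.0, 5.0, 3) * 10
        F[1, 3:6] = rng.uniform(1.0, 5.0, 3) * 10
        F[2, 6:] = rng.uniform(1.0, 5.0, m - 6) * 10
        return G, F

    def test_noiseless_recovery_and_objective(self):
        G, F = self.make_rank3()
        X = pd.DataFrame(G @ F)
        model = pmf_fit(X, uniform_mu(X), 3, n_runs=10, seed=0)
        n, m = X.shape
        assert model.Q < 1e-6 * n * m
        _, cos = match_factors(model.F.to_numpy(), F)
        assert (cos > 0.99).all()

    def test_rank_one_reconstruction(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(np.outer(rng.uniform(1, 2, 30), rng.uniform(1, 5, 6)))
        model = pmf_fit(X, uniform_mu(X), 1, n_runs=3, seed=0)
        rel = np.linalg.norm(X.to_numpy() - model.reconstruction().to_numpy()) / np.linalg.norm(X.to_numpy())
        assert rel < 1e-6

    def test_doubling_mu_divides_q_by_four(self):
        G, F = self.make_rank3(seed=2)
        rng = np.random.default_rng(3)
        X = pd.DataFrame((G @ F) * rng.lognormal(0, 0.2, size=(60, 8)))
        m1 = pmf_fit(X, uniform_mu(X), 3, n_runs=2, seed=4, max_iter=50)
        # evaluate Q of the *same* G, F under doubled mu
        r = (X.to_numpy() - m1.G.to_numpy() @ m1.F.to_numpy())
        q1 = (r**2).sum()
        q2 = ((r / 2.0) ** 2).sum()
        assert q2 == pytest.approx(q1 / 4.0, rel=1e-12)

    def test_q_monotone_within_every_run(self):
        G, F = self.make_rank3(seed=5)
        rng = np.random.default_rng(6)
        X = pd.DataFrame((G @ F) * rng.lognormal(0, 0.3, size=(60, 8)))
        model = pmf_fit(X, uniform_mu(X), 3, n_runs=5, seed=7)
        for hist in model.q_history:
            assert np.all(np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0))

    def test_nonnegativity_and_factor_order(self):
        G, F = self.make_rank3(seed=8)
        X = pd.DataFrame(G @ F)
        model = pmf_fit(X, uniform_mu(X), 3, n_runs=3, seed=9)
        assert (model.G.to_numpy() >= 0).all()
        assert (model.F.to_numpy() >= 0).all()
        assert np.all(np.diff(model.explained_variance_pct) <= 1e-12)

    def test_deterministic_given_seed(self):
        G, F = self.make_rank3(seed=10)
        X = pd.DataFrame(G @ F)
        m1 = pmf_fit(X, uniform_mu(X), 2, n_runs=3, seed=11, max_iter=60)
        m2 = pmf_fit(X, uniform_mu(X), 2, n_runs=3, seed=11, max_iter=60)
        np.testing.assert_array_equal(m1.G.to_numpy(), m2.G.to_numpy())

    def test_invalid_inputs_rejected(self):
        X = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError):
            pmf_fit(X, uniform_mu(X), 4, n_runs=1, seed=0)  # k not < min(n, m)
        with pytest.raises(ValueError):
            pmf_fit(X, uniform_mu(X, 0.0), 2, n_runs=1, seed=0)  # zero mu

    def test_q_scan_reports_requested_counts(self):
        G, F = self.make_rank3(seed=12)
        X = pd.DataFrame(G @ F)
        scan = q_scan(X, uniform_mu(X), [1, 2, 3], n_runs=2, seed=0, max_iter=100)
        assert list(scan.index) == [1, 2, 3]
        assert scan.loc[3, "Q"] <= scan.loc[1, "Q"]


class TestPmfDiagnostics:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(0)
        G = rng.uniform(0.5, 2, (20, 2))
        F = rng.uniform(1, 5, (2, 5))
        X = pd.DataFrame(G @ F)
        model = pmf_fit(X, uniform_mu(X), 2, n_runs=5, seed=1)
        diag = model.diagnostics
        assert np.abs(model.scaled_residuals.to_numpy()).max() < 1e-3
        assert (diag["r2"] > 0.999999).all()
        assert (diag["pct_resid_in_3"] == 100.0).all()

    def test_profile_pct_columns_sum_to_100(self, three_source):
        cfg, table, _, _ = three_source
        spec = UncertaintySpec(sigma={e: 0.1 for e in table.elements}, mdl=cfg.mdl)
        mu = uncertainty_matrix(table.conc, spec)
        model = pmf_fit(table.conc, mu, 3, n_runs=3, seed=0, max_iter=300)
        np.testing.assert_allclose(
            model.profile_pct.sum(axis=0).to_numpy(), 100.0, atol=1e-9
        )

    def test_snr_limiting_behaviour(self):
        # conc >> mu -> large S/N; conc << mu -> ~0
        X = pd.DataFrame({"hi": np.full(10, 100.0), "lo": np.full(10, 0.01)})
        mu = pd.DataFrame({"hi": np.full(10, 1.0), "lo": np.full(10, 1.0)})
        model = pmf_fit(X + 0.0, mu, 1, n_runs=2, seed=0, max_iter=50)
        diag = pmf_diagnostics(model, X, mu)
        assert diag.loc["hi", "snr"] > 6.0
        assert diag.loc["lo", "snr"] < 0.1
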