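import numpy as np
import pytest

from tmrnet import (
    AssociationEdge,
    build_network,
    edges_to_frame,
    fit_joint_model,
    fit_ols,
    resolve_bidirectional,
    t_pvalue,
    tmr_scan,
)
from tmrnet.datasets import gut_taxa_damping_fit
from tmrnet.exceptions import (
    CollinearityError,
    InsufficientDataError,
    ParameterError,
)
from tmrnet.tmr_regression import scan_measured_pair


def edge(pred, resp, p, t=1.0, beta=1.0, category=2, surfaced=False):
    return AssociationEdge(
        predictor=("a", pred), response=("b", resp), beta=beta, se=abs(beta / t),
        t=t, p_value=p, category=category, covariate_surfaced=surfaced,
    )


class TestTPvalue:
    def test_center_of_distribution(self):
        assert t_pvalue(0.0, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "t,expected",
        [(2.5791, 0.0275), (-2.4371, 0.0350), (1.9021, 0.0863)],
    )
    def test_reported_wald_pairs_reproduced(self, t, expected):
        """Printed t -> p pairs of the gut-taxa model (10 residual df)."""
        assert t_pvalue(t, 10) == pytest.approx(expected, abs=5e-4)

    def test_matches_numerical_integration(self):
        # oracle: numerically integrate the t density
        from scipy.integrate import quad
        from scipy.special import gammaln

        df, t = 10, 2.5791
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
        dens = lambda x: np.exp(logc) * (1 + x**2 / df) ** (-(df + 1) / 2)
        tail, _ = quad(dens, t, np.inf)
        assert t_pvalue(t, df) == pytest.approx(2 * tail, abs=1e-9)

    def test_invalid_df_rejected(self):
        with pytest.raises(ParameterError):
            t_pvalue(1.0, 0)


class TestFitOLS:
    def test_perfect_fit(self):
        x = np.array([1.0, 2, 3, 4, 5])
        fs = fit_ols(x, x)
        assert fs.coef[1] == pytest.approx(1.0, abs=1e-12)
        assert fs.coef[0] == pytest.approx(0.0, abs=1e-12)
        assert fs.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        x = rng.normal(size=100)
        y = 2.0 * x + 0.1 * rng.normal(size=100)
        fs = fit_ols(y, x)
        assert abs(fs.coef[1] - 2.0) < 3 * fs.se[1]
        # oracle 1: closed-form normal equations
        X = np.column_stack([np.ones(100), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fs.coef, beta, atol=1e-10)
        # oracle 2: statsmodels
        import statsmodels.api as sm

        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fs.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(fs.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fs.p_values, ref.pvalues, atol=1e-10)
        assert fs.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_wald_identities_hold(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ [1.0, 0.0, -0.5] + rng.normal(size=40)
        fs = fit_ols(y, x)
        np.testing.assert_allclose(fs.t_values, fs.coef / fs.se, atol=1e-12)
        for t, p in zip(fs.t_values, fs.p_values):
            assert p == pytest.approx(t_pvalue(t, fs.df_resid), abs=1e-12)
        assert fs.df_resid == 40 - 3 - 1

    def test_reported_taxa_model_row(self):
        """A published coefficient of 0.4111 with SE 0.1594 must imply t=2.5791."""
        row = gut_taxa_damping_fit().set_index("predictor").loc["Oscillospiraceae_uncl"]
        assert row.beta / row.se == pytest.approx(row.t, abs=5e-4)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=(30, 2))
        X = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(CollinearityError):
            fit_ols(rng.normal(size=30), X)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_ols(np.ones(4), rng.normal(size=(4, 3)))


class TestScan:
    def test_planted_effect_recovered(self, small_dataset):
        edges = tmr_scan(small_dataset)
        hits = [
            e for e in edges
            if e.predictor == ("omics_a", "u") and e.response == ("omics_b", "v")
        ]
        assert len(hits) == 1
        e = hits[0]
        assert e.p_value < 0.005
        assert 2.5 <= e.beta <= 3.5
        assert e.category == 2
        assert e.sign == "positive"

    def test_category_assignment_and_counts(self, small_dataset):
        edges = tmr_scan(small_dataset, include_covariate_edges=False)
        by_cat = {c: [e for e in edges if e.category == c] for c in (1, 2, 3)}
        n_measured = 7  # 4 + 3 variables
        assert len(by_cat[1]) == 2 * n_measured          # 2 covariates
        assert len(by_cat[2]) == 2 * 4 * 3               # ordered cross-group pairs
        assert len(by_cat[3]) == n_measured * 2          # 2 response variables

    def test_self_pairing_rejected(self, small_dataset):
        with pytest.raises(ParameterError, match="distinct"):
            scan_measured_pair(small_dataset, "omics_a", "omics_a")

    def test_covariate_surfaced_edges_flagged(self, small_dataset):
        edges = tmr_scan(small_dataset, alpha_report=1.0)
        surfaced = [e for e in edges if e.covariate_surfaced]
        assert surfaced
        assert all(e.predictor[0] == "treatments" for e in surfaced)
        assert all(e.category in (2, 3) for e in surfaced)


class TestResolveBidirectional:
    def test_smaller_p_wins(self):
        e1 = edge("u", "v", 0.001)
        e2 = AssociationEdge(("b", "v"), ("a", "u"), 1.0, 0.5, 2.0, 0.004, 2)
        kept = resolve_bidirectional([e1, e2], alpha=0.005)
        assert kept == [e1]

    def test_one_directional_pair_untouched(self):
        e1 = edge("u", "v", 0.001)
        e2 = AssociationEdge(("b", "v"), ("a", "u"), 1.0, 0.5, 2.0, 0.5, 2)
        assert resolve_bidirectional([e1, e2], alpha=0.005) == [e1, e2]

    def test_equal_p_breaks_by_larger_t(self):
        e1 = edge("u", "v", 0.002, t=2.9)
        e2 = AssociationEdge(("b", "v"), ("a", "u"), 1.0, 0.3, 3.2, 0.002, 2)
        kept = resolve_bidirectional([e1, e2], alpha=0.005)
        assert kept == [e2]

    def test_never_increases_edge_count(self, small_dataset, rng):
        edges = tmr_scan(small_dataset)
        resolved = resolve_bidirectional(edges, alpha=0.05)
        assert len(resolved) <= len(edges)

    def test_empty_input(self):
        assert resolve_bidirectional([]) == []


class TestNetwork:
    def test_empty_edge_list(self):
        net = build_network([], alpha=0.005)
        assert net.edges == [] and net.nodes == []

    def test_strict_threshold(self):
        edges = [edge("u", "v", 0.004), edge("u", "w", 0.006)]
        net = build_network(edges, alpha=0.005)
        assert len(net.edges) == 1
        assert net.edges[0].response == ("b", "v")

    def test_matches_brute_force_filter(self, small_dataset):
        edges = tmr_scan(small_dataset, alpha_report=1.0)
        net = build_network(edges, alpha=0.01)
        expected = [e for e in edges if e.p_value < 0.01]
        assert net.edges == expected
        assert set(net.node_groups) == {e.predictor for e in expected} | {
            e.response for e in expected
        }

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            build_network([], alpha=1.5)

    def test_graphml_round_trip(self, small_dataset, tmp_path):
        import networkx as nx

        net = build_network(tmr_scan(small_dataset), alpha=0.005)
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(net.edges)
        signs = nx.get_edge_attributes(g, "sign")
        assert set(signs.values()) <= {"positive", "negative"}


class TestJointModel:
    def test_joint_fit_uses_all_predictors(self, small_dataset):
        fits = fit_joint_model(small_dataset.get("omics_a"), small_dataset.get("outcome"))
        assert len(fits) == 2
        for fs in fits:
            assert len(fs.predictors) == 4
            assert fs.df_resid == 60 - 4 - 1

    def test_edge_table_columns(self, small_dataset):
        frame = edges_to_frame(tmr_scan(small_dataset))
        assert list(frame.columns[:4]) == [
            "predictor_group", "predictor", "response_group", "response"
        ]
        assert frame.p.between(0, 1).all()
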