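"""Correlation matrices, significance filtering, node/network strength."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anthonet.netstat import (
    CorrelationResult,
    build_network,
    correlation_matrix,
    network_strength,
    node_strength,
    significance_threshold,
    to_graphml,
)


def random_data(seed, n_features=10, n_samples=9):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_features, n_samples)),
        index=[f"f{i:02d}" for i in range(n_features)],
    )


def handmade_result(rho, pval, alpha=0.05):
    features = [f"n{i}" for i in range(rho.shape[0])]
    sig = pval <= alpha
    np.fill_diagonal(sig, False)
    return CorrelationResult(
        features=features,
        rho=pd.DataFrame(rho, index=features, columns=features),
        pval=pd.DataFrame(pval, index=features, columns=features),
        significant=pd.DataFrame(sig, index=features, columns=features),
        n_samples=9,
        alpha=alpha,
    )


class TestCorrelationMatrix:
    def test_duplicate_rows_are_perfectly_correlated_and_significant(self):
        data = random_data(1, n_features=3)
        data.loc["f01"] = data.loc["f00"]
        cr = correlation_matrix(data)
        assert cr.rho.at["f00", "f01"] == pytest.approx(1.0)
        assert cr.pval.at["f00", "f01"] == pytest.approx(0.0, abs=1e-12)
        assert cr.significant.at["f00", "f01"]

    def test_negated_row_has_rho_minus_one(self):
        data = random_data(2, n_features=3)
        data.loc["f01"] = -data.loc["f00"]
        cr = correlation_matrix(data)
        assert cr.rho.at["f00", "f01"] == pytest.approx(-1.0)

    def test_pvalues_match_pearsonr_oracle(self):
        data = random_data(5)
        cr = correlation_matrix(data)
        for i, a in enumerate(cr.features):
            for b in cr.features[i + 1:]:
                rho, p = stats.pearsonr(data.loc[a], data.loc[b])
                assert cr.rho.at[a, b] == pytest.approx(rho, abs=1e-12)
                assert cr.pval.at[a, b] == pytest.approx(p, abs=1e-9)

    def test_matrices_are_symmetric_with_unit_diagonal(self):
        cr = correlation_matrix(random_data(6))
        assert np.allclose(cr.rho, cr.rho.T, atol=1e-12)
        assert np.allclose(np.diag(cr.rho), 1.0)
        assert (cr.significant.to_numpy() == cr.significant.to_numpy().T).all()
        assert not np.diag(cr.significant).any()

    def test_raising_alpha_never_loses_significant_pairs(self):
        data = random_data(7)
        tight = correlation_matrix(data, alpha=0.01).significant.to_numpy()
        loose = correlation_matrix(data, alpha=0.10).significant.to_numpy()
        assert (loose | ~tight).all()

    def test_constant_feature_dropped_with_warning(self):
        data = random_data(8, n_features=4)
        data.loc["f02"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            cr = correlation_matrix(data)
        assert "f02" not in cr.features

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(random_data(9, n_samples=2))


class TestNodeStrength:
    def test_all_unit_correlations_give_unit_strength(self):
        rho = np.ones((3, 3))
        pval = np.zeros((3, 3))
        ns = node_strength(handmade_result(rho, pval))
        assert (ns == 1.0).all()

    def test_absolute_value_convention_on_negative_rho(self):
        rho = np.array([[1.0, -0.8], [-0.8, 1.0]])
        pval = np.full((2, 2), 0.01)
        ns = node_strength(handmade_result(rho, pval))
        assert np.allclose(ns, 0.8)

    def test_isolated_node_gets_zero_strength(self):
        rho = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        pval = np.array([[0.0, 0.01, 0.9], [0.01, 0.0, 0.8], [0.9, 0.8, 0.0]])
        ns = node_strength(handmade_result(rho, pval))
        assert ns["n2"] == 0.0
        assert ns["n0"] == pytest.approx(0.9)

    def test_matches_per_node_loop_oracle(self):
        cr = correlation_matrix(random_data(10, n_features=12))
        ns = node_strength(cr)
        for i, feat in enumerate(cr.features):
            vals = [
                abs(cr.rho.iat[i, j])
                for j in range(len(cr.features))
                if j != i and cr.significant.iat[i, j]
            ]
            expected = float(np.mean(vals)) if vals else 0.0
            assert ns[feat] == pytest.approx(expected, abs=1e-9)

    def test_signed_flag_averages_raw_rho(self):
        rho = np.array([[1.0, -0.8], [-0.8, 1.0]])
        pval = np.full((2, 2), 0.01)
        ns = node_strength(handmade_result(rho, pval), absolute=False)
        assert np.allclose(ns, -0.8)


class TestNetworkStrength:
    def test_trivial_means(self):
        assert network_strength([1.0, 1.0, 1.0]) == 1.0
        assert network_strength([0.8, 0.4]) == pytest.approx(0.6)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            network_strength([])

    def test_invariant_under_relabeling(self):
        data = random_data(11)
        ns_a = node_strength(correlation_matrix(data))
        relabeled = data.copy()
        relabeled.index = [f"z{i}" for i in range(len(data))][::-1]
        ns_b = node_strength(correlation_matrix(relabeled))
        assert network_strength(ns_a) == pytest.approx(network_strength(ns_b), abs=1e-12)


class TestBuildNetwork:
    def test_display_threshold_filters_edges_but_not_ns(self):
        rho = np.array(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.0], [0.5, 0.0, 1.0]]
        )
        pval = np.array(
            [[0.0, 0.01, 0.02], [0.01, 0.0, 0.9], [0.02, 0.9, 0.0]]
        )
        net = build_network(handmade_result(rho, pval), display_threshold=0.65)
        assert len(net.edges) == 1  # only the 0.9 pair is drawn
        # ns still averages both significant partners of n0
        assert net.ns["n0"] == pytest.approx((0.9 + 0.5) / 2)

    def test_zero_threshold_draws_every_significant_pair(self):
        cr = correlation_matrix(random_data(12))
        net = build_network(cr, display_threshold=0.0)
        n_sig = int(cr.significant.to_numpy().sum() // 2)
        assert len(net.edges) == n_sig

    def test_edge_list_matches_brute_force_filter(self):
        cr = correlation_matrix(random_data(13, n_features=14))
        net = build_network(cr, display_threshold=0.65)
        expected = set()
        for i, a in enumerate(cr.features):
            for j, b in enumerate(cr.features):
                if i < j and cr.significant.iat[i, j] and abs(cr.rho.iat[i, j]) >= 0.65:
                    expected.add((a, b))
        assert set(zip(net.edges["source"], net.edges["target"])) == expected

    def test_ns_recomputable_from_full_edge_list(self):
        cr = correlation_matrix(random_data(14))
        net = build_network(cr, display_threshold=0.0)
        recomputed = {f: [] for f in cr.features}
        for row in net.edges.itertuples(index=False):
            recomputed[row.source].append(abs(row.rho))
            recomputed[row.target].append(abs(row.rho))
        for feat in cr.features:
            expected = float(np.mean(recomputed[feat])) if recomputed[feat] else 0.0
            assert net.ns[feat] == pytest.approx(expected, abs=1e-9)

    def test_graphml_carries_node_attributes(self):
        data = random_data(15, n_features=4)
        types = pd.Series(
            ["metabolite", "metabolite", "transcript", "transcript"], index=data.index
        )
        cr = correlation_matrix(data, feature_types=types)
        net = build_network(cr)
        g = to_graphml(cr, net)
        assert set(g.nodes) == set(cr.features)
        assert g.nodes["f00"]["feature_type"] == "metabolite"
        assert g.nodes["f00"]["ns"] == pytest.approx(float(net.ns["f00"]))


class TestSignificanceThreshold:
    def test_closed_form_boundary_at_nine_samples(self):
        rho_crit = significance_threshold(9, alpha=0.05)
        # the t statistic at the boundary must sit exactly at the critical value
        t = rho_crit * np.sqrt((9 - 2) / (1 - rho_crit**2))
        assert t == pytest.approx(stats.t.ppf(0.975, df=7), abs=1e-9)
        # p-value exactly alpha at the boundary
        p = 2 * stats.t.sf(t, df=7)
        assert p == pytest.approx(0.05, abs=1e-9)
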