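"""Partial-correlation estimation and edge selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from metabonet import (
    NODES,
    DegenerateVariableError,
    EstimationError,
    PartialCorrelationNetwork,
    SampleSizeError,
    compute_correlation_matrix,
    compute_partial_correlations,
    edge_pvalue,
    select_edges,
)
from metabonet.errors import ConfigurationError

from conftest import partial_corr_regression_oracle


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        r, n = compute_correlation_matrix(rng.standard_normal((40, 5)))
        assert n == 40
        np.testing.assert_array_equal(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_independent_columns_have_small_correlations(self):
        rng = np.random.default_rng(7)
        r, _ = compute_correlation_matrix(rng.standard_normal((10_000, 13)))
        off = r[~np.eye(13, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_column_named(self):
        x = np.random.default_rng(1).standard_normal((30, 4))
        x[:, 2] = 5.0
        with pytest.raises(DegenerateVariableError, match="V2"):
            compute_correlation_matrix(x)

    def test_sample_size_floor(self):
        x = np.random.default_rng(1).standard_normal((14, 13))
        with pytest.raises(SampleSizeError):
            compute_correlation_matrix(x)

    def test_collinear_columns_give_unit_correlation(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        x = np.column_stack([a, 2.0 * a + 1.0, rng.standard_normal(50)])
        r, _ = compute_correlation_matrix(x)
        assert r[0, 1] == pytest.approx(1.0)
        with pytest.raises(EstimationError):
            compute_partial_correlations(r)


class TestPartialCorrelations:
    def test_identity_gives_zero_partials(self):
        rp = compute_partial_correlations(np.eye(6))
        np.testing.assert_allclose(rp, np.eye(6))

    def test_three_variable_closed_form(self):
        # equicorrelated r = 0.5: Rp = (0.5 - 0.25) / (1 - 0.25) = 1/3
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        rp = compute_partial_correlations(r)
        off = rp[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 3.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_regression_residual_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 9))
        x = rng.standard_normal((60, p)) @ rng.uniform(0.5, 1.5, (p, p))
        corr, _ = compute_correlation_matrix(x)
        rp = compute_partial_correlations(corr)
        np.testing.assert_allclose(rp, partial_corr_regression_oracle(x), atol=1e-8)

    def test_ridge_rescues_near_singular_matrix(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(40)
        x = np.column_stack([a, a + 1e-9 * rng.standard_normal(40), rng.standard_normal(40)])
        corr, _ = compute_correlation_matrix(x)
        with pytest.raises(EstimationError, match="ridge"):
            compute_partial_correlations(corr)
        rp = compute_partial_correlations(corr, ridge_lambda=0.01)
        assert np.all(np.abs(rp) <= 1.0)


class TestEdgePvalue:
    def test_zero_partial_gives_p_one(self):
        assert edge_pvalue(0.0, 132, 11) == pytest.approx(1.0)

    @pytest.mark.parametrize("rp", [0.3, 0.05, -0.2])
    def test_matches_student_t_oracle(self, rp):
        df = 132 - 2 - 11
        t = rp * np.sqrt(df / (1 - rp**2))
        expected = 2 * stats.t.sf(abs(t), df)
        assert edge_pvalue(rp, 132, 11) == pytest.approx(expected, rel=1e-12)

    def test_reference_magnitudes(self):
        assert edge_pvalue(0.3, 132, 11) == pytest.approx(0.000824, abs=5e-5)
        assert edge_pvalue(0.05, 132, 11) == pytest.approx(0.587, abs=5e-3)

    def test_insufficient_degrees_of_freedom(self):
        with pytest.raises(SampleSizeError):
            edge_pvalue(0.3, 13, 11)


class TestSelectEdges:
    def _rp_with_pairs(self, pairs, value=0.4):
        rp = np.eye(13)
        for i, j in pairs:
            rp[i, j] = rp[j, i] = value
        return rp

    def test_all_zero_selects_nothing(self):
        edges = select_edges(np.eye(13), 132, NODES)
        assert len(edges) == 78
        assert edges["selected"].sum() == 0

    def test_five_strong_pairs_selected_in_both_modes(self):
        rp = self._rp_with_pairs([(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)], 0.4)
        for mode, threshold in (("pvalue", 0.25), ("magnitude", 0.25)):
            edges = select_edges(rp, 132, NODES, mode=mode, threshold=threshold)
            assert edges["selected"].sum() == 5

    def test_candidate_pair_count_is_78(self):
        assert len(select_edges(np.eye(13), 132, NODES)) == 13 * 12 // 2

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((60, 13))
        corr, n = compute_correlation_matrix(x)
        rp = compute_partial_correlations(corr)
        previous: set = set()
        for threshold in (0.01, 0.05, 0.25, 0.5, 0.9):
            sel = select_edges(rp, n, NODES, threshold=threshold)
            current = {(r.node_i, r.node_j) for r in sel.itertuples() if r.selected}
            assert previous <= current
            previous = current

    def test_invalid_mode_and_threshold(self):
        with pytest.raises(ConfigurationError):
            select_edges(np.eye(13), 132, NODES, mode="bayes")
        with pytest.raises(ConfigurationError):
            select_edges(np.eye(13), 132, NODES, threshold=1.5)


class TestEstimator:
    def test_fitted_attributes_and_sklearn_protocol(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.standard_normal((80, 4)), columns=list("abcd"))
        est = PartialCorrelationNetwork(threshold=0.1)
        assert clone(est).get_params() == est.get_params()
        est.fit(x)
        assert est.nodes_ == list("abcd")
        assert est.n_samples_ == 80
        assert est.partial_corr_.shape == (4, 4)
        assert est.graph_.n == 4
        assert est.n_selected_edges_ == int(est.edges_["selected"].sum())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((100, 6)) @ rng.uniform(0.5, 1.5, (6, 6))
        cols = [f"v{i}" for i in range(6)]
        base = PartialCorrelationNetwork().fit(pd.DataFrame(x, columns=cols))
        perm = rng.permutation(6)
        permuted = PartialCorrelationNetwork().fit(
            pd.DataFrame(x[:, perm], columns=[cols[k] for k in perm]))
        # Rp matrix permutes identically
        np.testing.assert_allclose(
            permuted.partial_corr_, base.partial_corr_[np.ix_(perm, perm)], atol=1e-12)
        # the selected edge set is the same set of node pairs
        as_pairs = lambda est: {frozenset((r.node_i, r.node_j))
                                for r in est.edges_.itertuples() if r.selected}
        assert as_pairs(base) == as_pairs(permuted)

    def test_selected_edges_carry_signed_weights(self):
        rng = np.random.default_rng(21)
        z = rng.standard_normal((200, 3))
        x = np.column_stack([z[:, 0], -0.7 * z[:, 0] + z[:, 1], z[:, 2]])
        est = PartialCorrelationNetwork().fit(x)
        sel = est.edges_[est.edges_["selected"]]
        negative = sel[(sel["node_i"] == "V0") & (sel["node_j"] == "V1")]
        assert len(negative) == 1 and negative["rp"].iloc[0] < 0
        for row in sel.itertuples():
            assert est.graph_.weight(row.node_i, row.node_j) == row.rp
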