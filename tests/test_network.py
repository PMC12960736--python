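import numpy as np
import pytest
import statsmodels.api as sm

import coendorse as ce
from coendorse.network import (
    NetworkError,
    NodewiseFit,
    lambda_max,
    make_lambda_grid,
    max_edges,
    penalized_logistic_path,
)
from coendorse.weighting import SurveyDesign


def toy_problem(seed=0, n=250, k=3, rare=False):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, k)) < 0.35).astype(float)
    eta = (-2.5 if rare else -0.5) + X @ np.linspace(1.2, -0.6, k)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    w = rng.uniform(0.5, 2.0, n)
    return y, X, w


def reference_proximal_path(y, X, w, lambda_grid, n_iter=30000):
    """Slow FISTA reference on the identical objective and standardization."""
    n, k = X.shape
    wn = w / w.sum()
    m = wn @ X
    s = np.sqrt(wn @ (X - m) ** 2)
    Z = np.column_stack([np.ones(n), (X - m) / s])
    # Lipschitz bound for the weighted-mean logistic loss
    H = 0.25 * (Z * wn[:, None]).T @ Z
    L = np.linalg.eigvalsh(H).max()
    out = []
    theta = np.zeros(k + 1)
    for lam in lambda_grid:
        x_cur = theta.copy()
        z_acc = theta.copy()
        t_acc = 1.0
        for _ in range(n_iter):
            eta = Z @ z_acc
            mu = 1 / (1 + np.exp(-eta))
            grad = (Z * wn[:, None]).T @ (mu - y)
            step = z_acc - grad / L
            new = step.copy()
            new[1:] = np.sign(step[1:]) * np.maximum(np.abs(step[1:]) - lam / L, 0.0)
            t_new = (1 + np.sqrt(1 + 4 * t_acc**2)) / 2
            z_acc = new + (t_acc - 1) / t_new * (new - x_cur)
            if np.abs(new - x_cur).max() < 1e-12:
                x_cur = new
                break
            x_cur = new
            t_acc = t_new
        theta = x_cur
        b = theta[1:] / s
        b0 = theta[0] - b @ m
        out.append(np.r_[b0, b])
    return np.array(out)


class TestPenalizedPath:
    def test_full_shrinkage_above_lambda_max(self):
        y, X, w = toy_problem()
        lam_max = lambda_max(y, X, w)
        grid = make_lambda_grid(lam_max, n_lambda=10)
        _, b0s, bs = penalized_logistic_path(y, X, w, grid)
        assert (bs[0] == 0.0).all()
        ybar = (w * y).sum() / w.sum()
        assert b0s[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)

    def test_small_lambda_matches_unpenalized_mle(self):
        from coendorse.glm import fit_weighted_logit

        y, X, w = toy_problem(seed=1)
        lam_max = lambda_max(y, X, w)
        grid = make_lambda_grid(lam_max, n_lambda=60, min_ratio=1e-8)
        _, b0s, bs = penalized_logistic_path(y, X, w, grid)
        mle = fit_weighted_logit(X, y, w)
        np.testing.assert_allclose(np.r_[b0s[-1], bs[-1]], mle.coef, atol=1e-4)

    def test_single_predictor_kkt_breakpoint(self):
        """Coefficient enters exactly where the weighted score hits lambda."""
        rng = np.random.default_rng(3)
        n = 400
        x = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < np.where(x == 1, 0.45, 0.25)).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        wn = w / w.sum()
        ybar = wn @ y
        m = wn @ x
        s = np.sqrt(wn @ (x - m) ** 2)
        kkt = abs(wn @ (((x - m) / s) * (y - ybar)))  # long-hand score bound
        assert lambda_max(y, x[:, None], w) == pytest.approx(kkt, abs=1e-12)
        grid = np.geomspace(kkt * 1.05, kkt * 0.5, 40)
        _, _, bs = penalized_logistic_path(y, x[:, None], w, grid)
        entered = np.flatnonzero(bs[:, 0] != 0.0)
        assert entered.size > 0
        first = entered[0]
        assert grid[first] <= kkt
        assert first == 0 or grid[first - 1] >= kkt

    def test_path_matches_slow_reference_optimizer(self):
        y, X, w = toy_problem(seed=2)
        lam_max = lambda_max(y, X, w)
        grid = np.geomspace(lam_max * 0.8, lam_max * 1e-3, 7)
        _, b0s, bs = penalized_logistic_path(y, X, w, grid)
        ref = reference_proximal_path(y, X, w, grid)
        ours = np.column_stack([b0s, bs])
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_unstandardized_mode(self):
        y, X, w = toy_problem(seed=4)
        grid = make_lambda_grid(lambda_max(y, X, w), n_lambda=20)
        _, _, b_std = penalized_logistic_path(y, X, w, grid, standardize=True)
        _, _, b_raw = penalized_logistic_path(y, X, w, grid, standardize=False)
        assert not np.allclose(b_std, b_raw)  # selection genuinely differs

    def test_increasing_grid_rejected(self):
        y, X, w = toy_problem()
        with pytest.raises(NetworkError, match="decreasing"):
            penalized_logistic_path(y, X, w, np.array([0.1, 0.2]))

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(NetworkError, match="binary"):
            penalized_logistic_path(np.array([0.0, 0.5]), np.zeros((2, 1)))


class TestCVOneSE:
    def test_lambda_1se_geq_lambda_min(self):
        for seed in range(4):
            y, X, w = toy_problem(seed=seed)
            cv = ce.cv_one_se(y, X, w, K=5, seed=seed)
            assert cv.lambda_1se >= cv.lambda_min

    def test_pure_noise_selects_sparse_model(self):
        rng = np.random.default_rng(7)
        n = 500
        X = (rng.random((n, 5)) < 0.3).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        cv = ce.cv_one_se(y, X, K=5, seed=1)
        grid = cv.lambda_grid
        _, _, bs = penalized_logistic_path(y, X, lambda_grid=grid)
        support = (bs[cv.index_1se] != 0).sum()
        assert support <= 2  # empty or near-empty
        assert cv.index_1se <= len(grid) // 4  # near the top of the grid

    def test_planted_predictor_selected(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 3000
            X = (rng.random((n, 5)) < 0.3).astype(float)
            eta = -2.0 + 1.5 * X[:, 0]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            cv = ce.cv_one_se(y, X, K=10, seed=seed)
            _, _, bs = penalized_logistic_path(y, X, lambda_grid=cv.lambda_grid)
            if bs[cv.index_1se, 0] != 0:
                hits += 1
        assert hits >= 2

    def test_deterministic_given_seed(self):
        y, X, w = toy_problem(seed=5)
        a = ce.cv_one_se(y, X, w, K=5, seed=11)
        b = ce.cv_one_se(y, X, w, K=5, seed=11)
        assert a.lambda_1se == b.lambda_1se
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)

    def test_impossible_stratification_errors(self):
        y = np.zeros(20)
        y[0] = 1  # single positive: every training split risk single-class
        X = np.ones((20, 2))
        with pytest.raises(NetworkError, match="folds"):
            ce.cv_one_se(y, X, K=10, seed=0)

    def test_unsupported_loss_rejected(self):
        y, X, w = toy_problem()
        with pytest.raises(NetworkError, match="loss"):
            ce.cv_one_se(y, X, w, K=5, loss="auc")

    def test_auc_in_unit_range(self):
        y, X, w = toy_problem(seed=6)
        cv = ce.cv_one_se(y, X, w, K=5, seed=2)
        assert 0.0 <= cv.cv_auc <= 1.0
        assert cv.cv_deviance >= 0.0


def _dummy_fit(node, predictors, support):
    L = 3
    return NodewiseFit(
        node=node,
        lambda_path=np.geomspace(1, 0.01, L),
        coef_path=np.zeros((L, len(predictors))),
        predictors=tuple(predictors),
        lambda_min=0.01,
        lambda_1se=0.1,
        cv_mean=np.zeros(L),
        cv_se=np.zeros(L),
        support=tuple(support),
        coef_1se=np.zeros(len(predictors)),
        cv_auc=0.5,
        cv_deviance=1.0,
    )


class TestSelectEdges:
    labels = ("a", "b", "c")

    def test_empty_supports_empty_graph(self):
        fits = [_dummy_fit(l, [m for m in self.labels if m != l], []) for l in self.labels]
        adj = ce.select_edges(fits, self.labels)
        assert not adj.any()

    def test_one_sided_link_discarded(self):
        fits = [
            _dummy_fit("a", ("b", "c"), ("b",)),
            _dummy_fit("b", ("a", "c"), ()),
            _dummy_fit("c", ("a", "b"), ()),
        ]
        adj = ce.select_edges(fits, self.labels)
        assert not adj.any()

    def test_mutual_selection_retained_and_subset_of_or_rule(self):
        fits = [
            _dummy_fit("a", ("b", "c"), ("b",)),
            _dummy_fit("b", ("a", "c"), ("a", "c")),
            _dummy_fit("c", ("a", "b"), ("b",)),
        ]
        adj = ce.select_edges(fits, self.labels)
        assert adj[0, 1] and adj[1, 0]
        assert adj[1, 2] and adj[2, 1]
        assert not adj[0, 2]
        # AND-rule graph is a subset of the OR-rule graph
        supports = {f.node: set(f.support) for f in fits}
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                if adj[i, j]:
                    assert lj in supports[li] or li in supports[lj]

    def test_wrong_fit_count_rejected(self):
        with pytest.raises(NetworkError, match="one fit per node"):
            ce.select_edges([], self.labels)


class TestRefitEdges:
    def test_symmetrized_or_is_arithmetic_mean(self, rng):
        n = 600
        values = (rng.random((n, 3)) < 0.3).astype(int)
        rm = ce.ResponseMatrix(values, ("a", "b", "c"))
        design = SurveyDesign.equal(n)
        adj = np.ones((3, 3), dtype=bool) ^ np.eye(3, dtype=bool)
        edge_or, directional = ce.refit_edges(rm, adj, design)
        # independent per-node fits via statsmodels
        for (i, j), (or_sym, lo, hi) in edge_or.items():
            or_ij, or_ji = directional[(i, j)]
            assert or_sym == pytest.approx((or_ij + or_ji) / 2, rel=1e-12)
            Xi = np.delete(values, i, axis=1).astype(float)
            ref = sm.GLM(
                values[:, i].astype(float), sm.add_constant(Xi),
                family=sm.families.Binomial(),
            ).fit()
            pos = [k for k in range(3) if k != i].index(j) + 1
            assert or_ij == pytest.approx(np.exp(ref.params[pos]), rel=1e-6)

    def test_p2_conditional_or_converges_to_omega(self):
        truth = ce.TrueIsingModel(
            tau=np.zeros(2),
            omega=np.log(2.0) * np.array([[0.0, 1.0], [1.0, 0.0]]),
            labels=("a", "b"),
        )
        rm = ce.simulate_ising(truth, 50000, method="exact", seed=10)
        adj = np.array([[False, True], [True, False]])
        edge_or, _ = ce.refit_edges(rm, adj, SurveyDesign.equal(rm.n))
        assert edge_or[(0, 1)][0] == pytest.approx(2.0, rel=0.08)

    def test_enumerated_pseudo_data_recovers_omega_exactly(self, default_truth):
        """Weighted pseudo-data over all states: refit log-ORs equal omega to 1e-6."""
        truth = ce.TrueIsingModel(
            tau=default_truth.tau[:4],
            omega=default_truth.omega[:4, :4],
            labels=default_truth.labels[:4],
        )
        states, probs = ce.exact_distribution(truth)
        rm = ce.ResponseMatrix(states, truth.labels)
        design = SurveyDesign(weights=probs, normalization="none")
        adj = np.ones((4, 4), dtype=bool) ^ np.eye(4, dtype=bool)
        edge_or, directional = ce.refit_edges(rm, adj, design)
        for (i, j), (or_ij, or_ji) in directional.items():
            assert np.log(or_ij) == pytest.approx(truth.omega[i, j], abs=1e-6)
            assert np.log(or_ji) == pytest.approx(truth.omega[i, j], abs=1e-6)

    def test_asymmetric_adjacency_rejected(self, rng):
        values = (rng.random((50, 3)) < 0.5).astype(int)
        rm = ce.ResponseMatrix(values, ("a", "b", "c"))
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = True
        with pytest.raises(NetworkError, match="symmetric"):
            ce.refit_edges(rm, adj, SurveyDesign.equal(50))


@pytest.fixture(scope="module")
def small_truth():
    full = ce.default_truth()
    return ce.TrueIsingModel(
        tau=full.tau[:5] + 1.0,  # commoner items so n can stay small
        omega=full.omega[:5, :5],
        labels=full.labels[:5],
    )


@pytest.fixture(scope="module")
def small_net(small_truth):
    rm = ce.simulate_ising(small_truth, 1500, method="exact", seed=21)
    net = ce.estimate_network(rm, K=5, seed=21, n_lambda=40)
    return rm, net


class TestEstimateNetwork:
    def test_determinism(self, small_truth, small_net):
        rm, net = small_net
        net2 = ce.estimate_network(rm, K=5, seed=21, n_lambda=40)
        np.testing.assert_array_equal(net.adjacency, net2.adjacency)
        assert net.edge_or == net2.edge_or
        for f1, f2 in zip(net.node_fits, net2.node_fits):
            assert f1.lambda_1se == f2.lambda_1se

    def test_adjacency_invariants(self, small_net):
        _, net = small_net
        adj = net.adjacency
        np.testing.assert_array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        assert net.edge_count <= max_edges(len(net.labels))
        for (i, j) in net.edge_or:
            assert adj[i, j]

    def test_monotone_sparsity_in_penalty_scale(self, small_net):
        rm, base = small_net
        counts = [base.edge_count]
        for scale in (2.0, 4.0):
            net = ce.estimate_network(
                rm, K=5, seed=21, n_lambda=40, penalty_scale=scale
            )
            counts.append(net.edge_count)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_max_edges(self):
        assert max_edges(10) == 45
        assert max_edges(2) == 1

    def test_tables_and_graph_export(self, small_net):
        _, net = small_net
        edges = net.edge_table()
        nodes = net.node_table()
        assert len(nodes) == 5
        graph = net.to_graph_json()
        assert set(graph) == {"nodes", "edges"}
        assert len(graph["edges"]) == net.edge_count
        if net.edge_count:
            assert {"or_sym", "ci_low", "ci_high"} <= set(edges.columns)
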