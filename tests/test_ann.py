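"""MLP construction, forward pass, Jacobian, LM training, topology search."""

import numpy as np
import pytest

from rwdry.ann import (
    ANNResults,
    AnnTopology,
    MLPRegressor,
    TrainConfig,
    compare_models,
    topology_search,
    train_lm,
)
from rwdry.kinetics import MoistureSeries, fit_thin_layer_model


def _linear_dataset(n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    temps = np.repeat([50.0, 60.0, 70.0, 80.0], n_per)
    times = rng.uniform(0, 150, temps.size)
    X = np.column_stack([temps, times])
    y = 0.3 * (temps / 100) + 0.5 * (times / 150)
    return X, y


class TestTopology:
    def test_parameter_count_2_15_14_1(self):
        topo = AnnTopology((2, 15, 14, 1), ("tansig", "logsig", "purelin"))
        assert topo.n_params == (2 * 15 + 15) + (15 * 14 + 14) + (14 * 1 + 1) == 284

    @pytest.mark.parametrize("sizes,acts", [
        ((3, 5, 1), ("tansig", "purelin")),          # wrong input width
        ((2, 5, 2), ("tansig", "purelin")),          # wrong output width
        ((2, 1, 1), ("tansig", "purelin")),          # hidden too small
        ((2, 16, 1), ("tansig", "purelin")),         # hidden too large
        ((2, 5, 1), ("tansig",)),                    # activation count
        ((2, 5, 1), ("tansig", "relu")),             # unknown activation
    ])
    def test_invalid_topologies_rejected(self, sizes, acts):
        with pytest.raises(ValueError):
            AnnTopology(sizes, acts)


class TestNetwork:
    def test_zeroed_parameters_give_zero_output(self):
        net = MLPRegressor(AnnTopology((2, 4, 1), ("tansig", "purelin")), seed=0)
        net.theta = np.zeros_like(net.theta)
        assert np.all(net.forward([[50.0, 10.0], [90.0, 0.0]]) == 0.0)

    def test_same_seed_bitwise_identical(self):
        a = MLPRegressor(AnnTopology((2, 15, 14, 1), ("tansig", "logsig", "purelin")), seed=7)
        b = MLPRegressor(AnnTopology((2, 15, 14, 1), ("tansig", "logsig", "purelin")), seed=7)
        assert np.array_equal(a.theta, b.theta)

    def test_single_purelin_layer_is_affine(self):
        # without hidden layers isn't allowed, so check through zero hidden weights:
        # activations at zero pre-activation anchor tansig(0)=0, logsig(0)=0.5
        assert np.tanh(0.0) == 0.0
        net = MLPRegressor(AnnTopology((2, 2, 1), ("logsig", "purelin")), seed=0)
        net.theta = np.zeros_like(net.theta)
        # logsig(0) = 0.5 on both hidden units; output = W2 . [0.5, 0.5] + b2 = 0
        assert net.forward([[10.0, 20.0]])[0] == 0.0

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        for acts in [("tansig", "purelin"), ("tansig", "logsig", "purelin")]:
            sizes = (2, 4, 1) if len(acts) == 2 else (2, 4, 3, 1)
            net = MLPRegressor(AnnTopology(sizes, acts), seed=2)
            X = rng.uniform(-1, 1, (6, 2))
            J = net.jacobian(X)
            eps = 1e-6
            for j in range(net.theta.size):
                tp, tm = net.theta.copy(), net.theta.copy()
                tp[j] += eps
                tm[j] -= eps
                col = (net.forward(X, tp) - net.forward(X, tm)) / (2 * eps)
                assert np.max(np.abs(J[:, j] - col)) < 1e-6

    def test_json_roundtrip(self):
        net = MLPRegressor(AnnTopology((2, 5, 1), ("tansig", "purelin")), seed=1)
        net.x_min, net.x_max = np.array([50.0, 0.0]), np.array([90.0, 150.0])
        back = MLPRegressor.from_json(net.to_json())
        X = [[70.0, 30.0], [50.0, 0.0]]
        np.testing.assert_array_equal(net.forward(X), back.forward(X))


class TestTrainLM:
    def test_linear_target_fit_to_machine_precision(self):
        X, y = _linear_dataset()
        net = MLPRegressor(AnnTopology((2, 3, 1), ("purelin", "purelin")), seed=1)
        res = train_lm(net, X, y, TrainConfig(seed=1))
        assert res.train_mse < 1e-10

    def test_identical_points_zero_residual_quickly(self):
        X = np.tile([[70.0, 30.0]], (12, 1))
        y = np.full(12, 0.4)
        net = MLPRegressor(AnnTopology((2, 2, 1), ("tansig", "purelin")), seed=0)
        res = train_lm(net, X, y, TrainConfig(seed=0))
        assert res.epoch <= 2
        assert res.train_mse < 1e-15

    def test_accepted_steps_never_increase_training_mse(self, page_surface):
        X, y = page_surface
        net = MLPRegressor(AnnTopology((2, 8, 1), ("tansig", "purelin")), seed=3)
        res = train_lm(net, X, y, TrainConfig(seed=3))
        acc = res.history[res.history["accepted"]]["train_mse"].to_numpy()
        assert np.all(np.diff(acc) <= 1e-18)

    def test_purelin_network_reaches_ols_solution(self):
        rng = np.random.default_rng(9)
        X, y = _linear_dataset(seed=9)
        y = y + rng.normal(0, 0.05, y.size)  # noisy linear data
        cfg = TrainConfig(seed=4)
        net = MLPRegressor(AnnTopology((2, 3, 1), ("purelin", "purelin")), seed=4)
        res = train_lm(net, X, y, cfg)
        # OLS on the same training partition and the same scaled inputs
        from rwdry.ann import _stratified_split

        itr, _, _ = _stratified_split(X, cfg)
        Xs = net._scale(X[itr])
        A = np.column_stack([np.ones(itr.size), Xs])
        beta, *_ = np.linalg.lstsq(A, y[itr], rcond=None)
        ols_mse = float(np.mean((A @ beta - y[itr]) ** 2))
        net.theta = res.network.theta  # final weights
        lm_mse = float(np.mean((net.forward(X[itr]) - y[itr]) ** 2))
        assert abs(lm_mse - ols_mse) < 1e-8

    def test_determinism_fixed_seed_and_data(self, page_surface):
        X, y = page_surface
        out = []
        for _ in range(2):
            net = MLPRegressor(AnnTopology((2, 6, 1), ("tansig", "purelin")), seed=5)
            out.append(train_lm(net, X, y, TrainConfig(seed=5)))
        assert np.array_equal(out[0].network.theta, out[1].network.theta)
        assert out[0].mse == out[1].mse and out[0].epoch == out[1].epoch

    def test_noiseless_page_surface_high_r2(self, page_surface):
        X, y = page_surface
        topo = AnnTopology((2, 15, 14, 1), ("tansig", "logsig", "purelin"))
        res = train_lm(MLPRegressor(topo, seed=0), X, y, TrainConfig(seed=0))
        assert res.r2 >= 0.999
        assert res.epoch <= 1200

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            train_lm(MLPRegressor(AnnTopology((2, 2, 1), ("tansig", "purelin"))),
                     np.zeros((5, 2)), np.zeros(5))


class TestTopologySearch:
    def test_single_candidate_grid(self, page_surface):
        X, y = page_surface
        topo = AnnTopology((2, 4, 1), ("tansig", "purelin"))
        results = topology_search(X, y, [topo], TrainConfig(seed=0))
        assert len(results) == 1 and results[0].topology == topo

    def test_purelin_candidates_win_on_linear_data(self):
        X, y = _linear_dataset()
        cands = [AnnTopology((2, 3, 1), ("purelin", "purelin")),
                 AnnTopology((2, 3, 1), ("tansig", "purelin"))]
        results = topology_search(X, y, cands, TrainConfig(seed=0))
        best_lin = min(r.mse for r in results if set(r.topology.activations) == {"purelin"})
        assert best_lin <= min(r.mse for r in results) + 1e-8

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            topology_search(np.zeros((12, 2)), np.zeros(12), [])


class TestCompareModels:
    def _setup(self, page_surface):
        X, y = page_surface
        sel = X[:, 0] == 70.0
        Xc, yc = X[sel], y[sel]
        fit = fit_thin_layer_model(MoistureSeries(Xc[:, 1], yc, 70.0), "page")
        topo = AnnTopology((2, 8, 1), ("tansig", "purelin"))
        ann = train_lm(MLPRegressor(topo, seed=0), X, y, TrainConfig(seed=0))
        return ann, fit, Xc, yc

    def test_winner_has_lower_mse(self, page_surface):
        ann, fit, Xc, yc = self._setup(page_surface)
        out = compare_models(ann, fit, Xc, yc)
        if out["winner"] == "ann":
            assert out["ann"]["mse"] <= out["page"]["mse"]
        elif out["winner"] == "page":
            assert out["page"]["mse"] <= out["ann"]["mse"]

    def test_mismatched_sets_rejected(self, page_surface):
        ann, fit, Xc, yc = self._setup(page_surface)
        with pytest.raises(ValueError):
            compare_models(ann, fit, Xc, yc[:-1])

    def test_exact_tie_flagged(self, page_surface):
        ann, fit, Xc, yc = self._setup(page_surface)
        out = compare_models(ann, fit, Xc, fit.predict(Xc[:, 1]))
        # kinetic model has zero error against its own predictions
        assert out[fit.model_name]["mse"] == pytest.approx(0.0, abs=1e-30)
        assert out["winner"] == fit.model_name
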