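"""Feedforward MLP for moisture-ratio prediction, trained from scratch by
Levenberg-Marquardt.

The network maps (water temperature, drying time) -> MR through one or two
hidden layers with activations drawn from {tansig, logsig, purelin}
(hyperbolic tangent, logistic, identity).  Training is damped Gauss-Newton
on the residual vector: solve (J^T J + lambda I) d = -J^T r, accept the
step if the training MSE drops (then lambda /= lambda_down), otherwise
reject and lambda *= lambda_up.  Validation-based early stopping returns
the best-validation weights.  The Jacobian is analytic (per-sample
backpropagation), checked against finite differences in the test suite.

Inputs are affinely scaled to [-1, 1] per feature; the scaling is stored
with the model so predictions accept raw units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnTopology",
    "TrainConfig",
    "MLPRegressor",
    "ANNResults",
    "train_lm",
    "topology_search",
    "compare_models",
    "default_candidates",
]

_ACT = {
    "tansig": (np.tanh, lambda a: 1.0 - a * a),          # derivative in terms of output
    "logsig": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "purelin": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass(frozen=True)
class AnnTopology:
    """Layer sizes (input 2, one or two hidden layers of 2-15 units,
    output 1) and per-layer activation names."""

    layer_sizes: tuple[int, ...]
    activations: tuple[str, ...]

    def __post_init__(self) -> None:
        sizes = tuple(self.layer_sizes)
        acts = tuple(self.activations)
        object.__setattr__(self, "layer_sizes", sizes)
        object.__setattr__(self, "activations", acts)
        if sizes[0] != 2 or sizes[-1] != 1:
            raise ValueError("topology must map 2 inputs to 1 output")
        hidden = sizes[1:-1]
        if not 1 <= len(hidden) <= 2:
            raise ValueError("one or two hidden layers supported")
        if any(not 2 <= h <= 15 for h in hidden):
            raise ValueError("hidden layer sizes must lie in [2, 15]")
        if len(acts) != len(sizes) - 1:
            raise ValueError("need one activation per non-input layer")
        for a in acts:
            if a not in _ACT:
                raise ValueError(f"unknown activation {a!r}; choose from {sorted(_ACT)}")

    @property
    def n_params(self) -> int:
        return sum((i + 1) * o for i, o in zip(self.layer_sizes, self.layer_sizes[1:]))

    def __str__(self) -> str:
        return "-".join(str(s) for s in self.layer_sizes)


@dataclass(frozen=True)
class TrainConfig:
    """LM training protocol: 70/15/15 seeded split (stratified by
    temperature), 1200-epoch cap, conventional lambda schedule, and
    validation patience."""

    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 1200
    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 10.0
    lambda_max: float = 1e10
    patience: int = 6
    grad_tol: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f <= 0 for f in self.split):
            raise ValueError("split fractions must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lambda_up <= 1 or self.lambda_down <= 1:
            raise ValueError("damping adjustment factors must exceed 1")


class MLPRegressor:
    """Small dense feedforward network with explicit flat parameter vector.

    Weight layout: for each layer, the (out x in) weight matrix row-major,
    then the bias vector.  Seeded uniform(-0.5, 0.5) initialisation.
    """

    def __init__(self, topology: AnnTopology, seed: int = 0):
        self.topology = topology
        rng = np.random.default_rng(seed)
        self.theta = rng.uniform(-0.5, 0.5, size=topology.n_params)
        # input scaling to [-1, 1]; identity until fit_scaling is called
        self.x_min = np.array([-1.0, -1.0])
        self.x_max = np.array([1.0, 1.0])

    # -- parameter (un)packing -------------------------------------------
    def _layers(self, theta: np.ndarray):
        sizes = self.topology.layer_sizes
        pos = 0
        for n_in, n_out in zip(sizes, sizes[1:]):
            W = theta[pos:pos + n_in * n_out].reshape(n_out, n_in)
            pos += n_in * n_out
            b = theta[pos:pos + n_out]
            pos += n_out
            yield W, b

    def fit_scaling(self, X: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        self.x_min = X.min(axis=0)
        self.x_max = X.max(axis=0)
        if np.any(self.x_max - self.x_min <= 0):
            # degenerate feature: leave it centred
            span = self.x_max - self.x_min
            self.x_max = np.where(span <= 0, self.x_min + 1.0, self.x_max)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    # -- forward / jacobian ----------------------------------------------
    def _forward_cached(self, X_raw: np.ndarray, theta: np.ndarray):
        a = self._scale(np.asarray(X_raw, dtype=float))
        acts = [a]
        for (W, b), name in zip(self._layers(theta), self.topology.activations):
            z = a @ W.T + b
            a = _ACT[name][0](z)
            acts.append(a)
        return acts

    def forward(self, X_raw, theta: np.ndarray | None = None) -> np.ndarray:
        """Predicted MR for raw (temperature, time) rows."""
        th = self.theta if theta is None else theta
        return self._forward_cached(np.atleast_2d(X_raw), th)[-1][:, 0]

    predict = forward

    def jacobian(self, X_raw, theta: np.ndarray | None = None) -> np.ndarray:
        """d y_i / d theta_j, shape (N, n_params); analytic backprop."""
        th = self.theta if theta is None else theta
        acts = self._forward_cached(np.atleast_2d(X_raw), th)
        layers = list(self._layers(th))
        names = self.topology.activations
        N = acts[0].shape[0]
        # delta_l = d y / d z_l, seeded at the output layer
        delta = _ACT[names[-1]][1](acts[-1])            # (N, 1)
        grads: list[np.ndarray] = [None] * len(layers)
        for li in range(len(layers) - 1, -1, -1):
            W, _ = layers[li]
            a_prev = acts[li]
            gW = np.einsum("no,ni->noi", delta, a_prev)  # (N, out, in)
            grads[li] = np.concatenate([gW.reshape(N, -1), delta], axis=1)
            if li > 0:
                delta = (delta @ W) * _ACT[names[li - 1]][1](acts[li])
        return np.concatenate(grads, axis=1)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "layer_sizes": list(self.topology.layer_sizes),
            "activations": list(self.topology.activations),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "theta": self.theta.tolist(),
        })

    @classmethod
    def from_json(cls, doc: str) -> "MLPRegressor":
        d = json.loads(doc)
        net = cls(AnnTopology(tuple(d["layer_sizes"]), tuple(d["activations"])))
        net.x_min = np.array(d["x_min"], dtype=float)
        net.x_max = np.array(d["x_max"], dtype=float)
        net.theta = np.array(d["theta"], dtype=float)
        return net


@dataclass
class ANNResults:
    """Trained network with split metrics and the accepted-step history."""

    network: MLPRegressor
    mse: float                      # test-set MSE
    r2: float                       # test-set R^2
    epoch: int
    history: pd.DataFrame           # columns: epoch, train_mse, val_mse, accepted
    train_mse: float
    val_mse: float
    converged: bool = True
    seed: int = 0

    @property
    def topology(self) -> AnnTopology:
        return self.network.topology

    def predict(self, X_raw) -> np.ndarray:
        return self.network.forward(X_raw)

    def summary(self) -> str:
        return (
            f"MLP {self.topology} [{'-'.join(self.topology.activations)}], "
            f"{self.topology.n_params} parameters\n"
            f"  epochs used = {self.epoch}\n"
            f"  train MSE = {self.train_mse:.4g}, val MSE = {self.val_mse:.4g}\n"
            f"  test  MSE = {self.mse:.4g}, test R^2 = {self.r2:.6f}"
        )


def _stratified_split(X: np.ndarray, config: TrainConfig):
    """70/15/15 index split, stratified on the temperature column so each
    partition covers every temperature level."""
    rng = np.random.default_rng(config.seed)
    tr, va, te = [], [], []
    for temp in np.unique(X[:, 0]):
        idx = np.flatnonzero(X[:, 0] == temp)
        rng.shuffle(idx)
        n = idx.size
        n_tr = max(1, int(round(config.split[0] * n)))
        n_va = max(1, int(round(config.split[1] * n)))
        n_tr = min(n_tr, n - 2)  # leave room for val and test
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr:n_tr + n_va])
        te.extend(idx[n_tr + n_va:])
    if not va or not te:
        raise ValueError("split produced an empty partition; need more data per temperature")
    return np.array(tr), np.array(va), np.array(te)


def _mse(net: MLPRegressor, theta, X, y) -> float:
    r = net.forward(X, theta) - y
    return float(np.mean(r * r))


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((pred - obs) ** 2))
    return math.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot


def train_lm(network: MLPRegressor, X, y, config: TrainConfig = TrainConfig()) -> ANNResults:
    """Levenberg-Marquardt training with validation early stopping.

    ``X`` holds raw (temperature, time) rows, ``y`` the observed MR.
    Returns the best-validation weights; training MSE over accepted steps
    is non-increasing by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if y.size < 10:
        raise ValueError("need at least 10 data points")
    itr, iva, ite = _stratified_split(X, config)
    network.fit_scaling(X[itr])

    theta = network.theta.copy()
    lam = config.lambda_init
    train_sse = float(np.sum((network.forward(X[itr], theta) - y[itr]) ** 2))
    best_val = _mse(network, theta, X[iva], y[iva])
    best_theta = theta.copy()
    stall = 0
    rows = []
    converged = True
    n_tr = itr.size

    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        r = network.forward(X[itr], theta) - y[itr]
        J = network.jacobian(X[itr], theta)
        g = J.T @ r
        if np.max(np.abs(g)) < config.grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while lam <= config.lambda_max:
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            cand = theta + step
            cand_sse = float(np.sum((network.forward(X[itr], cand) - y[itr]) ** 2))
            if cand_sse < train_sse:
                theta = cand
                train_sse = cand_sse
                lam = max(lam / config.lambda_down, 1e-15)
                accepted = True
                break
            lam *= config.lambda_up
        val = _mse(network, theta, X[iva], y[iva])
        rows.append({"epoch": epoch, "train_mse": train_sse / n_tr,
                     "val_mse": val, "accepted": accepted})
        if not accepted:
            # damping exhausted without a usable step
            converged = train_sse / n_tr < 1e-16
            break
        if val < best_val - 1e-18:
            best_val = val
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        if train_sse / n_tr < 1e-16:
            # at machine precision for unit-scale targets
            break

    network.theta = best_theta
    pred_te = network.forward(X[ite])
    return ANNResults(
        network=network,
        mse=float(np.mean((pred_te - y[ite]) ** 2)),
        r2=_r2(pred_te, y[ite]),
        epoch=epoch,
        history=pd.DataFrame(rows),
        train_mse=train_sse / n_tr,
        val_mse=best_val,
        converged=converged,
        seed=config.seed,
    )


def default_candidates() -> list[AnnTopology]:
    """Topology grid: single hidden layer 2-15 (tansig-purelin) plus the
    two-hidden-layer tansig-logsig-purelin family."""
    cands = [AnnTopology((2, h, 1), ("tansig", "purelin")) for h in range(2, 16)]
    cands += [AnnTopology((2, h, max(2, h - 1), 1), ("tansig", "logsig", "purelin"))
              for h in (5, 10, 15)]
    return cands


def topology_search(X, y, candidates: list[AnnTopology] | None = None,
                    config: TrainConfig = TrainConfig()) -> list[ANNResults]:
    """Train every candidate topology (fixed per-candidate seed schedule)
    and return results ranked by ascending test MSE."""
    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("empty topology grid")
    results = []
    for i, topo in enumerate(candidates):
        net = MLPRegressor(topo, seed=config.seed + 1000 * i)
        try:
            results.append(train_lm(net, X, y, config))
        except Exception as exc:  # record the failure, keep searching
            results.append(ANNResults(
                network=net, mse=math.inf, r2=-math.inf, epoch=0,
                history=pd.DataFrame(), train_mse=math.inf, val_mse=math.inf,
                converged=False, seed=config.seed + 1000 * i,
            ))
            results[-1].error = str(exc)
    return sorted(results, key=lambda r: (math.isnan(r.mse), r.mse))


def search_report(results: list[ANNResults]) -> pd.DataFrame:
    """Tabular report of a topology search (topology, activations, MSE,
    R^2, epochs)."""
    return pd.DataFrame([
        {"topology": str(r.topology), "activations": "-".join(r.topology.activations),
         "mse": r.mse, "r2": r.r2, "epoch": r.epoch} for r in results
    ])


def compare_models(ann_result: ANNResults, kinetic_fit, X, y) -> dict:
    """Side-by-side ANN vs thin-layer-model metrics on one evaluation set.

    ``X`` rows are (temperature, time); the kinetic fit is evaluated on the
    time column.  Winner is the lower MSE; exact ties are flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("mismatched evaluation sets")
    pred_ann = ann_result.predict(X)
    pred_kin = kinetic_fit.predict(X[:, 1])
    mse_ann = float(np.mean((pred_ann - y) ** 2))
    mse_kin = float(np.mean((pred_kin - y) ** 2))
    if mse_ann == mse_kin:
        winner = "tie"
    else:
        winner = "ann" if mse_ann < mse_kin else kinetic_fit.model_name
    return {
        "ann": {"mse": mse_ann, "r2": _r2(pred_ann, y)},
        kinetic_fit.model_name: {"mse": mse_kin, "r2": _r2(pred_kin, y)},
        "winner": winner,
    }
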