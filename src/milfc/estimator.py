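"""Weakly-supervised fold-change estimator for one chromosome arm.

The model is a min-max multiple-instance regressor in the CHOWDER family:

1. a linear layer scores every patch feature vector (the raw score is the
   patch-level evidence for copy-number state);
2. the ``N`` highest and ``N`` lowest scores of the bag are selected and
   concatenated (top block then bottom block, each sorted descending);
3. a three-layer MLP (200, 100, 1 channels, sigmoid after every layer)
   maps the ``2N`` extreme scores to the slide-level fold change in (0, 1).

Training minimizes mean squared error against slide-level FC labels with
Adam (learning rate 1e-4, weight decay 5e-4) and dropout 0.5 on the linear
layers; only the slide label supervises the patch scorer — patches are
never annotated. One network is trained per arm (1p and 19q).

Everything is plain NumPy: forward, backward, Adam and dropout are
implemented here and checked against finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .bags import FeatureBag, SlidePrediction, sigmoid

_HIDDEN_1 = 200
_HIDDEN_2 = 100


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``N`` extreme patches are taken per side (2N scores feed the MLP);
    optimizer settings follow the min-max MIL literature defaults.
    """

    N: int = 100
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    dropout_p: float = 0.5
    max_epochs: int = 100
    batch_size: int = 1
    early_stop_patience: int = 10
    scorer_dropout: bool = True
    scorer_init: str = "pca"  # "pca": warm-start restart 0 on PC1; "random"
    n_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay nonnegative")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.scorer_init not in ("pca", "random"):
            raise ValueError("scorer_init must be 'pca' or 'random'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class FCEstimatorParams:
    """All weights of one arm's estimator."""

    arm: str
    scorer_weights: np.ndarray  # (D,)
    scorer_bias: float
    mlp_w1: np.ndarray  # (2N, 200)
    mlp_b1: np.ndarray  # (200,)
    mlp_w2: np.ndarray  # (200, 100)
    mlp_b2: np.ndarray  # (100,)
    mlp_w3: np.ndarray  # (100, 1)
    mlp_b3: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        for name in ("scorer_weights", "mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2", "mlp_w3", "mlp_b3"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if not np.isfinite(self.scorer_bias):
            raise ValueError("non-finite scorer_bias")
        if self.mlp_w1.shape[1] != self.mlp_b1.shape[0] or self.mlp_w2.shape != (
            self.mlp_w1.shape[1],
            self.mlp_b2.shape[0],
        ):
            raise ValueError("inconsistent MLP layer dimensions")
        if self.mlp_w1.shape[0] % 2 != 0:
            raise ValueError("MLP input length must be 2N (even)")

    @property
    def N(self) -> int:
        return self.mlp_w1.shape[0] // 2

    @property
    def feature_dim(self) -> int:
        return self.scorer_weights.shape[0]

    def copy(self) -> "FCEstimatorParams":
        return FCEstimatorParams(
            arm=self.arm,
            scorer_weights=self.scorer_weights.copy(),
            scorer_bias=float(self.scorer_bias),
            mlp_w1=self.mlp_w1.copy(),
            mlp_b1=self.mlp_b1.copy(),
            mlp_w2=self.mlp_w2.copy(),
            mlp_b2=self.mlp_b2.copy(),
            mlp_w3=self.mlp_w3.copy(),
            mlp_b3=self.mlp_b3.copy(),
        )

    def save(self, path: str | Path, config: TrainConfig | None = None, extractor_id: str = "unknown") -> Path:
        """Serialize to a single ``.npz`` with embedded config provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {"format_version": 1, "arm": self.arm, "extractor_id": extractor_id}
        if config is not None:
            meta["train_config"] = asdict(config)
        np.savez(
            path,
            meta=np.array(json.dumps(meta)),
            scorer_weights=self.scorer_weights,
            scorer_bias=np.array(self.scorer_bias),
            mlp_w1=self.mlp_w1,
            mlp_b1=self.mlp_b1,
            mlp_w2=self.mlp_w2,
            mlp_b2=self.mlp_b2,
            mlp_w3=self.mlp_w3,
            mlp_b3=self.mlp_b3,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FCEstimatorParams":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                arm=meta["arm"],
                scorer_weights=z["scorer_weights"],
                scorer_bias=float(z["scorer_bias"]),
                mlp_w1=z["mlp_w1"],
                mlp_b1=z["mlp_b1"],
                mlp_w2=z["mlp_w2"],
                mlp_b2=z["mlp_b2"],
                mlp_w3=z["mlp_w3"],
                mlp_b3=z["mlp_b3"],
            )


def init_params(arm: str, feature_dim: int, N: int, rng: np.random.Generator) -> FCEstimatorParams:
    """Glorot-uniform initialization of all layers."""

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return FCEstimatorParams(
        arm=arm,
        scorer_weights=glorot(feature_dim, 1)[:, 0],
        scorer_bias=0.0,
        mlp_w1=glorot(2 * N, _HIDDEN_1),
        mlp_b1=np.zeros(_HIDDEN_1),
        mlp_w2=glorot(_HIDDEN_1, _HIDDEN_2),
        mlp_b2=np.zeros(_HIDDEN_2),
        mlp_w3=glorot(_HIDDEN_2, 1),
        mlp_b3=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------


def score_patches(bag: FeatureBag, params: FCEstimatorParams) -> np.ndarray:
    """Raw (unbounded) patch-level scores: ``w . feature_i + b``."""
    if bag.feature_dim != params.feature_dim:
        raise ValueError(
            f"feature dim mismatch: bag has {bag.feature_dim}, scorer expects {params.feature_dim}"
        )
    return bag.features @ params.scorer_weights + params.scorer_bias


def select_extremes(scores: np.ndarray, N: int, return_indices: bool = False):
    """The ``N`` highest scores (descending) followed by the ``N`` lowest
    (descending).

    Ties are broken toward the lower patch index. Bags with fewer than
    ``2N`` patches recycle the sorted score list cyclically so the output
    always has length ``2N`` and keeps the bag's score scale.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D vector")
    P = scores.size
    order_desc = np.argsort(-scores, kind="stable")  # ties -> lower index first
    top = order_desc[[i % P for i in range(N)]]
    # lowest N (ties -> lower index), then presented in descending order
    order_asc = np.argsort(scores, kind="stable")
    bottom = order_asc[[i % P for i in range(N)]][::-1]
    idx = np.concatenate([top, bottom])
    if return_indices:
        return scores[idx], idx
    return scores[idx]


def aggregate_slide_fc(selected: np.ndarray, params: FCEstimatorParams) -> float:
    """Forward pass of the 200-100-1 MLP with per-layer sigmoids."""
    selected = np.asarray(selected, dtype=np.float64)
    if selected.shape != (params.mlp_w1.shape[0],):
        raise ValueError(
            f"selected has shape {selected.shape}, expected ({params.mlp_w1.shape[0]},)"
        )
    h1 = sigmoid(selected @ params.mlp_w1 + params.mlp_b1)
    h2 = sigmoid(h1 @ params.mlp_w2 + params.mlp_b2)
    return float(sigmoid(h2 @ params.mlp_w3 + params.mlp_b3)[0])


def estimate_fc(bag: FeatureBag, params: FCEstimatorParams, N: int | None = None) -> tuple[float, np.ndarray]:
    """Slide-level FC estimate and the per-patch scores for one arm."""
    N = params.N if N is None else N
    scores = score_patches(bag, params)
    selected = select_extremes(scores, N)
    return aggregate_slide_fc(selected, params), scores


def predict_slide(
    bag: FeatureBag,
    params_1p: FCEstimatorParams,
    params_19q: FCEstimatorParams,
    N: int | None = None,
) -> SlidePrediction:
    """Run both arm estimators on one bag (invariant to patch row order)."""
    fc1, s1 = estimate_fc(bag, params_1p, N)
    fc19, s19 = estimate_fc(bag, params_19q, N)
    return SlidePrediction(
        slide_id=bag.slide_id,
        fc_1p_hat=fc1,
        fc_19q_hat=fc19,
        patch_scores_1p=s1,
        patch_scores_19q=s19,
    )


def mse_loss(predictions, labels) -> float:
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must have equal nonzero length")
    return float(np.mean((predictions - labels) ** 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

_PARAM_NAMES = (
    "scorer_weights",
    "scorer_bias",
    "mlp_w1",
    "mlp_b1",
    "mlp_w2",
    "mlp_b2",
    "mlp_w3",
    "mlp_b3",
)


def _clip_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64)
    if np.any(labels <= 0) or np.any(labels > 1.5):
        raise ValueError("FC labels must lie in (0, 1.5]")
    if np.any(labels >= 1.0):
        warnings.warn(
            "FC labels >= 1 clipped to 0.999 (the sigmoid output is open at 1)",
            stacklevel=3,
        )
        labels = np.minimum(labels, 0.999)
    return labels


def _forward_backward(
    params: FCEstimatorParams,
    bag: FeatureBag,
    label: float,
    N: int,
    dropout_p: float,
    rng: np.random.Generator,
    grads: dict[str, np.ndarray],
    scorer_dropout: bool = True,
) -> float:
    """Accumulate gradients of the squared error for one slide.

    Dropout (inverted, probability ``dropout_p``) is applied to the inputs
    of the three linear maps: the patch scorer, MLP layer 1 and MLP layer 2.
    Selection uses the dropped-out scores; gradients flow only through the
    selected patches (hard top/bottom selection, as in max pooling).
    """
    X = bag.features
    keep = 1.0 - dropout_p
    if dropout_p > 0 and scorer_dropout:
        mask_x = (rng.random(X.shape) < keep) / keep
        Xd = X * mask_x
    else:
        Xd = X
    s = Xd @ params.scorer_weights + params.scorer_bias
    v, idx = select_extremes(s, N, return_indices=True)

    if dropout_p > 0:
        mask_v = (rng.random(v.shape) < keep) / keep
        a0 = v * mask_v
    else:
        a0 = v
    z1 = a0 @ params.mlp_w1 + params.mlp_b1
    h1 = sigmoid(z1)
    if dropout_p > 0:
        mask_h1 = (rng.random(h1.shape) < keep) / keep
        a1 = h1 * mask_h1
    else:
        a1 = h1
    z2 = a1 @ params.mlp_w2 + params.mlp_b2
    h2 = sigmoid(z2)
    z3 = h2 @ params.mlp_w3 + params.mlp_b3
    y_hat = sigmoid(z3)[0]

    err = y_hat - label
    # d(err^2)/dz3
    d3 = np.array([2.0 * err * y_hat * (1.0 - y_hat)])
    grads["mlp_w3"] += np.outer(h2, d3)
    grads["mlp_b3"] += d3
    d_h2 = params.mlp_w3[:, 0] * d3[0]
    d2 = d_h2 * h2 * (1.0 - h2)
    grads["mlp_w2"] += np.outer(a1, d2)
    grads["mlp_b2"] += d2
    d_a1 = params.mlp_w2 @ d2
    d_h1 = d_a1 * (mask_h1 if dropout_p > 0 else 1.0)
    d1 = d_h1 * h1 * (1.0 - h1)
    grads["mlp_w1"] += np.outer(a0, d1)
    grads["mlp_b1"] += d1
    d_a0 = params.mlp_w1 @ d1
    d_v = d_a0 * (mask_v if dropout_p > 0 else 1.0)

    d_s = np.zeros_like(s)
    np.add.at(d_s, idx, d_v)
    grads["scorer_weights"] += Xd.T @ d_s
    grads["scorer_bias"] += d_s.sum()
    return float(err * err)


class _Adam:
    """Adam with decoupled-from-nothing L2 (weight decay added to the raw
    gradient, as in the reference implementation most MIL code uses)."""

    def __init__(self, lr: float, weight_decay: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: FCEstimatorParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name in _PARAM_NAMES:
            p = np.asarray(getattr(params, name), dtype=np.float64)
            g = grads[name] + self.wd * p
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            new = p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if name == "scorer_bias":
                params.scorer_bias = float(new)
            else:
                setattr(params, name, new)


def _dataset_loss(params: FCEstimatorParams, bags, labels, N: int) -> float:
    preds = [estimate_fc(bag, params, N)[0] for bag in bags]
    return mse_loss(preds, labels)


def _pc1(train_bags: list[FeatureBag]) -> np.ndarray:
    """Leading principal component of the pooled training patch features."""
    X = np.concatenate([b.features for b in train_bags])
    X = X - X.mean(axis=0)
    # covariance eigenvector via SVD of the (D, D) Gram matrix
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    return v / np.linalg.norm(v)


def _train_once(
    params: FCEstimatorParams,
    train_bags,
    train_labels,
    val_bags,
    val_labels,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[FCEstimatorParams, dict]:
    use_val = val_bags is not None and len(val_bags) > 0
    opt = _Adam(config.learning_rate, config.weight_decay)
    log = {"train_mse": [], "val_mse": []}
    best = params.copy()
    best_loss = np.inf
    best_epoch = -1
    n = len(train_bags)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = {
                name: np.zeros_like(np.asarray(getattr(params, name), dtype=np.float64))
                for name in _PARAM_NAMES
            }
            for i in batch:
                epoch_loss += _forward_backward(
                    params,
                    train_bags[i],
                    float(train_labels[i]),
                    config.N,
                    config.dropout_p,
                    rng,
                    grads,
                    scorer_dropout=config.scorer_dropout,
                )
            for name in _PARAM_NAMES:
                grads[name] /= len(batch)
            opt.step(params, grads)
        train_mse = epoch_loss / n
        if not np.isfinite(train_mse):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; last good snapshot "
                f"is from epoch {best_epoch}"
            )
        monitor = _dataset_loss(params, val_bags, val_labels, config.N) if use_val else train_mse
        log["train_mse"].append(train_mse)
        log["val_mse"].append(monitor if use_val else float("nan"))
        if monitor < best_loss:
            best_loss = monitor
            best = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    log["best_epoch"] = best_epoch
    log["best_loss"] = float(best_loss)
    return best, log


def train_fc_estimator(
    train_bags: list[FeatureBag],
    train_labels,
    val_bags: list[FeatureBag] | None = None,
    val_labels=None,
    config: TrainConfig | None = None,
    arm: str = "1p",
) -> tuple[FCEstimatorParams, dict]:
    """Train one arm's FC estimator against slide-level labels.

    The min-max selection makes the loss surface rough, so training runs
    ``config.n_restarts`` independent restarts and keeps the one with the
    best monitored loss (validation MSE when a validation set is given,
    else training MSE). The first restart warm-starts the patch scorer on
    the leading principal component of the pooled training features (an
    unsupervised guess at the dominant tissue axis); the remaining
    restarts are fully random. Deterministic given ``config.seed``.

    Returns the best parameter snapshot and a log with the per-epoch loss
    trajectory of every restart.
    """
    config = config or TrainConfig()
    if len(train_bags) == 0:
        raise ValueError("empty training set")
    train_labels = _clip_labels(train_labels)
    if len(train_labels) != len(train_bags):
        raise ValueError("one label per training bag required")
    use_val = val_bags is not None and len(val_bags) > 0
    if use_val:
        val_labels = _clip_labels(val_labels)
    if any(b.n_patches < 2 * config.N for b in train_bags):
        warnings.warn(
            f"some bags have fewer than 2N={2 * config.N} patches; "
            "extreme scores are recycled for those slides",
            stacklevel=2,
        )

    D = train_bags[0].feature_dim
    pc1 = _pc1(train_bags) if config.scorer_init == "pca" else None
    best_params, best_log, best_loss = None, None, np.inf
    restart_logs = []
    for r in range(config.n_restarts):
        seed_r = int(
            np.random.SeedSequence(config.seed, spawn_key=(r,)).generate_state(1)[0]
        )
        rng = np.random.default_rng(seed_r)
        params = init_params(arm, D, config.N, rng)
        if r == 0 and pc1 is not None:
            # scaled to the norm a Glorot draw would have in expectation
            glorot_sd = np.sqrt(6.0 / (D + 1)) / np.sqrt(3.0)
            params.scorer_weights = pc1 * glorot_sd * np.sqrt(D)
        params, log = _train_once(
            params, train_bags, train_labels, val_bags, val_labels, config, rng
        )
        restart_logs.append(log)
        if log["best_loss"] < best_loss:
            best_loss = log["best_loss"]
            best_params, best_log = params, log
    best_log = dict(best_log)
    best_log["restarts"] = restart_logs
    return best_params, best_log
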