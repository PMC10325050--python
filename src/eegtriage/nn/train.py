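"""Training loop (Adam, cross-entropy, holdout validation) and prediction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from ..recording import CLASSES
from .network import Model, NetworkSpec

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Stated training regime: Adam at 3e-4 for at most 90 epochs, with a
    holdout fraction of 0.2 for featureless networks and 0.1 for
    feature-based ones. Classes are weighted inversely to their counts so
    the three classes contribute equally."""

    learning_rate: float = 3e-4
    max_epochs: int = 90
    holdout: float = 0.2
    batch_size: int = 32
    seed: int = 0
    standardize: bool = False
    patience: int = 10

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.holdout < 1.0:
            raise ValueError("holdout must lie in (0, 1)")


@dataclass
class TrainedModel:
    model: Model
    classes: list[str]
    history: list[dict] = field(default_factory=list)
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)
    idx_train: np.ndarray | None = None
    idx_holdout: np.ndarray | None = None

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1:] != tuple(self.model.spec.input_shape):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match network input "
                f"{tuple(self.model.spec.input_shape)}"
            )
        if self.scaler is not None:
            mu, sd = self.scaler
            X = (X - mu) / sd
        return self.model.predict_proba(X)


class Adam:
    def __init__(self, items, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {(node, key): np.zeros_like(arr) for node, key, arr in items}
        self.v = {(node, key): np.zeros_like(arr) for node, key, arr in items}

    def step(self, params_by_node: dict, grads_by_node: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for node, grads in grads_by_node.items():
            for key, g in grads.items():
                k = (node, key)
                self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
                self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
                update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
                params_by_node[node][key] -= self.lr * update


def _encode_labels(y, classes):
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def _ce_loss_and_grad(logits, y_idx, sample_w):
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -(sample_w * logp[np.arange(n), y_idx]).sum() / sample_w.sum()
    p = np.exp(logp)
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    grad *= (sample_w / sample_w.sum())[:, None]
    return loss, grad


def train_network(
    spec: NetworkSpec,
    X: np.ndarray,
    y,
    cfg: TrainConfig | None = None,
    classes: list[str] | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train a network with Adam / weighted cross-entropy.

    The holdout split is stratified at the stated fraction with the config
    seed (``split`` overrides it with explicit train/holdout indices, e.g.
    for recording-level splitting); per-epoch train and validation losses
    are recorded; training stops early when the validation loss has not
    improved for ``patience`` epochs, or at ``max_epochs``. Non-finite loss
    aborts with a diagnostic.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"data shape {X.shape[1:]} does not match spec input "
            f"{tuple(spec.input_shape)}"
        )
    if classes is None:
        classes = [c for c in CLASSES if c in set(y)] or sorted(set(y))
    y_idx = _encode_labels(y, classes)

    if split is not None:
        idx_tr, idx_va = (np.asarray(split[0]), np.asarray(split[1]))
    else:
        try:
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)),
                test_size=cfg.holdout,
                random_state=cfg.seed,
                stratify=y_idx,
            )
        except ValueError:
            # a class too small to stratify: plain shuffled split
            logger.warning(
                "stratified holdout impossible; using a shuffled split"
            )
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)), test_size=cfg.holdout, random_state=cfg.seed
            )
    Xtr, Xva = X[idx_tr], X[idx_va]
    ytr, yva = y_idx[idx_tr], y_idx[idx_va]

    scaler = None
    if cfg.standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr - mu) / sd
        Xva = (Xva - mu) / sd
        scaler = (mu, sd)

    # equal class weighting: inverse class frequency, mean-normalized
    counts = np.bincount(ytr, minlength=len(classes)).astype(float)
    class_w = np.where(counts > 0, counts.sum() / (len(classes) * counts), 0.0)
    wtr = class_w[ytr]
    wva = class_w[yva]

    model = Model(spec, seed=cfg.seed)
    softmax_in = model.softmax_input()
    opt = Adam(list(model.trainable_items()), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    history: list[dict] = []
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            _, acts = model.forward(Xtr[sel], training=True, keep_caches=True)
            logits = acts[softmax_in]
            loss, dlogits = _ce_loss_and_grad(logits, ytr[sel], wtr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch + 1} (non-finite loss); "
                    "reduce the learning rate"
                )
            pgrads, _ = model.backward(acts, softmax_in, dlogits)
            opt.step(model.params, pgrads)
            train_losses.append(loss)
        _, acts = model.forward(Xva, training=False, keep_caches=False)
        val_loss, _ = _ce_loss_and_grad(acts[softmax_in], yva, wva)
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": float(val_loss),
            }
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {
                n: {k: v.copy() for k, v in p.items()}
                for n, p in model.params.items()
            }
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d", epoch + 1)
                break
    if best_params is not None:
        model.params = best_params
    return TrainedModel(model=model, classes=list(classes), history=history,
                        scaler=scaler, idx_train=idx_tr, idx_holdout=idx_va)


def predict_scores(trained: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class-probability rows (summing to 1) for a batch of inputs."""
    return trained.predict_scores(X)
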