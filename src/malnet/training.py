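"""Training: imbalance-weighted BCE, Adam, and five-fold cross-validation.

The loss treats each of the five subtypes as an independent binary
problem and up-weights the positive term of the rarer class:

    w_i    = N_negative,i / N_positive,i
    Loss   = -(1/N) Σ [ w_i · y · log σ(ŷ) + (1 - y) · log(1 - σ(ŷ)) ]

computed directly from logits in a numerically stable form
(log σ(z) = -softplus(-z), log(1-σ(z)) = -softplus(z)), averaged over
all (sample, label) terms.  Optimization is mini-batch Adam with
per-epoch reshuffling; class weights and preprocessing statistics are
always fitted on the training portion of the split or fold at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .network import (ModelConfig, ModelParams, forward_graph, init_params,
                      predict_labels)
from .preprocess import Preprocessor, stratified_kfold

__all__ = [
    "TrainConfig", "TrainingHistory", "TrainingError", "class_weights",
    "weighted_bce_loss", "train", "cross_validate",
]


class TrainingError(ValueError):
    """Unusable labels, divergence, or invalid training configuration."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the published sweep optima: learning rate 1e-4,
    batch size 64, 500 epochs (the initially reported 1e-3 learning
    rate remains selectable).  Adam moment constants are the standard
    β1=0.9, β2=0.999, ε=1e-8.
    """

    learning_rate: float = 1e-4
    epochs: int = 500
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    use_class_weights: bool = True

    def __post_init__(self):
        if self.learning_rate < 0:
            raise TrainingError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise TrainingError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch mean loss and per-label training accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "loss": self.loss, "accuracy": self.accuracy})


def class_weights(Y: np.ndarray) -> np.ndarray:
    """Positive-class weights w_i = N_negative,i / N_positive,i."""
    Y = np.asarray(Y, dtype=float)
    pos = Y.sum(axis=0)
    neg = Y.shape[0] - pos
    if (pos == 0).any():
        bad = list(np.flatnonzero(pos == 0))
        raise TrainingError(
            f"label column(s) {bad} have zero positives; re-stratify the "
            "split so every subtype is represented")
    return neg / pos


def _loss_graph(logits: Tensor, Y: np.ndarray, w: np.ndarray) -> Tensor:
    """Stable weighted BCE on logits; mean over all (sample,label) terms."""
    Yt = Tensor(Y)
    wt = Tensor(w)
    # -log σ(z) = softplus(-z);  -log(1-σ(z)) = softplus(z)
    pos_term = wt * Yt * (-logits).softplus()
    neg_term = (1.0 - Yt) * logits.softplus()
    return (pos_term + neg_term).mean()


def weighted_bce_loss(logits: np.ndarray, Y: np.ndarray,
                      w: np.ndarray | float = 1.0) -> float:
    """Imbalance-weighted binary cross-entropy from raw logits.

    The weight multiplies the positive term only.  Stable for |logit|
    well beyond 100.
    """
    logits = np.asarray(logits, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if logits.shape != Y.shape:
        raise TrainingError("logits and labels must share a shape")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise TrainingError("labels must be binary")
    w = np.broadcast_to(np.asarray(w, dtype=float),
                        (Y.shape[-1],) if Y.ndim else ())
    return float(_loss_graph(Tensor(logits), Y, np.asarray(w)).data)


class _Adam:
    """Adam with bias-corrected moment estimates."""

    def __init__(self, tensors: list[Tensor], config: TrainConfig):
        self.tensors = tensors
        self.cfg = config
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self) -> None:
        cfg = self.cfg
        self.t += 1
        for i, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[i] = cfg.beta1 * self.m[i] + (1 - cfg.beta1) * g
            self.v[i] = cfg.beta2 * self.v[i] + (1 - cfg.beta2) * g * g
            m_hat = self.m[i] / (1 - cfg.beta1 ** self.t)
            v_hat = self.v[i] / (1 - cfg.beta2 ** self.t)
            tensor.data -= (cfg.learning_rate * m_hat
                            / (np.sqrt(v_hat) + cfg.eps))


def train(X: np.ndarray, Y: np.ndarray, model_config: ModelConfig,
          train_config: TrainConfig | None = None,
          params: ModelParams | None = None
          ) -> tuple[ModelParams, TrainingHistory]:
    """Mini-batch Adam training on the weighted BCE loss.

    Dropout is active during training; batches are reshuffled each
    epoch from a seed derived from ``train_config.seed``, so the same
    seed reproduces the same history exactly.
    """
    cfg = train_config or TrainConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise TrainingError("X and Y row counts differ")
    w = (class_weights(Y) if cfg.use_class_weights
         else np.ones(Y.shape[1]))
    root = np.random.SeedSequence(cfg.seed)
    init_seed, *_ = root.spawn(1)
    if params is None:
        params = init_params(model_config, X.shape[1],
                             np.random.default_rng(init_seed))
    opt = _Adam(params.tensors(), cfg)
    history = TrainingHistory()
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        ep_seq = np.random.SeedSequence(entropy=cfg.seed,
                                        spawn_key=(1, epoch))
        rng = np.random.default_rng(ep_seq)
        order = rng.permutation(n)
        losses, sizes, correct = [], [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            params.zero_grad()
            logits = forward_graph(Tensor(X[idx]), params, model_config,
                                   train=True, rng=rng)
            loss = _loss_graph(logits, Y[idx], w)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"training diverged at epoch {epoch + 1}: "
                    f"loss = {loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            sizes.append(len(idx))
            # per-label training accuracy from the batch logits
            pred = predict_labels(0.5 * (1 + np.tanh(0.5 * logits.data)),
                                  model_config.decision_threshold)
            correct += int((pred == Y[idx]).sum())
        history.loss.append(float(np.average(losses, weights=sizes)))
        history.accuracy.append(correct / (n * Y.shape[1]))
    return params, history


def cross_validate(df: pd.DataFrame, schema, model_config: ModelConfig,
                   train_config: TrainConfig | None = None, k: int = 5,
                   seed: int = 0, metrics_fn=None) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the full pipeline.

    For each fold the preprocessor and class weights are fitted on the
    k-1 training folds only; the held-out fold is transformed with
    those statistics and scored.  Returns a per-fold metric table with
    a trailing ``mean`` and ``sd`` row.
    """
    from .evaluation import evaluate_probabilities  # local: avoid cycle

    cfg = train_config or TrainConfig()
    folds = stratified_kfold(df, schema, k, seed=seed)
    metrics_fn = metrics_fn or evaluate_probabilities
    rows = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(df)), test_idx)
        train_df = df.iloc[train_idx]
        test_df = df.iloc[test_idx]
        prep = Preprocessor(schema).fit(train_df)
        enc_train = prep.transform(train_df, require_labels=True)
        enc_test = prep.transform(test_df, require_labels=True)
        fold_cfg = replace(cfg, seed=cfg.seed + fold_id)
        params, _ = train(enc_train.X, enc_train.Y, model_config, fold_cfg)
        from .network import forward
        probs, _ = forward(enc_test.X, params, model_config, mode="eval")
        row = metrics_fn(probs, enc_test.Y,
                         threshold=model_config.decision_threshold)
        row["fold"] = fold_id
        row["n_test"] = len(test_idx)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("fold")
    numeric = table.select_dtypes("number")
    table.loc["mean"] = numeric.mean()
    table.loc["sd"] = numeric.std(ddof=1)
    return table
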