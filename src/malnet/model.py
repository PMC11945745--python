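"""Model/Results interface over the full pipeline.

:class:`MALNet` is constructed from a labeled cohort table plus its
schema (statsmodels-style: the model object holds data and settings,
``fit`` does the work and returns a :class:`MALNetResults` carrying the
fitted parameters, training history, held-out metrics and a
``summary()`` table).

    >>> schema = default_schema()
    >>> cohort = generate_cohort(500, seed=7)
    >>> model = MALNet.from_dataframe(cohort, schema)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())

``fit`` runs the whole protocol: missingness screen, stratified 80/20
split, leakage-free preprocessing, class-weighted training, held-out
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import network
from .evaluation import evaluate_probabilities, permutation_importance
from .network import ModelConfig, ModelParams, count_parameters, forward
from .preprocess import Preprocessor, balance_report, screen_missing, \
    split_cohort
from .schema import FeatureSchema
from .training import TrainConfig, TrainingHistory, train, cross_validate

__all__ = ["MALNet", "MALNetResults"]


class MALNet:
    """Multi-label LSTM + multi-head-attention classifier for a cohort.

    Parameters
    ----------
    cohort : labeled patient table (one row per patient)
    schema : the :class:`FeatureSchema` describing its columns
    model_config, train_config : architecture / optimization settings
    test_fraction : held-out fraction for the internal split (default 0.2)
    max_missing_fraction : per-patient missingness screen (default 0.2)
    """

    def __init__(self, cohort: pd.DataFrame, schema: FeatureSchema,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 test_fraction: float = 0.2,
                 max_missing_fraction: float = 0.2):
        self.schema = schema
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.test_fraction = test_fraction
        self.max_missing_fraction = max_missing_fraction
        self.cohort, self.dropped = screen_missing(
            cohort, schema, max_missing_fraction)

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, schema: FeatureSchema,
                       **kwargs) -> "MALNet":
        return cls(cohort, schema, **kwargs)

    @property
    def n_params(self) -> int:
        return count_parameters(self.model_config, self.schema.n_encoded,
                                scope="full")

    def fit(self, seed: int | None = None) -> "MALNetResults":
        """Split, preprocess, train and evaluate; returns the results."""
        cfg = self.train_config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        train_df, test_df = split_cohort(
            self.cohort, self.schema, self.test_fraction, seed=cfg.seed)
        prep = Preprocessor(self.schema).fit(train_df)
        enc_train = prep.transform(train_df, require_labels=True)
        enc_test = prep.transform(test_df, require_labels=True)
        params, history = train(enc_train.X, enc_train.Y,
                                self.model_config, cfg)
        probs, _ = forward(enc_test.X, params, self.model_config,
                           mode="eval")
        metrics = evaluate_probabilities(
            probs, enc_test.Y,
            threshold=self.model_config.decision_threshold)
        return MALNetResults(model=self, params=params, preprocessor=prep,
                             history=history, metrics=metrics,
                             train_df=train_df, test_df=test_df,
                             train_config=cfg)

    def cross_validate(self, k: int = 5, seed: int | None = None
                       ) -> pd.DataFrame:
        cfg = self.train_config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        return cross_validate(self.cohort, self.schema, self.model_config,
                              cfg, k=k, seed=cfg.seed)

    def balance_report(self, seed: int | None = None) -> pd.DataFrame:
        cfg_seed = self.train_config.seed if seed is None else seed
        train_df, test_df = split_cohort(
            self.cohort, self.schema, self.test_fraction, seed=cfg_seed)
        return balance_report(train_df, test_df, self.schema)


@dataclass
class MALNetResults:
    """Fitted parameters, history and held-out metrics of one run."""

    model: MALNet
    params: ModelParams
    preprocessor: Preprocessor
    history: TrainingHistory
    metrics: dict
    train_df: pd.DataFrame
    test_df: pd.DataFrame
    train_config: TrainConfig

    # -- prediction -------------------------------------------------------

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        """Per-subtype probabilities for new patients."""
        enc = self.preprocessor.transform(cohort)
        probs, _ = forward(enc.X, self.params, self.model.model_config,
                           mode="eval")
        return probs

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """Thresholded 0/1 subtype calls (multi-label)."""
        return network.predict_labels(
            self.predict_proba(cohort),
            self.model.model_config.decision_threshold)

    def evaluate(self, cohort: pd.DataFrame) -> dict:
        enc = self.preprocessor.transform(cohort, require_labels=True)
        probs, _ = forward(enc.X, self.params, self.model.model_config,
                           mode="eval")
        return evaluate_probabilities(
            probs, enc.Y, threshold=self.model.model_config.decision_threshold)

    def feature_importance(self, repeats: int = 5,
                           seed: int = 0) -> pd.DataFrame:
        enc = self.preprocessor.transform(self.test_df, require_labels=True)
        return permutation_importance(
            self.params, enc.X, enc.Y, self.model.model_config,
            column_names=enc.column_names, repeats=repeats, seed=seed)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        mc = self.model.model_config
        lines = [
            "MAL-Net multi-label subtype classifier",
            "=" * 54,
            f"patients (train/test): {len(self.train_df)}/"
            f"{len(self.test_df)}   encoded width d = "
            f"{self.model.schema.n_encoded}",
            f"architecture: token_dim={mc.token_dim} hidden={mc.hidden_dim} "
            f"heads={mc.n_heads if mc.use_mha else 0} fc={mc.fc_dim} "
            f"dropout={mc.dropout_p}",
            f"trainable parameters: {self.model.n_params:,}",
            f"epochs: {len(self.history.loss)}   "
            f"final train loss: {self.history.loss[-1]:.4f}   "
            f"final train accuracy: {self.history.accuracy[-1]:.3f}",
            "-" * 54,
            "held-out test metrics (per-label macro unless noted):",
        ]
        for key in ("accuracy", "precision", "recall", "f1",
                    "subset_accuracy", "micro_auc", "macro_auc"):
            lines.append(f"  {key:16s} {self.metrics[key]:.4f}")
        lines.append("-" * 54)
        lines.append("per-subtype F1 / AUC:")
        for j, name in enumerate(self.model.schema.label_names):
            lines.append(f"  {name:20s} F1 {self.metrics[f'f1_label_{j}']:.3f}"
                         f"   AUC {self.metrics[f'auc_label_{j}']:.3f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        network.save_checkpoint(path, self.params, self.model.model_config,
                                self.model.schema.fingerprint())

    # -- plotting ---------------------------------------------------------

    def plot_history(self, ax=None):
        """Training loss and per-label accuracy per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history.loss) + 1)
        ax.plot(epochs, self.history.loss, label="training loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("weighted BCE loss")
        twin = ax.twinx()
        twin.plot(epochs, self.history.accuracy, color="tab:orange",
                  label="training accuracy")
        twin.set_ylabel("per-label accuracy")
        twin.set_ylim(0, 1.02)
        ax.figure.legend(loc="center right")
        return ax

    def plot_roc(self, ax=None):
        """Pooled (micro) and per-subtype ROC curves on the test split."""
        import matplotlib.pyplot as plt

        from .evaluation import roc_curve

        if ax is None:
            _, ax = plt.subplots()
        enc = self.preprocessor.transform(self.test_df, require_labels=True)
        probs = self.predict_proba(self.test_df)
        fpr, tpr, _ = roc_curve(probs.ravel(), enc.Y.ravel())
        ax.plot(fpr, tpr, lw=2,
                label=f"micro (AUC {self.metrics['micro_auc']:.3f})")
        for j, name in enumerate(self.model.schema.label_names):
            col = enc.Y[:, j]
            if 0 < col.sum() < len(col):
                f, t, _ = roc_curve(probs[:, j], col)
                ax.plot(f, t, lw=1, alpha=0.6,
                        label=f"{name} (AUC "
                              f"{self.metrics[f'auc_label_{j}']:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=8)
        return ax
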