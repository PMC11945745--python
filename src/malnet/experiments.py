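"""Canned end-to-end experiments on synthetic cohorts.

These functions run the full protocol — generate a cohort, screen,
split, preprocess, train, evaluate — under fixed study conditions, and
are shared by the test-suite and the results-reproduction script:

* learnability on the separable preset (500 patients, 80/20 split),
* a null-link control (no feature→label association: micro-AUC ≈ 0.5),
* the class-weighting benefit on a rare (8%) subtype,
* the attention-module ablation on the same imbalanced preset.

All experiments use one configuration (see the methods note): the
published 32-unit hidden layer and four attention heads, sum
aggregation over the attended sequence, dropout 0.2 with the faster
published learning rate 1e-3 and batch size 16 — the small-batch,
lighter-dropout end of the published sweep, which generalizes best in
the 400-patient training regime.  Cohorts are 500 patients (the study
size); comparison runs train 100 epochs per arm so multi-seed
experiments stay tractable on one CPU, the learnability run 300.

Identical (preset, seed) arms are computed once and cached, so the
imbalance and ablation analyses share their full-model runs.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .evaluation import paired_comparison
from .model import MALNet
from .network import ModelConfig
from .simulate import (default_schema, generate_cohort, null_link,
                       rare_label_link, separable_link, published_marginals)
from .training import TrainConfig

__all__ = [
    "learnability_run", "null_control_runs", "imbalance_benefit_runs",
    "mha_ablation_runs", "ablation_significance",
]

#: label index of the rare severe-subtype analogue in the presets
RARE_LABEL = 4

#: shared end-to-end experiment configuration (see module docstring)
EXP_MODEL = ModelConfig(dropout_p=0.2, aggregation="sum")
EXP_TRAIN = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=100)

#: comparison-arm / learnability / null-control epoch counts
COMPARE_EPOCHS = 100
LEARNABILITY_EPOCHS = 300
NULL_EPOCHS = 40


@lru_cache(maxsize=2)
def _preset_link(name: str):
    if name == "separable":
        return separable_link()
    if name == "rare":
        return rare_label_link()
    if name == "null":
        return null_link()
    raise ValueError(name)


def _fit_once(preset: str, seed: int, epochs: int, use_class_weights: bool,
              use_mha: bool, n: int):
    df = generate_cohort(n, published_marginals(), _preset_link(preset),
                         seed=seed)
    mc = replace(EXP_MODEL, use_mha=use_mha)
    tc = replace(EXP_TRAIN, epochs=epochs,
                 use_class_weights=use_class_weights, seed=seed)
    model = MALNet.from_dataframe(df, default_schema(), model_config=mc,
                                  train_config=tc)
    return model.fit()


#: evaluation-cohort size for the multi-seed comparisons: a synthetic
#: setting permits scoring on a large fresh draw from the same preset,
#: which makes rare-label F1 (≈ 8 positives in a 100-patient test set)
#: a stable quantity
EVAL_N = 2000


@lru_cache(maxsize=64)
def _run_metrics(preset: str, seed: int, epochs: int,
                 use_class_weights: bool, use_mha: bool, n: int,
                 eval_n: int | None) -> tuple[tuple[str, float], ...]:
    res = _fit_once(preset, seed, epochs, use_class_weights, use_mha, n)
    metrics = res.metrics
    if eval_n is not None:
        fresh = generate_cohort(eval_n, published_marginals(),
                                _preset_link(preset),
                                seed=seed + 1_000_003)
        metrics = res.evaluate(fresh)
    return tuple(sorted(metrics.items()))


def _metrics(preset: str, seed: int, *, epochs: int,
             use_class_weights: bool = True, use_mha: bool = True,
             n: int = 500, eval_n: int | None = None) -> dict:
    return dict(_run_metrics(preset, int(seed), epochs,
                             use_class_weights, use_mha, n, eval_n))


def learnability_run(seed: int = 0, n: int = 500,
                     epochs: int = LEARNABILITY_EPOCHS) -> dict:
    """Train on the separable preset; report held-out metrics."""
    return _metrics("separable", seed, epochs=epochs, n=n)


def null_control_runs(seeds, n: int = 400,
                      epochs: int = NULL_EPOCHS) -> np.ndarray:
    """Held-out micro-AUC per seed on the no-association preset.

    With B = 0 the labels carry no feature signal, so any systematic
    departure of AUC from 0.5 would indicate leakage in the pipeline.
    Short training suffices: there is nothing to learn.
    """
    return np.array([_metrics("null", s, epochs=epochs, n=n)["micro_auc"]
                     for s in seeds])


def imbalance_benefit_runs(seeds, n: int = 500,
                           epochs: int = COMPARE_EPOCHS,
                           eval_n: int = EVAL_N) -> pd.DataFrame:
    """Rare-label F1 with and without class weighting, per seed.

    Arms are scored on a fresh ``eval_n``-patient cohort from the same
    preset so the rare-label F1 is measured with adequate precision."""
    rows = []
    for seed in seeds:
        m_w = _metrics("rare", seed, epochs=epochs, n=n, eval_n=eval_n)
        m_u = _metrics("rare", seed, epochs=epochs, n=n, eval_n=eval_n,
                       use_class_weights=False)
        rows.append({
            "seed": seed,
            "f1_weighted": m_w[f"f1_label_{RARE_LABEL}"],
            "f1_uniform": m_u[f"f1_label_{RARE_LABEL}"],
            "micro_auc_weighted": m_w["micro_auc"],
        })
    return pd.DataFrame(rows)


def mha_ablation_runs(seeds, n: int = 500,
                      epochs: int = COMPARE_EPOCHS,
                      eval_n: int = EVAL_N) -> pd.DataFrame:
    """Full model vs attention-free baseline on the imbalanced preset.

    The full-model arm is shared with ``imbalance_benefit_runs`` (same
    preset, configuration and seeds), mirroring an ablation table's
    reuse of the headline runs.
    """
    rows = []
    for seed in seeds:
        m_full = _metrics("rare", seed, epochs=epochs, n=n, eval_n=eval_n)
        m_base = _metrics("rare", seed, epochs=epochs, n=n, eval_n=eval_n,
                          use_mha=False)
        rows.append({
            "seed": seed,
            "f1_full": m_full[f"f1_label_{RARE_LABEL}"],
            "f1_baseline": m_base[f"f1_label_{RARE_LABEL}"],
            "micro_auc_full": m_full["micro_auc"],
            "micro_auc_baseline": m_base["micro_auc"],
        })
    return pd.DataFrame(rows)


def ablation_significance(table: pd.DataFrame,
                          column_a: str = "f1_full",
                          column_b: str = "f1_baseline"
                          ) -> tuple[float, float]:
    """Paired t-test across seeds for an ablation table."""
    return paired_comparison(table[column_a].to_numpy(),
                             table[column_b].to_numpy())
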