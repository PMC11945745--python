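"""Cohort preprocessing: missingness screen, imputation, encoding, split.

The pipeline mirrors standard clinical-tabular practice:

1.  Patients missing more than a fraction of their feature values are
    dropped (default 20%).
2.  Remaining gaps are imputed — mean for continuous features, mode for
    binary/categorical — with statistics fitted on the training
    partition only (no leakage into test folds).
3.  Continuous features are min-max scaled to [0, 1] using training
    min/max (out-of-range test values are clipped); binary features stay
    as a single 0/1 column; categorical features are one-hot encoded.
4.  The cohort is split 80/20 (or k-fold) with greedy multi-label
    stratification so every subtype keeps a comparable prevalence in
    both partitions, rare subtypes first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (BINARY, CATEGORICAL, CONTINUOUS, FeatureSchema,
                     SchemaError, _canon)

__all__ = [
    "EncodedMatrix", "Preprocessor", "screen_missing", "split_cohort",
    "stratified_kfold", "balance_report", "PreprocessError",
]


class PreprocessError(ValueError):
    """Raised for unfittable features or unfitted transforms."""


@dataclass
class EncodedMatrix:
    """Encoded design matrix plus (optionally) the label matrix."""

    X: np.ndarray                  # n x d, all values in [0, 1]
    column_names: list[str]
    Y: np.ndarray | None = None    # n x 5 binary, None for unlabeled data

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def screen_missing(df: pd.DataFrame, schema: FeatureSchema,
                   max_missing_fraction: float = 0.2
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop patients whose missing-feature fraction exceeds the threshold.

    A row is dropped iff (missing feature cells / number of schema
    features) is strictly greater than ``max_missing_fraction``.  Order
    is preserved; ``kept`` and ``dropped`` partition the input.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise PreprocessError("max_missing_fraction must lie in [0, 1]")
    feats = schema.feature_names
    if not feats:
        raise SchemaError("schema declares no features")
    frac = df[feats].isna().sum(axis=1) / len(feats)
    keep = frac <= max_missing_fraction
    return df.loc[keep], df.loc[~keep]


class Preprocessor:
    """Fitted imputation + scaling state (training partition only).

    Holds, per continuous feature, the observed mean/min/max, and per
    binary/categorical feature the observed mode.  ``transform`` imputes
    from these statistics and encodes per the schema.
    """

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self.means: dict[str, float] = {}
        self.mins: dict[str, float] = {}
        self.maxs: dict[str, float] = {}
        self.modes: dict[str, object] = {}
        self.fitted = False

    def fit(self, df: pd.DataFrame) -> "Preprocessor":
        if len(df) == 0:
            raise PreprocessError("cannot fit preprocessor on empty cohort")
        for f in self.schema.features:
            observed = df[f.name].dropna()
            if len(observed) == 0:
                raise PreprocessError(
                    f"feature {f.name!r} has no observed values to fit")
            if f.kind == CONTINUOUS:
                vals = observed.astype(float)
                if not np.isfinite(vals).all():
                    raise PreprocessError(
                        f"feature {f.name!r} has non-finite values")
                self.means[f.name] = float(vals.mean())
                self.mins[f.name] = float(vals.min())
                self.maxs[f.name] = float(vals.max())
            else:
                # deterministic mode: most frequent, ties to smallest code
                counts = observed.value_counts()
                top = counts[counts == counts.max()]
                self.modes[f.name] = sorted(top.index, key=str)[0]
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame,
                  require_labels: bool = False) -> EncodedMatrix:
        if not self.fitted:
            raise PreprocessError("transform called before fit")
        n = len(df)
        cols: list[np.ndarray] = []
        for f in self.schema.features:
            series = df[f.name]
            if f.kind == CONTINUOUS:
                vals = series.astype(float).to_numpy(copy=True)
                vals[np.isnan(vals)] = self.means[f.name]
                lo, hi = self.mins[f.name], self.maxs[f.name]
                if hi == lo:
                    warnings.warn(
                        f"feature {f.name!r} is constant in the training "
                        "data; scaled column set to 0.0", stacklevel=2)
                    scaled = np.zeros(n)
                else:
                    scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
                cols.append(scaled)
            elif f.kind == BINARY:
                vals = series.to_numpy(dtype=object, copy=True)
                missing = pd.isna(series).to_numpy()
                vals[missing] = self.modes[f.name]
                arr = np.asarray(vals, dtype=float)
                if not np.isin(arr, (0.0, 1.0)).all():
                    raise PreprocessError(
                        f"binary feature {f.name!r} has values outside 0/1")
                cols.append(arr)
            else:  # categorical -> one-hot
                vals = series.to_numpy(dtype=object, copy=True)
                missing = pd.isna(series).to_numpy()
                vals[missing] = self.modes[f.name]
                codes = np.array([_canon(v) for v in vals])
                unknown = set(codes) - set(f.categories)
                if unknown:
                    raise PreprocessError(
                        f"feature {f.name!r}: unseen category code(s) "
                        f"{sorted(unknown)}")
                for cat in f.categories:
                    cols.append((codes == cat).astype(float))
        X = np.column_stack(cols) if n else np.empty((0, self.schema.n_encoded))
        if not np.isfinite(X).all():
            raise PreprocessError("encoded matrix contains non-finite values")
        Y = None
        if all(l in df.columns for l in self.schema.label_names):
            Y = df[list(self.schema.label_names)].to_numpy(dtype=float)
        elif require_labels:
            raise PreprocessError("cohort lacks label columns")
        return EncodedMatrix(X=X, column_names=self.schema.encoded_columns(),
                             Y=Y)


# -- stratified partitioning ---------------------------------------------

def _greedy_assign(Y: np.ndarray, fractions: list[float],
                   seed: int) -> np.ndarray:
    """Greedy iterative multi-label stratification.

    Processes labels from rarest to most common; within a label, assigns
    its remaining positive rows to the partition whose quota for that
    label is least filled.  Returns a partition index per row.
    """
    rng = np.random.default_rng(seed)
    n, n_labels = Y.shape
    k = len(fractions)
    desired_n = np.array(fractions) * n                 # rows per partition
    desired = np.outer(Y.sum(axis=0), fractions)        # positives per part
    assign = np.full(n, -1)
    label_order = np.argsort(Y.sum(axis=0), kind="stable")  # rarest first
    for lab in label_order:
        rows = np.flatnonzero((Y[:, lab] == 1) & (assign == -1))
        rng.shuffle(rows)
        for r in rows:
            gap = desired[lab] - np.array(
                [np.sum(Y[assign == p, lab]) for p in range(k)])
            # prefer the partition missing most positives; break ties by
            # overall remaining capacity, then randomly
            cap = desired_n - np.bincount(assign[assign >= 0], minlength=k)
            order = np.lexsort((rng.random(k), -cap, -gap))
            assign[r] = order[0]
    rest = np.flatnonzero(assign == -1)
    rng.shuffle(rest)
    for r in rest:
        cap = desired_n - np.bincount(assign[assign >= 0], minlength=k)
        order = np.lexsort((rng.random(k), -cap))
        assign[r] = order[0]
    return assign


def split_cohort(df: pd.DataFrame, schema: FeatureSchema,
                 test_fraction: float = 0.2, seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split preserving per-subtype prevalence.

    The split is reproducible per seed; every subtype's positive
    prevalence in each partition stays close to its overall prevalence
    (rare labels are stratified first).  Partition sizes are
    ``round(n * test_fraction)`` for the test arm.
    """
    if not 0 < test_fraction < 1:
        raise PreprocessError("test_fraction must lie in (0, 1)")
    Y = df[list(schema.label_names)].to_numpy(dtype=float)
    n_test = int(round(len(df) * test_fraction))
    if min(Y.sum(axis=0)) < 2:
        warnings.warn("a subtype has fewer positives than partitions; "
                      "best-effort assignment", stacklevel=2)
    fractions = [1 - test_fraction, test_fraction]
    assign = _greedy_assign(Y, fractions, seed)
    # repair sizes exactly to (n - n_test, n_test)
    assign = _fix_sizes(assign, [len(df) - n_test, n_test], seed)
    train = df.iloc[np.flatnonzero(assign == 0)]
    test = df.iloc[np.flatnonzero(assign == 1)]
    return train, test


def _fix_sizes(assign: np.ndarray, sizes: list[int], seed: int) -> np.ndarray:
    """Move randomly chosen rows between partitions to hit exact sizes."""
    rng = np.random.default_rng(seed + 1)
    assign = assign.copy()
    k = len(sizes)
    for _ in range(assign.size * k):
        counts = np.bincount(assign, minlength=k)
        over = np.flatnonzero(counts > np.array(sizes))
        under = np.flatnonzero(counts < np.array(sizes))
        if len(over) == 0:
            break
        src, dst = over[0], under[0]
        rows = np.flatnonzero(assign == src)
        assign[rng.choice(rows)] = dst
    return assign


def stratified_kfold(df: pd.DataFrame, schema: FeatureSchema, k: int,
                     seed: int = 0) -> list[np.ndarray]:
    """k disjoint, label-stratified folds covering the cohort.

    Returns positional row indices per fold; sizes differ by at most 1.
    """
    if k < 2:
        raise PreprocessError("k must be >= 2")
    Y = df[list(schema.label_names)].to_numpy(dtype=float)
    if (Y.sum(axis=0) < k).any():
        raise PreprocessError(
            "a label has fewer positives than folds; cannot stratify")
    assign = _greedy_assign(Y, [1.0 / k] * k, seed)
    base, extra = divmod(len(df), k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    assign = _fix_sizes(assign, sizes, seed)
    return [np.flatnonzero(assign == i) for i in range(k)]


# -- balance report -------------------------------------------------------

def balance_report(train: pd.DataFrame, test: pd.DataFrame,
                   schema: FeatureSchema) -> pd.DataFrame:
    """Compare feature marginals across partitions (cohort-table style).

    Continuous features: Welch two-sample t-test, summary "mean ± SEM".
    Binary/categorical: Pearson chi-square on the contingency table,
    summary as per-category percentages.  Features constant in both
    partitions are flagged degenerate with p = 1.0.
    """
    if len(train) == 0 or len(test) == 0:
        raise PreprocessError("both partitions must be non-empty")
    rows = []
    for f in schema.features:
        a = train[f.name].dropna()
        b = test[f.name].dropna()
        degenerate = False
        if f.kind == CONTINUOUS:
            a, b = a.astype(float), b.astype(float)
            if a.nunique() <= 1 and b.nunique() <= 1 and \
                    (a.nunique() == 0 or b.nunique() == 0 or
                     a.iloc[0] == b.iloc[0]):
                p, degenerate = 1.0, True
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            summ_a = _mean_sem(a)
            summ_b = _mean_sem(b)
        else:
            cats = (list(f.categories) if f.kind == CATEGORICAL
                    else ["0", "1"])
            ca = np.array([(a.map(_canon) == c).sum() for c in cats])
            cb = np.array([(b.map(_canon) == c).sum() for c in cats])
            table = np.vstack([ca, cb])
            nonzero = table.sum(axis=0) > 0
            if nonzero.sum() < 2:
                p, degenerate = 1.0, True
            else:
                p = float(stats.chi2_contingency(table[:, nonzero]).pvalue)
            summ_a = _percentages(ca, cats)
            summ_b = _percentages(cb, cats)
        rows.append({"feature": f.name, "train_summary": summ_a,
                     "test_summary": summ_b, "p_value": p,
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


def _mean_sem(x: pd.Series) -> str:
    sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return f"{x.mean():.2f} ± {sem:.3f}"


def _percentages(counts: np.ndarray, cats: list[str]) -> str:
    total = counts.sum()
    pct = counts / total * 100 if total else counts * 0.0
    return " ".join(f"{c} ({p:.2f}%)" for c, p in zip(cats, pct))
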