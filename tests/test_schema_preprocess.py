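"""Schema declaration, missingness screen, encoding and splitting."""

import numpy as np
import pandas as pd
import pytest

from malnet.preprocess import (PreprocessError, Preprocessor, balance_report,
                               screen_missing, split_cohort,
                               stratified_kfold)
from malnet.schema import (BINARY, CATEGORICAL, FeatureDef, FeatureSchema,
                           SchemaError, read_cohort, write_cohort)
from malnet.simulate import default_schema, generate_cohort


# -- schema ---------------------------------------------------------------

def test_schema_rejects_bad_declarations():
    with pytest.raises(SchemaError):
        FeatureSchema(features=(), label_names=("a",))
    with pytest.raises(SchemaError):
        FeatureDef("g", CATEGORICAL, ("only",))
    with pytest.raises(SchemaError):
        FeatureSchema(features=(FeatureDef("x", BINARY),
                                FeatureDef("x", BINARY)),
                      label_names=("a",))
    with pytest.raises(SchemaError):  # label/feature overlap
        FeatureSchema(features=(FeatureDef("x", BINARY),),
                      label_names=("x",))


def test_encoded_column_order_is_deterministic(tiny_schema):
    assert tiny_schema.encoded_columns() == [
        "age", "fever", "grade=a", "grade=b", "grade=c"]
    assert tiny_schema.n_encoded == 5
    # same declaration => same order and fingerprint
    clone = FeatureSchema.from_dict(tiny_schema.to_dict())
    assert clone.encoded_columns() == tiny_schema.encoded_columns()
    assert clone.fingerprint() == tiny_schema.fingerprint()


def test_schema_yaml_roundtrip(tiny_schema, tmp_path):
    path = tmp_path / "schema.yaml"
    tiny_schema.to_yaml(path)
    assert FeatureSchema.from_yaml(path) == tiny_schema


# -- missingness screen ---------------------------------------------------

@pytest.mark.parametrize("n_missing,threshold,kept", [
    (3, 0.2, True),    # 3/33 ≈ 0.091 <= 0.2
    (8, 0.2, False),   # 8/33 ≈ 0.242 > 0.2
    (1, 0.0, False),   # any missing at threshold 0
    (0, 0.0, True),
])
def test_screen_missing_fraction_rule(n_missing, threshold, kept):
    schema = default_schema()  # 33 features
    row = {f.name: (1 if f.kind == BINARY else
                    f.categories[0] if f.kind == CATEGORICAL else 50.0)
           for f in schema.features}
    for name in [f.name for f in schema.features][:n_missing]:
        row[name] = np.nan
    df = pd.DataFrame([row])
    kept_df, dropped_df = screen_missing(df, schema, threshold)
    assert (len(kept_df) == 1) == kept
    assert len(kept_df) + len(dropped_df) == 1


def test_screen_missing_preserves_order_and_partitions(tiny_schema):
    df = pd.DataFrame({
        "age": [30.0, np.nan, 41.0, np.nan],
        "fever": [1, np.nan, 0, np.nan],
        "grade": ["a", np.nan, "b", np.nan],
        "lab1": [0, 1, 0, 1], "lab2": [1, 0, 0, 1],
    })
    kept, dropped = screen_missing(df, tiny_schema, 0.5)
    assert list(kept.index) == [0, 2]
    assert list(dropped.index) == [1, 3]


# -- fit / transform ------------------------------------------------------

def test_fit_statistics(tiny_schema):
    df = pd.DataFrame({
        "age": [30.0, 40.0, np.nan],
        "fever": [1, 1, 0],
        "grade": ["a", "b", "a"],
        "lab1": [0, 1, 0], "lab2": [1, 0, 0],
    })
    prep = Preprocessor(tiny_schema).fit(df)
    assert prep.means["age"] == pytest.approx(35.0)
    assert prep.mins["age"] == 30.0 and prep.maxs["age"] == 40.0
    assert prep.modes["fever"] == 1
    assert prep.modes["grade"] == "a"


def test_fit_errors_on_all_missing_feature(tiny_schema):
    df = pd.DataFrame({"age": [np.nan, np.nan], "fever": [1, 0],
                       "grade": ["a", "b"], "lab1": [0, 1], "lab2": [1, 0]})
    with pytest.raises(PreprocessError, match="age"):
        Preprocessor(tiny_schema).fit(df)


def test_transform_minmax_scaling_and_onehot(tiny_schema):
    train = pd.DataFrame({"age": [0.0, 10.0, 5.0], "fever": [1, 0, 1],
                          "grade": ["a", "b", "c"],
                          "lab1": [1, 0, 1], "lab2": [0, 1, 0]})
    prep = Preprocessor(tiny_schema).fit(train)
    enc = prep.transform(train)
    # endpoints hit 0 and 1; midpoint at 0.5
    np.testing.assert_allclose(enc.X[:, 0], [0.0, 1.0, 0.5])
    # one-hot for categorical
    np.testing.assert_allclose(enc.X[0, 2:], [1, 0, 0])
    np.testing.assert_allclose(enc.X[1, 2:], [0, 1, 0])
    # out-of-range test value clips to [0, 1] (unclipped would be 1.2)
    test = pd.DataFrame({"age": [12.0], "fever": [0], "grade": ["b"]})
    assert prep.transform(test).X[0, 0] == 1.0


def test_transform_imputes_and_leaves_no_missing(tiny_schema, rng):
    train = pd.DataFrame({"age": [0.0, 10.0], "fever": [1, 1],
                          "grade": ["a", "b"], "lab1": [1, 0],
                          "lab2": [0, 1]})
    prep = Preprocessor(tiny_schema).fit(train)
    test = pd.DataFrame({"age": [np.nan], "fever": [np.nan],
                         "grade": [np.nan]})
    X = prep.transform(test).X
    assert np.isfinite(X).all()
    assert X[0, 0] == 0.5    # mean 5 scaled into [0,10]
    assert X[0, 1] == 1.0    # mode imputation


def test_transform_rejects_unseen_category(tiny_schema):
    train = pd.DataFrame({"age": [1.0, 2.0], "fever": [0, 1],
                          "grade": ["a", "b"], "lab1": [1, 0],
                          "lab2": [0, 1]})
    prep = Preprocessor(tiny_schema).fit(train)
    bad = pd.DataFrame({"age": [1.0], "fever": [0], "grade": ["zz"]})
    with pytest.raises((PreprocessError, SchemaError), match="zz"):
        prep.transform(bad)


def test_degenerate_constant_feature_warns(tiny_schema):
    train = pd.DataFrame({"age": [5.0, 5.0], "fever": [0, 1],
                          "grade": ["a", "b"], "lab1": [1, 0],
                          "lab2": [0, 1]})
    prep = Preprocessor(tiny_schema).fit(train)
    with pytest.warns(UserWarning, match="constant"):
        X = prep.transform(train).X
    assert (X[:, 0] == 0.0).all()


def test_column_count_invariant_across_cohorts():
    schema = default_schema()
    prep = Preprocessor(schema).fit(generate_cohort(50, seed=1))
    for seed in (2, 3):
        enc = prep.transform(generate_cohort(30, seed=seed))
        assert enc.d == schema.n_encoded
        assert (enc.X >= 0).all() and (enc.X <= 1).all()


def test_refit_on_transformed_training_data_is_stable(tiny_schema):
    """transform∘fit idempotence: re-fitting on imputed data reproduces
    the same continuous statistics."""
    train = pd.DataFrame({"age": [0.0, 10.0, np.nan], "fever": [1, 0, 1],
                          "grade": ["a", "b", "a"], "lab1": [1, 0, 1],
                          "lab2": [0, 1, 0]})
    prep = Preprocessor(tiny_schema).fit(train)
    imputed = train.copy()
    imputed["age"] = imputed["age"].fillna(prep.means["age"])
    imputed["fever"] = imputed["fever"].fillna(prep.modes["fever"])
    prep2 = Preprocessor(tiny_schema).fit(imputed)
    assert prep2.means == prep.means
    assert prep2.mins == prep.mins and prep2.maxs == prep.maxs
    assert prep2.modes == prep.modes


# -- splitting ------------------------------------------------------------

def test_split_sizes_80_20():
    df = generate_cohort(500, seed=5)
    train, test = split_cohort(df, default_schema(), 0.2, seed=5)
    assert len(train) == 400 and len(test) == 100
    assert len(set(train.index) & set(test.index)) == 0
    assert set(train.index) | set(test.index) == set(df.index)


def test_split_is_deterministic_per_seed():
    df = generate_cohort(200, seed=8)
    s = default_schema()
    a1, b1 = split_cohort(df, s, 0.2, seed=42)
    a2, b2 = split_cohort(df, s, 0.2, seed=42)
    assert list(a1.index) == list(a2.index)
    assert list(b1.index) == list(b2.index)
    a3, _ = split_cohort(df, s, 0.2, seed=43)
    assert list(a1.index) != list(a3.index)


def test_split_keeps_subtype_prevalence_within_5pp():
    from malnet.simulate import rare_label_link
    s = default_schema()
    df = generate_cohort(500, link=rare_label_link(), seed=9)
    train, test = split_cohort(df, s, 0.2, seed=9)
    for name in s.label_names:
        overall = df[name].mean()
        assert abs(train[name].mean() - overall) <= 0.05
        assert abs(test[name].mean() - overall) <= 0.05


def test_kfold_partitions_cohort():
    s = default_schema()
    df = generate_cohort(500, seed=11)
    folds = stratified_kfold(df, s, k=5, seed=11)
    assert [len(f) for f in folds] == [100] * 5
    all_idx = np.concatenate(folds)
    assert len(all_idx) == 500 and len(set(all_idx)) == 500
    # determinism
    folds2 = stratified_kfold(df, s, k=5, seed=11)
    for f1, f2 in zip(folds, folds2):
        np.testing.assert_array_equal(f1, f2)


# -- balance report -------------------------------------------------------

def test_balance_report_identical_partitions(tiny_schema):
    df = pd.DataFrame({"age": [30.0, 40.0, 50.0], "fever": [1, 0, 1],
                       "grade": ["a", "b", "c"], "lab1": [1, 0, 1],
                       "lab2": [0, 1, 0]})
    rep = balance_report(df, df.copy(), tiny_schema)
    assert (rep["p_value"] == 1.0).all()


def test_balance_report_flags_constant_feature(tiny_schema):
    df = pd.DataFrame({"age": [5.0] * 4, "fever": [1] * 4,
                       "grade": ["a"] * 4, "lab1": [1, 0, 1, 0],
                       "lab2": [0, 1, 0, 1]})
    rep = balance_report(df, df.copy(), tiny_schema).set_index("feature")
    assert rep.loc["age", "degenerate"]
    assert rep.loc["age", "p_value"] == 1.0
    assert rep.loc["fever", "degenerate"]


def test_balance_report_null_distribution():
    """Partitions drawn from one distribution: >90% of p-values > 0.05."""
    s = default_schema()
    df = generate_cohort(2000, seed=21)
    train, test = split_cohort(df, s, 0.5, seed=21)
    rep = balance_report(train, test, s)
    assert (rep["p_value"] > 0.05).mean() > 0.9


# -- cohort CSV round-trip -------------------------------------------------

def test_cohort_csv_roundtrip(tmp_path):
    s = default_schema()
    df = generate_cohort(40, seed=13)
    from malnet.simulate import inject_missingness
    df = inject_missingness(df, 0.1, seed=13)
    path = tmp_path / "cohort.csv"
    write_cohort(df, path)
    back = read_cohort(path, s)
    for f in s.features:
        a, b = df[f.name], back[f.name]
        assert (a.isna() == b.isna()).all()
        if f.kind == CATEGORICAL:
            assert (a.dropna().map(str).to_numpy()
                    == b.dropna().map(str).to_numpy()).all()
        else:
            np.testing.assert_allclose(a.dropna().astype(float),
                                       b.dropna().astype(float), rtol=1e-9)
    pd.testing.assert_frame_equal(
        df[list(s.label_names)].astype(int),
        back[list(s.label_names)].astype(int))
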