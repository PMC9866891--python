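"""Splitting, scaling, OLS and GA subset selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pfascreen.modeling import (
    Dataset,
    GASettings,
    MLRModel,
    NoFeasibleSubsetError,
    ZeroVarianceError,
    fit,
    fit_mlr,
    ga_select,
    loo_predictions,
    split_one_to_z,
    standard_scale,
)
from pfascreen.validation import loo_cv


def toy_dataset(X: np.ndarray, y=None, names=None) -> Dataset:
    names = names or [f"d{i}" for i in range(X.shape[1])]
    n = len(X)
    return Dataset(
        ids=[f"c{i}" for i in range(n)],
        smiles=["C"] * n,
        X=pd.DataFrame(X, columns=names),
        y=y,
    )


# ---------------------------------------------------------------- splitting

@pytest.mark.parametrize("n, z, n_val", [(43, 3, 14), (43, 4, 10), (5, 5, 1)])
def test_split_sizes(n, z, n_val):
    rng = np.random.default_rng(0)
    ds = toy_dataset(rng.normal(size=(n, 2)), y=rng.normal(size=n))
    sp = split_one_to_z(ds, z)
    assert len(sp.val_idx) == n_val == n // z
    assert len(sp.train_idx) == n - n_val
    assert set(sp.train_idx) | set(sp.val_idx) == set(range(n))
    assert set(sp.train_idx) & set(sp.val_idx) == set()


def test_split_takes_every_zth_in_endpoint_order():
    y = np.array([5.0, 1.0, 4.0, 2.0, 3.0, 0.0])
    ds = toy_dataset(np.zeros((6, 1)) + np.arange(6)[:, None], y=y)
    sp = split_one_to_z(ds, 3)
    # ascending order is rows [5,1,3,4,2,0]; positions 3 and 6 -> rows 3, 0
    assert sorted(sp.val_idx) == [0, 3]


def test_split_n5_z5_takes_largest_endpoint_row():
    y = np.array([0.0, 3.0, 1.0, 9.0, 2.0])
    ds = toy_dataset(np.arange(10.0).reshape(5, 2), y=y)
    sp = split_one_to_z(ds, 5)
    assert list(sp.val_idx) == [3]


def test_split_rejects_empty_validation_and_missing_endpoint():
    ds = toy_dataset(np.arange(8.0).reshape(4, 2), y=np.arange(4.0))
    with pytest.raises(ValueError):
        split_one_to_z(ds, 5)
    with pytest.raises(ValueError):
        split_one_to_z(toy_dataset(np.arange(8.0).reshape(4, 2)), 2)


# ------------------------------------------------------------------ scaling

def test_standard_scale_unit_stats_and_reuse():
    X = np.array([[1.0, 10.0], [2.0, 30.0], [3.0, 20.0]])
    Z, means, sds = standard_scale(X)
    assert np.allclose(Z.mean(axis=0), 0.0)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0)
    assert np.allclose(Z[:, 0], [-1.0, 0.0, 1.0])  # SD of [1,2,3] is 1 (n-1)
    row = means[None, :]
    Zrow, _, _ = standard_scale(row, means, sds)
    assert np.allclose(Zrow, 0.0)


def test_standard_scale_names_zero_variance_column():
    X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
    with pytest.raises(ZeroVarianceError, match="flat"):
        standard_scale(X)


# ---------------------------------------------------------------------- OLS

def test_fit_mlr_recovers_noiseless_coefficients():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(10, 2))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    y = 2.0 + 3.0 * Z[:, 0] - 1.0 * Z[:, 1]
    b0, b, se0, se = fit_mlr(Z, y)
    assert b0 == pytest.approx(2.0, abs=1e-10)
    assert np.allclose(b, [3.0, -1.0], atol=1e-10)
    assert se0 == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(se, 0.0, atol=1e-8)


def test_intercept_equals_mean_response_for_standardized_predictors():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(15, 3))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    y = rng.normal(size=15)
    b0, _, _, _ = fit_mlr(Z, y)
    assert b0 == pytest.approx(y.mean(), abs=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10**6))
def test_fit_mlr_matches_statsmodels(seed):
    """Independent oracle: statsmodels OLS on the same design."""
    rng = np.random.default_rng(seed)
    n, p = int(rng.integers(8, 25)), int(rng.integers(1, 4))
    Z = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    b0, b, se0, se = fit_mlr(Z, y)
    ref = sm.OLS(y, sm.add_constant(Z)).fit()
    assert np.allclose([b0, *b], ref.params, atol=1e-10)
    assert np.allclose([se0, *se], ref.bse, atol=1e-10)


def test_fit_mlr_names_collinear_columns():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    ds = toy_dataset(np.column_stack([x, 2 * x]), y=rng.normal(size=12),
                     names=["a", "b"])
    with pytest.raises(Exception, match="a.*b|rank"):
        fit(ds, ("a", "b"))


def test_parameter_recovery_with_noise():
    rng = np.random.default_rng(4)
    Z = rng.normal(size=(43, 2))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    y = -7.5 - 0.9 * Z[:, 0] - 0.4 * Z[:, 1] + rng.normal(0, 0.35, size=43)
    b0, b, _, se = fit_mlr(Z, y)
    assert abs(b[0] + 0.9) < 2.5 * se[0] + 1e-9
    assert abs(b[1] + 0.4) < 2.5 * se[1] + 1e-9


# ------------------------------------------------------------------ predict

def test_predict_centroid_and_affinity(benchmark):
    model = fit(benchmark, ("ICR", "PW2"))
    centroid = pd.DataFrame(
        [model.scaler_means], columns=["ICR", "PW2"]
    )
    assert model.predict(centroid)[0] == pytest.approx(model.intercept, abs=1e-12)

    x1 = benchmark.X.iloc[[0]][["ICR", "PW2"]]
    x2 = benchmark.X.iloc[[7]][["ICR", "PW2"]]
    alpha = 0.3
    blend = alpha * x1.to_numpy() + (1 - alpha) * x2.to_numpy()
    blended = pd.DataFrame(blend, columns=["ICR", "PW2"])
    expected = alpha * model.predict(x1)[0] + (1 - alpha) * model.predict(x2)[0]
    assert model.predict(blended)[0] == pytest.approx(expected, abs=1e-10)


def test_predict_requires_descriptor_columns(benchmark):
    model = fit(benchmark, ("ICR", "PW2"))
    with pytest.raises(KeyError, match="PW2"):
        model.predict(benchmark.X[["ICR"]])


def test_model_serialization_bit_exact_roundtrip(tmp_path, benchmark):
    model = fit(benchmark, ("ICR", "PW2"))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = MLRModel.load(path)
    assert loaded.descriptor_names == model.descriptor_names
    assert loaded.intercept == model.intercept
    assert np.array_equal(loaded.coefficients, model.coefficients)
    assert np.array_equal(loaded.coefficient_ses, model.coefficient_ses)
    assert np.array_equal(loaded.scaler_means, model.scaler_means)
    assert np.array_equal(loaded.scaler_sds, model.scaler_sds)
    assert loaded.n_train == model.n_train


# ----------------------------------------------------------------------- GA

def exhaustive_select(ds, pool, k=2, cap=0.6):
    """Oracle: scan all feasible subsets for the best LOO Q2."""
    corr = ds.X[list(pool)].corr().abs()
    best, best_q = None, -np.inf
    for subset in itertools.combinations(pool, k):
        if k > 1 and any(
            corr.loc[a, b] > cap for a, b in itertools.combinations(subset, 2)
        ):
            continue
        q = loo_cv(ds, subset)[0]
        if q > best_q:
            best, best_q = tuple(subset), q
    return best


def with_noise_columns(ds, n_noise, seed):
    rng = np.random.default_rng(seed)
    X = ds.X.copy()
    for i in range(n_noise):
        X[f"noise{i}"] = rng.normal(size=ds.n)
    return Dataset(ids=ds.ids, smiles=ds.smiles, X=X, y=ds.y)


def test_ga_finds_true_pair_among_noise(benchmark):
    ds = with_noise_columns(benchmark, 3, seed=21)
    pool = ["ICR", "PW2", "noise0", "noise1", "noise2"]
    chosen = ga_select(ds, pool, seed=9)
    assert set(chosen) == {"ICR", "PW2"}
    assert chosen == exhaustive_select(ds, pool)


def test_ga_matches_exhaustive_on_pool_of_twelve(benchmark):
    ds = with_noise_columns(benchmark, 3, seed=22)
    pool = list(benchmark.X.columns) + ["noise0", "noise1", "noise2"]
    assert len(pool) == 12
    assert ga_select(ds, pool, seed=10) == exhaustive_select(ds, pool)


def test_ga_subset_size_one_equals_scan(benchmark):
    cfg = GASettings(subset_size=1)
    chosen = ga_select(benchmark, list(benchmark.X.columns), cfg, seed=3)
    best = max(
        benchmark.X.columns, key=lambda c: loo_cv(benchmark, (c,))[0]
    )
    assert chosen == (best,)


def test_ga_rejects_pool_with_no_feasible_pair():
    rng = np.random.default_rng(6)
    x = rng.normal(size=20)
    ds = toy_dataset(
        np.column_stack([x, x + 0.01 * rng.normal(size=20)]),
        y=rng.normal(size=20),
        names=["a", "b"],
    )
    assert abs(np.corrcoef(ds.X["a"], ds.X["b"])[0, 1]) > 0.9
    with pytest.raises(NoFeasibleSubsetError):
        ga_select(ds, ["a", "b"], seed=1)


def test_ga_deterministic_given_seed(benchmark):
    ds = with_noise_columns(benchmark, 3, seed=23)
    pool = list(ds.X.columns)
    assert ga_select(ds, pool, seed=42) == ga_select(ds, pool, seed=42)


def test_ga_requires_seed(benchmark):
    with pytest.raises(ValueError, match="seed"):
        ga_select(benchmark, list(benchmark.X.columns))


# ----------------------------------------------------------------- LOO core

def test_loo_predictions_exact_on_noiseless_data():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(12, 2))
    y = 1.0 + X @ np.array([2.0, -1.0])
    ds = toy_dataset(X, y=y)
    preds = loo_predictions(ds, ("d0", "d1"))
    assert np.allclose(preds, y, atol=1e-9)
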