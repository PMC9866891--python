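"""Model quality statistics: goodness of fit, leave-one-out cross-validation,
external validation (Q2 F1/F2/F3, CCC) and Y-randomization.

Conventions, chosen to match standard QSAR reporting:

* RMSE uses the plain 1/n denominator on every set (calibration,
  cross-validation, external).
* Q2_LOO = 1 - PRESS / SST, with SST about the full training mean.
* Lin's concordance correlation coefficient uses sample (1/n) moments.
* The Y-randomization statistic is the mean R2 over seeded endpoint
  permutations; for p predictors and n rows its chance expectation is
  about p/(n - 1), which is what a sound model must stay far above.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .modeling import Dataset, MLRModel, loo_predictions, standard_scale


def r2_score(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R2 undefined: endpoint is constant")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    d = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean(d**2)))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    d = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.mean(np.abs(d)))


def ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (sample-moment form)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    my, mp = y.mean(), yhat.mean()
    sy = np.mean((y - my) ** 2)
    sp = np.mean((yhat - mp) ** 2)
    syp = np.mean((y - my) * (yhat - mp))
    return float(2.0 * syp / (sy + sp + (my - mp) ** 2))


@dataclass
class ValidationReport:
    """The full statistics block for one receptor model (RMSE/MAE in
    kcal/mol, everything else dimensionless)."""

    r2: float
    rmse_c: float
    mae_c: float
    q2_loo: float
    rmse_cv: float
    mae_cv: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    rmse_ext: float
    mae_ext: float
    ccc_ext: float
    r2_yscr: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def format_table(self, precision: int = 3) -> str:
        """Text table in the conventional reporting layout."""
        labels = {
            "r2": "R2",
            "rmse_c": "RMSE_C",
            "mae_c": "MAE_C",
            "q2_loo": "Q2_LOO",
            "rmse_cv": "RMSE_CV",
            "mae_cv": "MAE_CV",
            "q2_f1": "Q2_F1",
            "q2_f2": "Q2_F2",
            "q2_f3": "Q2_F3",
            "rmse_ext": "RMSE_EXT",
            "mae_ext": "MAE_EXT",
            "ccc_ext": "CCC_EXT",
            "r2_yscr": "R2_YSCR",
        }
        lines = [
            f"{labels[k]:<10}{v:.{precision}f}" for k, v in self.to_dict().items()
        ]
        return "\n".join(lines)


def goodness_of_fit(
    model: MLRModel, train: Dataset
) -> tuple[float, float, float]:
    """(R2, RMSE_C, MAE_C) of the calibrated model on its training set."""
    if train.y is None:
        raise ValueError("goodness of fit requires an endpoint")
    yhat = model.predict(train.X)
    return r2_score(train.y, yhat), rmse(train.y, yhat), mae(train.y, yhat)


def loo_cv(
    train: Dataset, names: tuple[str, ...] | list[str]
) -> tuple[float, float, float]:
    """(Q2_LOO, RMSE_CV, MAE_CV) with scaler and model refit per fold."""
    names = tuple(names)
    if train.n < len(names) + 3:
        raise ValueError("too few training rows for leave-one-out")
    preds = loo_predictions(train, names)
    press = float(np.sum((train.y - preds) ** 2))
    sst = float(np.sum((train.y - train.y.mean()) ** 2))
    return 1.0 - press / sst, rmse(train.y, preds), mae(train.y, preds)


def external_validation(
    model: MLRModel, val: Dataset, train_ref: Dataset
) -> tuple[float, float, float, float, float, float]:
    """External predictivity: (Q2_F1, Q2_F2, Q2_F3, RMSE_EXT, MAE_EXT, CCC_EXT).

    F1 references the training mean, F2 the external mean, and F3 compares
    per-compound external error against training-set endpoint variance.
    """
    if val.n == 0:
        raise ValueError("empty validation set")
    if val.y is None or train_ref.y is None:
        raise ValueError("external validation requires endpoints on both sets")
    yhat = model.predict(val.X)
    y = val.y
    sse = float(np.sum((y - yhat) ** 2))
    y_tr_mean = float(train_ref.y.mean())
    q2_f1 = 1.0 - sse / float(np.sum((y - y_tr_mean) ** 2))
    q2_f2 = 1.0 - sse / float(np.sum((y - y.mean()) ** 2))
    q2_f3 = 1.0 - (sse / val.n) / (
        float(np.sum((train_ref.y - y_tr_mean) ** 2)) / train_ref.n
    )
    return q2_f1, q2_f2, q2_f3, rmse(y, yhat), mae(y, yhat), ccc(y, yhat)


def y_scramble(
    train: Dataset,
    names: tuple[str, ...] | list[str],
    n_iter: int = 1000,
    seed: int | None = None,
) -> float:
    """Mean R2 over ``n_iter`` seeded random permutations of the endpoint.

    The identity permutation is not excluded; with enough iterations its
    weight vanishes.  The design is fixed, so each permutation only needs
    one projection onto the column space (R2 is invariant to how the
    predictors are scaled).
    """
    if n_iter < 100:
        raise ValueError("use at least 100 scrambling iterations")
    if seed is None:
        raise ValueError("y_scramble requires an explicit seed")
    if train.y is None:
        raise ValueError("Y-randomization requires an endpoint")
    rng = np.random.default_rng(seed)
    names = tuple(names)
    Zs, _, _ = standard_scale(train.X[list(names)].to_numpy(dtype=float))
    n = train.n
    design = np.column_stack([np.ones(n), Zs])
    q, _ = np.linalg.qr(design)
    r2s = np.empty(n_iter)
    y = train.y
    sst = float(np.sum((y - y.mean()) ** 2))  # permutation-invariant
    for i in range(n_iter):
        yp = rng.permutation(y)
        resid = yp - q @ (q.T @ yp)
        r2s[i] = 1.0 - float(resid @ resid) / sst
    return float(r2s.mean())


def validate_model(
    model: MLRModel,
    train: Dataset,
    val: Dataset,
    seed: int,
    n_scrambles: int = 1000,
) -> ValidationReport:
    """Assemble the full report for a fitted model and its data split."""
    r2, rmse_c, mae_c = goodness_of_fit(model, train)
    q2, rmse_cv, mae_cv = loo_cv(train, model.descriptor_names)
    f1, f2, f3, rmse_e, mae_e, ccc_e = external_validation(model, val, train)
    yscr = y_scramble(train, model.descriptor_names, n_iter=n_scrambles, seed=seed)
    return ValidationReport(
        r2=r2,
        rmse_c=rmse_c,
        mae_c=mae_c,
        q2_loo=q2,
        rmse_cv=rmse_cv,
        mae_cv=mae_cv,
        q2_f1=f1,
        q2_f2=f2,
        q2_f3=f3,
        rmse_ext=rmse_e,
        mae_ext=mae_e,
        ccc_ext=ccc_e,
        r2_yscr=yscr,
    )
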