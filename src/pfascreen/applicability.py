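"""Leverage-based applicability-domain assessment.

A prediction is trustworthy only for compounds structurally similar to the
calibration set.  Similarity is measured by the leverage h — the hat-matrix
diagonal of the compound's standardized descriptor vector — against the
critical value h* = 3(p + 1)/n.  Labeled compounds are additionally judged
by their standardized residual (the Williams-plot axes); unlabeled
screening compounds by whether their predicted score falls inside the
calibration endpoint range (the Insubria-graph logic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modeling import Dataset, MLRModel, RankDeficientError

IN_DOMAIN = "in-domain"
HIGH_LEVERAGE = "high-leverage"
RESIDUAL_OUTLIER = "residual-outlier"
OUT_OF_RANGE = "out-of-range"


@dataclass
class ADResult:
    """Applicability-domain verdict for one query compound."""

    id: str
    h: float
    z: float | None  # standardized residual; None for unlabeled compounds
    predicted: float
    h_star: float
    in_domain: bool
    reason: str


def leverage(train_Xs: np.ndarray, query_Xs: np.ndarray) -> np.ndarray:
    """Leverages h = x'(X'X)^-1 x with an intercept column in both X and x.

    ``train_Xs`` and ``query_Xs`` must already be in the same standardized
    descriptor space.  Training rows' leverages sum to p + 1 (hat-matrix
    trace); a query at the training centroid has h = 1/n.
    """
    train_Xs = np.atleast_2d(np.asarray(train_Xs, dtype=float))
    query_Xs = np.atleast_2d(np.asarray(query_Xs, dtype=float))
    n = train_Xs.shape[0]
    X = np.column_stack([np.ones(n), train_Xs])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise RankDeficientError("X'X is singular; cannot compute leverages")
    xtx_inv = np.linalg.inv(xtx)
    Q = np.column_stack([np.ones(query_Xs.shape[0]), query_Xs])
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def critical_leverage(n: int, p: int) -> float:
    """Warning leverage h* = 3(p + 1)/n for n training rows, p descriptors."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    return 3.0 * (p + 1) / n


def standardized_residuals(
    y: np.ndarray, yhat: np.ndarray, scale_rmse: float
) -> np.ndarray:
    """Residuals divided by the RMSE of the set the compounds belong to.

    With a zero RMSE all residuals are necessarily zero, so zeros are
    returned rather than dividing by zero.
    """
    resid = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    if scale_rmse == 0.0:
        return np.zeros_like(resid)
    return resid / scale_rmse


def assess_domain(
    model: MLRModel,
    train: Dataset,
    query: Dataset,
    range_basis: str = "observed",
    residual_cutoff: float = 3.0,
) -> list[ADResult]:
    """Classify each query compound as in- or out-of-domain.

    Rules (reason codes in priority order):

    * ``high-leverage`` — h >= h* (strict h < h* is required to stay in
      domain; boundary equality is out).
    * ``residual-outlier`` — labeled compounds with |standardized residual|
      above ``residual_cutoff`` (the +/-3 sigma Williams band).
    * ``out-of-range`` — unlabeled compounds whose predicted score falls
      outside the calibration endpoint range.  ``range_basis`` selects the
      observed training endpoints (default) or the model's predictions on
      the training set.
    """
    if range_basis not in ("observed", "predicted"):
        raise ValueError("range_basis must be 'observed' or 'predicted'")
    train_Z = model.transform(train.X)
    query_Z = model.transform(query.X)
    h_query = leverage(train_Z, query_Z)
    h_star = critical_leverage(train.n, model.p)
    preds = model.predict_scaled(query_Z)

    if range_basis == "observed":
        if train.y is None:
            raise ValueError("observed range basis requires a labeled training set")
        lo, hi = float(train.y.min()), float(train.y.max())
    else:
        train_pred = model.predict_scaled(train_Z)
        lo, hi = float(train_pred.min()), float(train_pred.max())

    z_vals: np.ndarray | None = None
    if query.y is not None:
        set_rmse = float(np.sqrt(np.mean((query.y - preds) ** 2)))
        z_vals = standardized_residuals(query.y, preds, set_rmse)

    results = []
    for i in range(query.n):
        z = float(z_vals[i]) if z_vals is not None else None
        if h_query[i] >= h_star:
            ok, reason = False, HIGH_LEVERAGE
        elif z is not None and abs(z) > residual_cutoff:
            ok, reason = False, RESIDUAL_OUTLIER
        elif z is None and not (lo <= preds[i] <= hi):
            ok, reason = False, OUT_OF_RANGE
        else:
            ok, reason = True, IN_DOMAIN
        results.append(
            ADResult(
                id=query.ids[i],
                h=float(h_query[i]),
                z=z,
                predicted=float(preds[i]),
                h_star=h_star,
                in_domain=ok,
                reason=reason,
            )
        )
    return results


def ad_table(results: list[ADResult]) -> pd.DataFrame:
    """Plot-ready Williams/Insubria export (one row per compound)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "h": [r.h for r in results],
            "z": [r.z for r in results],
            "predicted_bs_kcal_mol": [r.predicted for r in results],
            "h_star": [r.h_star for r in results],
            "in_domain": [r.in_domain for r in results],
            "reason": [r.reason for r in results],
        }
    )
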