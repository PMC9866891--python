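"""Dataset handling, 1:Z splitting, standard scaling, MLR fitting and
genetic-algorithm descriptor selection.

The regression always operates in standardized descriptor space: predictors
are centered and scaled by training-set statistics (sample SD, n-1
denominator), so the fitted coefficients are directly comparable effect
sizes in kcal/mol per standard deviation, matching how the published
receptor equations are written.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ZeroVarianceError(ValueError):
    """A descriptor column is constant on the fitting set."""


class RankDeficientError(ValueError):
    """The scaled design matrix is not full rank (collinear descriptors)."""


class NoFeasibleSubsetError(ValueError):
    """No descriptor subset satisfies the pairwise-correlation cap."""


@dataclass
class Dataset:
    """Compound identifiers, structures, descriptor matrix and optional
    docking-score endpoint (kcal/mol, more negative = stronger binding)."""

    ids: list[str]
    smiles: list[str]
    X: pd.DataFrame
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.X):
            raise ValueError("ids and descriptor matrix length mismatch")
        if len(self.smiles) != len(self.X):
            raise ValueError("smiles and descriptor matrix length mismatch")
        if self.X.isna().any().any():
            raise ValueError("descriptor matrix contains missing values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if len(self.y) != len(self.X):
                raise ValueError("endpoint length mismatch")

    @property
    def n(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(
            ids=[self.ids[i] for i in idx],
            smiles=[self.smiles[i] for i in idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            y=None if self.y is None else self.y[idx],
        )


def dataset_from_table(table: pd.DataFrame, y_column: str | None = None) -> Dataset:
    """Build a Dataset from a descriptor table (as produced by
    :func:`pfascreen.descriptors.descriptor_table`), optionally pulling the
    endpoint out of ``y_column``."""
    meta = {"id", "smiles"}
    if y_column is not None:
        meta.add(y_column)
    desc_cols = [c for c in table.columns if c not in meta]
    return Dataset(
        ids=[str(v) for v in table["id"]],
        smiles=[str(v) for v in table["smiles"]],
        X=table[desc_cols].astype(float).reset_index(drop=True),
        y=table[y_column].to_numpy(dtype=float) if y_column else None,
    )


@dataclass(frozen=True)
class SplitResult:
    """Training/validation row indices from the 1:Z endpoint-ordered split."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    z: int


def split_one_to_z(ds: Dataset, z: int) -> SplitResult:
    """Endpoint-ordered systematic split: sort rows ascending by docking
    score (stable, so input order breaks ties) and send every Z-th compound
    (1-based positions Z, 2Z, 3Z, ...) to the validation set.

    With n = 43 this yields 29/14 at Z = 3 and 33/10 at Z = 4.
    """
    if ds.y is None:
        raise ValueError("1:Z split requires an endpoint")
    if z < 2:
        raise ValueError("Z must be >= 2")
    if z > ds.n:
        raise ValueError(f"Z = {z} exceeds dataset size {ds.n}: empty validation set")
    order = np.argsort(ds.y, kind="stable")
    val = order[z - 1 :: z]
    mask = np.ones(ds.n, dtype=bool)
    mask[val] = False
    train = np.arange(ds.n)[mask]
    return SplitResult(train_idx=train, val_idx=np.sort(val), z=z)


def standard_scale(
    X: pd.DataFrame | np.ndarray,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise (x - mean)/SD scaling with the sample (n-1) SD.

    Without explicit ``means``/``sds`` the statistics are estimated from
    ``X`` itself (the fitting set); pass stored training statistics to
    transform validation or screening data consistently.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    arr = np.asarray(X, dtype=float)
    if means is None:
        means = arr.mean(axis=0)
        with np.errstate(invalid="ignore"):
            sds = arr.std(axis=0, ddof=1)
        # a single-row set has an undefined sample SD: treat as zero variance
        bad = np.flatnonzero(~np.isfinite(sds) | (sds == 0.0))
        if bad.size:
            labels = [names[i] if names else str(i) for i in bad]
            raise ZeroVarianceError(
                f"zero-variance descriptor column(s): {', '.join(labels)}"
            )
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    return (arr - means) / sds, means, sds


@dataclass
class MLRModel:
    """Ordinary-least-squares model in standardized descriptor space.

    ``intercept`` and ``coefficients`` are in kcal/mol (per SD of the raw
    descriptor for the coefficients); scaler parameters are stored so the
    model maps raw descriptor rows to predictions.
    """

    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    intercept_se: float
    coefficient_ses: np.ndarray
    scaler_means: np.ndarray
    scaler_sds: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.coefficient_ses = np.asarray(self.coefficient_ses, dtype=float)
        self.scaler_means = np.asarray(self.scaler_means, dtype=float)
        self.scaler_sds = np.asarray(self.scaler_sds, dtype=float)
        if self.p < 1 or len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("coefficient count must match descriptor names")
        if np.any(self.scaler_sds <= 0):
            raise ValueError("scaler SDs must be positive")

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.descriptor_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor column(s): {', '.join(missing)}")
        raw = X[list(self.descriptor_names)].to_numpy(dtype=float)
        z, _, _ = standard_scale(raw, self.scaler_means, self.scaler_sds)
        return z

    def predict_scaled(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.intercept + Z @ self.coefficients

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict docking scores (kcal/mol) for raw descriptor rows."""
        return self.predict_scaled(self.transform(X))

    # -- serialization: flat JSON document, bit-exact round trip ----------

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "intercept_se": self.intercept_se,
            "coefficient_ses": self.coefficient_ses.tolist(),
            "scaler_means": self.scaler_means.tolist(),
            "scaler_sds": self.scaler_sds.tolist(),
            "n_train": self.n_train,
            "p": self.p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept_se=float(d["intercept_se"]),
            coefficient_ses=np.asarray(d["coefficient_ses"], dtype=float),
            scaler_means=np.asarray(d["scaler_means"], dtype=float),
            scaler_sds=np.asarray(d["scaler_sds"], dtype=float),
            n_train=int(d["n_train"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "MLRModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # point at the most correlated descriptor pair as the likely culprit
        worst, pair = 0.0, None
        for i, j in itertools.combinations(range(1, design.shape[1]), 2):
            r = abs(np.corrcoef(design[:, i], design[:, j])[0, 1])
            if r > worst:
                worst, pair = r, (names[i - 1], names[j - 1])
        hint = f" (collinear: {pair[0]} vs {pair[1]}, |r| = {worst:.4f})" if pair else ""
        raise RankDeficientError(f"design matrix is rank deficient{hint}")


def fit_mlr(
    Xs: np.ndarray, y: np.ndarray, names: tuple[str, ...] | None = None
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """OLS on an already standardized design.

    Returns ``(intercept, coefficients, intercept_se, coefficient_ses)``.
    Standard errors use the residual variance with n - p - 1 degrees of
    freedom; with standardized predictors the intercept equals mean(y).
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xs.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n = {n}, p = {p})")
    design = np.column_stack([np.ones(n), Xs])
    _check_rank(design, list(names) if names else [f"x{i}" for i in range(p)])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sse = float(resid @ resid)
    s2 = sse / (n - p - 1)
    cov = s2 * np.linalg.inv(design.T @ design)
    ses = np.sqrt(np.diag(cov))
    return float(beta[0]), beta[1:], float(ses[0]), ses[1:]


def fit(ds: Dataset, names: tuple[str, ...] | list[str]) -> MLRModel:
    """Scale the selected descriptor columns on ``ds`` and fit the MLR."""
    if ds.y is None:
        raise ValueError("fitting requires an endpoint")
    names = tuple(names)
    raw = ds.X[list(names)].to_numpy(dtype=float)
    Zs, means, sds = standard_scale(raw)
    b0, b, se0, se = fit_mlr(Zs, ds.y, names)
    return MLRModel(
        descriptor_names=names,
        intercept=b0,
        coefficients=b,
        intercept_se=se0,
        coefficient_ses=se,
        scaler_means=means,
        scaler_sds=sds,
        n_train=ds.n,
    )


def loo_predictions(ds: Dataset, names: tuple[str, ...] | list[str]) -> np.ndarray:
    """Leave-one-out predictions with the scaler refit inside every fold.

    Each held-out compound is predicted by a model (scaling included)
    calibrated on the remaining n - 1 rows, so no information leaks from
    the left-out row.
    """
    if ds.y is None:
        raise ValueError("LOO requires an endpoint")
    names = tuple(names)
    raw = ds.X[list(names)].to_numpy(dtype=float)
    n = ds.n
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            Zs, means, sds = standard_scale(raw[mask])
            b0, b, _, _ = fit_mlr(Zs, ds.y[mask], names)
        except (ZeroVarianceError, RankDeficientError) as exc:
            raise RankDeficientError(
                f"LOO refit failed with compound {ds.ids[i]!r} left out: {exc}"
            ) from exc
        z = (raw[i] - means) / sds
        preds[i] = b0 + z @ b
    return preds


def _q2_loo(ds: Dataset, names: tuple[str, ...]) -> float:
    preds = loo_predictions(ds, names)
    press = float(np.sum((ds.y - preds) ** 2))
    sst = float(np.sum((ds.y - ds.y.mean()) ** 2))
    return 1.0 - press / sst


@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm configuration for fixed-size subset selection.

    Fitness is the leave-one-out Q2 of the candidate subset; subsets in
    which any descriptor pair has |Pearson r| above ``corr_cap`` are
    infeasible outright (hard constraint, not a penalty).
    """

    subset_size: int = 2
    population: int = 50
    generations: int = 100
    tournament: int = 3
    crossover_rate: float = 0.5
    mutation_rate: float = 0.01
    corr_cap: float = 0.6
    elitism: int = 1


def _feasible(subset: tuple[int, ...], corr: np.ndarray, cap: float) -> bool:
    return all(
        abs(corr[i, j]) <= cap for i, j in itertools.combinations(subset, 2)
    )


def ga_select(
    ds: Dataset,
    pool: list[str] | tuple[str, ...],
    cfg: GASettings | None = None,
    seed: int | None = None,
) -> tuple[str, ...]:
    """Select the descriptor subset maximizing leave-one-out Q2.

    Deterministic for a given ``seed``.  On the small pools this package
    works with, the GA reproduces exhaustive search; it exists so the same
    interface scales to larger pools.
    """
    if cfg is None:
        cfg = GASettings()
    if seed is None:
        raise ValueError("ga_select requires an explicit seed")
    if ds.y is None:
        raise ValueError("descriptor selection requires an endpoint")
    pool = list(pool)
    k = cfg.subset_size
    if len(pool) < k:
        raise ValueError("pool smaller than requested subset size")
    rng = np.random.default_rng(seed)
    raw = ds.X[pool].to_numpy(dtype=float)
    corr = np.corrcoef(raw, rowvar=False)
    if corr.ndim == 0:  # single-column pool
        corr = np.ones((1, 1))

    n_idx = len(pool)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: tuple[int, ...]) -> float:
        subset = tuple(sorted(subset))
        if subset in cache:
            return cache[subset]
        if k > 1 and not _feasible(subset, corr, cfg.corr_cap):
            score = -math.inf
        else:
            try:
                score = _q2_loo(ds, tuple(pool[i] for i in subset))
            except (ZeroVarianceError, RankDeficientError):
                score = -math.inf
        cache[subset] = score
        return score

    def random_feasible() -> tuple[int, ...] | None:
        for _ in range(200):
            cand = tuple(sorted(rng.choice(n_idx, size=k, replace=False)))
            if k == 1 or _feasible(cand, corr, cfg.corr_cap):
                return cand
        return None

    # seed the population; fall back to a scan if rejection sampling fails
    population: list[tuple[int, ...]] = []
    for _ in range(cfg.population):
        cand = random_feasible()
        if cand is not None:
            population.append(cand)
    if not population:
        for cand in itertools.combinations(range(n_idx), k):
            if _feasible(cand, corr, cfg.corr_cap):
                population = [cand] * cfg.population
                break
        else:
            raise NoFeasibleSubsetError(
                f"no {k}-descriptor subset satisfies |r| <= {cfg.corr_cap}"
            )

    def tournament() -> tuple[int, ...]:
        picks = rng.integers(0, len(population), size=cfg.tournament)
        return max((population[i] for i in picks), key=fitness)

    for _ in range(cfg.generations):
        scored = sorted(population, key=fitness, reverse=True)
        nxt: list[tuple[int, ...]] = scored[: cfg.elitism]
        while len(nxt) < cfg.population:
            a, b = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                common = set(a) & set(b)
                rest = list((set(a) | set(b)) - common)
                need = k - len(common)
                child = set(common)
                if need > 0:
                    child |= set(rng.choice(rest, size=need, replace=False))
            else:
                child = set(a)
            # mutation: swap a member for a random outsider
            child = set(child)
            for gene in sorted(child):
                if rng.random() < cfg.mutation_rate:
                    outside = [i for i in range(n_idx) if i not in child]
                    if outside:
                        child.discard(gene)
                        child.add(int(rng.choice(outside)))
            cand = tuple(sorted(child))
            if len(cand) == k and (k == 1 or _feasible(cand, corr, cfg.corr_cap)):
                nxt.append(cand)
        population = nxt

    best = max(population, key=fitness)
    if fitness(best) == -math.inf:
        raise NoFeasibleSubsetError(
            f"no {k}-descriptor subset satisfies |r| <= {cfg.corr_cap}"
        )
    return tuple(pool[i] for i in sorted(best))


def predict(model: MLRModel, X: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`MLRModel.predict`."""
    return model.predict(X)
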