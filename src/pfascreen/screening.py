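"""Virtual screening with the frozen published receptor models.

Five nuclear-receptor equations (PPAR alpha/beta/gamma, TR alpha/beta) are
bundled as a versioned registry, each a two-descriptor MLR in standardized
space plus three binding-score thresholds that cut the kcal/mol axis into
four probability classes (high / moderately high / moderate / low, the
familiar red/orange/yellow/green coding).

The published equations act on standardized descriptors, but the original
calibration means and SDs were never printed.  ``screen`` therefore takes
an explicit reference dataset whose descriptor statistics realize the
frozen equations on raw descriptor values; the registry itself stores only
the printed numbers.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .applicability import ADResult, assess_domain
from .modeling import Dataset, MLRModel, standard_scale


class BindingClass(enum.IntEnum):
    """Binding-probability class, ordered weakest (LOW) to strongest (HIGH)."""

    LOW = 0
    MODERATE = 1
    MODERATELY_HIGH = 2
    HIGH = 3

    @property
    def color(self) -> str:
        return {"LOW": "green", "MODERATE": "yellow",
                "MODERATELY_HIGH": "orange", "HIGH": "red"}[self.name]

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ReceptorSpec:
    """One receptor's frozen equation and class thresholds.

    ``thresholds`` = (T1, T2, T3) in kcal/mol with T1 < T2 < T3 (T1 the
    most negative); scores below T1 are high-probability binders, scores at
    or above T3 low-probability.
    """

    receptor: str
    pdb: str
    descriptor_names: tuple[str, ...]
    intercept: float
    intercept_se: float
    coefficients: tuple[float, ...]
    coefficient_ses: tuple[float, ...]
    thresholds: tuple[float, float, float]

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not t1 < t2 < t3:
            raise ValueError("thresholds must increase (T1 most negative)")
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("coefficient count mismatch")


def frozen_registry() -> dict[str, ReceptorSpec]:
    """Load the bundled registry of the five published receptor models."""
    doc = json.loads(
        resources.files("pfascreen").joinpath("data/receptor_registry.json").read_text()
    )
    registry = {}
    for rid, r in doc["receptors"].items():
        registry[rid] = ReceptorSpec(
            receptor=rid,
            pdb=r["pdb"],
            descriptor_names=tuple(r["descriptors"]),
            intercept=float(r["intercept"]),
            intercept_se=float(r["intercept_se"]),
            coefficients=tuple(float(c) for c in r["coefficients"]),
            coefficient_ses=tuple(float(s) for s in r["coefficient_ses"]),
            thresholds=tuple(float(t) for t in r["thresholds"]),
        )
    return registry


def classify_score(score: float, spec: ReceptorSpec) -> BindingClass:
    """Map a binding score (kcal/mol) to its probability class.

    A score exactly on a threshold goes to the weaker class, so T1 itself
    is already only moderately-high.
    """
    if not np.isfinite(score):
        raise ValueError("binding score must be finite")
    t1, t2, t3 = spec.thresholds
    if score < t1:
        return BindingClass.HIGH
    if score < t2:
        return BindingClass.MODERATELY_HIGH
    if score < t3:
        return BindingClass.MODERATE
    return BindingClass.LOW


def realize_model(spec: ReceptorSpec, reference: Dataset) -> MLRModel:
    """Bind a frozen standardized-space equation to raw descriptor scales.

    The reference dataset (the user's re-derived calibration table or a
    synthetic stand-in) supplies the descriptor means and SDs that turn
    standardized coefficients into a raw-descriptor predictor.
    """
    names = list(spec.descriptor_names)
    _, means, sds = standard_scale(reference.X[names].to_numpy(dtype=float))
    return MLRModel(
        descriptor_names=spec.descriptor_names,
        intercept=spec.intercept,
        coefficients=np.asarray(spec.coefficients),
        intercept_se=spec.intercept_se,
        coefficient_ses=np.asarray(spec.coefficient_ses),
        scaler_means=means,
        scaler_sds=sds,
        n_train=reference.n,
    )


def screen(
    query: Dataset,
    spec: ReceptorSpec,
    reference: Dataset,
    range_basis: str | None = None,
) -> pd.DataFrame:
    """Predict, classify and domain-check every query compound.

    The reference dataset provides the scaler statistics and the
    applicability-domain geometry (leverage space and endpoint range).
    Out-of-domain compounds keep their predicted score and class but are
    flagged unreliable via ``in_domain``/``reason``.
    """
    model = realize_model(spec, reference)
    if range_basis is None:
        range_basis = "observed" if reference.y is not None else "predicted"
    ad: list[ADResult] = assess_domain(
        model, reference, query, range_basis=range_basis
    )
    preds = np.array([r.predicted for r in ad])
    classes = [classify_score(float(s), spec) for s in preds]
    out = pd.DataFrame(
        {
            "id": query.ids,
            "smiles": query.smiles,
            **{
                name: query.X[name].to_numpy()
                for name in spec.descriptor_names
            },
            "predicted_bs_kcal_mol": preds,
            "class": [c.label for c in classes],
            "color": [c.color for c in classes],
            "h": [r.h for r in ad],
            "h_star": [r.h_star for r in ad],
            "in_domain": [r.in_domain for r in ad],
            "reason": [r.reason for r in ad],
        }
    )
    return out
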