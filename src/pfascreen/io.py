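"""CSV/JSON input-output and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .applicability import ad_table, assess_domain
from .descriptors import descriptor_table
from .modeling import (
    Dataset,
    GASettings,
    MLRModel,
    dataset_from_table,
    fit,
    ga_select,
    split_one_to_z,
)
from .screening import frozen_registry, screen
from .synthetic import SyntheticConfig, make_benchmark
from .validation import validate_model

log = logging.getLogger("pfascreen")


def read_compound_csv(path, endpoint_column: str | None = None) -> pd.DataFrame:
    """Read an ``id,smiles[,endpoint]`` table, dropping empty-SMILES rows.

    Returns the curated raw table (descriptors are computed downstream).
    Rows without a SMILES are removed with a logged count, mirroring the
    usual curation step for screening databases.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if endpoint_column is not None and endpoint_column not in df.columns:
        raise ValueError(f"missing endpoint column {endpoint_column!r} in {path}")
    blank = df["smiles"].isna() | (df["smiles"].astype(str).str.strip() == "")
    if blank.any():
        log.info("dropped %d row(s) without SMILES from %s", int(blank.sum()), path)
    return df[~blank].reset_index(drop=True)


def load_dataset(
    path, endpoint_column: str | None = None, include_pool: bool = False
) -> tuple[Dataset, pd.DataFrame]:
    """Read a compound CSV and attach descriptors; returns (dataset, rejects)."""
    raw = read_compound_csv(path, endpoint_column)
    mols = list(zip(raw["id"].astype(str), raw["smiles"].astype(str)))
    table, rejects = descriptor_table(mols, include_pool=include_pool)
    if not rejects.empty:
        log.warning("rejected %d unparsable structure(s)", len(rejects))
    if endpoint_column is not None:
        ok = raw.set_index("id").loc[table["id"], endpoint_column]
        table = table.assign(**{endpoint_column: ok.to_numpy(dtype=float)})
        ds = dataset_from_table(table, y_column=endpoint_column)
    else:
        ds = dataset_from_table(table)
    return ds, rejects


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    input_path: str
    outdir: str
    seed: int
    endpoint_column: str | None = "bs"
    query_path: str | None = None
    receptor: str | None = None  # frozen-model mode when set
    z: int = 3
    descriptors: tuple[str, ...] | None = None
    pool: tuple[str, ...] | None = None
    ga: GASettings = field(default_factory=GASettings)
    n_scrambles: int = 1000
    precision: int = 3


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Descriptors -> split -> fit (or frozen model) -> validate -> AD -> classify.

    Writes five artifacts into ``cfg.outdir`` (descriptor table, model
    document, validation report, applicability-domain export, screening
    results) and returns their paths.  All artifacts keep full float
    precision; only the human-readable report is rounded.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    ds, rejects = load_dataset(
        cfg.input_path, endpoint_column=cfg.endpoint_column, include_pool=True
    )
    desc_path = outdir / "descriptors.csv"
    ds.X.assign(id=ds.ids, smiles=ds.smiles).to_csv(desc_path, index=False)
    artifacts["descriptors"] = str(desc_path)
    if not rejects.empty:
        rej_path = outdir / "rejects.csv"
        rejects.to_csv(rej_path, index=False)
        artifacts["rejects"] = str(rej_path)

    registry = frozen_registry()
    if cfg.receptor is not None:
        # frozen-model mode: published equation, input set as reference
        spec = registry[cfg.receptor]
        query_ds = ds
        if cfg.query_path is not None:
            query_ds, _ = load_dataset(cfg.query_path, include_pool=True)
        results = screen(query_ds, spec, reference=ds)
        screen_path = outdir / "screening.csv"
        results.to_csv(screen_path, index=False)
        artifacts["screening"] = str(screen_path)
        return artifacts

    if ds.y is None:
        raise ValueError("fitting mode requires an endpoint column")
    split = split_one_to_z(ds, cfg.z)
    train, val = ds.subset(split.train_idx), ds.subset(split.val_idx)

    names = cfg.descriptors
    if names is None:
        pool = list(cfg.pool) if cfg.pool else list(ds.X.columns)
        names = ga_select(train, pool, cfg.ga, seed=cfg.seed)
    model = fit(train, names)
    model_path = outdir / "model.json"
    model.save(model_path)
    artifacts["model"] = str(model_path)

    report = validate_model(
        model, train, val, seed=cfg.seed, n_scrambles=cfg.n_scrambles
    )
    report_path = outdir / "validation.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["validation"] = str(report_path)
    (outdir / "validation.txt").write_text(
        report.format_table(cfg.precision) + "\n", encoding="utf-8"
    )
    artifacts["validation_table"] = str(outdir / "validation.txt")

    ad = assess_domain(model, train, ds)
    ad_path = outdir / "applicability.csv"
    ad_table(ad).to_csv(ad_path, index=False)
    artifacts["applicability"] = str(ad_path)

    # classify with the thresholds of the chosen receptor family (the
    # fitted model's own scores, PPARA thresholds by default)
    spec = registry["PPARA"]
    query_ds = ds
    if cfg.query_path is not None:
        query_ds, _ = load_dataset(cfg.query_path, include_pool=True)
    from .screening import classify_score  # local to avoid cycle at import

    preds = model.predict(query_ds.X)
    classes = [classify_score(float(s), spec) for s in preds]
    ad_q = assess_domain(model, train, query_ds)
    screen_df = pd.DataFrame(
        {
            "id": query_ds.ids,
            "smiles": query_ds.smiles,
            "predicted_bs_kcal_mol": preds,
            "class": [c.label for c in classes],
            "color": [c.color for c in classes],
            "h": [r.h for r in ad_q],
            "h_star": [r.h_star for r in ad_q],
            "in_domain": [r.in_domain for r in ad_q],
            "reason": [r.reason for r in ad_q],
        }
    )
    screen_path = outdir / "screening.csv"
    screen_df.to_csv(screen_path, index=False)
    artifacts["screening"] = str(screen_path)
    return artifacts


def write_benchmark_csv(path, cfg: SyntheticConfig) -> None:
    """Write a labeled synthetic benchmark plus a sidecar of the truth."""
    ds = make_benchmark(cfg)
    groups = [cid[0] if not cid.endswith("FTOH") else "F" for cid in ds.ids]
    pd.DataFrame(
        {"id": ds.ids, "smiles": ds.smiles, "group": groups, "bs": ds.y}
    ).to_csv(path, index=False)
    sidecar = Path(str(path) + ".truth.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "intercept": cfg.intercept,
                "coefficients": cfg.coefficients,
                "sigma": cfg.sigma,
                "n": cfg.n,
                "seed": cfg.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
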