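# pfascreen

QSAR screening of per- and polyfluoroalkyl substances (PFAS) for binding
probability to five nuclear hormone receptors: the peroxisome
proliferator-activated receptors PPARα/β/γ and the thyroid hormone
receptors TRα/β.

PFAS docking scores to these receptors (AutoDock-Vina-style binding
energies, kcal/mol, more negative = stronger predicted binding) can be
modeled remarkably well from nothing but 2D topology. `pfascreen` is for
computational toxicologists who want to reproduce, extend or apply that
workflow: it computes the four topological descriptors involved, fits and
validates multiple-linear-regression (MLR) models of the binding score,
checks the applicability domain by leverage, and classifies screening
compounds into four binding-probability classes with published
receptor-specific equations and thresholds.

## The model

For each receptor, a two-descriptor MLR in standardized descriptor space:

    BS = β₀ + β₁·z₁ + β₂·z₂,    z_j = (x_j − mean_j) / SD_j

where the x_j are drawn from:

* **X%** — percentage of halogen atoms over all atoms (implicit hydrogens
  included in the denominator);
* **ICR** — radial centric information index: Shannon entropy (bits, base
  2) of the partition of heavy atoms into equal-eccentricity classes;
* **PW2** — path/walk-2 Randić shape index: atom-averaged ratio of order-2
  simple-path to walk counts;
* **TPC** — total path count: ln of the number of simple paths (length ≥ 0)
  in the hydrogen-suppressed graph.

Model building follows the standard QSAR protocol: a 1:Z endpoint-ordered
split into training/validation sets, standard scaling on training
statistics, genetic-algorithm descriptor selection under a pairwise
|r| ≤ 0.6 cap with leave-one-out Q² as the objective, then a full
statistics block (R², RMSE/MAE on all sets, Q²_LOO, Q²_F1/F2/F3, CCC_EXT,
Y-scrambling mean R²). The applicability domain uses the leverage
h = x'(X'X)⁻¹x against h* = 3(p+1)/n (Williams plot for labeled data,
prediction-range + leverage logic for unlabeled screening data).

The five published receptor equations (e.g. PPARα:
BS = −7.499 − 0.947·ICR − 0.394·PW2 in standardized space) ship as a
frozen registry together with the class thresholds, e.g. TRα
(−10.2, −9.2, −7.2): scores below the first threshold are
high-probability binders (red), above the last low-probability (green).

## Worked example

```python
import pfascreen as pf

# a labeled 43-compound synthetic calibration set (five homologous series)
ds = pf.make_benchmark(pf.SyntheticConfig(seed=11))
split = pf.split_one_to_z(ds, 3)                      # 29 train / 14 validation
train, val = ds.subset(split.train_idx), ds.subset(split.val_idx)

model = pf.fit(train, ("ICR", "PW2"))
report = pf.validate_model(model, train, val, seed=11)
print(report.format_table())
```

prints

```
R2        0.951
RMSE_C    0.290
MAE_C     0.250
Q2_LOO    0.939
RMSE_CV   0.325
MAE_CV    0.281
Q2_F1     0.944
Q2_F2     0.944
Q2_F3     0.953
RMSE_EXT  0.285
MAE_EXT   0.223
CCC_EXT   0.972
R2_YSCR   0.070
```

— a well-fitted, internally stable and externally predictive model
(Q² close to R², CCC_EXT near 1) whose chance correlation (R2_YSCR,
mean R² after endpoint permutation) sits at the p/(n−1) noise floor.
Screening the first five carboxylic homologs against the frozen TRβ model,

```python
out = pf.screen(ds.subset(range(5)), pf.frozen_registry()["TRB"], reference=ds)
```

yields predicted scores falling from −4.74 to −8.80 kcal/mol as CF₂ units
are added — class low (green) → moderate (yellow) — with the shortest
homolog (a TFA analogue) flagged `high-leverage`: structurally atypical for
the series, so its prediction is an extrapolation.

A CLI mirrors the library: `pfascreen simulate | descriptors | fit |
validate | screen | run` (see `pfascreen --help`).

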