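# Methods

## Scope

`pfascreen` implements a descriptor-based screening workflow for PFAS
binding probability to five nuclear receptors. Docking itself is out of
scope: binding scores (BS, kcal/mol) are inputs, either supplied by the
user or simulated by the synthetic generator. Likewise no attempt is made
to reproduce screening counts that depend on external compound databases
or a commercial descriptor engine; the package computes the four
descriptors the published models use plus a small demonstration pool.

## Descriptors

All descriptors act on the hydrogen-suppressed constitution graph; bond
order, aromatic perception and stereochemistry are discarded, so every
value is invariant under SMILES rewriting. Implicit hydrogens survive only
as per-atom counts.

* **X%** = 100 · (F + Cl + Br + I count) / (heavy atoms + implicit H).
  Including implicit hydrogens in the denominator is what reproduces the
  printed reference values (53.33 for 8:2 FTUCA; 36.36 for a 22-atom,
  8-fluorine compound); a heavy-atom-only denominator does not.
* **ICR**: heavy atoms are partitioned into classes of equal eccentricity
  and the Shannon entropy (base 2) of the class sizes is returned. The
  eccentricity partition with log₂ follows the information-index
  convention for "radial centric" indices; a distance-from-center
  partition would differ on asymmetric trees, but no printed value
  discriminates the two, so the eccentricity convention was fixed once.
* **PW2**: the atom-averaged ratio p₂(i)/w₂(i) (atoms with w₂ = 0
  contribute 0), the Randić shape-index convention used by descriptor
  software. A literal reading of "quotient of path count and walk count"
  (molecule-level totals) is exposed as `pw2_molecular` but is not the
  default; the two differ on asymmetric trees (e.g. 2-methylbutane:
  0.517 vs 0.500).
* **TPC** = ln(A + P) with A the heavy-atom count (zero-length paths) and
  P the number of simple paths of length ≥ 1 counted once per unordered
  pair-and-route. ln(A + P) reproduces the printed 6.39 for both
  34-heavy-atom reference compounds; the alternative ln(1 + A + P) differs
  by < 0.01 there. For trees P = A(A−1)/2 exactly (used as a fast path and
  as a test oracle); cyclic graphs are enumerated exhaustively by DFS.

Descriptors are computed and consumed at full precision; tables round to
2 decimals only at the reporting edge.

## Model calibration

The 1:Z split sorts compounds ascending by endpoint (stable sort; input
order breaks ties — reproducibility over an unstated convention) and sends
1-based positions Z, 2Z, … to validation: 43 compounds yield 29/14 at
Z = 3 and 33/10 at Z = 4. Predictors are standardized with training-set
mean and sample SD (n−1 denominator, the dominant QSAR convention; a
single code path would flip it). OLS is solved by least squares on the
intercept-augmented design; coefficient standard errors use the residual
variance with n − p − 1 degrees of freedom. Rank-deficient designs abort
with the most collinear descriptor pair named.

Descriptor selection is a fixed-size-subset genetic algorithm (default
size 2, matching all five published models): population 50, 100
generations, tournament size 3, uniform crossover 0.5, per-gene mutation
0.01, elitism 1, mandatory seed. Fitness is leave-one-out Q²; any subset
containing a descriptor pair with |Pearson r| > 0.6 is infeasible outright.
These hyperparameters are conventional defaults; on the pool sizes used in
tests the GA provably matches exhaustive search, which serves as its
correctness oracle.

## Validation statistics

R² is about the training mean; RMSE uses 1/n on every set. Leave-one-out
refits both the scaler and the model on each fold's n−1 rows (no leakage),
and Q²_LOO = 1 − PRESS/SST. External Q²_F1/F2/F3 and Lin's CCC (sample
moments) follow their standard definitions. The Y-scrambling statistic is
the mean R² over seeded endpoint permutations (identity permutation not
excluded); its chance expectation p/(n−1) — 0.071 at n = 29, 0.063 at
n = 33 for two descriptors — matches the published magnitudes, which is
why the mean (not max) convention was adopted.

## Applicability domain

Leverages include the intercept column, so training leverages sum to
p + 1 and h* = 3(p+1)/n (0.310 at n = 29, 0.273 at n = 33 for p = 2).
In-domain requires strictly h < h*; boundary equality is out. Labeled
compounds are additionally screened by |standardized residual| > 3, scaled
by the RMSE of the set they belong to. Unlabeled screening compounds must
also predict inside the calibration endpoint range; whether that range is
taken from observed or predicted training endpoints is ambiguous in
practice, so observed is the default with `range_basis="predicted"` as the
option.

## Frozen registry and classification

The five published equations and threshold triples are bundled verbatim in
`data/receptor_registry.json` (versioned). Because the original
standardization constants (descriptor means/SDs of the calibration set)
were never published, `screen()` requires an explicit reference dataset to
realize the standardized-space equations on raw descriptors; the registry
stores only printed numbers. Classification sends a score exactly on a
threshold to the weaker class — the convention consistent with the
strongest printed screening hit (−10.5 kcal/mol on a −10.5 threshold)
being reported as moderately-high rather than high; a conflicting printed
class range elsewhere is attributable to 2-decimal rounding.

## Synthetic data

The generator emulates the study design, not any real docking values:

* **Structures**: homologous series built by CF₂ insertion from five head
  groups — carboxylic (COOH-(CF₂)ₙ-CF₃), sulfonic, phosphonic,
  dicarboxylic, and fluorotelomer alcohols (OH-(CH₂)ₘ-(CF₂)ₙ-CF₃). The
  default benchmark is 43 compounds: ten carboxylic (n = 0–9, the shortest
  being TFA), eight each sulfonic/phosphonic/dicarboxylic (n = 1–8), nine
  fluorotelomer alcohols with spacer m ∈ {1, 2, 3} — mirroring the
  published calibration-set size and its series mix.
* **Endpoint**: y = β₀ + Σ βⱼ zⱼ + ε with z standardized within the
  generated set and ε ~ N(0, σ²), homoscedastic (no published residual
  diagnostics justify more). Defaults copy the PPARα equation
  (−7.499, −0.947 on ICR, −0.394 on PW2) with σ = 0.35 kcal/mol, the
  midpoint of the published calibration-RMSE range (0.276–0.384).
* **Decoys**: seeded random branched / partially fluorinated / small-ring
  structures to exercise out-of-domain code paths.

What the synthetic set does **not** emulate: real docking physics, the
actual descriptor correlation structure of the published 43 compounds
(our ICR–PW2 correlation is 0.51 vs the published 0.31, and our X%–TPC
correlation, 0.78, exceeds the 0.6 selection cap although the published
TRβ model used that pair at r = 0.47), head-group-specific binding
effects, or the structural diversity of a real screening database.
Passing tests therefore demonstrate that the machinery is correct and
well-calibrated under the stated statistical assumptions — not that the
published docking scores themselves are reproduced.

## Problem sizes and determinism

All simulations are desk-scale by design: the benchmark is 43 compounds,
Y-scrambling uses 1000 permutations (computed via a single QR projection
per permutation), LOO envelopes use 100 seeds, and GA-vs-exhaustive
comparisons use pools of ≤ 12 descriptors. Every stochastic entry point
(simulation, GA, scrambling, decoys) takes a mandatory seed; serialized
artifacts round-trip bit-exactly, and a pipeline rerun with the same seed
produces byte-identical model documents.

## Known limitations

* Path enumeration is exponential in highly cyclic graphs; PFAS inputs are
  (near-)acyclic, where the tree closed form applies, but dense polycyclic
  input would be slow.
* The GA is exact only insofar as the exhaustive oracle confirms it on
  small pools; very large pools have no optimality guarantee.
* Frozen-registry screening inherits whatever reference set the user
  supplies for standardization: with a reference unlike the original
  calibration compounds, the realized raw-space equations shift
  accordingly.
* ICR and PW2 conventions were fixed by consistency arguments (see above);
  if the upstream descriptor software used different variants, absolute
  descriptor values — not the workflow — would change.
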