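"""The four model descriptors and a small demonstration pool.

All values are connectivity indices computed on the hydrogen-suppressed
graph:

* ``X%``  — percentage of halogen atoms over all atoms, implicit hydrogens
  included in the denominator (constitutional index; grows with each CF2
  insertion in a perfluorinated homologous series).
* ``ICR`` — radial centric information index: Shannon entropy (base 2) of
  the partition of heavy atoms into equal-eccentricity classes; a 2D
  measure of how centric/branched the skeleton is.
* ``PW2`` — path/walk-2 Randic shape index: the atom-averaged ratio of
  order-2 simple-path counts to order-2 walk counts.
* ``TPC`` — total path count: natural log of the number of simple paths of
  length >= 0 (each atom counts as one zero-length path), a size/complexity
  measure.

Models consume full-precision values; the conventional 2-decimal rounding
is applied only when tables are written.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .molgraph import (
    HALOGENS,
    MolecularGraph,
    SmilesParseError,
    atomic_path_walk_counts,
    count_simple_paths,
    eccentricities,
    parse_smiles,
)

#: Column order of the four modeled descriptors, as used everywhere downstream.
DESCRIPTOR_NAMES = ("X%", "ICR", "PW2", "TPC")

#: Extra pool descriptors available to subset selection.
POOL_NAMES = ("nHeavy", "nX", "nF", "W", "eccMean")


@dataclass
class DescriptorVector:
    """Descriptor values for one compound."""

    x_percent: float
    icr: float
    pw2: float
    tpc: float
    pool: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        core = (self.x_percent, self.icr, self.pw2, self.tpc)
        if not all(math.isfinite(v) for v in core):
            raise ValueError("descriptor values must be finite")
        if not 0.0 <= self.x_percent <= 100.0:
            raise ValueError("X% outside [0, 100]")
        if self.pw2 < 0.0 or self.pw2 > 1.0:
            raise ValueError("PW2 outside [0, 1]")
        if self.icr < 0.0 or self.tpc < 0.0:
            raise ValueError("ICR and TPC must be non-negative")

    def as_dict(self, include_pool: bool = False) -> dict[str, float]:
        d = {
            "X%": self.x_percent,
            "ICR": self.icr,
            "PW2": self.pw2,
            "TPC": self.tpc,
        }
        if include_pool:
            d.update(self.pool)
        return d


def x_percent(mg: MolecularGraph) -> float:
    """Percentage of halogen atoms (F, Cl, Br, I) over all atoms.

    The denominator counts heavy atoms plus implicit hydrogens, which is
    what makes a CF3 terminus and a CH3 terminus differ in X% even though
    the hydrogen-suppressed graphs match.
    """
    return 100.0 * mg.halogen_count / mg.total_atom_count


def icr(mg: MolecularGraph) -> float:
    """Radial centric information index, in bits.

    Heavy atoms are partitioned into classes of equal eccentricity and the
    Shannon entropy of the class-size distribution is returned; a graph in
    which all atoms share one eccentricity (e.g. ethane) scores 0.
    """
    n = mg.heavy_atom_count
    classes = Counter(eccentricities(mg))
    ent = 0.0
    for size in classes.values():
        p = size / n
        ent -= p * math.log2(p)
    return ent


def pw2(mg: MolecularGraph) -> float:
    """Atom-averaged path/walk-2 shape index (Randic convention).

    Each atom contributes its ratio of order-2 simple-path count to order-2
    walk count; atoms with no order-2 walks contribute 0.  The molecular
    variant (quotient of the summed counts) is exposed separately as
    :func:`pw2_molecular`.
    """
    counts = atomic_path_walk_counts(mg, k=2)
    total = 0.0
    for p2, w2 in counts:
        if w2 > 0:
            total += p2 / w2
    return total / mg.heavy_atom_count


def pw2_molecular(mg: MolecularGraph) -> float:
    """Molecule-level path/walk-2 quotient: (sum of P2) / (sum of W2).

    Alternative reading of "quotient of the path length of 2 and walk
    length of 2"; kept for comparison, not used by the published models.
    """
    counts = atomic_path_walk_counts(mg, k=2)
    p_tot = sum(p for p, _ in counts)
    w_tot = sum(w for _, w in counts)
    return p_tot / w_tot if w_tot else 0.0


def tpc(mg: MolecularGraph) -> float:
    """Total path count descriptor: ln(A + number of simple paths).

    Paths of length zero are included as one per atom, so a tree with A
    heavy atoms scores ln(A + A(A-1)/2).
    """
    return math.log(mg.heavy_atom_count + count_simple_paths(mg))


def pool_descriptors(mg: MolecularGraph) -> dict[str, float]:
    """Demonstration pool for subset selection: simple counts plus a
    Wiener-type distance sum and the mean eccentricity."""
    n = mg.heavy_atom_count
    if n > 1:
        wiener = float(
            sum(
                d
                for _, targets in nx.shortest_path_length(mg.graph)
                for d in targets.values()
            )
            / 2
        )
    else:
        wiener = 0.0
    ecc = eccentricities(mg)
    return {
        "nHeavy": float(n),
        "nX": float(mg.halogen_count),
        "nF": float(sum(1 for a in mg.atoms if a.symbol == "F")),
        "W": wiener,
        "eccMean": sum(ecc) / n,
    }


def compute_descriptors(
    mg: MolecularGraph, include_pool: bool = False
) -> DescriptorVector:
    return DescriptorVector(
        x_percent=x_percent(mg),
        icr=icr(mg),
        pw2=pw2(mg),
        tpc=tpc(mg),
        pool=pool_descriptors(mg) if include_pool else {},
    )


def descriptor_table(
    molecules: list[tuple[str, str]], include_pool: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute descriptors for a batch of ``(id, SMILES)`` pairs.

    Returns ``(table, rejects)``: one result row per parsable compound in
    input order, and one reject row (id, smiles, error) per failure.  A bad
    row never aborts the batch.
    """
    rows: list[dict] = []
    rejects: list[dict] = []
    for cid, smi in molecules:
        try:
            mg = parse_smiles(smi)
            vec = compute_descriptors(mg, include_pool=include_pool)
        except SmilesParseError as exc:
            rejects.append({"id": cid, "smiles": smi, "error": str(exc)})
            continue
        row = {"id": cid, "smiles": mg.smiles}
        row.update(vec.as_dict(include_pool=include_pool))
        rows.append(row)
    cols = ["id", "smiles", *DESCRIPTOR_NAMES]
    if include_pool:
        cols += list(POOL_NAMES)
    table = pd.DataFrame(rows, columns=cols)
    reject_table = pd.DataFrame(rejects, columns=["id", "smiles", "error"])
    return table, reject_table
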