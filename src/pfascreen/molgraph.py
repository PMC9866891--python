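"""Hydrogen-suppressed molecular graphs and their path/walk primitives.

SMILES input is parsed with RDKit; the working representation is a plain
undirected :class:`networkx.Graph` over heavy atoms, with implicit hydrogens
kept only as per-atom counts.  Bond order, aromaticity and stereochemistry
are deliberately discarded: every descriptor built on this module is a pure
connectivity index, so two SMILES of the same constitution must yield
identical values regardless of atom ordering, kekulization or stereo marks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger

# RDKit writes parse failures to its own log stream; we raise instead.
RDLogger.DisableLog("rdApp.*")

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

# Daylight organic-subset tokens plus ring/branch/charge/stereo punctuation.
_TOKEN = re.compile(r"Cl|Br|[CNOSPFI]|[cnosp]|[0-9()=#+\-\[\]@/\\%.Hh]")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a single connected graph."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, implicit hydrogen count, formal charge."""

    symbol: str
    implicit_h: int
    charge: int


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed constitution of a single-fragment molecule.

    ``graph`` nodes are integer atom indices aligned with ``atoms``; edges
    carry no order information.  Implicit hydrogens enter only through the
    per-atom counts (used by the halogen-percentage descriptor), never as
    graph vertices.
    """

    atoms: list[Atom]
    graph: nx.Graph
    smiles: str

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    @property
    def implicit_h_count(self) -> int:
        return sum(a.implicit_h for a in self.atoms)

    @property
    def total_atom_count(self) -> int:
        """Heavy atoms plus implicit hydrogens."""
        return self.heavy_atom_count + self.implicit_h_count

    @property
    def halogen_count(self) -> int:
        return sum(1 for a in self.atoms if a.symbol in HALOGENS)

    def is_tree(self) -> bool:
        # parse_smiles guarantees connectivity, so |E| = |V| - 1 suffices.
        return self.graph.number_of_edges() == self.heavy_atom_count - 1


def _first_bad_position(smiles: str) -> int | None:
    """Index of the first character outside the accepted SMILES vocabulary."""
    i = 0
    while i < len(smiles):
        m = _TOKEN.match(smiles, i)
        if m is None:
            return i
        i = m.end()
    return None


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Accepts the Daylight organic subset (C, N, O, S, P, F, Cl, Br, I),
    branches, rings, multiple bonds and bracket atoms; stereo markers are
    tolerated and ignored.  Implicit hydrogens are assigned by standard
    valence rules and recorded per atom.

    Raises
    ------
    SmilesParseError
        For empty or syntactically invalid input (naming the offending
        position when it can be located) and for multi-fragment input.
    """
    if smiles is None or not str(smiles).strip():
        raise SmilesParseError("empty SMILES string")
    s = str(smiles).strip()
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        pos = _first_bad_position(s)
        if pos is not None:
            raise SmilesParseError(
                f"unparsable SMILES {s!r}: unrecognized token at position {pos}"
            )
        raise SmilesParseError(f"unparsable SMILES {s!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise SmilesParseError(f"multi-fragment SMILES rejected: {s!r}")

    atoms = [
        Atom(a.GetSymbol(), a.GetTotalNumHs(), a.GetFormalCharge())
        for a in mol.GetAtoms()
    ]
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    g.add_edges_from(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, graph=g, smiles=s)


def eccentricities(mg: MolecularGraph) -> list[int]:
    """Per-atom eccentricity: the longest shortest-path distance (in bonds)
    from each heavy atom to any other.  A single-atom graph yields ``[0]``."""
    n = mg.heavy_atom_count
    if n == 1:
        return [0]
    ecc = nx.eccentricity(mg.graph)
    return [ecc[i] for i in range(n)]


def count_simple_paths(mg: MolecularGraph) -> int:
    """Number of simple paths of length >= 1 between unordered heavy-atom pairs.

    Each path is counted once, not per traversal direction.  For acyclic
    graphs every pair is joined by exactly one path, so the count is the
    closed form C(A, 2); cyclic graphs fall back to exhaustive depth-first
    enumeration of simple vertex sequences, halved to merge directions.
    """
    n = mg.heavy_atom_count
    if mg.is_tree():
        return n * (n - 1) // 2
    adj = {v: sorted(mg.graph[v]) for v in mg.graph}
    total = 0

    def dfs(v: int, visited: set[int]) -> None:
        nonlocal total
        for w in adj[v]:
            if w not in visited:
                total += 1
                visited.add(w)
                dfs(w, visited)
                visited.remove(w)

    for s in adj:
        dfs(s, {s})
    # every simple path was generated from both of its endpoints
    return total // 2


def _paths_of_length_from(adj: dict[int, list[int]], start: int, k: int) -> int:
    """Count simple paths with exactly ``k`` edges starting at ``start``."""
    count = 0

    def dfs(v: int, depth: int, visited: set[int]) -> None:
        nonlocal count
        if depth == k:
            count += 1
            return
        for w in adj[v]:
            if w not in visited:
                visited.add(w)
                dfs(w, depth + 1, visited)
                visited.remove(w)

    dfs(start, 0, {start})
    return count


def atomic_path_walk_counts(
    mg: MolecularGraph, k: int = 2
) -> list[tuple[int, int]]:
    """Per-atom ``(path count, walk count)`` of order ``k``.

    The walk count of order k from atom i is the number of length-k walks
    starting at i (row sum of the k-th adjacency power); the path count is
    the number of k-edge simple paths starting at i, obtained by exhaustive
    enumeration so cyclic neighborhoods are handled exactly.
    """
    if k < 1:
        raise ValueError("order k must be >= 1")
    n = mg.heavy_atom_count
    A = nx.to_numpy_array(mg.graph, nodelist=range(n), dtype=np.int64)
    walks = np.linalg.matrix_power(A, k).sum(axis=1)
    adj = {v: sorted(mg.graph[v]) for v in mg.graph}
    return [
        (_paths_of_length_from(adj, i, k), int(walks[i])) for i in range(n)
    ]
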