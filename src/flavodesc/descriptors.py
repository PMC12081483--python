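"""Molecular descriptors over heavy-atom graphs and 3D conformers.

Molecules are hydrogen-suppressed: the graph holds heavy atoms only, with
per-atom implicit hydrogen counts. Descriptor dialects in the literature
differ in pair counting, log scaling and weighting conventions; the choices
here are:

* walk counts: raw count = sum of the k-th adjacency-matrix power, with a
  log10(1+count) variant exposed via ``log_scaled``;
* Broto-Moreau autocorrelation: each unordered pair at topological distance
  k counted once (self-pairs only at lag 0); centered variants subtract the
  molecular mean weight first; disconnected (infinite-distance) pairs are
  excluded;
* E-states: the Kier-Hall scheme, intrinsic state
  I = ((2/N)^2 * delta_v + 1)/delta with delta the heavy-neighbor count,
  delta_v = (valence electrons) - (attached hydrogens), N the principal
  quantum number; field effect sum_j (I_i - I_j)/(d_ij + 1)^2;
* RDF: f(R) = sum_{i<j} w_i w_j exp(-beta (R - r_ij)^2) with beta =
  100 1/A^2 and the coded index/10 as the radius (index 105 -> 10.5 A);
  element weights taken relative to carbon;
* TDB lag k: the average of w_i w_j r_ij over atom pairs at topological
  distance k, with 3D Euclidean r_ij.

No bit-compatibility with any specific descriptor package is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import _elements as el

RDF_BETA = 100.0  # 1/A^2

WEIGHT_TABLES = {
    "mass": el.MASS,
    "pauling_en": el.PAULING_EN,
    "sanderson_en": el.SANDERSON_EN,
    "polarizability": el.POLARIZABILITY,
}


@dataclass
class Atom:
    """One heavy atom; hydrogens are implicit via ``n_hydrogens``."""

    element: str
    partial_charge: float = 0.0
    n_hydrogens: int = 0
    position: Optional[np.ndarray] = None  # Angstrom
    intrinsic_state: Optional[float] = None  # override; computed if None


@dataclass
class MoleculeRecord:
    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = dc_field(default_factory=list)  # (i, j, order)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"{self.id}: invalid bond ({i}, {j})")
        for a in self.atoms:
            if not math.isfinite(a.partial_charge):
                raise ValueError(f"{self.id}: non-finite partial charge")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A

    def topological_distances(self) -> np.ndarray:
        """Shortest-path matrix; disconnected pairs are +inf."""
        D = np.full((self.n_atoms, self.n_atoms), np.inf)
        np.fill_diagonal(D, 0.0)
        for i, lengths in nx.all_pairs_shortest_path_length(self.graph()):
            for j, d in lengths.items():
                D[i, j] = d
        return D

    def positions(self) -> np.ndarray:
        if any(a.position is None for a in self.atoms):
            raise ValueError(f"{self.id}: 3D coordinates missing")
        return np.array([np.asarray(a.position, float) for a in self.atoms])

    def weights(self, name: str, relative: bool = False) -> np.ndarray:
        """Per-atom weight vector by property name.

        ``unit`` gives ones, ``charge`` the partial charges,
        ``intrinsic_state`` the Kier-Hall intrinsic states; element
        properties come from the internal tables, optionally relative to
        carbon.
        """
        if name == "unit":
            return np.ones(self.n_atoms)
        if name == "charge":
            return np.array([a.partial_charge for a in self.atoms])
        if name == "intrinsic_state":
            return intrinsic_states(self)
        table = WEIGHT_TABLES.get(name)
        if table is None:
            raise KeyError(f"unknown weight property {name!r}")
        w = np.array(
            [el.require(table, a.element, name) for a in self.atoms]
        )
        if relative:
            w = w / table["C"]
        return w


# ---------------------------------------------------------------------------
# charge and graph descriptors

def rncg(mol: MoleculeRecord) -> float:
    """Relative negative charge: most negative atomic charge over the total
    negative charge (both as magnitudes); in (0, 1]."""
    charges = np.array([a.partial_charge for a in mol.atoms])
    neg = charges[charges < 0]
    if neg.size == 0:
        raise ValueError(f"{mol.id}: no negatively charged atoms")
    return float(neg.min() / neg.sum())


def walk_count(mol: MoleculeRecord, k: int, log_scaled: bool = False) -> float:
    """Total number of walks of length k on the heavy-atom graph
    (sum of the entries of A^k); ``log_scaled`` returns log10(1+count)."""
    if k < 1:
        raise ValueError("walk order k must be >= 1")
    if mol.n_atoms == 0:
        raise ValueError("empty molecular graph")
    A = mol.adjacency()
    count = float(np.linalg.matrix_power(A, k).sum())
    return math.log10(1.0 + count) if log_scaled else count


def autocorrelation(
    mol: MoleculeRecord, lag: int, weight: str, centered: bool = False
) -> float:
    """Broto-Moreau autocorrelation at a topological lag.

    ATS_k = sum over unordered atom pairs at topological distance k of
    w_i * w_j (self-pairs at k=0); the centered variant (ATSC) uses
    w - mean(w). Disconnected pairs are excluded.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    w = mol.weights(weight) if isinstance(weight, str) else np.asarray(weight, float)
    if centered:
        w = w - w.mean()
    if lag == 0:
        return float(np.sum(w * w))
    D = mol.topological_distances()
    total = 0.0
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if D[i, j] == lag:
                total += w[i] * w[j]
    return float(total)


def intrinsic_states(mol: MoleculeRecord) -> np.ndarray:
    """Kier-Hall intrinsic states; NaN for isolated heavy atoms (delta=0)."""
    deg = dict(mol.graph().degree())
    out = np.empty(mol.n_atoms)
    for i, a in enumerate(mol.atoms):
        delta = deg[i]
        if delta == 0:
            out[i] = np.nan
            continue
        zv = el.require(el.VALENCE_ELECTRONS, a.element, "valence electron count")
        n_q = el.require(el.PRINCIPAL_QUANTUM_NUMBER, a.element, "quantum number")
        delta_v = zv - a.n_hydrogens
        out[i] = ((2.0 / n_q) ** 2 * delta_v + 1.0) / delta
    # honor explicit overrides
    for i, a in enumerate(mol.atoms):
        if a.intrinsic_state is not None:
            out[i] = a.intrinsic_state
    return out


def estate_values(mol: MoleculeRecord) -> np.ndarray:
    """Atomic E-state values S_i = I_i + sum_j (I_i - I_j)/(d_ij + 1)^2,
    the field sum running over connected heavy-atom partners."""
    I = intrinsic_states(mol)
    D = mol.topological_distances()
    S = I.copy()
    for i in range(mol.n_atoms):
        if not np.isfinite(I[i]):
            continue
        for j in range(mol.n_atoms):
            if j == i or not np.isfinite(D[i, j]) or not np.isfinite(I[j]):
                continue
            S[i] += (I[i] - I[j]) / (D[i, j] + 1.0) ** 2
    return S


def estate_sum_ssCH2(mol: MoleculeRecord) -> float:
    """Sum of E-states over -CH2- carbons: C with exactly two hydrogens and
    two single bonds to heavy atoms. 0.0 when no atom matches."""
    single_heavy = np.zeros(mol.n_atoms, dtype=int)
    all_single = np.ones(mol.n_atoms, dtype=bool)
    for i, j, order in mol.bonds:
        for a in (i, j):
            single_heavy[a] += 1
            if order != 1:
                all_single[a] = False
    S = estate_values(mol)
    total = 0.0
    for i, a in enumerate(mol.atoms):
        if (
            a.element == "C"
            and a.n_hydrogens == 2
            and single_heavy[i] == 2
            and all_single[i]
        ):
            total += S[i]
    return float(total)


# ---------------------------------------------------------------------------
# 3D descriptors

def rdf(mol: MoleculeRecord, index: int, weight: str = "unit") -> float:
    """Radial distribution function score at the coded radius index/10 A.

    f(R) = sum_{i<j} w_i w_j exp(-beta (R - r_ij)^2), beta = 100 1/A^2;
    element-property weights are relative to carbon.
    """
    R = index / 10.0
    X = mol.positions()
    w = mol.weights(weight, relative=weight in WEIGHT_TABLES)
    total = 0.0
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            r_ij = float(np.linalg.norm(X[i] - X[j]))
            total += w[i] * w[j] * math.exp(-RDF_BETA * (R - r_ij) ** 2)
    return float(total)


def tdb(mol: MoleculeRecord, lag: int, weight: str = "unit") -> float:
    """3D topological-distance-based autocorrelation: average of
    w_i w_j r_ij (Euclidean) over atom pairs at topological distance
    ``lag``; 0.0 when no pair is at that lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    X = mol.positions()
    w = mol.weights(weight, relative=weight in WEIGHT_TABLES)
    D = mol.topological_distances()
    terms = []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if D[i, j] == lag:
                terms.append(w[i] * w[j] * float(np.linalg.norm(X[i] - X[j])))
    return float(np.mean(terms)) if terms else 0.0


def geometry_descriptor(
    mol: MoleculeRecord, family: str, index: int, weight: str = "unit"
) -> float:
    """Dispatch for the coded 3D descriptors (RDF<index>, TDB lag)."""
    if family == "RDF":
        return rdf(mol, index, weight)
    if family == "TDB":
        return tdb(mol, index, weight)
    raise ValueError(f"unknown geometry descriptor family {family!r}")
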