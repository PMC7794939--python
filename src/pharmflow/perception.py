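"""Ligand pharmacophore feature perception.

Feature points are detected on a single conformer of a :class:`Molecule`
with an explicit, versioned rule table (documented below) rather than an
opaque third-party typer, so results are reproducible and auditable. The
vocabulary covers the four kinds a receptor-based model needs:

HBA  hydrogen-bond acceptor, one point per accepting N/O atom
HBD  hydrogen-bond donor, one point per N/O bearing >= 1 hydrogen
     (explicit neighbour or implied by standard valence)
ARO  aromatic ring centroid, with the ring-plane normal as direction
HYD  hydrophobic centroid: every aromatic ring centroid, every maximal
     connected set of >= 2 non-ring apolar heavy atoms, and every halogen
     bonded to carbon

Rule table (version 1):

* apolar atom = C, S or halogen with no bonded N/O
* HBA excludes positively charged N, amide/sulfonamide N (N bonded to a
  C or S that carries a double-bonded O), aniline-type N (N single-bonded
  to an aromatic atom) and aromatic N carrying a hydrogen (pyrrole-type);
  pyridine-type ring N and all neutral O (including sulfonyl O) accept.
* aromatic rings are cycles in the subgraph of aromatic bonds.
* every ARO is duplicated as a HYD so a model "hydrophobic" sphere can
  match a ring; matchers use the HYD copy and ignore ARO duplicates.

Perception is conformer-independent in kinds and source atoms; only the
positions change between conformers. Output order is deterministic for a
fixed atom order.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chem_structures import AROMATIC, Molecule
from .errors import MoleculeError
from ._geom import plane_normal

RULE_TABLE_VERSION = 1

HALOGENS = {"F", "Cl", "Br", "I"}

KIND_HBA = "HBA"
KIND_HBD = "HBD"
KIND_HYD = "HYD"
KIND_ARO = "ARO"

_KIND_ORDER = {KIND_HBA: 0, KIND_HBD: 1, KIND_ARO: 2, KIND_HYD: 3}


@dataclass(frozen=True)
class FeaturePoint:
    kind: str
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]
    direction: tuple[float, float, float] | None = None

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.position, dtype=float)


def aromatic_rings(mol: Molecule) -> list[tuple[int, ...]]:
    """Smallest-set-of-smallest-rings over the aromatic-bond subgraph."""
    G = nx.Graph()
    for b in mol.bonds:
        if b.order == AROMATIC:
            G.add_edge(b.i, b.j)
    if G.number_of_edges() == 0:
        return []
    rings = nx.minimum_cycle_basis(G)
    return sorted(tuple(sorted(r)) for r in rings if len(r) >= 3)


def is_apolar(mol: Molecule, i: int) -> bool:
    """C, S or halogen with no bonded N/O (rule table v1)."""
    el = mol.atoms[i].element
    if el not in {"C", "S"} | HALOGENS:
        return False
    return all(mol.atoms[j].element not in ("N", "O") for j in mol.neighbors(i))


def _is_amide_like_n(mol: Molecule, i: int) -> bool:
    """N bonded to a C or S that carries a double-bonded O (amide/sulfonamide)."""
    for j in mol.neighbors(i):
        if mol.atoms[j].element in ("C", "S"):
            for b in mol.bonds:
                if b.order == 2 and j in (b.i, b.j):
                    other = b.j if b.i == j else b.i
                    if other != i and mol.atoms[other].element == "O":
                        return True
    return False


def _aromatic_atoms(mol: Molecule) -> set[int]:
    out = set()
    for b in mol.bonds:
        if b.order == AROMATIC:
            out.add(b.i)
            out.add(b.j)
    return out


def _is_acceptor(mol: Molecule, i: int, aro_atoms: set[int]) -> bool:
    a = mol.atoms[i]
    if a.element == "O":
        return a.formal_charge <= 0
    if a.element == "N":
        if a.formal_charge > 0:
            return False
        if _is_amide_like_n(mol, i):
            return False
        if i in aro_atoms:
            # pyridine-type accepts; pyrrole-type (ring N-H) does not
            return mol.total_h_count(i) == 0
        # aniline-type: N single-bonded to an aromatic atom
        if any(j in aro_atoms for j in mol.neighbors(i)):
            return False
        return True
    return False


def _is_donor(mol: Molecule, i: int) -> bool:
    a = mol.atoms[i]
    if a.element not in ("N", "O"):
        return False
    return mol.total_h_count(i) >= 1


def perceive_features(mol: Molecule, conformer: int = 0) -> list[FeaturePoint]:
    """Detect HBA/HBD/ARO/HYD feature points on one conformer of ``mol``."""
    if conformer >= len(mol.conformers):
        raise MoleculeError(
            f"{mol.name!r}: no conformer {conformer} "
            f"(has {len(mol.conformers)})"
        )
    xyz = mol.coords(conformer)
    aro_atoms = _aromatic_atoms(mol)
    rings = aromatic_rings(mol)
    ring_atoms = {i for r in rings for i in r}

    feats: list[FeaturePoint] = []

    # HBA / HBD: single-atom features on N/O
    for i, a in enumerate(mol.atoms):
        if not a.is_heavy:
            continue
        if _is_acceptor(mol, i, aro_atoms):
            feats.append(FeaturePoint(KIND_HBA, tuple(xyz[i]), (i,)))
        if _is_donor(mol, i):
            feats.append(FeaturePoint(KIND_HBD, tuple(xyz[i]), (i,)))

    # ARO: ring centroid + plane normal; duplicated as HYD
    for ring in rings:
        centroid = xyz[list(ring)].mean(axis=0)
        normal = plane_normal(xyz[list(ring)])
        feats.append(
            FeaturePoint(KIND_ARO, tuple(centroid), tuple(ring), tuple(normal))
        )
        feats.append(FeaturePoint(KIND_HYD, tuple(centroid), tuple(ring)))

    # HYD (b): maximal connected sets of >= 2 non-ring apolar heavy atoms
    G = nx.Graph()
    apolar_nonring = [
        i
        for i in range(mol.n_atoms)
        if mol.atoms[i].is_heavy and i not in ring_atoms and is_apolar(mol, i)
    ]
    G.add_nodes_from(apolar_nonring)
    apolar_set = set(apolar_nonring)
    for b in mol.bonds:
        if b.i in apolar_set and b.j in apolar_set:
            G.add_edge(b.i, b.j)
    for comp in nx.connected_components(G):
        if len(comp) >= 2:
            idx = sorted(comp)
            centroid = xyz[idx].mean(axis=0)
            feats.append(FeaturePoint(KIND_HYD, tuple(centroid), tuple(idx)))

    # HYD (c): halogen bonded to carbon
    for i, a in enumerate(mol.atoms):
        if a.element in HALOGENS and any(
            mol.atoms[j].element == "C" for j in mol.neighbors(i)
        ):
            feats.append(FeaturePoint(KIND_HYD, tuple(xyz[i]), (i,)))

    feats.sort(key=lambda f: (_KIND_ORDER[f.kind], f.source_atoms))
    return feats


def feature_counts(mol: Molecule, conformer: int = 0) -> dict[str, int]:
    """Per-kind feature totals, consistent with :func:`perceive_features`."""
    return dict(Counter(f.kind for f in perceive_features(mol, conformer)))


def features_to_json_lines(feats: list[FeaturePoint]) -> str:
    """One JSON object per feature (kind, position, atoms, direction)."""
    import json

    lines = []
    for f in feats:
        lines.append(
            json.dumps(
                {
                    "kind": f.kind,
                    "position": [round(v, 4) for v in f.position],
                    "atoms": list(f.source_atoms),
                    "direction": (
                        [round(v, 6) for v in f.direction] if f.direction else None
                    ),
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines)
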