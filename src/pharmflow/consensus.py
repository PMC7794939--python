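"""Pose RMSD, self-docking validation and pose-consensus clustering.

The RMSD here is the docking-community convention: in place (no
superposition), heavy atoms only, optionally minimized over the graph
automorphisms of the molecule so that topologically equivalent atoms
(e.g. the two arms of a para-disubstituted ring) do not inflate the value.

Consensus across docking methods is quantified by the matrix of reciprocal
pairwise RMSDs; "full consensus" means every pair is below the threshold,
which is provably equivalent to the complete-linkage clustering at that
threshold producing a single cluster.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .chem_structures import Molecule, Pose
from .errors import ConnectivityError, PharmflowError

MAX_AUTOMORPHISMS = 10_000


# ---------------------------------------------------------------------------
# RMSD


def _mol_graph(mol: Molecule) -> nx.Graph:
    G = nx.Graph()
    for i, a in enumerate(mol.atoms):
        G.add_node(i, element=a.element, charge=a.formal_charge)
    for b in mol.bonds:
        G.add_edge(b.i, b.j, order=b.order)
    return G


def _same_connectivity(a: Molecule, b: Molecule) -> bool:
    if a.n_atoms != b.n_atoms:
        return False
    if [x.element for x in a.atoms] != [x.element for x in b.atoms]:
        return False
    return {(bd.i, bd.j, bd.order) for bd in a.bonds} == {
        (bd.i, bd.j, bd.order) for bd in b.bonds
    }


def molecule_automorphisms(
    mol: Molecule, cap: int = MAX_AUTOMORPHISMS
) -> list[dict[int, int]]:
    """Graph automorphisms respecting element, charge and bond order."""
    G = _mol_graph(mol)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        G,
        G,
        node_match=lambda x, y: x["element"] == y["element"]
        and x["charge"] == y["charge"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    out = []
    for mapping in gm.isomorphisms_iter():
        out.append(mapping)
        if len(out) >= cap:
            break
    return out


def pose_rmsd(a: Pose, b: Pose, symmetry: bool = True) -> float:
    """In-place heavy-atom RMSD between two poses of the same molecule.

    With ``symmetry`` the value is minimized over graph automorphisms
    (capped at 10^4), mirroring symmetry-aware docking RMSD tools.
    """
    if not _same_connectivity(a.molecule, b.molecule):
        raise ConnectivityError(
            f"poses {a.molecule.name!r}/{b.molecule.name!r} differ in connectivity"
        )
    heavy = a.molecule.heavy_indices
    xa = a.coords[heavy]
    xb = b.coords[heavy]
    identity = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    if not symmetry:
        return identity
    best = identity
    for mapping in molecule_automorphisms(a.molecule):
        perm = [mapping[i] for i in heavy]
        val = float(
            np.sqrt(np.mean(np.sum((a.coords[perm] - xb) ** 2, axis=1)))
        )
        if val < best:
            best = val
    return best


# ---------------------------------------------------------------------------
# RMSD matrix + clustering


@dataclass
class RmsdMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise PharmflowError(
                f"matrix shape {self.values.shape} != ({n}, {n})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise PharmflowError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise PharmflowError("RMSD matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise PharmflowError("RMSD matrix must be nonnegative")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)

    @property
    def max_offdiag(self) -> float:
        if len(self.labels) < 2:
            return 0.0
        mask = ~np.eye(len(self.labels), dtype=bool)
        return float(self.values[mask].max())


@dataclass
class ConsensusResult:
    clusters: list[tuple[str, ...]]
    threshold: float
    full_consensus: bool
    matrix: RmsdMatrix | None = None


def complete_linkage(matrix: RmsdMatrix, threshold: float) -> ConsensusResult:
    """Agglomerative complete-linkage clustering with a distance threshold.

    Merging stops when the smallest inter-cluster complete-linkage distance
    (maximum pairwise member distance) reaches the threshold. Ties are
    broken by merging the pair whose combined smallest labels are
    lexicographically first, making the partition label-order invariant.
    """
    labels = list(matrix.labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(lab,) for lab in sorted(labels)]

    def linkage_dist(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return max(
            matrix.values[idx[a], idx[b]] for a in c1 for b in c2
        )

    while len(clusters) > 1:
        best: tuple[float, tuple[str, str], int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkage_dist(clusters[i], clusters[j])
                tie = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                key = (d, tie)
                if best is None or key < (best[0], best[1]):
                    best = (d, tie, i, j)
        assert best is not None
        d, _, i, j = best
        if d >= threshold:
            break
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [merged]
        clusters.sort(key=lambda c: c[0])

    clusters.sort(key=lambda c: c[0])
    return ConsensusResult(
        clusters=clusters,
        threshold=threshold,
        full_consensus=(len(clusters) == 1),
        matrix=matrix,
    )


def full_consensus(
    poses: dict[str, Pose], threshold: float = 2.0, symmetry: bool = True
) -> tuple[bool, RmsdMatrix]:
    """True iff every reciprocal pose RMSD is strictly below the threshold."""
    if len(poses) < 2:
        raise PharmflowError("full consensus needs poses from >= 2 methods")
    methods = sorted(poses)
    n = len(methods)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pose_rmsd(poses[methods[i]], poses[methods[j]], symmetry=symmetry)
            values[i, j] = values[j, i] = r
    matrix = RmsdMatrix(labels=methods, values=values)
    flag = bool(matrix.max_offdiag < threshold)
    return flag, matrix


# ---------------------------------------------------------------------------
# Self-docking validation


@dataclass
class SelfDockReport:
    table: pd.DataFrame  # columns: method, rmsd, passed; sorted by rmsd
    threshold: float

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def passing_methods(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "method"])


def selfdock_validate(
    predicted: dict[str, "Pose | float"],
    reference: Pose | None = None,
    threshold: float = 2.0,
    symmetry: bool = True,
) -> SelfDockReport:
    """Per-method self-docking RMSD table with strict-threshold pass flags.

    ``predicted`` maps method labels to either poses (RMSD computed against
    ``reference``) or precomputed RMSD values in Å. A method passes when
    its RMSD is strictly below the threshold (boundary values fail).
    """
    rows = []
    for method in sorted(predicted):
        value = predicted[method]
        if isinstance(value, Pose):
            if reference is None:
                raise PharmflowError(
                    "reference pose required when poses are supplied"
                )
            rmsd_val = pose_rmsd(reference, value, symmetry=symmetry)
        else:
            rmsd_val = float(value)
        rows.append({"method": method, "rmsd": rmsd_val})
    table = pd.DataFrame(rows).sort_values(
        ["rmsd", "method"], kind="mergesort", ignore_index=True
    )
    table["passed"] = table["rmsd"] < threshold
    return SelfDockReport(table=table, threshold=threshold)
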