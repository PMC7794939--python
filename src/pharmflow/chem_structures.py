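"""Domain types and file I/O for molecules, proteins, poses and trajectories.

Small molecules are carried by :class:`Molecule` (explicit atoms, bonds and
one or more conformers); proteins by :class:`ProteinStructure` (residues with
named atoms, waters flagged). Coordinates are in Å everywhere. PDB reading
and writing is backed by gemmi; SDF/MOL2/SMILES by RDKit. Hydrogens are
optional throughout: all downstream geometric criteria operate on heavy
atoms, so un-protonated inputs work.

Trajectories are multi-model PDB only — a deliberate, documented limitation
that keeps the toolkit free of binary-format dependencies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    MoleculeError,
    PDBParseError,
    PharmflowError,
    SelectorError,
    TrajectoryError,
)

WATER_NAMES = {"HOH", "WAT", "H2O", "TIP3"}

#: Aromatic bond order sentinel used in Bond.order.
AROMATIC = "ar"

_DEFAULT_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3, "Si": 4,
}

#: Rough single-bond covalent radii (Å) for distance-based bond inference.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Si": 1.11,
}


# ---------------------------------------------------------------------------
# Small-molecule types


@dataclass(frozen=True)
class MolAtom:
    element: str
    formal_charge: int = 0
    #: hydrogens bound to this atom but absent from the graph; None means
    #: "derive from standard valence" (set by RDKit-backed readers)
    hydrogens: int | None = None

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class Bond:
    """Bond between atom indices i < j; order in {1, 2, 3, 'ar'}."""

    i: int
    j: int
    order: int | str = 1

    def __post_init__(self):
        if self.i == self.j:
            raise MoleculeError(f"self-bond on atom {self.i}")
        if self.order not in (1, 2, 3, AROMATIC):
            raise MoleculeError(f"unsupported bond order {self.order!r}")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def order_value(self) -> float:
        return 1.5 if self.order == AROMATIC else float(self.order)


@dataclass
class Molecule:
    """A small molecule: atoms, bonds and >= 1 conformer (coordinates in Å)."""

    name: str
    atoms: list[MolAtom]
    bonds: list[Bond]
    conformers: list[np.ndarray]
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        if sum(a.is_heavy for a in self.atoms) < 1:
            raise MoleculeError(f"{self.name!r}: needs at least one heavy atom")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise MoleculeError(
                    f"{self.name!r}: bond ({b.i},{b.j}) references a missing atom"
                )
            if (b.i, b.j) in seen:
                raise MoleculeError(f"{self.name!r}: duplicate bond ({b.i},{b.j})")
            seen.add((b.i, b.j))
        if not self.conformers:
            raise MoleculeError(f"{self.name!r}: needs at least one conformer")
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for k, c in enumerate(self.conformers):
            if c.shape != (n, 3):
                raise MoleculeError(
                    f"{self.name!r}: conformer {k} has shape {c.shape}, expected ({n}, 3)"
                )

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def coords(self, conformer: int = 0) -> np.ndarray:
        return self.conformers[conformer]

    def heavy_coords(self, conformer: int = 0) -> np.ndarray:
        return self.conformers[conformer][self.heavy_indices]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def adjacency(self) -> dict[int, list[tuple[int, Bond]]]:
        adj: dict[int, list[tuple[int, Bond]]] = {i: [] for i in range(self.n_atoms)}
        for b in self.bonds:
            adj[b.i].append((b.j, b))
            adj[b.j].append((b.i, b))
        return adj

    def explicit_h_count(self, i: int) -> int:
        return sum(1 for j in self.neighbors(i) if self.atoms[j].element == "H")

    def implicit_h_count(self, i: int) -> int:
        """Hydrogens implied by standard valence minus the explicit bond sum.

        Uses effective valence = default + formal charge (correct for the
        common organic cases N+, O-, N-...); aromatic bonds count 1.5.
        """
        a = self.atoms[i]
        default = _DEFAULT_VALENCE.get(a.element)
        if default is None:
            return 0
        bond_sum = 0.0
        for b in self.bonds:
            if i in (b.i, b.j):
                bond_sum += b.order_value
        return max(0, int(round(default + a.formal_charge - bond_sum)))

    def total_h_count(self, i: int) -> int:
        stored = self.atoms[i].hydrogens
        extra = stored if stored is not None else self.implicit_h_count(i)
        return self.explicit_h_count(i) + extra

    # -- derived copies -----------------------------------------------------

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Molecule":
        return Molecule(
            name=name or self.name,
            atoms=list(self.atoms),
            bonds=list(self.bonds),
            conformers=[np.asarray(coords, dtype=float)],
            properties=dict(self.properties),
        )

    def translated(self, vec, conformer: int = 0) -> "Molecule":
        return self.with_coords(self.conformers[conformer] + np.asarray(vec, float))

    def transformed(self, R: np.ndarray, t: np.ndarray, conformer: int = 0) -> "Molecule":
        return self.with_coords(self.conformers[conformer] @ R.T + t)

    # -- RDKit bridge -------------------------------------------------------

    def to_rdkit(self, sanitize: bool = True):
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}
        rw = Chem.RWMol()
        for a in self.atoms:
            atom = Chem.Atom(a.element)
            atom.SetFormalCharge(a.formal_charge)
            if a.hydrogens is not None:
                atom.SetNumExplicitHs(a.hydrogens)
                atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_map[b.order])
            if b.order == AROMATIC:
                rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
                rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
                rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
        mol = rw.GetMol()
        mol.SetProp("_Name", self.name)
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # noqa: BLE001 - surface as domain error
                raise MoleculeError(f"{self.name!r}: RDKit sanitization failed: {exc}")
        for conf_xyz in self.conformers:
            conf = Chem.Conformer(self.n_atoms)
            for i, (x, y, z) in enumerate(conf_xyz):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
        return mol

    @classmethod
    def from_rdkit(cls, mol, name: str | None = None) -> "Molecule":
        from rdkit import Chem

        atoms = [
            MolAtom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(False))
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC or b.GetIsAromatic():
                order: int | str = AROMATIC
            else:
                order = int(round(b.GetBondTypeAsDouble()))
            bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        if mol.GetNumConformers() == 0:
            conformers = [np.zeros((mol.GetNumAtoms(), 3))]
        else:
            conformers = [
                np.array(c.GetPositions(), dtype=float) for c in mol.GetConformers()
            ]
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else "molecule"
        return cls(name=name, atoms=atoms, bonds=bonds, conformers=conformers)


# ---------------------------------------------------------------------------
# Protein types


@dataclass
class ProteinAtom:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[ProteinAtom]
    insertion: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.insertion)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> ProteinAtom:
        hits = [a for a in self.atoms if a.name == name]
        if len(hits) != 1:
            raise SelectorError(
                f"residue {self.chain}{self.number}{self.insertion} {self.name}: "
                f"{len(hits)} atoms named {name!r}"
            )
        return hits[0]


@dataclass
class ProteinStructure:
    """Residue-ordered protein (plus waters and any other HET groups)."""

    residues: list[Residue]

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.key in seen:
                raise PharmflowError(f"duplicate residue key {r.key}")
            seen.add(r.key)
        for r in self.residues:
            if r.is_water:
                n_ox = sum(1 for a in r.atoms if a.element == "O")
                if n_ox != 1:
                    raise PharmflowError(
                        f"water {r.key} has {n_ox} oxygen atoms, expected 1"
                    )

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def iter_atoms(self):
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def heavy_atom_coords(self) -> np.ndarray:
        return np.array(
            [a.coords for _, a in self.iter_atoms() if a.is_heavy], dtype=float
        )

    def all_coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        """Copy with atom coordinates replaced (flat residue-major order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise PharmflowError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        residues = []
        k = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(ProteinAtom(a.name, a.element, coords[k]))
                k += 1
            residues.append(Residue(r.chain, r.number, r.name, atoms, r.insertion))
        return ProteinStructure(residues)


@dataclass(frozen=True)
class ResidueSelector:
    """Names one residue (and optionally one atom) in a ProteinStructure."""

    chain: str
    number: int
    name: str | None = None
    atom: str | None = None
    insertion: str = ""

    def resolve(self, protein: ProteinStructure) -> Residue:
        hits = [
            r
            for r in protein.residues
            if r.chain == self.chain
            and r.number == self.number
            and r.insertion == self.insertion
            and (self.name is None or r.name == self.name)
        ]
        if len(hits) != 1:
            raise SelectorError(f"selector {self} resolved {len(hits)} residues")
        return hits[0]

    def resolve_atom(self, protein: ProteinStructure) -> tuple[Residue, ProteinAtom]:
        res = self.resolve(protein)
        if self.atom is None:
            raise SelectorError(f"selector {self} names no atom")
        return res, res.atom(self.atom)

    def label(self) -> str:
        base = f"{self.chain}:{self.name or '?'}{self.number}{self.insertion}"
        return f"{base}.{self.atom}" if self.atom else base


# ---------------------------------------------------------------------------
# Pose and trajectory


@dataclass
class Pose:
    """A single-conformer molecule fixed in the receptor frame."""

    molecule: Molecule
    method: str
    score: float | None = None

    def __post_init__(self):
        if not self.method:
            raise PharmflowError("pose method label must be non-empty")
        if len(self.molecule.conformers) != 1:
            self.molecule = self.molecule.with_coords(self.molecule.coords(0))

    @property
    def coords(self) -> np.ndarray:
        return self.molecule.coords(0)


@dataclass
class Trajectory:
    """Frames of a protein-ligand complex (protein atoms first, then ligand)."""

    protein: ProteinStructure
    ligand: Molecule
    frames: np.ndarray  # (n_frames, n_protein_atoms + n_ligand_atoms, 3)
    frame_interval_ns: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        n_total = self.protein.n_atoms + self.ligand.n_atoms
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_total, 3):
            raise TrajectoryError(
                f"frames shape {self.frames.shape} incompatible with topology "
                f"({n_total} atoms)"
            )
        if self.frames.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def protein_coords(self, frame: int) -> np.ndarray:
        return self.frames[frame, : self.protein.n_atoms]

    def ligand_coords(self, frame: int) -> np.ndarray:
        return self.frames[frame, self.protein.n_atoms :]

    def protein_at(self, frame: int) -> ProteinStructure:
        return self.protein.with_coords(self.protein_coords(frame))

    def ligand_at(self, frame: int) -> Molecule:
        return self.ligand.with_coords(self.ligand_coords(frame))


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)


def _prevalidate_pdb(path: str) -> None:
    """Cheap scan guaranteeing line-numbered errors for malformed records."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError("truncated ATOM/HETATM record", lineno)
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise PDBParseError("unparsable coordinates", lineno)
                try:
                    int(line[22:26])
                except ValueError:
                    raise PDBParseError("unparsable residue number", lineno)


def _gemmi_model_to_residues(model) -> list[Residue]:
    residues = []
    for chain in model:
        for res in chain:
            atoms = []
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue  # keep altloc A or blank, drop others
                atoms.append(
                    ProteinAtom(
                        name=atom.name,
                        element=atom.element.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain=chain.name,
                        number=res.seqid.num,
                        name=res.name,
                        atoms=atoms,
                        insertion=(res.seqid.icode or "").strip(),
                    )
                )
    return residues


def _residue_to_molecule(res: Residue, name: str) -> Molecule:
    atoms = [MolAtom(a.element) for a in res.atoms]
    coords = np.array([a.coords for a in res.atoms])
    elements = [a.element for a in res.atoms]
    bonds = assign_bond_orders(elements, coords, infer_bonds(elements, coords))
    return Molecule(name=name, atoms=atoms, bonds=bonds, conformers=[coords])


def infer_bonds(elements: list[str], coords: np.ndarray, slack: float = 0.45) -> list[Bond]:
    """Distance-based bond inference from covalent radii (single bonds only).

    Used for ligands extracted from PDB, where connectivity is not recorded.
    """
    coords = np.asarray(coords, dtype=float)
    bonds = []
    n = len(elements)
    for i in range(n):
        ri = _COVALENT_RADII.get(elements[i], 0.77)
        for j in range(i + 1, n):
            rj = _COVALENT_RADII.get(elements[j], 0.77)
            if np.linalg.norm(coords[i] - coords[j]) <= ri + rj + slack:
                bonds.append(Bond(i, j, 1))
    return bonds


def assign_bond_orders(
    elements: list[str], coords: np.ndarray, bonds: list[Bond]
) -> list[Bond]:
    """Geometric bond-order assignment for PDB-extracted ligands.

    PDB records carry no ligand bond orders, so orders are inferred from
    geometry: terminal O at carbonyl/sulfonyl distance (C=O <= 1.30 Å,
    S=O <= 1.50 Å) becomes a double bond, and planar 5/6-rings of C/N with
    bond lengths in the aromatic window (1.30-1.45 Å) become aromatic.
    A documented heuristic, not a valence model.
    """
    import networkx as nx

    coords = np.asarray(coords, dtype=float)
    degree: dict[int, int] = {}
    for b in bonds:
        degree[b.i] = degree.get(b.i, 0) + 1
        degree[b.j] = degree.get(b.j, 0) + 1

    def dist(i, j):
        return float(np.linalg.norm(coords[i] - coords[j]))

    G = nx.Graph()
    for b in bonds:
        if elements[b.i] in ("C", "N") and elements[b.j] in ("C", "N"):
            if 1.30 <= dist(b.i, b.j) <= 1.45:
                G.add_edge(b.i, b.j)
    aromatic_edges: set[tuple[int, int]] = set()
    if G.number_of_edges() >= 5:
        for ring in nx.minimum_cycle_basis(G):
            if len(ring) not in (5, 6):
                continue
            pts = coords[list(ring)]
            centered = pts - pts.mean(axis=0)
            if np.linalg.svd(centered, compute_uv=False)[-1] > 0.15:
                continue  # non-planar ring
            ring_set = set(ring)
            for b in bonds:
                if b.i in ring_set and b.j in ring_set and G.has_edge(b.i, b.j):
                    aromatic_edges.add((b.i, b.j))

    out = []
    for b in bonds:
        if (b.i, b.j) in aromatic_edges:
            out.append(Bond(b.i, b.j, AROMATIC))
            continue
        pair = {elements[b.i], elements[b.j]}
        terminal_o = (elements[b.i] == "O" and degree[b.i] == 1) or (
            elements[b.j] == "O" and degree[b.j] == 1
        )
        if terminal_o and pair == {"C", "O"} and dist(b.i, b.j) <= 1.30:
            out.append(Bond(b.i, b.j, 2))
        elif terminal_o and pair == {"O", "S"} and dist(b.i, b.j) <= 1.50:
            out.append(Bond(b.i, b.j, 2))
        else:
            out.append(b)
    return out


def read_pdb(
    path: str, ligand_resname: str | None = None
) -> ProteinStructure | tuple[ProteinStructure, Molecule]:
    """Read a PDB file; optionally extract a bound HET ligand by residue name.

    Waters (HOH/WAT) are flagged on the returned structure; hydrogens are
    kept if present. With ``ligand_resname`` the matching residue is removed
    from the protein and returned as a Molecule (bonds inferred by distance).
    """
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # noqa: BLE001
        raise PDBParseError(f"gemmi failed to parse {path}: {exc}")
    if len(st) == 0:
        raise PDBParseError(f"no models in {path}")
    residues = _gemmi_model_to_residues(st[0])
    if ligand_resname is None:
        return ProteinStructure(residues)
    lig_res = [r for r in residues if r.name == ligand_resname]
    if len(lig_res) != 1:
        raise SelectorError(
            f"{len(lig_res)} residues named {ligand_resname!r} in {path}"
        )
    rest = [r for r in residues if r is not lig_res[0]]
    ligand = _residue_to_molecule(lig_res[0], name=ligand_resname)
    return ProteinStructure(rest), ligand


def _build_gemmi_structure(
    protein: ProteinStructure,
    ligand: Molecule | None = None,
    frames: list[tuple[np.ndarray, np.ndarray | None]] | None = None,
    ligand_resname: str = "LIG",
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "pharmflow"
    if frames is None:
        lig_xyz = ligand.coords(0) if ligand is not None else None
        frames = [(protein.all_coords(), lig_xyz)]
    for model_no, (prot_xyz, lig_xyz) in enumerate(frames, start=1):
        model = gemmi.Model(model_no)
        chains: dict[str, gemmi.Chain] = {}
        k = 0
        for r in protein.residues:
            if r.chain not in chains:
                chains[r.chain] = gemmi.Chain(r.chain)
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.insertion or " ")
            res.het_flag = "H" if r.is_water else "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                x, y, z = prot_xyz[k]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                res.add_atom(atom)
                k += 1
            chains[r.chain].add_residue(res)
        if lig_xyz is not None and ligand is not None:
            lig_chain = gemmi.Chain("X")
            res = gemmi.Residue()
            res.name = ligand_resname
            res.seqid = gemmi.SeqId(900, " ")
            res.het_flag = "H"
            counts: dict[str, int] = {}
            for i, a in enumerate(ligand.atoms):
                counts[a.element] = counts.get(a.element, 0) + 1
                atom = gemmi.Atom()
                atom.name = f"{a.element}{counts[a.element]}"[:4]
                atom.element = gemmi.Element(a.element)
                x, y, z = lig_xyz[i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                res.add_atom(atom)
            lig_chain.add_residue(res)
            model.add_chain(lig_chain)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    return st


def write_pdb(
    path: str,
    protein: ProteinStructure,
    ligand: Molecule | None = None,
    ligand_resname: str = "LIG",
) -> None:
    st = _build_gemmi_structure(protein, ligand, ligand_resname=ligand_resname)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Small-molecule I/O (RDKit-backed)


def read_molecules(
    path: str,
    fmt: str | None = None,
    strict: bool = False,
    merge_conformers: bool = False,
) -> list[Molecule]:
    """Read molecules from SDF, MOL2 or SMILES files.

    Unparsable records are skipped with a warning (or raise in strict mode).
    With ``merge_conformers``, consecutive SDF records sharing a name and
    heavy-atom count are merged into one multi-conformer Molecule.
    """
    from rdkit import Chem

    path = str(path)
    if fmt is None:
        low = path.lower()
        if low.endswith((".sdf", ".sd", ".mol")):
            fmt = "sdf"
        elif low.endswith(".mol2"):
            fmt = "mol2"
        elif low.endswith((".smi", ".smiles")):
            fmt = "smiles"
        else:
            raise PharmflowError(f"cannot infer molecule format from {path!r}")
    fmt = fmt.lower()

    mols: list[Molecule] = []
    skipped = 0
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        for idx, rd in enumerate(supplier):
            if rd is None:
                skipped += 1
                if strict:
                    raise MoleculeError(f"unparsable SDF record {idx} in {path}")
                continue
            mols.append(Molecule.from_rdkit(rd))
    elif fmt == "mol2":
        # Tripos atom typing is read for element inference only (via RDKit).
        rd = Chem.MolFromMol2File(path, removeHs=False, sanitize=True)
        if rd is None:
            rd = Chem.MolFromMol2File(path, removeHs=False, sanitize=False)
        if rd is None:
            if strict:
                raise MoleculeError(f"unparsable MOL2 file {path}")
            skipped += 1
        else:
            mols.append(Molecule.from_rdkit(rd))
    elif fmt == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rd = Chem.MolFromSmiles(parts[0])
                if rd is None:
                    skipped += 1
                    if strict:
                        raise MoleculeError(
                            f"unparsable SMILES on line {idx + 1} of {path}"
                        )
                    continue
                name = parts[1].strip() if len(parts) > 1 else f"smi{idx}"
                mols.append(Molecule.from_rdkit(rd, name=name))
    else:
        raise PharmflowError(f"unsupported molecule format {fmt!r}")

    if skipped:
        warnings.warn(f"skipped {skipped} unparsable record(s) in {path}")
    if merge_conformers and fmt == "sdf":
        mols = _merge_consecutive_conformers(mols)
    return mols


def molecule_from_smiles(smiles: str, name: str = "molecule") -> Molecule:
    from rdkit import Chem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise MoleculeError(f"unparsable SMILES {smiles!r}")
    return Molecule.from_rdkit(rd, name=name)


def _merge_consecutive_conformers(mols: list[Molecule]) -> list[Molecule]:
    merged: list[Molecule] = []
    for m in mols:
        if (
            merged
            and merged[-1].name == m.name
            and merged[-1].n_atoms == m.n_atoms
            and [a.element for a in merged[-1].atoms] == [a.element for a in m.atoms]
        ):
            merged[-1] = replace(
                merged[-1], conformers=merged[-1].conformers + m.conformers
            )
        else:
            merged.append(m)
    return merged


def write_molecules(path: str, molecules: list[Molecule]) -> None:
    """Write molecules (all conformers) to an SDF (V2000) file."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    try:
        for m in molecules:
            rd = m.to_rdkit()
            for conf in rd.GetConformers():
                writer.write(rd, confId=conf.GetId())
    finally:
        writer.close()


def read_poses(path: str, method_label: str) -> list[Pose]:
    """Read docking poses (receptor frame) from an SDF file, tagged by method."""
    if not method_label:
        raise PharmflowError("method label must be non-empty")
    out = []
    for m in read_molecules(path, fmt="sdf"):
        out.append(Pose(molecule=m, method=method_label))
    return out


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-model PDB)


def read_trajectory(
    path: str, ligand_resname: str = "LIG", frame_interval_ns: float | None = None
) -> Trajectory:
    """Read a multi-model PDB of a complex; frames ordered by MODEL number."""
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # noqa: BLE001
        raise PDBParseError(f"gemmi failed to parse {path}: {exc}")
    if len(st) == 0:
        raise TrajectoryError(f"no models in {path}")

    models = sorted(st, key=lambda m: m.num)
    ref_residues = _gemmi_model_to_residues(models[0])
    lig_res = [r for r in ref_residues if r.name == ligand_resname]
    if len(lig_res) != 1:
        raise SelectorError(
            f"{len(lig_res)} residues named {ligand_resname!r} in {path}"
        )
    protein = ProteinStructure([r for r in ref_residues if r is not lig_res[0]])
    ligand = _residue_to_molecule(lig_res[0], name=ligand_resname)

    n_expected = protein.n_atoms + ligand.n_atoms
    frames = []
    for model in models:
        residues = _gemmi_model_to_residues(model)
        n_here = sum(len(r.atoms) for r in residues)
        if n_here != n_expected:
            raise TrajectoryError(
                f"model {model.num} has {n_here} atoms, expected {n_expected}"
            )
        prot_xyz = []
        lig_xyz = None
        for r in residues:
            if r.name == ligand_resname:
                lig_xyz = [a.coords for a in r.atoms]
            else:
                prot_xyz.extend(a.coords for a in r.atoms)
        if lig_xyz is None or len(lig_xyz) != ligand.n_atoms:
            raise TrajectoryError(f"model {model.num} is missing ligand atoms")
        frames.append(np.vstack([np.array(prot_xyz), np.array(lig_xyz)]))
    return Trajectory(
        protein=protein,
        ligand=ligand,
        frames=np.array(frames),
        frame_interval_ns=frame_interval_ns,
    )


def write_trajectory(path: str, traj: Trajectory, ligand_resname: str = "LIG") -> None:
    frames = [
        (traj.protein_coords(f), traj.ligand_coords(f)) for f in range(traj.n_frames)
    ]
    st = _build_gemmi_structure(
        traj.protein, traj.ligand, frames=frames, ligand_resname=ligand_resname
    )
    st.setup_entities()
    st.write_pdb(str(path))
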