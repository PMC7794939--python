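"""Geometric detection of protein-ligand interactions and pose filtering.

Detection covers the inventory a reversible serine-hydrolase inhibitor
campaign cares about: direct hydrogen bonds (e.g. to the oxyanion-hole
backbone nitrogens), water-bridged hydrogen-bond networks, per-residue
hydrophobic contacts and face-to-face pi-stacking with aromatic side
chains. Criteria are heavy-atom based by default (donor-H angle applied
only when hydrogens are present), so un-protonated X-ray structures and
docking poses are handled uniformly.

The pose filter reproduces an interaction-based post-docking triage: a pose
passes when every required hydrogen-bond partner is engaged (the structural
water via its bridge) and at least ``min_hydrophobic`` of the model's
hydrophobic spheres are matched in place.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geom import angle_deg, interplanar_angle, plane_normal
from .chem_structures import (
    Molecule,
    Pose,
    ProteinAtom,
    ProteinStructure,
    Residue,
    ResidueSelector,
)
from .errors import PharmflowError, SelectorError
from .perception import (
    KIND_HBA,
    KIND_HBD,
    HALOGENS,
    perceive_features,
)

HBOND = "HBOND"
WATER_BRIDGE = "WATER_BRIDGE"
HYDROPHOBIC = "HYDROPHOBIC"
PI_STACK = "PI_STACK"

_TYPE_ORDER = {HBOND: 0, WATER_BRIDGE: 1, HYDROPHOBIC: 2, PI_STACK: 3}

#: Hydroxyl oxygens that can donate as well as accept.
_DONOR_OXYGENS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}

#: Aromatic side-chain ring atom names (6-rings and the HIS/TRP 5-rings).
SIDECHAIN_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs. Defaults are common literature values; the source
    software for such inventories never publishes its own, so these are
    explicit, configurable data."""

    hbond_dist: float = 3.5
    hbond_min_donor_angle: float = 120.0
    hydrophobic_dist: float = 4.5
    pistack_dist: float = 4.5
    pistack_max_angle: float = 30.0

    def __post_init__(self):
        for name in ("hbond_dist", "hydrophobic_dist", "pistack_dist"):
            if getattr(self, name) <= 0:
                raise PharmflowError(f"{name} must be positive")
        for name in ("hbond_min_donor_angle", "pistack_max_angle"):
            if not (0.0 < getattr(self, name) < 180.0):
                raise PharmflowError(f"{name} must be in (0, 180) degrees")


@dataclass(frozen=True)
class InteractionRecord:
    itype: str
    ligand_atoms: tuple[int, ...]
    residue_key: tuple[str, int, str]
    residue_name: str
    atom_names: tuple[str, ...]
    distance: float
    angle: float | None = None
    bridged_partners: tuple[str, ...] = ()

    def __str__(self) -> str:
        chain, num, icode = self.residue_key
        tag = f"{self.itype} {chain}:{self.residue_name}{num}{icode}"
        return f"{tag} {'/'.join(self.atom_names)} d={self.distance:.2f}"


# ---------------------------------------------------------------------------
# Protein-side atom typing


def _intra_residue_bonds(res: Residue, cutoff: float = 1.8) -> dict[int, list[int]]:
    xyz = np.array([a.coords for a in res.atoms])
    n = len(res.atoms)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    if n > 1:
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] < cutoff:
                    adj[i].append(j)
                    adj[j].append(i)
    return adj


def protein_apolar_atoms(
    protein: ProteinStructure, include_waters: bool = False
) -> list[tuple[Residue, ProteinAtom]]:
    """C/S/halogen protein atoms with no covalently attached N/O.

    Connectivity is inferred within each residue by distance, which is
    sufficient to exclude backbone CA (bonded to N) and carbonyl C.
    """
    out = []
    for res in protein.residues:
        if res.is_water and not include_waters:
            continue
        adj = _intra_residue_bonds(res)
        for i, atom in enumerate(res.atoms):
            if atom.element not in {"C", "S"} | HALOGENS:
                continue
            if any(res.atoms[j].element in ("N", "O") for j in adj[i]):
                continue
            out.append((res, atom))
    return out


def _protein_donor_atoms(res: Residue) -> list[ProteinAtom]:
    donors = []
    for a in res.atoms:
        if a.element == "N":
            donors.append(a)
        elif a.element == "O":
            if res.is_water or (res.name, a.name) in _DONOR_OXYGENS:
                donors.append(a)
    return donors


def _protein_acceptor_atoms(res: Residue) -> list[ProteinAtom]:
    acceptors = []
    for a in res.atoms:
        if a.element == "O":
            acceptors.append(a)
        elif a.element == "N" and res.name == "HIS" and a.name in ("ND1", "NE2"):
            acceptors.append(a)
    return acceptors


def _attached_hydrogens(res: Residue, donor: ProteinAtom) -> list[ProteinAtom]:
    return [
        a
        for a in res.atoms
        if a.element == "H" and np.linalg.norm(a.coords - donor.coords) < 1.3
    ]


def _ligand_attached_hydrogens(mol: Molecule, i: int, xyz: np.ndarray) -> list[np.ndarray]:
    return [xyz[j] for j in mol.neighbors(i) if mol.atoms[j].element == "H"]


def _donor_angle_ok(
    donor_xyz: np.ndarray,
    h_positions: list[np.ndarray],
    acceptor_xyz: np.ndarray,
    criteria: InteractionCriteria,
) -> tuple[bool, float | None]:
    """D-H...A angle test; skipped (True) when no hydrogen is present."""
    if not h_positions:
        return True, None
    best = max(angle_deg(donor_xyz, h, acceptor_xyz) for h in h_positions)
    return best >= criteria.hbond_min_donor_angle, best


# ---------------------------------------------------------------------------
# Detection


def detect_interactions(
    protein: ProteinStructure,
    pose: Pose,
    criteria: InteractionCriteria | None = None,
    include_waters: bool = True,
) -> list[InteractionRecord]:
    """All H-bond, hydrophobic and pi-stacking contacts of a pose.

    Water oxygens participate as H-bond partners when ``include_waters``
    (bridge topology is resolved separately by :func:`detect_water_bridge`).
    Records are sorted by type, then residue.
    """
    criteria = criteria or InteractionCriteria()
    mol = pose.molecule
    xyz = pose.coords

    lig_centroid = xyz[mol.heavy_indices].mean(axis=0)
    prot_xyz = protein.heavy_atom_coords()
    if len(prot_xyz) and np.linalg.norm(lig_centroid - prot_xyz.mean(axis=0)) > 50.0:
        warnings.warn(
            "ligand centroid > 50 Å from protein centroid; frames may differ"
        )

    feats = perceive_features(mol, 0)
    lig_acceptors = sorted(
        {f.source_atoms[0] for f in feats if f.kind == KIND_HBA}
    )
    lig_donors = sorted({f.source_atoms[0] for f in feats if f.kind == KIND_HBD})
    lig_apolar = [
        i
        for i in mol.heavy_indices
        if mol.atoms[i].element in {"C", "S"} | HALOGENS
        and all(mol.atoms[j].element not in ("N", "O") for j in mol.neighbors(i))
    ]
    from .perception import aromatic_rings

    lig_rings = aromatic_rings(mol)

    records: list[InteractionRecord] = []
    for res in protein.residues:
        if res.is_water and not include_waters:
            continue

        # H-bonds: ligand acceptor vs protein donor
        for d in _protein_donor_atoms(res):
            for i in lig_acceptors:
                dist = float(np.linalg.norm(xyz[i] - d.coords))
                if dist <= criteria.hbond_dist:
                    ok, ang = _donor_angle_ok(
                        d.coords, [h.coords for h in _attached_hydrogens(res, d)],
                        xyz[i], criteria,
                    )
                    if ok:
                        records.append(
                            InteractionRecord(
                                HBOND, (i,), res.key, res.name, (d.name,), dist, ang
                            )
                        )
        # H-bonds: ligand donor vs protein acceptor
        for a in _protein_acceptor_atoms(res):
            for i in lig_donors:
                dist = float(np.linalg.norm(xyz[i] - a.coords))
                if dist <= criteria.hbond_dist:
                    ok, ang = _donor_angle_ok(
                        xyz[i], _ligand_attached_hydrogens(mol, i, xyz),
                        a.coords, criteria,
                    )
                    if ok:
                        records.append(
                            InteractionRecord(
                                HBOND, (i,), res.key, res.name, (a.name,), dist, ang
                            )
                        )

        # hydrophobic contacts, aggregated per residue
        if not res.is_water:
            adj = _intra_residue_bonds(res)
            res_apolar = [
                (j, atom)
                for j, atom in enumerate(res.atoms)
                if atom.element in {"C", "S"} | HALOGENS
                and not any(res.atoms[k].element in ("N", "O") for k in adj[j])
            ]
            best: tuple[float, int, str] | None = None
            involved: set[int] = set()
            for i in lig_apolar:
                for _, atom in res_apolar:
                    dist = float(np.linalg.norm(xyz[i] - atom.coords))
                    if dist <= criteria.hydrophobic_dist:
                        involved.add(i)
                        if best is None or dist < best[0]:
                            best = (dist, i, atom.name)
            if best is not None:
                records.append(
                    InteractionRecord(
                        HYDROPHOBIC,
                        tuple(sorted(involved)),
                        res.key,
                        res.name,
                        (best[2],),
                        best[0],
                    )
                )

        # pi-stacking with aromatic side chains
        for ring_names in SIDECHAIN_RINGS.get(res.name, []):
            try:
                ring_xyz = np.array([res.atom(n).coords for n in ring_names])
            except SelectorError:
                continue  # incomplete side chain
            p_centroid = ring_xyz.mean(axis=0)
            p_normal = plane_normal(ring_xyz)
            for ring in lig_rings:
                l_xyz = xyz[list(ring)]
                l_centroid = l_xyz.mean(axis=0)
                dist = float(np.linalg.norm(l_centroid - p_centroid))
                if dist > criteria.pistack_dist:
                    continue
                ang = interplanar_angle(plane_normal(l_xyz), p_normal)
                if ang <= criteria.pistack_max_angle:
                    records.append(
                        InteractionRecord(
                            PI_STACK, tuple(ring), res.key, res.name,
                            ring_names, dist, ang,
                        )
                    )

    records.sort(key=lambda r: (_TYPE_ORDER[r.itype], r.residue_key, r.ligand_atoms))
    return records


def detect_water_bridge(
    protein: ProteinStructure,
    pose: Pose,
    water: ResidueSelector,
    partners: list[ResidueSelector],
    criteria: InteractionCriteria | None = None,
) -> InteractionRecord | None:
    """Water-bridged H-bond: ligand <-> water O <-> >= 1 named partner.

    Returns a WATER_BRIDGE record naming the bridged partners, or None.
    The bridge is satisfied by any one partner arm; requiring every arm
    each frame would overstate what a fluctuating network maintains.
    """
    criteria = criteria or InteractionCriteria()
    wres = water.resolve(protein)
    if not wres.is_water:
        raise SelectorError(f"selector {water} resolves to non-water {wres.name}")
    w_o = next(a for a in wres.atoms if a.element == "O")

    mol = pose.molecule
    xyz = pose.coords
    feats = perceive_features(mol, 0)
    polar = sorted(
        {f.source_atoms[0] for f in feats if f.kind in (KIND_HBA, KIND_HBD)}
    )
    lig_hits = [
        i
        for i in polar
        if np.linalg.norm(xyz[i] - w_o.coords) <= criteria.hbond_dist
    ]
    if not lig_hits:
        return None

    bridged = []
    for sel in partners:
        res = sel.resolve(protein)
        if sel.atom is not None:
            atoms = [res.atom(sel.atom)]
        else:
            atoms = [a for a in res.atoms if a.element in ("N", "O")]
        if any(
            np.linalg.norm(a.coords - w_o.coords) <= criteria.hbond_dist
            for a in atoms
        ):
            bridged.append(sel.label())
    if not bridged:
        return None

    best = min(float(np.linalg.norm(xyz[i] - w_o.coords)) for i in lig_hits)
    return InteractionRecord(
        WATER_BRIDGE,
        tuple(lig_hits),
        wres.key,
        wres.name,
        ("O",),
        best,
        bridged_partners=tuple(bridged),
    )


# ---------------------------------------------------------------------------
# Pose filter


@dataclass
class PoseFilterSpec:
    """Requirements for the interaction-based pose filter.

    ``hbond_partners`` are residues that must each receive a direct H-bond;
    the structural water (with its network partners) is required as a
    bridge; at least ``min_hydrophobic`` of the model's hydrophobic
    features must be matched in place.
    """

    hbond_partners: list[ResidueSelector] = field(default_factory=list)
    structural_water: ResidueSelector | None = None
    water_partners: list[ResidueSelector] = field(default_factory=list)
    min_hydrophobic: int = 2


@dataclass
class PoseFilterResult:
    passed: bool
    reasons: list[str]
    n_hydrophobic_matched: int
    records: list[InteractionRecord]


def filter_pose(
    protein: ProteinStructure,
    pose: Pose,
    spec: PoseFilterSpec,
    model,
    criteria: InteractionCriteria | None = None,
) -> PoseFilterResult:
    """Pass/fail with reasons; ``model`` supplies the hydrophobic spheres."""
    from .pharmacophore import KIND_HYD_MODEL, match_features_inplace

    criteria = criteria or InteractionCriteria()
    records = detect_interactions(protein, pose, criteria)
    reasons: list[str] = []

    hbonded_keys = {
        (r.residue_key, name)
        for r in records
        if r.itype == HBOND
        for name in r.atom_names
    }
    hbonded_res = {r.residue_key for r in records if r.itype == HBOND}
    for sel in spec.hbond_partners:
        res = sel.resolve(protein)
        ok = (
            (res.key, sel.atom) in hbonded_keys
            if sel.atom is not None
            else res.key in hbonded_res
        )
        if not ok:
            reasons.append(f"missing H-bond with {sel.label()}")

    if spec.structural_water is not None:
        bridge = detect_water_bridge(
            protein, pose, spec.structural_water, spec.water_partners, criteria
        )
        if bridge is None:
            reasons.append(
                f"missing water bridge via {spec.structural_water.label()}"
            )
        else:
            records = records + [bridge]

    hyd_features = [f for f in model.features if f.kind == KIND_HYD_MODEL]
    n_hyd = 0
    if hyd_features:
        feats = perceive_features(pose.molecule, 0)
        matched, _ = match_features_inplace(hyd_features, feats)
        n_hyd = len(matched)
    if n_hyd < spec.min_hydrophobic:
        reasons.append(
            f"only {n_hyd}/{len(hyd_features)} hydrophobic features matched "
            f"(need {spec.min_hydrophobic})"
        )

    return PoseFilterResult(
        passed=not reasons,
        reasons=reasons,
        n_hydrophobic_matched=n_hyd,
        records=records,
    )


def intersect_by_method(results: dict[str, set[str]]) -> set[str]:
    """Compound ids passing the filter under every docking method."""
    if not results:
        raise PharmflowError("need results from at least one method")
    sets = list(results.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out
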