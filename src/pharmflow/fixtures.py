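"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generators build a toy serine-hydrolase-like pocket and matching
ligands entirely from explicit geometry, so that every downstream analysis
(model building, matching, pose filtering, consensus, MD occupancy) has a
known right answer by construction:

* :func:`make_reference_complex` — a ~11-residue pocket mimicking the
  canonical binding-site inventory: two backbone-N donors (oxyanion-hole
  analogues, residues 51/123), a side-chain donor (arginine analogue, 57),
  a structural water H-bonded to a glutamate/histidine pair (53/272), four
  apolar contact clusters and a stacking tyrosine (194). The ligand carries
  four acceptor oxygens (two carbonyls plus a sulfonyl group), two aromatic
  rings, an aliphatic bridge and a chlorine, posed to realize four H-bonds,
  the water bridge, four hydrophobic sites and one pi-stack exactly.
* :func:`make_library` — molecules with planted best-match sizes k in
  {5..8}, produced by structurally disabling optional features (chlorine
  swapped to H, bridge carbon to ether oxygen, distal ring displaced well
  beyond twice the tolerance radius) and re-posing in a random rigid frame.
* :func:`make_pose_ensemble` — rigid translations embedding a requested
  pairwise-RMSD matrix (classical MDS + least-squares refinement).
* :func:`make_trajectory` — frames with exact planted per-interaction
  occupancancy: interaction partners are repositioned frame-by-frame just
  inside (or 0.3 Å outside) the distance cutoff relative to the jittered
  ligand, so counting is immune to noise at the boundary.

Fixtures are geometric, not energetic: bond lengths and pocket packing are
chemically plausible but no force field would accept them. Every generator
is bit-stable under a fixed seed, and self-checks its planted truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import random_rotation
from .benchmarks import CONSENSUS_METHODS
from .chem_structures import (
    AROMATIC,
    Bond,
    MolAtom,
    Molecule,
    Pose,
    ProteinAtom,
    ProteinStructure,
    Residue,
    ResidueSelector,
    Trajectory,
)
from .errors import PharmflowError
from .interactions import (
    HBOND,
    HYDROPHOBIC,
    PI_STACK,
    InteractionCriteria,
    PoseFilterSpec,
    detect_interactions,
    detect_water_bridge,
)
from .trajectory import HBondSpec, WaterBridgeSpec

_CHAIN = "A"

# unit directions of the four planted H-bonds (base frame); the sulfonyl
# oxygens sit perpendicular to the S-C axes so distance-based connectivity
# inference cannot mistake them for ring-carbon bonds
_U_A51 = np.array([-0.5, np.sqrt(3) / 2, 0.0])      # off carbonyl O1
_U_M123 = np.array([0.0, 1.0, 0.0])                 # off sulfonyl O3
_U_R57 = np.array([-0.5, -np.sqrt(3) / 2, 0.0])     # off carbonyl O2
_U_WAT = np.array([0.0, -1.0, 0.0])                 # off sulfonyl O4
_U_E53 = np.array([0.2588, -0.9659, 0.0])           # water -> glutamate arm
_U_H272 = np.array([np.sqrt(3) / 2, -0.5, 0.0])     # water -> histidine arm

#: displacement that disables the distal-ring feature; its magnitude
#: exceeds twice the tolerance radius so no rigid placement can rescue it
_RINGB_BREAK = np.array([0.0, 0.0, -3.2])

OPTIONAL_BREAKS = ("ringB", "Cl", "bridge")


def _hexagon(center, radius, start_angle=0.0, z=0.0):
    out = []
    for k in range(6):
        a = np.radians(start_angle + 60.0 * k)
        out.append(
            np.array(center) + np.array([radius * np.cos(a), radius * np.sin(a), z])
        )
    return out


def _reference_ligand() -> Molecule:
    """The reference-mimic ligand in the base pocket frame (22 heavy atoms)."""
    xyz: list[np.ndarray] = []
    # 0-5: ring A (phenyl) centred at the origin
    xyz.extend(_hexagon((0.0, 0.0, 0.0), 1.39))
    # 6,7: aliphatic bridge; 8: sulfonyl S; 9,10: sulfonyl oxygens
    xyz.append(np.array([2.89, 0.0, 0.0]))
    xyz.append(np.array([4.39, 0.0, 0.0]))
    s = np.array([6.19, 0.0, 0.0])
    xyz.append(s)
    xyz.append(s + 1.43 * _U_M123)
    xyz.append(s + 1.43 * _U_WAT)
    # 11-16: ring B (chlorophenyl), attached to S at its 180-degree vertex
    xyz.extend(_hexagon((9.38, 0.0, 0.0), 1.39, start_angle=180.0))
    # 17: chlorine para to the S attachment
    xyz.append(np.array([12.51, 0.0, 0.0]))
    # 18,19: acyl carbon + carbonyl O1 off ring A vertex A2
    a2 = xyz[2]
    u2 = a2 / np.linalg.norm(a2)
    xyz.append(a2 + 1.5 * u2)
    xyz.append(a2 + (1.5 + 1.23) * u2)
    # 20,21: acyl carbon + carbonyl O2 off ring A vertex A4
    a4 = xyz[4]
    u4 = a4 / np.linalg.norm(a4)
    xyz.append(a4 + 1.5 * u4)
    xyz.append(a4 + (1.5 + 1.23) * u4)

    atoms = [MolAtom("C")] * 8 + [MolAtom("S"), MolAtom("O"), MolAtom("O")]
    atoms += [MolAtom("C")] * 6 + [MolAtom("Cl"), MolAtom("C"), MolAtom("O")]
    atoms += [MolAtom("C"), MolAtom("O")]

    bonds = [Bond(i, (i + 1) % 6, AROMATIC) for i in range(6)]
    bonds += [Bond(0, 6), Bond(6, 7), Bond(7, 8), Bond(8, 9, 2), Bond(8, 10, 2)]
    bonds += [Bond(11 + i, 11 + (i + 1) % 6, AROMATIC) for i in range(6)]
    bonds += [Bond(8, 11), Bond(14, 17), Bond(2, 18), Bond(18, 19, 2)]
    bonds += [Bond(4, 20), Bond(20, 21, 2)]
    return Molecule(
        name="refmimic", atoms=atoms, bonds=bonds, conformers=[np.array(xyz)]
    )


def _backbone(anchor, v, perp) -> list[ProteinAtom]:
    anchor = np.asarray(anchor, float)
    v = np.asarray(v, float)
    n = anchor
    ca = anchor + 1.46 * v
    c = ca + 1.52 * v
    o = c + 1.23 * np.asarray(perp, float)
    return [
        ProteinAtom("N", "N", n),
        ProteinAtom("CA", "C", ca),
        ProteinAtom("C", "C", c),
        ProteinAtom("O", "O", o),
    ]


def _reference_pocket(lig: Molecule) -> ProteinStructure:
    xyz = lig.coords(0)
    o1, o2, o3, o4 = xyz[19], xyz[21], xyz[9], xyz[10]
    w = o4 + 2.8 * _U_WAT
    perp_xy = np.array([0.0, 1.0, 0.0])

    residues = []
    # oxyanion-hole analogue 1: backbone N donates to carbonyl O1
    residues.append(
        Residue(_CHAIN, 51, "ALA", _backbone(o1 + 2.9 * _U_A51, _U_A51,
                                             [np.sqrt(3) / 2, 0.5, 0.0]))
    )
    # glutamate analogue: OE1 H-bonds the structural water
    oe1 = w + 2.8 * _U_E53
    cd = oe1 + 1.31 * _U_E53
    glu_atoms = _backbone(cd + 2.0 * _U_E53 + np.array([1.0, -1.0, 0.0]),
                          _U_E53, perp_xy)
    glu_atoms += [
        ProteinAtom("CD", "C", cd),
        ProteinAtom("OE1", "O", oe1),
        ProteinAtom("OE2", "O", cd + 1.23 * np.array([np.sqrt(3) / 2, 0.5, 0.0])),
    ]
    residues.append(Residue(_CHAIN, 53, "GLU", glu_atoms))
    # arginine analogue: NH1 donates to carbonyl O2
    nh1 = o2 + 2.9 * _U_R57
    cz = nh1 + 1.33 * _U_R57
    arg_atoms = _backbone(cz + 3.0 * _U_R57, _U_R57, perp_xy)
    arg_atoms += [
        ProteinAtom("NE", "N", cz + 1.33 * np.array([np.sqrt(3) / 2, -0.5, 0.0])),
        ProteinAtom("CZ", "C", cz),
        ProteinAtom("NH1", "N", nh1),
        ProteinAtom("NH2", "N", cz + 1.33 * np.array([-np.sqrt(3) / 2, 0.5, 0.0])),
    ]
    residues.append(Residue(_CHAIN, 57, "ARG", arg_atoms))
    # oxyanion-hole analogue 2: backbone N donates to sulfonyl O3
    residues.append(
        Residue(_CHAIN, 123, "MET", _backbone(o3 + 2.9 * _U_M123, _U_M123,
                                              [np.sqrt(3) / 2, -0.5, 0.0]))
    )
    # apolar clusters: isoleucine/leucine analogues boxing the four
    # hydrophobic sites (ring A above+below, bridge, chlorine)
    ile_atoms = _backbone([0.3, 0.3, 6.9], [0.0, 0.0, 1.0], perp_xy)
    ile_atoms += [
        ProteinAtom("CB", "C", [0.0, 0.0, 4.0]),
        ProteinAtom("CG1", "C", [1.0, 0.5, 4.0]),
        ProteinAtom("CG2", "C", [0.0, -1.0, 4.2]),
        ProteinAtom("CD1", "C", [-1.0, 0.5, 4.0]),
    ]
    residues.append(Residue(_CHAIN, 179, "ILE", ile_atoms))
    # stacking tyrosine analogue above ring B
    tyr_ring = _hexagon((9.38, 0.0, 0.0), 1.39, start_angle=180.0, z=3.8)
    tyr_atoms = _backbone([7.99, 0.0, 7.4], [0.0, 0.0, 1.0], perp_xy)
    for name, pos in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                         (tyr_ring[0], tyr_ring[1], tyr_ring[5],
                          tyr_ring[2], tyr_ring[4], tyr_ring[3])):
        tyr_atoms.append(ProteinAtom(name, "C", pos))
    tyr_atoms.append(ProteinAtom("OH", "O", np.array([12.13, 0.0, 3.8])))
    residues.append(Residue(_CHAIN, 194, "TYR", tyr_atoms))
    leu205 = _backbone([13.0, 0.4, -7.5], [0.0, 0.0, -1.0], perp_xy)
    leu205 += [
        ProteinAtom("CD1", "C", [12.51, 0.0, -4.0]),
        ProteinAtom("CD2", "C", [13.3, 0.8, -3.9]),
    ]
    residues.append(Residue(_CHAIN, 205, "LEU", leu205))
    leu213 = _backbone([3.3, 0.4, 7.6], [0.0, 0.0, 1.0], perp_xy)
    leu213 += [
        ProteinAtom("CD1", "C", [3.64, 0.0, 4.0]),
        ProteinAtom("CD2", "C", [3.0, 0.8, 4.2]),
    ]
    residues.append(Residue(_CHAIN, 213, "LEU", leu213))
    leu241 = _backbone([0.3, -0.3, -6.9], [0.0, 0.0, -1.0], perp_xy)
    leu241 += [
        ProteinAtom("CD1", "C", [0.0, 0.0, -4.0]),
        ProteinAtom("CD2", "C", [1.0, -0.5, -4.0]),
    ]
    residues.append(Residue(_CHAIN, 241, "LEU", leu241))
    # histidine analogue: NE2 completes the water network
    ne2 = w + 3.0 * _U_H272
    ctr = ne2 + 1.14 * _U_H272
    his_atoms = _backbone([16.0, -3.7, 0.0], [1.0, 0.0, 0.0], perp_xy)
    ring_names = ("NE2", "CE1", "ND1", "CG", "CD2")
    angles = (180.0, 108.0, 36.0, -36.0, -72.0 - 36.0)
    for name, ang in zip(ring_names, angles):
        a = np.radians(ang)
        pos = ctr + 1.14 * np.array([np.cos(a), np.sin(a), 0.0])
        his_atoms.append(
            ProteinAtom(name, "N" if name.startswith("N") else "C", pos)
        )
    residues.append(Residue(_CHAIN, 272, "HIS", his_atoms))
    # the structural water
    residues.append(Residue(_CHAIN, 401, "HOH", [ProteinAtom("O", "O", w)]))
    return ProteinStructure(residues)


@dataclass
class ReferenceComplex:
    """Toy pocket + posed ligand with full planted interaction inventory."""

    protein: ProteinStructure
    ligand: Molecule
    water: ResidueSelector
    partners: dict[str, ResidueSelector]
    acceptor_atoms: dict[str, int]
    hbond_directions: dict[str, np.ndarray]
    axis_z: np.ndarray  # pocket-frame z axis after the seed rigid motion
    seed: int

    def pose(self, method: str = "reference") -> Pose:
        return Pose(molecule=self.ligand, method=method)

    def pose_filter_spec(self, min_hydrophobic: int = 2) -> PoseFilterSpec:
        return PoseFilterSpec(
            hbond_partners=[
                self.partners["A51"],
                self.partners["M123"],
                self.partners["R57"],
            ],
            structural_water=self.water,
            water_partners=[self.partners["E53"], self.partners["H272"]],
            min_hydrophobic=min_hydrophobic,
        )

    def md_specs(self) -> list[HBondSpec | WaterBridgeSpec]:
        return [
            HBondSpec("A51", self.partners["A51"],
                      (self.acceptor_atoms["A51"],)),
            HBondSpec("M123", self.partners["M123"],
                      (self.acceptor_atoms["M123"],)),
            HBondSpec("R57", self.partners["R57"],
                      (self.acceptor_atoms["R57"],)),
            WaterBridgeSpec(
                "water", self.water,
                (self.partners["E53"], self.partners["H272"]),
            ),
        ]


def _rigid_move_complex(
    protein: ProteinStructure, ligand: Molecule, R: np.ndarray, t: np.ndarray
) -> tuple[ProteinStructure, Molecule]:
    prot = protein.with_coords(protein.all_coords() @ R.T + t)
    lig = ligand.transformed(R, t)
    return prot, lig


def make_reference_complex(seed: int = 0) -> ReferenceComplex:
    """Build the reference-mimic complex, rigidly re-framed by the seed.

    The internal geometry is seed-independent; the seed only rotates and
    translates the whole complex, so different seeds yield different
    coordinates with identical planted interactions. The planted inventory
    (4 H-bonds, a two-armed water bridge, >= 4 hydrophobic residue
    contacts, 1 pi-stack) is verified before returning.
    """
    ligand = _reference_ligand()
    protein = _reference_pocket(ligand)
    rng = np.random.default_rng(seed)
    R = random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, 3)
    protein, ligand = _rigid_move_complex(protein, ligand, R, t)

    sel = lambda num, name, atom=None: ResidueSelector(  # noqa: E731
        _CHAIN, num, name, atom
    )
    ref = ReferenceComplex(
        protein=protein,
        ligand=ligand,
        water=sel(401, "HOH", "O"),
        partners={
            "A51": sel(51, "ALA", "N"),
            "M123": sel(123, "MET", "N"),
            "R57": sel(57, "ARG", "NH1"),
            "E53": sel(53, "GLU", "OE1"),
            "H272": sel(272, "HIS", "NE2"),
        },
        acceptor_atoms={"A51": 19, "M123": 9, "R57": 21, "water": 10},
        hbond_directions={
            "A51": R @ _U_A51,
            "M123": R @ _U_M123,
            "R57": R @ _U_R57,
            "water": R @ _U_WAT,
            "E53": R @ _U_E53,
            "H272": R @ _U_H272,
        },
        axis_z=R @ np.array([0.0, 0.0, 1.0]),
        seed=seed,
    )
    _verify_reference(ref)
    return ref


def _verify_reference(ref: ReferenceComplex) -> None:
    records = detect_interactions(ref.protein, ref.pose())
    hbonds = {
        (r.residue_key[1], r.atom_names[0], r.ligand_atoms[0])
        for r in records
        if r.itype == HBOND
    }
    expected = {
        (51, "N", ref.acceptor_atoms["A51"]),
        (123, "N", ref.acceptor_atoms["M123"]),
        (57, "NH1", ref.acceptor_atoms["R57"]),
        (401, "O", ref.acceptor_atoms["water"]),
    }
    if hbonds != expected:
        raise PharmflowError(
            f"fixture self-check: planted H-bonds {expected} != detected {hbonds}"
        )
    hyd_res = {r.residue_key[1] for r in records if r.itype == HYDROPHOBIC}
    if not {179, 205, 213, 241} <= hyd_res:
        raise PharmflowError(
            f"fixture self-check: hydrophobic contacts missing ({hyd_res})"
        )
    if not any(r.itype == PI_STACK for r in records):
        raise PharmflowError("fixture self-check: pi-stack not detected")
    bridge = detect_water_bridge(
        ref.protein, ref.pose(), ref.water,
        [ref.partners["E53"], ref.partners["H272"]],
    )
    if bridge is None or len(bridge.bridged_partners) != 2:
        raise PharmflowError("fixture self-check: water bridge not detected")


# ---------------------------------------------------------------------------
# Planted-match library


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic generators (all seeded)."""

    seed: int = 0
    n_molecules: int = 100
    match_size_weights: dict[int, float] = field(
        default_factory=lambda: {8: 0.10, 7: 0.20, 6: 0.30, 5: 0.40}
    )
    pose_perturbation: float = 0.1
    n_frames: int = 100
    occupancies: dict[str, float] = field(
        default_factory=lambda: {"R57": 0.98, "water": 0.94,
                                 "A51": 0.82, "M123": 0.30}
    )
    ligand_jitter: float = 0.1


def make_variant(
    ref: ReferenceComplex, broken: set[str], name: str
) -> Molecule:
    """Reference-frame ligand with the given optional features disabled.

    'Cl' swaps the chlorine for H, 'bridge' turns one bridge carbon into an
    ether oxygen, 'ringB' displaces the distal ring beyond recovery. Atom
    indexing is preserved across variants.
    """
    broken = {str(b) for b in broken}
    bad = broken - set(OPTIONAL_BREAKS)
    if bad:
        raise PharmflowError(f"unknown optional features {bad}")
    atoms = list(ref.ligand.atoms)
    xyz = ref.ligand.coords(0).copy()
    if "Cl" in broken:
        atoms[17] = MolAtom("H")
    if "bridge" in broken:
        atoms[7] = MolAtom("O")
    if "ringB" in broken:
        xyz[11:17] += -3.2 * ref.axis_z
    mol = Molecule(
        name=name, atoms=atoms, bonds=list(ref.ligand.bonds), conformers=[xyz]
    )
    mol.properties["broken"] = tuple(sorted(broken))
    mol.properties["planted_n_matched"] = 8 - len(broken)
    return mol


def _level_allocation(n: int, weights: dict[int, float]) -> list[int]:
    levels = sorted(weights, reverse=True)
    counts = {k: int(np.floor(weights[k] * n)) for k in levels}
    rest = n - sum(counts.values())
    fracs = sorted(
        levels, key=lambda k: (weights[k] * n - counts[k], k), reverse=True
    )
    for k in fracs[:rest]:
        counts[k] += 1
    out = []
    for k in levels:
        out.extend([k] * counts[k])
    return out


def make_library(
    spec: FixtureSpec, ref: ReferenceComplex
) -> tuple[list[Molecule], dict[str, int]]:
    """Molecules with planted best-match sizes, in random rigid frames."""
    rng = np.random.default_rng(spec.seed + 1)
    levels = _level_allocation(spec.n_molecules, spec.match_size_weights)
    rng.shuffle(levels)
    molecules = []
    labels: dict[str, int] = {}
    for i, k in enumerate(levels):
        n_break = 8 - k
        broken = set(
            rng.choice(OPTIONAL_BREAKS, size=n_break, replace=False)
        ) if n_break else set()
        name = f"lib{i:03d}"
        mol = make_variant(ref, broken, name)
        R = random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, 3)
        mol = mol.transformed(R, t)
        mol.properties["broken"] = tuple(sorted(broken))
        mol.properties["planted_n_matched"] = k
        molecules.append(mol)
        labels[name] = k
    return molecules, labels


# ---------------------------------------------------------------------------
# Pose ensembles with target RMSD matrices


def _embed_distances(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """3-D point configuration realizing distance matrix D (MDS + refine)."""
    from scipy.optimize import least_squares

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:3]
    L = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(L)

    iu = np.triu_indices(n, 1)

    def residual(flat):
        P = flat.reshape(n, 3)
        d = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        return d[iu] - D[iu]

    if np.max(np.abs(residual(X.ravel()))) > 0.02:
        sol = least_squares(residual, X.ravel(), method="lm")
        X = sol.x.reshape(n, 3)
    return X


def make_pose_ensemble(
    molecule: Molecule,
    methods: list[str] | int,
    target: np.ndarray,
    seed: int = 0,
    tolerance: float = 0.05,
) -> dict[str, Pose]:
    """Poses (rigid translations) realizing a target pairwise-RMSD matrix.

    Pure translations make the identity-mapping RMSD equal the relative
    translation exactly; the realized symmetry-aware RMSD matrix is
    verified against the target within ``tolerance`` and a failure raises.
    """
    from .consensus import pose_rmsd

    if isinstance(methods, int):
        methods = [f"m{i + 1}" for i in range(methods)]
    target = np.asarray(target, dtype=float)
    n = len(methods)
    if target.shape != (n, n):
        raise PharmflowError(f"target matrix shape {target.shape} != ({n},{n})")
    rng = np.random.default_rng(seed)
    if np.allclose(target, 0.0):
        X = np.zeros((n, 3))
    else:
        X = _embed_distances(target, rng)
    poses = {
        m: Pose(molecule=molecule.translated(X[i]), method=m)
        for i, m in enumerate(methods)
    }
    for i in range(n):
        for j in range(i + 1, n):
            got = pose_rmsd(poses[methods[i]], poses[methods[j]])
            if abs(got - target[i, j]) > tolerance:
                raise PharmflowError(
                    f"pose ensemble: pair ({methods[i]},{methods[j]}) realized "
                    f"{got:.3f} Å vs target {target[i, j]:.3f} Å"
                )
    return poses


# ---------------------------------------------------------------------------
# Trajectories with planted occupancy


@dataclass
class TrajectorySpec:
    seed: int = 0
    n_frames: int = 100
    occupancies: dict[str, float] = field(
        default_factory=lambda: {"R57": 0.98, "water": 0.94,
                                 "A51": 0.82, "M123": 0.30}
    )
    jitter_sigma: float = 0.1
    drift: float = 0.0  # total linear ligand drift over the run, Å
    frame_interval_ns: float = 0.01


def _flat_atom_index(protein: ProteinStructure) -> dict[tuple, int]:
    out = {}
    k = 0
    for r in protein.residues:
        for a in r.atoms:
            out[(r.key, a.name)] = k
            k += 1
    return out


def make_trajectory(
    ref: ReferenceComplex,
    spec: TrajectorySpec,
    ligand: Molecule | None = None,
) -> tuple[Trajectory, dict]:
    """Trajectory with exact planted occupancies and Gaussian ligand jitter.

    Occupancy planting repositions each H-bond partner atom along its fixed
    bond direction relative to the *jittered* acceptor position: present
    frames sit at the planted bond length, absent frames 0.3 Å beyond the
    cutoff, so recovered occupancies equal the planted fractions exactly.
    The structural water follows its ligand acceptor; the bridge is toggled
    through its protein arms. Frame 0 is the unperturbed starting pose.
    """
    lig = ligand if ligand is not None else ref.ligand
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_frames
    if n < 2:
        raise PharmflowError("need at least 2 frames")
    for key, p in spec.occupancies.items():
        if not (0.0 <= p <= 1.0):
            raise PharmflowError(f"occupancy[{key!r}]={p} outside [0,1]")

    criteria = InteractionCriteria()
    base_prot = ref.protein.all_coords()
    base_lig = lig.coords(0)
    flat = _flat_atom_index(ref.protein)
    partner_flat = {
        key: flat[(ref.partners[key].resolve(ref.protein).key,
                   ref.partners[key].atom)]
        for key in ("A51", "M123", "R57", "E53", "H272")
    }
    water_flat = flat[(ref.water.resolve(ref.protein).key, "O")]

    present_dist = {"A51": 2.9, "M123": 2.9, "R57": 2.9}
    absent = criteria.hbond_dist + 0.3
    arm_present = {"E53": 2.8, "H272": 3.0}
    arm_absent = {"E53": absent, "H272": absent + 0.1}

    masks: dict[str, np.ndarray] = {}
    for key in ("A51", "M123", "R57", "water"):
        p = spec.occupancies.get(key, 1.0)
        n_present = int(round(p * n))
        mask = np.zeros(n, dtype=bool)
        mask[:n_present] = True
        rng.shuffle(mask)
        masks[key] = mask

    frames = np.empty((n, len(base_prot) + len(base_lig), 3))
    for f in range(n):
        lig_xyz = base_lig.copy()
        if f > 0:
            lig_xyz = lig_xyz + rng.normal(0.0, spec.jitter_sigma, lig_xyz.shape)
        lig_xyz = lig_xyz + ref.axis_z * spec.drift * (f / (n - 1))
        prot_xyz = base_prot.copy()
        for key in ("A51", "M123", "R57"):
            acc = lig_xyz[ref.acceptor_atoms[key]]
            d = present_dist[key] if masks[key][f] else absent
            prot_xyz[partner_flat[key]] = acc + d * ref.hbond_directions[key]
        w = lig_xyz[ref.acceptor_atoms["water"]] + 2.8 * ref.hbond_directions["water"]
        prot_xyz[water_flat] = w
        for arm in ("E53", "H272"):
            d = arm_present[arm] if masks["water"][f] else arm_absent[arm]
            prot_xyz[partner_flat[arm]] = w + d * ref.hbond_directions[arm]
        frames[f, : len(base_prot)] = prot_xyz
        frames[f, len(base_prot):] = lig_xyz

    traj = Trajectory(
        protein=ref.protein,
        ligand=lig,
        frames=frames,
        frame_interval_ns=spec.frame_interval_ns,
    )
    truth = {
        "occupancies": {k: float(m.mean()) for k, m in masks.items()},
        "jitter_sigma": spec.jitter_sigma,
        "drift": spec.drift,
        # isotropic per-atom jitter => E[per-frame RMSD] ~= sigma*sqrt(3);
        # frame 0 is exact, drift adds its running mean
        "expected_mean_rmsd": (
            (n - 1) / n * spec.jitter_sigma * np.sqrt(3.0)
            + spec.drift * 0.5
        ),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# End-to-end funnel fixture


@dataclass
class FunnelFixture:
    reference: ReferenceComplex
    model: "object"
    library: list[Molecule]
    labels: dict[str, int]
    methods: list[str]
    poses: dict[str, dict[str, Pose]]
    trajectories: dict[str, Trajectory]
    expected: dict


def make_funnel_fixture(
    seed: int = 0,
    n_molecules: int = 30,
    n_frames: int = 50,
) -> FunnelFixture:
    """Full planted cascade: screen -> pose filter -> consensus -> MD.

    Library levels are allocated 10/20/30/40 % to planted sizes 8/7/6/5;
    the screen (>= 7 features) keeps the 8s and 7s. Two 7-level compounds
    get one docking method's pose displaced out of the binding site
    (interaction-filter casualties), two 8-level compounds get one method's
    distal arm swung away (consensus casualties), and of the remaining
    survivors' trajectories one breaks the arginine H-bond occupancy and
    one drifts beyond the RMSD bound, leaving three final compounds.
    """
    from .pharmacophore import build_receptor_model

    ref = make_reference_complex(seed)
    model = build_receptor_model(
        ref.protein, ref.ligand, structural_waters=[ref.water]
    )
    spec = FixtureSpec(seed=seed, n_molecules=n_molecules)
    library, labels = make_library(spec, ref)
    rng = np.random.default_rng(seed + 3)

    screen_names = sorted(n for n, k in labels.items() if k >= 7)
    level7 = sorted(n for n, k in labels.items() if k == 7)
    level8 = sorted(n for n, k in labels.items() if k == 8)
    if len(level7) < 2 or len(level8) < 2:
        raise PharmflowError("funnel fixture needs >= 2 compounds at levels 7 and 8")
    interaction_fail = level7[:2]
    consensus_fail = level8[:2]

    methods = list(CONSENSUS_METHODS)
    poses: dict[str, dict[str, Pose]] = {m: {} for m in methods}
    name_to_mol = {m.name: m for m in library}
    for name in screen_names:
        broken = set(name_to_mol[name].properties["broken"])
        base = make_variant(ref, broken, name)
        for mi, m in enumerate(methods):
            delta = rng.uniform(-0.1, 0.1, 3)
            xyz = base.coords(0) + delta
            if name in interaction_fail and mi == 2:
                xyz = xyz + 2.5 * ref.axis_z  # out of H-bond range
            if name in consensus_fail and mi == 5:
                xyz = xyz.copy()
                swing = [11, 12, 13, 14, 15, 16]
                if "Cl" not in broken:
                    swing.append(17)
                xyz[swing] += -5.0 * ref.axis_z  # distal arm swung away
            poses[m][name] = Pose(molecule=base.with_coords(xyz), method=m)

    expected_intersection = sorted(set(screen_names) - set(interaction_fail))
    expected_consensus = sorted(set(expected_intersection) - set(consensus_fail))

    trajectories: dict[str, Trajectory] = {}
    md_pass_expected = []
    for i, name in enumerate(expected_consensus):
        if i == 3:
            tspec = TrajectorySpec(
                seed=seed + 10 + i, n_frames=n_frames,
                occupancies={"R57": 0.50, "water": 0.94,
                             "A51": 0.82, "M123": 0.30},
            )
        elif i == 4:
            tspec = TrajectorySpec(
                seed=seed + 10 + i, n_frames=n_frames, drift=6.0
            )
        else:
            tspec = TrajectorySpec(seed=seed + 10 + i, n_frames=n_frames)
            md_pass_expected.append(name)
        variant = make_variant(
            ref, set(name_to_mol[name].properties["broken"]), name
        )
        trajectories[name], _ = make_trajectory(ref, tspec, ligand=variant)

    expected = {
        "n_library": n_molecules,
        "level_counts": {
            k: sum(1 for v in labels.values() if v == k) for k in (8, 7, 6, 5)
        },
        "screen": screen_names,
        "intersection": expected_intersection,
        "consensus": expected_consensus,
        "md": sorted(md_pass_expected),
    }
    return FunnelFixture(
        reference=ref,
        model=model,
        library=library,
        labels=labels,
        methods=methods,
        poses=poses,
        trajectories=trajectories,
        expected=expected,
    )
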