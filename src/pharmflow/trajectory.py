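"""MD-trajectory analytics: RMSD time series, H-bond occupancy, MD filter.

Works on :class:`~pharmflow.chem_structures.Trajectory` objects (multi-model
PDB complexes). Per-frame interaction presence reuses the geometric criteria
of :mod:`pharmflow.interactions`, so trajectory occupancies and static pose
analysis agree by construction. Ligand RMSD is measured against frame 0
after optional least-squares superposition of the protein α-carbons; on
trajectories run with restrained α-carbons the superposition is nearly a
no-op, but it makes the analysis robust to unrestrained inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import apply_rigid, kabsch
from .chem_structures import Pose, ResidueSelector, Trajectory
from .errors import PharmflowError, SelectorError, TrajectoryError
from .interactions import (
    HBOND,
    InteractionCriteria,
    detect_interactions,
    detect_water_bridge,
)


@dataclass
class RmsdSeries:
    values: np.ndarray  # per-frame RMSD vs frame 0, Å

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))


@dataclass(frozen=True)
class HBondSpec:
    """A direct ligand-residue H-bond to track, e.g. the oxyanion hole."""

    key: str
    partner: ResidueSelector
    ligand_atoms: tuple[int, ...] | None = None


@dataclass(frozen=True)
class WaterBridgeSpec:
    """A water-bridged H-bond network (ligand <-> water <-> partners)."""

    key: str
    water: ResidueSelector
    partners: tuple[ResidueSelector, ...]


@dataclass
class OccupancyReport:
    occupancy: dict[str, float]
    tracks: dict[str, np.ndarray]  # per-frame boolean presence
    ligand_rmsd_mean: float
    ligand_rmsd_max: float
    water_rmsd_mean: float | None
    n_frames: int

    def __post_init__(self):
        for key, frac in self.occupancy.items():
            if not (0.0 <= frac <= 1.0):
                raise PharmflowError(f"occupancy[{key!r}]={frac} outside [0,1]")


@dataclass
class MdFilterSpec:
    """Acceptance thresholds for the MD stage of the screening cascade.

    A complex passes when the mean ligand RMSD is strictly below
    ``max_mean_ligand_rmsd`` and every clause holds with strict inequality:
    all interactions in ``require_all`` and at least one in ``require_any``
    must be maintained for more than ``occupancy_threshold`` of the frames.
    """

    max_mean_ligand_rmsd: float = 2.0
    occupancy_threshold: float = 0.70
    require_all: tuple[str, ...] = ("R57", "water")
    require_any: tuple[str, ...] = ("A51", "M123")

    def __post_init__(self):
        if not (0.0 < self.occupancy_threshold < 1.0):
            raise PharmflowError("occupancy threshold must be in (0, 1)")


@dataclass
class MdFilterResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# RMSD time series


def _ca_indices(traj: Trajectory) -> list[int]:
    idx = []
    k = 0
    for r in traj.protein.residues:
        for a in r.atoms:
            if a.name == "CA":
                idx.append(k)
            k += 1
    return idx


def ligand_rmsd_series(
    traj: Trajectory, superpose_on: str = "protein-CA"
) -> RmsdSeries:
    """Per-frame heavy-atom ligand RMSD vs frame 0.

    ``superpose_on``: 'protein-CA' (least-squares fit of α-carbons before
    measuring) or 'none' (raw coordinates, the convention for restrained
    trajectories).
    """
    if superpose_on not in ("none", "protein-CA"):
        raise PharmflowError(f"unknown superposition mode {superpose_on!r}")
    heavy = traj.ligand.heavy_indices
    ref_lig = traj.ligand_coords(0)[heavy]
    ca = _ca_indices(traj) if superpose_on == "protein-CA" else []
    if superpose_on == "protein-CA" and not ca:
        raise TrajectoryError("no α-carbons found for superposition")
    ref_ca = traj.protein_coords(0)[ca] if ca else None

    values = []
    for f in range(traj.n_frames):
        lig = traj.ligand_coords(f)[heavy]
        if ca:
            R, t = kabsch(traj.protein_coords(f)[ca], ref_ca)
            lig = apply_rigid(lig, R, t)
        values.append(float(np.sqrt(np.mean(np.sum((lig - ref_lig) ** 2, axis=1)))))
    return RmsdSeries(values=np.array(values))


def _water_oxygen_flat_index(traj: Trajectory, water: ResidueSelector) -> int:
    res = water.resolve(traj.protein)
    if not res.is_water:
        raise SelectorError(f"selector {water} resolves to non-water {res.name}")
    k = 0
    for r in traj.protein.residues:
        for a in r.atoms:
            if r.key == res.key and a.element == "O":
                return k
            k += 1
    raise SelectorError(f"water oxygen of {water} not found")


def _all_water_oxygen_indices(traj: Trajectory) -> list[int]:
    idx = []
    k = 0
    for r in traj.protein.residues:
        for a in r.atoms:
            if r.is_water and a.element == "O":
                idx.append(k)
            k += 1
    return idx


def water_rmsd_series(
    traj: Trajectory, water: ResidueSelector, tracking: str = "identity"
) -> RmsdSeries:
    """Displacement of a structural water oxygen from its frame-0 site.

    'identity' follows the same water molecule in every frame (the default:
    a conserved crystallographic water is one molecule); 'nearest' follows
    whichever water oxygen is closest to the frame-0 site each frame, for
    engines that exchange waters.
    """
    if tracking not in ("identity", "nearest"):
        raise PharmflowError(f"unknown tracking mode {tracking!r}")
    site0_idx = _water_oxygen_flat_index(traj, water)
    site0 = traj.protein_coords(0)[site0_idx]
    if tracking == "identity":
        values = [
            float(np.linalg.norm(traj.protein_coords(f)[site0_idx] - site0))
            for f in range(traj.n_frames)
        ]
    else:
        all_idx = _all_water_oxygen_indices(traj)
        values = []
        for f in range(traj.n_frames):
            pos = traj.protein_coords(f)[all_idx]
            values.append(float(np.min(np.linalg.norm(pos - site0, axis=1))))
    return RmsdSeries(values=np.array(values))


# ---------------------------------------------------------------------------
# Occupancy


def _frame_hbond_present(
    traj: Trajectory, frame: int, spec: HBondSpec, criteria: InteractionCriteria
) -> bool:
    protein = traj.protein_at(frame)
    pose = Pose(molecule=traj.ligand_at(frame), method="frame")
    res = spec.partner.resolve(protein)
    for rec in detect_interactions(protein, pose, criteria):
        if rec.itype != HBOND or rec.residue_key != res.key:
            continue
        if spec.partner.atom is not None and spec.partner.atom not in rec.atom_names:
            continue
        if spec.ligand_atoms is not None and not (
            set(rec.ligand_atoms) & set(spec.ligand_atoms)
        ):
            continue
        return True
    return False


def hbond_occupancy(
    traj: Trajectory,
    interactions: list["HBondSpec | WaterBridgeSpec"],
    criteria: InteractionCriteria | None = None,
    superpose_on: str = "protein-CA",
) -> OccupancyReport:
    """Fraction of frames in which each tracked interaction is present.

    Direct H-bonds are evaluated with the static-pose geometry per frame;
    a water bridge counts in a frame only when the ligand-water H-bond
    holds AND at least one partner arm holds. Ligand (and, when a bridge
    is tracked, structural-water) RMSD statistics are included.
    """
    criteria = criteria or InteractionCriteria()
    for spec in interactions:
        if isinstance(spec, HBondSpec):
            spec.partner.resolve(traj.protein)
        else:
            spec.water.resolve(traj.protein)
            for p in spec.partners:
                p.resolve(traj.protein)

    tracks: dict[str, np.ndarray] = {}
    for spec in interactions:
        present = np.zeros(traj.n_frames, dtype=bool)
        for f in range(traj.n_frames):
            if isinstance(spec, HBondSpec):
                present[f] = _frame_hbond_present(traj, f, spec, criteria)
            else:
                protein = traj.protein_at(f)
                pose = Pose(molecule=traj.ligand_at(f), method="frame")
                present[f] = (
                    detect_water_bridge(
                        protein, pose, spec.water, list(spec.partners), criteria
                    )
                    is not None
                )
        tracks[spec.key] = present

    lig_series = ligand_rmsd_series(traj, superpose_on=superpose_on)
    water_specs = [s for s in interactions if isinstance(s, WaterBridgeSpec)]
    water_mean = None
    if water_specs:
        water_mean = water_rmsd_series(traj, water_specs[0].water).mean

    return OccupancyReport(
        occupancy={k: float(v.mean()) for k, v in tracks.items()},
        tracks=tracks,
        ligand_rmsd_mean=lig_series.mean,
        ligand_rmsd_max=lig_series.max,
        water_rmsd_mean=water_mean,
        n_frames=traj.n_frames,
    )


def md_filter(report: OccupancyReport, spec: MdFilterSpec | None = None) -> MdFilterResult:
    """Apply the MD acceptance filter to an occupancy report (strict bounds)."""
    spec = spec or MdFilterSpec()
    for key in list(spec.require_all) + list(spec.require_any):
        if key not in report.occupancy:
            raise PharmflowError(f"report lacks required interaction {key!r}")
    reasons: list[str] = []
    if not report.ligand_rmsd_mean < spec.max_mean_ligand_rmsd:
        reasons.append(
            f"mean ligand RMSD {report.ligand_rmsd_mean:.2f} Å not below "
            f"{spec.max_mean_ligand_rmsd:.2f} Å"
        )
    for key in spec.require_all:
        occ = report.occupancy[key]
        if not occ > spec.occupancy_threshold:
            reasons.append(
                f"{key} occupancy {occ:.2f} not above {spec.occupancy_threshold:.2f}"
            )
    if spec.require_any:
        if not any(
            report.occupancy[k] > spec.occupancy_threshold for k in spec.require_any
        ):
            reasons.append(
                "none of "
                + "/".join(spec.require_any)
                + f" maintained above {spec.occupancy_threshold:.2f}"
            )
    return MdFilterResult(passed=not reasons, reasons=reasons)
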