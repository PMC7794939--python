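"""Receptor-based pharmacophore models: construction, matching, screening.

A model is a set of typed tolerance spheres (H-bond acceptor/donor and
ring-compatible hydrophobic features), a mandatory flag per feature, and
excluded-volume spheres marking receptor-occupied space. Two matching modes
are provided:

* in-place (:func:`match_pose`): docked poses are compared against the
  model directly from the supplied coordinates, without moving them —
  a maximum-cardinality one-to-one assignment of kind-compatible ligand
  feature points to model spheres.
* alignment (:func:`match_conformers`): each conformer is rigidly
  superposed onto the model by enumerating correspondences between the
  mandatory features and kind-compatible ligand features (pruned by
  pairwise-distance compatibility), then extended greedily to optional
  features; excluded-volume clashes disqualify a placement.

Feature directionality is deliberately ignored in matching: features are
distance-only spheres, and no angle tolerances are part of the contract.
Default tolerance radii (1.5 Å) and the excluded-volume radius (1.2 Å) are
near common pharmacophore-software defaults and are stored in the model
JSON so they are explicit data rather than code.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._geom import kabsch
from .chem_structures import Molecule, Pose, ProteinStructure, ResidueSelector
from .errors import EmptyModelError, PharmflowError
from .interactions import (
    InteractionCriteria,
    _protein_donor_atoms,
    protein_apolar_atoms,
)
from .perception import (
    KIND_ARO,
    KIND_HBA,
    KIND_HBD,
    KIND_HYD,
    FeaturePoint,
    perceive_features,
)

#: Model feature kinds. HYD spheres are ring-compatible (they match both
#: aliphatic hydrophobic centroids and aromatic ring centroids).
KIND_HBA_MODEL = KIND_HBA
KIND_HBD_MODEL = KIND_HBD
KIND_HYD_MODEL = KIND_HYD

DEFAULT_TOLERANCE = {KIND_HBA: 1.5, KIND_HBD: 1.5, KIND_HYD: 1.5}
DEFAULT_EV_RADIUS = 1.2


@dataclass(frozen=True)
class ModelFeature:
    id: int
    kind: str
    center: tuple[float, float, float]
    radius: float
    mandatory: bool = False

    def __post_init__(self):
        if self.radius <= 0:
            raise PharmflowError("feature tolerance radius must be positive")
        if self.kind not in (KIND_HBA, KIND_HBD, KIND_HYD):
            raise PharmflowError(f"unsupported model feature kind {self.kind!r}")

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.center, dtype=float)


@dataclass(frozen=True)
class ExcludedVolume:
    center: tuple[float, float, float]
    radius: float = DEFAULT_EV_RADIUS

    def __post_init__(self):
        if self.radius <= 0:
            raise PharmflowError("excluded-volume radius must be positive")

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    features: list[ModelFeature]
    excluded_volumes: list[ExcludedVolume] = field(default_factory=list)
    frame_note: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise PharmflowError("model feature ids must be unique")
        if not any(f.mandatory for f in self.features):
            raise PharmflowError("a model needs at least one mandatory feature")

    @property
    def mandatory_ids(self) -> list[int]:
        return sorted(f.id for f in self.features if f.mandatory)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def kind_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    # -- JSON dialect -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "id": f.id,
                    "kind": f.kind,
                    "center": [round(v, 4) for v in f.center],
                    "radius": f.radius,
                    "mandatory": f.mandatory,
                }
                for f in self.features
            ],
            "excluded_volumes": [
                {"center": [round(v, 4) for v in e.center], "radius": e.radius}
                for e in self.excluded_volumes
            ],
            "meta": {"frame": self.frame_note, **self.meta},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        meta = dict(d.get("meta", {}))
        frame = meta.pop("frame", "")
        return cls(
            features=[
                ModelFeature(
                    id=int(f["id"]),
                    kind=f["kind"],
                    center=tuple(float(v) for v in f["center"]),
                    radius=float(f["radius"]),
                    mandatory=bool(f["mandatory"]),
                )
                for f in d["features"]
            ],
            excluded_volumes=[
                ExcludedVolume(
                    center=tuple(float(v) for v in e["center"]),
                    radius=float(e["radius"]),
                )
                for e in d.get("excluded_volumes", [])
            ],
            frame_note=frame,
            meta=meta,
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "PharmacophoreModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class MatchResult:
    matched_ids: tuple[int, ...]
    assignment: dict[int, FeaturePoint]
    n_matched: int
    mandatory_satisfied: bool
    ev_clash: bool
    rms: float = 0.0
    transform: tuple[np.ndarray, np.ndarray] | None = None
    conformer: int | None = None

    def __post_init__(self):
        assert self.n_matched == len(self.matched_ids)


# ---------------------------------------------------------------------------
# Model construction


@dataclass
class BuildConfig:
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    min_apolar_contacts: int = 2
    ev_shell: float = 6.0
    ev_radius: float = DEFAULT_EV_RADIUS
    tolerances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANCE)
    )
    mandatory_override: list[int] | None = None


def build_receptor_model(
    protein: ProteinStructure,
    ligand: Molecule,
    structural_waters: list[ResidueSelector] | None = None,
    config: BuildConfig | None = None,
) -> PharmacophoreModel:
    """Build a pharmacophore model from a posed protein-ligand complex.

    HBA features are placed on ligand acceptor atoms H-bonded to a protein
    donor or to a listed structural water; HYD features on ligand
    hydrophobic/ring centroids with enough apolar protein contacts.
    Excluded volumes mark every protein heavy atom within ``ev_shell`` of
    the ligand, except H-bond partner atoms of a feature. By default all
    HBA features plus the best-contacted HYD feature are mandatory.
    """
    config = config or BuildConfig()
    structural_waters = structural_waters or []
    feats = perceive_features(ligand, 0)
    lig_xyz = ligand.coords(0)
    cutoff = config.criteria.hbond_dist

    water_oxygens = []
    for sel in structural_waters:
        res = sel.resolve(protein)
        water_oxygens.append(
            (res, next(a for a in res.atoms if a.element == "O"))
        )

    partner_atom_ids: set[tuple[tuple[str, int, str], str]] = set()
    hba_entries = []  # (feature point, partner label)
    for f in feats:
        if f.kind != KIND_HBA:
            continue
        pos = f.pos
        partner = None
        for res in protein.residues:
            if res.is_water:
                continue
            for d in _protein_donor_atoms(res):
                if np.linalg.norm(pos - d.coords) <= cutoff:
                    partner = (res.key, d.name)
                    break
            if partner:
                break
        if partner is None:
            for res, w_o in water_oxygens:
                if np.linalg.norm(pos - w_o.coords) <= cutoff:
                    partner = (res.key, w_o.name)
                    break
        if partner is not None:
            partner_atom_ids.add(partner)
            hba_entries.append((f, partner))

    apolar = protein_apolar_atoms(protein)
    apolar_xyz = (
        np.array([a.coords for _, a in apolar]) if apolar else np.zeros((0, 3))
    )
    hyd_entries = []  # (feature point, n_contacts)
    for f in feats:
        if f.kind != KIND_HYD:
            continue
        if len(apolar_xyz):
            n_contacts = int(
                np.sum(
                    np.linalg.norm(apolar_xyz - f.pos, axis=1)
                    <= config.criteria.hydrophobic_dist
                )
            )
        else:
            n_contacts = 0
        if n_contacts >= config.min_apolar_contacts:
            hyd_entries.append((f, n_contacts))

    if not hba_entries and not hyd_entries:
        raise EmptyModelError(
            "no protein-ligand interactions detected; cannot build a model"
        )

    # order: HBA by ligand feature order, then HYD by contact count (desc)
    hyd_entries.sort(key=lambda e: (-e[1], e[0].source_atoms))
    features: list[ModelFeature] = []
    next_id = 1
    for f, _partner in hba_entries:
        features.append(
            ModelFeature(
                id=next_id,
                kind=KIND_HBA,
                center=f.position,
                radius=config.tolerances[KIND_HBA],
                mandatory=True,
            )
        )
        next_id += 1
    for rank, (f, _n) in enumerate(hyd_entries):
        features.append(
            ModelFeature(
                id=next_id,
                kind=KIND_HYD,
                center=f.position,
                radius=config.tolerances[KIND_HYD],
                mandatory=(rank == 0),  # best-contacted hydrophobic site
            )
        )
        next_id += 1

    if config.mandatory_override is not None:
        override = set(config.mandatory_override)
        features = [
            ModelFeature(f.id, f.kind, f.center, f.radius, f.id in override)
            for f in features
        ]

    # excluded volumes: in-shell protein heavy atoms that are not partners
    lig_heavy = lig_xyz[ligand.heavy_indices]
    evs: list[ExcludedVolume] = []
    for res in protein.residues:
        for a in res.atoms:
            if not a.is_heavy:
                continue
            if (res.key, a.name) in partner_atom_ids:
                continue
            if np.min(np.linalg.norm(lig_heavy - a.coords, axis=1)) <= config.ev_shell:
                evs.append(
                    ExcludedVolume(center=tuple(a.coords), radius=config.ev_radius)
                )

    return PharmacophoreModel(
        features=features,
        excluded_volumes=evs,
        frame_note="receptor frame of the source complex",
        meta={
            "builder": "build_receptor_model",
            "n_hba_partners": len(hba_entries),
            "hyd_contact_counts": [n for _, n in hyd_entries],
        },
    )


# ---------------------------------------------------------------------------
# In-place matching


def _usable_ligand_features(feats: list[FeaturePoint]) -> list[FeaturePoint]:
    # ARO points are duplicated as HYD by perception; the HYD copy is the
    # matchable one, which also deduplicates rings per assignment.
    return [f for f in feats if f.kind in (KIND_HBA, KIND_HBD, KIND_HYD)]


def match_features_inplace(
    model_features: list[ModelFeature],
    ligand_features: list[FeaturePoint],
    positions: np.ndarray | None = None,
) -> tuple[dict[int, int], float]:
    """Maximum-cardinality, minimum-total-distance one-to-one assignment.

    Returns ({model feature id -> ligand feature index}, sum of distances).
    ``positions`` overrides the ligand feature positions (alignment mode).
    Solved as a rectangular linear assignment with a large bonus per
    feasible pair, which makes cardinality dominate distance.
    """
    lig = _usable_ligand_features(ligand_features)
    if positions is None:
        positions = np.array([f.pos for f in lig]) if lig else np.zeros((0, 3))
    else:
        keep = [
            k for k, f in enumerate(ligand_features)
            if f.kind in (KIND_HBA, KIND_HBD, KIND_HYD)
        ]
        positions = positions[keep]
    if not model_features or not len(lig):
        return {}, 0.0

    BIG = 1.0e6
    n_m, n_l = len(model_features), len(lig)
    cost = np.zeros((n_m, n_l))
    feasible = np.zeros((n_m, n_l), dtype=bool)
    for a, mf in enumerate(model_features):
        for b, lf in enumerate(lig):
            if mf.kind != lf.kind:
                continue
            d = float(np.linalg.norm(mf.pos - positions[b]))
            if d <= mf.radius:
                cost[a, b] = d - BIG
                feasible[a, b] = True
    rows, cols = linear_sum_assignment(cost)
    assignment: dict[int, int] = {}
    total = 0.0
    lig_index = [
        k for k, f in enumerate(ligand_features)
        if f.kind in (KIND_HBA, KIND_HBD, KIND_HYD)
    ]
    for a, b in zip(rows, cols):
        if feasible[a, b]:
            assignment[model_features[a].id] = lig_index[b]
            total += cost[a, b] + BIG
    return assignment, total


def ev_clash(
    model: PharmacophoreModel, heavy_coords: np.ndarray
) -> bool:
    """True iff any heavy-atom center lies strictly inside an EV sphere."""
    for ev in model.excluded_volumes:
        if np.any(np.linalg.norm(heavy_coords - ev.pos, axis=1) < ev.radius):
            return True
    return False


def match_pose(
    model: PharmacophoreModel,
    pose: Pose,
    ligand_features: list[FeaturePoint] | None = None,
) -> MatchResult:
    """In-place match of a docked pose against the model (no re-alignment)."""
    feats = (
        ligand_features
        if ligand_features is not None
        else perceive_features(pose.molecule, 0)
    )
    assignment, total = match_features_inplace(model.features, feats)
    matched_ids = tuple(sorted(assignment))
    mandatory_ok = set(model.mandatory_ids) <= set(matched_ids)
    clash = ev_clash(model, pose.molecule.heavy_coords(0))
    rms = float(np.sqrt(total / len(assignment))) if assignment else 0.0
    return MatchResult(
        matched_ids=matched_ids,
        assignment={fid: feats[idx] for fid, idx in assignment.items()},
        n_matched=len(matched_ids),
        mandatory_satisfied=mandatory_ok,
        ev_clash=clash,
        rms=rms,
    )


# ---------------------------------------------------------------------------
# Alignment-mode matching


def _enumerate_correspondences(
    mandatory: list[ModelFeature],
    lig_feats: list[FeaturePoint],
    cap: int,
) -> tuple[list[list[int]], bool]:
    """Backtracking enumeration of mandatory-feature correspondences.

    A partial assignment survives only if every pair of assigned features
    is pairwise-distance compatible: |d_model - d_ligand| <= r_i + r_j.
    Returns (list of ligand-feature index tuples, cap_exceeded flag).
    """
    candidates = [
        [k for k, lf in enumerate(lig_feats) if lf.kind == mf.kind]
        for mf in mandatory
    ]
    m_pos = [mf.pos for mf in mandatory]
    l_pos = [lf.pos for lf in lig_feats]
    out: list[list[int]] = []
    visited = 0
    cap_hit = False

    def backtrack(depth: int, chosen: list[int]):
        nonlocal visited, cap_hit
        if cap_hit:
            return
        if depth == len(mandatory):
            out.append(list(chosen))
            return
        for k in candidates[depth]:
            if k in chosen:
                continue
            ok = True
            for prev_depth, prev_k in enumerate(chosen):
                dm = np.linalg.norm(m_pos[depth] - m_pos[prev_depth])
                dl = np.linalg.norm(l_pos[k] - l_pos[prev_k])
                if abs(dm - dl) > mandatory[depth].radius + mandatory[prev_depth].radius:
                    ok = False
                    break
            if not ok:
                continue
            visited += 1
            if visited > cap:
                cap_hit = True
                return
            chosen.append(k)
            backtrack(depth + 1, chosen)
            chosen.pop()

    backtrack(0, [])
    return out, cap_hit


def match_conformers(
    model: PharmacophoreModel,
    mol: Molecule,
    max_correspondences: int = 100_000,
) -> MatchResult:
    """Best alignment-mode match over all conformers of a molecule.

    For each candidate mandatory-feature correspondence the matched centers
    are superposed by least squares, optional features are extended
    greedily (nearest unused compatible feature within tolerance), and
    excluded volumes are tested on the placed conformer. Placements that
    clash are discarded. Returns the result maximizing
    (mandatory_satisfied, n_matched, -RMS of matched centers).
    """
    mandatory = sorted(
        (f for f in model.features if f.mandatory), key=lambda f: f.id
    )
    optional = sorted(
        (f for f in model.features if not f.mandatory), key=lambda f: f.id
    )
    best: MatchResult | None = None

    for ci in range(len(mol.conformers)):
        feats = _usable_ligand_features(perceive_features(mol, ci))
        if not feats:
            continue
        heavy = mol.heavy_coords(ci)
        feat_pos = np.array([f.pos for f in feats])

        corrs, cap_hit = _enumerate_correspondences(
            mandatory, feats, max_correspondences
        )
        if cap_hit:
            warnings.warn(
                f"{mol.name!r}: correspondence cap {max_correspondences} "
                "exceeded; using best placement found so far"
            )
        for corr in corrs:
            P = feat_pos[corr]
            Q = np.array([mf.pos for mf in mandatory])
            R, t = kabsch(P, Q)
            placed_feats = feat_pos @ R.T + t
            placed_heavy = heavy @ R.T + t
            if ev_clash(model, placed_heavy):
                continue

            assignment: dict[int, int] = {}
            dists: list[float] = []
            used: set[int] = set()
            mandatory_ok = True
            for mf, k in zip(mandatory, corr):
                d = float(np.linalg.norm(placed_feats[k] - mf.pos))
                if d <= mf.radius:
                    assignment[mf.id] = k
                    used.add(k)
                    dists.append(d)
                else:
                    mandatory_ok = False
            # greedy extension to optional features, in feature-id order
            for mf in optional:
                cands = [
                    (float(np.linalg.norm(placed_feats[k] - mf.pos)), k)
                    for k, lf in enumerate(feats)
                    if lf.kind == mf.kind and k not in used
                ]
                cands = [(d, k) for d, k in cands if d <= mf.radius]
                if cands:
                    d, k = min(cands)
                    assignment[mf.id] = k
                    used.add(k)
                    dists.append(d)

            rms = float(np.sqrt(np.mean(np.square(dists)))) if dists else 0.0
            result = MatchResult(
                matched_ids=tuple(sorted(assignment)),
                assignment={fid: feats[k] for fid, k in assignment.items()},
                n_matched=len(assignment),
                mandatory_satisfied=mandatory_ok,
                ev_clash=False,
                rms=rms,
                transform=(R, t),
                conformer=ci,
            )
            key = (result.mandatory_satisfied, result.n_matched, -result.rms)
            if best is None or key > (
                best.mandatory_satisfied,
                best.n_matched,
                -best.rms,
            ):
                best = result

    if best is None:
        return MatchResult(
            matched_ids=(),
            assignment={},
            n_matched=0,
            mandatory_satisfied=False,
            ev_clash=False,
        )
    return best


# ---------------------------------------------------------------------------
# Library screening


@dataclass
class ScreenHit:
    name: str
    result: MatchResult


@dataclass
class ScreenResult:
    hits: list[ScreenHit]
    min_features: int
    n_screened: int

    def level_counts(self) -> dict[int, int]:
        """Exact number of hits at each matched-feature level."""
        out: dict[int, int] = {}
        for h in self.hits:
            out[h.result.n_matched] = out.get(h.result.n_matched, 0) + 1
        return dict(sorted(out.items(), reverse=True))

    def cumulative_counts(self) -> dict[int, int]:
        """Hits matching at least k features, for each observed level k."""
        exact = self.level_counts()
        out: dict[int, int] = {}
        total = 0
        for k in sorted(exact, reverse=True):
            total += exact[k]
            out[k] = total
        return out

    @property
    def hit_names(self) -> list[str]:
        return [h.name for h in self.hits]


def screen_library(
    model: PharmacophoreModel,
    molecules: list[Molecule],
    min_features: int | None = None,
) -> ScreenResult:
    """Alignment-mode screen; hits ranked by matched features (desc, name).

    A molecule is a hit when all mandatory features are satisfied, at least
    ``min_features`` features match overall, and no excluded volume is
    violated. ``min_features`` defaults to the number of mandatory
    features and may not be smaller.
    """
    n_mand = len(model.mandatory_ids)
    if min_features is None:
        min_features = n_mand
    if min_features < n_mand:
        raise PharmflowError(
            f"min_features ({min_features}) below mandatory count ({n_mand})"
        )
    hits: list[ScreenHit] = []
    for mol in molecules:
        res = match_conformers(model, mol)
        if res.mandatory_satisfied and res.n_matched >= min_features:
            hits.append(ScreenHit(mol.name, res))
    hits.sort(key=lambda h: (-h.result.n_matched, h.name))
    return ScreenResult(hits=hits, min_features=min_features, n_screened=len(molecules))


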