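"""End-to-end virtual-screening cascade and the similarity novelty check.

The cascade mirrors a pharmacophore-first screening funnel: pharmacophore
screen (>= min matched features with all mandatory satisfied) -> per-method
interaction-based pose filter -> intersection across docking methods ->
full pose consensus (all reciprocal RMSDs below threshold) -> MD occupancy
filter. Docking poses and MD trajectories are consumed as inputs, never
produced. Every rejection is recorded per compound, and stages whose inputs
are missing are skipped with an explicit flag, never silently.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .chem_structures import Molecule, Pose, ProteinStructure, Trajectory
from .consensus import full_consensus
from .errors import PharmflowError
from .interactions import (
    InteractionCriteria,
    PoseFilterSpec,
    filter_pose,
    intersect_by_method,
)
from .pharmacophore import PharmacophoreModel, screen_library
from .trajectory import (
    HBondSpec,
    MdFilterSpec,
    WaterBridgeSpec,
    hbond_occupancy,
    md_filter,
)


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    survivors: list[str]
    skipped: bool = False
    detail: dict = field(default_factory=dict)


@dataclass
class FunnelReport:
    stages: list[StageReport]
    dossier: dict[str, list[str]]
    config: dict
    config_hash: str
    seed: int

    @property
    def survivors(self) -> list[str]:
        for stage in reversed(self.stages):
            if not stage.skipped:
                return stage.survivors
        return []

    def stage(self, name: str) -> StageReport:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "survivors": list(s.survivors),
                    "skipped": s.skipped,
                    "detail": s.detail,
                }
                for s in self.stages
            ],
            "dossier": {k: list(v) for k, v in sorted(self.dossier.items())},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_table(self) -> str:
        lines = [f"{'stage':<16}{'in':>8}{'out':>8}  note"]
        for s in self.stages:
            note = "skipped" if s.skipped else ""
            lines.append(f"{s.name:<16}{s.n_in:>8}{s.n_out:>8}  {note}")
        return "\n".join(lines)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    model: PharmacophoreModel,
    library: list[Molecule],
    min_features: int = 7,
    protein: ProteinStructure | None = None,
    poses: dict[str, dict[str, Pose]] | None = None,
    pose_filter_spec: PoseFilterSpec | None = None,
    criteria: InteractionCriteria | None = None,
    consensus_threshold: float = 2.0,
    trajectories: dict[str, Trajectory] | None = None,
    md_interactions: list[HBondSpec | WaterBridgeSpec] | None = None,
    md_filter_spec: MdFilterSpec | None = None,
    seed: int = 0,
) -> FunnelReport:
    """Run the screening cascade; returns the stage-by-stage funnel report.

    ``poses`` maps docking-method label -> compound name -> Pose. Stages
    whose inputs are absent (no poses, no trajectories) are reported as
    skipped. The pipeline itself is deterministic; ``seed`` is recorded
    for provenance of seeded inputs.
    """
    criteria = criteria or InteractionCriteria()
    md_filter_spec = md_filter_spec or MdFilterSpec()
    config = {
        "min_features": min_features,
        "consensus_threshold": consensus_threshold,
        "hbond_dist": criteria.hbond_dist,
        "hydrophobic_dist": criteria.hydrophobic_dist,
        "md_max_mean_rmsd": md_filter_spec.max_mean_ligand_rmsd,
        "md_occupancy_threshold": md_filter_spec.occupancy_threshold,
        "n_model_features": model.n_features,
        "n_library": len(library),
    }
    stages: list[StageReport] = []
    dossier: dict[str, list[str]] = {m.name: [] for m in library}

    # 1) pharmacophore screen
    screen = screen_library(model, library, min_features=min_features)
    screen_names = sorted(screen.hit_names)
    by_name = {h.name: h.result for h in screen.hits}
    for m in library:
        if m.name in by_name:
            dossier[m.name].append(
                f"screen: matched {by_name[m.name].n_matched} features"
            )
        else:
            dossier[m.name].append(
                f"screen: rejected (needs >= {min_features} features with "
                "all mandatory)"
            )
    stages.append(
        StageReport(
            "screen",
            len(library),
            len(screen_names),
            screen_names,
            detail={
                "level_counts": {
                    str(k): v for k, v in screen.level_counts().items()
                },
                "cumulative_counts": {
                    str(k): v for k, v in screen.cumulative_counts().items()
                },
            },
        )
    )
    current = screen_names

    # 2) per-method pose filter + 3) intersection
    if poses and protein is not None and pose_filter_spec is not None:
        per_method: dict[str, set[str]] = {}
        per_method_counts: dict[str, int] = {}
        for method in sorted(poses):
            passing: set[str] = set()
            for name in current:
                pose = poses[method].get(name)
                if pose is None:
                    dossier[name].append(f"pose-filter[{method}]: no pose supplied")
                    continue
                res = filter_pose(protein, pose, pose_filter_spec, model, criteria)
                if res.passed:
                    passing.add(name)
                else:
                    dossier[name].append(
                        f"pose-filter[{method}]: " + "; ".join(res.reasons)
                    )
            per_method[method] = passing
            per_method_counts[method] = len(passing)
        intersected = sorted(intersect_by_method(per_method))
        stages.append(
            StageReport(
                "pose_filter",
                len(current),
                len(intersected),
                intersected,
                detail={"per_method": per_method_counts},
            )
        )
        current = intersected
    else:
        stages.append(
            StageReport("pose_filter", len(current), len(current), current,
                        skipped=True)
        )

    # 4) full pose consensus
    if poses and len(poses) >= 2:
        kept = []
        for name in current:
            method_poses = {
                m: poses[m][name] for m in poses if name in poses[m]
            }
            if len(method_poses) < 2:
                dossier[name].append("consensus: fewer than 2 poses; kept")
                kept.append(name)
                continue
            flag, matrix = full_consensus(
                method_poses, threshold=consensus_threshold
            )
            if flag:
                kept.append(name)
                dossier[name].append(
                    f"consensus: full (max pairwise {matrix.max_offdiag:.2f} Å)"
                )
            else:
                dossier[name].append(
                    f"consensus: rejected (max pairwise "
                    f"{matrix.max_offdiag:.2f} Å >= {consensus_threshold} Å)"
                )
        kept = sorted(kept)
        stages.append(StageReport("consensus", len(current), len(kept), kept))
        current = kept
    else:
        stages.append(
            StageReport("consensus", len(current), len(current), current,
                        skipped=True)
        )

    # 5) MD filter
    if trajectories and md_interactions:
        kept = []
        for name in current:
            traj = trajectories.get(name)
            if traj is None:
                dossier[name].append("md: no trajectory supplied; dropped")
                continue
            report = hbond_occupancy(traj, md_interactions, criteria)
            verdict = md_filter(report, md_filter_spec)
            occ = ", ".join(
                f"{k}={v:.2f}" for k, v in sorted(report.occupancy.items())
            )
            if verdict.passed:
                kept.append(name)
                dossier[name].append(
                    f"md: passed (mean RMSD {report.ligand_rmsd_mean:.2f} Å; {occ})"
                )
            else:
                dossier[name].append("md: rejected (" + "; ".join(verdict.reasons) + ")")
        kept = sorted(kept)
        stages.append(StageReport("md_filter", len(current), len(kept), kept))
    else:
        stages.append(
            StageReport("md_filter", len(current), len(current), current,
                        skipped=True)
        )

    return FunnelReport(
        stages=stages,
        dossier=dossier,
        config=config,
        config_hash=_config_hash(config),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Novelty check


@dataclass
class NoveltyEntry:
    name: str
    max_score: int | None
    nearest_reference: str | None
    novel: bool | None
    error: str | None = None


def _fingerprint(entry, n_bits: int):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    if isinstance(entry, Molecule):
        rd = entry.to_rdkit()
        name = entry.name
    elif isinstance(entry, str):
        rd = Chem.MolFromSmiles(entry)
        if rd is None:
            raise PharmflowError(f"unparsable SMILES {entry!r}")
        name = entry
    else:
        rd = entry
        name = rd.GetProp("_Name") if rd.HasProp("_Name") else "molecule"
    return name, gen.GetFingerprint(rd)


def novelty_check(
    candidates: list,
    references: list,
    bound: int = 80,
    n_bits: int = 2048,
) -> list[NoveltyEntry]:
    """2-D Tanimoto similarity vs a reference set, scaled 0-100.

    Fingerprints are hashed path-based (RDKit, ``n_bits`` bits): an
    explicit, reproducible stand-in for proprietary 2-D comparison engines,
    hence the bound is configurable. A score of 100 means identical 2-D
    structures; a candidate is novel iff its best score is <= ``bound``.
    Unparsable candidates yield per-record error entries.
    """
    from rdkit import DataStructs

    if not references:
        raise PharmflowError("need at least one reference compound")
    refs = [_fingerprint(r, n_bits) for r in references]
    out: list[NoveltyEntry] = []
    for cand in candidates:
        try:
            name, fp = _fingerprint(cand, n_bits)
        except Exception as exc:  # noqa: BLE001 - per-record error entries
            cname = cand.name if isinstance(cand, Molecule) else str(cand)
            out.append(NoveltyEntry(cname, None, None, None, error=str(exc)))
            continue
        scores = [
            (int(round(100.0 * DataStructs.TanimotoSimilarity(fp, rfp))), rname)
            for rname, rfp in refs
        ]
        best_score, best_name = max(scores)
        out.append(
            NoveltyEntry(
                name=name,
                max_score=best_score,
                nearest_reference=best_name,
                novel=best_score <= bound,
            )
        )
    return out


def tanimoto_score(a, b, n_bits: int = 2048) -> int:
    """Similarity score (0-100) between two molecules/SMILES."""
    from rdkit import DataStructs

    _, fa = _fingerprint(a, n_bits)
    _, fb = _fingerprint(b, n_bits)
    return int(round(100.0 * DataStructs.TanimotoSimilarity(fa, fb)))
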