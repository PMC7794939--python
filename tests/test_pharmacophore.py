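"""Model building, in-place/alignment matching, screening — with oracles."""
import itertools

import numpy as np
import pytest

from pharmflow._geom import random_rotation
from pharmflow.chem_structures import Pose
from pharmflow.errors import EmptyModelError, PharmflowError
from pharmflow.fixtures import (
    FixtureSpec,
    make_library,
    make_reference_complex,
    make_variant,
)
from pharmflow.interactions import protein_apolar_atoms
from pharmflow.perception import KIND_HBA, KIND_HBD, KIND_HYD, FeaturePoint
from pharmflow.pharmacophore import (
    BuildConfig,
    ExcludedVolume,
    ModelFeature,
    PharmacophoreModel,
    build_receptor_model,
    match_conformers,
    match_features_inplace,
    match_pose,
    screen_library,
)


def brute_force_max_matching(model_features, ligand_features):
    """Exhaustive assignment enumeration (independent oracle, <= 8 features).

    Tries every injective map from every subset of model features to
    kind-compatible in-tolerance ligand features, largest subsets first.
    """
    usable = [f for f in ligand_features if f.kind in (KIND_HBA, KIND_HBD, KIND_HYD)]
    compat = []
    for mf in model_features:
        compat.append(
            [
                b
                for b, lf in enumerate(usable)
                if lf.kind == mf.kind
                and np.linalg.norm(mf.pos - lf.pos) <= mf.radius
            ]
        )
    n = len(model_features)
    for size in range(n, 0, -1):
        for subset in itertools.combinations(range(n), size):
            for chosen in itertools.product(*(compat[i] for i in subset)):
                if len(set(chosen)) == size:
                    return size
    return 0


def random_instance(rng, n_model=None):
    n_model = n_model or rng.integers(2, 9)
    kinds = [rng.choice([KIND_HBA, KIND_HBD, KIND_HYD]) for _ in range(n_model)]
    features = [
        ModelFeature(
            id=i + 1,
            kind=kinds[i],
            center=tuple(rng.uniform(-4, 4, 3)),
            radius=1.5,
            mandatory=(i == 0),
        )
        for i in range(n_model)
    ]
    n_lig = int(rng.integers(1, 10))
    lig = [
        FeaturePoint(
            kind=str(rng.choice([KIND_HBA, KIND_HBD, KIND_HYD])),
            position=tuple(rng.uniform(-4, 4, 3)),
            source_atoms=(k,),
        )
        for k in range(n_lig)
    ]
    return features, lig


class TestModelBuilding:
    def test_reference_topology_recovered(self, ref, model):
        assert model.kind_counts() == {KIND_HBA: 4, KIND_HYD: 4}
        assert len(model.mandatory_ids) == 5
        # the mandatory hydrophobic feature is the best-contacted one
        counts = model.meta["hyd_contact_counts"]
        assert counts == sorted(counts, reverse=True)

    def test_ligand_far_from_pocket_gives_empty_model(self, ref):
        far = ref.ligand.translated([20.0, 0.0, 0.0])
        with pytest.raises(EmptyModelError):
            build_receptor_model(ref.protein, far, [ref.water])

    def test_excluded_volume_count_matches_brute_force_shell_scan(self, ref, model):
        cfg = BuildConfig()
        lig_heavy = ref.ligand.heavy_coords(0)
        partner_positions = []
        for key in ("A51", "M123", "R57"):
            _, atom = ref.partners[key].resolve_atom(ref.protein)
            partner_positions.append(atom.coords)
        wres = ref.water.resolve(ref.protein)
        partner_positions.append(next(a for a in wres.atoms if a.element == "O").coords)
        count = 0
        for res in ref.protein.residues:
            for a in res.atoms:
                if not a.is_heavy:
                    continue
                if any(np.allclose(a.coords, p) for p in partner_positions):
                    continue
                if np.min(np.linalg.norm(lig_heavy - a.coords, axis=1)) <= cfg.ev_shell:
                    count += 1
        assert len(model.excluded_volumes) == count

    def test_mandatory_override(self, ref):
        cfg = BuildConfig(mandatory_override=[1, 2])
        m = build_receptor_model(ref.protein, ref.ligand, [ref.water], cfg)
        assert m.mandatory_ids == [1, 2]

    def test_model_json_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PharmacophoreModel.from_json(path)
        assert back.kind_counts() == model.kind_counts()
        assert back.mandatory_ids == model.mandatory_ids
        assert len(back.excluded_volumes) == len(model.excluded_volumes)
        got = {(f.id, f.kind, f.radius, f.mandatory) for f in back.features}
        want = {(f.id, f.kind, f.radius, f.mandatory) for f in model.features}
        assert got == want

    def test_model_invariants(self):
        with pytest.raises(PharmflowError, match="mandatory"):
            PharmacophoreModel(
                features=[ModelFeature(1, KIND_HBA, (0, 0, 0), 1.5, False)]
            )
        with pytest.raises(PharmflowError, match="unique"):
            PharmacophoreModel(
                features=[
                    ModelFeature(1, KIND_HBA, (0, 0, 0), 1.5, True),
                    ModelFeature(1, KIND_HYD, (1, 0, 0), 1.5, False),
                ]
            )
        with pytest.raises(PharmflowError, match="radius"):
            ExcludedVolume((0, 0, 0), radius=0.0)


class TestInPlaceMatching:
    def test_self_match_is_complete(self, ref, model):
        res = match_pose(model, ref.pose())
        assert res.n_matched == model.n_features == 8
        assert res.mandatory_satisfied
        assert not res.ev_clash
        assert res.rms < 1e-6

    def test_displaced_mandatory_feature_drops_match(self, ref, model):
        # move the carbonyl acceptor bonded pair past tolerance + 0.1
        xyz = ref.ligand.coords(0).copy()
        hba_id = 3  # feature on atom 19 (carbonyl O1) per construction
        feat = next(f for f in model.features if f.id == hba_id)
        direction = ref.hbond_directions["A51"]
        xyz[19] += (feat.radius + 0.1) * -direction
        pose = Pose(ref.ligand.with_coords(xyz), method="x")
        res = match_pose(model, pose)
        assert res.n_matched == 7
        assert not res.mandatory_satisfied

    def test_matching_equals_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            features, lig = random_instance(rng)
            assignment, _ = match_features_inplace(features, lig)
            assert len(assignment) == brute_force_max_matching(features, lig)

    def test_ev_clash_detected_strictly_inside(self, ref, model):
        inside = ExcludedVolume(tuple(ref.ligand.coords(0)[0]), radius=0.5)
        clashing = PharmacophoreModel(
            features=model.features, excluded_volumes=[inside]
        )
        assert match_pose(clashing, ref.pose()).ev_clash
        # a sphere whose boundary exactly touches an atom does not clash
        d = 0.8
        boundary = ExcludedVolume(
            tuple(ref.ligand.coords(0)[0] + np.array([d, 0, 0])), radius=d
        )
        touching = PharmacophoreModel(
            features=model.features, excluded_volumes=[boundary]
        )
        assert not match_pose(touching, ref.pose()).ev_clash


class TestAlignmentMatching:
    def test_rigid_rotation_recovered(self, ref, model):
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        t = rng.uniform(-15, 15, 3)
        mol = ref.ligand.transformed(R, t)
        res = match_conformers(model, mol)
        assert res.n_matched == 8
        assert res.mandatory_satisfied
        assert res.rms < 1e-6

    def test_molecule_without_acceptors_fails_mandatory(self, model):
        from pharmflow.chem_structures import molecule_from_smiles

        mol = molecule_from_smiles("c1ccccc1", "benzene")
        res = match_conformers(model, mol)
        assert not res.mandatory_satisfied

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_match_sizes_recovered(self, seed):
        ref = make_reference_complex(seed)
        model = build_receptor_model(ref.protein, ref.ligand, [ref.water])
        mols, labels = make_library(FixtureSpec(seed=seed, n_molecules=20), ref)
        seen = set()
        for mol in mols:
            res = match_conformers(model, mol)
            assert res.n_matched == labels[mol.name], mol.name
            assert res.mandatory_satisfied
            seen.add(labels[mol.name])
        assert seen == {5, 6, 7, 8}

    def test_rigid_invariance_of_inplace_match(self, ref, model):
        rng = np.random.default_rng(3)
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        moved_model = PharmacophoreModel(
            features=[
                ModelFeature(f.id, f.kind, tuple(R @ f.pos + t), f.radius, f.mandatory)
                for f in model.features
            ],
            excluded_volumes=[
                ExcludedVolume(tuple(R @ e.pos + t), e.radius)
                for e in model.excluded_volumes
            ],
        )
        moved_pose = Pose(ref.ligand.transformed(R, t), method="x")
        a = match_pose(model, ref.pose())
        b = match_pose(moved_model, moved_pose)
        assert a.n_matched == b.n_matched
        assert a.ev_clash == b.ev_clash
        assert abs(a.rms - b.rms) < 1e-6


class TestScreening:
    def test_planted_proportions_give_cumulative_level_counts(self, ref, model):
        mols, _ = make_library(FixtureSpec(seed=11, n_molecules=40), ref)
        result = screen_library(model, mols, min_features=5)
        assert result.level_counts() == {8: 4, 7: 8, 6: 12, 5: 16}
        assert result.cumulative_counts() == {8: 4, 7: 12, 6: 24, 5: 40}

    def test_cumulativity_is_monotone(self, ref, model):
        mols, _ = make_library(FixtureSpec(seed=12, n_molecules=25), ref)
        result = screen_library(model, mols, min_features=5)
        cum = result.cumulative_counts()
        ks = sorted(cum)
        for lo, hi in zip(ks, ks[1:]):
            assert cum[hi] <= cum[lo]

    def test_higher_level_hits_are_subset_of_lower(self, ref, model):
        mols, _ = make_library(FixtureSpec(seed=13, n_molecules=20), ref)
        at6 = set(screen_library(model, mols, min_features=6).hit_names)
        at7 = set(screen_library(model, mols, min_features=7).hit_names)
        assert at7 <= at6

    def test_empty_library(self, model):
        result = screen_library(model, [], min_features=5)
        assert result.hits == []
        assert result.level_counts() == {}

    def test_min_features_below_mandatory_rejected(self, model):
        with pytest.raises(PharmflowError, match="mandatory"):
            screen_library(model, [], min_features=3)
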