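"""Interaction geometry, water bridges, pose filter, method intersection."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmflow.chem_structures import (
    Bond,
    MolAtom,
    Molecule,
    Pose,
    ProteinAtom,
    ProteinStructure,
    Residue,
    ResidueSelector,
)
from pharmflow.errors import PharmflowError, SelectorError
from pharmflow.interactions import (
    HBOND,
    HYDROPHOBIC,
    PI_STACK,
    InteractionCriteria,
    detect_interactions,
    detect_water_bridge,
    filter_pose,
    intersect_by_method,
)


def carbonyl_probe(offset):
    """A minimal acetaldehyde-like probe with its O at ``offset``."""
    o = np.asarray(offset, float)
    c = o - np.array([1.23, 0.0, 0.0])
    c2 = c - np.array([1.5, 0.0, 0.0])
    return Molecule(
        "probe",
        [MolAtom("O"), MolAtom("C"), MolAtom("C")],
        [Bond(0, 1, 2), Bond(1, 2)],
        [np.array([o, c, c2])],
    )


def backbone_n_residue(pos, number=1):
    return Residue("A", number, "GLY", [ProteinAtom("N", "N", pos)])


class TestHbondDetection:
    def test_carbonyl_at_2p9_from_backbone_n_is_hbond(self):
        prot = ProteinStructure([backbone_n_residue([2.9, 0, 0])])
        pose = Pose(carbonyl_probe([0, 0, 0]).translated([0, 0, 0]), "m")
        recs = detect_interactions(prot, pose)
        hb = [r for r in recs if r.itype == HBOND]
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9)

    def test_beyond_cutoff_is_not_hbond(self):
        prot = ProteinStructure([backbone_n_residue([3.6, 0, 0])])
        pose = Pose(carbonyl_probe([0, 0, 0]), "m")
        assert [r for r in detect_interactions(prot, pose) if r.itype == HBOND] == []

    def test_reference_complex_has_exactly_planted_interactions(self, ref):
        recs = detect_interactions(ref.protein, ref.pose())
        hbonds = {(r.residue_key[1], r.ligand_atoms[0])
                  for r in recs if r.itype == HBOND}
        assert hbonds == {(51, 19), (57, 21), (123, 9), (401, 10)}
        hyd_residues = {r.residue_key[1] for r in recs if r.itype == HYDROPHOBIC}
        assert {179, 205, 213, 241} <= hyd_residues
        stacks = [r for r in recs if r.itype == PI_STACK]
        assert len(stacks) == 1 and stacks[0].residue_name == "TYR"
        assert stacks[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_loosening_cutoffs_never_removes_records(self, ref):
        tight = InteractionCriteria()
        loose = InteractionCriteria(
            hbond_dist=4.2, hydrophobic_dist=5.5, pistack_dist=5.5,
            pistack_max_angle=45.0,
        )
        def ids(recs):
            # per-residue aggregates are identified by residue alone
            return {
                (r.itype, r.residue_key)
                if r.itype == HYDROPHOBIC
                else (r.itype, r.residue_key, r.ligand_atoms)
                for r in recs
            }

        a = ids(detect_interactions(ref.protein, ref.pose(), tight))
        b = ids(detect_interactions(ref.protein, ref.pose(), loose))
        assert a <= b

    def test_rigid_motion_preserves_record_set(self, ref):
        from pharmflow._geom import random_rotation

        rng = np.random.default_rng(8)
        R, t = random_rotation(rng), rng.uniform(-8, 8, 3)
        prot2 = ref.protein.with_coords(ref.protein.all_coords() @ R.T + t)
        pose2 = Pose(ref.ligand.transformed(R, t), "m")
        key = lambda recs: [  # noqa: E731
            (r.itype, r.residue_key, r.ligand_atoms, round(r.distance, 6))
            for r in recs
        ]
        assert key(detect_interactions(ref.protein, ref.pose())) == key(
            detect_interactions(prot2, pose2)
        )

    def test_far_ligand_warns_of_frame_mismatch(self, ref):
        pose = Pose(ref.ligand.translated([200.0, 0, 0]), "m")
        with pytest.warns(UserWarning, match="frames"):
            detect_interactions(ref.protein, pose)

    def test_donor_angle_applied_when_hydrogen_present(self):
        # donor N with an anti-positioned H: D-H...A angle ~0 -> rejected
        n = np.array([2.9, 0.0, 0.0])
        h_anti = n + np.array([1.0, 0.0, 0.0])
        res = Residue("A", 1, "GLY", [ProteinAtom("N", "N", n),
                                      ProteinAtom("H", "H", h_anti)])
        pose = Pose(carbonyl_probe([0, 0, 0]), "m")
        recs = detect_interactions(ProteinStructure([res]), pose)
        assert [r for r in recs if r.itype == HBOND] == []
        # flip the H between donor and acceptor: angle ~180 -> accepted
        res2 = Residue("A", 1, "GLY", [ProteinAtom("N", "N", n),
                                       ProteinAtom("H", "H", n - [1.0, 0, 0])])
        recs2 = detect_interactions(ProteinStructure([res2]), pose)
        assert len([r for r in recs2 if r.itype == HBOND]) == 1


class TestWaterBridge:
    def test_planted_bridge_lists_both_partners(self, ref):
        rec = detect_water_bridge(
            ref.protein, ref.pose(), ref.water,
            [ref.partners["E53"], ref.partners["H272"]],
        )
        assert rec is not None
        assert len(rec.bridged_partners) == 2
        assert rec.distance == pytest.approx(2.8, abs=1e-6)

    def test_displaced_water_breaks_bridge(self, ref):
        # move the ligand 5 Å away instead of rebuilding the pocket
        pose = Pose(ref.ligand.translated(5.0 * ref.axis_z), "m")
        rec = detect_water_bridge(
            ref.protein, pose, ref.water,
            [ref.partners["E53"], ref.partners["H272"]],
        )
        assert rec is None

    def test_non_water_selector_rejected(self, ref):
        with pytest.raises(SelectorError, match="non-water"):
            detect_water_bridge(
                ref.protein, ref.pose(), ref.partners["E53"], [ref.water]
            )

    def test_predicate_equals_brute_force_distance_check(self, ref):
        rng = np.random.default_rng(21)
        criteria = InteractionCriteria()
        wres = ref.water.resolve(ref.protein)
        w = next(a for a in wres.atoms if a.element == "O").coords
        _, oe1 = ref.partners["E53"].resolve_atom(ref.protein)
        _, ne2 = ref.partners["H272"].resolve_atom(ref.protein)
        arm_ok = (
            np.linalg.norm(oe1.coords - w) <= criteria.hbond_dist
            or np.linalg.norm(ne2.coords - w) <= criteria.hbond_dist
        )
        polar = [i for i, a in enumerate(ref.ligand.atoms) if a.element in "NO"]
        for _ in range(40):
            shift = rng.uniform(-2.0, 2.0, 3)
            pose = Pose(ref.ligand.translated(shift), "m")
            expected = arm_ok and any(
                np.linalg.norm(pose.coords[i] - w) <= criteria.hbond_dist
                for i in polar
            )
            got = (
                detect_water_bridge(
                    ref.protein, pose, ref.water,
                    [ref.partners["E53"], ref.partners["H272"]],
                )
                is not None
            )
            assert got == expected


class TestPoseFilter:
    def test_reference_pose_passes_cleanly(self, ref, model):
        res = filter_pose(ref.protein, ref.pose(), ref.pose_filter_spec(), model)
        assert res.passed and res.reasons == []
        assert res.n_hydrophobic_matched == 4

    def test_deleting_arginine_contact_names_the_reason(self, ref, model):
        xyz = ref.ligand.coords(0).copy()
        xyz[21] += 2.0 * -ref.hbond_directions["R57"]  # pull O2 off NH1
        pose = Pose(ref.ligand.with_coords(xyz), "m")
        res = filter_pose(ref.protein, pose, ref.pose_filter_spec(), model)
        assert not res.passed
        assert len(res.reasons) == 1
        assert "57" in res.reasons[0]

    def test_pass_fail_matches_compositional_oracle(self, ref, model):
        """100 perturbed poses vs an independent distance/assignment oracle."""
        rng = np.random.default_rng(5)
        criteria = InteractionCriteria()
        spec = ref.pose_filter_spec()
        acceptors = [i for i, a in enumerate(ref.ligand.atoms) if a.element == "O"]
        partner_pos = {}
        for key in ("A51", "M123", "R57"):
            _, atom = ref.partners[key].resolve_atom(ref.protein)
            partner_pos[key] = atom.coords
        wres = ref.water.resolve(ref.protein)
        w = next(a for a in wres.atoms if a.element == "O").coords
        hyd_feats = [f for f in model.features if f.kind == "HYD"]

        def oracle(pose):
            xyz = pose.coords
            for key in ("A51", "M123", "R57"):
                if not any(
                    np.linalg.norm(xyz[i] - partner_pos[key]) <= criteria.hbond_dist
                    for i in acceptors
                ):
                    return False
            if not any(
                np.linalg.norm(xyz[i] - w) <= criteria.hbond_dist for i in acceptors
            ):
                return False
            # best one-to-one hydrophobic assignment by exhaustive search
            from pharmflow.perception import perceive_features

            hyd_pos = [f.pos for f in perceive_features(pose.molecule)
                       if f.kind == "HYD"]
            best = 0
            for subset in itertools.permutations(range(len(hyd_pos)),
                                                 min(len(hyd_pos), len(hyd_feats))):
                n_ok = sum(
                    1
                    for mf, k in zip(hyd_feats, subset)
                    if np.linalg.norm(mf.pos - hyd_pos[k]) <= mf.radius
                )
                best = max(best, n_ok)
            return best >= spec.min_hydrophobic

        n_pass = 0
        for _ in range(100):
            pose = Pose(ref.ligand.translated(rng.uniform(-1.2, 1.2, 3)), "m")
            got = filter_pose(ref.protein, pose, spec, model, criteria).passed
            assert got == oracle(pose)
            n_pass += got
        assert 0 < n_pass < 100  # perturbations straddle the boundary

    def test_pass_implies_required_interactions_detected(self, ref, model):
        res = filter_pose(ref.protein, ref.pose(), ref.pose_filter_spec(), model)
        assert res.passed
        hb_residues = {r.residue_key[1] for r in res.records if r.itype == HBOND}
        assert {51, 57, 123} <= hb_residues
        assert any(r.itype == "WATER_BRIDGE" for r in res.records)


class TestIntersection:
    def test_basic_and_identity(self):
        assert intersect_by_method({"m1": {"a", "b"}, "m2": {"b", "c"}}) == {"b"}
        assert intersect_by_method({"only": {"x", "y"}}) == {"x", "y"}

    def test_empty_mapping_rejected(self):
        with pytest.raises(PharmflowError):
            intersect_by_method({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.text(min_size=1, max_size=3),
            st.sets(st.integers(0, 12).map(str), max_size=8),
            min_size=1,
            max_size=5,
        )
    )
    def test_equals_pairwise_fold_in_any_order(self, results):
        expected = None
        for s in sorted(results.values(), key=sorted):
            expected = set(s) if expected is None else expected & s
        assert intersect_by_method(results) == expected
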