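"""Trajectory analytics: RMSD series, occupancancy recovery, MD filter."""
import numpy as np
import pytest

from pharmflow.chem_structures import Trajectory
from pharmflow.errors import PharmflowError
from pharmflow.fixtures import TrajectorySpec, make_trajectory
from pharmflow.interactions import InteractionCriteria
from pharmflow.trajectory import (
    MdFilterSpec,
    OccupancyReport,
    hbond_occupancy,
    ligand_rmsd_series,
    md_filter,
    water_rmsd_series,
)


def static_trajectory(ref, n_frames=5):
    base = np.concatenate([ref.protein.all_coords(), ref.ligand.coords(0)])
    return Trajectory(ref.protein, ref.ligand, np.tile(base, (n_frames, 1, 1)))


class TestLigandRmsd:
    def test_identical_frames_are_zero(self, ref):
        series = ligand_rmsd_series(static_trajectory(ref))
        assert np.allclose(series.values, 0.0, atol=1e-12)
        assert series.mean < 1e-12

    def test_pure_ligand_translation_is_exact_without_superposition(self, ref):
        traj = static_trajectory(ref, 3)
        frames = traj.frames.copy()
        frames[2, ref.protein.n_atoms:] += np.array([0.0, 1.0, 0.0])
        traj2 = Trajectory(ref.protein, ref.ligand, frames)
        series = ligand_rmsd_series(traj2, superpose_on="none")
        assert series.values[2] == pytest.approx(1.0, abs=1e-12)
        assert series.values[1] == 0.0

    def test_planted_gaussian_jitter_matches_expectation(self, ref):
        sigma = 0.15
        traj, truth = make_trajectory(
            ref, TrajectorySpec(seed=9, n_frames=200, jitter_sigma=sigma)
        )
        series = ligand_rmsd_series(traj)
        se = np.std(series.values[1:]) / np.sqrt(len(series.values) - 1)
        assert abs(series.mean - truth["expected_mean_rmsd"]) < 3 * se

    def test_ca_superposition_undoes_global_motion(self, ref):
        from pharmflow._geom import random_rotation

        traj = static_trajectory(ref, 3)
        rng = np.random.default_rng(6)
        R, t = random_rotation(rng), rng.uniform(-3, 3, 3)
        frames = traj.frames.copy()
        frames[2] = frames[2] @ R.T + t  # rigid motion of the whole complex
        series = ligand_rmsd_series(
            Trajectory(ref.protein, ref.ligand, frames), superpose_on="protein-CA"
        )
        assert series.values[2] == pytest.approx(0.0, abs=1e-9)


class TestWaterRmsd:
    def test_identical_frames_zero_and_modes_agree(self, ref):
        traj = static_trajectory(ref)
        for mode in ("identity", "nearest"):
            assert water_rmsd_series(traj, ref.water, mode).mean == 0.0

    def test_planted_constant_displacement(self, ref):
        traj = static_trajectory(ref, 4)
        widx = None
        k = 0
        for r in ref.protein.residues:
            for a in r.atoms:
                if r.is_water:
                    widx = k
                k += 1
        frames = traj.frames.copy()
        frames[1:, widx] += 0.5 * np.array([1.0, 0.0, 0.0])
        series = water_rmsd_series(
            Trajectory(ref.protein, ref.ligand, frames), ref.water
        )
        assert np.allclose(series.values[1:], 0.5)
        assert series.mean == pytest.approx(0.5 * 3 / 4)

    def test_identity_vs_nearest_differ_only_under_exchange(self, ref):
        traj, _ = make_trajectory(ref, TrajectorySpec(seed=4, n_frames=30))
        ident = water_rmsd_series(traj, ref.water, "identity")
        near = water_rmsd_series(traj, ref.water, "nearest")
        # single water, no exchange planted: the two tracks agree
        assert np.allclose(ident.values, near.values)


class TestOccupancy:
    def test_planted_seven_of_ten(self, ref):
        traj, truth = make_trajectory(
            ref,
            TrajectorySpec(seed=2, n_frames=10,
                           occupancies={"A51": 0.7, "M123": 1.0,
                                        "R57": 1.0, "water": 1.0}),
        )
        report = hbond_occupancy(traj, ref.md_specs())
        assert report.occupancy["A51"] == pytest.approx(0.7, abs=1e-12)
        assert report.occupancy["M123"] == 1.0
        assert int(report.tracks["A51"].sum()) == 7

    def test_planted_occupancies_recovered_exactly(self, ref):
        spec = TrajectorySpec(seed=8, n_frames=50)
        traj, truth = make_trajectory(ref, spec)
        report = hbond_occupancy(traj, ref.md_specs())
        assert report.occupancy == truth["occupancies"]
        assert report.n_frames == 50

    def test_occupancy_equals_brute_force_frame_loop(self, ref):
        """Direct per-frame distance re-check, independent of the detector."""
        traj, _ = make_trajectory(ref, TrajectorySpec(seed=14, n_frames=25))
        criteria = InteractionCriteria()
        report = hbond_occupancy(traj, ref.md_specs())
        flat = {}
        k = 0
        for r in ref.protein.residues:
            for a in r.atoms:
                flat[(r.key[1], a.name)] = k
                k += 1
        n_prot = ref.protein.n_atoms
        for key, resnum, atom in (("A51", 51, "N"), ("M123", 123, "N"),
                                  ("R57", 57, "NH1")):
            lig_atom = ref.acceptor_atoms[key]
            expected = np.array([
                np.linalg.norm(
                    traj.frames[f, n_prot + lig_atom]
                    - traj.frames[f, flat[(resnum, atom)]]
                ) <= criteria.hbond_dist
                for f in range(traj.n_frames)
            ])
            assert np.array_equal(report.tracks[key], expected)
        w_expected = np.array([
            np.linalg.norm(
                traj.frames[f, n_prot + ref.acceptor_atoms["water"]]
                - traj.frames[f, flat[(401, "O")]]
            ) <= criteria.hbond_dist
            and (
                np.linalg.norm(
                    traj.frames[f, flat[(53, "OE1")]] - traj.frames[f, flat[(401, "O")]]
                ) <= criteria.hbond_dist
                or np.linalg.norm(
                    traj.frames[f, flat[(272, "NE2")]] - traj.frames[f, flat[(401, "O")]]
                ) <= criteria.hbond_dist
            )
            for f in range(traj.n_frames)
        ])
        assert np.array_equal(report.tracks["water"], w_expected)

    def test_occupancy_invariant_under_frame_permutation(self, ref):
        traj, _ = make_trajectory(ref, TrajectorySpec(seed=3, n_frames=20))
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        # keep frame 0 first so the RMSD reference is unchanged
        perm = np.concatenate([[0], perm[perm != 0]])
        shuffled = Trajectory(ref.protein, ref.ligand, traj.frames[perm])
        a = hbond_occupancy(traj, ref.md_specs())
        b = hbond_occupancy(shuffled, ref.md_specs())
        assert a.occupancy == b.occupancy
        assert a.ligand_rmsd_mean == pytest.approx(b.ligand_rmsd_mean)

    def test_unresolvable_selector_errors(self, ref):
        from pharmflow.chem_structures import ResidueSelector
        from pharmflow.trajectory import HBondSpec

        traj, _ = make_trajectory(ref, TrajectorySpec(seed=1, n_frames=5))
        bad = HBondSpec("nope", ResidueSelector("A", 999))
        with pytest.raises(Exception):
            hbond_occupancy(traj, [bad])


def report_with(occ, mean_rmsd, n=50):
    return OccupancyReport(
        occupancy=occ,
        tracks={k: np.zeros(n, dtype=bool) for k in occ},
        ligand_rmsd_mean=mean_rmsd,
        ligand_rmsd_max=mean_rmsd,
        water_rmsd_mean=0.1,
        n_frames=n,
    )


class TestMdFilter:
    def test_typical_hit_profile_passes(self):
        rep = report_with(
            {"R57": 0.98, "water": 0.94, "A51": 0.82, "M123": 0.30}, 1.2
        )
        assert md_filter(rep).passed

    def test_high_rmsd_fails_with_rmsd_reason_only(self):
        rep = report_with(
            {"R57": 1.0, "water": 1.0, "A51": 1.0, "M123": 1.0}, 2.5
        )
        res = md_filter(rep)
        assert not res.passed
        assert len(res.reasons) == 1 and "RMSD" in res.reasons[0]

    def test_boundary_occupancy_and_rmsd_fail_strictly(self):
        at_theta = report_with(
            {"R57": 0.70, "water": 0.94, "A51": 0.82, "M123": 0.30}, 1.0
        )
        assert not md_filter(at_theta).passed
        at_rmsd = report_with(
            {"R57": 0.98, "water": 0.94, "A51": 0.82, "M123": 0.30}, 2.0
        )
        assert not md_filter(at_rmsd).passed

    def test_oxyanion_clause_is_an_or(self):
        a_only = report_with(
            {"R57": 0.9, "water": 0.9, "A51": 0.9, "M123": 0.0}, 1.0
        )
        m_only = report_with(
            {"R57": 0.9, "water": 0.9, "A51": 0.0, "M123": 0.9}, 1.0
        )
        neither = report_with(
            {"R57": 0.9, "water": 0.9, "A51": 0.1, "M123": 0.1}, 1.0
        )
        assert md_filter(a_only).passed
        assert md_filter(m_only).passed
        assert not md_filter(neither).passed

    def test_monotonicity_improvements_never_flip_pass_to_fail(self):
        rng = np.random.default_rng(12)
        spec = MdFilterSpec()
        for _ in range(50):
            occ = {k: float(rng.uniform(0, 1))
                   for k in ("R57", "water", "A51", "M123")}
            rmsd = float(rng.uniform(0, 3))
            base = md_filter(report_with(occ, rmsd), spec).passed
            better_occ = {k: min(1.0, v + rng.uniform(0, 0.3))
                          for k, v in occ.items()}
            better = md_filter(
                report_with(better_occ, max(0.0, rmsd - rng.uniform(0, 1))), spec
            ).passed
            assert better >= base

    def test_missing_required_key_errors(self):
        rep = report_with({"R57": 0.9}, 1.0)
        with pytest.raises(PharmflowError, match="water"):
            md_filter(rep)
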