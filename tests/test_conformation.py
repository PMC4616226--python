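"""Structural descriptors: tilt angles, protein axis, B-factors, RMSD,
centroid distances and hydrogen-bond occupancy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lhcswitch import (
    AnalysisError,
    Atom,
    AtomSelection,
    DomainDefinition,
    GeometryError,
    HBondSpec,
    ProteinAxis,
    StructureModel,
    Trajectory,
    TransitionDipole,
    com_distance_series,
    domain_rmsd_series,
    hbond_occupancy,
    per_atom_bfactor,
    protein_axis,
    tilt_angle,
)
from lhcswitch.synthetic import FrameTransformSchedule, make_trajectory
from tests.conftest import random_rotation

Z = ProteinAxis(direction=np.array([0.0, 0.0, 1.0]))


def unit_dipole(v):
    v = np.asarray(v, float)
    return TransitionDipole(center=np.zeros(3), direction=v / np.linalg.norm(v),
                            magnitude_debye=1.0)


def grid_model(n=4, spacing=3.0):
    atoms = []
    k = 0
    for i in range(n):
        for j in range(n):
            for l in range(n):
                k += 1
                atoms.append(Atom(serial=k, name="CA", resname="ALA", resid=k,
                                  chain="A",
                                  position=[i * spacing, j * spacing, l * spacing]))
    return StructureModel(atoms)


class TestTiltAngle:
    @pytest.mark.parametrize("v,expected", [
        ((0, 0, 1), 0.0),
        ((1, 0, 0), 90.0),
        ((1, 0, 1), 45.0),
        ((0, 0, -1), 0.0),        # sign of the dipole is unphysical
        ((-1, 0, -1), 45.0),
    ])
    def test_analytic_cases_folded_to_first_quadrant(self, v, expected):
        assert tilt_angle(unit_dipole(v), Z) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_common_rotation(self, rng):
        v = np.array([0.3, -0.5, 0.8])
        rot = random_rotation(rng)
        before = tilt_angle(unit_dipole(v), Z)
        after = tilt_angle(unit_dipole(rot.apply(v)),
                           ProteinAxis(direction=rot.apply(Z.direction)))
        assert after == pytest.approx(before, abs=1e-9)


class TestProteinAxis:
    def _bundle(self, rotation=None):
        from lhcswitch.synthetic import _helix_ca
        atoms = (_helix_ca("A", 1, 30, (0, 0, 0), 1)
                 + _helix_ca("A", 40, 30, (10, 0, 0), 100)
                 + _helix_ca("A", 80, 30, (5, 8, 0), 200))
        m = StructureModel(atoms)
        if rotation is not None:
            m = m.with_coords(rotation.apply(m.coords))
        return m

    def test_helix_bundle_axis_is_z(self):
        axis = protein_axis(self._bundle(), AtomSelection(names=("CA",)))
        assert np.degrees(np.arccos(abs(axis.direction @ [0, 0, 1]))) < 1.0

    def test_equivariance_under_rotation(self):
        rot = Rotation.from_euler("x", 30, degrees=True)
        axis = protein_axis(self._bundle(rot), AtomSelection(names=("CA",)))
        expected = rot.apply([0, 0, 1])
        assert np.degrees(np.arccos(abs(axis.direction @ expected))) < 1.0

    def test_sign_points_towards_reference_atom(self):
        m = self._bundle()
        top = max(m.atoms, key=lambda a: a.position[2])
        axis = protein_axis(m, AtomSelection(names=("CA",)),
                            reference_atom=("A", top.resid, "CA"))
        assert axis.direction[2] > 0

    def test_too_few_atoms_is_an_error(self):
        m = self._bundle()
        with pytest.raises(GeometryError):
            protein_axis(m, AtomSelection(residue_ranges=[(1, 2)]))

    def test_lab_z_mode(self):
        axis = protein_axis(self._bundle(), AtomSelection(names=("CA",)),
                            mode="lab_z_after_alignment")
        assert np.allclose(axis.direction, [0, 0, 1])


class TestBFactor:
    def test_static_trajectory_gives_zero(self):
        m = grid_model()
        traj = Trajectory(m, np.stack([m.coords] * 5), np.arange(5.0))
        res = per_atom_bfactor(traj)
        assert np.allclose(res.bfactor, 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        m = grid_model()
        traj = Trajectory(m, m.coords[None], np.array([0.0]))
        with pytest.raises(AnalysisError):
            per_atom_bfactor(traj)

    def test_gaussian_jitter_recovers_8pi2_sigma2(self):
        """B = 8π²σ² for isotropic jitter σ per coordinate."""
        sigma = 0.5
        m = grid_model()
        traj, _ = make_trajectory(m, n_frames=2000, noise_sigma=sigma, seed=7)
        res = per_atom_bfactor(traj)
        expected = 8 * np.pi**2 * sigma**2
        assert np.mean(res.bfactor) == pytest.approx(expected, rel=0.05)

    def test_global_rotation_does_not_inflate_b(self):
        """Superposition removes a rigid tumbling overlaid on the jitter."""
        sigma, n_frames = 0.5, 400
        m = grid_model()
        plain, _ = make_trajectory(m, n_frames=n_frames, noise_sigma=sigma, seed=3)
        rots = [Rotation.from_euler("z", 0.25 * i, degrees=True)
                for i in range(n_frames)]
        sched = FrameTransformSchedule(selection=AtomSelection(),
                                       rotations=rots,
                                       pivot=m.coords.mean(axis=0))
        tumbled, _ = make_trajectory(m, n_frames=n_frames, noise_sigma=sigma,
                                     seed=3, schedules=(sched,))
        b_plain = np.mean(per_atom_bfactor(plain).bfactor)
        b_tumbled = np.mean(per_atom_bfactor(tumbled).bfactor)
        assert b_tumbled == pytest.approx(b_plain, rel=0.05)


class TestDomainRmsd:
    def _protein(self):
        # rigid core residues 1-64, mobile domain residues 100-107
        core = grid_model()
        atoms = list(core.atoms)
        k = len(atoms)
        for i in range(8):
            atoms.append(Atom(serial=k + i + 1, name="CA", resname="GLY",
                              resid=100 + i, chain="A",
                              position=[20.0 + i, 0.0, 0.0]))
        return StructureModel(atoms)

    def test_reference_trajectory_gives_zero(self):
        m = self._protein()
        traj = Trajectory(m, np.stack([m.coords] * 3), np.arange(3.0))
        ts = domain_rmsd_series(traj, m, DomainDefinition("dom", [(100, 107)]),
                                AtomSelection(residue_ranges=[(1, 64)]))
        assert np.allclose(ts.values, 0.0, atol=1e-9)

    def test_rigid_domain_displacement_reads_exactly(self):
        m = self._protein()
        coords = m.coords.copy()
        dom_idx = [i for i, a in enumerate(m.atoms) if a.resid >= 100]
        coords[dom_idx] += np.array([0.0, 2.0, 0.0])
        traj = Trajectory(m, np.stack([coords] * 3), np.arange(3.0))
        ts = domain_rmsd_series(traj, m, DomainDefinition("dom", [(100, 107)]),
                                AtomSelection(residue_ranges=[(1, 64)]))
        assert np.allclose(ts.values, 2.0, atol=1e-9)

    def test_domain_noise_gives_sqrt3_sigma(self):
        """Monte-Carlo: Gaussian σ on the domain only → mean RMSD ≈ √3σ."""
        m = self._protein()
        sigma = 0.4
        rng = np.random.default_rng(11)
        dom_idx = [i for i, a in enumerate(m.atoms) if a.resid >= 100]
        frames = np.stack([m.coords] * 300)
        frames[:, dom_idx] += rng.normal(0, sigma, size=(300, len(dom_idx), 3))
        traj = Trajectory(m, frames, np.arange(300.0))
        ts = domain_rmsd_series(traj, m, DomainDefinition("dom", [(100, 107)]),
                                AtomSelection(residue_ranges=[(1, 64)]))
        assert np.mean(ts.values) == pytest.approx(np.sqrt(3) * sigma, rel=0.1)


class TestComDistance:
    def _pair_model(self):
        atoms = [Atom(serial=1, name="P1", resname="LIG", resid=1, chain="A",
                      position=[0, 0, 0])]
        for i, (x, y) in enumerate([(-1, -1), (-1, 1), (1, -1), (1, 1)]):
            atoms.append(Atom(serial=2 + i, name=f"Q{i}", resname="LIG",
                              resid=2, chain="A", position=[x + 3, y, 4]))
        return StructureModel(atoms)

    def test_two_single_atoms(self):
        m = self._pair_model()
        traj = Trajectory(m, np.stack([m.coords] * 2), np.arange(2.0))
        a = AtomSelection(residue_ranges=[(1, 1)])
        b = AtomSelection(names=("Q0",))
        ts = com_distance_series(traj, a, b, mass_weighting=False)
        assert np.allclose(ts.values, np.linalg.norm([2, -1, 4]))

    def test_square_centroid_distance_and_symmetry(self):
        m = self._pair_model()
        traj = Trajectory(m, np.stack([m.coords] * 2), np.arange(2.0))
        a = AtomSelection(residue_ranges=[(1, 1)])
        b = AtomSelection(residue_ranges=[(2, 2)])
        ts_ab = com_distance_series(traj, a, b, mass_weighting=False)
        ts_ba = com_distance_series(traj, b, a, mass_weighting=False)
        assert np.allclose(ts_ab.values, 5.0)          # centroid (3,0,4)
        assert np.allclose(ts_ab.values, ts_ba.values)

    def test_empty_selection_is_an_error(self):
        m = self._pair_model()
        traj = Trajectory(m, np.stack([m.coords] * 2), np.arange(2.0))
        with pytest.raises(AnalysisError):
            com_distance_series(traj, AtomSelection(resnames=("XXX",)),
                                AtomSelection(residue_ranges=[(1, 1)]))


class TestHBond:
    def _traj(self, distances, with_h=True):
        atoms = [
            Atom(serial=1, name="NE2", resname="GLN", resid=131, chain="A",
                 position=[0, 0, 0], element="N"),
            Atom(serial=2, name="HE2", resname="GLN", resid=131, chain="A",
                 position=[0, 1.0, 0], element="H"),
            Atom(serial=3, name="OBD", resname="CHL", resid=607, chain="A",
                 position=[0, 3.0, 0], element="O"),
        ]
        m = StructureModel(atoms)
        frames = np.stack([m.coords] * len(distances))
        for i, d in enumerate(distances):
            frames[i, 2] = [0, d, 0]
        return Trajectory(m, frames, np.arange(float(len(distances))))

    def _spec(self, **kw):
        return HBondSpec(donor=("A", 131, "NE2"), acceptor=("A", 607, "OBD"),
                         hydrogen=("A", 131, "HE2"), **kw)

    def test_bond_present_within_cutoffs(self):
        occ, present = hbond_occupancy(self._traj([2.9, 2.9]), self._spec())
        assert occ == 1.0 and present.all()

    def test_bond_absent_beyond_distance_cutoff(self):
        occ, _ = hbond_occupancy(self._traj([4.0, 4.0]), self._spec())
        assert occ == 0.0

    def test_angle_criterion(self):
        # move H off-axis: H-donor-acceptor angle 90° > 30° cutoff
        traj = self._traj([2.9, 2.9])
        coords = traj.frames.copy()
        coords[:, 1] = [1.0, 0.0, 0.0]
        traj = Trajectory(traj.topology, coords, traj.times)
        occ, _ = hbond_occupancy(traj, self._spec())
        assert occ == 0.0

    def test_toggle_schedule_occupancy_is_exact(self):
        """30% of frames under the cutoff → occupancy 0.300 exactly."""
        distances = [2.9] * 3 + [4.0] * 7
        occ, present = hbond_occupancy(self._traj(distances), self._spec())
        assert occ == pytest.approx(0.300, abs=0)
        assert present.sum() == 3

    def test_occupancy_monotone_in_distance_cutoff(self):
        traj = self._traj([2.0, 2.5, 3.0, 3.5, 4.0, 4.5])
        occs = [hbond_occupancy(traj, self._spec(d_cut=d))[0]
                for d in (2.2, 2.7, 3.2, 3.7, 4.2, 4.7)]
        assert all(a <= b for a, b in zip(occs, occs[1:]))
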