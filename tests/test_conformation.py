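"""Superposition, domain motion, helix tilts, crosslink checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from redoxmap import fixtures
from redoxmap.conformation import (
    SelectionSpec,
    GeometryError,
    superpose,
    domain_motion,
    helix_tilt,
    crosslink_check,
    kabsch,
)
from redoxmap.fixtures import rotation_about_axis
from redoxmap.structures import Structure, AtomRecord
from conftest import random_rigid_transform

CORE = SelectionSpec("A", ((1, 20),))
DOMAIN = SelectionSpec("B", ((1, 20),))


class TestSuperpose:
    def test_identity_on_same_structure(self):
        s = fixtures.make_ideal_helix(20)
        tf, rmsd = superpose(s, s, CORE)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self):
        s = fixtures.make_ideal_helix(20)
        R = rotation_about_axis(np.array([0, 0, 1.0]), 30.0)
        t = np.array([1.0, 2.0, 3.0])
        mov = s.transformed(R, t)
        tf, rmsd = superpose(s, mov, CORE)
        assert rmsd < 1e-6
        # recovered transform inverts the applied one
        assert np.allclose(tf.rotation, R.T, atol=1e-9)
        assert np.allclose(tf.apply(mov.coords), s.coords, atol=1e-6)

    def test_kabsch_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(25, 3))
        R, t = random_rigid_transform(rng)
        Q = P @ R.T + t
        tf = kabsch(P, Q)
        est, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(tf.rotation, est.as_matrix(), atol=1e-8)

    def test_reflection_pair_yields_proper_rotation(self):
        s = fixtures.make_ideal_helix(20)
        mirrored = Structure("mir", [
            AtomRecord(a.serial, a.name, a.element, a.altloc, a.residue_name,
                       a.chain_id, a.residue_seq, a.insertion_code,
                       a.position * np.array([1.0, 1.0, -1.0]))
            for a in s.atoms])
        tf, rmsd = superpose(s, mirrored, CORE)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        assert rmsd > 0.5  # no improper solution can hide the handedness flip

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(7)
        ref, mov = fixtures.make_hinge_pair(10.0)
        _, rmsd0 = superpose(ref, mov, CORE)
        R, t = random_rigid_transform(rng)
        _, rmsd1 = superpose(ref, mov.transformed(R, t), CORE)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_too_few_or_collinear_atoms_rejected(self):
        s = fixtures.make_ideal_helix(20)
        with pytest.raises(GeometryError, match=">= 3"):
            superpose(s, s, SelectionSpec("A", ((1, 2),)))
        line = Structure("line", [
            AtomRecord(i + 1, "CA", "C", "", "ALA", "A", i + 1, "",
                       np.array([0.0, 0.0, float(i)]))
            for i in range(10)])
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, line, SelectionSpec("A", ((1, 10),)))


class TestDomainMotion:
    def test_no_motion_gives_zero(self):
        ref, _ = fixtures.make_hinge_pair(15.0)
        dt = domain_motion(ref, ref, CORE, DOMAIN)
        assert dt.rotation_angle == pytest.approx(0.0, abs=1e-6)
        assert dt.max_displacement == pytest.approx(0.0, abs=1e-9)

    def test_recovers_constructed_hinge_angle(self):
        ref, mov = fixtures.make_hinge_pair(26.0)
        dt = domain_motion(ref, mov, CORE, DOMAIN)
        assert dt.rotation_angle == pytest.approx(26.0, abs=0.1)
        assert dt.rmsd_domain < 1e-6

    def test_hundred_random_hinges_recovered(self):
        """Angle recovery within 0.1 degrees over 100 seeded axis/angle draws."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            angle = rng.uniform(1.0, 179.0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ref, mov = fixtures.make_hinge_pair(angle, axis=axis,
                                                pivot=rng.uniform(-10, 10, 3))
            dt = domain_motion(ref, mov, CORE, DOMAIN)
            worst = max(worst, abs(dt.rotation_angle - angle))
        assert worst < 0.1

    def test_axis_is_rotation_invariant_direction(self):
        ref, mov = fixtures.make_hinge_pair(30.0, axis=(0, 1, 0))
        dt = domain_motion(ref, mov, CORE, DOMAIN)
        R = rotation_about_axis(dt.rotation_axis, dt.rotation_angle)
        assert np.allclose(R @ dt.rotation_axis, dt.rotation_axis, atol=1e-6)
        assert abs(abs(np.dot(dt.rotation_axis, [0, 1, 0])) - 1.0) < 1e-6

    def test_max_displacement_matches_construction(self):
        angle, pivot = 26.0, np.array([0.0, 0.0, 30.0])
        ref, mov = fixtures.make_hinge_pair(angle, axis=(0, 1, 0), pivot=pivot)
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), angle)
        dom = [a.position for a in ref.chain_atoms("B")]
        truth = max(np.linalg.norm(R @ (p - pivot) + pivot - p) for p in dom)
        dt = domain_motion(ref, mov, CORE, DOMAIN)
        assert dt.max_displacement == pytest.approx(truth, abs=1e-6)

    def test_overlapping_core_and_domain_rejected(self):
        ref, mov = fixtures.make_hinge_pair(10.0)
        with pytest.raises(ValueError, match="overlap"):
            domain_motion(ref, mov, SelectionSpec("B", ((1, 5),)), DOMAIN)


class TestHelixTilt:
    def test_same_structure_zero_tilt(self):
        ref, _ = fixtures.make_hinge_pair(20.0)
        r = helix_tilt(ref, ref, CORE, DOMAIN)
        assert r.tilt_deg == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("tilt", [7.0, 12.0, 25.0])
    def test_recovers_constructed_tilt(self, tilt):
        core = fixtures.make_ideal_helix(20, chain_id="A")
        hel = fixtures.make_ideal_helix(14, axis=(1, 0, 0), origin=(10, 0, 0), chain_id="H")
        ref = Structure("r", list(core.atoms) + list(hel.atoms))
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), tilt)
        tilted = hel.transformed(R, np.zeros(3))
        mov = Structure("m", list(core.atoms) + list(tilted.atoms))
        r = helix_tilt(ref, mov, CORE, SelectionSpec("H", ((1, 14),)))
        assert r.tilt_deg == pytest.approx(tilt, abs=0.5)
        assert r.fit_rmsd_ref < 1.0

    def test_symmetric_in_argument_order(self):
        ref, mov = fixtures.make_hinge_pair(18.0)
        a = helix_tilt(ref, mov, CORE, DOMAIN).tilt_deg
        b = helix_tilt(mov, ref, CORE, DOMAIN).tilt_deg
        assert a == pytest.approx(b, abs=1e-6)

    def test_shared_rigid_motion_gives_zero_tilt(self):
        rng = np.random.default_rng(3)
        ref, _ = fixtures.make_hinge_pair(0.0)
        R, t = random_rigid_transform(rng)
        moved = ref.transformed(R, t)
        r = helix_tilt(ref, moved, CORE, DOMAIN)
        assert r.tilt_deg == pytest.approx(0.0, abs=1e-6)

    def test_short_helix_rejected(self):
        ref, mov = fixtures.make_hinge_pair(5.0)
        with pytest.raises(ValueError, match=">= 7"):
            helix_tilt(ref, mov, CORE, SelectionSpec("B", ((1, 5),)))

    def test_nonhelical_selection_warns(self):
        rng = np.random.default_rng(9)
        atoms = [AtomRecord(i + 1, "CA", "C", "", "ALA", "Z", i + 1, "",
                            rng.uniform(-4, 4, 3) + np.array([0, 0, 2.0 * i]))
                 for i in range(10)]
        blob = Structure("blob", atoms)
        core = fixtures.make_ideal_helix(20, chain_id="A", origin=(30, 0, 0))
        ref = Structure("r", list(core.atoms) + atoms)
        with pytest.warns(UserWarning, match="helical"):
            helix_tilt(ref, ref, CORE, SelectionSpec("Z", ((1, 10),)))


class TestCrosslinks:
    def test_adjacent_residues_compatible(self):
        s = fixtures.make_ideal_helix(10)
        recs = crosslink_check(s, [("A", 1, "A", 2)], max_allowed=30.0)
        assert recs[0].compatible and recs[0].ca_distance < 5.0

    def test_distant_pair_incompatible(self):
        a = fixtures.make_ideal_helix(8, chain_id="A")
        b = fixtures.make_ideal_helix(8, chain_id="B", origin=(35.0, 0, 0))
        s = Structure("s", list(a.atoms) + list(b.atoms))
        recs = crosslink_check(s, [("A", 1, "B", 1)], max_allowed=30.0)
        assert recs[0].resolved and not recs[0].compatible
        assert recs[0].ca_distance > 30.0

    def test_empty_pair_list_gives_empty_report(self):
        s = fixtures.make_ideal_helix(8)
        assert crosslink_check(s, []) == []

    def test_missing_residue_flagged_not_dropped(self):
        s = fixtures.make_ideal_helix(8)
        recs = crosslink_check(s, [("A", 1, "Q", 99)])
        assert len(recs) == 1
        assert not recs[0].resolved and recs[0].compatible is None
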