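"""Tetrad detection and fold classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import TWIST_RH, mirror
from g4kit.core import AtomRecord, Model, Structure
from g4kit.topology import (HBondGeomCriteria, analyze_topology,
                            classify_glyco, classify_helicity, detect_hbonds,
                            detect_tetrads, fit_plane, glycosidic_chi,
                            stack_axis, twist_angle)


class TestFitPlane:
    def test_coplanar_points_have_zero_residual(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        _, normal, resid = fit_plane(pts)
        assert resid < 1e-12
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_symmetric_noise_keeps_centroid(self):
        pts = np.array([[1, 0, 0.3], [0, 1, -0.3], [-1, 0, 0.3],
                        [0, -1, -0.3]], float)
        centroid, _, _ = fit_plane(pts)
        assert np.allclose(centroid, pts.mean(axis=0))

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float)
        with pytest.raises(ValueError):
            fit_plane(pts)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_against_brute_force_normal_search(self, seed):
        """SVD plane fit agrees with a dense grid search over normals on
        random 6-point sets."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        _, normal, resid = fit_plane(pts)
        c = pts.mean(axis=0)
        # brute force: residual minimized over a fine spherical grid
        th = np.linspace(0, np.pi, 180)
        ph = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        normals = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P),
                            np.cos(T)], axis=-1).reshape(-1, 3)
        res = np.sqrt(np.mean(((pts - c) @ normals.T) ** 2, axis=0))
        best = res.min()
        # the grid is ~0.5 deg coarse; the SVD optimum must not exceed it
        assert resid <= best + 1e-4
        assert resid <= best * 1.001 + 1e-9


class TestGlycosidic:
    def test_builder_default_is_anti(self, rh_minus):
        chi = glycosidic_chi(rh_minus.models[0], "A", 1)
        assert classify_glyco(chi) == "anti"

    @pytest.mark.parametrize("chi,expected", [
        (60.0, "syn"), (180.0, "anti"), (-120.0, "anti"), (0.0, "syn"),
        (90.0, "syn"), (-90.0001, "anti")])
    def test_syn_anti_boundaries(self, chi, expected):
        assert classify_glyco(chi) == expected

    def test_missing_atom_raises(self, rh_minus):
        sub = Model([a for a in rh_minus.models[0].atoms
                     if not (a.residue_index == 1 and a.chain_id == "A"
                             and a.name == "O4'")])
        with pytest.raises(ValueError, match="O4'"):
            glycosidic_chi(sub, "A", 1)


class TestHbondCriteria:
    def _pair(self, da_dist, dha_deg):
        """Donor N1(H1) of one guanine-like residue and acceptor O6 of
        another, with controlled geometry."""
        h = np.array([1.01, 0.0, 0.0])
        ang = np.radians(180.0 - dha_deg)
        acc = h + (da_dist - 1.01) * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms = [
            AtomRecord(1, "N1", "N", "DG", 1, "A", np.zeros(3)),
            AtomRecord(2, "H1", "H", "DG", 1, "A", h),
            AtomRecord(3, "O6", "O", "DG", 2, "A", acc),
        ]
        return Model(atoms)

    def test_good_geometry_accepted(self):
        assert len(detect_hbonds(self._pair(2.9, 170.0))) == 1

    def test_long_distance_excluded(self):
        assert detect_hbonds(self._pair(4.0, 180.0)) == []

    def test_bent_angle_excluded(self):
        assert detect_hbonds(self._pair(3.0, 120.0)) == []

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondGeomCriteria(max_DA_A=5.0)
        with pytest.raises(ValueError):
            HBondGeomCriteria(min_DHA_deg=60.0)

    def test_inferred_hydrogens_match_explicit(self, tetrad_model):
        """Dropping the hydrogens and re-detecting with idealized H
        placement finds the same eight Hoogsteen bonds."""
        noh = Model([a for a in tetrad_model.atoms if a.element != "H"])
        bonds = detect_hbonds(noh)
        pairs = {(noh.atoms[b.donor_index].name,
                  noh.atoms[b.acceptor_index].name) for b in bonds}
        assert ("N1", "O6") in pairs and ("N2", "N7") in pairs
        assert len([b for b in bonds
                    if (noh.atoms[b.donor_index].name,
                        noh.atoms[b.acceptor_index].name)
                    in {("N1", "O6"), ("N2", "N7")}]) == 8


class TestDetectTetrads:
    def test_two_layer_build_gives_two_stacked_tetrads(self, rh_minus):
        tets = detect_tetrads(rh_minus.models[0])
        assert len(tets) == 2

    def test_broken_bond_removes_tetrad_under_strict_rule(self, tetrad_model):
        """Displacing one acceptor O6 breaks one of the eight bonds; the
        strict both-bond rule then rejects the 4-cycle."""
        atoms = []
        for a in tetrad_model.atoms:
            if a.chain_id == "B" and a.name == "O6":
                a = AtomRecord(a.serial, a.name, a.element, a.residue_name,
                               a.residue_index, a.chain_id,
                               a.xyz + np.array([0.0, 0.0, 3.0]))
            atoms.append(a)
        broken = Model(atoms)
        assert detect_tetrads(broken) == []
        assert len(detect_tetrads(broken, require_both_bonds=False)) == 1

    def test_atom_order_permutation_invariant(self, tetrad_model):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tetrad_model.atoms))
        shuffled = Model([tetrad_model.atoms[i] for i in perm])
        a = detect_tetrads(tetrad_model)[0]
        b = detect_tetrads(shuffled)[0]
        assert a.residues == b.residues

    def test_duplex_like_input_has_no_tetrads(self, tetrad_model):
        """Two guanines cannot form a 4-cycle."""
        sub = Model([a for a in tetrad_model.atoms if a.chain_id in "AB"])
        assert detect_tetrads(sub) == []


class TestStackAxis:
    def test_two_tetrad_axis_is_centroid_difference(self, rh_minus):
        tets = detect_tetrads(rh_minus.models[0])
        axis = stack_axis(tets)
        assert abs(abs(axis[2]) - 1.0) < 1e-6

    def test_axis_flips_with_order(self, rh_minus):
        tets = detect_tetrads(rh_minus.models[0])
        assert np.allclose(stack_axis(tets), -stack_axis(tets[::-1]))

    def test_three_collinear_centroids(self):
        s = analyze_topology(
            __import__("g4kit").build_g4(
                __import__("g4kit").HelicalParams(n_tetrads=3, twist_deg=29.0,
                                                  progression="-",
                                                  loop_lengths=(0, 0, 0))))
        assert abs(abs(s.axis[2]) - 1.0) < 1e-6
        assert len(s.tetrads) == 3
        assert len(s.twist_per_step_deg) == 2


class TestTwistAngle:
    def test_rigid_motion_invariance(self, rh_minus):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [20, -35, 70], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])
        moved = Structure([rh_minus.models[0].with_coords(
            rh_minus.models[0].coords @ R.T + t)])
        topo = analyze_topology(moved)
        assert topo.mean_twist_deg == pytest.approx(TWIST_RH, abs=1e-6)

    def test_mirror_antisymmetry(self, rh_minus):
        topo = analyze_topology(mirror(rh_minus))
        assert topo.mean_twist_deg == pytest.approx(-TWIST_RH, abs=1e-6)

    def test_unstacked_tetrads_rejected(self, rh_minus):
        tets = detect_tetrads(rh_minus.models[0])
        far = tets[1]
        far.centroid = far.centroid + np.array([0.0, 0.0, 10.0])
        with pytest.raises(ValueError, match="stacked"):
            twist_angle(rh_minus.models[0], tets[0], far,
                        np.array([0.0, 0.0, 1.0]))


class TestClassifyHelicity:
    @pytest.mark.parametrize("twist,expected", [
        (29.0, "RH"), (-27.0, "LH"), (2.0, "indeterminate"),
        (-5.0, "indeterminate"), (5.1, "RH")])
    def test_dead_zone(self, twist, expected):
        assert classify_helicity(twist) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_helicity(float("nan"))


@pytest.mark.parametrize("twist", [10.0, 20.0, 30.0, 40.0,
                                   -10.0, -20.0, -30.0, -40.0])
@pytest.mark.parametrize("progression", ["+", "-"])
def test_classifier_round_trip_suite(twist, progression):
    """Helicity and progression labels recover the build parameters for
    every twist in the +/-10..40 deg range and both progressions."""
    from g4kit.builder import HelicalParams, build_g4
    s = build_g4(HelicalParams(twist_deg=twist, progression=progression,
                               loop_lengths=(0, 0, 0)))
    topo = analyze_topology(s)
    assert topo.helicity == ("RH" if twist > 0 else "LH")
    assert topo.progression == progression
    assert topo.mean_twist_deg == pytest.approx(twist, abs=1e-6)
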