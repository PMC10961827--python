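"""Collective variables: channel RoG, Kabsch/delta-RMSD, loop spans,
SASA with S/E classification, occupancy decomposition, QM fragments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from g4kit.core import AtomRecord, AtomSelector, Model, Structure, Trajectory
from g4kit.cv import (FragmentSet, HBondSpec, channel_rog, classify_folded,
                      classify_SE, delta_rmsd, extract_qm_fragments,
                      hbond_occupancy, loop_span, shrake_rupley_sasa,
                      superpose)
from g4kit.kinetics import StateSeries
from g4kit.topology import HBondGeomCriteria, analyze_topology


def _dummy(name, xyz, res=1, chain="A", elem=None, serial=None, resname="DG"):
    return AtomRecord(serial or 1, name, elem or name[0], resname, res,
                      chain, np.asarray(xyz, float))


class TestChannelRog:
    def test_prism_closed_form(self):
        """8 atoms at cylinder radius a in two planes +-h/2 give
        RoG = sqrt(a^2 + h^2/4)."""
        a, h = 2.2, 3.4
        atoms = []
        k = 0
        for z in (-h / 2, h / 2):
            for phi in (0, 90, 180, 270):
                k += 1
                atoms.append(_dummy("O6", [a * np.cos(np.radians(phi)),
                                           a * np.sin(np.radians(phi)), z],
                                    elem="O", serial=k, res=k))
        m = Model(atoms)
        rog = channel_rog(m, atom_indices=list(range(8)))
        assert rog * 10.0 == pytest.approx(np.sqrt(a ** 2 + h ** 2 / 4),
                                           abs=1e-12)

    def test_coincident_atoms_give_zero(self):
        atoms = [_dummy("O6", [1.0, 2.0, 3.0], elem="O", serial=i, res=i)
                 for i in range(1, 5)]
        assert channel_rog(Model(atoms), atom_indices=[0, 1, 2, 3]) == 0.0

    def test_on_built_structure(self, rh_minus, rh_minus_topology):
        rog = channel_rog(rh_minus.models[0], rh_minus_topology)
        assert classify_folded(rog) == "F"

    def test_rigid_motion_invariance(self, rh_minus, rh_minus_topology):
        m = rh_minus.models[0]
        R = Rotation.from_euler("zyx", [10, 40, -70], degrees=True).as_matrix()
        moved = m.with_coords(m.coords @ R.T + np.array([3.0, 4.0, -5.0]))
        assert channel_rog(moved, rh_minus_topology) == pytest.approx(
            channel_rog(m, rh_minus_topology), abs=1e-12)


class TestClassifyFolded:
    @pytest.mark.parametrize("rog,expected", [
        (0.355, "F"), (0.37, "U"), (1.0, "U"), (0.3699, "F")])
    def test_strict_boundary(self, rog, expected):
        assert classify_folded(rog) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_folded(float("nan"))


class TestSuperpose:
    def test_rigid_rotation_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        R = Rotation.random(rng=np.random.default_rng(2)).as_matrix()
        Y = X @ R.T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = superpose(X, Y)
        assert rmsd < 1e-9

    def test_mirror_of_chiral_set_keeps_residual(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 0] *= -1
        _, _, rmsd = superpose(X, Y)
        assert rmsd > 0.1

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_against_quaternion_grid_oracle(self, seed):
        """Kabsch RMSD matches a brute-force search over a dense random
        quaternion grid (the grid can only be worse or equal)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(X, Y)
        q = np.random.default_rng(seed + 1).normal(size=(20000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        best = np.inf
        mats = Rotation.from_quat(q).as_matrix()
        for R in mats:
            r = np.sqrt(np.mean(np.sum((Xc - Yc @ R.T) ** 2, axis=1)))
            best = min(best, r)
        assert rmsd <= best + 1e-6
        # and the dense grid comes close, so the oracle is meaningful
        assert best - rmsd < 0.05


class TestDeltaRmsd:
    def test_endpoints_and_antisymmetry(self, rh_minus, lh_minus):
        sel = AtomSelector(atom_names={"C1'", "N9", "O6"})
        m_rh = rh_minus.models[0]
        m_lh = lh_minus.models[0]
        d_at_rh = delta_rmsd(m_rh, m_lh, m_rh, sel)
        d_at_lh = delta_rmsd(m_lh, m_lh, m_rh, sel)
        cross = superpose(
            np.array([a.xyz for a in m_lh.atoms if sel.matches(a)]),
            np.array([a.xyz for a in m_rh.atoms if sel.matches(a)]))[2] / 10.0
        assert d_at_rh == pytest.approx(cross, abs=1e-7)
        assert d_at_lh == pytest.approx(-cross, abs=1e-7)
        # swapping the references negates the CV
        assert delta_rmsd(m_rh, m_rh, m_lh, sel) == pytest.approx(-d_at_rh,
                                                                  abs=1e-12)

    def test_rigid_motion_of_probe_model(self, rh_minus, lh_minus, rh_plus):
        sel = AtomSelector(atom_names={"C1'"})
        m = rh_plus.models[0]
        R = Rotation.from_euler("xyz", [5, 15, 25], degrees=True).as_matrix()
        moved = m.with_coords(m.coords @ R.T + 7.0)
        a = delta_rmsd(m, lh_minus.models[0], rh_minus.models[0], sel)
        b = delta_rmsd(moved, lh_minus.models[0], rh_minus.models[0], sel)
        assert a == pytest.approx(b, abs=1e-9)


class TestLoopSpan:
    def test_identical_builds_have_identical_spans(self, rh_minus,
                                                   rh_minus_topology):
        s1 = loop_span(rh_minus, rh_minus_topology, 0)
        s2 = loop_span(rh_minus, rh_minus_topology, 1)
        assert s1 == pytest.approx(s2, abs=1e-6)   # C4 symmetry

    def test_minus_progression_lh_longer_than_rh(self, rh_minus, lh_minus,
                                                 rh_minus_topology):
        t_lh = analyze_topology(lh_minus)
        assert (loop_span(lh_minus, t_lh, 0)
                > loop_span(rh_minus, rh_minus_topology, 0))

    def test_plus_progression_lh_shorter_than_rh(self, rh_plus, lh_plus,
                                                 lh_plus_topology):
        t_rh = analyze_topology(rh_plus)
        assert (loop_span(lh_plus, lh_plus_topology, 0)
                < loop_span(rh_plus, t_rh, 0))

    def test_missing_attachment_raises(self, rh_minus, rh_minus_topology):
        stripped = Structure([Model([a for a in rh_minus.models[0].atoms
                                     if a.name != "P"])])
        with pytest.raises(ValueError, match="attachment"):
            loop_span(stripped, rh_minus_topology, 0)


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        m = Model([_dummy("C1", [0, 0, 0], elem="C")])
        sasa = shrake_rupley_sasa(m)[("A", 1)]
        exact = 4 * np.pi * (1.7 + 1.4) ** 2 / 100.0
        assert sasa == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_is_zero(self):
        atoms = [_dummy("C1", [0, 0, 0], elem="C")]
        # tight icosahedral-ish shell of large atoms
        from g4kit.cv import _golden_spiral
        for k, v in enumerate(_golden_spiral(40), start=2):
            atoms.append(_dummy("P", 2.2 * v, elem="P", res=k, serial=k))
        m = Model(atoms)
        sasa = shrake_rupley_sasa(m, AtomSelector(residue_indices={1}))
        assert sasa[("A", 1)] == 0.0

    def test_distant_atoms_are_additive(self):
        m1 = Model([_dummy("C1", [0, 0, 0], elem="C")])
        m2 = Model([_dummy("O1", [0, 0, 0], elem="O")])
        both = Model([_dummy("C1", [0, 0, 0], elem="C"),
                      _dummy("O1", [100.0, 0, 0], elem="O", res=2, serial=2)])
        total = sum(shrake_rupley_sasa(both).values())
        solo = (shrake_rupley_sasa(m1)[("A", 1)]
                + shrake_rupley_sasa(m2)[("A", 1)])
        assert total == pytest.approx(solo, rel=1e-12)

    def test_unknown_element_rejected(self):
        m = Model([_dummy("XX", [0, 0, 0], elem="Zn")])
        with pytest.raises(ValueError, match="Zn"):
            shrake_rupley_sasa(m)

    @settings(deadline=None, max_examples=5, derandomize=True)
    @given(st.integers(0, 1000))
    def test_against_monte_carlo_oracle(self, seed):
        """Golden-spiral SASA agrees with a 1e5-point Monte-Carlo estimate
        on random 5-atom clusters within 2%."""
        rng = np.random.default_rng(seed)
        elems = ["C", "N", "O", "P", "C"]
        coords = rng.uniform(-2.0, 2.0, size=(5, 3))
        m = Model([_dummy(f"A{i}", coords[i], elem=e, res=i + 1, serial=i + 1)
                   for i, e in enumerate(elems)])
        total = sum(shrake_rupley_sasa(m).values())
        from g4kit.cv import BONDI_RADII_A
        rads = np.array([BONDI_RADII_A[e] + 1.4 for e in elems])
        mc_total = 0.0
        mc_rng = np.random.default_rng(seed + 77)
        for i in range(5):
            pts = mc_rng.normal(size=(100_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + rads[i] * pts
            others = [j for j in range(5) if j != i]
            d2 = np.sum((pts[:, None, :] - coords[others][None]) ** 2, axis=2)
            acc = ~np.any(d2 < rads[others] ** 2, axis=1)
            mc_total += acc.mean() * 4 * np.pi * rads[i] ** 2 / 100.0
        assert total == pytest.approx(mc_total, rel=0.02)


class TestClassifySE:
    @pytest.mark.parametrize("sasa,expected", [
        (1.00, "S"), (1.63, "E"), (3.00, "E"), (1.6299, "S")])
    def test_boundary(self, sasa, expected):
        assert classify_SE(sasa) == expected


class TestHbondOccupancy:
    def _traj_with_bond_pattern(self, pattern):
        """Frames with a donor/acceptor pair bonded (True) or separated."""
        models = []
        for bonded in pattern:
            d = 2.9 if bonded else 6.0
            atoms = [
                _dummy("N1", [0, 0, 0], elem="N"),
                _dummy("H1", [1.01, 0, 0], elem="H"),
                _dummy("C2", [-0.7, 1.1, 0], elem="C"),
                _dummy("C6", [-0.7, -1.1, 0], elem="C"),
                _dummy("O6", [d, 0, 0], elem="O", res=2, serial=5),
            ]
            models.append(Model(atoms))
        st_ = Structure(models)
        return Trajectory(st_, np.arange(len(pattern), dtype=float))

    def _spec(self):
        return HBondSpec(donor=AtomSelector(atom_names={"N1"}),
                         acceptor=AtomSelector(atom_names={"O6"}))

    def test_always_bonded_all_S(self):
        traj = self._traj_with_bond_pattern([True] * 5)
        states = StateSeries(traj.times, np.array(["S"] * 5))
        stats = hbond_occupancy(traj, self._spec(), states)
        assert (stats.p_total, stats.p_S_fraction, stats.p_E_fraction) == \
            (1.0, 1.0, 0.0)

    def test_bond_only_in_E_frames(self):
        pattern = [False, True, False, True, False,
                   False, False, False, False, False]
        labels = np.array(["E" if b else "S" for b in pattern])
        traj = self._traj_with_bond_pattern(pattern)
        stats = hbond_occupancy(traj, self._spec(),
                                StateSeries(traj.times, labels))
        assert stats.p_total == pytest.approx(0.2)
        assert stats.p_E_fraction == pytest.approx(0.2)
        assert stats.p_S_fraction == 0.0

    def test_no_matching_frames(self):
        traj = self._traj_with_bond_pattern([False] * 4)
        states = StateSeries(traj.times, np.array(["S", "S", "E", "E"]))
        stats = hbond_occupancy(traj, self._spec(), states)
        assert (stats.p_total, stats.p_S_fraction, stats.p_E_fraction) == \
            (0.0, 0.0, 0.0)

    def test_fractions_sum_exactly(self):
        rng = np.random.default_rng(9)
        pattern = list(rng.random(50) < 0.5)
        labels = np.array(["S" if v < 0.6 else "E" for v in rng.random(50)])
        traj = self._traj_with_bond_pattern(pattern)
        stats = hbond_occupancy(traj, self._spec(),
                                StateSeries(traj.times, labels))
        assert stats.p_S_fraction + stats.p_E_fraction == stats.p_total

    def test_misaligned_states_rejected(self):
        traj = self._traj_with_bond_pattern([True] * 4)
        with pytest.raises(ValueError, match="aligned"):
            hbond_occupancy(traj, self._spec(),
                            StateSeries(np.arange(3.0), np.array(["S"] * 3)))


class TestQmFragments:
    @pytest.fixture(scope="class")
    def dinucleotide(self, rh_minus):
        m = rh_minus.models[0]
        return Model([a for a in m.atoms if a.chain_id == "A"])

    def test_heavy_atom_partition_is_exact(self, dinucleotide):
        fs = extract_qm_fragments(dinucleotide)
        parent = {a.key for a in dinucleotide.atoms if a.element != "H"}
        back = {a.key for a in fs.backbone_fragment.atoms
                if a.element != "H" or a.name != "Hcap"}
        stack = {a.key for a in fs.base_stack_fragment.atoms
                 if a.element != "H" or a.name != "Hcap"}
        back = {k for k in back if not k[2].startswith("H")}
        stack = {k for k in stack if not k[2].startswith("H")}
        assert back | stack == parent
        assert back & stack == set()

    def test_cap_bond_lengths(self, dinucleotide):
        fs = extract_qm_fragments(dinucleotide)
        for key, frag, ref_name, length in [
                ("backbone", fs.backbone_fragment, "C1'", 1.09),
                ("bases", fs.base_stack_fragment, "N9", 1.01)]:
            caps = [a for a in frag.atoms if a.name == "Hcap"]
            assert len(caps) == 2
            for cap in caps:
                ref = frag.atom(cap.chain_id, cap.residue_index, ref_name)
                assert np.linalg.norm(cap.xyz - ref.xyz) == pytest.approx(
                    length, abs=1e-9)

    def test_non_cap_coordinates_unmoved(self, dinucleotide):
        fs = extract_qm_fragments(dinucleotide)
        for frag in (fs.backbone_fragment, fs.base_stack_fragment):
            for a in frag.atoms:
                if a.name == "Hcap":
                    continue
                orig = dinucleotide.atom(a.chain_id, a.residue_index, a.name)
                assert np.array_equal(a.xyz, orig.xyz)

    def test_wrong_input_rejected(self, rh_minus):
        with pytest.raises(ValueError):
            extract_qm_fragments(rh_minus.models[0])   # eight residues
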