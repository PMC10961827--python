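"""Collective variables and per-frame classifiers for G-quadruplexes.

Implements the folding CV (radius of gyration of the channel-lining O6
atoms, boundary 0.37 nm), the helicity-transition CV (difference of
RMSDs to left- and right-handed reference conformations after
independent Kabsch superposition), loop attachment spans, deterministic
Shrake-Rupley solvent-accessible surface areas with the stacked/exposed
(S/E) thymine classifier at 1.63 nm^2, state-decomposed hydrogen-bond
occupancies, and the backbone/base-stack fragment preparation for
external quantum-chemistry single points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AtomRecord, Model, Structure, Trajectory, AtomSelector
from .kinetics import StateSeries
from .topology import G4Topology, HBondGeomCriteria, detect_hbonds

__all__ = [
    "channel_rog",
    "classify_folded",
    "superpose",
    "delta_rmsd",
    "loop_span",
    "shrake_rupley_sasa",
    "classify_SE",
    "HBondSpec",
    "HBondStats",
    "hbond_occupancy",
    "FragmentSet",
    "extract_qm_fragments",
    "ROG_BOUNDARY_NM",
    "SASA_SE_BOUNDARY_NM2",
]

#: folded/unfolded boundary on the channel RoG, nm
ROG_BOUNDARY_NM = 0.37
#: stacked/exposed boundary on the 3'-thymine SASA, nm^2
SASA_SE_BOUNDARY_NM2 = 1.63

#: Bondi van der Waals radii, Angstrom
BONDI_RADII_A = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
                 "S": 1.80}


# ---------------------------------------------------------------------------
# channel radius of gyration

def channel_rog(model: Model, topology: G4Topology | None = None,
                atom_indices: list[int] | None = None) -> float:
    """Mass-unweighted RoG of the G4 central-channel atoms, nm.

    The channel atoms are the O6 of all tetrad guanines of ``topology``;
    an explicit ``atom_indices`` list overrides that choice.
    """
    if atom_indices is not None:
        pts = model.coords[atom_indices]
    else:
        if topology is None or not topology.tetrads:
            raise ValueError("need a topology with tetrads or explicit atoms")
        residues = {r for t in topology.tetrads for r in t.residues}
        pts = np.array([a.xyz for a in model.atoms
                        if (a.chain_id, a.residue_index) in residues
                        and a.name == "O6"])
    if len(pts) == 0:
        raise ValueError("no channel atoms found")
    c = pts.mean(axis=0)
    rog_A = np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1)))
    return float(rog_A) / 10.0


def classify_folded(rog_nm: float, boundary_nm: float = ROG_BOUNDARY_NM) -> str:
    """F iff rog < boundary (strict), else U."""
    if not np.isfinite(rog_nm):
        raise ValueError("RoG must be finite")
    return "F" if rog_nm < boundary_nm else "U"


# ---------------------------------------------------------------------------
# superposition and delta-RMSD

def superpose(X: np.ndarray, Y: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper-rotation superposition of Y onto X (Kabsch).

    Returns (R, t, rmsd_A) with the aligned coordinates Y @ R.T + t.
    Mirror images of chiral sets keep a positive residual because
    improper rotations are excluded.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(X - xc, Y - yc)
    R = rot.as_matrix()
    t = xc - yc @ R.T
    rmsd = rssd / np.sqrt(n)
    return R, t, float(rmsd)


def rmsd_after_superposition(X: np.ndarray, Y: np.ndarray) -> float:
    return superpose(X, Y)[2]


def _selected_coords(model: Model, selector: AtomSelector | None) -> np.ndarray:
    if selector is None:
        return np.array([a.xyz for a in model.atoms if a.element != "H"])
    pts = [a.xyz for a in model.atoms if selector.matches(a)]
    if not pts:
        raise ValueError("selection matched no atoms")
    return np.array(pts)


def delta_rmsd(model: Model, ref_LH: Model, ref_RH: Model,
               selection: AtomSelector | None = None) -> float:
    """RMSD(model, ref_LH) - RMSD(model, ref_RH) in nm, each after an
    independent optimal superposition on the same atom selection
    (heavy atoms when no selector is given).

    Negative values are LH-like, positive values RH-like.
    """
    x = _selected_coords(model, selection)
    xl = _selected_coords(ref_LH, selection)
    xr = _selected_coords(ref_RH, selection)
    if not (x.shape == xl.shape == xr.shape):
        raise ValueError("selection resolves differently on the three models")
    return (rmsd_after_superposition(xl, x)
            - rmsd_after_superposition(xr, x)) / 10.0


# ---------------------------------------------------------------------------
# loop spans

def loop_span(structure: Structure, topology: G4Topology, tract_index: int,
              model_index: int = 0, attachment: str = "O3P") -> float:
    """Distance (A) between the loop attachment points bracketing loop
    ``tract_index``: O3' of the 3'-terminal guanine of tract i and P of
    the 5'-terminal guanine of tract i+1 (``attachment="C1"`` switches
    both to C1')."""
    if not (0 <= tract_index < len(topology.tracts) - 1):
        raise ValueError("tract_index out of range")
    model = structure.models[model_index]
    ch1, r1 = topology.tracts[tract_index][-1]
    ch2, r2 = topology.tracts[tract_index + 1][0]
    n1, n2 = ("O3'", "P") if attachment == "O3P" else ("C1'", "C1'")
    try:
        a = model.atom(ch1, r1, n1)
        b = model.atom(ch2, r2, n2)
    except KeyError as e:
        raise ValueError(f"missing attachment atom: {e}")
    return float(np.linalg.norm(a.xyz - b.xyz))


# ---------------------------------------------------------------------------
# solvent-accessible surface area

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley_sasa(model: Model,
                       residues: AtomSelector | None = None,
                       probe_A: float = 1.4, n_points: int = 960,
                       radii: dict[str, float] | None = None
                       ) -> dict[tuple[str, int], float]:
    """Shrake-Rupley SASA per residue, nm^2.

    Every atom of the model occludes; ``residues`` only restricts which
    residues are reported. Sphere points come from a deterministic golden
    spiral so results are bit-for-bit reproducible.
    """
    radii = radii or BONDI_RADII_A
    unknown = {a.element for a in model.atoms} - set(radii)
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s) {unknown}")
    coords = model.coords
    rads = np.array([radii[a.element] + probe_A for a in model.atoms])
    sphere = _golden_spiral(n_points)
    out: dict[tuple[str, int], float] = {}
    n_atoms = len(model.atoms)
    for i, atom in enumerate(model.atoms):
        key = (atom.chain_id, atom.residue_index)
        if residues is not None and not residues.matches(atom):
            continue
        pts = coords[i] + rads[i] * sphere
        d = np.linalg.norm(coords[i] - coords, axis=1)
        nb = np.flatnonzero((d < rads[i] + rads) & (np.arange(n_atoms) != i))
        if nb.size:
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < rads[nb][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area_A2 = frac * 4.0 * np.pi * rads[i] ** 2
        out[key] = out.get(key, 0.0) + area_A2 / 100.0
    return out


def classify_SE(sasa_nm2: float,
                boundary_nm2: float = SASA_SE_BOUNDARY_NM2) -> str:
    """S (stacked) iff sasa < boundary (strict), else E (exposed)."""
    if not np.isfinite(sasa_nm2):
        raise ValueError("SASA must be finite")
    return "S" if sasa_nm2 < boundary_nm2 else "E"


# ---------------------------------------------------------------------------
# hydrogen-bond occupancy

@dataclass
class HBondSpec:
    """A specific donor->acceptor hydrogen-bond class, e.g. N2 of the
    3'-tetrad guanines to the loop 3'-phosphate oxygens."""

    donor: AtomSelector
    acceptor: AtomSelector
    criteria: HBondGeomCriteria = field(default_factory=HBondGeomCriteria)


@dataclass
class HBondStats:
    p_total: float
    p_S_fraction: float
    p_E_fraction: float
    n_frames: int


def hbond_occupancy(traj: Trajectory, spec: HBondSpec,
                    states: StateSeries | None = None) -> HBondStats:
    """Fraction of frames with >=1 bond matching ``spec``; when a state
    series is given, the total probability is decomposed exactly into the
    fractions contributed by S and E frames."""
    n = traj.n_frames
    if states is not None and len(states) != n:
        raise ValueError("state series not aligned with trajectory frames")
    bonded = np.zeros(n, dtype=bool)
    for k, model in enumerate(traj.structure.models):
        for b in detect_hbonds(model, spec.criteria):
            if spec.donor.matches(model.atoms[b.donor_index]) and \
               spec.acceptor.matches(model.atoms[b.acceptor_index]):
                bonded[k] = True
                break
    if states is None:
        return HBondStats(float(bonded.mean()), float("nan"), float("nan"), n)
    s_mask = np.asarray(states.labels) == "S"
    p_s = float(np.mean(bonded & s_mask))
    p_e = float(np.mean(bonded & ~s_mask))
    # total defined as the sum so the S/E decomposition is exact by
    # construction (it equals the frame fraction up to fp rounding)
    return HBondStats(p_s + p_e, p_s, p_e, n)


# ---------------------------------------------------------------------------
# QM fragment preparation

GUANINE_BASE_ATOMS = {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2",
                      "N3", "C4", "H8", "H1", "H21", "H22"}


@dataclass
class FragmentSet:
    backbone_fragment: Model
    base_stack_fragment: Model
    cap_report: list   # (description, capped atom key, bond length A)


def _cap_atom(serial: int, pos: np.ndarray, res: AtomRecord) -> AtomRecord:
    return AtomRecord(serial, "Hcap", "H", res.residue_name,
                      res.residue_index, res.chain_id, pos)


def extract_qm_fragments(dinucleotide: Model) -> FragmentSet:
    """Split a stacked guanine dinucleotide into a sugar-phosphate
    backbone fragment and a guanine base-stack fragment.

    The severed glycosidic C1'-N9 bonds are capped with hydrogens: on the
    backbone side along C1'->N9 at 1.09 A (C-H), on the base side along
    N9->C1' at 1.01 A (N-H). Heavy atoms partition exactly; original
    coordinates are untouched. Fragments are meant to be written with
    write_xyz for external QM engines.
    """
    res_keys = sorted({(a.chain_id, a.residue_index)
                       for a in dinucleotide.atoms})
    if len(res_keys) != 2 or any(a.residue_name != "DG"
                                 for a in dinucleotide.atoms):
        raise ValueError("expected exactly two guanosine nucleotides")
    backbone, bases, caps = [], [], []
    serial_b = serial_s = 1000
    for a in dinucleotide.atoms:
        if a.name in GUANINE_BASE_ATOMS:
            bases.append(a)
        else:
            backbone.append(a)
    for key in res_keys:
        try:
            c1 = dinucleotide.atom(key[0], key[1], "C1'")
            n9 = dinucleotide.atom(key[0], key[1], "N9")
        except KeyError:
            raise ValueError(f"residue {key} lacks C1' or N9")
        u = (n9.xyz - c1.xyz) / np.linalg.norm(n9.xyz - c1.xyz)
        serial_b += 1
        backbone.append(_cap_atom(serial_b, c1.xyz + 1.09 * u, c1))
        caps.append(("C1'-N9 backbone cap", c1.key, 1.09))
        serial_s += 1
        bases.append(_cap_atom(serial_s, n9.xyz - 1.01 * u, n9))
        caps.append(("N9-C1' base cap", n9.key, 1.01))
    return FragmentSet(Model(backbone), Model(bases), caps)
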