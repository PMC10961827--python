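"""G-quadruplex fold analysis.

Detects Hoogsteen-bonded G-tetrads and classifies the fold: glycosidic
conformation (syn/anti), tetrad polarity, signed inter-tetrad twist,
helicity (LH/RH) and strand-progression direction (+/-).

Conventions
-----------
* The stack axis points from the 5'-side tetrad to the 3'-side tetrad.
* Twist is positive for a right-handed screw about that axis.
* Helicity is RH for twist > +5 deg, LH for < -5 deg, else indeterminate
  (dead zone configurable).
* Strand progression: tract azimuths are measured in a right-handed frame
  (e1, e2, axis); progression is "+" (clockwise viewed from the 5' side)
  when the azimuth decreases by ~90 deg from tract i to tract i+1, "-"
  when it increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Model, Structure

__all__ = [
    "HBondGeomCriteria",
    "HBond",
    "TetradAssignment",
    "G4Topology",
    "detect_hbonds",
    "detect_tetrads",
    "glycosidic_chi",
    "classify_glyco",
    "fit_plane",
    "stack_axis",
    "twist_angle",
    "classify_helicity",
    "strand_progression",
    "tetrad_polarity",
    "analyze_topology",
]

GUANINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]

# donor heavy atom -> (attached hydrogens, bonded heavy neighbors, ring
# atoms defining the sp2 plane for inferred-H placement)
_DONORS = {
    "DG": {"N1": (["H1"], ["C2", "C6"], []),
           "N2": (["H21", "H22"], ["C2"], ["N1", "N3"])},
    "DT": {"N3": (["H3"], ["C2", "C4"], [])},
    "DA": {"N6": (["H61", "H62"], ["C6"], ["N1", "C5"])},
    "DC": {"N4": (["H41", "H42"], ["C4"], ["N3", "C5"])},
}
_ACCEPTORS = {
    "DG": ["O6", "N7", "N3", "O4'", "O3'", "O5'", "OP1", "OP2"],
    "DT": ["O2", "O4", "O4'", "O3'", "O5'", "OP1", "OP2"],
    "DA": ["N7", "N1", "N3", "O4'", "O3'", "O5'", "OP1", "OP2"],
    "DC": ["O2", "N3", "O4'", "O3'", "O5'", "OP1", "OP2"],
}


@dataclass
class HBondGeomCriteria:
    """Geometric hydrogen-bond criteria (donor-acceptor distance, D-H-A angle)."""

    max_DA_A: float = 3.5
    min_DHA_deg: float = 135.0

    def __post_init__(self):
        if not (2.5 < self.max_DA_A < 4.5):
            raise ValueError("max_DA_A must lie in (2.5, 4.5) A")
        if not (90.0 < self.min_DHA_deg <= 180.0):
            raise ValueError("min_DHA_deg must lie in (90, 180]")


@dataclass(frozen=True)
class HBond:
    donor_index: int           # atom index of donor heavy atom
    hydrogen_index: int | None  # atom index of H, or None if inferred
    acceptor_index: int
    distance_A: float
    angle_deg: float


@dataclass
class TetradAssignment:
    """A detected G-tetrad: four guanines in cyclic Hoogsteen donor order."""

    residues: list          # 4 (chain_id, residue_index) in donor order
    centroid: np.ndarray    # A
    normal: np.ndarray      # unit
    polarity: int = 0       # +1 / -1, set once an axis is known
    planarity_A: float = 0.0

    def residue_set(self) -> frozenset:
        return frozenset(self.residues)


@dataclass
class G4Topology:
    tetrads: list            # TetradAssignment, ordered 5'-side -> 3'-side
    tracts: list             # list of lists of (chain, idx)
    loops: list              # list of lists of (chain, idx)
    axis: np.ndarray         # unit, 5' -> 3'
    mean_twist_deg: float
    twist_per_step_deg: list
    helicity: str            # "LH" / "RH" / "indeterminate"
    progression: str         # "+" / "-" / "indeterminate"
    chi_classes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tetrads": len(self.tetrads),
            "tetrads": [{"residues": [list(r) for r in t.residues],
                         "polarity": t.polarity,
                         "planarity_A": round(t.planarity_A, 4)}
                        for t in self.tetrads],
            "tracts": [[list(r) for r in t] for t in self.tracts],
            "loops": [[list(r) for r in l] for l in self.loops],
            "axis": [round(v, 6) for v in self.axis],
            "mean_twist_deg": round(self.mean_twist_deg, 3),
            "twist_per_step_deg": [round(v, 3) for v in self.twist_per_step_deg],
            "helicity": self.helicity,
            "progression": self.progression,
            "chi_classes": {f"{c}:{i}": v for (c, i), v in self.chi_classes.items()},
        }


# ---------------------------------------------------------------------------
# elementary geometry

def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through >=3 points.

    Returns (centroid, unit normal, RMS out-of-plane residual in A).
    The normal sign is arbitrary here; callers orient it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-10:
        raise ValueError("collinear points: plane is degenerate")
    normal = vt[2]
    residual = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    return centroid, normal, residual


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def _angle_deg(a, b, c) -> float:
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# hydrogen bonds

def _residue_atom_map(model: Model) -> dict:
    res: dict = {}
    for i, a in enumerate(model.atoms):
        res.setdefault((a.chain_id, a.residue_index), {})[a.name] = i
    return res


def _inferred_h_positions(model: Model, donor_i: int, neighbor_names,
                          plane_names, res_atoms: dict) -> list[np.ndarray]:
    """Idealized H position(s) for a donor lacking explicit hydrogens.

    Ring N-H: the direction opposite the mean of the two bonded ring
    neighbors (sp2 bisector). Amino -NH2: two in-plane candidates at
    +/-60 deg from the extended C-N bond, the plane being the aromatic
    ring plane spanned by the listed reference atoms.
    """
    donor = model.atoms[donor_i]
    ra = res_atoms.get((donor.chain_id, donor.residue_index), {})
    dpos = donor.xyz
    npos = [model.atoms[ra[nm]].xyz for nm in neighbor_names if nm in ra]
    if not npos:
        return []
    if len(npos) >= 2:
        d = dpos - np.mean(npos, axis=0)
        d /= np.linalg.norm(d)
        return [dpos + 1.01 * d]
    # single neighbor (amino group): two sp2 H in the ring plane
    u = dpos - npos[0]
    u /= np.linalg.norm(u)
    refs = [model.atoms[ra[nm]].xyz for nm in plane_names if nm in ra]
    if not refs:
        return [dpos + 1.01 * u]
    v = refs[0] - npos[0]
    n = np.cross(u, v)
    if np.linalg.norm(n) < 1e-6 and len(refs) > 1:
        n = np.cross(u, refs[1] - npos[0])
    n /= np.linalg.norm(n)
    w = np.cross(n, u)
    out = []
    for sgn in (+1.0, -1.0):
        d = np.cos(np.radians(60.0)) * u + sgn * np.sin(np.radians(60.0)) * w
        out.append(dpos + 1.01 * d)
    return out


def detect_hbonds(model: Model,
                  criteria: HBondGeomCriteria | None = None) -> list[HBond]:
    """All inter-residue hydrogen bonds meeting the geometric criteria.

    Donors/acceptors come from a fixed table for standard deoxynucleotides.
    When explicit hydrogens are present they are used; otherwise an
    idealized H is placed along the donor's expected bond direction.
    """
    criteria = criteria or HBondGeomCriteria()
    res_atoms = _residue_atom_map(model)
    donors = []   # (donor_i, [h_positions], [h_indices])
    acceptors = []
    for i, a in enumerate(model.atoms):
        dtab = _DONORS.get(a.residue_name, {})
        if a.name in dtab:
            h_names, nb_names, plane_names = dtab[a.name]
            ra = res_atoms[(a.chain_id, a.residue_index)]
            h_idx = [ra[h] for h in h_names if h in ra]
            if h_idx:
                donors.append((i, [model.atoms[j].xyz for j in h_idx], h_idx))
            else:
                donors.append((i, _inferred_h_positions(
                    model, i, nb_names, plane_names, res_atoms), None))
        if a.name in _ACCEPTORS.get(a.residue_name, []):
            acceptors.append(i)

    bonds = []
    for (di, hpos, hidx) in donors:
        d = model.atoms[di]
        for ai in acceptors:
            acc = model.atoms[ai]
            if (d.chain_id, d.residue_index) == (acc.chain_id, acc.residue_index):
                continue
            dist = float(np.linalg.norm(d.xyz - acc.xyz))
            if dist > criteria.max_DA_A:
                continue
            best_ang, best_h = -1.0, None
            for k, hp in enumerate(hpos):
                ang = _angle_deg(d.xyz, hp, acc.xyz)
                if ang > best_ang:
                    best_ang, best_h = ang, (hidx[k] if hidx else None)
            if best_ang >= criteria.min_DHA_deg:
                bonds.append(HBond(di, best_h, ai, dist, best_ang))
    bonds.sort(key=lambda b: (b.donor_index, b.acceptor_index))
    return bonds


# ---------------------------------------------------------------------------
# tetrads

def detect_tetrads(model: Model,
                   criteria: HBondGeomCriteria | None = None,
                   require_both_bonds: bool = True,
                   max_planarity_A: float = 0.5) -> list[TetradAssignment]:
    """Detect G-tetrads as directed Hoogsteen 4-cycles of guanines.

    Edge i->j exists iff N1(i)->O6(j) and N2(i)->N7(j) hydrogen bonds are
    both present (``require_both_bonds=False`` relaxes to either bond).
    Cycles must pass an RMS planarity check on the guanine ring atoms.
    """
    bonds = detect_hbonds(model, criteria)
    res_atoms = _residue_atom_map(model)
    # per ordered guanine pair, which Hoogsteen bonds are present
    pair_bonds: dict = {}
    for b in bonds:
        d = model.atoms[b.donor_index]
        a = model.atoms[b.acceptor_index]
        if d.residue_name != "DG" or a.residue_name != "DG":
            continue
        key = ((d.chain_id, d.residue_index), (a.chain_id, a.residue_index))
        if d.name == "N1" and a.name == "O6":
            pair_bonds.setdefault(key, set()).add("N1O6")
        elif d.name == "N2" and a.name == "N7":
            pair_bonds.setdefault(key, set()).add("N2N7")
    need = {"N1O6", "N2N7"}
    edges = {k for k, v in pair_bonds.items()
             if (v >= need if require_both_bonds else v)}
    adj: dict = {}
    for (i, j) in edges:
        adj.setdefault(i, []).append(j)

    tetrads, seen = [], set()
    for a in sorted(adj):
        for b in adj.get(a, []):
            for c in adj.get(b, []):
                if c == a:
                    continue
                for d in adj.get(c, []):
                    if d in (a, b):
                        continue
                    if a in adj.get(d, []):
                        key = frozenset((a, b, c, d))
                        if key in seen:
                            continue
                        cyc = [a, b, c, d]
                        k0 = cyc.index(min(cyc))
                        cyc = cyc[k0:] + cyc[:k0]
                        ring_pts = []
                        for r in cyc:
                            ra = res_atoms[r]
                            ring_pts.extend(model.atoms[ra[nm]].xyz
                                            for nm in GUANINE_RING if nm in ra)
                        centroid, normal, resid = fit_plane(np.array(ring_pts))
                        if resid > max_planarity_A:
                            continue
                        seen.add(key)
                        tetrads.append(TetradAssignment(
                            residues=cyc, centroid=centroid, normal=normal,
                            planarity_A=resid))
    tetrads.sort(key=lambda t: t.residues[0])
    return tetrads


# ---------------------------------------------------------------------------
# glycosidic angle

def glycosidic_chi(model: Model, chain_id: str, residue_index: int) -> float:
    """Glycosidic torsion chi = O4'-C1'-N9-C4 (purines), degrees."""
    ra = _residue_atom_map(model).get((chain_id, residue_index))
    if ra is None:
        raise KeyError(f"no residue {chain_id}:{residue_index}")
    try:
        pts = [model.atoms[ra[n]].xyz for n in ("O4'", "C1'", "N9", "C4")]
    except KeyError as e:
        raise ValueError(f"residue {chain_id}:{residue_index} missing atom {e}")
    return dihedral(*pts)


def classify_glyco(chi_deg: float) -> str:
    """syn for chi in (-90, 90], anti otherwise."""
    return "syn" if -90.0 < chi_deg <= 90.0 else "anti"


# ---------------------------------------------------------------------------
# axis, twist, labels

def stack_axis(tetrads: list[TetradAssignment]) -> np.ndarray:
    """Unit stack axis from tetrad centroids, oriented first -> last.

    For two tetrads this is the normalized centroid difference; for more,
    the first principal direction of the centroids.
    """
    if len(tetrads) < 2:
        raise ValueError("need at least 2 tetrads")
    cents = np.array([t.centroid for t in tetrads])
    if len(tetrads) == 2:
        v = cents[1] - cents[0]
    else:
        c0 = cents.mean(axis=0)
        _, _, vt = np.linalg.svd(cents - c0)
        v = vt[0]
        if v @ (cents[-1] - cents[0]) < 0:
            v = -v
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("coincident tetrad centroids")
    return v / n


def _strand_pairs(t_low: TetradAssignment, t_high: TetradAssignment):
    """Match each guanine of t_high to its same-tract guanine in t_low.

    Same tract = same chain and sequence-adjacent residue indices, with a
    consistent direction across all four strands.
    """
    for step in (+1, -1):
        pairs = []
        for (ch, ri) in t_low.residues:
            target = (ch, ri + step)
            if target in t_high.residues:
                pairs.append(((ch, ri), target))
        if len(pairs) == 4:
            return pairs
    raise ValueError("unresolvable strand correspondence between tetrads")


def twist_angle(model: Model, t_low: TetradAssignment,
                t_high: TetradAssignment, axis: np.ndarray) -> float:
    """Signed inter-tetrad twist, degrees.

    For each pair of adjacent strands the C1'(s)->C1'(next s) edge vector
    is projected perpendicular to the axis in both tetrads and the signed
    angle between the two projections is taken; the result is the circular
    mean over the four strand pairs. Positive = right-handed screw about
    the 5'->3' axis.
    """
    sep = np.linalg.norm(t_high.centroid - t_low.centroid)
    if sep > 6.0:
        raise ValueError(f"tetrads not stacked (centroid separation {sep:.1f} A)")
    res_atoms = _residue_atom_map(model)
    pairs = _strand_pairs(t_low, t_high)
    low_of = dict(pairs)  # low residue -> high residue
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    def c1(res):
        return model.atoms[res_atoms[res]["C1'"]].xyz

    def perp(v):
        return v - (v @ axis) * axis

    angles = []
    lows = [p[0] for p in pairs]
    order = t_low.residues  # cyclic donor order of the low tetrad
    for k in range(4):
        s, s_next = order[k], order[(k + 1) % 4]
        if s not in low_of or s_next not in low_of:
            raise ValueError("strand pairing incomplete")
        v_low = perp(c1(s_next) - c1(s))
        v_high = perp(c1(low_of[s_next]) - c1(low_of[s]))
        ang = np.arctan2(axis @ np.cross(v_low, v_high), v_low @ v_high)
        angles.append(ang)
    mean = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    return float(np.degrees(mean))


def classify_helicity(mean_twist_deg: float, dead_zone_deg: float = 5.0) -> str:
    if not np.isfinite(mean_twist_deg):
        raise ValueError("twist must be finite")
    if mean_twist_deg > dead_zone_deg:
        return "RH"
    if mean_twist_deg < -dead_zone_deg:
        return "LH"
    return "indeterminate"


def _orthonormal_frame(axis: np.ndarray):
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def strand_progression(model: Model, tracts: list, axis: np.ndarray,
                       origin: np.ndarray) -> str:
    """Direction of strand progression: "+" (clockwise from the 5' side),
    "-" (anti-clockwise), or "indeterminate".

    Tract azimuths are measured in a right-handed frame (e1, e2, axis);
    "+" corresponds to an azimuth decrement of ~90 deg per tract.
    """
    if len(tracts) != 4:
        raise ValueError("need exactly 4 tracts")
    res_atoms = _residue_atom_map(model)
    e1, e2 = _orthonormal_frame(axis)
    phis = []
    for tract in tracts:
        pts = [model.atoms[res_atoms[r]["C1'"]].xyz for r in tract]
        c = np.mean(pts, axis=0) - origin
        phis.append(np.degrees(np.arctan2(c @ e2, c @ e1)))
    diffs = [(phis[(i + 1) % 4] - phis[i]) % 360.0 for i in range(3)]
    if all(abs(d - 270.0) <= 45.0 for d in diffs):
        return "+"     # azimuth decrements by ~90 deg
    if all(abs(d - 90.0) <= 45.0 for d in diffs):
        return "-"
    return "indeterminate"


def tetrad_polarity(model: Model, tetrad: TetradAssignment,
                    axis: np.ndarray) -> int:
    """+1 if the Hoogsteen donor cycle circulates counterclockwise about
    ``axis`` (right-hand rule), -1 otherwise."""
    res_atoms = _residue_atom_map(model)
    pts = []
    for r in tetrad.residues:
        ra = res_atoms[r]
        ring = [model.atoms[ra[nm]].xyz for nm in GUANINE_RING if nm in ra]
        pts.append(np.mean(ring, axis=0))
    pts = np.array(pts) - tetrad.centroid
    circ = np.zeros(3)
    for i in range(4):
        circ += np.cross(pts[i], pts[(i + 1) % 4])
    s = float(np.asarray(axis) @ circ)
    if abs(s) < 1e-12:
        raise ValueError("degenerate tetrad geometry: polarity undefined")
    return 1 if s > 0 else -1


def donor_cycle_tract_circulation(tetrad: TetradAssignment, tracts: list) -> int:
    """+1 if the donor cycle visits tracts in ascending sequence order,
    -1 if descending.

    This sequence-order circulation (donor cycle vs tract order) is the
    quantity that flips when strand progression is reversed at fixed
    helicity; the geometric polarity about the 5'->3' axis does not.
    """
    tract_of = {}
    for ti, tract in enumerate(tracts):
        for r in tract:
            tract_of[r] = ti
    order = [tract_of[r] for r in tetrad.residues if r in tract_of]
    if len(order) != 4:
        raise ValueError("tetrad residues not all assigned to tracts")
    up = sum(1 for i in range(4) if (order[(i + 1) % 4] - order[i]) % 4 == 1)
    down = sum(1 for i in range(4) if (order[i] - order[(i + 1) % 4]) % 4 == 1)
    if up == 4:
        return 1
    if down == 4:
        return -1
    raise ValueError("donor cycle does not follow tract order")


# ---------------------------------------------------------------------------
# whole-fold analysis

def _find_tracts(structure: Structure, tetrads: list[TetradAssignment]):
    """Tracts = chain-contiguous runs of tetrad guanines; loops = residues
    between consecutive tracts of the same chain."""
    members = sorted({r for t in tetrads for r in t.residues})
    tracts, current = [], []
    for r in members:
        if current and (r[0] == current[-1][0] and r[1] == current[-1][1] + 1):
            current.append(r)
        else:
            if current:
                tracts.append(current)
            current = [r]
    if current:
        tracts.append(current)
    loops = []
    keys = structure.residue_keys
    for t1, t2 in zip(tracts, tracts[1:]):
        if t1[-1][0] != t2[0][0]:
            loops.append([])
            continue
        loop = [k for k in keys
                if k[0] == t1[-1][0] and t1[-1][1] < k[1] < t2[0][1]]
        loops.append(loop)
    return tracts, loops


def analyze_topology(structure: Structure, model_index: int = 0,
                     criteria: HBondGeomCriteria | None = None,
                     dead_zone_deg: float = 5.0) -> G4Topology:
    """Full fold classification of one model of a Structure."""
    model = structure.models[model_index]
    tetrads = detect_tetrads(model, criteria)
    if len(tetrads) < 2:
        raise ValueError(f"found {len(tetrads)} tetrad(s); need >=2 for topology")
    # order tetrads 5' -> 3' using mean residue index along the stack
    cents = np.array([t.centroid for t in tetrads])
    c0 = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - c0)
    v = vt[0]
    proj = (cents - c0) @ v
    mean_idx = np.array([np.mean([r[1] for r in t.residues]) for t in tetrads])
    if np.corrcoef(proj, mean_idx)[0, 1] < 0:
        proj = -proj
    order = np.argsort(proj)
    tetrads = [tetrads[i] for i in order]
    axis = stack_axis(tetrads)
    for t in tetrads:
        t.polarity = tetrad_polarity(model, t, axis)
        if t.normal @ axis < 0:
            t.normal = -t.normal
    twists = []
    for t_low, t_high in zip(tetrads, tetrads[1:]):
        try:
            twists.append(twist_angle(model, t_low, t_high, axis))
        except ValueError:
            continue   # e.g. block-stacking interface without shared tracts
    if not twists:
        raise ValueError("no tetrad step with resolvable strand correspondence")
    mean_twist = float(np.degrees(np.arctan2(
        np.mean(np.sin(np.radians(twists))), np.mean(np.cos(np.radians(twists))))))
    tracts, loops = _find_tracts(structure, tetrads)
    progression = "indeterminate"
    if len(tracts) == 4:
        progression = strand_progression(model, tracts, axis,
                                         tetrads[0].centroid)
    chi = {}
    for (ch, ri) in sorted({r for t in tetrads for r in t.residues}):
        chi[(ch, ri)] = classify_glyco(glycosidic_chi(model, ch, ri))
    return G4Topology(
        tetrads=tetrads, tracts=tracts, loops=loops, axis=axis,
        mean_twist_deg=mean_twist, twist_per_step_deg=twists,
        helicity=classify_helicity(mean_twist, dead_zone_deg),
        progression=progression, chi_classes=chi)
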