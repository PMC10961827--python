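"""Idealized G-quadruplex construction.

Builds parallel-stranded two-(or more-)layer G4 cores with controllable
inter-tetrad twist, rise, C1' radius, strand-progression direction and
loop length, plus Gaussian-perturbed pseudo-trajectories.

The single-nucleotide internal geometry comes from the standard chemical
component definitions bundled with biotite (idealized deoxyguanosine /
deoxythymidine), repuckered to the C2'-endo sugar conformation. The
builder solves the in-plane placement that realizes the Hoogsteen
N1(H)->O6 / N2(H)->N7 contacts of a C4-symmetric tetrad, then solves the
G-tract backbone conformation (glycosidic chi within the anti window,
gamma, beta) once per twist so that each phosphate reaches bonding
distance of the O3' of its 5'-neighbor in the tract; the strand
direction that closes couples tetrad polarity to helicity.

Loops are geometric placeholders (rigid thymidines along a Bezier arc
between the attachment atoms); no torsional realism is claimed for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

import biotite.structure.info as _bsinfo

from .core import AtomRecord, Model, Structure, Trajectory

__all__ = ["HelicalParams", "build_tetrad", "build_g4", "perturb_ensemble",
           "default_c1_radius", "tract_conformation"]

_HOOGSTEEN_NO = 2.90     # target N1-O6 donor-acceptor distance, A
_HOOGSTEEN_NN = 2.90     # target N2-N7 distance, A

_DROP_ATOMS = {"OP3", "HOP3", "HOP2", "HO3'", "HO5'"}

GUANINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]


# ---------------------------------------------------------------------------
# small rigid-body helpers

def _rotz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rodrigues(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


# ---------------------------------------------------------------------------
# nucleotide template

class _Template:
    """A rigid nucleotide with torsion machinery on its bond graph."""

    def __init__(self, resname: str):
        res = _bsinfo.residue(resname)
        keep = [i for i in range(res.array_length())
                if res.atom_name[i] not in _DROP_ATOMS]
        self.resname = resname
        self.names = [str(res.atom_name[i]) for i in keep]
        self.elements = [str(res.element[i]) for i in keep]
        self.coords = np.array([res.coord[i] for i in keep], dtype=float)
        old2new = {o: n for n, o in enumerate(keep)}
        self.bonds: dict[int, set[int]] = {i: set() for i in range(len(keep))}
        for a, b, _ in res.bonds.as_array():
            if a in old2new and b in old2new:
                self.bonds[old2new[a]].add(old2new[b])
                self.bonds[old2new[b]].add(old2new[a])
        self.index = {n: i for i, n in enumerate(self.names)}

    def xyz(self, name: str) -> np.ndarray:
        return self.coords[self.index[name]]

    _subtree_cache: dict[tuple, list[int]] = {}

    def _subtree(self, root: str, excluded: str) -> list[int]:
        """Atoms reachable from ``root`` without passing through ``excluded``."""
        ck = (self.resname, root, excluded)
        if ck in _Template._subtree_cache:
            return _Template._subtree_cache[ck]
        start, block = self.index[root], self.index[excluded]
        seen, stack = {start}, [start]
        while stack:
            i = stack.pop()
            for j in self.bonds[i]:
                if j != block and j not in seen:
                    seen.add(j)
                    stack.append(j)
        out = sorted(seen - {start})
        _Template._subtree_cache[ck] = out
        return out

    def set_torsion(self, a: str, b: str, c: str, d: str, target_deg: float):
        """Set dihedral a-b-c-d by rotating the subtree beyond bond b-c."""
        cur = _dihedral(self.xyz(a), self.xyz(b), self.xyz(c), self.xyz(d))
        axis = self.xyz(c) - self.xyz(b)
        # rotating the subtree beyond b-c by +x about (c-b) decreases the
        # a-b-c-d dihedral as measured by _dihedral
        R = _rodrigues(axis, cur - target_deg)
        moving = self._subtree(c, b)
        origin = self.xyz(c).copy()
        for i in moving:
            self.coords[i] = R @ (self.coords[i] - origin) + origin

    def transform(self, R: np.ndarray, t: np.ndarray):
        self.coords = self.coords @ R.T + t

    def copy(self) -> "_Template":
        t = object.__new__(_Template)
        t.resname, t.names, t.elements = self.resname, list(self.names), list(self.elements)
        t.coords = self.coords.copy()
        t.bonds, t.index = self.bonds, self.index
        return t


_RING = ["C1'", "C2'", "C3'", "C4'", "O4'"]
#: substituents attached to each deoxyribose ring atom
_RING_SUBST = {
    "C1'": ["H1'"],          # the base is handled separately (stays fixed)
    "C2'": ["H2'", "H2''"],
    "C3'": ["O3'", "H3'"],
    "C4'": ["C5'", "H4'"],
    "O4'": [],
}


def _repucker(t: _Template, phase_deg: float = 162.0, amplitude_deg: float = 38.0):
    """Rebuild the deoxyribose ring at the given pseudorotation phase.

    Ring bond lengths and angles are kept from the template; the five
    endocyclic torsions are set to nu_j = tau_m cos(P + 144 deg (j-2))
    in the least-squares sense, and each ring atom's substituents (O3',
    C5', hydrogens) are carried along by local-frame transfer. The default
    is the B-form C2'-endo (South) pucker typical of parallel G4 tracts.
    """
    from scipy.optimize import least_squares

    ring_i = [t.index[n] for n in _RING]
    old = t.coords[ring_i].copy()
    n = len(_RING)

    lengths = [np.linalg.norm(old[(j + 1) % n] - old[j]) for j in range(n)]
    angles = []
    for j in range(n):
        a, b, c = old[(j - 1) % n], old[j], old[(j + 1) % n]
        v1, v2 = a - b, c - b
        angles.append(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    # target endocyclic torsions: nu_j about bond (j, j+1); nu_0 is
    # C4'-O4'-C1'-C2' i.e. about O4'-C1'. With ring order C1',C2',C3',C4',O4'
    # torsion about bond (j,j+1) uses atoms (j-1, j, j+1, j+2).
    P, tm = np.radians(phase_deg), np.radians(amplitude_deg)
    # nu indexed as in the standard convention: nu2 = C1'-C2'-C3'-C4'
    nu = [np.degrees(tm) * np.cos(P + np.radians(144.0) * (j - 2))
          for j in range(5)]
    # torsion about bond (ring[j], ring[j+1]) equals nu_{j+1} with this
    # atom ordering: bond C1'-C2' -> nu1, C2'-C3' -> nu2, etc.
    tors_target = [nu[(j + 1) % 5] for j in range(n)]

    def resid(x):
        pts = x.reshape(n, 3)
        out = []
        for j in range(n):
            out.append(10.0 * (np.linalg.norm(pts[(j + 1) % n] - pts[j]) - lengths[j]))
        for j in range(n):
            a, b, c = pts[(j - 1) % n], pts[j], pts[(j + 1) % n]
            v1, v2 = a - b, c - b
            ang = np.arccos(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
            out.append(5.0 * (ang - angles[j]))
        for j in range(n):
            d = _dihedral(pts[(j - 1) % n], pts[j], pts[(j + 1) % n], pts[(j + 2) % n])
            err = (d - tors_target[j] + 180.0) % 360.0 - 180.0
            out.append(0.05 * err)
        # anchor: keep C1' and the C1'->C2' direction roughly in place
        out.extend(2.0 * (pts[0] - old[0]))
        return out

    sol = least_squares(resid, old.flatten(), method="lm", max_nfev=20000)
    new = sol.x.reshape(n, 3)

    # rigidly re-anchor the new ring: C1' exactly fixed, ring plane aligned
    # by Kabsch fit on all five atoms, then snap C1'
    oldc, newc = old - old.mean(0), new - new.mean(0)
    H = newc.T @ oldc
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    new = (new - new.mean(0)) @ R.T + old.mean(0)
    new = new + (old[0] - new[0])

    # transfer substituents by local frames (prev, this, next ring atoms)
    def frame(a, b, c):
        e1 = (c - a)
        e1 /= np.linalg.norm(e1)
        v = b - 0.5 * (a + c)
        e2 = v - (v @ e1) * e1
        e2 /= np.linalg.norm(e2)
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    glyco_n = "N9" if "N9" in t.index else "N1"
    for j, name in enumerate(_RING):
        subs = [s for s in _RING_SUBST[name] if s in t.index]
        if name == "C1'":
            subs = subs + [glyco_n]   # the base rides with C1'
        if not subs:
            continue
        Fo = frame(old[(j - 1) % n], old[j], old[(j + 1) % n])
        Fn = frame(new[(j - 1) % n], new[j], new[(j + 1) % n])
        Rj = Fn @ Fo.T
        for s in subs:
            moving = set([t.index[s]] + t._subtree(s, name))
            for i in moving:
                t.coords[i] = Rj @ (t.coords[i] - old[j]) + new[j]
    for j, name in enumerate(_RING):
        t.coords[t.index[name]] = new[j]


def _base_frame_template(resname: str, chi_deg: float, face_up: bool) -> _Template:
    """Template with chi set, base ring in the z=0 plane, centroid at origin.

    ``face_up`` selects the sign of the ring-circulation normal relative
    to +z (which guanine face points toward +z).
    """
    t = _Template(resname)
    _repucker(t)
    if resname == "DG":
        t.set_torsion("O4'", "C1'", "N9", "C4", chi_deg)
        ring = GUANINE_RING
    else:
        t.set_torsion("O4'", "C1'", "N1", "C2", chi_deg)
        ring = ["N1", "C2", "N3", "C4", "C5", "C6"]
    pts = np.array([t.xyz(n) for n in ring])
    centroid = pts.mean(axis=0)
    # ring circulation normal
    circ = np.zeros(3)
    rel = pts - centroid
    for i in range(len(rel)):
        circ += np.cross(rel[i], rel[(i + 1) % len(rel)])
    circ /= np.linalg.norm(circ)
    target = np.array([0.0, 0.0, 1.0 if face_up else -1.0])
    v = np.cross(circ, target)
    s, c = np.linalg.norm(v), float(circ @ target)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s ** 2)
    t.transform(R, np.zeros(3))
    t.transform(np.eye(3), -np.array([t.xyz(n) for n in ring]).mean(axis=0))
    return t


# ---------------------------------------------------------------------------
# tetrad geometry solve

def _place_in_wedge(t: _Template, alpha_deg: float, radius: float) -> _Template:
    """Rotate by alpha about z (at base centroid ~ origin), then translate in
    the xy plane so that C1' projects onto (radius, 0)."""
    p = t.copy()
    p.transform(_rotz(alpha_deg), np.zeros(3))
    c1 = p.xyz("C1'")
    p.transform(np.eye(3), np.array([radius - c1[0], -c1[1], 0.0]))
    return p


def _tetrad_residual(t: _Template, alpha_deg: float, radius: float) -> float:
    p = _place_in_wedge(t, alpha_deg, radius)
    Rn = _rotz(90.0)
    d1 = np.linalg.norm(p.xyz("N1") - Rn @ p.xyz("O6"))
    d2 = np.linalg.norm(p.xyz("N2") - Rn @ p.xyz("N7"))
    cost = (d1 - _HOOGSTEEN_NO) ** 2 + (d2 - _HOOGSTEEN_NN) ** 2
    # steric guard: reject arrangements where neighbor copies interpenetrate
    heavy = p.coords[[i for i, e in enumerate(p.elements) if e != "H"]]
    dmin = np.linalg.norm(heavy[:, None] - (heavy @ Rn.T)[None], axis=-1).min()
    if dmin < 2.5:
        cost += 100.0 * (2.5 - dmin) ** 2
    return cost


def _solve_alpha(t: _Template, radius: float) -> tuple[float, float]:
    grid = np.arange(0.0, 360.0, 2.0)
    vals = [_tetrad_residual(t, a, radius) for a in grid]
    a0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(lambda a: _tetrad_residual(t, a, radius),
                          bounds=(a0 - 5.0, a0 + 5.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x), float(res.fun)


def _canonical_radius(t: _Template) -> float:
    def f(r):
        return _solve_alpha(t, r)[1]
    res = minimize_scalar(f, bounds=(6.5, 9.5), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


_CANONICAL_CACHE: dict[tuple, float] = {}

#: guanine facing that realizes the counterclockwise (+z) Hoogsteen donor
#: cycle with near-exact bond geometry; fixed by one-time numerical probe
_DEFAULT_FACE_UP = False
_DEFAULT_CHI = -120.0


def default_c1_radius(chi_deg: float = _DEFAULT_CHI) -> float:
    """Canonical C1' radius (A) of the idealized tetrad construction."""
    key = ("radius", chi_deg)
    if key not in _CANONICAL_CACHE:
        t = _base_frame_template("DG", chi_deg, _DEFAULT_FACE_UP)
        _CANONICAL_CACHE[key] = _canonical_radius(t)
    return _CANONICAL_CACHE[key]


def _tetrad_templates(c1_radius_A: float | None, chi_deg: float = _DEFAULT_CHI
                      ) -> list[_Template]:
    """The four symmetry copies of the solved tetrad, donor cycle 0->1->2->3
    counterclockwise about +z."""
    radius = c1_radius_A if c1_radius_A is not None else default_c1_radius(chi_deg)
    if not (5.0 <= radius <= 12.0):
        raise ValueError("c1_radius_A must lie in [5, 12] A")
    t = _base_frame_template("DG", chi_deg, _DEFAULT_FACE_UP)
    alpha, _ = _solve_alpha(t, radius)
    placed = _place_in_wedge(t, alpha, radius)
    copies = []
    for k in range(4):
        c = placed.copy()
        c.transform(_rotz(90.0 * k), np.zeros(3))
        copies.append(c)
    return copies


def _to_model(units: list[tuple[_Template, str, int]]) -> Model:
    atoms, serial = [], 0
    for tpl, chain, ridx in units:
        for name, elem, xyz in zip(tpl.names, tpl.elements, tpl.coords):
            serial += 1
            atoms.append(AtomRecord(serial, name, elem, tpl.resname,
                                    ridx, chain, xyz.copy()))
    return Model(atoms)


def build_tetrad(c1_radius_A: float | None = None) -> Model:
    """One planar C4-symmetric G-tetrad of four guanosine nucleotides.

    The Hoogsteen donor cycle (residues 1->2->3->4, one per chain A-D)
    circulates counterclockwise about +z, so ``tetrad_polarity`` with
    axis +z returns +1 for the default build.
    """
    copies = _tetrad_templates(c1_radius_A)
    return _to_model([(c, "ABCD"[k], 1) for k, c in enumerate(copies)])


# ---------------------------------------------------------------------------
# full G4 core

@dataclass
class HelicalParams:
    """Builder input for an idealized parallel G4.

    twist_deg follows the topology convention: positive = right-handed
    screw about the 5'->3' axis. loop_lengths are thymines per loop
    (0 = no loops; the structure is then built as four chains).
    """

    n_tetrads: int = 2
    twist_deg: float = 29.0
    rise_A: float = 3.4
    c1_radius_A: float | None = None
    progression: str = "-"
    loop_lengths: tuple[int, int, int] = (1, 1, 1)
    chi_deg: float = _DEFAULT_CHI

    def __post_init__(self):
        if self.n_tetrads < 2:
            raise ValueError("n_tetrads must be >= 2")
        if self.rise_A <= 0:
            raise ValueError("rise_A must be positive")
        if abs(self.twist_deg) >= 90:
            raise ValueError("|twist_deg| must be < 90")
        if self.progression not in ("+", "-"):
            raise ValueError("progression must be '+' or '-'")
        if len(self.loop_lengths) != 3 or any(l < 0 for l in self.loop_lengths):
            raise ValueError("loop_lengths must be 3 integers >= 0")

    @property
    def sequence(self) -> str:
        g = "G" * self.n_tetrads
        if all(l == 0 for l in self.loop_lengths):
            return g * 4
        parts = [g]
        for l in self.loop_lengths:
            parts.append("T" * l)
            parts.append(g)
        return "".join(parts)


#: hard anti-window for the glycosidic torsion, degrees
_CHI_WINDOW = (-170.0, -90.0)
#: canonical B-form reference torsions (chi, gamma, beta) used as weak
#: priors to break the degeneracy of the closure solve
_CANONICAL_TORSIONS = (-117.0, 54.0, 171.0)
_PRIOR_WEIGHT = 2e-4
#: relaxed conformation of an unconstrained 5'-phosphate arm (gamma, beta)
_FREE_ARM = (54.0, 171.0)

_CLOSURE_CACHE: dict[tuple, tuple] = {}


def _wrap_deg(x):
    return (x + 180.0) % 360.0 - 180.0


def solve_tract_torsions(base: _Template, twist_deg: float, rise_A: float
                         ) -> tuple[tuple[float, float, float], bool, float]:
    """Solve the G-tract conformation (chi, gamma, beta) for a given twist.

    The phosphate of each guanine is driven toward bonding distance
    (1.60 A) of the O3' of its 5'-neighbor in the tract, with a plausible
    O3'-P-O5' angle, chi restricted to the anti window and all three
    torsions weakly biased toward canonical B-form values. Both strand
    directions relative to the stack (5'-tetrad bottom or top) are tried;
    the one that closes determines the relaxed conformation.

    Returns ((chi, gamma, beta), five_prime_top_of_relaxed_direction,
    closure_distance_error_A). The chi rotation pivots about C1'-N9, so
    the base and C1' stay fixed and tetrad hydrogen bonds are untouched.
    """
    key = (round(twist_deg, 6), round(rise_A, 6),
           tuple(np.round(base.xyz("C1'"), 4)))
    if key in _CLOSURE_CACHE:
        return _CLOSURE_CACHE[key]
    sols = {top: _solve_closure(base, twist_deg, rise_A, top)
            for top in (False, True)}
    top = sols[True][1] < sols[False][1]
    x, cost, derr = sols[top]
    out = (tuple(float(v) for v in x), bool(top), float(derr))
    _CLOSURE_CACHE[key] = out
    return out


def _solve_closure(base: _Template, twist_deg: float, rise_A: float,
                   five_prime_top: bool):
    """One-direction closure solve; returns (x, cost, |d-1.6|)."""
    screw_R, screw_t = _rotz(twist_deg), np.array([0.0, 0.0, rise_A])
    cos104 = np.cos(np.radians(104.0))
    lo, hi = _CHI_WINDOW
    chi0, g0, b0 = _CANONICAL_TORSIONS
    w = _PRIOR_WEIGHT

    def prior(chi, g, b):
        pen = 0.0
        chiw = _wrap_deg(chi)
        if chiw > hi:
            pen += 0.05 * (chiw - hi) ** 2
        if chiw < lo:
            pen += 0.05 * (chiw - lo) ** 2
        return pen + w * (_wrap_deg(chi - chi0) ** 2 + _wrap_deg(g - g0) ** 2
                          + _wrap_deg(b - b0) ** 2)

    def eval_cost(chi, g, b):
        t = base.copy()
        t.set_torsion("C4", "N9", "C1'", "O4'", chi)
        t.set_torsion("C3'", "C4'", "C5'", "O5'", g)
        t.set_torsion("C4'", "C5'", "O5'", "P", b)
        p, o3, o5 = t.xyz("P"), t.xyz("O3'"), t.xyz("O5'")
        if five_prime_top:
            o3 = screw_R @ o3 + screw_t
        else:
            p = screw_R @ p + screw_t
            o5 = screw_R @ o5 + screw_t
        d = np.linalg.norm(p - o3)
        v1, v2 = o5 - p, o3 - p
        ca = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return ((d - 1.60) ** 2 + 0.5 * (ca - cos104) ** 2
                + prior(chi, g, b), d)

    # coarse grid, vectorized over beta (P rotates about the C5'-O5' axis)
    best = (np.inf, None)
    betas = np.arange(0.0, 360.0, 5.0)
    cosb = np.cos(np.radians(betas))[:, None]
    sinb = np.sin(np.radians(betas))[:, None]
    beta_prior = w * _wrap_deg(betas - b0) ** 2
    for chi in np.arange(lo, hi + 1e-9, 5.0):
        t1 = base.copy()
        t1.set_torsion("C4", "N9", "C1'", "O4'", chi)
        for g in np.arange(0.0, 360.0, 5.0):
            t2 = t1.copy()
            t2.set_torsion("C3'", "C4'", "C5'", "O5'", g)
            c5, o5, o3 = t2.xyz("C5'"), t2.xyz("O5'"), t2.xyz("O3'")
            u = (o5 - c5) / np.linalg.norm(o5 - c5)
            r0 = t2.xyz("P") - o5
            r_par = (r0 @ u) * u
            r_perp = r0 - r_par
            wv = np.cross(u, r_perp)
            P = o5 + r_par + cosb * r_perp + sinb * wv   # all beta at once
            if five_prime_top:
                tgt = screw_R @ o3 + screw_t
                pp, o5v = P, np.broadcast_to(o5, P.shape)
            else:
                tgt = o3
                pp = P @ screw_R.T + screw_t
                o5v = np.broadcast_to(screw_R @ o5 + screw_t, P.shape)
            d = np.linalg.norm(pp - tgt, axis=1)
            v1 = o5v - pp
            v2 = tgt - pp
            ca = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            cost = ((d - 1.60) ** 2 + 0.5 * (ca - cos104) ** 2 + beta_prior
                    + w * (_wrap_deg(chi - chi0) ** 2 + _wrap_deg(g - g0) ** 2))
            k = int(np.argmin(cost))
            if cost[k] < best[0]:
                best = (float(cost[k]), (float(chi), float(g), float(betas[k])))
    res = minimize(lambda x: eval_cost(*x)[0], list(best[1]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 3000})
    _, d = eval_cost(*res.x)
    return res.x, float(res.fun), abs(float(d) - 1.60)


def tract_conformation(twist_deg: float, rise_A: float = 3.4,
                       c1_radius_A: float | None = None) -> dict:
    """Relaxed G-tract conformation for a given twist: solved torsions,
    which stack end is the 5'-side when the backbone closes, and the
    residual closure error (A)."""
    base = _tetrad_templates(c1_radius_A)[0]
    x, top, derr = solve_tract_torsions(base, twist_deg, rise_A)
    return {"chi_deg": _wrap_deg(x[0]), "gamma_deg": _wrap_deg(x[1]),
            "beta_deg": _wrap_deg(x[2]), "five_prime_top": top,
            "closure_error_A": derr}


def _loop_arc(start: np.ndarray, end: np.ndarray, n_res: int,
              outward: np.ndarray) -> list[np.ndarray]:
    """Quadratic Bezier control points for placing n_res loop residues."""
    mid = 0.5 * (start + end) + outward * (2.0 + 1.5 * n_res)
    pts = []
    for j in range(1, n_res + 1):
        s = j / (n_res + 1.0)
        pts.append((1 - s) ** 2 * start + 2 * (1 - s) * s * mid + s ** 2 * end)
    return pts


def _place_loop_thymine(anchor: np.ndarray, tangent: np.ndarray,
                        outward: np.ndarray, chi_deg: float) -> _Template:
    t = _base_frame_template("DT", chi_deg, True)
    bb = t.xyz("O3'") - t.xyz("P")
    bb = bb / np.linalg.norm(bb)
    tangent = tangent / np.linalg.norm(tangent)
    v = np.cross(bb, tangent)
    s, c = np.linalg.norm(v), float(bb @ tangent)
    if s < 1e-9:
        R1 = np.eye(3) if c > 0 else -np.eye(3)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + K + K @ K * ((1 - c) / s ** 2)
    t.transform(R1, np.zeros(3))
    # swing the base toward `outward` by rotating about the backbone tangent
    centb = np.array([t.xyz(n) for n in ("N1", "C2", "N3", "C4", "C5", "C6")]).mean(axis=0)
    mid = 0.5 * (t.xyz("P") + t.xyz("O3'"))
    w = centb - mid
    w_perp = w - (w @ tangent) * tangent
    o_perp = outward - (outward @ tangent) * tangent
    if np.linalg.norm(w_perp) > 1e-9 and np.linalg.norm(o_perp) > 1e-9:
        ang = np.degrees(np.arctan2(tangent @ np.cross(w_perp, o_perp),
                                    w_perp @ o_perp))
        t.transform(_rodrigues(tangent, ang), np.zeros(3))
    t.transform(np.eye(3), anchor - 0.5 * (t.xyz("P") + t.xyz("O3'")))
    return t


def build_g4(params: HelicalParams) -> Structure:
    """Idealized parallel-stranded G4 core, optionally with thymine loops.

    Tetrad k+1 is tetrad k rotated by twist_deg about the stack axis and
    translated by rise_A. The G-tract backbone conformation (chi within
    the anti window, gamma, beta) is solved once per twist so that, in the
    relaxed strand direction, each phosphate sits at bonding distance of
    the O3' below/above it in the tract. Strand progression is the
    threading order of the tracts (the loop connectivity): it determines
    which stack end is the 5'-side, so reversing the progression at fixed
    helicity flips the tetrad polarity, while the core conformation stays
    keyed to the helicity. The 5'-terminal guanine of each tract carries a
    free phosphate arm in the canonical relaxed (gamma+/beta trans)
    conformation, since it has no upstream tract neighbor.
    """
    copies = _tetrad_templates(params.c1_radius_A, params.chi_deg)
    x, relaxed_top, _ = solve_tract_torsions(copies[0], params.twist_deg,
                                             params.rise_A)
    junctions = []
    for c in copies:
        j = c.copy()
        j.set_torsion("C4", "N9", "C1'", "O4'", x[0])
        j.set_torsion("C3'", "C4'", "C5'", "O5'", _FREE_ARM[0])
        j.set_torsion("C4'", "C5'", "O5'", "P", _FREE_ARM[1])
        junctions.append(j)
        c.set_torsion("C4", "N9", "C1'", "O4'", x[0])
        c.set_torsion("C3'", "C4'", "C5'", "O5'", x[1])
        c.set_torsion("C4'", "C5'", "O5'", "P", x[2])

    # the threading direction realizes the progression: "+" threads with
    # the 5'-side on top, "-" with the 5'-side at the bottom
    five_prime_top = params.progression == "+"

    # strand s, layer l nucleotide (layer 0 = bottom)
    def nucleotide(s: int, l: int, junction: bool = False) -> _Template:
        t = (junctions if junction else copies)[s].copy()
        t.transform(_rotz(params.twist_deg * l),
                    np.array([0.0, 0.0, params.rise_A * l]))
        return t

    nt = params.n_tetrads

    def layer_of(j: int) -> int:
        """Layer of the j-th residue of a tract (j = 0 is the 5'-most)."""
        return (nt - 1 - j) if five_prime_top else j

    strand_of_tract = list(range(4))   # tract t at azimuth +90 t deg
    n_loops = [l for l in params.loop_lengths]
    has_loops = any(l > 0 for l in n_loops)

    units: list[tuple[_Template, str, int]] = []
    if not has_loops:
        for t_i, s in enumerate(strand_of_tract):
            chain = "ABCD"[t_i]
            for j in range(nt):
                units.append((nucleotide(s, layer_of(j), junction=(j == 0)),
                              chain, j + 1))
    else:
        ridx = 0
        for t_i, s in enumerate(strand_of_tract):
            tract_units = []
            for j in range(nt):
                ridx += 1
                tract_units.append((nucleotide(s, layer_of(j),
                                               junction=(j == 0)), "A", ridx))
            units.extend(tract_units)
            if t_i < 3 and n_loops[t_i] > 0:
                s_next = strand_of_tract[t_i + 1]
                a = tract_units[-1][0].xyz("O3'")
                b = nucleotide(s_next, layer_of(0), junction=True).xyz("P")
                outward = 0.5 * (a + b)
                outward[2] = 0.0
                nrm = np.linalg.norm(outward)
                outward = outward / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                pts = _loop_arc(a, b, n_loops[t_i], outward)
                pts_all = [a] + pts + [b]
                for j, p in enumerate(pts, start=1):
                    ridx += 1
                    tangent = pts_all[min(j + 1, len(pts_all) - 1)] - pts_all[j - 1]
                    units.append((_place_loop_thymine(p, tangent, outward,
                                                      params.chi_deg), "A", ridx))
    model = _to_model(units)
    if has_loops:
        _warn_on_clashes(model)
    return Structure([model])


def _warn_on_clashes(model: Model, tol_A: float = 1.5):
    heavy = [(a, a.xyz) for a in model.atoms if a.element != "H"]
    loop = [(a, x) for a, x in heavy if a.residue_name == "DT"]
    core = [(a, x) for a, x in heavy if a.residue_name == "DG"]
    if not loop or not core:
        return
    lx = np.array([x for _, x in loop])
    cx = np.array([x for _, x in core])
    d = np.linalg.norm(lx[:, None, :] - cx[None, :, :], axis=-1)
    nclash = int(np.sum(d.min(axis=1) < tol_A))
    if nclash:
        warnings.warn(f"{nclash} loop atom(s) overlap the core within {tol_A} A "
                      "(loops are geometric placeholders)")


def perturb_ensemble(structure: Structure, sigma_A: float, n_frames: int,
                     seed: int, dt_ns: float = 1.0) -> Trajectory:
    """iid Gaussian coordinate noise (sd sigma_A per coordinate) applied to
    model 0; frames at times 0, dt, 2 dt, ... ns."""
    if sigma_A < 0:
        raise ValueError("sigma_A must be >= 0")
    rng = np.random.default_rng(seed)
    ref = structure.models[0]
    models = [ref.with_coords(ref.coords + rng.normal(0.0, sigma_A,
                                                      ref.coords.shape))
              for _ in range(n_frames)]
    return Trajectory(Structure(models), np.arange(n_frames) * dt_ns)
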