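"""Internal-coordinate geometry: atom placement, dihedrals, residue templates.

Residue templates are idealized heavy-atom geometries (chair pyranoses,
planar aromatic rings) expressed in a local frame.  Chemistry beyond
heavy-atom connectivity is not modelled; bond lengths / angles are standard
textbook values.  Templates carry a virtual glycosidic oxygen ``O1v`` on the
anomeric carbon that is consumed when the next residue is attached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# standard heavy-atom bond lengths (A)
B_CC = 1.52
B_CO = 1.42
B_GLYC = 1.41   # anomeric C1 - glycosidic O
B_AROM = 1.40
ANGLE_GLYC = 116.0  # C-O-C glycosidic angle


def unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    # IUPAC sign convention (matches MDAnalysis calc_dihedrals)
    ang = -np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def wrap_angle(a):
    """Fold angle(s) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = np.mod(-a + 180.0, 360.0)
    out = 180.0 - out
    if out.ndim == 0:
        return float(out)
    return out


def angle_between(p1, p2, p3) -> float:
    """Angle at p2 in degrees."""
    v1 = unit(np.asarray(p1) - np.asarray(p2))
    v2 = unit(np.asarray(p3) - np.asarray(p2))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: return point d with |c-d|=bond, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _frame(p0, p1, p2) -> np.ndarray:
    """Right-handed orthonormal frame from three non-collinear points."""
    e1 = unit(np.asarray(p1) - np.asarray(p0))
    v = np.asarray(p2) - np.asarray(p0)
    e2 = unit(v - np.dot(v, e1) * e1)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def rigid_fit_3pt(src, dst):
    """Rotation R and translation t mapping the congruent point triple
    src onto dst (exact when the triangles are congruent)."""
    Fs = _frame(*src)
    Fd = _frame(*dst)
    R = Fd @ Fs.T
    t = np.asarray(dst[0]) - R @ np.asarray(src[0])
    return R, t


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    M = rng.standard_normal((3, 3))
    Q, Rr = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(Rr)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ----------------------------------------------------------------------
# chair-ring pyranose templates


def _chair_ring(bond: float = B_CC):
    """Six ring positions in an ideal chair (alternating-z hexagon)."""
    R = 1.45
    z0 = np.sqrt(max(bond**2 - R**2, 1e-6)) / 2.0
    pts = []
    for k in range(6):
        th = np.radians(60.0 * k)
        pts.append([R * np.cos(th), R * np.sin(th), z0 * (-1) ** k])
    return np.asarray(pts)


def _substituent_dirs(P, A, B):
    """Two tetrahedral substituent unit vectors at ring atom P with ring
    neighbours A and B."""
    n1 = unit(A - P)
    n2 = unit(B - P)
    bis = -unit(n1 + n2)
    perp = unit(np.cross(n1, n2))
    # choose half-angle so that angle(d, n1) ~ 109.47 deg
    target = np.cos(np.radians(109.47))
    denom = np.dot(bis, n1)
    c = np.clip(target / denom, -1.0, 1.0)
    s = np.sqrt(max(0.0, 1.0 - c * c))
    d_plus = unit(bis * c + perp * s)
    d_minus = unit(bis * c - perp * s)
    return d_plus, d_minus


def _equatorial_axial(P, A, B):
    """(equatorial, axial) directions: equatorial has the smaller |z|."""
    d1, d2 = _substituent_dirs(P, A, B)
    if abs(d1[2]) <= abs(d2[2]):
        return d1, d2
    return d2, d1


# ring atom order around the pyranose: O5, C1, C2, C3, C4, C5
_RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")


@lru_cache(maxsize=None)
def pyranose_template(kind: str = "GLC") -> dict:
    """Heavy-atom template for a beta-pyranose residue.

    kind: GLC (glucose), XYL (xylose), GLCA (glucuronate).
    All oxygen substituents equatorial (beta-D pattern); ``O1v`` marks the
    glycosidic bond direction on C1.
    """
    ring = _chair_ring()
    t = {name: ring[i] for i, name in enumerate(_RING_NAMES)}

    def nbrs(i):
        return ring[(i - 1) % 6], ring[(i + 1) % 6]

    # C1 (index 1): equatorial O1v (beta-glycosidic)
    eq, _ax = _equatorial_axial(ring[1], *nbrs(1))
    t["O1v"] = ring[1] + eq * B_GLYC
    # C2, C3, C4: equatorial hydroxyl oxygens
    for i, name in ((2, "O2"), (3, "O3"), (4, "O4")):
        eq, _ax = _equatorial_axial(ring[i], *nbrs(i))
        t[name] = ring[i] + eq * B_CO
    # C5 substituent
    if kind in ("GLC", "GLCA"):
        eq, _ax = _equatorial_axial(ring[5], *nbrs(5))
        t["C6"] = ring[5] + eq * B_CC
        if kind == "GLC":
            t["O6"] = place_atom(t["O5"], t["C5"], t["C6"], B_CO, 109.5, 180.0)
        else:  # carboxylate
            t["O6A"] = place_atom(t["O5"], t["C5"], t["C6"], 1.25, 120.0, 0.0)
            t["O6B"] = place_atom(t["O5"], t["C5"], t["C6"], 1.25, 120.0, 180.0)
    elif kind != "XYL":
        raise ValueError(f"unknown pyranose kind {kind!r}")
    # mirror to the D-sugar enantiomer: the twofold screw then sits at the
    # canonical negative phi/psi (wrapped sum ~ +120 deg) under the IUPAC
    # dihedral convention
    return {k: np.asarray(v, dtype=float) * np.array([1.0, 1.0, -1.0]) for k, v in t.items()}


# ----------------------------------------------------------------------
# lignin monomer templates


@lru_cache(maxsize=None)
def lignin_template(kind: str = "GUA") -> dict:
    """Heavy-atom template of a lignin monomer (GUA or SYR).

    Ring carbons C1..C6 (planar hexagon); C4 carries the phenolic / linkage
    oxygen O4; C3 (and C5 for syringyl) carry methoxy O3/C3M (O5M/C5M); C1
    carries the propanoid side chain CA-CB-CG with hydroxyls OA and OG.
    The beta-O-4 linkage is realized between CB of one unit and O4 of the
    next.
    """
    if kind not in ("GUA", "SYR"):
        raise ValueError(f"unknown lignin kind {kind!r}")
    t = {}
    for k in range(6):  # regular hexagon: vertex radius == edge length
        th = np.radians(60.0 * k)
        t[f"C{k + 1}"] = B_AROM * np.array([np.cos(th), np.sin(th), 0.0])

    def ring_out(name):
        return unit(t[name])

    t["O4"] = t["C4"] + ring_out("C4") * 1.36
    t["O3"] = t["C3"] + ring_out("C3") * 1.36
    t["C3M"] = t["O3"] + unit(ring_out("C3") + np.array([0, 0, 0.9])) * 1.43
    if kind == "SYR":
        t["O5M"] = t["C5"] + ring_out("C5") * 1.36
        t["C5M"] = t["O5M"] + unit(ring_out("C5") + np.array([0, 0, 0.9])) * 1.43
    # propanoid side chain on C1, lifted out of the ring plane
    ca_dir = unit(ring_out("C1") + np.array([0, 0, 0.4]))
    t["CA"] = t["C1"] + ca_dir * 1.51
    t["CB"] = place_atom(t["C2"], t["C1"], t["CA"], B_CC, 111.0, 120.0)
    t["CG"] = place_atom(t["C1"], t["CA"], t["CB"], B_CC, 111.0, 180.0)
    t["OA"] = place_atom(t["C1"], t["CA"], t["CB"], B_CO, 109.5, -60.0)
    t["OG"] = place_atom(t["CA"], t["CB"], t["CG"], B_CO, 109.5, 180.0)
    return {k: np.asarray(v, dtype=float) for k, v in t.items()}


def transform_template(template: dict, R: np.ndarray, t: np.ndarray) -> dict:
    return {k: R @ v + t for k, v in template.items()}


# ----------------------------------------------------------------------
# regular helical glycan growth


def grow_glycan(template: dict, n: int, phis, psis) -> list:
    """Grow an n-residue beta(1->4) glycan from per-linkage (phi, psi).

    Residue g+1 attaches through its O4 to the anomeric carbon C1 of
    residue g (the template's virtual O1v becomes the next residue's O4).
    phi = dihedral(O5_g, C1_g, O4_{g+1}, C4_{g+1});
    psi = dihedral(C1_g, O4_{g+1}, C4_{g+1}, C5_{g+1}).

    Returns a list of dicts label->position; each residue keeps its own O4;
    O1v remains only meaningful on the final residue (reducing end).
    """
    phis = np.broadcast_to(np.asarray(phis, dtype=float), (max(n - 1, 0),))
    psis = np.broadcast_to(np.asarray(psis, dtype=float), (max(n - 1, 0),))
    d_o4_c4 = np.linalg.norm(template["O4"] - template["C4"])
    d_c4_c5 = np.linalg.norm(template["C4"] - template["C5"])
    ang_o4c4c5 = angle_between(template["O4"], template["C4"], template["C5"])
    residues = [dict(template)]
    for g in range(1, n):
        prev = residues[-1]
        o4n = prev["O1v"]
        c4n = place_atom(prev["O5"], prev["C1"], o4n, d_o4_c4, ANGLE_GLYC, phis[g - 1])
        c5n = place_atom(prev["C1"], o4n, c4n, d_c4_c5, ang_o4c4c5, psis[g - 1])
        R, t = rigid_fit_3pt(
            (template["O4"], template["C4"], template["C5"]), (o4n, c4n, c5n)
        )
        residues.append(transform_template(template, R, t))
    return residues


def screw_parameters(res_a: dict, res_b: dict, template: dict):
    """Twist (deg), rise (A), unit axis and a point on the axis of the rigid
    transform taking residue a onto residue b."""
    keys = ("O4", "C4", "C5")
    R, t = rigid_fit_3pt([res_a[k] for k in keys], [res_b[k] for k in keys])
    # rotation angle and axis
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.degrees(np.arccos(tr))
    w, V = np.linalg.eig(R)
    axis = np.real(V[:, np.argmin(np.abs(w - 1.0))])
    axis = unit(axis)
    rise = float(np.dot(t, axis))
    if rise < 0:
        axis, rise = -axis, -rise
    # point on axis: solve (I - R) p = t_perp
    t_perp = t - rise * axis
    A = np.eye(3) - R
    p0, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    return theta, rise, axis, p0


@lru_cache(maxsize=None)
def tuned_glycan_torsions(kind: str, fold: int, anchor_sum: float, window: float = 20.0):
    """Torsions (phi, psi) whose regular helix is as close as possible to an
    exact ``fold``-fold screw, with phi+psi constrained to
    [anchor_sum - window, anchor_sum + window].

    For the ideal chair template the screw twist depends on phi and psi only
    through their sum, so the sum is scanned and phi = psi = sum/2 is used
    (the symmetric split, which also maximizes the rise).  anchor_sum is
    given unwrapped, e.g. -240 for the canonical twofold 120-degree anchor
    and -170 for the threefold 190-degree regime.

    Returns (phi, psi, rise, twist).
    """
    template = pyranose_template(kind)
    target = 360.0 / fold

    def twist_rise(total):
        res = grow_glycan(template, 3, total / 2.0, total / 2.0)
        theta, rise, _, _ = screw_parameters(res[0], res[1], template)
        return theta, rise

    sums = np.linspace(anchor_sum - window, anchor_sum + window, 161)
    best = None
    for s in sums:
        theta, rise = twist_rise(float(s))
        if rise <= 3.0:
            continue
        cand = (abs(theta - target), float(s), rise, theta)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise ValueError("no helical solution with positive rise")
    _, total, rise, twist = best
    # local refinement by golden-section around the best scanned sum
    lo, hi = total - 0.3, total + 0.3
    for _ in range(40):
        m1 = lo + 0.382 * (hi - lo)
        m2 = lo + 0.618 * (hi - lo)
        if abs(twist_rise(m1)[0] - target) < abs(twist_rise(m2)[0] - target):
            hi = m2
        else:
            lo = m1
    total = float(np.clip(0.5 * (lo + hi), anchor_sum - window, anchor_sum + window))
    twist, rise = twist_rise(total)
    return total / 2.0, total / 2.0, float(rise), float(twist)


def align_to_z(points_by_res: list, axis, origin):
    """Rigidly transform residue dicts so that the helix axis maps onto +z
    through the coordinate origin."""
    axis = unit(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3) if np.dot(axis, z) > 0 else rotation_matrix([1, 0, 0], 180.0)
    else:
        c = np.dot(axis, z)
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    origin = np.asarray(origin, dtype=float)
    return [{k: R @ (p - origin) for k, p in res.items()} for res in points_by_res]
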