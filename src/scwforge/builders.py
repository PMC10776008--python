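"""Single-polymer builders: cellulose elementary fibrils, decorated xylan
chains, and lignin 20-mers.

All builders emit heavy atoms only.  Residues are numbered from the
reducing end (residue 1 carries the free anomeric oxygen O1); decoration
residues (ACE, GLCA) receive indices after the backbone and are tied to
their parent xylose geometrically (the acetyl carbonyl carbon is bonded to
the parent O2 or O3).

Crystal-geometry constants for the cellulose I-beta lattice (unit cell
a = 7.784, b = 8.201, c = 10.380 A, gamma = 96.5 deg) follow the
fiber-diffraction structure of the I-beta allomorph; the fibril uses the
sheet spacing a/2 = 3.89 A and the intra-sheet chain spacing b = 8.20 A
derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .core import Structure

__all__ = [
    "FibrilSpec",
    "XylanSpec",
    "LigninSpec",
    "build_cellulose_fibril",
    "build_xylan",
    "build_lignin",
    "build_lignin_ensemble",
    "lignin_contour_length",
    "DEFAULT_LINKAGE_FRACTIONS",
]

# I-beta derived packing constants (A)
SHEET_SPACING = 3.89     # a / 2
CHAIN_SPACING = 8.20     # b
C_AXIS = 10.38           # c (two residues)

# canonical phi+psi anchors (unwrapped sums; wrap to ~120 and ~190 deg)
TWOFOLD_SUM = -240.0
THREEFOLD_SUM = -170.0


@dataclass(frozen=True)
class FibrilSpec:
    """Elementary cellulose fibril: 18 chains, 234432 cross-section, DP 40."""

    n_chains: int = 18
    arrangement: tuple = (2, 3, 4, 4, 3, 2)
    dp: int = 40
    allomorph: str = "Ibeta"

    def __post_init__(self):
        if sum(self.arrangement) != self.n_chains:
            raise ValueError(
                f"arrangement {self.arrangement} does not sum to n_chains={self.n_chains}"
            )
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if self.allomorph != "Ibeta":
            raise ValueError("only the I-beta allomorph is supported")


@dataclass(frozen=True)
class XylanSpec:
    """Glucuronoxylan chain: acetyl every 2nd residue, GlcA every 8th.

    Decorations sit on even residues counted from the reducing end; a
    residue whose O2 carries GlcA carries its acetyl on O3 instead.
    """

    dp: int = 40
    acetyl_period: int = 2
    glca_period: int = 8
    glca_phase: int = 2
    conformation: str = "twofold"

    def __post_init__(self):
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if self.glca_phase % 2 != 0:
            raise ValueError("glca_phase must be even (decorations sit on even residues)")
        if self.conformation not in ("twofold", "threefold", "random"):
            raise ValueError(f"unknown conformation {self.conformation!r}")

    def acetyl_residues(self) -> list:
        return [r for r in range(2, self.dp + 1, self.acetyl_period)]

    def glca_residues(self) -> list:
        return [r for r in range(self.glca_phase, self.dp + 1, self.glca_period)]


#: minor linkage split applied to the 20 percent that is not beta-O-4
DEFAULT_LINKAGE_FRACTIONS = {
    "beta-O-4": 0.80,
    "beta-beta": 0.08,
    "beta-5": 0.06,
    "5-5": 0.03,
    "4-O-5": 0.03,
}


@dataclass(frozen=True)
class LigninSpec:
    """Hardwood-type lignin 20-mer: 13 S + 7 G, 80 percent beta-O-4."""

    n_monomers: int = 20
    n_syringyl: int = 13
    n_guaiacyl: int = 7
    linkage_fractions: tuple = tuple(sorted(DEFAULT_LINKAGE_FRACTIONS.items()))
    shape: str = "extended"

    def __post_init__(self):
        if self.n_syringyl + self.n_guaiacyl != self.n_monomers:
            raise ValueError("n_syringyl + n_guaiacyl must equal n_monomers")
        fr = dict(self.linkage_fractions)
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("linkage fractions must sum to 1")
        if self.shape not in ("extended", "globular"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def fractions(self) -> dict:
        return dict(self.linkage_fractions)


# ----------------------------------------------------------------------
# structure assembly helpers


def _structure_from_residues(residue_records, polymer_class, box=None) -> Structure:
    """residue_records: list of (residue_index, residue_type, [(label, element, xyz)])."""
    pos, el, lab, rix, rty, cid, pcl = [], [], [], [], [], [], []
    for residue_index, residue_type, atoms in residue_records:
        for label, element, xyz in atoms:
            pos.append(xyz)
            el.append(element)
            lab.append(label)
            rix.append(residue_index)
            rty.append(residue_type)
            cid.append(0)
            pcl.append(polymer_class)
    return Structure(
        np.asarray(pos, dtype=float) if pos else np.zeros((0, 3)),
        el, lab, rix, rty, cid, pcl, box=box, periodic=False,
    )


def _element_of(label: str) -> str:
    return "O" if label.startswith("O") or label == "AcOd" else "C"


_BACKBONE_EMIT = {
    "XYL": ("C1", "C2", "C3", "C4", "C5", "O5", "O2", "O3", "O4"),
    "GLC": ("C1", "C2", "C3", "C4", "C5", "C6", "O5", "O2", "O3", "O4", "O6"),
    "GLCA": ("C1", "C2", "C3", "C4", "C5", "C6", "O5", "O2", "O3", "O4", "O6A", "O6B"),
}


def _emit_residue(coords: dict, rtype: str, with_o1: bool = False):
    atoms = [(lbl, _element_of(lbl), np.asarray(coords[lbl])) for lbl in _BACKBONE_EMIT[rtype]]
    if with_o1:
        atoms.append(("O1", "O", np.asarray(coords["O1v"])))
    return atoms


def _torsions_for(conformation: str, kind: str, n_links: int, rng):
    if conformation == "twofold":
        phi, psi, _, _ = geo.tuned_glycan_torsions(kind, 2, TWOFOLD_SUM)
        return np.full(n_links, phi), np.full(n_links, psi)
    if conformation == "threefold":
        phi, psi, _, _ = geo.tuned_glycan_torsions(kind, 3, THREEFOLD_SUM)
        return np.full(n_links, phi), np.full(n_links, psi)
    # random: disordered glycosidic torsions
    return (
        rng.uniform(-180.0, 180.0, n_links),
        rng.uniform(-180.0, 180.0, n_links),
    )


def _grow_aligned_chain(kind: str, dp: int, conformation: str, rng) -> list:
    """Grow a glycan chain and (for regular conformations) align its helix
    axis with +z through the origin.  Returns residue coordinate dicts in
    build order (non-reducing end first)."""
    template = geo.pyranose_template(kind)
    phis, psis = _torsions_for(conformation, kind, max(dp - 1, 1), rng)
    residues = geo.grow_glycan(template, dp, phis, psis)
    if conformation in ("twofold", "threefold") and dp >= 2:
        _, _, axis, p0 = geo.screw_parameters(residues[0], residues[1], template)
        residues = geo.align_to_z(residues, axis, p0)
    return residues


# ----------------------------------------------------------------------
# cellulose


def build_cellulose_fibril(spec: FibrilSpec = FibrilSpec()) -> Structure:
    """Construct an elementary cellulose fibril.

    Chains are exact-2ated twofold glucan helices stacked in sheets: rows of
    the ``arrangement`` profile are separated by the I-beta sheet spacing
    (3.89 A) along x, chains within a row by 8.20 A along y, with alternate
    rows offset by half a chain spacing and a quarter c-axis stagger (the
    origin/center two-chain motif of the I-beta cell).
    """
    rng = np.random.default_rng(0)
    chain_res = _grow_aligned_chain("GLC", spec.dp, "twofold", rng)
    # orient mean ring normal along x so sheets stack face-to-face
    normal = np.zeros(3)
    for res in chain_res:
        v1 = res["C2"] - res["O5"]
        v2 = res["C4"] - res["O5"]
        normal += np.cross(v1, v2)
    normal[2] = 0.0
    if np.linalg.norm(normal) > 1e-9:
        # rotate about z so the thin (ring-normal) direction lies along x
        ang = np.degrees(np.arctan2(normal[1], normal[0]))
        R = geo.rotation_matrix([0, 0, 1], -ang + 90.0)
        chain_res = [{k: R @ p for k, p in res.items()} for res in chain_res]

    nrows = len(spec.arrangement)
    parts = []
    chain_id = 0
    for i, row_size in enumerate(spec.arrangement):
        x = (i - (nrows - 1) / 2.0) * SHEET_SPACING
        for j in range(row_size):
            y = (j - (row_size - 1) / 2.0) * CHAIN_SPACING + (i % 2) * (CHAIN_SPACING / 2.0)
            z = (i % 2) * (C_AXIS / 4.0)
            rot = geo.rotation_matrix([0, 0, 1], 180.0 * (i % 2))
            records = []
            dp = spec.dp
            for g, res in enumerate(chain_res):
                coords = {k: rot @ p + np.array([x, y, z]) for k, p in res.items()}
                rix = dp - g  # numbered from the reducing end
                records.append((rix, "GLC", _emit_residue(coords, "GLC", with_o1=(g == dp - 1))))
            records.sort(key=lambda r: r[0])
            part = _structure_from_residues(records, "cellulose")
            part.chain_id[:] = chain_id
            parts.append(part)
            chain_id += 1
    out = Structure.concat(parts)
    return out


# ----------------------------------------------------------------------
# xylan


def build_xylan(spec: XylanSpec = XylanSpec(), seed: int = 0) -> Structure:
    """Construct one decorated xylan chain (heavy atoms, chain axis ~ +z
    for regular conformations)."""
    rng = np.random.default_rng(seed)
    residues = _grow_aligned_chain("XYL", spec.dp, spec.conformation, rng)
    dp = spec.dp
    glca_set = set(spec.glca_residues())
    acetyl_set = set(spec.acetyl_residues())

    records = []
    # backbone first, in reducing-end order
    backbone = {}
    for g, res in enumerate(residues):
        rix = dp - g
        backbone[rix] = res
        records.append((rix, "XYL", _emit_residue(res, "XYL", with_o1=(g == dp - 1))))
    records.sort(key=lambda r: r[0])

    next_rix = dp + 1
    glca_template = geo.pyranose_template("GLCA")
    for rix in sorted(acetyl_set | glca_set):
        res = backbone[rix]
        if rix in glca_set:
            # GlcA on O2; displace the acetyl of this residue to O3
            records.append((next_rix, "GLCA", _attach_glca(res, glca_template)))
            next_rix += 1
        if rix in acetyl_set:
            on = "O3" if rix in glca_set else "O2"
            records.append((next_rix, "ACE", _attach_acetyl(res, on)))
            next_rix += 1
    return _structure_from_residues(records, "xylan")


def _attach_acetyl(res: dict, on: str):
    """Acetyl ester on hydroxyl ``on`` (O2 or O3): AcCO (C=O carbon),
    AcOd (carbonyl O), AcMe (methyl C)."""
    parent_c = "C2" if on == "O2" else "C3"
    ref = "C1" if on == "O2" else "C2"
    o = res[on]
    acco = geo.place_atom(res[ref], res[parent_c], o, 1.36, 117.0, 180.0)
    acod = geo.place_atom(res[parent_c], o, acco, 1.21, 123.0, 0.0)
    acme = geo.place_atom(res[parent_c], o, acco, 1.50, 114.0, 180.0)
    return [
        ("AcCO", "C", acco),
        ("AcOd", "O", acod),
        ("AcMe", "C", acme),
    ]


def _attach_glca(res: dict, template: dict):
    """Glucuronate ring alpha-linked onto the backbone O2 (its own O1v is
    the backbone oxygen and is not emitted)."""
    o2 = res["O2"]
    d_c1_o5 = np.linalg.norm(template["C1"] - template["O5"])
    ang = geo.angle_between(template["O1v"], template["C1"], template["O5"])
    c1g = geo.place_atom(res["C1"], res["C2"], o2, 1.41, 116.0, -60.0)
    o5g = geo.place_atom(res["C2"], o2, c1g, d_c1_o5, ang, 60.0)
    R, t = geo.rigid_fit_3pt(
        (template["O1v"], template["C1"], template["O5"]), (o2, c1g, o5g)
    )
    coords = geo.transform_template(template, R, t)
    return [(lbl, _element_of(lbl), coords[lbl]) for lbl in _BACKBONE_EMIT["GLCA"]]


# ----------------------------------------------------------------------
# lignin


def _linkage_counts(fractions: dict, n_links: int) -> dict:
    """Largest-remainder apportionment of linkage types (deterministic)."""
    items = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    floors = {k: int(np.floor(v * n_links)) for k, v in items}
    rem = n_links - sum(floors.values())
    by_rem = sorted(
        items, key=lambda kv: (-(kv[1] * n_links - np.floor(kv[1] * n_links)), kv[0])
    )
    for k, _ in by_rem[:rem]:
        floors[k] += 1
    return floors


def lignin_contour_length(spec: LigninSpec = LigninSpec()) -> float:
    """Contour length (A) of a fully extended chain: per-monomer span of the
    O4 -> CB linkage vector plus the inter-unit bond, summed over links."""
    t = geo.lignin_template("GUA")
    span = float(np.linalg.norm(t["CB"] - t["O4"]))
    return (spec.n_monomers - 1) * (span + 1.42)


def _monomer_sequence(spec: LigninSpec, rng) -> list:
    seq = ["SYR"] * spec.n_syringyl + ["GUA"] * spec.n_guaiacyl
    rng.shuffle(seq)
    return seq


def _linkage_sequence(spec: LigninSpec, rng) -> list:
    counts = _linkage_counts(spec.fractions, spec.n_monomers - 1)
    pool = [k for k, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(pool)
    return pool


def build_lignin(spec: LigninSpec = LigninSpec(), seed: int = 0):
    """Build one lignin chain.  Returns (Structure, linkage list).

    Monomers are rigid templates joined through the previous unit's CB and
    the next unit's O4 with an idealized 1.42 A bond; the linkage TYPE is
    drawn to realize the spec fractions (largest-remainder, seeded order)
    and recorded as metadata -- heavy-atom connectivity beyond the chain
    backbone is not modelled.  ``extended`` aligns the linkage vectors along
    +z; ``globular`` follows a seeded compact self-avoiding walk.
    """
    rng = np.random.default_rng(seed)
    seq = _monomer_sequence(spec, rng)
    link_types = _linkage_sequence(spec, rng)
    placed = _place_lignin_monomers(seq, spec.shape, rng)
    records = []
    for m, (kind, coords) in enumerate(zip(seq, placed), start=1):
        atoms = [(lbl, _element_of(lbl), xyz) for lbl, xyz in coords.items()]
        records.append((m, kind, atoms))
    struct = _structure_from_residues(records, "lignin")
    linkages = [
        {"from_residue": m, "to_residue": m + 1, "type": link_types[m - 1]}
        for m in range(1, spec.n_monomers)
    ]
    return struct, linkages


def _place_lignin_monomers(seq: list, shape: str, rng) -> list:
    templates = {k: geo.lignin_template(k) for k in ("SYR", "GUA")}
    # local frame: put O4 at origin with the O4->CB vector along +z
    locals_ = {}
    for k, t in templates.items():
        v = t["CB"] - t["O4"]
        z = np.array([0.0, 0.0, 1.0])
        axis = np.cross(geo.unit(v), z)
        if np.linalg.norm(axis) < 1e-9:
            R = np.eye(3)
        else:
            ang = np.degrees(
                np.arccos(np.clip(np.dot(geo.unit(v), z), -1.0, 1.0))
            )
            R = geo.rotation_matrix(axis, ang)
        locals_[k] = {lbl: R @ (p - t["O4"]) for lbl, p in t.items()}
    span = float(np.linalg.norm(templates["GUA"]["CB"] - templates["GUA"]["O4"]))
    step = span + 1.42

    placed = []
    if shape == "extended":
        z = 0.0
        for kind in seq:
            spin = geo.rotation_matrix([0, 0, 1], rng.uniform(0.0, 360.0))
            placed.append({lbl: spin @ p + np.array([0.0, 0.0, z]) for lbl, p in locals_[kind].items()})
            z += step
        return placed

    # globular: compact seeded walk with centroid self-avoidance
    centers = [np.zeros(3)]
    anchor = np.zeros(3)
    for m, kind in enumerate(seq):
        for attempt in range(200):
            if m == 0:
                direction = geo.unit(rng.standard_normal(3))
            else:
                pull = -geo.unit(centers[-1] + 1e-9)  # bias back toward origin
                direction = geo.unit(rng.standard_normal(3) * 1.2 + pull)
            o4 = anchor if m == 0 else anchor + direction * 1.42
            R = geo.random_rotation(rng)
            vz = R @ np.array([0.0, 0.0, 1.0])
            Ralign = _align_vec_rotation(vz, direction)
            Rm = Ralign @ R
            coords = {lbl: Rm @ p + o4 for lbl, p in locals_[kind].items()}
            centroid = np.mean(list(coords.values()), axis=0)
            ok = all(
                np.linalg.norm(centroid - c) > 4.5 for c in centers[:-1]
            )
            if ok or attempt == 199:
                placed.append(coords)
                centers.append(centroid)
                anchor = coords["CB"]
                break
    return placed


def _align_vec_rotation(v_from, v_to) -> np.ndarray:
    v_from, v_to = geo.unit(v_from), geo.unit(v_to)
    axis = np.cross(v_from, v_to)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if np.dot(v_from, v_to) > 0:
            return np.eye(3)
        return geo.rotation_matrix([1, 0, 0], 180.0)
    ang = np.degrees(np.arccos(np.clip(np.dot(v_from, v_to), -1.0, 1.0)))
    return geo.rotation_matrix(axis, ang)


def build_lignin_ensemble(spec: LigninSpec, n_chains: int, seed: int = 0):
    """Build an ensemble of lignin chains whose POOLED linkage-type counts
    realize the spec fractions exactly (largest remainder over the whole
    pool, dealt to chains deterministically).

    Returns list of (Structure, linkages).
    """
    n_links = spec.n_monomers - 1
    total = n_chains * n_links
    counts = _linkage_counts(spec.fractions, total)
    rng = np.random.default_rng(seed)
    pool = [k for k, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(pool)
    out = []
    for c in range(n_chains):
        chain_types = pool[c * n_links : (c + 1) * n_links]
        rng_c = np.random.default_rng(np.random.SeedSequence([seed, c]))
        seq = _monomer_sequence(spec, rng_c)
        placed = _place_lignin_monomers(seq, spec.shape, rng_c)
        records = []
        for m, (kind, coords) in enumerate(zip(seq, placed), start=1):
            atoms = [(lbl, _element_of(lbl), xyz) for lbl, xyz in coords.items()]
            records.append((m, kind, atoms))
        struct = _structure_from_residues(records, "lignin")
        linkages = [
            {"from_residue": m, "to_residue": m + 1, "type": chain_types[m - 1]}
            for m in range(1, spec.n_monomers)
        ]
        out.append((struct, linkages))
    return out
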