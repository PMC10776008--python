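"""Whole-SCW periodic model assembly under named packing scenarios, plus
density compression and moisture solvation.

Scenario letters follow the polar-plot naming; the Methods-style Roman
numerals map onto them through :data:`SCENARIO_ROMAN` (the single source of
truth for the two naming systems):

====== ======= ==========================================================
letter roman   packing rule
====== ======= ==========================================================
a      i       all xylan (twofold) bound on cellulose; lignin random
b      ii      70% xylan bound; remaining 30% + lignin random
c      iii     all xylan (twofold) random; lignin random
b.8    iv      8 fibrils in two bundles; 10% xylan trapped between the
               bundles, 60% bound, 30% + lignin random
b.10   v       10 fibrils; 10% xylan trapped between fibrils, 60% bound
f      vi      like b, with 30% of lignin chains globular
g      vii     like f, plus 10% xylan trapped inside the cluster
h      viii    xylan interspersed within the widened fibril cluster,
               leaving direct lignin-cellulose contact
e      ix      threefold xylan random in the top half, lignin random in
               the bottom half (phase separated)
d      x       lignin laid against cellulose first; threefold xylan
               placed in the outer shell (negative control)
====== ======= ==========================================================

Compression substitutes a deterministic seeded scale-and-relax loop for the
slow barostat-driven MD of the original protocol; this is a documented
fidelity limitation, not an approximation of the dynamics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geo
from .builders import (
    FibrilSpec,
    LigninSpec,
    XylanSpec,
    build_cellulose_fibril,
    build_lignin,
    build_xylan,
)
from .core import Structure, WATER_MASS

__all__ = [
    "ScenarioSpec",
    "AssemblyReport",
    "AssemblyError",
    "assemble_scenario",
    "compress_to_density",
    "solvate_and_neutralize",
    "moisture_percent",
    "SCENARIO_ROMAN",
]

log = logging.getLogger(__name__)

SCENARIO_ROMAN = {
    "a": "i", "b": "ii", "c": "iii", "b.8": "iv", "b.10": "v",
    "f": "vi", "g": "vii", "h": "viii", "e": "ix", "d": "x",
}

# per-scenario packing defaults: (n_fibrils, bound, trapped, xylan conf,
# globular lignin fraction)
_SCENARIO_DEFAULTS = {
    "a":    (4, 1.0, 0.0, "twofold", 0.0),
    "b":    (4, 0.7, 0.0, "twofold", 0.0),
    "c":    (4, 0.0, 0.0, "twofold", 0.0),
    "b.8":  (8, 0.6, 0.1, "twofold", 0.0),
    "b.10": (10, 0.6, 0.1, "twofold", 0.0),
    "f":    (4, 0.7, 0.0, "twofold", 0.3),
    "g":    (4, 0.6, 0.1, "twofold", 0.3),
    "h":    (4, 0.0, 1.0, "twofold", 0.0),
    "e":    (4, 0.0, 0.0, "threefold", 0.0),
    "d":    (4, 0.0, 0.0, "threefold", 0.0),
}

_DEFAULT_LIGNIN_COUNT = {4: 58, 8: 116, 10: 145}

CONTACT_DIST = 1.8        # hard steric floor (A)
PLACE_CLEARANCE = 2.2     # clearance used during initial placement (A)
FIBRIL_SPACING_X = 25.0   # center-to-center of adjacent fibrils (sheet dir.)
FIBRIL_SPACING_Y = 33.0   # looser spacing across the wide fibril face
RING_STEP = 9.0           # spacing of surface-laid chains along a ring


class AssemblyError(RuntimeError):
    """Raised when chains cannot be placed within the retry budget."""


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str = "a"
    n_fibrils: int | None = None
    n_xylan: int | None = None
    n_lignin: int | None = None
    bound_fraction: float | None = None
    trapped_fraction: float | None = None
    target_density: float = 1.5
    moisture: float = 3.0
    seed: int = 0
    fibril_dp: int = 40
    xylan_dp: int = 40
    glca_phase: int = 2

    def __post_init__(self):
        key = self.scenario
        roman_to_letter = {v: k for k, v in SCENARIO_ROMAN.items()}
        if key in roman_to_letter:
            object.__setattr__(self, "scenario", roman_to_letter[key])
        elif key not in _SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario {key!r}")
        r = self.resolved()
        if not (0.0 <= r["bound"] and 0.0 <= r["trapped"]
                and r["bound"] + r["trapped"] <= 1.0 + 1e-9):
            raise ValueError("bound + trapped + interspersed fractions must sum to 1")
        if r["n_xylan"] < 0 or r["n_lignin"] < 0 or r["n_fibrils"] <= 0:
            raise ValueError("counts must be non-negative")

    def resolved(self) -> dict:
        nf_def, bound_def, trapped_def, conf, glob_frac = _SCENARIO_DEFAULTS[self.scenario]
        nf = self.n_fibrils if self.n_fibrils is not None else nf_def
        n_xyl = (
            self.n_xylan
            if self.n_xylan is not None
            else int(round(30 * nf / 4))
        )
        n_lig = (
            self.n_lignin
            if self.n_lignin is not None
            else _DEFAULT_LIGNIN_COUNT.get(nf, int(round(58 * nf / 4)))
        )
        bound = self.bound_fraction if self.bound_fraction is not None else bound_def
        trapped = self.trapped_fraction if self.trapped_fraction is not None else trapped_def
        return {
            "scenario": self.scenario,
            "roman": SCENARIO_ROMAN[self.scenario],
            "n_fibrils": nf,
            "n_xylan": n_xyl,
            "n_lignin": n_lig,
            "bound": bound,
            "trapped": trapped,
            "xylan_conformation": conf,
            "globular_lignin_fraction": glob_frac,
        }


@dataclass
class AssemblyReport:
    scenario: str
    roman: str
    chain_counts: dict
    n_atoms: int
    mass_da: float
    box: list
    density: float
    moisture_percent: float
    n_waters: int
    n_counterions: int
    placement: dict = field(default_factory=dict)  # chain_id -> class
    seed: int = 0

    def placement_counts(self, polymer: str | None = None) -> dict:
        counts: dict = {}
        for _cid, (pclass, place) in self.placement.items():
            if polymer is not None and pclass != polymer:
                continue
            counts[place] = counts.get(place, 0) + 1
        return counts

    def to_json(self, **kw) -> str:
        d = dict(self.__dict__)
        d["placement"] = {str(k): list(v) for k, v in self.placement.items()}
        return json.dumps(d, indent=2, **kw)


# ----------------------------------------------------------------------
# placement machinery


class _Packer:
    """Tracks placed chains and provides periodic clash checking."""

    def __init__(self, box, rng):
        self.box = np.asarray(box, dtype=float)
        self.rng = rng
        self.parts: list = []          # (Structure, placement_class)
        self._tree = None
        self._tree_size = 0
        self._recent: list = []

    def _all_positions(self):
        return [p.positions for p, _ in self.parts]

    def _refresh_tree(self, force=False):
        n_recent = sum(len(x) for x in self._recent)
        if self._tree is None or force or n_recent > 8000:
            blocks = self._all_positions()
            if blocks:
                pts = np.mod(np.concatenate(blocks), self.box)
                self._tree = cKDTree(pts, boxsize=self.box)
            self._recent = []

    def clashes(self, positions, clearance=PLACE_CLEARANCE) -> bool:
        pts = np.mod(positions, self.box)
        if self._tree is not None:
            hits = self._tree.query_ball_point(pts, r=clearance)
            if any(hits):
                return True
        for block in self._recent:
            d = pts[:, None, :] - np.mod(block, self.box)[None, :, :]
            d -= self.box * np.round(d / self.box)
            if np.any((d * d).sum(axis=-1) < clearance**2):
                return True
        return False

    def add(self, part: Structure, placement: str):
        self.parts.append((part, placement))
        self._recent.append(part.positions)
        self._refresh_tree()

    def finish(self, periodic=True) -> tuple:
        """Merge parts; returns (Structure, {chain_id: (class, placement)}).

        Chain ids are renumbered monotonically across parts by concat, so
        the map is built by walking parts in order."""
        merged = Structure.concat(
            [p for p, _ in self.parts], box=self.box, periodic=periodic
        )
        placement_map: dict = {}
        offset = 0
        for p, place in self.parts:
            if p.n_atoms == 0:
                continue
            n_chains = len(np.unique(p.chain_id))
            pclass = str(p.polymer_class[0])
            for k in range(n_chains):
                placement_map[offset + k] = (pclass, place)
            offset += n_chains
        return merged, placement_map


def _fibril_centers(n_fibrils: int, scenario: str):
    """(x, y) centers of the fibril cluster plus trap-line anchor points."""
    dx, dy = FIBRIL_SPACING_X, FIBRIL_SPACING_Y
    traps: list = []
    if n_fibrils == 1:
        centers = [(0.0, 0.0)]
    elif n_fibrils == 2:
        centers = [(-dx / 2, 0.0), (dx / 2, 0.0)]
        traps = [(0.0, 0.0)] if scenario in ("b.8", "b.10", "g", "h") else []
    elif n_fibrils == 4:
        if scenario == "h":  # widened cluster leaves interstitial channels
            dxw = 38.0
            centers = [(-dxw / 2, -dy / 2), (dxw / 2, -dy / 2),
                       (-dxw / 2, dy / 2), (dxw / 2, dy / 2)]
            traps = [(0.0, -dy / 2), (0.0, dy / 2), (0.0, 0.0)]
        else:
            centers = [(-dx / 2, -dy / 2), (dx / 2, -dy / 2),
                       (-dx / 2, dy / 2), (dx / 2, dy / 2)]
            traps = [(0.0, 0.0)]
    elif n_fibrils == 8:
        # two 2x2 bundles with a trap channel between them
        gap = 70.0
        bundle = [(-dx / 2, -dy / 2), (dx / 2, -dy / 2),
                  (-dx / 2, dy / 2), (dx / 2, dy / 2)]
        centers = [(x - gap / 2, y) for x, y in bundle] + [
            (x + gap / 2, y) for x, y in bundle
        ]
        traps = [(0.0, -dy), (0.0, -dy / 2), (0.0, 0.0), (0.0, dy / 2), (0.0, dy)]
    elif n_fibrils == 10:
        # two columns of five, channel between the columns widened
        dxw = 40.0
        centers = [
            (sx * dxw / 2, (row - 2) * dy)
            for sx in (-1, 1)
            for row in range(5)
        ]
        traps = [(0.0, (row - 2) * dy) for row in range(5)]
    else:
        # generic near-square grid
        ncol = int(np.ceil(np.sqrt(n_fibrils)))
        centers = []
        for k in range(n_fibrils):
            centers.append(((k % ncol) * dx, (k // ncol) * dy))
        c = np.mean(centers, axis=0)
        centers = [(x - c[0], y - c[1]) for x, y in centers]
        traps = [(0.0, 0.0)]
    return centers, traps


def _ring_positions(centers, n_chains, start_clearance=7.0):
    """Positions and outward normals on concentric ellipses enclosing the
    fibril cluster; rings are filled outward until n_chains are placed."""
    centers = np.asarray(centers, dtype=float)
    cx, cy = centers.mean(axis=0)
    half_x = np.max(np.abs(centers[:, 0] - cx)) + 12.0
    half_y = np.max(np.abs(centers[:, 1] - cy)) + 15.0
    out = []
    ring = 0
    while len(out) < n_chains and ring < 12:
        ax = half_x + start_clearance + ring * RING_STEP
        ay = half_y + start_clearance + ring * RING_STEP
        per = 2 * np.pi * np.sqrt((ax**2 + ay**2) / 2)
        k = max(int(per // RING_STEP), 4)
        for m in range(k):
            th = 2 * np.pi * m / k
            x = cx + ax * np.cos(th)
            y = cy + ay * np.sin(th)
            nrm = np.array([np.cos(th) / ax, np.sin(th) / ay, 0.0])
            nrm = nrm / np.linalg.norm(nrm)
            out.append((np.array([x, y]), nrm, ring))
            if len(out) >= n_chains + k:  # keep whole rings for slack
                break
        ring += 1
    return out


def _decoration_direction(xyl: Structure) -> np.ndarray:
    """Mean xy direction from the chain axis (z) to the acetyl methyls."""
    m = xyl.atom_label == "AcMe"
    if not np.any(m):
        return np.array([1.0, 0.0, 0.0])
    v = xyl.positions[m].mean(axis=0)
    v[2] = 0.0
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def _spin_to(structure: Structure, from_dir, to_dir) -> Structure:
    ang = np.degrees(
        np.arctan2(to_dir[1], to_dir[0]) - np.arctan2(from_dir[1], from_dir[0])
    )
    R = geo.rotation_matrix([0, 0, 1], ang)
    out = structure.copy()
    out.positions = out.positions @ R.T
    return out


def _place_random(
    packer: _Packer,
    part: Structure,
    rng,
    placement: str,
    xy_predicate=None,
    max_tries: int = 600,
    along_z: bool = True,
):
    """Place one chain at a seeded random pose without steric overlap.

    The clearance relaxes from the placement default down to the hard
    steric floor for late attempts, which keeps dense systems packable."""
    box = packer.box
    base = part.positions - part.positions.mean(axis=0)
    for attempt in range(max_tries):
        clearance = PLACE_CLEARANCE if attempt < max_tries // 2 else CONTACT_DIST + 0.05
        if along_z:
            R = geo.rotation_matrix([0, 0, 1], rng.uniform(0, 360.0))
            tilt_ax = [np.cos(a := rng.uniform(0, 2 * np.pi)), np.sin(a), 0.0]
            R = geo.rotation_matrix(tilt_ax, rng.uniform(-10.0, 10.0)) @ R
        else:
            R = geo.random_rotation(rng)
        xy = rng.uniform(0, box[:2])
        if xy_predicate is not None and not xy_predicate(xy):
            continue
        z = rng.uniform(0, box[2])
        pos = base @ R.T + np.array([xy[0], xy[1], z])
        if not packer.clashes(pos, clearance=clearance):
            placed = part.copy()
            placed.positions = pos
            packer.add(placed, placement)
            return
    raise AssemblyError(
        f"failed to place a {part.polymer_class[0] if part.n_atoms else '?'} chain "
        f"({placement}) after {max_tries} tries; "
        f"{len(packer.parts)} chains placed so far -- box too small or too dense"
    )


# ----------------------------------------------------------------------
# main assembly


def assemble_scenario(spec: ScenarioSpec) -> tuple:
    """Assemble a periodic SCW model under the given packing scenario.

    Returns (Structure, AssemblyReport).  Fibrils are placed first (with
    trapped xylan between bundles where the scenario calls for it), bound
    xylan is laid on the cluster surface decorated-face outward, and the
    remaining xylan and all lignin are placed randomly (seeded) without
    steric overlap.
    """
    r = spec.resolved()
    rng = np.random.default_rng(spec.seed)

    fibril = build_cellulose_fibril(FibrilSpec(dp=spec.fibril_dp))
    _, _, rise, _ = geo.tuned_glycan_torsions("GLC", 2, -240.0)
    lz = spec.fibril_dp * rise + 4.0

    centers, trap_anchors = _fibril_centers(r["n_fibrils"], r["scenario"])

    n_bound = int(round(r["bound"] * r["n_xylan"]))
    n_trapped = int(round(r["trapped"] * r["n_xylan"]))
    n_bound = min(n_bound, r["n_xylan"])
    n_trapped = min(n_trapped, r["n_xylan"] - n_bound)
    n_free_xylan = r["n_xylan"] - n_bound - n_trapped

    # --- box: volume for a roomy starting density, centred on the cluster
    xyl_proto = build_xylan(
        XylanSpec(dp=spec.xylan_dp, conformation=r["xylan_conformation"],
                  glca_phase=spec.glca_phase),
        seed=spec.seed,
    )
    lig_proto, _ = build_lignin(LigninSpec(), seed=spec.seed)
    mass_est = (
        r["n_fibrils"] * fibril.mass()
        + r["n_xylan"] * xyl_proto.mass()
        + r["n_lignin"] * lig_proto.mass()
    )
    v_target = mass_est * 1.66053906660 / 0.40  # A^3 at ~0.4 g/cm^3 start
    area = v_target / lz
    cen = np.asarray(centers)
    span_x = (cen[:, 0].max() - cen[:, 0].min()) + 60.0
    span_y = (cen[:, 1].max() - cen[:, 1].min()) + 60.0
    scale = max(np.sqrt(area / (span_x * span_y)), 1.0)
    box = np.array([span_x * scale, span_y * scale, lz])
    origin = box[:2] / 2.0

    packer = _Packer(box, rng)

    # --- fibrils
    for fx, fy in centers:
        part = fibril.translate([origin[0] + fx, origin[1] + fy, box[2] / 2.0])
        packer.add(part, "fibril")
    packer._refresh_tree(force=True)

    # --- trapped xylan (between bundles / fibrils)
    dec_dir = _decoration_direction(xyl_proto)
    trapped_left = n_trapped if r["scenario"] != "h" else min(r["n_xylan"], len(trap_anchors) * 4)
    if r["scenario"] == "h":
        n_free_xylan = r["n_xylan"] - trapped_left
    ti = 0
    placed_trapped = 0
    while placed_trapped < trapped_left and trap_anchors:
        ax, ay = trap_anchors[ti % len(trap_anchors)]
        jitter = rng.uniform(-3.0, 3.0, 2)
        off = (ti // len(trap_anchors)) * RING_STEP - RING_STEP
        chain = _spin_to(xyl_proto, dec_dir, np.array([1.0, 0.0]))
        chain = chain.translate(
            [origin[0] + ax + jitter[0], origin[1] + ay + off + jitter[1], box[2] / 2.0]
        )
        if not packer.clashes(chain.positions):
            packer.add(chain, "trapped")
            placed_trapped += 1
        ti += 1
        if ti > 50 * max(trapped_left, 1):
            raise AssemblyError(
                f"could not fit {trapped_left} trapped xylan chains; placed {placed_trapped}"
            )

    # --- bound xylan on the cluster surface, decorations outward
    if n_bound:
        # request generous slack: corner positions of the innermost ring can
        # clash with fibril corners and get skipped
        ring = _ring_positions(
            [(origin[0] + x, origin[1] + y) for x, y in centers], 2 * n_bound + 20
        )
        placed_bound = 0
        for xy, nrm, _ringno in ring:
            if placed_bound >= n_bound:
                break
            chain = _spin_to(xyl_proto, dec_dir, nrm[:2])
            chain = chain.translate([xy[0], xy[1], box[2] / 2.0])
            if not packer.clashes(chain.positions):
                packer.add(chain, "bound")
                placed_bound += 1
        if placed_bound < n_bound:
            raise AssemblyError(
                f"surface rings exhausted: placed {placed_bound}/{n_bound} bound xylan"
            )

    # --- scenario d: lignin against cellulose first
    lignin_chains = []
    n_glob = int(round(r["globular_lignin_fraction"] * r["n_lignin"]))
    for k in range(r["n_lignin"]):
        shape = "globular" if k < n_glob else "extended"
        lig, _links = build_lignin(
            LigninSpec(shape=shape), seed=int(rng.integers(0, 2**31 - 1))
        )
        lignin_chains.append(lig)

    cluster_xy = np.array([origin[0], origin[1]])
    if r["scenario"] == "d":
        ring = _ring_positions(
            [(origin[0] + x, origin[1] + y) for x, y in centers], 2 * r["n_lignin"] + 20
        )
        placed_l = 0
        max_ring_radius = 0.0
        for (xy, _nrm, _ringno), lig in zip(ring, lignin_chains):
            if placed_l >= r["n_lignin"]:
                break
            chain = lig.translate(
                [xy[0], xy[1], box[2] / 2.0] - lig.positions.mean(axis=0)
            )
            if not packer.clashes(chain.positions):
                packer.add(chain, "bound")
                placed_l += 1
                max_ring_radius = max(
                    max_ring_radius, float(np.linalg.norm(xy - cluster_xy))
                )
        if placed_l < r["n_lignin"]:
            # place the remainder randomly near the cluster
            for lig in lignin_chains[placed_l:]:
                _place_random(packer, lig, rng, "interspersed")
                placed_l += 1
        shell = max_ring_radius + 6.0

        def outside_shell(xy):
            d = xy - cluster_xy
            return float(np.hypot(d[0], d[1])) > shell

        for _ in range(n_free_xylan):
            _place_random(packer, xyl_proto, rng, "interspersed", xy_predicate=outside_shell)
    else:
        xy_pred_x = xy_pred_l = None
        if r["scenario"] == "e":  # phase separation top/bottom
            mid = origin[1]

            def xy_pred_x(xy, _mid=mid):
                return xy[1] > _mid + 5.0

            def xy_pred_l(xy, _mid=mid):
                return xy[1] < _mid - 5.0

        for _ in range(n_free_xylan):
            _place_random(packer, xyl_proto, rng, "interspersed", xy_predicate=xy_pred_x)
        for lig in lignin_chains:
            along_z = str(lig.residue_type[0]) is not None  # extended chains lie along z
            _place_random(
                packer, lig, rng, "interspersed", xy_predicate=xy_pred_l,
                along_z=True,
            )

    structure, placement_map = packer.finish(periodic=True)
    counts: dict = {}
    for _cid, (pclass, _place) in placement_map.items():
        counts[pclass] = counts.get(pclass, 0) + 1

    report = AssemblyReport(
        scenario=r["scenario"],
        roman=r["roman"],
        chain_counts=counts,
        n_atoms=structure.n_atoms,
        mass_da=structure.mass(),
        box=[float(b) for b in structure.box],
        density=structure.density(),
        moisture_percent=0.0,
        n_waters=0,
        n_counterions=0,
        placement=placement_map,
        seed=spec.seed,
    )
    return structure, report


# ----------------------------------------------------------------------
# compression and solvation


def _rigid_groups(s: Structure):
    """Atom index groups moved rigidly: whole chains, except water/ion
    residues which move individually."""
    groups = []
    for cid, idx in s.chain_atom_indices().items():
        cls = str(s.polymer_class[idx[0]])
        if cls in ("water", "ion"):
            for rix in np.unique(s.residue_index[idx]):
                groups.append(idx[s.residue_index[idx] == rix])
        else:
            groups.append(idx)
    return groups


def _relax_overlaps(s: Structure, rng, min_dist=CONTACT_DIST, max_iter=40):
    """Nudge rigid groups apart until no inter-group contact is below
    min_dist (best effort within max_iter)."""
    groups = _rigid_groups(s)
    gid = np.empty(s.n_atoms, dtype=int)
    for g, idx in enumerate(groups):
        gid[idx] = g
    for _ in range(max_iter):
        pts = np.mod(s.positions, s.box)
        tree = cKDTree(pts, boxsize=s.box)
        pairs = tree.query_pairs(min_dist, output_type="ndarray")
        if len(pairs) == 0:
            return True
        bad = pairs[gid[pairs[:, 0]] != gid[pairs[:, 1]]]
        if len(bad) == 0:
            return True
        moved = set()
        for i, j in bad:
            gi, gj = gid[i], gid[j]
            if gi in moved and gj in moved:
                continue
            d = pts[j] - pts[i]
            d -= s.box * np.round(d / s.box)
            nd = np.linalg.norm(d)
            push = (
                d / nd if nd > 1e-9 else geo.unit(rng.standard_normal(3))
            ) * (min_dist - nd + 0.05) / 2.0
            s.positions[groups[gj]] += push + rng.normal(0, 0.02, 3)
            s.positions[groups[gi]] -= push + rng.normal(0, 0.02, 3)
            moved.update((gi, gj))
    return False


def compress_to_density(
    s: Structure,
    target: float = 1.5,
    seed: int = 0,
    shrink: float = 0.99,
    relax: bool = True,
) -> Structure:
    """Isotropically compress a periodic structure to the target density.

    The box and rigid-group centroids are scaled in steps of ``shrink``
    with seeded steric relaxation between steps; internal chain geometry is
    untouched.  The final step scales exactly onto the target, so the
    output density matches ``target`` to floating-point precision.
    """
    if not s.periodic:
        raise ValueError("compression requires a periodic structure")
    rho = s.density()
    if rho >= target * (1 - 1e-9):
        if rho > target * 1.01:
            raise ValueError(
                f"structure density {rho:.3f} already exceeds target {target}"
            )
        return s.copy()
    rng = np.random.default_rng(seed)
    out = s.copy()
    groups = _rigid_groups(out)
    while True:
        rho = out.density()
        f = (rho / target) ** (1.0 / 3.0)
        f = max(f, shrink)
        centre = out.box / 2.0
        for idx in groups:
            c = out.positions[idx].mean(axis=0)
            out.positions[idx] += (c - centre) * (f - 1.0)
        out.box = out.box * f
        # keep groups within the new box
        if relax:
            _relax_overlaps(out, rng)
        if abs(out.density() - target) / target < 1e-9 or f > shrink:
            break
    if relax:
        ok = _relax_overlaps(out, rng)
        if not ok:
            log.warning(
                "steric relaxation incomplete at %.3f g/cm3 (residual contacts "
                "below %.1f A remain)", out.density(), CONTACT_DIST,
            )
    return out


def solvate_and_neutralize(s: Structure, moisture: float = 3.0, seed: int = 0) -> Structure:
    """Add water to the requested moisture (mass percent) and one sodium per
    glucuronate carboxylate.

    Water count n_w solves n_w*18.015 / (dry_mass + n_w*18.015) = moisture%,
    to within one water.  Waters are single O sites (implicit H) dropped on
    a seeded grid scan of interstitial voids, at least 2.4 A from any heavy
    atom.
    """
    if not s.periodic:
        raise ValueError("solvation requires a periodic structure")
    rng = np.random.default_rng(seed)
    dry_mass = s.mass()
    p = moisture / 100.0
    n_w = int(round(dry_mass * p / (1.0 - p) / WATER_MASS)) if p > 0 else 0

    n_glca = sum(1 for _, _, rt, _ in s.residues() if rt == "GLCA")

    parts = [s.copy()]
    heavy = np.mod(s.positions, s.box)
    tree = cKDTree(heavy, boxsize=s.box) if s.n_atoms else None

    # counterions next to each carboxylate
    ion_positions = []
    if n_glca:
        glca_c6 = np.flatnonzero((s.residue_type == "GLCA") & (s.atom_label == "C6"))
        taken: list = []
        for i in glca_c6[:n_glca]:
            base = s.positions[i]
            for _try in range(60):
                d = geo.unit(rng.standard_normal(3)) * 3.0
                cand = np.mod(base + d, s.box)
                near = tree.query_ball_point(cand, r=2.0) if tree else []
                if not near and all(
                    np.linalg.norm(cand - t) > 2.5 for t in taken[-50:]
                ):
                    ion_positions.append(cand)
                    taken.append(cand)
                    break
    if ion_positions:
        k = len(ion_positions)
        parts.append(
            Structure(
                np.asarray(ion_positions),
                ["NA"] * k, ["NA"] * k,
                np.arange(1, k + 1), ["NA"] * k,
                np.zeros(k, dtype=int), ["ion"] * k,
            )
        )

    if n_w > 0:
        spacing = 3.0
        nx, ny, nz = np.maximum((s.box / spacing).astype(int), 1)
        gx = (np.arange(nx) + 0.5) * s.box[0] / nx
        gy = (np.arange(ny) + 0.5) * s.box[1] / ny
        gz = (np.arange(nz) + 0.5) * s.box[2] / nz
        grid = np.array(np.meshgrid(gx, gy, gz, indexing="ij")).reshape(3, -1).T
        if tree is not None:
            d, _ = tree.query(grid, k=1)
            grid = grid[d >= 2.4]
        rng.shuffle(grid)
        if len(grid) < n_w:
            raise AssemblyError(
                f"only {len(grid)} interstitial sites for {n_w} waters; "
                "no space to solvate"
            )
        wpos = grid[:n_w] + rng.uniform(-0.3, 0.3, (n_w, 3))
        parts.append(
            Structure(
                wpos,
                ["O"] * n_w, ["OW"] * n_w,
                np.arange(1, n_w + 1), ["WAT"] * n_w,
                np.zeros(n_w, dtype=int), ["water"] * n_w,
            )
        )

    out = Structure.concat(parts, box=s.box, periodic=True)
    return out


def moisture_percent(s: Structure) -> float:
    """Mass percent of water in a structure."""
    n_w = sum(1 for _, _, rt, _ in s.residues() if rt == "WAT")
    total = s.mass()
    return 100.0 * n_w * WATER_MASS / total if total else 0.0
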