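"""Xylan conformational metrics: glycosidic phi+psi sums, the acetate-face
dihedral theta2f, and cellulose-bound/unbound chain classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Structure, Selection, min_image_distance
from .geometry import dihedral, wrap_angle

__all__ = ["TorsionSeries", "phi_psi_sum", "theta_2f", "classify_bound"]

log = logging.getLogger(__name__)

BOND_CUTOFF = 1.7  # heavy-atom covalent bond detection


@dataclass
class TorsionSeries:
    """Per-residue-pair torsion metric along one chain."""

    chain_id: int
    metric: str  # phi_psi_sum | theta_2f
    values: list = field(default_factory=list)
    residue_pairs: list = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.as_array())) if self.values else float("nan")

    @property
    def circular_mean(self) -> float:
        if not self.values:
            return float("nan")
        a = np.radians(self.as_array())
        return wrap_angle(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))

    @property
    def sd(self) -> float:
        if not self.values:
            return float("nan")
        # circular standard deviation, mapped to degrees
        a = np.radians(self.as_array())
        R = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
        R = min(max(R, 1e-12), 1.0)
        return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


def _chain_residue_atoms(s: Structure, chain: int) -> dict:
    """(residue_index -> {label: position}) for backbone sugar residues of
    one chain, plus the residue_type map."""
    atoms: dict = {}
    rtypes: dict = {}
    mask = s.chain_id == chain
    for i in np.flatnonzero(mask):
        rix = int(s.residue_index[i])
        atoms.setdefault(rix, {})[str(s.atom_label[i])] = s.positions[i]
        rtypes[rix] = str(s.residue_type[i])
    return atoms, rtypes


def phi_psi_sum(s: Structure, chain: int) -> TorsionSeries:
    """Glycosidic phi+psi sums (deg) for each adjacent backbone residue pair.

    phi = O5-C1-O4'-C4', psi = C1-O4'-C4'-C5', where the primed atoms belong
    to the residue closer to the reducing end and C1/O5 to its neighbour;
    sums are folded into (-180, 180].  Pairs with missing atoms are skipped
    with a logged gap.
    """
    atoms, rtypes = _chain_residue_atoms(s, chain)
    backbone = sorted(r for r in atoms if rtypes[r] in ("GLC", "XYL"))
    series = TorsionSeries(chain_id=chain, metric="phi_psi_sum")
    for r in backbone:
        nxt = r + 1
        if nxt not in atoms or rtypes.get(nxt) not in ("GLC", "XYL"):
            continue
        lower, upper = atoms[r], atoms[nxt]
        needed_l = ("O4", "C4", "C5")
        needed_u = ("O5", "C1")
        if any(k not in lower for k in needed_l) or any(k not in upper for k in needed_u):
            log.warning("chain %d residues %d-%d: missing atoms, pair skipped", chain, r, nxt)
            continue
        if np.linalg.norm(upper["C1"] - lower["O4"]) > BOND_CUTOFF:
            log.warning("chain %d residues %d-%d: no glycosidic bond, pair skipped", chain, r, nxt)
            continue
        phi = dihedral(upper["O5"], upper["C1"], lower["O4"], lower["C4"])
        psi = dihedral(upper["C1"], lower["O4"], lower["C4"], lower["C5"])
        series.values.append(wrap_angle(phi + psi))
        series.residue_pairs.append((r, nxt))
    return series


def acetylated_residues(s: Structure, chain: int) -> dict:
    """Map backbone residue_index -> position of its acetate-bound oxygen
    (O2, or O3 when the acetyl was displaced by GlcA), detected by the
    covalent contact between the acetyl carbonyl carbon and the backbone
    hydroxyl oxygen."""
    atoms, rtypes = _chain_residue_atoms(s, chain)
    backbone = {r: d for r, d in atoms.items() if rtypes[r] in ("XYL", "GLC")}
    out = {}
    for r, d in atoms.items():
        if rtypes[r] != "ACE" or "AcCO" not in d:
            continue
        acco = d["AcCO"]
        best = None
        for rb, db in backbone.items():
            for o in ("O2", "O3"):
                if o in db:
                    dist = float(np.linalg.norm(acco - db[o]))
                    if best is None or dist < best[0]:
                        best = (dist, rb, o)
        if best is not None and best[0] < BOND_CUTOFF:
            out[best[1]] = backbone[best[1]][best[2]]
    return out


def theta_2f(s: Structure, chain: int) -> TorsionSeries:
    """Acetate-face dihedral (O-C5 ... C5-O, deg) for each consecutive pair
    of acetylated xylose residues; uses the O3 oxygen for residues whose
    acetyl sits on O3.  Fewer than 2 acetylated residues gives an empty
    series."""
    atoms, rtypes = _chain_residue_atoms(s, chain)
    ac = acetylated_residues(s, chain)
    series = TorsionSeries(chain_id=chain, metric="theta_2f")
    keys = sorted(ac)
    for a, b in zip(keys, keys[1:]):
        da, db = atoms[a], atoms[b]
        if "C5" not in da or "C5" not in db:
            continue
        series.values.append(dihedral(ac[a], da["C5"], db["C5"], ac[b]))
        series.residue_pairs.append((a, b))
    return series


def classify_bound(s: Structure, chain: int, cutoff: float = 4.5, majority: float = 0.5):
    """Classify a xylan chain as cellulose-bound or unbound.

    A backbone residue is in contact when any of its heavy atoms lies within
    ``cutoff`` (A) of any cellulose atom (minimum image when periodic); the
    chain is bound when at least ``majority`` of its backbone residues are
    in contact.  Returns (label, contact_fraction).
    """
    cell_idx = Selection(polymer_class="cellulose").resolve(s)
    if len(cell_idx) == 0:
        raise ValueError("no cellulose in structure")
    cell_pos = s.positions[cell_idx]
    atoms, rtypes = _chain_residue_atoms(s, chain)
    backbone = [r for r in sorted(atoms) if rtypes[r] in ("XYL", "GLC")]
    if not backbone:
        return "unbound", 0.0
    n_contact = 0
    for r in backbone:
        pos = np.asarray(list(atoms[r].values()))
        if s.periodic:
            d = min_image_distance(pos[:, None, :], cell_pos[None, :, :], s.box)
        else:
            d = np.linalg.norm(pos[:, None, :] - cell_pos[None, :, :], axis=-1)
        if np.any(d <= cutoff):
            n_contact += 1
    frac = n_contact / len(backbone)
    return ("bound" if frac >= majority else "unbound"), float(frac)
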