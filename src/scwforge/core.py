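"""Core domain types, periodic geometry helpers, and structure file I/O.

Coordinates are Angstrom throughout; nanometres appear only at CLI
boundaries.  Structures are stored column-wise in numpy arrays for speed,
with :class:`AtomSite` provided as a lightweight per-atom view.

PDB convention used by this package (documented in the README):
the polymer class is encoded in both the chainID column and the first
character of the segid -- C=cellulose, X=xylan, L=lignin, W=water, I=ion --
and the remaining segid characters carry the chain number modulo 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomSite",
    "Structure",
    "Selection",
    "min_image_distance",
    "min_image_displacement",
    "read_structure",
    "write_structure",
    "read_frames",
    "write_frames",
]

POLYMER_CLASSES = ("cellulose", "xylan", "lignin", "water", "ion")

CLASS_LETTER = {
    "cellulose": "C",
    "xylan": "X",
    "lignin": "L",
    "water": "W",
    "ion": "I",
}
LETTER_CLASS = {v: k for k, v in CLASS_LETTER.items()}

#: residue_type -> polymer_class consistency map
RESIDUE_CLASS = {
    "GLC": "cellulose",
    "XYL": "xylan",
    "GLCA": "xylan",
    "ACE": "xylan",
    "SYR": "lignin",
    "GUA": "lignin",
    "WAT": "water",
    "NA": "ion",
}

ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
}

# Implicit hydrogen count per residue type.  Builders emit heavy atoms only;
# total mass adds these nominal hydrogens so densities are comparable to
# all-atom bookkeeping.  WAT (single O site) carries 2 H -> 18.015 Da.
RESIDUE_H = {
    "GLC": 10,
    "XYL": 8,
    "GLCA": 8,
    "ACE": 3,
    "SYR": 13,
    "GUA": 11,
    "WAT": 2,
    "NA": 0,
}

WATER_MASS = 18.015


class ParseError(ValueError):
    """Raised when a structure file has a malformed record."""


@dataclass(frozen=True)
class AtomSite:
    """One atom: identity, residue/chain bookkeeping and position (A)."""

    atom_id: int
    element: str
    atom_label: str
    residue_index: int
    residue_type: str
    chain_id: int
    polymer_class: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        expected = RESIDUE_CLASS.get(self.residue_type)
        if expected is not None and expected != self.polymer_class:
            raise ValueError(
                f"residue_type {self.residue_type} inconsistent with "
                f"polymer_class {self.polymer_class}"
            )
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered atom collection with an optional orthorhombic box.

    Parameters
    ----------
    positions : (N, 3) array, Angstrom
    element, atom_label, residue_type, polymer_class : (N,) str arrays
    residue_index, chain_id : (N,) int arrays
    box : 3 positive lengths (A) or None
    periodic : bool
    """

    def __init__(
        self,
        positions,
        element,
        atom_label,
        residue_index,
        residue_type,
        chain_id,
        polymer_class,
        box=None,
        periodic=False,
    ):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.element = np.asarray(element, dtype=object)
        self.atom_label = np.asarray(atom_label, dtype=object)
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.residue_type = np.asarray(residue_type, dtype=object)
        self.chain_id = np.asarray(chain_id, dtype=int)
        self.polymer_class = np.asarray(polymer_class, dtype=object)
        for arr in (
            self.element,
            self.atom_label,
            self.residue_index,
            self.residue_type,
            self.chain_id,
            self.polymer_class,
        ):
            if len(arr) != n:
                raise ValueError("column length mismatch")
        if box is not None:
            box = np.asarray(box, dtype=float).reshape(3)
            if periodic and not np.all(box > 0):
                raise ValueError("periodic box lengths must be positive")
        elif periodic:
            raise ValueError("periodic structure requires a box")
        self.box = box
        self.periodic = bool(periodic)

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, box=None, periodic=False) -> "Structure":
        return cls(
            np.zeros((0, 3)),
            [], [], [], [], [], [],
            box=box, periodic=periodic,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[AtomSite]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def atom(self, i: int) -> AtomSite:
        return AtomSite(
            atom_id=i,
            element=str(self.element[i]),
            atom_label=str(self.atom_label[i]),
            residue_index=int(self.residue_index[i]),
            residue_type=str(self.residue_type[i]),
            chain_id=int(self.chain_id[i]),
            polymer_class=str(self.polymer_class[i]),
            position=self.positions[i].copy(),
        )

    def copy(self) -> "Structure":
        return Structure(
            self.positions.copy(),
            self.element.copy(),
            self.atom_label.copy(),
            self.residue_index.copy(),
            self.residue_type.copy(),
            self.chain_id.copy(),
            self.polymer_class.copy(),
            box=None if self.box is None else self.box.copy(),
            periodic=self.periodic,
        )

    # ------------------------------------------------------------------
    def translate(self, vec) -> "Structure":
        out = self.copy()
        out.positions = out.positions + np.asarray(vec, dtype=float)
        return out

    def wrapped(self) -> "Structure":
        """Return a copy with coordinates wrapped into [0, box)."""
        if not self.periodic:
            return self.copy()
        out = self.copy()
        out.positions = np.mod(out.positions, out.box)
        return out

    @staticmethod
    def concat(parts: Sequence["Structure"], box=None, periodic=False) -> "Structure":
        """Concatenate structures, renumbering chain ids to stay unique."""
        cols = {k: [] for k in (
            "positions", "element", "atom_label", "residue_index",
            "residue_type", "chain_id", "polymer_class")}
        offset = 0
        for p in parts:
            cols["positions"].append(p.positions)
            cols["element"].append(p.element)
            cols["atom_label"].append(p.atom_label)
            cols["residue_index"].append(p.residue_index)
            cols["residue_type"].append(p.residue_type)
            if p.n_atoms:
                cols["chain_id"].append(p.chain_id + offset)
                offset += int(p.chain_id.max()) + 1
            else:
                cols["chain_id"].append(p.chain_id)
            cols["polymer_class"].append(p.polymer_class)
        if not parts:
            return Structure.empty(box=box, periodic=periodic)
        return Structure(
            np.concatenate(cols["positions"]),
            np.concatenate(cols["element"]),
            np.concatenate(cols["atom_label"]),
            np.concatenate(cols["residue_index"]),
            np.concatenate(cols["residue_type"]),
            np.concatenate(cols["chain_id"]),
            np.concatenate(cols["polymer_class"]),
            box=box,
            periodic=periodic,
        )

    # ------------------------------------------------------------------
    def chain_atom_indices(self) -> dict:
        """chain_id -> atom index array, in file order."""
        out: dict = {}
        for cid in np.unique(self.chain_id):
            out[int(cid)] = np.flatnonzero(self.chain_id == cid)
        return out

    def residues(self, chain: int | None = None):
        """Yield (chain_id, residue_index, residue_type, atom index array)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask = self.chain_id == chain
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return
        keys = list(zip(self.chain_id[idx], self.residue_index[idx]))
        seen = {}
        for pos, key in zip(idx, keys):
            seen.setdefault(key, []).append(pos)
        for (cid, rix), atoms in seen.items():
            arr = np.asarray(atoms)
            yield int(cid), int(rix), str(self.residue_type[arr[0]]), arr

    # ------------------------------------------------------------------
    def mass(self) -> float:
        """Total mass in Da, including nominal implicit hydrogens."""
        m = sum(ELEMENT_MASS[str(e).upper()] for e in self.element)
        for _, _, rtype, _atoms in self.residues():
            m += RESIDUE_H.get(rtype, 0) * ELEMENT_MASS["H"]
        return float(m)

    def density(self) -> float:
        """Mass density in g/cm^3 (requires a box)."""
        if self.box is None:
            raise ValueError("density requires a box")
        vol_A3 = float(np.prod(self.box))
        # Da / A^3 -> g/cm^3
        return self.mass() / vol_A3 * 1.66053906660

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.periodic and (self.box is None or not np.all(self.box > 0)):
            raise ValueError("invalid periodic box")
        for e, r, p in zip(self.element, self.residue_type, self.polymer_class):
            expected = RESIDUE_CLASS.get(str(r))
            if expected is not None and expected != str(p):
                raise ValueError(f"residue_type {r} inconsistent with class {p}")


@dataclass(frozen=True)
class Selection:
    """Reproducible atom predicate: class, optional label set, optional chains."""

    polymer_class: str | None = None
    atom_labels: frozenset | None = None
    chains: frozenset | None = None
    element: str | None = None

    def resolve(self, s: Structure) -> np.ndarray:
        mask = np.ones(s.n_atoms, dtype=bool)
        if self.polymer_class is not None:
            mask &= s.polymer_class == self.polymer_class
        if self.atom_labels is not None:
            mask &= np.isin(s.atom_label.astype(str), sorted(self.atom_labels))
        if self.chains is not None:
            mask &= np.isin(s.chain_id, sorted(self.chains))
        if self.element is not None:
            mask &= s.element.astype(str) == self.element
        return np.flatnonzero(mask)


# ----------------------------------------------------------------------
# periodic geometry


def min_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement b-a for an orthorhombic box (vectorized)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum-image distance between points a and b (A)."""
    d = min_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


# ----------------------------------------------------------------------
# file I/O

_PDB_FMT = (
    "{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<4s}{chain:1s}{resseq:>4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}      "
    "{segid:<4s}{element:>2s}\n"
)


def _pdb_atom_name(label: str) -> str:
    return label[:4]


def write_structure(s: Structure, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "pdb":
        with open(path, "w") as fh:
            _write_pdb_body(s, fh)
            fh.write("END\n")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            _write_xyz_body(s, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_pdb_body(s: Structure, fh) -> None:
    if s.box is not None:
        a, b, c = s.box
        fh.write(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
    for i in range(s.n_atoms):
        cls = str(s.polymer_class[i])
        letter = CLASS_LETTER.get(cls, "Z")
        segid = f"{letter}{int(s.chain_id[i]) % 1000:03d}"
        x, y, z = s.positions[i]
        fh.write(
            _PDB_FMT.format(
                rec="ATOM",
                serial=(i + 1) % 100000,
                name=_pdb_atom_name(str(s.atom_label[i])),
                alt=" ",
                res=str(s.residue_type[i])[:4],
                chain=letter,
                resseq=int(s.residue_index[i]) % 10000,
                icode=" ",
                x=x, y=y, z=z,
                occ=1.0, b=0.0,
                segid=segid,
                element=str(s.element[i])[:2].upper(),
            )
        )


def _write_xyz_body(s: Structure, fh) -> None:
    fh.write(f"{s.n_atoms}\n")
    if s.box is not None:
        a, b, c = s.box
        fh.write(f"box={a:.6f} {b:.6f} {c:.6f}\n")
    else:
        fh.write("generated by scwforge\n")
    for i in range(s.n_atoms):
        x, y, z = s.positions[i]
        fh.write(f"{str(s.element[i]):<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or XYZ file.

    The box comes from CRYST1 (PDB) or a ``box=a b c`` comment line (XYZ);
    without one the structure is non-periodic.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "pdb":
        frames = _read_pdb_frames(path)
        if not frames:
            return Structure.empty()
        return frames[0]
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_frames(path) -> list:
    """Read all MODELs of a (possibly multi-model) PDB file."""
    frames = _read_pdb_frames(Path(path))
    return frames if frames else [Structure.empty()]


def write_frames(frames: Iterable[Structure], path) -> None:
    with open(path, "w") as fh:
        frames = list(frames)
        if frames and frames[0].box is not None:
            a, b, c = frames[0].box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for m, fr in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            fr2 = fr.copy()
            fr2.box = None
            _write_pdb_body(fr2, fh)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb_frames(path: Path) -> list:
    box = None
    frames: list = []
    cur = None

    def new_accum():
        return {k: [] for k in (
            "pos", "element", "label", "resix", "restype", "segid", "chain_letter")}

    cur = new_accum()
    any_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad CRYST1 record") from exc
            elif rec == "MODEL":
                any_model = True
                cur = new_accum()
            elif rec == "ENDMDL":
                frames.append(_finish_pdb_frame(cur, box))
            elif rec in ("ATOM", "HETATM"):
                try:
                    cur["label"].append(line[12:16].strip())
                    cur["restype"].append(line[17:21].strip())
                    cur["chain_letter"].append(line[21])
                    cur["resix"].append(int(line[22:26]))
                    cur["pos"].append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                    segid = line[72:76].strip()
                    cur["segid"].append(segid)
                    el = line[76:78].strip()
                    if not el:
                        el = line[12:16].strip()[0]
                    cur["element"].append(el.capitalize())
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed atom record") from exc
    if not any_model:
        if cur["pos"]:
            frames.append(_finish_pdb_frame(cur, box))
        elif box is not None:
            frames.append(Structure.empty(box=box, periodic=True))
    return frames


def _finish_pdb_frame(cur, box) -> Structure:
    n = len(cur["pos"])
    if n == 0:
        return Structure.empty(box=box, periodic=box is not None)
    # reconstruct chain ids: a new chain starts whenever the segid changes
    # or the residue index decreases.
    chain_ids = np.zeros(n, dtype=int)
    cid = 0
    for i in range(1, n):
        if (
            cur["segid"][i] != cur["segid"][i - 1]
            or cur["resix"][i] < cur["resix"][i - 1]
        ):
            cid += 1
        chain_ids[i] = cid
    pclass = []
    for seg, letter, rtype in zip(cur["segid"], cur["chain_letter"], cur["restype"]):
        key = seg[0] if seg else letter
        pclass.append(LETTER_CLASS.get(key, RESIDUE_CLASS.get(rtype, "cellulose")))
    return Structure(
        np.asarray(cur["pos"], dtype=float),
        cur["element"],
        cur["label"],
        cur["resix"],
        cur["restype"],
        chain_ids,
        pclass,
        box=box,
        periodic=box is not None,
    )


def _read_xyz(path: Path) -> Structure:
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        return Structure.empty()
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:1: expected atom count") from exc
    box = None
    if len(lines) > 1 and "box=" in lines[1]:
        try:
            vals = lines[1].split("box=")[1].split()[:3]
            box = np.array([float(v) for v in vals])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:2: malformed box comment") from exc
    pos, elements = [], []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: malformed XYZ atom line")
        elements.append(parts[0])
        try:
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coordinate") from exc
    if len(pos) != n:
        raise ParseError(f"{path}: expected {n} atoms, found {len(pos)}")
    n_at = len(pos)
    return Structure(
        np.asarray(pos, dtype=float) if pos else np.zeros((0, 3)),
        elements,
        [e for e in elements],
        np.ones(n_at, dtype=int),
        ["UNK"] * n_at,
        np.zeros(n_at, dtype=int),
        ["cellulose"] * n_at,
        box=box,
        periodic=box is not None,
    )
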