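"""Coordinate model: reading, normalizing and writing multi-model structures.

Deposited quadruplex ensembles mix atom-name dialects (``O4'``, ``O4*``,
unicode primes) and use inconsistent residue codes for chemically modified
nucleotides (LNA, 2'-fluoro sugars).  This module normalizes names on read
and derives sugar chemistry from the atom inventory and geometry alone, so
downstream analyses never depend on residue-code conventions.
"""
from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional

import gemmi
import numpy as np

from .geometry import plane_normal

__all__ = [
    "Atom",
    "Residue",
    "Model",
    "Ensemble",
    "FormatError",
    "InventoryError",
    "normalize_atom_name",
    "read_structure",
    "write_pdb",
    "classify_sugar_chemistry",
]

#: sugar chemistry labels
DEOXYRIBOSE = "deoxyribose"
RIBOSE = "ribose"
LOCKED = "locked"
F_RIBO = "2'F-ribo"
F_ARABINO = "2'F-arabino"
UNKNOWN = "unknown"

_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")
_PHOSPHATE_REMAP = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3"}
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """The file could not be parsed in the requested coordinate format."""


class InventoryError(ValueError):
    """Models of one ensemble disagree in residue sequence or atom inventory."""


def normalize_atom_name(name: str) -> str:
    """Canonical atom label: primes unified to ``'``, old phosphate names mapped."""
    n = name.strip().replace("′", "'").replace("*", "'")
    return _PHOSPHATE_REMAP.get(n, n)


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)) or self.position.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_index: int          # 1-based position in chain, file order
    name: str               # residue code as deposited
    atoms: List[Atom] = field(default_factory=list)
    auth_seq: Optional[int] = None  # author residue number, for reporting

    def __post_init__(self):
        self._index = {a.name: a for a in self.atoms}

    # -- atom access -------------------------------------------------
    def atom(self, name: str) -> Atom:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"residue {self.chain_id}{self.auth_seq or self.seq_index} "
                f"({self.name}) has no atom {name!r}"
            ) from None

    def has(self, *names: str) -> bool:
        return all(n in self._index for n in names)

    def get(self, name: str) -> Optional[Atom]:
        return self._index.get(name)

    def pos(self, name: str) -> np.ndarray:
        return self.atom(name).position

    def add_atom(self, atom: Atom) -> None:
        self.atoms.append(atom)
        self._index[atom.name] = atom

    @property
    def key(self):
        return (self.chain_id, self.seq_index)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.auth_seq if self.auth_seq is not None else self.seq_index}"

    # -- classification ----------------------------------------------
    @property
    def is_nucleotide(self) -> bool:
        return self.has("C1'", "O4'") and self.name not in _WATER_NAMES

    @property
    def base_type(self) -> str:
        if self.has("N9", "N7", "C8", "C4"):
            return "purine"
        if self.has("N1", "C2", "N3", "C4", "C5", "C6") and not self.has("N9"):
            return "pyrimidine"
        return "other"

    @property
    def is_guanine(self) -> bool:
        return self.base_type == "purine" and self.has("O6", "N1", "N2")

    @property
    def glycosidic_nitrogen(self) -> Optional[str]:
        if self.base_type == "purine":
            return "N9"
        if self.base_type == "pyrimidine":
            return "N1"
        return None

    @property
    def sugar_chemistry(self) -> str:
        return classify_sugar_chemistry(self)

    def coords(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.pos(n) for n in names])


def classify_sugar_chemistry(residue: Residue) -> str:
    """Derive sugar chemistry from the atom inventory and local geometry.

    The rule never consults the residue code: a carbon bridging O2' and C4'
    (both bonds < 1.8 A) marks a locked (LNA) sugar; a fluorine bonded to
    C2' marks a 2'F sugar, with the ribo/arabino epimer decided by whether
    the fluorine sits on the opposite or the same furanose face as the
    base; a plain O2' means ribose, none of the above deoxyribose.
    """
    if not residue.has(*_RING_ATOMS):
        return UNKNOWN
    c2 = residue.pos("C2'")
    c4 = residue.pos("C4'")

    o2 = residue.get("O2'")
    if o2 is not None:
        for atom in residue.atoms:
            if atom.element != "C" or atom.name in _RING_ATOMS:
                continue
            if (np.linalg.norm(atom.position - o2.position) < 1.8
                    and np.linalg.norm(atom.position - c4) < 1.8):
                return LOCKED

    fluorine = None
    for atom in residue.atoms:
        if atom.element == "F" and np.linalg.norm(atom.position - c2) < 1.8:
            fluorine = atom
            break
    if fluorine is not None:
        normal = plane_normal(residue.coords(_RING_ATOMS))
        # reference for the base face: glycosidic nitrogen, else C5'
        marker = residue.glycosidic_nitrogen
        ref = residue.get(marker) if marker else None
        if ref is None:
            ref = residue.get("C5'")
        if ref is None:
            return UNKNOWN
        face_f = np.sign(normal @ (fluorine.position - c2))
        face_base = np.sign(normal @ (ref.position - residue.pos("C1'")))
        return F_ARABINO if face_f == face_base else F_RIBO

    return RIBOSE if o2 is not None else DEOXYRIBOSE


@dataclass
class Model:
    residues: List[Residue]
    number: int = 1

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def nucleotides(self) -> List[Residue]:
        return [r for r in self.residues if r.is_nucleotide]

    def guanines(self) -> List[Residue]:
        return [r for r in self.residues if r.is_guanine]

    def residue(self, chain_id: str, seq_index: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_index == seq_index:
                return r
        raise KeyError(f"no residue {chain_id}/{seq_index}")

    def inventory(self):
        return [
            (r.chain_id, r.seq_index, r.name, tuple(sorted(a.name for a in r.atoms)))
            for r in self.residues
        ]


@dataclass
class Ensemble:
    models: List[Model]
    path: Optional[str] = None
    format: Optional[str] = None
    entry_id: Optional[str] = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("an ensemble holds at least one model")
        self.validate_inventory()

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[Model]:
        return iter(self.models)

    def validate_inventory(self) -> None:
        ref = self.models[0].inventory()
        for m in self.models[1:]:
            inv = m.inventory()
            if inv == ref:
                continue
            for a, b in zip(ref, inv):
                if a != b:
                    raise InventoryError(
                        f"model {m.number} disagrees with model "
                        f"{self.models[0].number} at residue {b[0]}{b[1]} ({b[2]})"
                    )
            raise InventoryError(
                f"model {m.number} has {len(inv)} residues, expected {len(ref)}"
            )


def _altloc_ok(atom: gemmi.Atom) -> bool:
    return atom.altloc in ("\0", "", "A")


def _from_gemmi(st: gemmi.Structure, path, fmt) -> Ensemble:
    models = []
    for i, gm in enumerate(st):
        residues = []
        for chain in gm:
            for j, gr in enumerate(chain, start=1):
                atoms = []
                seen = set()
                for ga in gr:
                    if not _altloc_ok(ga):
                        continue
                    name = normalize_atom_name(ga.name)
                    if name in seen:
                        continue
                    seen.add(name)
                    element = ga.element.name if ga.element else ""
                    if not element or element == "X":
                        element = "".join(c for c in name if c.isalpha())[:1]
                    atoms.append(Atom(name, element, np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
                residues.append(
                    Residue(chain.name, j, gr.name.strip(), atoms, auth_seq=gr.seqid.num)
                )
        number = i + 1
        try:
            number = int(getattr(gm, "num", None) or getattr(gm, "name", number))
        except (TypeError, ValueError):
            pass
        models.append(Model(residues, number=number))
    if not models or not any(m.residues for m in models):
        raise FormatError(f"no coordinates found in {path}")
    return Ensemble(models, path=str(path), format=fmt, entry_id=st.name or None)


def read_structure(path, format: str = "auto") -> Ensemble:
    """Read a PDB or mmCIF file into an :class:`Ensemble`.

    ``format`` may be ``pdb``, ``mmcif`` or ``auto`` (extension-based).
    All models are returned; atom names are normalized; alternate
    locations other than blank/A are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
            fmt = "pdb"
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
            fmt = "mmcif"
        elif format == "auto":
            st = gemmi.read_structure(str(path))
            fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_gemmi(st, path, fmt)


def write_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL records)."""
    st = gemmi.Structure()
    st.name = ensemble.entry_id or "MOCK"
    for model in ensemble:
        gm = gemmi.Model(model.number)
        chains = collections.OrderedDict()
        for res in model:
            if res.chain_id not in chains:
                chains[res.chain_id] = gemmi.Chain(res.chain_id)
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.auth_seq if res.auth_seq is not None else res.seq_index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                gr.add_atom(ga)
            chains[res.chain_id].add_residue(gr)
        for chain in chains.values():
            gm.add_chain(chain)
        st.add_model(gm)
    st.write_pdb(str(path))
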