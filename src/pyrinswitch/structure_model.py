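"""Lightweight hierarchical coordinate model for protein structures.

The model (``Structure`` -> chains -> ``Residue`` -> ``Atom``) keeps author
residue numbering throughout, assigns a fixed heavy-atom van der Waals radius
to every atom at load time, and round-trips through PDB text to three decimal
places.  Parsing of PDB/mmCIF files is delegated to :mod:`gemmi`; the writer
is a plain fixed-width ATOM-record formatter so the round-trip contract does
not depend on any third-party writer dialect.

Hydrogens are dropped everywhere: the crystal structures this package targets
(2-3 A resolution pyrin domains) do not resolve them, and the synthetic
generator never emits them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomSelection",
    "VDW_RADII",
    "THREE_TO_ONE",
    "ParseError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "select",
]

# Bondi-style heavy-atom radii (A).  One fixed table; unknown elements raise
# rather than defaulting silently, so a radius is never fabricated.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class ParseError(ValueError):
    """Raised when a structure or alignment file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when no protein atoms survive filtering."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")
        if self.vdw_radius == 0.0:
            try:
                self.vdw_radius = VDW_RADII[self.element.upper()]
            except KeyError:
                raise ValueError(
                    f"no van der Waals radius for element {self.element!r} "
                    f"(atom {self.name}); known: {sorted(VDW_RADII)}"
                ) from None


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain_id}/{self.name}{self.number}{self.icode}>"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    def validate(self) -> None:
        ids = self.chain_ids
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.id!r}")
        if not any(len(c) for c in self.chains):
            raise EmptyStructureError(f"structure {self.id!r} has no residues")
        for c in self.chains:
            keys = [r.key for r in c.residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue identifiers in chain {c.chain_id}")


@dataclass
class AtomSelection:
    """A resolved set of atoms with their parent residues.

    Resolution is deterministic given a Structure: atoms appear in structure
    order.  The empty selection is representable (and valid for set algebra,
    not for SASA).
    """

    description: str
    pairs: list[tuple[Residue, Atom]] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for _, a in self.pairs]

    def coords(self) -> np.ndarray:
        if not self.pairs:
            return np.empty((0, 3))
        return np.array([a.coords for _, a in self.pairs])

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for _, a in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)

    def __add__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(
            description=f"({self.description})+({other.description})",
            pairs=list(self.pairs) + list(other.pairs),
        )


def _parse_range_spec(spec) -> set[int] | None:
    """``"70-96"``, ``"26,84,86"``, iterables and ranges -> set of ints."""
    if spec is None:
        return None
    if isinstance(spec, str):
        out: set[int] = set()
        for part in spec.split(","):
            part = part.strip()
            if "-" in part[1:]:  # allow negative leading numbers
                lo, hi = part.rsplit("-", 1)
                out.update(range(int(lo), int(hi) + 1))
            elif part:
                out.add(int(part))
        return out
    if isinstance(spec, int):
        return {spec}
    return set(int(x) for x in spec)


def select(
    s: Structure,
    chains: str | Sequence[str] | None = None,
    resnums=None,
    resnames: Iterable[str] | None = None,
    atom_names: Iterable[str] | None = None,
    sidechain: bool = False,
    backbone: bool = False,
) -> AtomSelection:
    """Resolve a predicate over a Structure into an :class:`AtomSelection`.

    ``sidechain`` and ``backbone`` restrict by atom role; both True is a
    contradiction and raises.
    """
    if sidechain and backbone:
        raise ValueError("sidechain and backbone are mutually exclusive")
    if isinstance(chains, str):
        chains = [chains]
    chain_set = set(chains) if chains is not None else None
    num_set = _parse_range_spec(resnums)
    name_set = {n.upper() for n in resnames} if resnames is not None else None
    atom_set = {n.upper() for n in atom_names} if atom_names is not None else None

    desc_parts = []
    if chain_set is not None:
        desc_parts.append("chain=" + ",".join(sorted(chain_set)))
    if num_set is not None:
        desc_parts.append(f"resnum[{len(num_set)}]")
    if name_set is not None:
        desc_parts.append("resname=" + ",".join(sorted(name_set)))
    if atom_set is not None:
        desc_parts.append("atom=" + ",".join(sorted(atom_set)))
    if sidechain:
        desc_parts.append("sidechain")
    if backbone:
        desc_parts.append("backbone")

    pairs: list[tuple[Residue, Atom]] = []
    for c in s.chains:
        if chain_set is not None and c.chain_id not in chain_set:
            continue
        for r in c.residues:
            if num_set is not None and r.number not in num_set:
                continue
            if name_set is not None and r.name.upper() not in name_set:
                continue
            for a in r.atoms:
                if atom_set is not None and a.name.upper() not in atom_set:
                    continue
                if sidechain and a.name in BACKBONE_ATOMS:
                    continue
                if backbone and a.name not in BACKBONE_ATOMS:
                    continue
                pairs.append((r, a))
    return AtomSelection(description="; ".join(desc_parts) or "all", pairs=pairs)


# ---------------------------------------------------------------------------
# Reading


def _element_of(gemmi_atom, atom_name: str) -> str:
    el = gemmi_atom.element.name.strip()
    if el:
        return el.upper()
    # fall back to first alphabetic character of the atom name
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(
    path: str | Path,
    format: str | None = None,
    keep_het: bool = False,
    altloc_policy: str = "highest_occupancy",
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Waters, heteroatoms (unless ``keep_het``) and hydrogens are dropped.  For
    alternate locations exactly one conformer is retained per atom: the
    highest-occupancy one (ties broken by altloc character order) or the first
    encountered, per ``altloc_policy``.  Author residue numbering is kept.
    Only the first model of multi-model files is read.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            gst = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(gst) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = gst[0]

    out = Structure(
        id=gst.name or path.stem,
        metadata={"source": str(path), "format": format, "altloc_policy": altloc_policy},
    )
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            resname = gres.name.strip().upper()
            if resname in _WATER_NAMES:
                continue
            is_protein = resname in THREE_TO_ONE
            if not is_protein and not keep_het:
                continue
            residue = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or " ").strip(),
                name=resname,
            )
            # group altloc variants by atom name, then keep one
            by_name: dict[str, list] = {}
            for ga in gres:
                el = _element_of(ga, ga.name)
                if el == "H" or el == "D":
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            for name, variants in by_name.items():
                if len(variants) == 1:
                    ga = variants[0]
                elif altloc_policy == "first":
                    ga = variants[0]
                else:
                    ga = max(variants, key=lambda g: (g.occ, -ord(g.altloc or "~")))
                residue.atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name,
                        element=_element_of(ga, name),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=(ga.altloc or "").strip(),
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise EmptyStructureError(f"{path}: zero protein atoms after filtering")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Writing


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB text (ATOM/TER/END records, 3-decimal coords).

    ``read_structure(write_structure(s))`` reproduces identifiers exactly and
    coordinates to three decimals.
    """
    s.validate()
    lines: list[str] = []
    serial = 0
    for chain in s.chains:
        last_res = None
        for res in chain.residues:
            if res.number > 9999 or res.number < -999:
                raise ValueError(
                    f"residue number {res.number} not encodable in PDB format"
                )
            for atom in res.atoms:
                serial += 1
                if serial > 99999:
                    raise ValueError("too many atoms for PDB serial field")
                name = atom.name
                # PDB convention: 1-2 char element names start at column 14
                if len(name) < 4 and len(atom.element) == 1:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                record = "HETATM" if res.name not in THREE_TO_ONE else "ATOM  "
                x, y, z = atom.coords
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise ValueError("coordinate out of PDB fixed-width range")
                lines.append(
                    f"{record}{serial:5d} {name_field}{atom.altloc or ' '}"
                    f"{res.name:>3s} {chain.chain_id[:1]}{res.number:4d}"
                    f"{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
            last_res = res
        if last_res is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_res.name:>3s} "
                f"{chain.chain_id[:1]}{last_res.number:4d}{last_res.icode or ' '}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(s: Structure, chain_id: str) -> tuple[str, dict[int, int]]:
    """One-letter sequence of a chain plus a residue-number -> position map.

    The map is bijective between author residue numbers and 0-based sequence
    positions (insertion-coded residues share the number of their parent and
    are therefore not representable in the map; pyrin-domain entries carry
    none).
    """
    chain = s.chain(chain_id)
    seq = []
    index_map: dict[int, int] = {}
    for i, res in enumerate(chain.residues):
        seq.append(res.one_letter)
        index_map[res.number] = i
    return "".join(seq), index_map
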