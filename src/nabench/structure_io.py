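"""Read protein–nucleic-acid complex structures into a uniform model.

Structures come from PDB or mmCIF files (parsed with :mod:`gemmi`) and are
normalized into plain dataclasses: :class:`Atom`, :class:`Residue`,
:class:`Chain`, :class:`ComplexStructure`.  Chains are classified as
``protein``, ``RNA``, ``DNA`` or ``other`` by majority vote over residue
names, with an alias table mapping modified residues to their parent type.

Conventions (applied uniformly downstream):

* only the first model of multi-model files is used;
* waters are always removed;
* for alternate locations, the conformer with the highest occupancy is kept
  (ties: first encountered);
* hydrogens are retained when present;
* author chain IDs and author residue numbering (with insertion codes) are
  the coordinate system everywhere, including prediction files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "ParseError",
    "EmptyStructureError",
    "parse_structure",
    "classify_chain",
    "detect_ca_only",
    "write_pdb",
    "structure_summary",
]

Moltype = Literal["protein", "RNA", "DNA", "other"]

# Residue-name vocabularies.  Aliases map common modified residues onto a
# parent so they count as standard for chain classification.
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
PROTEIN_ALIASES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "MLY": "LYS", "CSO": "CYS",
    "PTR": "TYR", "SEP": "SER", "TPO": "THR", "HYP": "PRO", "KCX": "LYS",
}
DNA_NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DI", "DU"}
DNA_ALIASES = {"5CM": "DC", "6OG": "DG", "8OG": "DG", "BRU": "DU"}
RNA_NUCLEOTIDES = {"A", "C", "G", "U", "I"}
RNA_ALIASES = {
    "PSU": "U", "1MA": "A", "5MC": "C", "OMG": "G", "OMC": "C", "7MG": "G",
    "2MG": "G", "M2G": "G", "1MG": "G", "5MU": "U", "4SU": "U", "H2U": "U",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a structure file cannot be read."""


class EmptyStructureError(ParseError):
    """Raised when no atoms remain after filtering (e.g. waters only)."""


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element symbol and coordinates in Å."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One residue, identified by (chain_id, seq_id, insertion_code)."""

    chain_id: str
    seq_id: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    is_standard: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    moltype: Moltype
    residues: list[Residue]


@dataclass
class ComplexStructure:
    """Parsed chains/residues/atoms of one co-crystal structure."""

    id: str
    chains: list[Chain]
    resolution: float | None = None

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.moltype == "protein"]

    @property
    def nucleic_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.moltype in ("RNA", "DNA")]

    def protein_residues(self) -> list[Residue]:
        return [r for c in self.protein_chains for r in c.residues]

    def nucleic_atoms(self) -> list[Atom]:
        return [a for c in self.nucleic_chains for r in c.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def classify_chain(
    residues: Sequence[Residue],
    threshold: float = 0.8,
    aliases: dict[str, str] | None = None,
) -> Moltype:
    """Classify a chain by majority vote over residue names.

    A chain is ``protein``/``DNA``/``RNA`` if at least ``threshold`` of its
    residues carry (possibly alias-mapped) standard names of that type,
    otherwise ``other``.
    """
    if not residues:
        raise ValueError("cannot classify an empty residue list")
    alias = dict(PROTEIN_ALIASES)
    alias.update(DNA_ALIASES)
    alias.update(RNA_ALIASES)
    if aliases:
        alias.update(aliases)
    n = len(residues)
    counts = {"protein": 0, "DNA": 0, "RNA": 0}
    for r in residues:
        name = alias.get(r.name, r.name)
        if name in STANDARD_AMINO_ACIDS:
            counts["protein"] += 1
        elif name in DNA_NUCLEOTIDES:
            counts["DNA"] += 1
        elif name in RNA_NUCLEOTIDES:
            counts["RNA"] += 1
    best = max(counts, key=counts.__getitem__)
    if counts[best] / n >= threshold:
        return best  # type: ignore[return-value]
    return "other"


def detect_ca_only(residues: Sequence[Residue], tolerance: float = 0.95) -> bool:
    """True iff ≥ ``tolerance`` of residues carry only a Cα (heavy) atom.

    Chains deposited with alpha-carbon traces only cannot be annotated
    (no side-chain atoms for distances or SASA) and are excluded upstream.
    """
    if not residues:
        return False
    n_ca_only = 0
    for r in residues:
        heavy = {a.name for a in r.atoms if not a.is_hydrogen}
        if heavy == {"CA"}:
            n_ca_only += 1
    return n_ca_only / len(residues) >= tolerance


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if el and el != "X":
        return el
    # fall back to the first alphabetic character of the label
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _dedup_altlocs(raw: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom label: highest occupancy, ties first."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in raw:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[name] for name in order]


def parse_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    classify_threshold: float = 0.8,
    aliases: dict[str, str] | None = None,
) -> ComplexStructure:
    """Parse a PDB/mmCIF file into a :class:`ComplexStructure`.

    Loads all ATOM/HETATM records of the first model, removes waters,
    resolves alternate locations (highest occupancy wins) and classifies
    every chain.  Raises :class:`ParseError` on unreadable input and
    :class:`EmptyStructureError` if nothing remains after filtering.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    seen_keys: set[tuple[str, int, str]] = set()
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in WATER_NAMES or gres.is_water():
                continue
            raw = [
                Atom(
                    name=ga.name,
                    element=_element_of(ga),
                    coord=(ga.pos.x, ga.pos.y, ga.pos.z),
                    occupancy=float(ga.occ),
                    altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                )
                for ga in gres
            ]
            atoms = _dedup_altlocs(raw)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            key = (gchain.name, gres.seqid.num, icode)
            if key in seen_keys:
                raise ParseError(f"{path}: duplicate residue {key}")
            seen_keys.add(key)
            name = gres.name.strip()
            is_standard = (
                name in STANDARD_AMINO_ACIDS
                or name in DNA_NUCLEOTIDES
                or name in RNA_NUCLEOTIDES
            )
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_id=gres.seqid.num,
                    insertion_code=icode,
                    name=name,
                    atoms=atoms,
                    is_standard=is_standard,
                )
            )
        if residues:
            moltype = classify_chain(residues, threshold=classify_threshold, aliases=aliases)
            chains.append(Chain(chain_id=gchain.name, moltype=moltype, residues=residues))

    if not chains:
        raise EmptyStructureError(f"{path}: no atoms after removing waters")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ComplexStructure(id=path.stem, chains=chains, resolution=resolution)


def _pdb_atom_name(name: str) -> str:
    # Standard PDB alignment: 1-2 char element names start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write the internal model as normalized PDB text (3-decimal coords)."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            record = "ATOM  " if res.is_standard else "HETATM"
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:5d} {_pdb_atom_name(atom.name)}"
                    f"{atom.altloc or ' '}{res.name:>3s} {chain.chain_id[:1]}"
                    f"{res.seq_id:4d}{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.chain_id[:1]}{chain.residues[-1].seq_id:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def structure_summary(structure: ComplexStructure) -> dict:
    """JSON-serializable summary: chains, moltypes, residue/atom counts."""
    return {
        "id": structure.id,
        "resolution": structure.resolution,
        "n_atoms": structure.n_atoms,
        "chains": [
            {
                "chain_id": c.chain_id,
                "moltype": c.moltype,
                "n_residues": len(c.residues),
                "n_atoms": sum(len(r.atoms) for r in c.residues),
            }
            for c in structure.chains
        ],
    }
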