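"""Read PDB-format structure models and FASTA sequences; write TSV outputs.

The PDB reader is a deliberately small fixed-column parser with explicit,
documented policies (first coordinate model only, highest-occupancy altloc,
waters dropped at parse time, ligand HETATMs kept apart from the polymer)
rather than a general-purpose loader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

_WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

# 20 canonical residues, 1- and 3-letter
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

_VALID_SEQ_CHARS = frozenset(AA_ORDER) | {"X"}


class StructureIOError(Exception):
    """Base class for reader/writer failures."""


class PdbParseError(StructureIOError):
    """Malformed fixed-column PDB record; message names the line number."""


class EmptyStructureError(StructureIOError):
    """A PDB file with no ATOM records."""


class FastaValidationError(StructureIOError):
    """A FASTA record violating the sequence contract."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record after altloc resolution."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray  # (3,) float, Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_het: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def atom_id(self) -> tuple[str, int, str, str, str]:
        """(chain, residue_seq, insertion_code, residue_name, atom name)."""
        return (self.chain_id, self.residue_seq, self.insertion_code,
                self.residue_name, self.name)


@dataclass
class Residue:
    chain_id: str
    residue_seq: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """One protein model: polymer chains plus any non-water ligand atoms."""

    protein_id: str
    chains: dict[str, list[Residue]]
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    source_path: str = ""

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def iter_protein_atoms(self) -> Iterator[AtomRecord]:
        for res in self.iter_residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues()) + len(self.ligand_atoms)


@dataclass(frozen=True)
class SequenceRecord:
    protein_id: str
    annotation: str
    sequence: str
    flagged: bool = False  # sequence contains X (missing/ambiguous residue)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _infer_element(atom_name_field: str, residue_name: str, is_het: bool) -> str:
    """Infer element from PDB atom-name columns 13-16 when column 77-78 is blank.

    Columns 13-14 hold the element for standard right-justified names; a
    character in column 13 of a polymer atom name is part of a two-letter
    element only for a handful of cases we do not model, so the first
    alphabetic character wins for ATOM records.
    """
    stripped = atom_name_field.strip()
    if not stripped:
        return ""
    if not is_het:
        for ch in stripped:
            if ch.isalpha():
                return ch.upper()
        return ""
    # HETATM names like "FE" / "CL" start in column 13 for two-letter elements
    two = atom_name_field[:2].strip()
    if len(two) == 2 and two.isalpha():
        return two.upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    is_het = line.startswith("HETATM")
    try:
        serial = int(line[6:11])
        name_field = line[12:16]
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip()
        residue_seq = int(line[22:26])
        insertion_code = line[26].strip() if len(line) > 26 else ""
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip() if len(line) > 54 else ""
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) > 76 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {exc}"
        ) from exc
    if not element:
        element = _infer_element(name_field, residue_name, is_het)
    coords = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise PdbParseError(f"non-finite coordinates at line {lineno}")
    return AtomRecord(
        serial=serial,
        name=name_field.strip(),
        element=element,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_seq=residue_seq,
        insertion_code=insertion_code,
        coords=coords,
        occupancy=occupancy,
        altloc=altloc,
        is_het=is_het,
    )


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Parse a fixed-column PDB file into a :class:`StructureModel`.

    Policies (fixed; `altloc_policy` exists for interface stability and only
    accepts "highest_occupancy"):

    * only the first coordinate MODEL of a multi-model file is retained;
    * water residues (HOH/WAT/H2O/DOD) are dropped entirely;
    * for alternate locations the altloc with the highest occupancy is kept,
      ties resolved to the lexicographically first altloc identifier;
    * non-water HETATM records are collected separately as ligand atoms.
    """
    if altloc_policy != "highest_occupancy":
        raise ValueError(f"unsupported altloc policy: {altloc_policy!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureIOError(f"cannot read PDB file {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    in_first_model = True
    model_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if model_seen:
                in_first_model = False
            model_seen = True
        elif rec == "ENDMDL":
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if not in_first_model:
                continue
            atom = _parse_atom_line(line, lineno)
            if atom.residue_name in _WATER_NAMES:
                continue
            atoms.append(atom)

    if not any(not a.is_het for a in atoms):
        raise EmptyStructureError(f"no ATOM records in {path}")

    # altloc resolution: keep the best record per (chain, seq, icode, name)
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_seq, atom.insertion_code,
               atom.name, atom.is_het)
        cur = best.get(key)
        if cur is None:
            best[key] = atom
            order.append(key)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
                cur.occupancy, _altloc_rank(cur.altloc)):
            best[key] = atom

    chains: dict[str, list[Residue]] = {}
    residue_index: dict[tuple, Residue] = {}
    ligand_atoms: list[AtomRecord] = []
    for key in order:
        atom = best[key]
        if atom.is_het:
            ligand_atoms.append(atom)
            continue
        rkey = atom.residue_key
        res = residue_index.get(rkey)
        if res is None:
            res = Residue(atom.chain_id, atom.residue_seq,
                          atom.insertion_code, atom.residue_name)
            residue_index[rkey] = res
            chains.setdefault(atom.chain_id, []).append(res)
        res.atoms.append(atom)

    return StructureModel(
        protein_id=path.stem,
        chains=chains,
        ligand_atoms=ligand_atoms,
        source_path=str(path),
    )


def _altloc_rank(altloc: str) -> float:
    # higher is better; empty altloc outranks any letter, then reverse
    # lexicographic so that max() picks the lexicographically first letter
    if not altloc:
        return math.inf
    return -ord(altloc)


def _parse_fasta_id(header: str) -> tuple[str, str]:
    token, _, annotation = header.partition(" ")
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        token = parts[1]
    return token, annotation.strip()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; UniProt-style ``db|ID|name`` headers reduce to ID.

    Sequences are restricted to the 20 canonical letters plus X; an X marks
    the record as flagged (missing or ambiguous residue). Empty sequences and
    duplicate protein IDs are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            protein_id, annotation = _parse_fasta_id(header)
            seq = seq.upper().replace(" ", "")
            if not seq:
                raise FastaValidationError(
                    f"empty sequence for {protein_id!r} in {path}")
            bad = sorted(set(seq) - _VALID_SEQ_CHARS)
            if bad:
                raise FastaValidationError(
                    f"invalid sequence characters {bad} for {protein_id!r} in {path}")
            if protein_id in seen:
                raise FastaValidationError(
                    f"duplicate protein id {protein_id!r} in {path}")
            seen.add(protein_id)
            records.append(SequenceRecord(
                protein_id=protein_id,
                annotation=annotation,
                sequence=seq,
                flagged="X" in seq,
            ))
    return records


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_tsv(records: Sequence[Mapping] | Iterable[Mapping], path: str | Path) -> None:
    """Write a non-empty sequence of mappings as a deterministic TSV file.

    Rows are sorted by ``protein_id`` / ``term_id`` / the first column, floats
    are rendered with 6 significant digits, so re-writing the same records
    yields a byte-identical file.
    """
    rows = [dict(r) for r in records]
    if not rows:
        raise ValueError("refusing to write an empty table")
    columns = list(rows[0].keys())
    sort_key = next((c for c in ("protein_id", "term_id") if c in columns),
                    columns[0])
    rows.sort(key=lambda r: str(r[sort_key]))
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as out:
            out.write("\t".join(columns) + "\n")
            for row in rows:
                out.write("\t".join(_format_value(row[c]) for c in columns) + "\n")
    except OSError as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc
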