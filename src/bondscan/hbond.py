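"""Hydrogen-bond enumeration under pure distance criteria.

A bond is any donor heavy atom / acceptor heavy atom pair within the
donor-acceptor cutoff (3.5 A by default, inclusive). No angle term. When the
model carries explicit hydrogens, an additional hydrogen-acceptor cutoff
(2.5 A) applies; crystallographic and homology models normally have none, in
which case the heavy-atom criterion alone decides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from bondscan.structure_io import AtomRecord, StructureModel

logger = logging.getLogger(__name__)

#: side-chain donor atoms per residue; backbone N is added for all but PRO
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

#: side-chain acceptor atoms; backbone O/OXT added for every residue
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

_SULFUR_DONORS = {"CYS": frozenset({"SG"})}
_SULFUR_ACCEPTORS = {"MET": frozenset({"SD"})}

_CANONICAL = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


@dataclass(frozen=True)
class HbondParams:
    max_donor_acceptor: float = 3.5
    max_hydrogen_acceptor: float = 2.5
    use_explicit_hydrogens: str = "auto"  # auto | always | never
    include_sulfur: bool = False
    include_ligand: bool = True

    def __post_init__(self) -> None:
        if self.max_donor_acceptor <= 0 or self.max_hydrogen_acceptor <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.max_hydrogen_acceptor >= self.max_donor_acceptor:
            raise ValueError(
                "max_hydrogen_acceptor must be smaller than max_donor_acceptor")
        if self.use_explicit_hydrogens not in ("auto", "always", "never"):
            raise ValueError(
                f"unknown hydrogen policy {self.use_explicit_hydrogens!r}")


@dataclass(frozen=True)
class ContactPair:
    """One detected hydrogen bond or salt bridge."""

    kind: str  # "hbond" | "saltbridge"
    donor_atom: tuple[str, int, str, str, str]
    acceptor_atom: tuple[str, int, str, str, str]
    distance: float
    involves_ligand: bool = False

    def as_row(self) -> dict:
        d, a = self.donor_atom, self.acceptor_atom
        return {
            "kind": self.kind,
            "donor_chain": d[0], "donor_seq": d[1], "donor_icode": d[2],
            "donor_res": d[3], "donor_atom": d[4],
            "acceptor_chain": a[0], "acceptor_seq": a[1], "acceptor_icode": a[2],
            "acceptor_res": a[3], "acceptor_atom": a[4],
            "distance": round(self.distance, 4),
            "involves_ligand": self.involves_ligand,
        }


def donor_atoms(residue_name: str, include_sulfur: bool = False) -> frozenset[str]:
    """Donor heavy-atom names for a canonical residue (backbone N included,
    except proline whose backbone nitrogen carries no hydrogen)."""
    if residue_name not in _CANONICAL:
        logger.warning("unknown residue name %r: no donors assigned", residue_name)
        return frozenset()
    names = set() if residue_name == "PRO" else {"N"}
    names |= SIDECHAIN_DONORS.get(residue_name, frozenset())
    if include_sulfur:
        names |= _SULFUR_DONORS.get(residue_name, frozenset())
    return frozenset(names)


def acceptor_atoms(residue_name: str, include_sulfur: bool = False) -> frozenset[str]:
    """Acceptor heavy-atom names (backbone carbonyl O plus terminal OXT always)."""
    if residue_name not in _CANONICAL:
        logger.warning("unknown residue name %r: no acceptors assigned", residue_name)
        return frozenset()
    names = {"O", "OXT"}
    names |= SIDECHAIN_ACCEPTORS.get(residue_name, frozenset())
    if include_sulfur:
        names |= _SULFUR_ACCEPTORS.get(residue_name, frozenset())
    return frozenset(names)


def _is_hydrogen(atom: AtomRecord) -> bool:
    return atom.element in ("H", "D")


def _collect_candidates(model: StructureModel, params: HbondParams):
    """Return (donors, acceptors) atom lists plus bookkeeping maps."""
    donors: list[AtomRecord] = []
    acceptors: list[AtomRecord] = []
    for res in model.iter_residues():
        dn = donor_atoms(res.name, params.include_sulfur)
        an = acceptor_atoms(res.name, params.include_sulfur)
        for atom in res.atoms:
            if atom.name in dn:
                donors.append(atom)
            if atom.name in an:
                acceptors.append(atom)
    if params.include_ligand:
        for atom in model.ligand_atoms:
            if atom.element in ("N", "O"):
                donors.append(atom)
                acceptors.append(atom)
    return donors, acceptors


def _chain_predecessor_map(model: StructureModel) -> dict[tuple, tuple]:
    """Map residue key -> key of the residue immediately before it in its chain."""
    pred: dict[tuple, tuple] = {}
    for residues in model.chains.values():
        for prev, cur in zip(residues, residues[1:]):
            pred[cur.key] = prev.key
    return pred


def _hydrogens_by_residue(model: StructureModel) -> dict[tuple, list[AtomRecord]]:
    table: dict[tuple, list[AtomRecord]] = {}
    for atom in model.iter_protein_atoms():
        if _is_hydrogen(atom):
            table.setdefault(atom.residue_key, []).append(atom)
    for atom in model.ligand_atoms:
        if _is_hydrogen(atom):
            table.setdefault(atom.residue_key, []).append(atom)
    return table


def detect_hbonds(model: StructureModel,
                  params: HbondParams | None = None) -> list[ContactPair]:
    """Enumerate hydrogen bonds in a model.

    Exclusions: intra-residue pairs, and the backbone amide N of residue *i*
    paired with the carbonyl O of residue *i-1* in the same chain (the only
    inter-residue donor-acceptor pair within two covalent bonds of the
    polypeptide). Each unordered atom pair is reported exactly once even when
    both atoms are bifunctional.
    """
    if params is None:
        params = HbondParams()
    donors, acceptors = _collect_candidates(model, params)
    if not donors or not acceptors:
        return []

    d_coords = np.array([a.coords for a in donors])
    a_coords = np.array([a.coords for a in acceptors])
    if not (np.all(np.isfinite(d_coords)) and np.all(np.isfinite(a_coords))):
        raise ValueError("model contains non-finite coordinates")

    hydrogens = _hydrogens_by_residue(model)
    any_h = bool(hydrogens)
    check_h = (params.use_explicit_hydrogens == "always"
               or (params.use_explicit_hydrogens == "auto" and any_h))

    pred = _chain_predecessor_map(model)

    tree = cKDTree(a_coords)
    neighbor_lists = tree.query_ball_point(d_coords, params.max_donor_acceptor)

    seen: set[frozenset] = set()
    out: list[ContactPair] = []
    for di, aidx in enumerate(neighbor_lists):
        donor = donors[di]
        for ai in aidx:
            acceptor = acceptors[ai]
            if donor.residue_key == acceptor.residue_key:
                continue
            # peptide-bond covalent pair: N(i) -> O(i-1), same chain
            if (donor.name == "N" and acceptor.name == "O"
                    and not donor.is_het and not acceptor.is_het
                    and pred.get(donor.residue_key) == acceptor.residue_key):
                continue
            pair_key = frozenset((donor.atom_id, acceptor.atom_id))
            if pair_key in seen:
                continue
            if check_h:
                hs = [h for h in hydrogens.get(donor.residue_key, [])
                      if np.linalg.norm(h.coords - donor.coords) <= 1.3]
                if hs:
                    if not any(np.linalg.norm(h.coords - acceptor.coords)
                               <= params.max_hydrogen_acceptor for h in hs):
                        continue
                elif params.use_explicit_hydrogens == "always":
                    continue
            seen.add(pair_key)
            dist = float(np.linalg.norm(donor.coords - acceptor.coords))
            out.append(ContactPair(
                kind="hbond",
                donor_atom=donor.atom_id,
                acceptor_atom=acceptor.atom_id,
                distance=dist,
                involves_ligand=donor.is_het or acceptor.is_het,
            ))
    out.sort(key=lambda c: (c.donor_atom, c.acceptor_atom))
    return out
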