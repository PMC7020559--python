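"""Salt-bridge enumeration.

A bridge exists when an Asp/Glu side-chain carboxyl oxygen and an
Arg/Lys/His side-chain nitrogen lie within the cutoff (4.0 A, inclusive).
Counting defaults to one event per residue pair; atom-pair counting is
available to mirror tools that report every qualifying atom contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bondscan.hbond import ContactPair
from bondscan.structure_io import StructureModel

ACIDIC_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

BASIC_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NH1", "NH2", "NE"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}


@dataclass(frozen=True)
class SaltbridgeParams:
    max_distance: float = 4.0
    counting_unit: str = "residue_pair"  # residue_pair | atom_pair
    include_his: bool = True

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.counting_unit not in ("residue_pair", "atom_pair"):
            raise ValueError(f"unknown counting unit {self.counting_unit!r}")


def detect_salt_bridges(model: StructureModel,
                        params: SaltbridgeParams | None = None) -> list[ContactPair]:
    """Enumerate salt bridges; ligand atoms never participate.

    In ``residue_pair`` mode each (acidic residue, basic residue) pair with at
    least one qualifying O-N contact yields one ContactPair carrying the
    minimum-distance atom pair; ``atom_pair`` mode reports every qualifying
    O-N contact. Donor is the basic nitrogen, acceptor the carboxyl oxygen.
    """
    if params is None:
        params = SaltbridgeParams()

    acid_atoms = []
    base_atoms = []
    for res in model.iter_residues():
        if res.name in ACIDIC_ATOMS:
            wanted = ACIDIC_ATOMS[res.name]
            acid_atoms.extend(a for a in res.atoms if a.name in wanted)
        elif res.name in BASIC_ATOMS:
            if res.name == "HIS" and not params.include_his:
                continue
            wanted = BASIC_ATOMS[res.name]
            base_atoms.extend(a for a in res.atoms if a.name in wanted)
    if not acid_atoms or not base_atoms:
        return []

    o_coords = np.array([a.coords for a in acid_atoms])
    n_coords = np.array([a.coords for a in base_atoms])
    if not (np.all(np.isfinite(o_coords)) and np.all(np.isfinite(n_coords))):
        raise ValueError("model contains non-finite coordinates")

    dists = np.linalg.norm(o_coords[:, None, :] - n_coords[None, :, :], axis=2)
    oi, ni = np.nonzero(dists <= params.max_distance)

    if params.counting_unit == "atom_pair":
        pairs = [
            ContactPair(
                kind="saltbridge",
                donor_atom=base_atoms[j].atom_id,
                acceptor_atom=acid_atoms[i].atom_id,
                distance=float(dists[i, j]),
            )
            for i, j in zip(oi, ni)
        ]
        pairs.sort(key=lambda c: (c.donor_atom, c.acceptor_atom))
        return pairs

    best: dict[tuple, tuple[float, int, int]] = {}
    for i, j in zip(oi, ni):
        rkey = (acid_atoms[i].residue_key, base_atoms[j].residue_key)
        d = float(dists[i, j])
        cur = best.get(rkey)
        if cur is None or (d, acid_atoms[i].name, base_atoms[j].name) < (
                cur[0], acid_atoms[cur[1]].name, base_atoms[cur[2]].name):
            best[rkey] = (d, i, j)
    pairs = [
        ContactPair(
            kind="saltbridge",
            donor_atom=base_atoms[j].atom_id,
            acceptor_atom=acid_atoms[i].atom_id,
            distance=d,
        )
        for d, i, j in best.values()
    ]
    pairs.sort(key=lambda c: (c.donor_atom, c.acceptor_atom))
    return pairs
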