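import numpy as np
import pytest

from bondscan.hbond import acceptor_atoms, donor_atoms
from bondscan.saltbridge import ACIDIC_ATOMS, BASIC_ATOMS
from bondscan.structure_io import AtomRecord, Residue, StructureModel


def make_atom(name, resname, chain, seq, xyz, serial=1, is_het=False,
              element=None, occupancy=1.0, altloc="", icode=""):
    return AtomRecord(
        serial=serial, name=name,
        element=element if element is not None else name[0],
        residue_name=resname, chain_id=chain, residue_seq=seq,
        insertion_code=icode, coords=np.asarray(xyz, dtype=float),
        occupancy=occupancy, altloc=altloc, is_het=is_het,
    )


def make_model(atom_specs, protein_id="test", ligand_specs=()):
    """Build a StructureModel from (name, resname, chain, seq, xyz) tuples."""
    chains = {}
    index = {}
    serial = 1
    for name, resname, chain, seq, xyz in atom_specs:
        key = (chain, seq)
        if key not in index:
            res = Residue(chain, seq, "", resname)
            index[key] = res
            chains.setdefault(chain, []).append(res)
        index[key].atoms.append(
            make_atom(name, resname, chain, seq, xyz, serial=serial))
        serial += 1
    ligands = [
        make_atom(name, resname, chain, seq, xyz, serial=1000 + i,
                  is_het=True, element=element)
        for i, (name, resname, chain, seq, xyz, element) in enumerate(ligand_specs)
    ]
    return StructureModel(protein_id=protein_id, chains=chains,
                          ligand_atoms=ligands)


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain double loops, no spatial index)

def brute_force_hbonds(model, max_da=3.5):
    """All-pairs donor/acceptor enumeration, unordered pairs counted once."""
    entries = []
    for res in enumerate_residues(model):
        dn = donor_atoms(res.name)
        an = acceptor_atoms(res.name)
        for atom in res.atoms:
            entries.append((atom, atom.name in dn, atom.name in an))
    for atom in model.ligand_atoms:
        if atom.element in ("N", "O"):
            entries.append((atom, True, True))

    order = {}  # residue key -> (chain, index) for peptide-bond exclusion
    for residues in model.chains.values():
        for i, res in enumerate(residues):
            order[res.key] = (res.chain_id, i)

    found = set()
    for a, a_don, a_acc in entries:
        for b, b_don, b_acc in entries:
            if a is b or a.residue_key == b.residue_key:
                continue
            if not ((a_don and b_acc) or (b_don and a_acc)):
                continue
            d = float(np.sqrt(((a.coords - b.coords) ** 2).sum()))
            if d > max_da:
                continue
            if _peptide_pair(a, b, order) or _peptide_pair(b, a, order):
                continue
            found.add(frozenset((a.atom_id, b.atom_id)))
    return found


def _peptide_pair(donor, acceptor, order):
    if donor.name != "N" or acceptor.name != "O":
        return False
    if donor.is_het or acceptor.is_het:
        return False
    cd = order.get(donor.residue_key)
    ca = order.get(acceptor.residue_key)
    return cd is not None and ca is not None and cd[0] == ca[0] and cd[1] - ca[1] == 1


def enumerate_residues(model):
    for residues in model.chains.values():
        yield from residues


def brute_force_salt_bridges(model, max_distance=4.0, include_his=True,
                             unit="residue_pair"):
    acids, bases = [], []
    for res in enumerate_residues(model):
        if res.name in ACIDIC_ATOMS:
            acids.extend(a for a in res.atoms if a.name in ACIDIC_ATOMS[res.name])
        if res.name in BASIC_ATOMS and (include_his or res.name != "HIS"):
            bases.extend(a for a in res.atoms if a.name in BASIC_ATOMS[res.name])
    atom_pairs = set()
    residue_pairs = set()
    for o in acids:
        for n in bases:
            d = float(np.sqrt(((o.coords - n.coords) ** 2).sum()))
            if d <= max_distance:
                atom_pairs.add((o.atom_id, n.atom_id))
                residue_pairs.add((o.residue_key, n.residue_key))
    return atom_pairs if unit == "atom_pair" else residue_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
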