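"""Generators for test inputs: ideal helices, salt-bridge dimers, random
structures, and two-species proteome ensembles with planted effects.

Every structural generator verifies its own geometric guarantee by brute
force before returning, so downstream bond-detection tests rest on checked
coordinates rather than trusted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bondscan.hbond import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
from bondscan.structure_io import (
    AA_ORDER,
    AA_ONE_TO_THREE,
    AtomRecord,
    Residue,
    SequenceRecord,
    StructureModel,
)

# ---------------------------------------------------------------------------
# geometry helpers

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond_length,
    angle(b,c,d) = bond_angle, dihedral(a,b,c,d) = torsion."""
    theta = math.radians(bond_angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * math.cos(theta),
        bond_length * math.sin(theta) * math.cos(chi),
        bond_length * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _atom(serial: int, name: str, resname: str, chain: str, seq: int,
          coords: np.ndarray, is_het: bool = False) -> AtomRecord:
    return AtomRecord(
        serial=serial, name=name, element=name[0], residue_name=resname,
        chain_id=chain, residue_seq=seq, insertion_code="",
        coords=np.asarray(coords, dtype=float), is_het=is_het,
    )


def model_to_pdb(model: StructureModel) -> str:
    """Serialize a model to fixed-column PDB text (ATOM/HETATM/TER/END)."""
    lines = []
    for res in model.iter_residues():
        for a in res.atoms:
            lines.append(_pdb_line("ATOM", a))
    lines.append("TER")
    for a in model.ligand_atoms:
        lines.append(_pdb_line("HETATM", a))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_line(record: str, a: AtomRecord) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (f"{record:<6s}{a.serial:>5d} {name}{a.altloc or ' '}"
            f"{a.residue_name:>3s} {a.chain_id}{a.residue_seq:>4d}"
            f"{a.insertion_code or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}")


# ---------------------------------------------------------------------------
# ideal alpha helix

# ideal backbone internal coordinates
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
# torsions sit at the tight end of the alpha-helical basin: with textbook
# (-57, -47) the i,i+2 N-O distance dips to ~3.37 A and would register as a
# spurious bond under a 3.5 A distance-only criterion; (-66, -44) keeps every
# non-(i,i+4) backbone N-O pair above 3.5 A while i,i+4 stays near 2.9 A
_PHI, _PSI, _OMEGA = -66.0, -44.0, 180.0


def make_ideal_helix(n_res: int, sequence: str | None = None) -> StructureModel:
    """Ideal poly-Ala alpha-helix backbone (N, CA, C, O per residue).

    Guarantees, verified by brute force on the generated coordinates: every
    i -> i+4 N-O distance lies in [2.8, 3.3] A and every other backbone N-O
    pair beyond the covalent exclusion is farther than 3.5 A, so distance-only
    bond detection must find exactly n_res - 4 backbone hydrogen bonds.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues for one helical turn")
    if sequence is not None:
        if len(sequence) != n_res:
            raise ValueError("sequence length must equal n_res")
        if any(ch not in AA_ONE_TO_THREE for ch in sequence):
            raise ValueError("sequence must use canonical 1-letter codes")
        if "P" in sequence or "G" in sequence:
            raise ValueError("Pro/Gly break ideal helical geometry")
    else:
        sequence = "A" * n_res

    # seed residue: N at origin, CA on x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([_N_CA, 0.0, 0.0])
    th = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _CA_C * np.array([-math.cos(th), math.sin(th), 0.0])

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _C_N, _ANG_CA_C_N, _PSI)
        ca_i = place_atom(ca_prev, c_prev, n_i, _N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, _CA_C, _ANG_N_CA_C, _PHI)
        backbone.append((n_i, ca_i, c_i))

    chains: dict[str, list[Residue]] = {"A": []}
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        resname = AA_ONE_TO_THREE[sequence[i]]
        if i + 1 < n_res:
            n_next = backbone[i + 1][0]
            o_i = place_atom(n_next, ca_i, c_i, _C_O, _ANG_CA_C_O, 180.0)
        else:  # C-terminal carbonyl: torsion from psi continuation
            o_i = place_atom(n_i, ca_i, c_i, _C_O, _ANG_CA_C_O, _PSI + 180.0)
        res = Residue("A", i + 1, "", resname)
        for name, xyz in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)):
            res.atoms.append(_atom(serial, name, resname, "A", i + 1, xyz))
            serial += 1
        chains["A"].append(res)

    model = StructureModel(protein_id=f"helix{n_res}", chains=chains)
    _verify_helix(model, n_res)
    return model


def _verify_helix(model: StructureModel, n_res: int) -> None:
    residues = model.chains["A"]
    n_xyz = [r.atom("N").coords for r in residues]
    o_xyz = [r.atom("O").coords for r in residues]
    for i in range(n_res):
        for j in range(n_res):
            if i == j or j == i - 1:  # intra-residue / peptide-bond pair
                continue
            d = float(np.linalg.norm(n_xyz[i] - o_xyz[j]))
            if i - j == 4:
                if not 2.8 <= d <= 3.3:
                    raise AssertionError(
                        f"helix guarantee violated: N{i+1}-O{j+1} = {d:.3f}")
            elif d <= 3.5:
                raise AssertionError(
                    f"helix guarantee violated: N{i+1}-O{j+1} = {d:.3f} <= 3.5")


# ---------------------------------------------------------------------------
# salt-bridge dimer

# residue templates are built as planar zig-zag chains extending toward +x;
# the last main-chain atom is the "tip" functional atom. Branch atoms hang
# off a parent with a fixed offset that keeps them behind the tip.
_MAIN_CHAINS: dict[str, list[str]] = {
    "ASP": ["N", "CA", "CB", "CG", "OD1"],
    "GLU": ["N", "CA", "CB", "CG", "CD", "OE1"],
    "LYS": ["N", "CA", "CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["N", "CA", "CB", "CG", "CD", "NE", "CZ", "NH1"],
    "HIS": ["N", "CA", "CB", "CG", "ND1"],
}
_BRANCHES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    # (atom, parent, offset); offsets keep x at or behind the parent
    "ASP": [("OD2", "CG", (0.0, -1.25, 0.0))],
    "GLU": [("OE2", "CD", (0.0, -1.25, 0.0))],
    "LYS": [],
    "ARG": [("NH2", "CZ", (-0.4, -1.25, 0.0))],
    "HIS": [("CD2", "CG", (0.0, -1.4, 0.0)),
            ("CE1", "ND1", (-0.5, 1.25, 0.0)),
            ("NE2", "CD2", (-0.5, 1.1, 0.8))],
}
_TIP = {"ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1", "HIS": "ND1"}

_ACID_ON = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASE_ON = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}


def _residue_template(resname: str) -> dict[str, np.ndarray]:
    """Zig-zag main chain (1.52 A steps, ~109.5 deg) plus branches; backbone
    C/O hang below CA, well behind the tip."""
    coords: dict[str, np.ndarray] = {}
    step = 1.52
    half = math.radians(109.5 / 2.0)
    pos = np.zeros(3)
    for k, name in enumerate(_MAIN_CHAINS[resname]):
        if k > 0:
            sign = 1.0 if k % 2 else -1.0
            pos = pos + step * np.array(
                [math.sin(half), sign * math.cos(half), 0.0])
        coords[name] = pos.copy()
    for name, parent, offset in _BRANCHES[resname]:
        coords[name] = coords[parent] + np.array(offset)
    coords["C"] = coords["CA"] + np.array([-0.52, -1.43, 0.0])
    coords["O"] = coords["C"] + np.array([-1.05, -0.64, 0.0])
    return coords


def make_salt_bridge_dimer(acid: str, base: str,
                           distance: float) -> StructureModel:
    """Two full-side-chain residues on separate chains, with the minimum
    acid-carboxyl-O to basic-N distance equal to ``distance`` (to 1e-3 A) and
    every other inter-residue O-N distance strictly larger (verified)."""
    if acid not in _ACID_ON or base not in _BASE_ON:
        raise ValueError(f"unsupported pair {acid}/{base}")
    if distance <= 0:
        raise ValueError("distance must be positive")
    if distance < 2.0:
        raise ValueError("requested distance clashes with van der Waals radii")

    acid_xyz = _residue_template(acid)
    base_xyz = _residue_template(base)
    # put the acid tip exactly at the origin so the bridge vector is exactly
    # (distance, 0, 0) and the reported distance is exact in fp
    tip_shift = acid_xyz[_TIP[acid]].copy()
    acid_xyz = {name: xyz - tip_shift for name, xyz in acid_xyz.items()}
    acid_xyz[_TIP[acid]] = np.zeros(3)

    # mirror the base residue through x so its chain extends toward -x, then
    # translate its tip onto the +x axis at the requested separation
    target = np.array([distance, 0.0, 0.0])
    tip_b = base_xyz[_TIP[base]]
    mirrored = {name: np.array([-xyz[0], xyz[1], xyz[2]])
                for name, xyz in base_xyz.items()}
    offset = target - mirrored[_TIP[base]]
    base_placed = {name: xyz + offset for name, xyz in mirrored.items()}
    # pin the tip exactly so the bridge distance is exact to fp precision
    base_placed[_TIP[base]] = target.copy()

    chains: dict[str, list[Residue]] = {}
    serial = 1
    for chain_id, resname, xyz_map, seq in (
            ("A", acid, acid_xyz, 1), ("B", base, base_placed, 1)):
        res = Residue(chain_id, seq, "", resname)
        for name in sorted(xyz_map, key=_atom_sort_key):
            res.atoms.append(_atom(serial, name, resname, chain_id, seq,
                                   xyz_map[name]))
            serial += 1
        chains[chain_id] = [res]
    model = StructureModel(protein_id=f"{acid.lower()}_{base.lower()}_dimer",
                           chains=chains)
    _verify_dimer(model, acid, base, distance)
    return model


def _atom_sort_key(name: str) -> tuple[int, str]:
    order = {"N": 0, "CA": 1, "C": 2, "O": 3}
    return (order.get(name, 4), name)


def _verify_dimer(model: StructureModel, acid: str, base: str,
                  distance: float) -> None:
    res_a = model.chains["A"][0]
    res_b = model.chains["B"][0]
    bridge_pairs = []
    other_pairs = []
    for a in res_a.atoms:
        for b in res_b.atoms:
            if a.element not in "ON" or b.element not in "ON":
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if a.name in _ACID_ON[acid] and b.name in _BASE_ON[base]:
                bridge_pairs.append(d)
            else:
                other_pairs.append(d)
    dmin = min(bridge_pairs)
    if abs(dmin - distance) > 1e-3:
        raise AssertionError(f"dimer min O-N distance {dmin:.4f} != {distance}")
    floor = min(other_pairs + [d for d in bridge_pairs if d > dmin + 1e-9])
    if floor <= dmin:
        raise AssertionError("non-bridge O-N pair at or inside the bridge distance")


# ---------------------------------------------------------------------------
# random structures (oracle fodder)

_RANDOM_RESIDUES = tuple(AA_ONE_TO_THREE[aa] for aa in AA_ORDER)


def make_random_structure(n_residues: int, seed: int,
                          density: float = 0.01,
                          n_chains: int = 2) -> StructureModel:
    """Random residues with their donor/acceptor/bridge atoms scattered in a
    box; no realistic geometry, intended purely as brute-force-oracle input."""
    rng = np.random.default_rng(seed)
    box = (max(n_residues * 6, 10) / density) ** (1.0 / 3.0)
    chains: dict[str, list[Residue]] = {}
    serial = 1
    for i in range(n_residues):
        chain_id = chr(ord("A") + int(rng.integers(n_chains)))
        resname = str(rng.choice(_RANDOM_RESIDUES))
        seq = i + 1
        res = Residue(chain_id, seq, "", resname)
        names = {"N", "CA", "C", "O"}
        names |= SIDECHAIN_DONORS.get(resname, frozenset())
        names |= SIDECHAIN_ACCEPTORS.get(resname, frozenset())
        from bondscan.saltbridge import ACIDIC_ATOMS, BASIC_ATOMS
        names |= ACIDIC_ATOMS.get(resname, frozenset())
        names |= BASIC_ATOMS.get(resname, frozenset())
        for name in sorted(names):
            xyz = rng.uniform(0, box, size=3)
            res.atoms.append(_atom(serial, name, resname, chain_id, seq, xyz))
            serial += 1
        chains.setdefault(chain_id, []).append(res)
    return StructureModel(protein_id=f"random{n_residues}_{seed}",
                          chains=chains)


# ---------------------------------------------------------------------------
# two-species ensembles

@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a reproducible two-species synthetic proteome."""

    n_proteins: int = 50
    length_min: int = 80
    length_max: int = 200
    base_freqs: tuple[float, ...] = tuple([1.0 / 20] * 20)  # AA_ORDER
    freq_shift_a: dict[str, float] = field(default_factory=dict)
    freq_shift_b: dict[str, float] = field(default_factory=dict)
    # bond-rate model: per-protein rates drawn uniformly
    hbond_rate_range: tuple[float, float] = (1.0, 4.0)
    saltbridge_rate_range: tuple[float, float] = (0.02, 0.14)
    # planted effect: multiply bond rates of the top `top_fraction` of
    # species A (ranked by rate) by `top_inflation`
    top_fraction: float = 0.0
    top_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or len(self.base_freqs) != 20:
            raise ValueError("base_freqs must be a 20-vector summing to 1")
        if not 0.0 <= self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("bad length range")


@dataclass(frozen=True)
class SimProtein:
    protein_id: str
    annotation: str
    sequence: str
    qmean: float
    n_hbonds: int
    n_saltbridges: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sequence_record(self) -> SequenceRecord:
        return SequenceRecord(self.protein_id, self.annotation, self.sequence)


@dataclass(frozen=True)
class Ensemble:
    spec: EnsembleSpec
    species_a: tuple[SimProtein, ...]
    species_b: tuple[SimProtein, ...]
    truth: dict

    def fasta_text(self, species: str) -> str:
        prots = self.species_a if species == "a" else self.species_b
        chunks = []
        for p in prots:
            seq = "\n".join(p.sequence[i:i + 60]
                            for i in range(0, len(p.sequence), 60))
            chunks.append(f">{p.protein_id} {p.annotation}\n{seq}\n")
        return "".join(chunks)

    def qmean_rows(self) -> list[dict]:
        return [
            {"protein_id": p.protein_id, "qmean": p.qmean}
            for p in self.species_a + self.species_b
        ]

    def truth_rows(self) -> list[dict]:
        return [{"key": k, "value": v} for k, v in sorted(self.truth.items())]


def _shifted_freqs(base: Sequence[float], shift: dict[str, float]) -> np.ndarray:
    freqs = np.array(base, dtype=float)
    for aa, delta in shift.items():
        freqs[AA_ORDER.index(aa)] += delta
    if np.any(freqs < 0):
        raise ValueError("frequency shift drives a frequency negative")
    return freqs / freqs.sum()


def _make_species(rng: np.random.Generator, spec: EnsembleSpec, label: str,
                  freqs: np.ndarray, inflate_top: bool) -> tuple[SimProtein, ...]:
    n = spec.n_proteins
    lengths = rng.integers(spec.length_min, spec.length_max + 1, size=n)
    letters = np.array(list(AA_ORDER))
    hb_rates = rng.uniform(*spec.hbond_rate_range, size=n)
    sb_rates = rng.uniform(*spec.saltbridge_rate_range, size=n)
    if inflate_top and spec.top_fraction > 0 and spec.top_inflation != 1.0:
        k = math.ceil(spec.top_fraction * n)
        top_hb = np.argsort(-hb_rates)[:k]
        top_sb = np.argsort(-sb_rates)[:k]
        hb_rates[top_hb] *= spec.top_inflation
        sb_rates[top_sb] *= spec.top_inflation
    qmeans = rng.uniform(-4.5, 0.0, size=n)
    prots = []
    for i in range(n):
        seq = "".join(rng.choice(letters, size=int(lengths[i]), p=freqs))
        prots.append(SimProtein(
            protein_id=f"{label.upper()}{i:05d}",
            annotation=f"synthetic protein {label}-{i}",
            sequence=seq,
            qmean=float(round(qmeans[i], 3)),
            n_hbonds=int(round(hb_rates[i] * lengths[i])),
            n_saltbridges=int(round(sb_rates[i] * lengths[i])),
        ))
    return tuple(prots)


def make_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Generate a two-species proteome ensemble; pure function of spec + seed.

    The truth record states which comparisons a correctly working pipeline is
    expected to flag: when bond rates are inflated only in the top fraction of
    species A, upper-quantile Mann-Whitney comparisons should reject while the
    full-set comparison generally should not.
    """
    rng = np.random.default_rng(spec.seed)
    freqs_a = _shifted_freqs(spec.base_freqs, spec.freq_shift_a)
    freqs_b = _shifted_freqs(spec.base_freqs, spec.freq_shift_b)
    species_a = _make_species(rng, spec, "a", freqs_a, inflate_top=True)
    species_b = _make_species(rng, spec, "b", freqs_b, inflate_top=False)
    planted_bond_effect = spec.top_fraction > 0 and spec.top_inflation != 1.0
    planted_freq_effect = bool(spec.freq_shift_a or spec.freq_shift_b)
    truth = {
        "planted_bond_effect": planted_bond_effect,
        "planted_freq_effect": planted_freq_effect,
        "expect_upper_quantile_reject": planted_bond_effect,
        "expect_full_set_reject": False,
        "expect_chi_square_reject": planted_freq_effect,
        "top_fraction": spec.top_fraction,
        "top_inflation": spec.top_inflation,
        "seed": spec.seed,
    }
    return Ensemble(spec=spec, species_a=species_a, species_b=species_b,
                    truth=truth)
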