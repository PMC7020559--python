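"""Amino-acid composition accounting and residue-property correlations.

Observed counts per residue per species feed a 20x2 chi-square test of
independence; deviations (observed - expected, on raw counts) are then
correlated against residue hydrophobicity and volume ranks. The default rank
tables are derived in code from the Kyte-Doolittle hydrophobicity scale and
the Zamyatnin residue volumes; both are user-replaceable because different
published scales order a few residues differently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from bondscan.stats import ChiSquareResult, CorrelationResult, chi_square_independence, spearman_rho
from bondscan.structure_io import AA_ORDER, SequenceRecord

logger = logging.getLogger(__name__)

#: the 11 residues most likely to form conventional hydrogen bonds
#: (hydroxyl, amide, aromatic N/O, charged groups)
HBOND_PRONE = frozenset("STNQHYWDERK")
POSITIVE = frozenset("RKH")
NEGATIVE = frozenset("DE")

# Kyte-Doolittle hydropathy values (more positive = more hydrophobic)
_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Zamyatnin residue volumes, A^3
_VOLUMES = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}


def _ranks_from_values(values: Mapping[str, float]) -> dict[str, int]:
    """Rank 1 = largest value; ties broken alphabetically (deterministic)."""
    ordered = sorted(values, key=lambda aa: (-values[aa], aa))
    return {aa: i + 1 for i, aa in enumerate(ordered)}


@dataclass(frozen=True)
class PropertyRanks:
    hydrophobicity_rank: Mapping[str, int]
    volume_rank: Mapping[str, int]
    provenance: str

    def __post_init__(self) -> None:
        for name, table in (("hydrophobicity", self.hydrophobicity_rank),
                            ("volume", self.volume_rank)):
            if sorted(table.get(aa) for aa in AA_ORDER) != list(range(1, 21)):
                raise ValueError(f"{name} ranks must be a permutation of 1..20")

    def rank_vector(self, which: str) -> np.ndarray:
        if which == "hydrophobicity":
            table = self.hydrophobicity_rank
        elif which == "volume":
            table = self.volume_rank
        else:
            raise ValueError(f"unknown property {which!r}")
        return np.array([table[aa] for aa in AA_ORDER], dtype=float)


def default_ranks() -> PropertyRanks:
    return PropertyRanks(
        hydrophobicity_rank=_ranks_from_values(_KYTE_DOOLITTLE),
        volume_rank=_ranks_from_values(_VOLUMES),
        provenance=("hydrophobicity: Kyte-Doolittle hydropathy, rank 1 = most "
                    "hydrophobic, ties alphabetical; volume: Zamyatnin residue "
                    "volumes, rank 1 = largest"),
    )


def load_ranks(hydro_path: str | Path, volume_path: str | Path) -> PropertyRanks:
    """Load (residue, rank) pairs from two two-column TSV files."""

    def _load(path: str | Path) -> dict[str, int]:
        table: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            table[parts[0].strip()] = int(parts[1])
        return table

    return PropertyRanks(
        hydrophobicity_rank=_load(hydro_path),
        volume_rank=_load(volume_path),
        provenance=f"user-supplied: {hydro_path}, {volume_path}",
    )


@dataclass
class UsageTable:
    """20-residue x 2-species composition table with chi-square results."""

    residues: str  # AA_ORDER
    observed_a: np.ndarray
    observed_b: np.ndarray
    expected_a: np.ndarray
    expected_b: np.ndarray
    chi2: ChiSquareResult
    n_excluded_x_a: int = 0
    n_excluded_x_b: int = 0
    label_a: str = "a"
    label_b: str = "b"

    @property
    def deviation_a(self) -> np.ndarray:
        return self.observed_a - self.expected_a

    @property
    def deviation_b(self) -> np.ndarray:
        return self.observed_b - self.expected_b

    @property
    def use_rate_delta(self) -> np.ndarray:
        """Percentage-point difference of per-species proportions (a - b)."""
        return 100.0 * (self.observed_a / self.observed_a.sum()
                        - self.observed_b / self.observed_b.sum())

    def group_sums(self) -> dict[str, float]:
        idx_h = [i for i, aa in enumerate(AA_ORDER) if aa in HBOND_PRONE]
        idx_p = [i for i, aa in enumerate(AA_ORDER) if aa in POSITIVE]
        idx_n = [i for i, aa in enumerate(AA_ORDER) if aa in NEGATIVE]
        dev = self.deviation_a
        delta = self.use_rate_delta
        return {
            "hbond_prone_deviation_a": float(dev[idx_h].sum()),
            "hbond_prone_use_rate_delta": float(delta[idx_h].sum()),
            "positive_deviation_a": float(dev[idx_p].sum()),
            "positive_use_rate_delta": float(delta[idx_p].sum()),
            "negative_deviation_a": float(dev[idx_n].sum()),
            "negative_use_rate_delta": float(delta[idx_n].sum()),
        }

    def rows(self) -> list[dict]:
        out = []
        for i, aa in enumerate(self.residues):
            out.append({
                "residue": aa,
                "observed_a": int(self.observed_a[i]),
                "observed_b": int(self.observed_b[i]),
                "expected_a": float(self.expected_a[i]),
                "expected_b": float(self.expected_b[i]),
                "deviation_a": float(self.deviation_a[i]),
                "use_rate_delta": float(self.use_rate_delta[i]),
                "is_hbond_prone": aa in HBOND_PRONE,
                "is_positive": aa in POSITIVE,
                "is_negative": aa in NEGATIVE,
            })
        return out


def _species_counts(seqs: Sequence[SequenceRecord]) -> tuple[np.ndarray, int]:
    counts = np.zeros(20, dtype=float)
    n_x = 0
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for s in seqs:
        for ch in s.sequence:
            i = index.get(ch)
            if i is None:
                n_x += 1
            else:
                counts[i] += 1
    return counts, n_x


def count_usage(seqs_a: Sequence[SequenceRecord],
                seqs_b: Sequence[SequenceRecord],
                label_a: str = "a", label_b: str = "b") -> UsageTable:
    """Totals per residue per species plus the chi-square comparison.

    X residues are excluded from the 20-letter table (their number is kept
    and logged).
    """
    if not seqs_a or not seqs_b:
        raise ValueError("both species need at least one sequence")
    counts_a, nx_a = _species_counts(seqs_a)
    counts_b, nx_b = _species_counts(seqs_b)
    if nx_a or nx_b:
        logger.info("excluded X residues: %d (%s), %d (%s)",
                    nx_a, label_a, nx_b, label_b)
    observed = np.column_stack([counts_a, counts_b])
    chi2 = chi_square_independence(observed)
    # map expected back to the full 20-residue layout (zero rows stay zero)
    expected_a = np.zeros(20)
    expected_b = np.zeros(20)
    nonzero = (counts_a + counts_b) > 0
    expected_a[nonzero] = chi2.expected[:, 0]
    expected_b[nonzero] = chi2.expected[:, 1]
    return UsageTable(
        residues=AA_ORDER,
        observed_a=counts_a, observed_b=counts_b,
        expected_a=expected_a, expected_b=expected_b,
        chi2=chi2, n_excluded_x_a=nx_a, n_excluded_x_b=nx_b,
        label_a=label_a, label_b=label_b,
    )


def deviation_rank_correlation(usage: UsageTable, ranks: PropertyRanks,
                               which: str) -> CorrelationResult:
    """Spearman rho between per-residue deviation (species a) and a property
    rank, over the 20 residues."""
    return spearman_rho(usage.deviation_a, ranks.rank_vector(which))
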