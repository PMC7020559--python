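"""Per-protein feature table: build, quality-filter, subset and summarize.

The table is the pipeline's central "database": one row per protein with its
sequence length, model quality score, bond counts and per-amino-acid rates.
Rates are normalized by the full-length FASTA sequence length, not by the
number of modeled residues, so multi-chain biounit models can legitimately
exceed one bond per residue.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from bondscan.hbond import HbondParams, detect_hbonds
from bondscan.saltbridge import SaltbridgeParams, detect_salt_bridges
from bondscan.structure_io import AA_ORDER, SequenceRecord, StructureModel

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")
UNCHARACTERIZED = "uncharacterized protein"


def normalize_annotation(annotation: str) -> str:
    """Case-fold and collapse whitespace so 'annotated exactly the same'
    is decidable."""
    return _WS.sub(" ", annotation.strip()).casefold()


@dataclass(frozen=True)
class FeatureRecord:
    protein_id: str
    annotation: str
    length: int
    qmean: float
    n_hbonds: int
    n_saltbridges: int
    aa_counts: tuple[int, ...]  # counts in AA_ORDER; X excluded

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: length must be positive")
        if len(self.aa_counts) != 20:
            raise ValueError(f"{self.protein_id}: aa_counts must have 20 entries")

    @property
    def hbonds_per_aa(self) -> float:
        return self.n_hbonds / self.length

    @property
    def saltbridges_per_aa(self) -> float:
        return self.n_saltbridges / self.length

    @property
    def normalized_annotation(self) -> str:
        return normalize_annotation(self.annotation)

    def metric(self, name: str) -> float:
        if name not in ("hbonds_per_aa", "saltbridges_per_aa"):
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)

    def as_row(self) -> dict:
        row = {
            "protein_id": self.protein_id,
            "annotation": self.annotation,
            "length": self.length,
            "qmean": self.qmean,
            "n_hbonds": self.n_hbonds,
            "n_saltbridges": self.n_saltbridges,
            "hbonds_per_aa": self.hbonds_per_aa,
            "saltbridges_per_aa": self.saltbridges_per_aa,
        }
        for aa, count in zip(AA_ORDER, self.aa_counts):
            row[f"n_{aa}"] = count
        return row


@dataclass
class FeatureTable:
    species_label: str
    records: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids in table: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> set[str]:
        return {r.protein_id for r in self.records}

    def metric_values(self, metric: str) -> list[float]:
        return [r.metric(metric) for r in self.records]

    def rows(self) -> list[dict]:
        return [r.as_row() for r in self.records]


@dataclass(frozen=True)
class FilterLog:
    """Accounting of the quality filters, one species at a time."""

    species_label: str
    n_input: int
    n_after_dedup: int
    n_after_qmean: int
    n_dropped_uncharacterized: int
    n_output: int

    def as_row(self) -> dict:
        return {
            "species": self.species_label,
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_after_qmean": self.n_after_qmean,
            "n_dropped_uncharacterized": self.n_dropped_uncharacterized,
            "n_output": self.n_output,
        }


def count_amino_acids(sequence: str) -> tuple[int, ...]:
    """Counts over the 20 canonical letters; X is excluded (and logged)."""
    counts = Counter(sequence)
    n_x = counts.pop("X", 0)
    if n_x:
        logger.info("excluded %d X residues from amino-acid counts", n_x)
    return tuple(counts.get(aa, 0) for aa in AA_ORDER)


def build_feature_table(
    seqs: Sequence[SequenceRecord],
    models: Iterable[StructureModel],
    qmeans: Mapping[str, float],
    hb_params: HbondParams | None = None,
    sb_params: SaltbridgeParams | None = None,
    species_label: str = "",
) -> FeatureTable:
    """Run bond detection per model and assemble one record per protein.

    Every model must have a matching sequence and QMEAN entry; sequences
    without a model are skipped with a warning (modeling failures).
    """
    seq_by_id = {s.protein_id: s for s in seqs}
    models = list(models)
    missing_seq = sorted(m.protein_id for m in models
                         if m.protein_id not in seq_by_id)
    if missing_seq:
        raise ValueError(f"models without a matching sequence: {missing_seq}")
    missing_q = sorted(m.protein_id for m in models if m.protein_id not in qmeans)
    if missing_q:
        raise ValueError(f"models without a QMEAN entry: {missing_q}")

    modeled = {m.protein_id for m in models}
    for s in seqs:
        if s.protein_id not in modeled:
            logger.warning("no model for sequence %s: skipped", s.protein_id)

    records = []
    for model in models:
        seq = seq_by_id[model.protein_id]
        hbonds = detect_hbonds(model, hb_params)
        bridges = detect_salt_bridges(model, sb_params)
        records.append(FeatureRecord(
            protein_id=model.protein_id,
            annotation=seq.annotation,
            length=seq.length,
            qmean=float(qmeans[model.protein_id]),
            n_hbonds=len(hbonds),
            n_saltbridges=len(bridges),
            aa_counts=count_amino_acids(seq.sequence),
        ))
    return FeatureTable(species_label=species_label, records=records)


def make_record(protein_id: str, annotation: str, length: int, qmean: float,
                n_hbonds: int, n_saltbridges: int,
                aa_counts: tuple[int, ...] | None = None) -> FeatureRecord:
    """Convenience constructor for records whose bond counts are already known
    (synthetic ensembles, TSV read-back)."""
    if aa_counts is None:
        aa_counts = (length,) + (0,) * 19
    return FeatureRecord(protein_id=protein_id, annotation=annotation,
                         length=length, qmean=qmean, n_hbonds=n_hbonds,
                         n_saltbridges=n_saltbridges, aa_counts=tuple(aa_counts))


def apply_quality_filters(
    table: FeatureTable, qmean_min: float = -5.0
) -> tuple[FeatureTable, FilterLog]:
    """Deduplicate by annotation, drop low-QMEAN models, drop uncharacterized.

    Order mirrors the accounting used to report the model counts: duplicates
    (same normalized annotation) collapse to the single highest-QMEAN record
    (ties to the lexicographically smallest protein_id), then records with
    qmean < qmean_min are removed (qmean == qmean_min survives), then records
    whose annotation contains "uncharacterized protein" are removed.
    Idempotent by construction.
    """
    n_input = len(table)

    best: dict[str, FeatureRecord] = {}
    for rec in table:
        key = rec.normalized_annotation
        cur = best.get(key)
        if cur is None or (rec.qmean, _neg_id(rec)) > (cur.qmean, _neg_id(cur)):
            best[key] = rec
    deduped = [r for r in table if best[r.normalized_annotation] is r]
    n_after_dedup = len(deduped)

    qmean_ok = [r for r in deduped if r.qmean >= qmean_min]
    n_after_qmean = len(qmean_ok)

    kept = [r for r in qmean_ok if UNCHARACTERIZED not in r.normalized_annotation]
    n_dropped_unchar = n_after_qmean - len(kept)

    log = FilterLog(
        species_label=table.species_label,
        n_input=n_input,
        n_after_dedup=n_after_dedup,
        n_after_qmean=n_after_qmean,
        n_dropped_uncharacterized=n_dropped_unchar,
        n_output=len(kept),
    )
    logger.info("%s: %d input, %d unique, %d pass QMEAN>=%g, %d dropped "
                "uncharacterized, %d retained", table.species_label, n_input,
                n_after_dedup, n_after_qmean, qmean_min, n_dropped_unchar,
                len(kept))
    if not kept:
        logger.warning("%s: no records survive quality filters",
                       table.species_label)
    return FeatureTable(species_label=table.species_label, records=kept), log


class _neg_id:
    """Orders protein_ids descending inside a max-comparison, so the
    lexicographically smallest id wins QMEAN ties."""

    __slots__ = ("pid",)

    def __init__(self, rec: FeatureRecord):
        self.pid = rec.protein_id

    def __lt__(self, other: "_neg_id") -> bool:
        return self.pid > other.pid

    def __gt__(self, other: "_neg_id") -> bool:
        return self.pid < other.pid

    def __eq__(self, other) -> bool:
        return self.pid == other.pid


def pair_orthologs(
    a: FeatureTable, b: FeatureTable
) -> list[tuple[FeatureRecord, FeatureRecord]]:
    """Pair records across species whose normalized annotations are identical.

    Tables are assumed deduplicated, so each annotation yields at most one
    pair. Pairs are returned sorted by annotation for determinism.
    """
    by_ann_a = {r.normalized_annotation: r for r in a}
    by_ann_b = {r.normalized_annotation: r for r in b}
    shared = sorted(set(by_ann_a) & set(by_ann_b))
    return [(by_ann_a[k], by_ann_b[k]) for k in shared]


def upper_fraction(table: FeatureTable, metric: str, fraction: float) -> FeatureTable:
    """Top ceil(fraction * n) records ranked descending by ``metric``.

    Ties in the metric break by ascending protein_id, so the subset is
    deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("table is empty")
    k = math.ceil(fraction * len(table))
    ranked = sorted(table, key=lambda r: (-r.metric(metric), r.protein_id))
    return FeatureTable(species_label=table.species_label, records=ranked[:k])


def threshold_percentages(table: FeatureTable, metric: str,
                          threshold: float) -> tuple[int, float]:
    """(count, percent) of records with metric strictly above ``threshold``;
    percent is rounded to one decimal."""
    if len(table) == 0:
        raise ValueError("table is empty")
    count = sum(1 for r in table if r.metric(metric) > threshold)
    percent = round(100.0 * count / len(table), 1)
    return count, percent


def histogram(table: FeatureTable, metric: str, bin_width: float) -> list[dict]:
    """Frequency histogram over half-open bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = table.metric_values(metric)
    if not values:
        return []
    n = len(values)
    counts: Counter[int] = Counter(math.floor(v / bin_width) for v in values)
    return [
        {
            "bin_low": k * bin_width,
            "bin_high": (k + 1) * bin_width,
            "count": counts[k],
            "percent": round(100.0 * counts[k] / n, 1),
        }
        for k in sorted(counts)
    ]


def overlap_stats(a: FeatureTable, b: FeatureTable) -> tuple[int, int]:
    """(|A ∩ B|, percent of |A ∪ B|) by protein_id; percent rounded to the
    nearest integer."""
    ids_a, ids_b = a.ids(), b.ids()
    inter = ids_a & ids_b
    union = ids_a | ids_b
    percent = round(100.0 * len(inter) / len(union)) if union else 0
    return len(inter), int(percent)
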