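import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bondscan.features import (
    FeatureTable,
    apply_quality_filters,
    build_feature_table,
    count_amino_acids,
    histogram,
    make_record,
    normalize_annotation,
    overlap_stats,
    pair_orthologs,
    threshold_percentages,
    upper_fraction,
)
from bondscan.structure_io import AA_ORDER, SequenceRecord
from bondscan.synthetic import make_ideal_helix


def table(records, label="sp"):
    return FeatureTable(species_label=label, records=records)


def rec(pid, qmean=0.0, annotation=None, length=100, hb=0, sb=0):
    return make_record(pid, annotation if annotation is not None else pid,
                       length, qmean, hb, sb)


class TestBuild:
    def test_rates_use_fasta_length(self):
        model = make_ideal_helix(10)
        seq = SequenceRecord(model.protein_id, "helical peptide", "A" * 20)
        t = build_feature_table([seq], [model], {model.protein_id: -1.0})
        [r] = t.records
        assert r.n_hbonds == 6
        assert r.hbonds_per_aa == pytest.approx(6 / 20)  # FASTA length, not modeled
        assert r.qmean == -1.0
        assert sum(r.aa_counts) == 20

    def test_missing_sequence_is_error(self):
        model = make_ideal_helix(10)
        with pytest.raises(ValueError, match=model.protein_id):
            build_feature_table([], [model], {model.protein_id: 0.0})

    def test_missing_qmean_is_error(self):
        model = make_ideal_helix(10)
        seq = SequenceRecord(model.protein_id, "x", "A" * 10)
        with pytest.raises(ValueError, match="QMEAN"):
            build_feature_table([seq], [model], {})

    def test_sequence_without_model_skipped(self):
        model = make_ideal_helix(10)
        seqs = [SequenceRecord(model.protein_id, "x", "A" * 10),
                SequenceRecord("orphan", "y", "CC")]
        t = build_feature_table(seqs, [model], {model.protein_id: 0.0})
        assert len(t) == 1

    def test_zero_features_retained(self):
        r = rec("P1", hb=0, sb=0)
        assert r.hbonds_per_aa == 0.0
        assert r.saltbridges_per_aa == 0.0

    def test_multichain_rate_can_exceed_monomer(self):
        r = rec("P1", length=50, hb=120)
        assert r.hbonds_per_aa == pytest.approx(2.4)

    def test_aa_counts(self):
        counts = count_amino_acids("AAXCD")
        assert counts[AA_ORDER.index("A")] == 2
        assert sum(counts) == 4  # X excluded


class TestQualityFilters:
    def test_qmean_boundary(self):
        t = table([rec("P1", -4.9), rec("P2", -5.0), rec("P3", -5.1)])
        kept, log = apply_quality_filters(t)
        assert kept.ids() == {"P1", "P2"}
        assert log.n_after_qmean == 2

    def test_dedup_keeps_highest_qmean(self):
        t = table([rec("P1", -2.0, "Cytochrome C oxidase 1"),
                   rec("P2", -1.0, "Cytochrome C oxidase 1"),
                   rec("P3", -3.0, "cytochrome  c Oxidase 1")])
        kept, log = apply_quality_filters(t)
        assert kept.ids() == {"P2"}
        assert log.n_after_dedup == 1

    def test_dedup_tie_smallest_id(self):
        t = table([rec("P9", 0.0, "same"), rec("P1", 0.0, "same")])
        kept, _ = apply_quality_filters(t)
        assert kept.ids() == {"P1"}

    def test_uncharacterized_dropped(self):
        t = table([rec("P1", 0.0, "Uncharacterized protein"),
                   rec("P2", 0.0, "Putative uncharacterized protein 12"),
                   rec("P3", 0.0, "Characterized protein")])
        kept, log = apply_quality_filters(t)
        assert kept.ids() == {"P3"}
        assert log.n_dropped_uncharacterized == 2

    def test_idempotent(self):
        t = table([rec(f"P{i}", qmean=-6 + i, annotation=f"ann {i % 4}")
                   for i in range(10)])
        once, _ = apply_quality_filters(t)
        twice, _ = apply_quality_filters(once)
        assert once.ids() == twice.ids()

    def test_empty_output_allowed(self):
        t = table([rec("P1", -10.0)])
        kept, log = apply_quality_filters(t)
        assert len(kept) == 0 and log.n_output == 0


class TestOrthologs:
    def test_case_folded_match(self):
        a = table([rec("A1", annotation="MDH"), rec("A2", annotation="IDH"),
                   rec("A3", annotation="actin")])
        b = table([rec("B1", annotation="idh"), rec("B2", annotation="tubulin")])
        pairs = pair_orthologs(a, b)
        assert len(pairs) == 1
        assert pairs[0][0].protein_id == "A2"

    def test_disjoint_empty(self):
        a = table([rec("A1", annotation="x")])
        b = table([rec("B1", annotation="y")])
        assert pair_orthologs(a, b) == []

    def test_identical_tables_full_pairing(self):
        recs = [rec(f"P{i}", annotation=f"ann{i}") for i in range(5)]
        assert len(pair_orthologs(table(recs), table(recs))) == 5

    def test_whitespace_collapse(self):
        assert normalize_annotation("  Heat   Shock\tProtein ") == "heat shock protein"


class TestUpperFraction:
    @pytest.mark.parametrize("n,frac,k", [
        (482, 0.25, 121), (482, 0.5, 241), (58, 0.25, 15), (58, 0.5, 29),
        (4, 0.5, 2),
    ])
    def test_subset_sizes(self, n, frac, k):
        t = table([rec(f"P{i:04d}", hb=i) for i in range(n)])
        assert len(upper_fraction(t, "hbonds_per_aa", frac)) == k

    def test_keeps_largest(self):
        t = table([rec(f"P{i}", hb=i * 10) for i in range(8)])
        top = upper_fraction(t, "hbonds_per_aa", 0.25)
        assert top.ids() == {"P7", "P6"}

    def test_tie_break_by_id(self):
        t = table([rec("P3", hb=5), rec("P1", hb=5), rec("P2", hb=5)])
        top = upper_fraction(t, "hbonds_per_aa", 1 / 3)
        assert top.ids() == {"P1"}

    def test_full_fraction_returns_all(self):
        t = table([rec(f"P{i}", hb=i) for i in range(7)])
        assert upper_fraction(t, "hbonds_per_aa", 1.0).ids() == t.ids()

    def test_quartile_subset_of_half(self):
        t = table([rec(f"P{i}", hb=(i * 37) % 101) for i in range(33)])
        q = upper_fraction(t, "hbonds_per_aa", 0.25).ids()
        h = upper_fraction(t, "hbonds_per_aa", 0.5).ids()
        assert q <= h

    def test_bad_fraction(self):
        t = table([rec("P1")])
        for frac in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                upper_fraction(t, "hbonds_per_aa", frac)

    @given(n=st.integers(1, 200), frac=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_k_is_ceil(self, n, frac):
        t = table([rec(f"P{i:04d}", hb=i) for i in range(n)])
        assert len(upper_fraction(t, "hbonds_per_aa", frac)) == math.ceil(frac * n)


class TestThresholds:
    @pytest.mark.parametrize("n,above,expected", [
        (482, 26, 5.4), (482, 32, 6.6), (58, 2, 3.4), (10, 0, 0.0),
    ])
    def test_printed_percentages(self, n, above, expected):
        recs = [rec(f"P{i:04d}", length=10, hb=50 if i < above else 10)
                for i in range(n)]
        count, percent = threshold_percentages(table(recs), "hbonds_per_aa", 4.0)
        assert count == above
        assert percent == expected

    def test_strictly_greater(self):
        t = table([rec("P1", length=10, hb=40)])  # rate exactly 4.0
        count, _ = threshold_percentages(t, "hbonds_per_aa", 4.0)
        assert count == 0


class TestHistogram:
    def test_worked_example(self):
        t = table([rec("P1", length=100, hb=10), rec("P2", length=100, hb=15),
                   rec("P3", length=100, hb=30)])
        rows = histogram(t, "hbonds_per_aa", 0.2)
        assert [(r["bin_low"], r["count"]) for r in rows] == [(0.0, 2), (0.2, 1)]
        assert [r["percent"] for r in rows] == [66.7, 33.3]

    def test_half_open_bins(self):
        t = table([rec("P1", length=10, hb=2)])  # rate exactly 0.2
        rows = histogram(t, "hbonds_per_aa", 0.2)
        assert rows[0]["bin_low"] == pytest.approx(0.2)

    def test_percent_sums_to_100(self):
        t = table([rec(f"P{i}", length=10, hb=i) for i in range(1, 30)])
        rows = histogram(t, "hbonds_per_aa", 0.25)
        assert sum(r["percent"] for r in rows) == pytest.approx(100, abs=0.5)
        assert sum(r["count"] for r in rows) == 29


class TestOverlap:
    def test_printed_percentage(self):
        shared = [rec(f"S{i:03d}") for i in range(200)]
        a = table(shared + [rec(f"A{i}") for i in range(41)])
        b = table(shared + [rec(f"B{i}") for i in range(41)])
        n, pct = overlap_stats(a, b)
        assert (n, pct) == (200, 71)

    def test_identical(self):
        t = table([rec(f"P{i}") for i in range(9)])
        assert overlap_stats(t, t) == (9, 100)

    def test_disjoint(self):
        a = table([rec("A1")])
        b = table([rec("B1")])
        assert overlap_stats(a, b) == (0, 0)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        table([rec("P1"), rec("P1")])
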