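import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandqc.io_model import (
    FLAG_DUPLICATE,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_UNMAPPED,
)
from strandqc.qc_metrics import (
    GeneExpressionVector,
    expression_correlation,
    genes_detected,
    intron_exon_ratio,
    profile_library,
    strand_specificity,
)

from conftest import make_record


def exonic_read(name, pos=120, contig="chr1"):
    return make_record(name, FLAG_PAIRED | FLAG_READ2, contig, pos, [("M", 75)])


class TestProfileLibrary:
    def test_single_gene_library(self, toy_index):
        records = [exonic_read(f"r{i}") for i in range(10)]
        report, expr = profile_library(records, toy_index)
        assert report.pct_exonic == 1.0
        assert report.total_reads == 10
        assert expr.read_counts["GENEA"] == 10
        assert genes_detected(expr, 1) == 1

    def test_category_percentages_by_construction(self, toy_index):
        records = (
            [exonic_read(f"e{i}") for i in range(10)]
            + [make_record(f"i{i}", 0, "chr1", 320, [("M", 75)]) for i in range(6)]
            + [make_record(f"g{i}", 0, "chr1", 8000, [("M", 75)]) for i in range(4)]
        )
        report, _ = profile_library(records, toy_index)
        assert (report.pct_exonic, report.pct_intronic, report.pct_intergenic) == (
            0.5,
            0.3,
            0.2,
        )
        assert report.intron_exon_ratio == 0.6
        assert intron_exon_ratio(records, toy_index) == 0.6

    def test_mitochondrial_fraction(self, toy_index):
        records = [exonic_read(f"e{i}") for i in range(32)] + [
            make_record(f"m{i}", 0, "chrM", 200, [("M", 75)]) for i in range(8)
        ]
        report, _ = profile_library(records, toy_index)
        assert report.pct_mitochondrial == pytest.approx(0.20)

    def test_rrna_fraction_from_biotype(self, toy_index):
        records = [exonic_read(f"e{i}") for i in range(9)] + [
            make_record("rr", 0, "chr1", 5100, [("M", 75)])
        ]
        report, _ = profile_library(records, toy_index)
        assert report.pct_rRNA == pytest.approx(0.1)

    def test_duplicates_excluded_from_metrics_but_counted_in_totals(self, toy_index):
        records = [exonic_read(f"e{i}") for i in range(5)] + [
            make_record("d", FLAG_DUPLICATE, "chr1", 320, [("M", 75)])
        ]
        report, _ = profile_library(records, toy_index)
        assert report.total_reads == 6
        assert report.aligned_fraction == 1.0
        assert report.pct_exonic == 1.0  # the duplicate intronic read is ignored

    def test_empty_stream_gives_null_report(self, toy_index):
        report, expr = profile_library([], toy_index)
        assert report.total_reads == 0
        assert report.pct_exonic is None and report.aligned_fraction is None
        assert expr.assigned_reads == 0

    def test_category_proportions_sum_to_one(self, small_simulation):
        report, _ = profile_library(small_simulation["records"], small_simulation["index"])
        assert report.pct_exonic + report.pct_intronic + report.pct_intergenic == (
            pytest.approx(1.0, abs=1e-9)
        )

    def test_gene_counts_sum_to_assigned_total(self, small_simulation):
        _, expr = profile_library(small_simulation["records"], small_simulation["index"])
        assert expr.read_counts.sum() == expr.assigned_reads
        # RPKM zero exactly when count zero
        zero = expr.read_counts == 0
        assert (expr.rpkm[zero] == 0).all() and (expr.rpkm[~zero] > 0).all()


class TestStrandSpecificity:
    def _spanning(self, name, sense, pos=270):
        flag = FLAG_READ2 if sense else FLAG_READ1
        return make_record(
            name, FLAG_PAIRED | flag, "chr1", pos, [("M", 30), ("N", 200), ("M", 45)]
        )

    def test_all_sense_reads_give_one(self, toy_index):
        records = [self._spanning(f"s{i}", True) for i in range(20)]
        value, n = strand_specificity(records, toy_index)
        assert value == 1.0 and n == 1

    def test_hand_built_antisense_fraction(self, toy_index):
        # junction 1 (TXA exon1/2) sees only sense reads; junction 2 gets
        # one antisense read -> half the observed junctions are clean
        records = [self._spanning(f"s{i}", True) for i in range(5)]
        records.append(
            make_record(
                "a1",
                FLAG_PAIRED | FLAG_READ1,
                "chr1",
                670,
                [("M", 30), ("N", 200), ("M", 45)],
            )
        )
        value, n = strand_specificity(records, toy_index)
        assert n == 2 and value == 0.5

    def test_literal_denominator_counts_all_junctions(self, toy_index):
        records = [self._spanning("s", True)]
        value, n = strand_specificity(records, toy_index, literal_denominator=True)
        # 3 annotated junctions, none with antisense reads
        assert value == 1.0 and n == 1

    def test_no_spanning_reads_returns_null(self, toy_index):
        with pytest.warns(UserWarning):
            value, n = strand_specificity([exonic_read("e")], toy_index)
        assert value is None and n == 0

    def test_error_rate_cannot_flip_strand(self, small_simulation):
        """Strand comes from flags, not sequence: substitutions leave the
        antisense-free library at exactly 1.0."""
        import dataclasses

        from strandqc.synthetic import simulate_library

        cfg = dataclasses.replace(
            small_simulation["config"],
            antisense_rate=0.0,
            substitution_rate=0.01,
            n_fragments=800,
        )
        records, _ = simulate_library(
            cfg,
            small_simulation["reference"],
            small_simulation["transcripts"],
            small_simulation["panel"],
        )
        value, _ = strand_specificity(records, small_simulation["index"])
        assert value == 1.0


class TestExpressionCorrelation:
    def _expr(self, toy_index, counts):
        return GeneExpressionVector.from_counts(counts, toy_index)

    def test_self_correlation_is_one(self, toy_index):
        a = self._expr(toy_index, {"GENEA": 50, "GENEB": 10, "GENER": 3})
        assert expression_correlation(a, a) == pytest.approx(1.0)

    def test_scale_invariance_up_to_pseudocount(self, toy_index):
        a = self._expr(toy_index, {"GENEA": 500, "GENEB": 100, "GENER": 30, "GENEM": 7})
        b = self._expr(toy_index, {"GENEA": 1000, "GENEB": 200, "GENER": 60, "GENEM": 14})
        # doubling all counts leaves RPKM unchanged -> exactly 1
        assert expression_correlation(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_genes_returns_null(self, toy_index):
        a = self._expr(toy_index, {"GENEA": 5})
        with pytest.warns(UserWarning):
            assert expression_correlation(a, a) is None

    def test_matches_two_pass_oracle(self):
        """Pearson via scipy agrees with the naive two-pass formula."""
        rng = np.random.default_rng(0)
        from scipy import stats

        for _ in range(100):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            assert stats.pearsonr(x, y).statistic == pytest.approx(
                num / den, abs=1e-12
            )


class TestGenesDetected:
    def test_threshold_behaviour(self, toy_index):
        expr = GeneExpressionVector.from_counts({"GENEA": 5, "GENEB": 1}, toy_index)
        assert genes_detected(expr, 1) == 2
        assert genes_detected(expr, 5) == 1
        assert genes_detected(expr, 6) == 0

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4))
    def test_monotone_in_threshold(self, toy_index, counts):
        genes = ["GENEA", "GENEB", "GENER", "GENEM"]
        expr = GeneExpressionVector.from_counts(dict(zip(genes, counts)), toy_index)
        values = [genes_detected(expr, m) for m in range(1, 10)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_brute_force_recount_on_simulation(self, small_simulation):
        _, expr = profile_library(small_simulation["records"], small_simulation["index"])
        brute = sum(1 for c in expr.read_counts if c >= 1)
        assert genes_detected(expr, 1) == brute
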