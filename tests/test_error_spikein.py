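import random

import numpy as np
import pytest

from strandqc.io_model import (
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_UNMAPPED,
    ReferenceSet,
    SpikeInPanel,
    reverse_complement,
)
from strandqc.error_spikein import (
    align_to_panel,
    base_error_rate,
    extract_spikein_pool,
    spikein_dose_response,
    spikein_error_rate,
)

from conftest import make_record


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 4000))
    return ReferenceSet({"chr1": seq})


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(6)
    ids = [f"E{i:03d}" for i in range(10)]
    seqs = {sid: "".join(rng.choice(list("ACGT"), 400)) for sid in ids}
    concs = {sid: float(2**i) for i, sid in enumerate(ids)}
    return SpikeInPanel(ids=ids, sequences=seqs, concentrations=concs)


class TestBaseErrorRate:
    def test_perfect_read_has_zero_mismatches(self, reference):
        seq = reference.sequences["chr1"][100:175]
        rec = make_record("r", 0, "chr1", 100, [("M", 75)], seq=seq)
        tally = base_error_rate([rec], reference)
        assert (tally.mismatches, tally.aligned_bases) == (0, 75)

    def test_three_substitutions_counted(self, reference):
        seq = list(reference.sequences["chr1"][100:175])
        for i in (5, 40, 70):
            seq[i] = "A" if seq[i] != "A" else "C"
        rec = make_record("r", 0, "chr1", 100, [("M", 75)], seq="".join(seq))
        tally = base_error_rate([rec], reference)
        assert tally.mismatches == 3
        assert tally.rate == pytest.approx(0.04)
        assert tally.rate_per_kb == pytest.approx(40.0)

    def test_clips_inserts_and_skips_excluded(self, reference):
        ref = reference.sequences["chr1"]
        seq = "TTTTT" + ref[100:130] + "GGG" + ref[330:370]
        rec = make_record(
            "r",
            0,
            "chr1",
            100,
            [("S", 5), ("M", 30), ("I", 3), ("N", 200), ("M", 40)],
            seq=seq,
        )
        tally = base_error_rate([rec], reference)
        assert (tally.mismatches, tally.aligned_bases) == (0, 70)

    def test_mask_on_all_mismatch_positions_gives_zero(self, reference):
        seq = list(reference.sequences["chr1"][100:175])
        for i in (5, 40):
            seq[i] = "A" if seq[i] != "A" else "C"
        rec = make_record("r", 0, "chr1", 100, [("M", 75)], seq="".join(seq))
        mask = {("chr1", 105), ("chr1", 140)}
        tally = base_error_rate([rec], reference, mask=mask)
        assert tally.mismatches == 0
        assert tally.masked_bases == 2
        assert tally.aligned_bases == 73

    def test_quality_filter_drops_low_quality_bases(self, reference):
        seq = list(reference.sequences["chr1"][100:175])
        seq[10] = "A" if seq[10] != "A" else "C"
        quals = [30] * 75
        quals[10] = 2
        rec = make_record("r", 0, "chr1", 100, [("M", 75)], seq="".join(seq), quals=quals)
        tally = base_error_rate([rec], reference, min_baseq=20)
        assert tally.mismatches == 0 and tally.aligned_bases == 74

    def test_unknown_contig_is_lookup_error(self, reference):
        rec = make_record("r", 0, "chrZ", 100, [("M", 75)])
        with pytest.raises(LookupError):
            base_error_rate([rec], reference)


class TestSpikeInPool:
    def _pair(self, name, unmapped=(False, False)):
        flags1 = FLAG_PAIRED | FLAG_READ1
        flags2 = FLAG_PAIRED | FLAG_READ2
        if unmapped[0]:
            flags1 |= FLAG_UNMAPPED
            flags2 |= FLAG_MATE_UNMAPPED
        if unmapped[1]:
            flags2 |= FLAG_UNMAPPED
            flags1 |= FLAG_MATE_UNMAPPED
        return [
            make_record(name, flags1, "chr1", 100, [("M", 75)]),
            make_record(name, flags2, "chr1", 300, [("M", 75)]),
        ]

    def test_pairs_with_any_unmapped_mate_selected(self):
        records = []
        for i in range(5):
            records += self._pair(f"m{i}")
        records += self._pair("h0", (True, False))
        records += self._pair("h1", (False, True))
        records += self._pair("u0", (True, True))
        pool = extract_spikein_pool(records)
        assert sorted(p[0].query_name for p in pool) == ["h0", "h1", "u0"]
        assert all(len(p) == 2 for p in pool)

    def test_fully_mapped_library_gives_empty_pool(self):
        records = [r for i in range(4) for r in self._pair(f"m{i}")]
        assert extract_spikein_pool(records) == []

    def test_pool_matches_brute_force_flag_scan(self):
        rng = random.Random(11)
        records = []
        truth = set()
        for i in range(10):
            um = (rng.random() < 0.3, rng.random() < 0.3)
            records += self._pair(f"p{i}", um)
            if any(um):
                truth.add(f"p{i}")
        pool = extract_spikein_pool(records)
        assert {p[0].query_name for p in pool} == truth

    def test_missing_mate_kept_as_singleton_with_warning(self):
        rec = make_record(
            "solo", FLAG_PAIRED | FLAG_READ1 | FLAG_UNMAPPED, seq="A" * 75
        )
        with pytest.warns(UserWarning, match="singleton"):
            pool = extract_spikein_pool([rec])
        assert len(pool) == 1 and len(pool[0]) == 1


def unmapped_pair(name, seq1, seq2):
    base = FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED
    return [
        make_record(name, base | FLAG_READ1, seq=seq1),
        make_record(name, base | FLAG_READ2, seq=seq2),
    ]


class TestAlignToPanel:
    def test_verbatim_read_assigned_with_identity_one(self, panel):
        sid = panel.ids[7]
        seq = panel.sequences[sid][50:125]
        pool = [unmapped_pair("p", seq, reverse_complement(seq))]
        result = align_to_panel(pool, panel)
        assert result.assigned_counts == {sid: 2}
        assert all(a.identity == 1.0 for a in result.assignments)

    def test_heavily_mutated_read_unassigned(self, panel):
        sid = panel.ids[0]
        seq = list(panel.sequences[sid][0:75])
        for i in range(0, 75, 10):  # 10% scattered substitutions
            seq[i] = "A" if seq[i] != "A" else "C"
        pool = [unmapped_pair("p", "".join(seq), "T" * 75)]
        result = align_to_panel(pool, panel, min_identity=0.95)
        assert result.assigned_counts == {}
        assert result.unassigned_reads == 2

    def test_assignment_recovers_true_source_under_errors(self, panel):
        rng = np.random.default_rng(9)
        pool, truth = [], []
        for i in range(300):
            sid = panel.ids[int(rng.integers(0, len(panel.ids)))]
            start = int(rng.integers(0, panel.length(sid) - 75))
            seq = list(panel.sequences[sid][start : start + 75])
            for j in range(75):  # substitution rate 0.005
                if rng.random() < 0.005:
                    seq[j] = "ACGT"[int(rng.integers(0, 4))]
            pool.append(unmapped_pair(f"p{i}", "".join(seq), "T" * 75)[0:1])
            truth.append(sid)
        result = align_to_panel(pool, panel)
        correct = sum(
            1 for a, sid in zip(result.assignments, truth) if a.spikein_id == sid
        )
        assert correct / len(truth) >= 0.99

    def test_deterministic_under_read_order(self, panel):
        rng = np.random.default_rng(10)
        pool = []
        for i in range(50):
            sid = panel.ids[int(rng.integers(0, len(panel.ids)))]
            seq = panel.sequences[sid][10:85]
            pool.append(unmapped_pair(f"p{i}", seq, reverse_complement(seq)))
        a = align_to_panel(pool, panel)
        b = align_to_panel(list(reversed(pool)), panel)
        assert a.assigned_counts == b.assigned_counts
        assert sorted(map(str, a.assignments)) == sorted(map(str, b.assignments))


class TestDoseResponse:
    def test_exactly_proportional_counts_give_r_one(self, panel):
        counts = {
            sid: panel.concentrations[sid] * panel.length(sid) / 1000.0
            for sid in panel.ids
        }
        assert spikein_dose_response(counts, panel) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_detected_returns_null(self, panel):
        with pytest.warns(UserWarning):
            assert spikein_dose_response({panel.ids[0]: 5}, panel) is None

    def test_half_min_pseudocount_option(self, panel):
        counts = {sid: panel.concentrations[sid] for sid in panel.ids}
        r = spikein_dose_response(counts, panel, pseudocount="half_min")
        assert r is not None and r > 0.5


class TestSpikeInErrorRate:
    def test_error_free_pool_rate_zero(self, panel):
        sid = panel.ids[3]
        pool = [
            unmapped_pair(f"p{i}", panel.sequences[sid][i : i + 75], "T" * 75)[0:1]
            for i in range(100)
        ]
        result = align_to_panel(pool, panel)
        assert spikein_error_rate(result, panel) == 0.0

    def test_rate_is_per_base_times_thousand(self, panel):
        sid = panel.ids[3]
        seq = list(panel.sequences[sid][0:75])
        seq[10] = "A" if seq[10] != "A" else "C"
        result = align_to_panel([unmapped_pair("p", "".join(seq), "T" * 75)[0:1]], panel)
        assert spikein_error_rate(result, panel) == pytest.approx(1 / 75 * 1000.0)
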