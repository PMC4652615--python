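import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txsimeval.matching import (
    MatchCandidate,
    find_candidates_coordinates,
    find_candidates_sequences,
    greedy_match,
    inner_exon_spliced_spans,
    match_sets,
    mismatch_score,
)
from txsimeval.pool import Exon, TranscriptModel, generate_synthetic_pool


def tx(tid, exon_coords, strand="+", gene=None, chrom="chr1"):
    return TranscriptModel(
        tid, gene or tid,
        tuple(Exon(chrom, s, e, strand) for s, e in exon_coords),
    )


class TestMismatchScore:
    def test_pythagorean_case(self):
        assert mismatch_score(3, 4) == pytest.approx(5.0)

    def test_exact_match_scores_zero(self):
        assert mismatch_score(0, 0) == 0.0

    @pytest.mark.parametrize("d", [1, 17, 300])
    def test_single_sided(self, d):
        assert mismatch_score(d, 0) == pytest.approx(d)
        assert mismatch_score(0, d) == pytest.approx(d)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mismatch_score(-1, 5)


class TestCoordinateBackend:
    def test_identical_transcript_scores_zero(self):
        t = tx("T", [(0, 100), (200, 300), (400, 500)])
        c = tx("C", [(0, 100), (200, 300), (400, 500)])
        pairs = find_candidates_coordinates([t], [c])
        assert len(pairs) == 1
        assert (pairs[0].d1, pairs[0].d2) == (0, 0)
        assert pairs[0].score == 0.0

    def test_missing_inner_exon_rejected(self):
        t = tx("T", [(0, 100), (200, 300), (400, 500), (600, 700)])
        c = tx("C", [(0, 100), (400, 500), (600, 700)])  # dropped inner exon
        assert find_candidates_coordinates([t], [c]) == []

    def test_extra_internal_intron_rejected(self):
        t = tx("T", [(0, 300), (400, 700)])
        c = tx("C", [(0, 100), (150, 300), (400, 700)])  # novel intron in exon 1
        assert find_candidates_coordinates([t], [c]) == []

    def test_truncation_thresholds_single_exon(self):
        # single-exon true transcript of length 1000, truncated from the 5' end
        t = tx("T", [(0, 1000)])
        keep_79 = tx("C79", [(210, 1000)])  # keeps 790 bases: common < 80%
        keep_81 = tx("C81", [(190, 1000)])  # keeps 810 bases
        assert find_candidates_coordinates([t], [keep_79]) == []
        pairs = find_candidates_coordinates([t], [keep_81])
        assert len(pairs) == 1
        assert (pairs[0].d1, pairs[0].d2) == (190, 0)

    def test_overextension_counts_into_both_ends(self):
        t = tx("T", [(100, 1000)])
        c = tx("C", [(50, 1040)])  # 50 extra 5' bases, 40 extra 3' bases
        (pair,) = find_candidates_coordinates([t], [c])
        assert (pair.d1, pair.d2) == (50, 40)

    def test_minus_strand_swaps_end_labels(self):
        t = tx("T", [(100, 1000)], strand="-")
        c = tx("C", [(50, 1000)], strand="-")  # extra genomic-left = 3' end
        (pair,) = find_candidates_coordinates([t], [c])
        assert (pair.d1, pair.d2) == (0, 50)

    def test_length_difference_over_20_percent_rejected(self):
        t = tx("T", [(0, 1000)])
        c = tx("C", [(0, 1250)])  # candidate 25% longer
        assert find_candidates_coordinates([t], [c]) == []

    def test_strand_and_chrom_must_agree(self):
        t = tx("T", [(0, 500)], strand="+")
        assert find_candidates_coordinates([t], [tx("C", [(0, 500)], strand="-")]) == []
        assert find_candidates_coordinates([t], [tx("C", [(0, 500)], chrom="chr2")]) == []


class TestSequenceBackend:
    def test_identical_sequence_scores_zero(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        pairs = find_candidates_sequences({"T": seq}, {"C": seq})
        assert len(pairs) == 1 and pairs[0].score == 0.0

    def test_reverse_complement_candidate_matches(self):
        from txsimeval.pool import reverse_complement

        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        pairs = find_candidates_sequences({"T": seq}, {"C": reverse_complement(seq)})
        assert len(pairs) == 1 and pairs[0].score == 0.0

    def test_truncation_thresholds(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        pairs_79 = find_candidates_sequences({"T": seq}, {"C": seq[210:]})
        pairs_81 = find_candidates_sequences({"T": seq}, {"C": seq[190:]})
        assert pairs_79 == []
        assert len(pairs_81) == 1
        assert (pairs_81[0].d1, pairs_81[0].d2) == (190, 0)

    def test_inner_exon_span_must_be_covered(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        # true transcript has an inner exon at spliced [300, 600)
        spans = {"T": [(300, 600)]}
        # candidate covering only [250, 900) misses part of the inner exon
        pairs = find_candidates_sequences(
            {"T": seq}, {"C": seq[310:]}, inner_spans=spans
        )
        assert pairs == []
        # candidate covering [100, 900) contains it (length diff 11% ok)
        pairs = find_candidates_sequences(
            {"T": seq}, {"C": seq[100:]}, inner_spans=spans
        )
        assert len(pairs) == 1

    def test_backends_agree_on_synthetic_pool(self):
        """Coordinate and sequence backends give the same TP/FN/FP labels
        when candidate chains come from the same genome."""
        pool = generate_synthetic_pool(n_genes=8, seed=31)
        txs = list(pool.transcripts())
        truth = txs[::2]
        candidates = [
            TranscriptModel(f"cand_{t.transcript_id}", t.gene_id, t.exons)
            for t in txs[: len(txs) // 2]
        ]
        coord = match_sets(truth, candidates, backend="coord")

        seqs = pool.spliced_sequences()
        truth_seqs = {t.transcript_id: seqs[t.transcript_id] for t in truth}
        cand_seqs = {
            c.transcript_id: c.spliced_sequence(pool.genome) for c in candidates
        }
        spans = {t.transcript_id: inner_exon_spliced_spans(t) for t in truth}
        seq_pairs = find_candidates_sequences(truth_seqs, cand_seqs, inner_spans=spans)
        seq_report = greedy_match(
            seq_pairs, list(truth_seqs), list(cand_seqs)
        )
        assert coord.tp_ids == seq_report.tp_ids
        assert coord.fn_ids == seq_report.fn_ids
        assert coord.fp_ids == seq_report.fp_ids


def brute_force_greedy(cands, true_ids, cand_ids):
    """Independent re-statement of the traversal: repeatedly pick the
    global minimum (score, true_id, candidate_id) among pairs whose ids
    are both unused."""
    remaining = list(cands)
    used_t, used_c, accepted = set(), set(), []
    while True:
        live = [
            c for c in remaining
            if c.true_id not in used_t and c.candidate_id not in used_c
        ]
        if not live:
            break
        best = min(live, key=lambda c: (c.score, c.true_id, c.candidate_id))
        accepted.append(best)
        used_t.add(best.true_id)
        used_c.add(best.candidate_id)
    return accepted


class TestGreedyMatching:
    def test_smaller_score_wins(self):
        cands = [
            MatchCandidate("t1", "c1", 2, 0),
            MatchCandidate("t1", "c2", 5, 0),
        ]
        report = greedy_match(cands, ["t1"], ["c1", "c2"])
        assert report.matched_pairs[0].candidate_id == "c1"
        assert report.fp_ids == {"c2"}

    def test_empty_candidate_list(self):
        report = greedy_match([], ["t1", "t2", "t3"], ["c1", "c2"])
        assert (len(report.tp_ids), len(report.fn_ids), len(report.fp_ids)) == (0, 3, 2)
        assert report.sensitivity == 0.0 and report.precision == 0.0

    def test_self_match_is_perfect(self):
        pool = generate_synthetic_pool(n_genes=10, seed=17)
        txs = list(pool.transcripts())
        report = match_sets(txs, txs, backend="coord")
        assert report.sensitivity == 1.0 and report.precision == 1.0
        assert all(p.score == 0.0 for p in report.matched_pairs)

    def test_added_unmatched_candidate_lowers_precision(self):
        t = tx("T", [(0, 1000)])
        good = tx("C", [(0, 1000)])
        junk = tx("J", [(5000, 6000)])
        before = match_sets([t], [good], backend="coord")
        after = match_sets([t], [good, junk], backend="coord")
        assert len(after.tp_ids) >= len(before.tp_ids)
        assert after.precision < before.precision

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        n_true=st.integers(0, 8),
        n_cand=st.integers(0, 8),
        seed=st.integers(0, 10_000),
    )
    def test_equivalent_to_bruteforce_traversal(self, n_true, n_cand, seed):
        rng = np.random.default_rng(seed)
        true_ids = [f"t{i}" for i in range(n_true)]
        cand_ids = [f"c{j}" for j in range(n_cand)]
        cands = [
            MatchCandidate(ti, cj, int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            for ti in true_ids
            for cj in cand_ids
            if rng.random() < 0.6
        ]
        fast = greedy_match(cands, true_ids, cand_ids)
        slow = brute_force_greedy(cands, true_ids, cand_ids)
        assert list(fast.matched_pairs) == slow
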