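"""One-to-one matching of candidate transcripts against the expressed truth.

A candidate transcript may be *matched* to a true (expressed) transcript
when three criteria hold:

(a) the common region covers at least 80% of the true spliced length,
(b) the common region contains every inner exon of the true transcript
    (internal splice boundaries must be recovered exactly),
(c) the candidate's total length differs from the true length by at
    most 20%.

Each admissible pair gets a mismatch score ``m = sqrt(d1^2 + d2^2)``
from the unmatched lengths ``d1`` (5' end) and ``d2`` (3' end); when
several anchorings are possible the one minimizing ``m`` is used.  The
pairs are then traversed in increasing-score order and accepted
greedily, so every true and every candidate transcript is used at most
once.  Matched candidates are TP, unmatched truths FN, unmatched
candidates FP.

Two backends produce the admissible pairs: a *coordinate* backend for
genome-guided candidates given as exon chains (common region = genomic
overlap under exact intron-chain agreement over the true transcript's
span) and a *sequence* backend for de novo candidates given as spliced
sequences (common region = longest exact common substring, found by
k-mer seeding and extension, in either orientation).  On error-free
data the two agree.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

from .pool import TranscriptModel, TranscriptPool, reverse_complement

__all__ = [
    "MatchCandidate",
    "MatchReport",
    "mismatch_score",
    "find_candidates",
    "find_candidates_coordinates",
    "find_candidates_sequences",
    "greedy_match",
    "match_sets",
]

MIN_COMMON_FRACTION = 0.8
MAX_LENGTH_DIFF_FRACTION = 0.2


def mismatch_score(d1: float, d2: float) -> float:
    """Euclidean combination of the two end-mismatch lengths."""
    if d1 < 0 or d2 < 0:
        raise ValueError("end-mismatch lengths must be non-negative")
    return math.hypot(d1, d2)


@dataclass(frozen=True)
class MatchCandidate:
    true_id: str
    candidate_id: str
    d1: int  # 5' end mismatch, bases
    d2: int  # 3' end mismatch, bases

    @property
    def score(self) -> float:
        return mismatch_score(self.d1, self.d2)


@dataclass(frozen=True)
class MatchReport:
    matched_pairs: tuple[MatchCandidate, ...]
    tp_ids: frozenset[str]  # true ids that were matched
    fn_ids: frozenset[str]
    fp_ids: frozenset[str]  # candidate ids left unmatched

    @property
    def sensitivity(self) -> float:
        denom = len(self.tp_ids) + len(self.fn_ids)
        return len(self.tp_ids) / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = len(self.tp_ids) + len(self.fp_ids)
        return len(self.tp_ids) / denom if denom else 0.0

    def candidate_of(self) -> dict[str, str]:
        """Matched true_id -> candidate_id."""
        return {p.true_id: p.candidate_id for p in self.matched_pairs}

    def true_of(self) -> dict[str, str]:
        """Matched candidate_id -> true_id."""
        return {p.candidate_id: p.true_id for p in self.matched_pairs}


# ---------------------------------------------------------------------------
# Coordinate backend
# ---------------------------------------------------------------------------

def _spliced_before(tx: TranscriptModel, pos: int) -> int:
    """Spliced bases of ``tx`` at genomic coordinates < pos."""
    total = 0
    for e in tx.exons:
        if e.end <= pos:
            total += len(e)
        elif e.start < pos:
            total += pos - e.start
    return total


def _spliced_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total genomic intersection of the two exon chains, in bases."""
    total = 0
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        ea, eb = a.exons[i], b.exons[j]
        lo, hi = max(ea.start, eb.start), min(ea.end, eb.end)
        if lo < hi:
            total += hi - lo
        if ea.end <= eb.end:
            i += 1
        else:
            j += 1
    return total


def _coord_pair(true_tx: TranscriptModel, cand_tx: TranscriptModel) -> MatchCandidate | None:
    if true_tx.chrom != cand_tx.chrom or true_tx.strand != cand_tx.strand:
        return None
    lt, lc = true_tx.spliced_length, cand_tx.spliced_length
    if abs(lc - lt) > MAX_LENGTH_DIFF_FRACTION * lt:
        return None

    # intron chains must agree over the true transcript's genomic span:
    # every true intron is a candidate intron, and the candidate has no
    # other introns inside the span (internal boundaries match exactly)
    cand_introns = set(cand_tx.introns)
    if not set(true_tx.introns) <= cand_introns:
        return None
    for s, e in cand_tx.introns:
        if e > true_tx.start and s < true_tx.end and (s, e) not in true_tx.introns:
            return None

    common = _spliced_overlap(true_tx, cand_tx)
    if common < MIN_COMMON_FRACTION * lt:
        return None

    ovl_start = max(true_tx.start, cand_tx.start)
    ovl_end = min(true_tx.end, cand_tx.end)
    if ovl_start >= ovl_end:
        return None
    d_left = _spliced_before(true_tx, ovl_start) + _spliced_before(cand_tx, ovl_start)
    d_right = (lt - _spliced_before(true_tx, ovl_end)) + (
        lc - _spliced_before(cand_tx, ovl_end)
    )
    if true_tx.strand == "+":
        d1, d2 = d_left, d_right
    else:
        d1, d2 = d_right, d_left
    return MatchCandidate(
        true_id=true_tx.transcript_id,
        candidate_id=cand_tx.transcript_id,
        d1=d1,
        d2=d2,
    )


def find_candidates_coordinates(
    truth: Sequence[TranscriptModel], candidates: Sequence[TranscriptModel]
) -> list[MatchCandidate]:
    """Admissible (true, candidate) pairs from exon-chain comparison."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)
    out: list[MatchCandidate] = []
    for t in truth:
        lst = by_chrom.get(t.chrom, [])
        starts = [c.start for c in lst]
        # candidates overlapping t's span can start anywhere before t.end
        hi = bisect_left(starts, t.end)
        for c in lst[:hi]:
            if c.end <= t.start:
                continue
            pair = _coord_pair(t, c)
            if pair is not None:
                out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Sequence backend
# ---------------------------------------------------------------------------

def _maximal_blocks(true_seq: str, cand_seq: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact common blocks (true_off, cand_off, length), k-mer seeded."""
    index: dict[str, list[int]] = {}
    for j in range(len(cand_seq) - k + 1):
        index.setdefault(cand_seq[j : j + k], []).append(j)
    blocks: list[tuple[int, int, int]] = []
    # furthest position already covered on each diagonal (i - j)
    covered: dict[int, int] = {}
    for i in range(len(true_seq) - k + 1):
        hits = index.get(true_seq[i : i + k])
        if not hits:
            continue
        for j in hits:
            diag = i - j
            if covered.get(diag, -1) >= i:
                continue
            a, b = i, j
            while a > 0 and b > 0 and true_seq[a - 1] == cand_seq[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = i + k, j + k
            while e1 < len(true_seq) and e2 < len(cand_seq) and true_seq[e1] == cand_seq[e2]:
                e1 += 1
                e2 += 1
            covered[diag] = e1
            blocks.append((a, b, e1 - a))
    return blocks


def inner_exon_spliced_spans(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Spliced-coordinate intervals of the inner exons, 5'->3' orientation."""
    exons = tx.exons if tx.strand == "+" else tuple(reversed(tx.exons))
    spans = []
    off = 0
    for idx, e in enumerate(exons):
        if 0 < idx < len(exons) - 1:
            spans.append((off, off + len(e)))
        off += len(e)
    return spans


def find_candidates_sequences(
    true_seqs: Mapping[str, str],
    candidate_seqs: Mapping[str, str],
    inner_spans: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    k: int = 31,
    both_orientations: bool = True,
) -> list[MatchCandidate]:
    """Admissible pairs from spliced-sequence comparison (de novo sets).

    ``inner_spans`` gives, per true transcript, the spliced intervals of
    its inner exons; when omitted (pure FASTA truth) the inner-exon
    criterion is vacuous.  Candidates are tried in both orientations by
    default since de novo assemblies are unstranded.
    """
    if inner_spans is None:
        inner_spans = {}
    if true_seqs and candidate_seqs:
        shortest = min(
            min(len(s) for s in true_seqs.values()),
            min(len(s) for s in candidate_seqs.values()),
        )
        k = max(min(k, shortest), 4)
    # prefilter: candidate ids sharing at least one k-mer with each truth
    kmer_cands: dict[str, set[str]] = {}
    cand_variants: dict[str, list[str]] = {}
    for cid, seq in candidate_seqs.items():
        variants = [seq, reverse_complement(seq)] if both_orientations else [seq]
        cand_variants[cid] = variants
        for v in variants:
            for j in range(0, max(len(v) - k + 1, 1), k):
                kmer_cands.setdefault(v[j : j + k], set()).add(cid)

    out: list[MatchCandidate] = []
    for tid, tseq in true_seqs.items():
        lt = len(tseq)
        hit_ids: set[str] = set()
        for i in range(len(tseq) - k + 1):
            s = kmer_cands.get(tseq[i : i + k])
            if s:
                hit_ids |= s
        spans = inner_spans.get(tid, [])
        for cid in sorted(hit_ids):
            lc = len(candidate_seqs[cid])
            if abs(lc - lt) > MAX_LENGTH_DIFF_FRACTION * lt:
                continue
            pair_best: MatchCandidate | None = None
            for v in cand_variants[cid]:
                for a, b, length in _maximal_blocks(tseq, v, min(k, lt, lc)):
                    if length < MIN_COMMON_FRACTION * lt:
                        continue
                    if any(not (a <= s and e <= a + length) for s, e in spans):
                        continue
                    d1 = a + b
                    d2 = (lt - (a + length)) + (lc - (b + length))
                    cand = MatchCandidate(tid, cid, d1, d2)
                    if pair_best is None or cand.score < pair_best.score:
                        pair_best = cand
            if pair_best is not None:
                out.append(pair_best)
    return out


# ---------------------------------------------------------------------------
# Greedy one-to-one matching
# ---------------------------------------------------------------------------

def greedy_match(
    candidates: Sequence[MatchCandidate],
    true_ids: Sequence[str],
    candidate_ids: Sequence[str],
) -> MatchReport:
    """Accept pairs in increasing mismatch-score order, one use per id.

    Ties are broken lexicographically on (true_id, candidate_id) so the
    traversal is deterministic.
    """
    order = sorted(candidates, key=lambda c: (c.score, c.true_id, c.candidate_id))
    used_true: set[str] = set()
    used_cand: set[str] = set()
    accepted: list[MatchCandidate] = []
    for c in order:
        if c.true_id in used_true or c.candidate_id in used_cand:
            continue
        accepted.append(c)
        used_true.add(c.true_id)
        used_cand.add(c.candidate_id)
    return MatchReport(
        matched_pairs=tuple(accepted),
        tp_ids=frozenset(used_true),
        fn_ids=frozenset(true_ids) - used_true,
        fp_ids=frozenset(candidate_ids) - used_cand,
    )


def find_candidates(
    truth,
    candidates,
    backend: str = "coord",
    truth_pool: TranscriptPool | None = None,
    k: int = 31,
) -> list[MatchCandidate]:
    """Dispatch to the coordinate or sequence backend.

    coord: ``truth`` and ``candidates`` are sequences of TranscriptModel.
    seq:   ``truth`` and ``candidates`` are id -> spliced sequence maps;
           pass ``truth_pool`` to enforce the inner-exon criterion.
    """
    if backend == "coord":
        return find_candidates_coordinates(truth, candidates)
    if backend == "seq":
        spans = None
        if truth_pool is not None:
            by_id = truth_pool.by_id()
            spans = {
                tid: inner_exon_spliced_spans(by_id[tid])
                for tid in truth
                if tid in by_id
            }
        return find_candidates_sequences(truth, candidates, inner_spans=spans, k=k)
    raise ValueError("backend must be 'coord' or 'seq'")


def match_sets(
    truth,
    candidates,
    backend: str = "coord",
    truth_pool: TranscriptPool | None = None,
) -> MatchReport:
    """find_candidates + greedy_match in one call."""
    pairs = find_candidates(truth, candidates, backend=backend, truth_pool=truth_pool)
    if backend == "coord":
        tids = [t.transcript_id for t in truth]
        cids = [c.transcript_id for c in candidates]
    else:
        tids, cids = list(truth), list(candidates)
    return greedy_match(pairs, tids, cids)
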