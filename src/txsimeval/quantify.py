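"""Expression estimation on a discovered transcript set, plus the
accuracy and signal-absorption metrics.

The built-in quantifier is a deliberately simple exact-match EM: each
error-free read pair is assigned the set of transcripts that contain
both mates at insert-consistent positions, pairs are collapsed into
equivalence classes by that set, and EM maximizes the multinomial
likelihood over per-transcript fragment proportions.  Estimates are
reported in FPKM-like units (proportion x 1e9 / effective length).
External quantifier output can be ingested instead via a two-column
table.

Evaluation reports the Pearson correlation of log true vs log estimated
expression over TP transcripts, and the signal-absorption ratio
FPbar/TPbar = mean(FP estimates) / mean(TP estimates): zero means false
transcripts absorbed no expression signal, one means they absorb as
much on average as the real ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import AnnotationSet
from .expression import ExpressionProfile
from .matching import MatchReport
from .reads import DEFAULT_INSERT_MEAN, DEFAULT_INSERT_SD

__all__ = [
    "ExpressionEstimate",
    "EvalMetrics",
    "quantify_em",
    "read_external_estimates",
    "evaluate",
]


@dataclass(frozen=True)
class ExpressionEstimate:
    values: dict[str, float]
    source: str  # "builtin-em" | "external-table"
    n_unmapped: int = 0
    log_likelihoods: tuple[float, ...] = ()
    proportions: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvalMetrics:
    corr_tp: float
    fp_tp_ratio: float
    sensitivity: float
    precision: float
    n_tp_used: int
    n_tp_zero_estimate: int


# ---------------------------------------------------------------------------
# Built-in EM quantifier
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _build_read_index(seqs: Mapping[str, str], read_length: int):
    tids = sorted(seqs)
    index: dict[str, list[tuple[int, int]]] = {}
    for t_idx, tid in enumerate(tids):
        seq = seqs[tid]
        for i in range(len(seq) - read_length + 1):
            index.setdefault(seq[i : i + read_length], []).append((t_idx, i))
    return tids, index


def _compatible_transcripts(
    m1: str,
    m2: str,
    index: Mapping[str, list[tuple[int, int]]],
    read_length: int,
    max_insert: float,
) -> frozenset[int] | None:
    """Transcript indices containing both mates at insert-consistent offsets."""
    occ1 = index.get(m1)
    if not occ1:
        return None
    occ2 = index.get(m2.translate(_COMPLEMENT)[::-1])
    if not occ2:
        return None
    pos1: dict[int, list[int]] = {}
    for t, p in occ1:
        pos1.setdefault(t, []).append(p)
    hits = set()
    for t, p2 in occ2:
        ps = pos1.get(t)
        if ps is None:
            continue
        for p1 in ps:
            ins = p2 + read_length - p1
            if read_length <= ins <= max_insert:
                hits.add(t)
                break
    return frozenset(hits) if hits else None


def quantify_em(
    read_pairs: Iterable[tuple[str, str]],
    transcript_seqs: Mapping[str, str],
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ExpressionEstimate:
    """Estimate transcript abundances from error-free pairs by EM.

    ``read_pairs`` are (mate1, mate2) sequences; ``transcript_seqs``
    the spliced sequences of the discovered set (TP and FP together,
    as a real experiment would quantify them).  Initialization is
    uniform so the fit is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic stages.
    """
    del seed
    if not transcript_seqs:
        raise ValueError("empty transcript set")
    pairs = list(read_pairs)
    read_length = len(pairs[0][0]) if pairs else 0
    tids, index = _build_read_index(transcript_seqs, read_length) if pairs else (sorted(transcript_seqs), {})
    max_insert = insert_mean + 4.0 * insert_sd

    class_counts: dict[frozenset[int], int] = {}
    n_unmapped = 0
    for m1, m2 in pairs:
        hit = _compatible_transcripts(m1, m2, index, read_length, max_insert)
        if hit is None:
            n_unmapped += 1
        else:
            class_counts[hit] = class_counts.get(hit, 0) + 1
    n_mapped = sum(class_counts.values())
    if n_mapped == 0:
        warnings.warn("no read pair mapped to the transcript set; all estimates zero")
        return ExpressionEstimate(
            values={t: 0.0 for t in tids}, source="builtin-em", n_unmapped=n_unmapped
        )

    n_tx = len(tids)
    classes = sorted(class_counts.items(), key=lambda kv: sorted(kv[0]))
    counts = np.array([c for _, c in classes], dtype=float)
    flat_t = np.concatenate([np.fromiter(sorted(s), int) for s, _ in classes])
    flat_c = np.concatenate(
        [np.full(len(s), ci, dtype=int) for ci, (s, _) in enumerate(classes)]
    )

    pi = np.full(n_tx, 1.0 / n_tx)
    log_liks: list[float] = []
    for _ in range(max_iter):
        w = pi[flat_t]
        denom = np.zeros(len(classes))
        np.add.at(denom, flat_c, w)
        log_liks.append(float(np.dot(counts, np.log(denom))))
        gamma = w * (counts[flat_c] / denom[flat_c])
        pi_new = np.zeros(n_tx)
        np.add.at(pi_new, flat_t, gamma)
        pi_new /= n_mapped
        delta = float(np.max(np.abs(pi_new - pi)))
        pi = pi_new
        if delta < tol:
            break
    w = pi[flat_t]
    denom = np.zeros(len(classes))
    np.add.at(denom, flat_c, w)
    with np.errstate(divide="ignore"):
        log_liks.append(float(np.dot(counts, np.log(denom))))

    # a transcript whose posterior fragment count is numerically zero is
    # undetected: report 0 rather than an underflowed positive residue
    pi[pi * n_mapped < 1e-3] = 0.0
    eff_len = np.array(
        [max(len(transcript_seqs[t]) - insert_mean + 1.0, 1.0) for t in tids]
    )
    fpkm = pi * 1e9 / eff_len
    return ExpressionEstimate(
        values={t: float(v) for t, v in zip(tids, fpkm)},
        source="builtin-em",
        n_unmapped=n_unmapped,
        log_likelihoods=tuple(log_liks),
        proportions={t: float(v) for t, v in zip(tids, pi)},
    )


# ---------------------------------------------------------------------------
# External estimates
# ---------------------------------------------------------------------------

def read_external_estimates(path: str, discovered_ids: Iterable[str]) -> ExpressionEstimate:
    """Read a two-column (transcript_id, value) table from another quantifier.

    Ids outside the discovered set are dropped (with a warning); ids of
    the discovered set missing from the table get value 0.
    """
    discovered = set(discovered_ids)
    values: dict[str, float] = {t: 0.0 for t in discovered}
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            tid, raw = fields[0], fields[1]
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value {raw!r}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative expression value {value}")
            if tid in discovered:
                values[tid] = value
            else:
                n_extra += 1
    if n_extra:
        warnings.warn(f"{n_extra} table rows outside the discovered set were dropped")
    return ExpressionEstimate(values=values, source="external-table")


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def _tp_fp_partition(labels, truth: ExpressionProfile):
    """(tp map: discovered id -> true id, fp ids, sensitivity, precision)."""
    if isinstance(labels, MatchReport):
        tp_map = {p.candidate_id: p.true_id for p in labels.matched_pairs}
        return tp_map, set(labels.fp_ids), labels.sensitivity, labels.precision
    if isinstance(labels, AnnotationSet):
        tp_ids = labels.ids_with_label("TP")
        fp_ids = labels.annotated_ids - tp_ids
        expressed = truth.expressed_ids()
        fn = len(expressed - tp_ids)
        sens = len(tp_ids) / (len(tp_ids) + fn) if tp_ids or fn else 0.0
        prec = len(tp_ids) / len(labels.annotated_ids) if labels.annotated_ids else 0.0
        return {t: t for t in tp_ids}, fp_ids, sens, prec
    raise TypeError("labels must be a MatchReport or an AnnotationSet")


def evaluate(
    truth: ExpressionProfile,
    estimate: ExpressionEstimate,
    labels,
) -> EvalMetrics:
    """Accuracy and signal-absorption metrics of a quantified set.

    corr_tp is the Pearson correlation of (ln true, ln estimated) over
    TP transcripts with a positive estimate (zero-estimate TPs are
    excluded and counted); FPbar/TPbar is a ratio of raw-scale means.
    The 'true' value of every FP transcript is zero by definition.
    """
    tp_map, fp_ids, sens, prec = _tp_fp_partition(labels, truth)

    tp_true, tp_est = [], []
    n_zero = 0
    for disc_id, true_id in sorted(tp_map.items()):
        est = estimate.values.get(disc_id, 0.0)
        if est > 0:
            tp_true.append(truth.values[true_id])
            tp_est.append(est)
        else:
            n_zero += 1
    if len(tp_true) < 3:
        raise ValueError(
            f"only {len(tp_true)} TP transcripts with positive estimates; "
            "correlation is undefined"
        )
    corr = float(stats.pearsonr(np.log(tp_true), np.log(tp_est)).statistic)

    all_tp_est = [estimate.values.get(d, 0.0) for d in tp_map]
    mean_tp = float(np.mean(all_tp_est))
    if mean_tp <= 0:
        raise ValueError("mean TP estimate is zero; FPbar/TPbar is undefined")
    fp_est = [estimate.values.get(d, 0.0) for d in sorted(fp_ids)]
    ratio = float(np.mean(fp_est)) / mean_tp if fp_est else 0.0

    return EvalMetrics(
        corr_tp=corr,
        fp_tp_ratio=ratio,
        sensitivity=sens,
        precision=prec,
        n_tp_used=len(tp_true),
        n_tp_zero_estimate=n_zero,
    )
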