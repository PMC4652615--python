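"""Simulation of imperfect curated annotations with controlled accuracy.

Given a requested sensitivity ``s`` and precision ``p`` relative to the
expressed transcripts, the annotation is described by four counts:

* ``TP``   annotated and expressed,
* ``FN``   expressed but not annotated,
* ``FP_a`` annotated false positives from unexpressed isoforms of
  active genes,
* ``FP_s`` annotated false positives from silent genes.

They satisfy four simultaneous constraints: N_e = TP + FN,
s = TP/(TP+FN), p = TP/(TP+FP_a+FP_s), and — because the annotated
fraction is assumed equal for active and silent genes —
(TP+FP_a)/FP_s = f_g/(1-f_g).  The closed-form solution is

    TP   = s * N_e
    FN   = (1-s) * N_e
    FP_s = (1-f_g) * TP / p
    FP_a = TP * (f_g - p) / p

which is feasible only when p <= f_g (or p = 1, a perfect annotation
with no false positives at all).  Sampling within each stratum is
uniform without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import PoolPartition

__all__ = [
    "AnnotationSpec",
    "AnnotationCounts",
    "AnnotationSet",
    "solve_annotation_counts",
    "sample_annotation",
    "InfeasibleAnnotationError",
]


class InfeasibleAnnotationError(ValueError):
    """The requested (s, p) cannot be realized for this partition."""


@dataclass(frozen=True)
class AnnotationSpec:
    s: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s <= 1.0):
            raise ValueError("sensitivity must lie in (0, 1]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("precision must lie in (0, 1]")


@dataclass(frozen=True)
class AnnotationCounts:
    TP: int
    FN: int
    FP_a: int
    FP_s: int

    @property
    def n_annotated(self) -> int:
        return self.TP + self.FP_a + self.FP_s

    @property
    def realized_sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def realized_precision(self) -> float:
        return self.TP / self.n_annotated if self.n_annotated else 0.0


@dataclass(frozen=True)
class AnnotationSet:
    annotated_ids: frozenset[str]
    labels: dict[str, str]  # id -> TP | FP_a | FP_s

    def ids_with_label(self, label: str) -> set[str]:
        return {t for t, lab in self.labels.items() if lab == label}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.labels.items())
        return pd.DataFrame(rows, columns=["transcript_id", "label"])


def solve_annotation_counts(
    spec: AnnotationSpec, f_g: float, N_e: int, N_u: int, N_s: int
) -> AnnotationCounts:
    """Solve the annotation-count equations for a requested (s, p).

    Rounding is deterministic: TP is rounded first and FN derived from
    N_e; then FP_s is rounded and FP_a rounded independently.  Callers
    should report the realized sensitivity/precision of the result,
    which can differ from the request by integer quantization only.
    """
    if not (0.0 < f_g < 1.0) and not (f_g == 1.0 and spec.p == 1.0):
        if f_g == 1.0:
            raise InfeasibleAnnotationError(
                "f_g = 1 leaves no silent genes: only p = 1 is representable"
            )
        raise ValueError("f_g must lie in (0, 1)")
    if N_e <= 0:
        raise ValueError("N_e must be positive")

    TP = int(round(spec.s * N_e))
    TP = max(TP, 1)  # s > 0 means at least one annotated expressed transcript
    FN = N_e - TP

    if spec.p == 1.0:
        counts = AnnotationCounts(TP=TP, FN=FN, FP_a=0, FP_s=0)
    else:
        if spec.p > f_g:
            raise InfeasibleAnnotationError(
                f"precision {spec.p} > f_g {f_g}: the equal-annotated-fraction "
                "constraint forces FP_a < 0; request p <= f_g (or p = 1)"
            )
        FP_s = int(round((1.0 - f_g) * TP / spec.p))
        FP_a = int(round(TP * (f_g - spec.p) / spec.p))
        counts = AnnotationCounts(TP=TP, FN=FN, FP_a=FP_a, FP_s=FP_s)
        if counts.FP_a > N_u or counts.FP_s > N_s:
            raise InfeasibleAnnotationError(
                f"annotation needs FP_a={counts.FP_a} (have N_u={N_u}) and "
                f"FP_s={counts.FP_s} (have N_s={N_s}); lower s, raise p "
                "towards f_g, or enlarge the pool"
            )
    return counts


def sample_annotation(
    partition: PoolPartition, counts: AnnotationCounts, seed: int = 0
) -> AnnotationSet:
    """Draw the annotated transcript set realizing the solved counts.

    TP ids come uniformly without replacement from the expressed set,
    FP_a from unexpressed isoforms of active genes, FP_s from silent
    genes.  Deterministic per seed.
    """
    if counts.TP > partition.n_expressed:
        raise InfeasibleAnnotationError("TP exceeds the number of expressed transcripts")
    if counts.FP_a > partition.n_unexpressed_active:
        raise InfeasibleAnnotationError("FP_a exceeds the unexpressed-active stratum")
    if counts.FP_s > partition.n_silent:
        raise InfeasibleAnnotationError("FP_s exceeds the silent stratum")
    rng = np.random.default_rng(seed)

    def draw(ids: frozenset[str], k: int) -> list[str]:
        return list(rng.choice(sorted(ids), size=k, replace=False)) if k else []

    labels: dict[str, str] = {}
    for tid in draw(partition.expressed_ids, counts.TP):
        labels[tid] = "TP"
    for tid in draw(partition.unexpressed_active_ids, counts.FP_a):
        labels[tid] = "FP_a"
    for tid in draw(partition.silent_ids, counts.FP_s):
        labels[tid] = "FP_s"
    return AnnotationSet(annotated_ids=frozenset(labels), labels=labels)
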