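"""Partitioning the pool into expressed / unexpressed / silent transcripts
and assigning gamma-distributed true expression values.

A fraction ``f_g`` of genes is designated *active*; within each active
gene a fraction ``f_t`` of isoforms is designated *expressed* (at least
one per active gene).  Transcripts of the remaining silent genes are
never expressed.  Expressed transcripts receive independent draws from
a Gamma(shape=alpha, rate=beta) distribution — by default alpha=1.2 and
beta=0.001, which spans the wide dynamic range of abundances seen in
real RNA samples; everything else is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import TranscriptPool

__all__ = [
    "PoolPartition",
    "ExpressionProfile",
    "partition_pool",
    "sample_expression",
    "DEFAULT_F_G",
    "DEFAULT_F_T",
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
]

DEFAULT_F_G = 0.5
DEFAULT_F_T = 0.5
DEFAULT_ALPHA = 1.2
DEFAULT_BETA = 0.001


@dataclass(frozen=True)
class PoolPartition:
    f_g: float
    f_t: float
    expressed_ids: frozenset[str]
    unexpressed_active_ids: frozenset[str]
    silent_ids: frozenset[str]

    @property
    def n_expressed(self) -> int:
        return len(self.expressed_ids)

    @property
    def n_unexpressed_active(self) -> int:
        return len(self.unexpressed_active_ids)

    @property
    def n_silent(self) -> int:
        return len(self.silent_ids)

    def labels(self) -> dict[str, str]:
        out = {t: "expressed" for t in self.expressed_ids}
        out.update({t: "unexpressed_active" for t in self.unexpressed_active_ids})
        out.update({t: "silent" for t in self.silent_ids})
        return out


@dataclass(frozen=True)
class ExpressionProfile:
    """True abundances: positive exactly on expressed transcripts."""

    alpha: float
    beta: float
    values: dict[str, float] = field(default_factory=dict)

    def expressed_ids(self) -> set[str]:
        return {t for t, v in self.values.items() if v > 0}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": list(self.values), "true_value": list(self.values.values())}
        )


def partition_pool(
    pool: TranscriptPool,
    f_g: float = DEFAULT_F_G,
    f_t: float = DEFAULT_F_T,
    seed: int = 0,
) -> PoolPartition:
    """Sample the expressed / unexpressed-active / silent partition.

    ``round(f_g * n_genes)`` genes are drawn uniformly as active;
    within each active gene ``round(f_t * n_isoforms)`` isoforms (at
    least one — an active gene must express something) are drawn
    uniformly as expressed.  Deterministic per seed.
    """
    if not (0.0 < f_g <= 1.0) or not (0.0 < f_t <= 1.0):
        raise ValueError("f_g and f_t must lie in (0, 1]")
    if pool.n_genes == 0:
        raise ValueError("cannot partition an empty pool")
    rng = np.random.default_rng(seed)

    gene_ids = sorted(pool.genes)
    n_active = int(round(f_g * len(gene_ids)))
    active = set(rng.choice(gene_ids, size=n_active, replace=False)) if n_active else set()

    expressed: set[str] = set()
    unexpressed_active: set[str] = set()
    silent: set[str] = set()
    for gene_id in gene_ids:
        tids = sorted(t.transcript_id for t in pool.genes[gene_id])
        if gene_id in active:
            k = max(1, int(round(f_t * len(tids))))
            chosen = set(rng.choice(tids, size=k, replace=False))
            expressed |= chosen
            unexpressed_active |= set(tids) - chosen
        else:
            silent |= set(tids)
    return PoolPartition(
        f_g=f_g,
        f_t=f_t,
        expressed_ids=frozenset(expressed),
        unexpressed_active_ids=frozenset(unexpressed_active),
        silent_ids=frozenset(silent),
    )


def sample_expression(
    partition: PoolPartition,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    seed: int = 0,
) -> ExpressionProfile:
    """Draw Gamma(alpha, rate=beta) abundances for expressed transcripts.

    Non-expressed transcripts get exactly 0.  Deterministic per seed.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma shape and rate must be positive")
    rng = np.random.default_rng(seed)
    expressed = sorted(partition.expressed_ids)
    draws = rng.gamma(shape=alpha, scale=1.0 / beta, size=len(expressed))
    values: dict[str, float] = {t: float(v) for t, v in zip(expressed, draws)}
    for t in partition.unexpressed_active_ids | partition.silent_ids:
        values[t] = 0.0
    return ExpressionProfile(alpha=alpha, beta=beta, values=values)


def write_partition_tsv(
    partition: PoolPartition, profile: ExpressionProfile, path: str
) -> None:
    """Serialize labels and true values as TSV (transcript_id, label, true_value)."""
    labels = partition.labels()
    rows = [
        {"transcript_id": t, "label": lab, "true_value": profile.values.get(t, 0.0)}
        for t, lab in sorted(labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
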