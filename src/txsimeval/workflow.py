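"""End-to-end experiment orchestration.

One config drives the whole simulation flow: pool -> partition ->
expression -> reads -> {simulated annotation grid | external candidate
sets} -> matching -> quantification -> metrics.  The pool is built once
per experiment; partition, expression values, reads and annotations are
resampled independently for every replicate, and each grid cell reports
the mean of its metrics over replicates.  A master seed fans out
deterministically to every stage and replicate, so a rerun of the same
config and seed reproduces the experiment exactly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd
import yaml

from . import annotation as ann
from . import expression as expr
from . import matching as mt
from . import quantify as qt
from . import reads as rd
from .pool import (
    ShiftedPoisson,
    TranscriptPool,
    UniformInt,
    filter_duplicates,
    generate_synthetic_pool,
    read_fasta,
    read_pool,
    write_pool,
)

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed"]


def stage_seed(master_seed: int, stage: str, replicate: int = 0, extra: int = 0) -> int:
    """Deterministic per-stage, per-replicate seed below 2^31."""
    key = f"{master_seed}:{stage}:{replicate}:{extra}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SyntheticPoolSpec:
    n_genes: int = 500
    isoform_mean: float = 4.0
    exon_count_mean: float = 8.0
    exon_len_range: tuple[int, int] = (100, 300)
    intron_len_range: tuple[int, int] = (200, 500)
    paralog_rate: float = 0.0


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    replicates: int = 1
    synthetic_pool: SyntheticPoolSpec | None = field(default_factory=SyntheticPoolSpec)
    pool_gtf: str | None = None
    pool_fasta: str | None = None
    f_g: float = expr.DEFAULT_F_G
    f_t: float = expr.DEFAULT_F_T
    alpha: float = expr.DEFAULT_ALPHA
    beta: float = expr.DEFAULT_BETA
    read_length: int = rd.DEFAULT_READ_LENGTH
    insert_mean: float = rd.DEFAULT_INSERT_MEAN
    insert_sd: float = rd.DEFAULT_INSERT_SD
    coverage: float | None = 100.0
    n_fragments: int | None = None
    annotation_grid: tuple[tuple[float, float], ...] = ()
    candidate_sets: tuple[tuple[str, str], ...] = ()  # (name, path to .gtf/.fa)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.synthetic_pool is None and self.pool_gtf is None:
            raise ValueError("configure either a synthetic pool or a pool GTF")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        pool = d.get("pool", {})
        syn = None
        if "synthetic" in pool or not pool.get("gtf"):
            s = pool.get("synthetic", {})
            syn = SyntheticPoolSpec(
                n_genes=int(s.get("n_genes", 500)),
                isoform_mean=float(s.get("isoform_mean", 4.0)),
                exon_count_mean=float(s.get("exon_count_mean", 8.0)),
                exon_len_range=tuple(s.get("exon_len_range", (100, 300))),
                intron_len_range=tuple(s.get("intron_len_range", (200, 500))),
                paralog_rate=float(s.get("paralog_rate", 0.0)),
            )
        gamma = d.get("gamma", {})
        reads = d.get("reads", {})
        grid = tuple(
            (float(c["s"]), float(c["p"])) for c in d.get("annotations", [])
        )
        cands = tuple(
            (str(c["name"]), str(c.get("gtf") or c["fasta"]))
            for c in d.get("candidates", [])
        )
        return cls(
            seed=int(d.get("seed", 0)),
            replicates=int(d.get("replicates", 1)),
            synthetic_pool=syn,
            pool_gtf=pool.get("gtf"),
            pool_fasta=pool.get("fasta"),
            f_g=float(d.get("f_g", expr.DEFAULT_F_G)),
            f_t=float(d.get("f_t", expr.DEFAULT_F_T)),
            alpha=float(gamma.get("alpha", expr.DEFAULT_ALPHA)),
            beta=float(gamma.get("beta", expr.DEFAULT_BETA)),
            read_length=int(reads.get("read_length", rd.DEFAULT_READ_LENGTH)),
            insert_mean=float(reads.get("insert_mean", rd.DEFAULT_INSERT_MEAN)),
            insert_sd=float(reads.get("insert_sd", rd.DEFAULT_INSERT_SD)),
            coverage=(
                float(reads["coverage"]) if "coverage" in reads
                else (None if "n_fragments" in reads else 100.0)
            ),
            n_fragments=(
                int(reads["n_fragments"]) if "n_fragments" in reads else None
            ),
            annotation_grid=grid,
            candidate_sets=cands,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build_pool(config: ExperimentConfig) -> TranscriptPool:
    if config.pool_gtf is not None:
        pool = read_pool(config.pool_gtf, config.pool_fasta)
    else:
        s = config.synthetic_pool
        pool = generate_synthetic_pool(
            n_genes=s.n_genes,
            isoform_dist=ShiftedPoisson(s.isoform_mean),
            exon_count_dist=ShiftedPoisson(s.exon_count_mean),
            exon_len_dist=UniformInt(*s.exon_len_range),
            intron_len_dist=UniformInt(*s.intron_len_range),
            paralog_rate=s.paralog_rate,
            seed=stage_seed(config.seed, "pool"),
        )
    return filter_duplicates(pool)


def _load_candidate_set(path: str):
    """(backend, payload) for an external candidate file (GTF or FASTA)."""
    if path.endswith((".gtf", ".gff")):
        cand_pool = read_pool(path)
        return "coord", list(cand_pool.transcripts())
    return "seq", read_fasta(path)


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | None = None,
) -> pd.DataFrame:
    """Run the full simulation/evaluation grid; return the metrics table.

    One row per (annotation cell | candidate set): requested s and p
    where applicable, and replicate-mean sensitivity, precision,
    corr_tp and FPbar/TPbar.  Infeasible annotation cells are recorded
    with an ``error`` message and the run continues.  When ``out_dir``
    is given, per-stage artifacts (pool GTF/FASTA, truth tables, FASTQ,
    label tables, metrics) and a manifest are written beneath it.
    """
    pool = _build_pool(config)
    writing = out_dir is not None
    manifest: dict[str, Any] = {"seed": config.seed, "replicates": config.replicates}
    if writing:
        os.makedirs(out_dir, exist_ok=True)
        write_pool(
            pool,
            os.path.join(out_dir, "pool.gtf"),
            os.path.join(out_dir, "pool.fa"),
        )
        manifest["pool"] = {"gtf": "pool.gtf", "fasta": "pool.fa"}

    rows: list[dict[str, Any]] = []
    for rep in range(config.replicates):
        partition = expr.partition_pool(
            pool, config.f_g, config.f_t, seed=stage_seed(config.seed, "partition", rep)
        )
        profile = expr.sample_expression(
            partition, config.alpha, config.beta,
            seed=stage_seed(config.seed, "expression", rep),
        )
        read_cfg = rd.ReadSimConfig(
            read_length=config.read_length,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            n_fragments=config.n_fragments,
            target_coverage=config.coverage,
            seed=stage_seed(config.seed, "reads", rep),
        )
        truth_table, expressed_seqs = rd.simulate_fragments(pool, profile, read_cfg)
        pairs = rd.extract_mates(truth_table, expressed_seqs, config.read_length)
        if writing:
            rep_dir = os.path.join(out_dir, f"rep{rep}")
            os.makedirs(rep_dir, exist_ok=True)
            expr.write_partition_tsv(
                partition, profile, os.path.join(rep_dir, "expression.tsv")
            )
            rd.simulate_reads(
                pool, profile, read_cfg,
                os.path.join(rep_dir, "reads_1.fastq"),
                os.path.join(rep_dir, "reads_2.fastq"),
                os.path.join(rep_dir, "fragments.tsv"),
            )

        all_seqs = pool.spliced_sequences()

        for cell_idx, (s, p) in enumerate(config.annotation_grid):
            row: dict[str, Any] = {
                "kind": "annotation", "name": f"s={s:g},p={p:g}",
                "s_requested": s, "p_requested": p, "replicate": rep,
            }
            try:
                counts = ann.solve_annotation_counts(
                    ann.AnnotationSpec(s=s, p=p),
                    config.f_g,
                    partition.n_expressed,
                    partition.n_unexpressed_active,
                    partition.n_silent,
                )
                annot = ann.sample_annotation(
                    partition, counts,
                    seed=stage_seed(config.seed, "annotation", rep, cell_idx),
                )
                est = qt.quantify_em(
                    pairs,
                    {t: all_seqs[t] for t in annot.annotated_ids},
                    insert_mean=config.insert_mean,
                    insert_sd=config.insert_sd,
                )
                metrics = qt.evaluate(profile, est, annot)
                row.update(
                    sensitivity=metrics.sensitivity,
                    precision=metrics.precision,
                    corr_tp=metrics.corr_tp,
                    fp_tp_ratio=metrics.fp_tp_ratio,
                )
                if writing:
                    annot.to_frame().to_csv(
                        os.path.join(rep_dir, f"annotation_{cell_idx}.tsv"),
                        sep="\t", index=False,
                    )
            except (ann.InfeasibleAnnotationError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)

        expressed_txs = [
            t for t in pool.transcripts() if t.transcript_id in partition.expressed_ids
        ]
        for name, path in config.candidate_sets:
            row = {"kind": "candidate", "name": name, "replicate": rep}
            backend, payload = _load_candidate_set(path)
            if backend == "coord":
                report = mt.match_sets(expressed_txs, payload, backend="coord")
                cand_seqs = {
                    t.transcript_id: t.spliced_sequence(pool.genome) for t in payload
                }
            else:
                truth_seqs = {t: all_seqs[t] for t in partition.expressed_ids}
                report = mt.match_sets(
                    truth_seqs, payload, backend="seq", truth_pool=pool
                )
                cand_seqs = payload
            try:
                est = qt.quantify_em(
                    pairs, cand_seqs,
                    insert_mean=config.insert_mean, insert_sd=config.insert_sd,
                )
                metrics = qt.evaluate(profile, est, report)
                row.update(
                    sensitivity=metrics.sensitivity,
                    precision=metrics.precision,
                    corr_tp=metrics.corr_tp,
                    fp_tp_ratio=metrics.fp_tp_ratio,
                )
            except ValueError as exc:
                row["error"] = str(exc)
            rows.append(row)

    per_rep = pd.DataFrame(rows)
    metric_cols = [
        c for c in ("sensitivity", "precision", "corr_tp", "fp_tp_ratio")
        if c in per_rep.columns
    ]
    grid = (
        per_rep.groupby(["kind", "name"], sort=False)[metric_cols]
        .mean()
        .reset_index()
    )
    if "error" in per_rep.columns:
        errs = per_rep.groupby(["kind", "name"], sort=False)["error"].first().reset_index()
        grid = grid.merge(errs, on=["kind", "name"], how="left")

    if writing:
        per_rep.to_csv(os.path.join(out_dir, "metrics_per_replicate.tsv"), sep="\t", index=False)
        grid.to_csv(os.path.join(out_dir, "metrics_grid.tsv"), sep="\t", index=False)
        manifest["metrics"] = {
            "per_replicate": "metrics_per_replicate.tsv",
            "grid": "metrics_grid.tsv",
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return grid
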