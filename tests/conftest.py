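import numpy as np
import pytest

from txsimeval.pool import Constant, Exon, TranscriptModel, TranscriptPool, generate_synthetic_pool


@pytest.fixture(scope="session")
def tiny_pool() -> TranscriptPool:
    """A small synthetic pool with sequences, shared across tests."""
    return generate_synthetic_pool(n_genes=12, seed=101)


def make_grid_pool(n_genes: int, n_isoforms: int, with_genome: bool = False) -> TranscriptPool:
    """Deterministic pool: every gene has exactly n_isoforms distinct isoforms.

    Gene g occupies its own coordinate block; isoform k of a gene keeps
    the first and last of (n_isoforms + 1) exons and drops the k-th
    internal exon, so all chains are distinct.
    """
    rng = np.random.default_rng(7)
    n_exons = n_isoforms + 1
    exon_len, intron_len = 120, 80
    block = n_exons * (exon_len + intron_len) + 500
    genes = {}
    chrom_len = 0
    for g in range(n_genes):
        gid = f"G{g:04d}"
        base = g * block
        exons = [
            Exon("chr1", base + i * (exon_len + intron_len),
                 base + i * (exon_len + intron_len) + exon_len, "+")
            for i in range(n_exons)
        ]
        txs = []
        for k in range(n_isoforms):
            chain = tuple(e for i, e in enumerate(exons) if i == 0 or i == n_exons - 1 or i != k + 1)
            if n_isoforms == 1:
                chain = tuple(exons)
            txs.append(TranscriptModel(f"{gid}.T{k}", gid, chain))
        genes[gid] = txs
        chrom_len = base + block
    genome = {}
    if with_genome:
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=chrom_len))}
    return TranscriptPool(genes=genes, genome=genome)
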