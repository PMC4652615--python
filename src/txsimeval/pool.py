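"""Transcript pools: genes, isoforms, exon chains and their sequences.

A *transcript pool* is the universe of transcript structures from which
everything downstream is sampled: expressed transcripts, simulated
annotations and simulated reads.  Pools can be read from a GTF (plus an
optional genome FASTA), written back out, filtered for duplicate
structures, or generated synthetically so that no external download is
ever needed.

Coordinates are 0-based half-open internally; GTF IO converts to and
from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Exon",
    "TranscriptModel",
    "TranscriptPool",
    "PoolStats",
    "Constant",
    "ShiftedPoisson",
    "UniformInt",
    "read_pool",
    "write_pool",
    "write_transcript_fasta",
    "read_fasta",
    "filter_duplicates",
    "generate_synthetic_pool",
    "pool_stats",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PoolError(ValueError):
    """Structural problem in a pool or one of its input files."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PoolError(
                f"exon requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise PoolError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """An isoform: an ordered, non-overlapping exon chain on one strand.

    Exons are kept in genomic order regardless of strand; the spliced
    sequence of a minus-strand transcript is the reverse complement of
    the concatenated exon sequences.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise PoolError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise PoolError(
                f"transcript {self.transcript_id}: exons must share chrom and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise PoolError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_chain(self) -> tuple[tuple[str, int, int, str], ...]:
        """Hashable full coordinate chain; identity key for duplicates."""
        return tuple((e.chrom, e.start, e.end, e.strand) for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (0-based half-open), in genomic order."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def inner_exons(self) -> tuple[Exon, ...]:
        """Exons other than the first and last (empty for <= 2 exons)."""
        return self.exons[1:-1]

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Sense-strand spliced sequence extracted from ``genome``."""
        chrom_seq = genome[self.chrom]
        if self.end > len(chrom_seq):
            raise PoolError(
                f"transcript {self.transcript_id} extends past end of {self.chrom}"
            )
        seq = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class TranscriptPool:
    """Genome sequences plus genes -> transcripts -> exon chains."""

    genes: dict[str, list[TranscriptModel]]
    genome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, txs in self.genes.items():
            for tx in txs:
                if tx.gene_id != gene_id:
                    raise PoolError(
                        f"transcript {tx.transcript_id} filed under gene "
                        f"{gene_id} but carries gene_id {tx.gene_id}"
                    )
                if tx.transcript_id in seen:
                    raise PoolError(f"duplicate transcript_id {tx.transcript_id}")
                seen.add(tx.transcript_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def transcripts(self) -> Iterable[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs

    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts()]

    def get(self, transcript_id: str) -> TranscriptModel:
        for tx in self.transcripts():
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)

    def by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts()}

    def gene_of(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self.transcripts()}

    def spliced_sequences(self) -> dict[str, str]:
        """transcript_id -> spliced sequence; requires an attached genome."""
        if not self.genome:
            raise PoolError("pool has no genome sequences attached")
        return {
            t.transcript_id: t.spliced_sequence(self.genome)
            for t in self.transcripts()
        }

    def subset(self, transcript_ids: Iterable[str]) -> "TranscriptPool":
        """Sub-pool restricted to the given transcript ids (genome shared)."""
        wanted = set(transcript_ids)
        genes: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts():
            if tx.transcript_id in wanted:
                genes.setdefault(tx.gene_id, []).append(tx)
        return TranscriptPool(genes=genes, genome=self.genome)


@dataclass(frozen=True)
class PoolStats:
    isoforms_per_gene_mean: float
    multi_gene_read_pair_fraction: float | None = None


# ---------------------------------------------------------------------------
# GTF / FASTA IO
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into name -> sequence (first word of header)."""
    seqs: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise PoolError(f"{path}: sequence before first FASTA header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path: str, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pool(gtf_path: str, fasta_path: str | None = None) -> TranscriptPool:
    """Build a pool from a GTF of exon features and an optional genome FASTA.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Exon chains are sorted genomically.
    """
    per_tx: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise PoolError(f"{gtf_path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise PoolError(
                    f"{gtf_path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            tid = attr["transcript_id"]
            exon = Exon(chrom=chrom, start=int(start) - 1, end=int(end), strand=strand)
            per_tx.setdefault(tid, []).append(exon)
            prev = tx_gene.setdefault(tid, attr["gene_id"])
            if prev != attr["gene_id"]:
                raise PoolError(
                    f"{gtf_path}:{lineno}: transcript {tid} assigned to two genes"
                )

    genome = read_fasta(fasta_path) if fasta_path else {}
    genes: dict[str, list[TranscriptModel]] = {}
    for tid, exons in per_tx.items():
        exons.sort(key=lambda e: e.start)
        tx = TranscriptModel(
            transcript_id=tid, gene_id=tx_gene[tid], exons=tuple(exons)
        )
        if genome:
            if tx.chrom not in genome:
                raise PoolError(f"transcript {tid}: chrom {tx.chrom} not in FASTA")
            if tx.end > len(genome[tx.chrom]):
                raise PoolError(
                    f"transcript {tid}: exon [{tx.start},{tx.end}) outside "
                    f"{tx.chrom} (length {len(genome[tx.chrom])})"
                )
        genes.setdefault(tx_gene[tid], []).append(tx)
    return TranscriptPool(genes=genes, genome=genome)


def write_pool(pool: TranscriptPool, gtf_path: str, fasta_path: str | None = None) -> None:
    """Write exon features as GTF (1-based inclusive) and, optionally, the genome."""
    with open(gtf_path, "w") as fh:
        for tx in pool.transcripts():
            for e in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    f"{e.chrom}\ttxsimeval\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
    if fasta_path is not None:
        write_fasta(fasta_path, pool.genome)


def write_transcript_fasta(pool: TranscriptPool, path: str) -> None:
    """Write spliced transcript sequences, one record per transcript_id."""
    write_fasta(path, pool.spliced_sequences())


# ---------------------------------------------------------------------------
# Duplicate filtering
# ---------------------------------------------------------------------------

def filter_duplicates(pool: TranscriptPool) -> TranscriptPool:
    """Collapse transcripts sharing an identical exon-coordinate chain.

    Such duplicates differ only in untranslated-region bookkeeping, not
    exonic structure, and would be indistinguishable to both the read
    simulator and the matcher.  Within each equivalence class the
    lexicographically smallest transcript_id survives.
    """
    by_chain: dict[tuple, TranscriptModel] = {}
    for tx in pool.transcripts():
        key = tx.exon_chain
        prev = by_chain.get(key)
        if prev is None or tx.transcript_id < prev.transcript_id:
            by_chain[key] = tx
    genes: dict[str, list[TranscriptModel]] = {}
    for gene_id, txs in pool.genes.items():
        kept = [t for t in txs if by_chain.get(t.exon_chain) is t]
        if kept:
            genes[gene_id] = kept
    return TranscriptPool(genes=genes, genome=pool.genome)


# ---------------------------------------------------------------------------
# Synthetic pool generation
# ---------------------------------------------------------------------------

class DistSpec:
    """A distribution over positive integers, sampled with a Generator."""

    def sample(self, rng: np.random.Generator) -> int:  # pragma: no cover
        raise NotImplementedError

    def mean(self) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Constant(DistSpec):
    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise PoolError("Constant distribution must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        return self.value

    def mean(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ShiftedPoisson(DistSpec):
    """1 + Poisson(mean - 1): strictly positive counts with a given mean."""

    mean_value: float

    def __post_init__(self) -> None:
        if self.mean_value < 1:
            raise PoolError("ShiftedPoisson mean must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        return 1 + int(rng.poisson(self.mean_value - 1.0))

    def mean(self) -> float:
        return self.mean_value


@dataclass(frozen=True)
class UniformInt(DistSpec):
    low: int
    high: int  # inclusive

    def __post_init__(self) -> None:
        if not (1 <= self.low <= self.high):
            raise PoolError("UniformInt requires 1 <= low <= high")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))

    def mean(self) -> float:
        return (self.low + self.high) / 2.0


def _make_isoforms(
    gene_id: str,
    prefix: str,
    exons: tuple[Exon, ...],
    n_isoforms: int,
    rng: np.random.Generator,
) -> list[TranscriptModel]:
    """Sample up to n_isoforms distinct exon-subset chains of a gene.

    Every isoform keeps the first and last exon of the gene so isoforms
    of one gene share sequence (the hard case for quantification);
    internal exons are included independently with probability 1/2.
    """
    n_exons = len(exons)
    chains: list[tuple[Exon, ...]] = [exons]  # isoform 1 = full chain
    attempts = 0
    max_distinct = 2 ** max(n_exons - 2, 0)
    while len(chains) < min(n_isoforms, max_distinct) and attempts < 50 * n_isoforms:
        attempts += 1
        keep = [True] + [bool(rng.integers(0, 2)) for _ in range(n_exons - 2)] + [True]
        if n_exons == 1:
            keep = [True]
        chain = tuple(e for e, k in zip(exons, keep) if k)
        if chain not in chains:
            chains.append(chain)
    return [
        TranscriptModel(
            transcript_id=f"{prefix}T{i + 1:02d}", gene_id=gene_id, exons=chain
        )
        for i, chain in enumerate(chains)
    ]


def generate_synthetic_pool(
    n_genes: int,
    isoform_dist: DistSpec = ShiftedPoisson(4.0),
    exon_count_dist: DistSpec = ShiftedPoisson(8.0),
    exon_len_dist: DistSpec = UniformInt(100, 300),
    intron_len_dist: DistSpec = UniformInt(200, 500),
    paralog_rate: float = 0.0,
    intergenic_len: int = 200,
    seed: int = 0,
) -> TranscriptPool:
    """Generate a random transcript pool with a uniform-random genome.

    Gene loci are laid out non-overlapping on a single synthetic
    chromosome; each gene carries >= 1 isoform sharing a subset of its
    exon chain.  With probability ``paralog_rate`` a gene's locus is a
    verbatim copy of an earlier gene's locus (a perfect paralog), which
    is what makes simulated read pairs map to multiple genes.  The
    output contains no duplicate exon chains, and is deterministic per
    seed.
    """
    if n_genes < 1:
        raise PoolError("n_genes must be >= 1")
    if not (0.0 <= paralog_rate <= 1.0):
        raise PoolError("paralog_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    genome_parts: list[str] = []
    genes: dict[str, list[TranscriptModel]] = {}
    cursor = 0
    bases = np.array(list("ACGT"))
    # (exon template offsets, locus sequence) of earlier genes, for paralogy
    templates: list[tuple[tuple[tuple[int, int], ...], str, str]] = []

    for g in range(n_genes):
        gene_id = f"G{g + 1:05d}"
        prefix = f"{gene_id}."
        make_copy = bool(templates) and rng.random() < paralog_rate
        if make_copy:
            offsets, locus_seq, strand = templates[int(rng.integers(len(templates)))]
        else:
            n_exons = exon_count_dist.sample(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            offsets_list: list[tuple[int, int]] = []
            pos = 0
            for i in range(n_exons):
                if i > 0:
                    pos += intron_len_dist.sample(rng)
                elen = exon_len_dist.sample(rng)
                offsets_list.append((pos, pos + elen))
                pos += elen
            offsets = tuple(offsets_list)
            locus_len = offsets[-1][1]
            locus_seq = "".join(rng.choice(bases, size=locus_len))
            templates.append((offsets, locus_seq, strand))

        locus_start = cursor
        exons = tuple(
            Exon(chrom=chrom, start=locus_start + a, end=locus_start + b, strand=strand)
            for a, b in offsets
        )
        genome_parts.append(locus_seq)
        cursor += len(locus_seq)
        spacer = "".join(rng.choice(bases, size=intergenic_len))
        genome_parts.append(spacer)
        cursor += intergenic_len

        n_iso = isoform_dist.sample(rng)
        genes[gene_id] = _make_isoforms(gene_id, prefix, exons, n_iso, rng)

    genome = {chrom: "".join(genome_parts)}
    return TranscriptPool(genes=genes, genome=genome)


# ---------------------------------------------------------------------------
# Pool statistics
# ---------------------------------------------------------------------------

def build_kmer_index(
    seqs: Mapping[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    """Exact k-mer index: k-mer -> list of (sequence name, offset)."""
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def pool_stats(
    pool: TranscriptPool,
    read_pairs: Sequence[tuple[str, str]] | None = None,
) -> PoolStats:
    """Isoforms per gene, and optionally the multi-gene read-pair fraction.

    ``read_pairs`` are (mate1, mate2) sequences as emitted by the read
    simulator (mate2 reverse-complemented relative to the sense strand).
    A pair counts as multi-gene iff both mates occur exactly, with the
    simulator's orientation, in spliced transcripts of more than one
    gene.  Exact substring search is sufficient because reads are
    error-free.
    """
    if pool.n_genes == 0:
        raise PoolError("empty pool")
    mean_iso = pool.n_transcripts / pool.n_genes
    if read_pairs is None:
        return PoolStats(isoforms_per_gene_mean=mean_iso)
    if not pool.genome:
        raise PoolError("multi-gene fraction requested but pool has no sequences")

    seqs = pool.spliced_sequences()
    gene_of = pool.gene_of()
    read_len = min(len(m) for pair in read_pairs for m in pair) if read_pairs else 0
    index = build_kmer_index(seqs, read_len) if read_len else {}

    def genes_containing(mate: str) -> set[str]:
        hits = index.get(mate[:read_len], [])
        out = set()
        for tid, off in hits:
            if seqs[tid][off : off + len(mate)] == mate:
                out.add(gene_of[tid])
        return out

    n_multi = 0
    for m1, m2 in read_pairs:
        g = genes_containing(m1) & genes_containing(reverse_complement(m2))
        if len(g) > 1:
            n_multi += 1
    frac = n_multi / len(read_pairs) if read_pairs else 0.0
    return PoolStats(isoforms_per_gene_mean=mean_iso, multi_gene_read_pair_fraction=frac)
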