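"""Error-free paired-end read simulation from expressed transcripts.

Fragments are allocated to transcripts multinomially with weights
proportional to (true abundance x effective length), the estimand of
FPKM-style quantifiers.  Each fragment's insert size (outer distance
between the two mates) is drawn from Normal(mu, sigma), rounded, and
resampled until it fits in [read_length, transcript length]; the start
is uniform over the valid offsets.  Mate 1 is the first ``read_length``
bases of the fragment on the transcript's sense strand and mate 2 the
reverse complement of its last ``read_length`` bases (FR orientation).
Reads carry no errors and no positional or sequence bias: the
simulation is a deliberately neutral baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionProfile
from .pool import TranscriptPool, reverse_complement

__all__ = [
    "ReadSimConfig",
    "FragmentRecord",
    "coverage_to_fragments",
    "simulate_fragments",
    "simulate_reads",
    "DEFAULT_READ_LENGTH",
    "DEFAULT_INSERT_MEAN",
    "DEFAULT_INSERT_SD",
]

DEFAULT_READ_LENGTH = 75
DEFAULT_INSERT_MEAN = 250.0
DEFAULT_INSERT_SD = 30.0


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation settings; set exactly one of n_fragments / target_coverage."""

    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    n_fragments: int | None = None
    target_coverage: float | None = None
    seed: int = 0
    length_weighting: str = "effective"  # "effective" (L - mu + 1) or "full" (L)

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if (self.n_fragments is None) == (self.target_coverage is None):
            raise ValueError("set exactly one of n_fragments / target_coverage")
        if self.length_weighting not in ("effective", "full"):
            raise ValueError("length_weighting must be 'effective' or 'full'")


@dataclass(frozen=True)
class FragmentRecord:
    transcript_id: str
    start: int
    insert_len: int


def coverage_to_fragments(
    target_coverage: float, read_length: int, expressed_total_length: int
) -> int:
    """Fragments needed for a coverage target.

    Coverage is 2 x fragments x read_length / total expressed length,
    so fragments = coverage x total length / (2 x read_length).
    """
    if expressed_total_length <= 0:
        raise ValueError("expressed_total_length must be positive")
    if target_coverage <= 0 or read_length <= 0:
        raise ValueError("coverage and read_length must be positive")
    return int(round(target_coverage * expressed_total_length / (2.0 * read_length)))


def _sample_inserts(
    n: int, mu: float, sigma: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Rounded Normal(mu, sigma) draws, rejection-sampled into [lo, hi]."""
    if lo > hi:
        raise ValueError("empty insert range")
    out = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(200):
        if todo.size == 0:
            break
        draws = np.rint(rng.normal(mu, sigma, size=todo.size)).astype(np.int64)
        ok = (draws >= lo) & (draws <= hi)
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    if todo.size:  # window far in the tail: clamp the stragglers
        out[todo] = np.clip(
            np.rint(rng.normal(mu, sigma, size=todo.size)).astype(np.int64), lo, hi
        )
    return out


def simulate_fragments(
    pool: TranscriptPool,
    profile: ExpressionProfile,
    config: ReadSimConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Sample fragment records (transcript, start, insert length).

    Returns the truth table and the spliced sequences of the expressed
    transcripts used (so callers can extract read sequences without
    re-deriving them).
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    seqs = pool.spliced_sequences()

    expressed = sorted(t for t, v in profile.values.items() if v > 0)
    usable, skipped = [], []
    for tid in expressed:
        (usable if len(seqs[tid]) >= rl else skipped).append(tid)
    if not usable:
        raise ValueError("no expressed transcript is at least one read length long")
    if skipped:
        warnings.warn(
            f"{len(skipped)} expressed transcripts shorter than the read length "
            "were excluded from read simulation"
        )

    lengths = np.array([len(seqs[t]) for t in usable], dtype=np.int64)
    rho = np.array([profile.values[t] for t in usable])
    if config.length_weighting == "effective":
        eff = np.maximum(lengths - config.insert_mean + 1.0, 1.0)
    else:
        eff = lengths.astype(float)
    weights = rho * eff
    weights /= weights.sum()

    total_len = int(lengths.sum())
    if config.n_fragments is not None:
        n_frag = config.n_fragments
    else:
        n_frag = coverage_to_fragments(config.target_coverage, rl, total_len)

    counts = rng.multinomial(n_frag, weights)
    tids_col: list[str] = []
    starts_col: list[np.ndarray] = []
    inserts_col: list[np.ndarray] = []
    for tid, L, c in zip(usable, lengths, counts):
        if c == 0:
            continue
        if L < config.insert_mean - 4 * config.insert_sd:
            warnings.warn(
                f"transcript {tid} (length {L}) is shorter than nearly all "
                "feasible inserts; its insert sizes truncate to the transcript length"
            )
        inserts = _sample_inserts(
            int(c), config.insert_mean, config.insert_sd, rl, int(L), rng
        )
        starts = rng.integers(0, L - inserts + 1)
        tids_col.extend([tid] * int(c))
        starts_col.append(starts)
        inserts_col.append(inserts)

    truth = pd.DataFrame(
        {
            "transcript_id": tids_col,
            "start": np.concatenate(starts_col) if starts_col else np.array([], int),
            "insert_len": np.concatenate(inserts_col) if inserts_col else np.array([], int),
        }
    )
    return truth, {t: seqs[t] for t in usable}


def extract_mates(
    truth: pd.DataFrame, seqs: dict[str, str], read_length: int
) -> list[tuple[str, str]]:
    """(mate1, mate2) sequences for each fragment record, FR orientation."""
    pairs: list[tuple[str, str]] = []
    tid_arr = truth["transcript_id"].to_numpy()
    start_arr = truth["start"].to_numpy()
    ins_arr = truth["insert_len"].to_numpy()
    for tid, start, ins in zip(tid_arr, start_arr, ins_arr):
        frag = seqs[tid][start : start + ins]
        pairs.append((frag[:read_length], reverse_complement(frag[-read_length:])))
    return pairs


def simulate_reads(
    pool: TranscriptPool,
    profile: ExpressionProfile,
    config: ReadSimConfig,
    fastq1_path: str,
    fastq2_path: str,
    truth_path: str | None = None,
) -> pd.DataFrame:
    """Simulate paired FASTQ files with the truth embedded in read names.

    Read names are ``sim:<n>:<transcript_id>:<start>:<insert>``; quality
    strings are a constant 'I' (the reads carry no errors).  Output is
    byte-identical for identical configs and seeds.
    """
    truth, seqs = simulate_fragments(pool, profile, config)
    pairs = extract_mates(truth, seqs, config.read_length)
    qual = "I" * config.read_length
    with open(fastq1_path, "w") as f1, open(fastq2_path, "w") as f2:
        buf1: list[str] = []
        buf2: list[str] = []
        for i, ((m1, m2), tid, start, ins) in enumerate(
            zip(pairs, truth["transcript_id"], truth["start"], truth["insert_len"])
        ):
            name = f"sim:{i}:{tid}:{start}:{ins}"
            buf1.append(f"@{name}/1\n{m1}\n+\n{qual[:len(m1)]}\n")
            buf2.append(f"@{name}/2\n{m2}\n+\n{qual[:len(m2)]}\n")
            if len(buf1) >= 100_000:
                f1.write("".join(buf1)); f2.write("".join(buf2))
                buf1, buf2 = [], []
        f1.write("".join(buf1))
        f2.write("".join(buf2))
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def read_fastq_pairs(fastq1_path: str, fastq2_path: str) -> list[tuple[str, str]]:
    """Load mate sequence pairs back from a pair of FASTQ files."""
    def seqs_of(path: str) -> list[str]:
        out = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    out.append(line.strip())
        return out

    s1, s2 = seqs_of(fastq1_path), seqs_of(fastq2_path)
    if len(s1) != len(s2):
        raise ValueError("FASTQ mate files have different record counts")
    return list(zip(s1, s2))
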