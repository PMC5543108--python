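"""Sparse seed selection from paired short reads.

Seeds are short, genome-unique fragments that serve as the sparse reference
for long-read alignment and as the nodes of the seed graph.  The selection
pipeline mirrors the classical short-read preparation: merge read pairs at
their terminal overlap, count canonical k-mers across the merged fragments,
discard any fragment containing an over-abundant k-mer, and finally keep only
fragments of one exact length so that every graph node has identical extent.

The module also provides the two closed-form planning statistics used to
reason about seed density: the minimum/typical long-read length able to link
two seeds, and the genomic occurrence implied by a k-mer abundance cap.
"""

from __future__ import annotations

import heapq
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from ._util import canonical_kmer, is_dna, revcomp, round_half_up, round_half_up_dp

logger = logging.getLogger(__name__)

__all__ = [
    "ReadPair",
    "MergedFragment",
    "KmerTable",
    "SeedSet",
    "SeedStats",
    "merge_pair",
    "count_kmers",
    "filter_unique",
    "select_by_length",
    "seed_stats",
    "occurrence_cap_estimate",
]


@dataclass
class ReadPair:
    """A paired short read prior to merging.

    ``seq2`` is in sequencing orientation, i.e. its reverse complement is
    expected to overlap the 3' end of ``seq1``.
    """

    id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None


@dataclass
class MergedFragment:
    """A merged pair: ``len(seq) == len(seq1) + len(seq2) - overlap_len``."""

    id: str
    seq: str
    overlap_len: int


@dataclass
class SeedSet:
    """Fixed-length unique fragments with stable identifiers."""

    seed_len: int
    seeds: list[tuple[str, str]]  # (seed_id, sequence)

    def __len__(self) -> int:
        return len(self.seeds)

    def sequences(self) -> dict[str, str]:
        return dict(self.seeds)

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.seeds]


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 15,
    max_mismatch_frac: float = 0.0,
) -> MergedFragment | None:
    """Merge a read pair at the longest terminal overlap of at least
    ``min_overlap`` nt between the 3' end of ``seq1`` and the reverse
    complement of ``seq2``.

    By default the overlap must match exactly; ``max_mismatch_frac`` > 0
    tolerates that fraction of mismatching positions within the overlap.
    Returns ``None`` when no acceptable overlap exists.  Pairs containing
    characters outside {A,C,G,T,N} are rejected (logged, not fatal).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (is_dna(pair.seq1) and is_dna(pair.seq2)):
        logger.warning("rejecting pair %s: non-DNA characters", pair.id)
        return None
    rc2 = revcomp(pair.seq2)
    limit = min(len(pair.seq1), len(rc2))
    for olen in range(limit, min_overlap - 1, -1):
        tail = pair.seq1[len(pair.seq1) - olen :]
        head = rc2[:olen]
        if max_mismatch_frac <= 0.0:
            if tail == head:
                return MergedFragment(pair.id, pair.seq1 + rc2[olen:], olen)
        else:
            mismatches = sum(a != b for a, b in zip(tail, head))
            if mismatches <= max_mismatch_frac * olen:
                return MergedFragment(pair.id, pair.seq1 + rc2[olen:], olen)
    return None


class KmerTable:
    """Canonical k-mer counts over a fragment collection.

    Keys are canonical k-mers (lexicographic minimum of the k-mer and its
    reverse complement); windows containing N are skipped.
    """

    def __init__(self, k: int, counts: Mapping[str, int] | None = None):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.counts: dict[str, int] = dict(counts or {})

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(canonical_kmer(kmer), 0)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, k: int | None = None) -> "KmerTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, count = line.rstrip("\n").split("\t")
                counts[kmer] = int(count)
        if k is None:
            k = len(next(iter(counts))) if counts else 1
        return cls(k, counts)


def _windows(seq: str, k: int) -> Iterator[str]:
    """Yield canonical k-mers for every N-free window of *seq*."""
    n = len(seq)
    if n < k:
        return
    # Track the most recent N so windows containing it are skipped in O(1).
    last_n = -1
    for i in range(k - 1):
        if seq[i] == "N":
            last_n = i
    for start in range(0, n - k + 1):
        end = start + k  # window [start, end)
        if seq[end - 1] == "N":
            last_n = end - 1
        if last_n >= start:
            continue
        yield canonical_kmer(seq[start:end])


def _fragment_seq(fragment) -> str:
    return fragment.seq if isinstance(fragment, MergedFragment) else fragment


def count_kmers(
    fragments: Iterable[MergedFragment | str],
    k: int = 25,
    max_in_memory: int | None = None,
    out_tsv: str | os.PathLike | None = None,
) -> KmerTable:
    """Count every canonical k-mer occurrence across *fragments*.

    Fragments are streamed; only the table is held in memory.  When the table
    grows beyond ``max_in_memory`` distinct k-mers, sorted partial tables are
    spilled to temporary files and merged at the end (external sort), which
    bounds peak memory at the cost of disk I/O.  ``out_tsv`` additionally
    writes the merged table as a two-column TSV.
    """
    counts: dict[str, int] = {}
    spills: list[str] = []
    warned_short = False

    def spill() -> None:
        fd, path = tempfile.mkstemp(prefix="kmers_", suffix=".tsv")
        with os.fdopen(fd, "w") as fh:
            for kmer in sorted(counts):
                fh.write(f"{kmer}\t{counts[kmer]}\n")
        spills.append(path)
        counts.clear()

    for fragment in fragments:
        seq = _fragment_seq(fragment)
        if len(seq) < k and not warned_short:
            logger.warning("fragment shorter than k=%d; no windows counted", k)
            warned_short = True
        for kmer in _windows(seq, k):
            counts[kmer] = counts.get(kmer, 0) + 1
        if max_in_memory is not None and len(counts) > max_in_memory:
            spill()

    if spills:
        if counts:
            spill()
        merged: dict[str, int] = {}

        def read_run(path: str) -> Iterator[tuple[str, int]]:
            with open(path) as fh:
                for line in fh:
                    kmer, count = line.rstrip("\n").split("\t")
                    yield kmer, int(count)

        for kmer, count in heapq.merge(*(read_run(p) for p in spills)):
            merged[kmer] = merged.get(kmer, 0) + count
        for path in spills:
            os.unlink(path)
        counts = merged

    table = KmerTable(k, counts)
    if out_tsv is not None:
        table.to_tsv(out_tsv)
    return table


def filter_unique(
    fragments: Sequence[MergedFragment | str],
    table: KmerTable,
    max_count: int = 25,
) -> list[MergedFragment | str]:
    """Keep fragments in which every k-mer window occurs at most ``max_count``
    times in *table* (the boundary is strict: a count of exactly ``max_count``
    is retained, ``max_count + 1`` is removed).

    Fragments containing N are excluded from seed candidacy: their skipped
    windows cannot be vouched for by the table.
    """
    kept: list[MergedFragment | str] = []
    for fragment in fragments:
        seq = _fragment_seq(fragment)
        if "N" in seq:
            continue
        if all(table.counts.get(kmer, 0) <= max_count for kmer in _windows(seq, table.k)):
            kept.append(fragment)
    return kept


def select_by_length(
    fragments: Sequence[MergedFragment | str],
    seed_len: int,
) -> SeedSet:
    """Keep fragments of exactly ``seed_len`` nt and assign stable sequential
    seed identifiers (``seed_1`` ... in input order)."""
    if seed_len <= 0:
        raise ValueError("seed_len must be positive")
    seqs = [_fragment_seq(f) for f in fragments]
    selected = [s for s in seqs if len(s) == seed_len]
    if not selected:
        raise ValueError(
            f"no fragments of length {seed_len} nt; try a different seed length"
        )
    seeds = [(f"seed_{i + 1}", seq) for i, seq in enumerate(selected)]
    return SeedSet(seed_len=seed_len, seeds=seeds)


@dataclass
class SeedStats:
    """Analytic seed-density statistics for a seed set against a genome.

    ``min_link_len`` is the shortest long read able to link two seeds end to
    end when at most ``max_overlap_frac`` of one seed length may overlap;
    ``typical_link_len`` adds the mean seed spacing to one seed length.
    """

    n_seeds: int
    seed_len: int
    genome_size: float
    fold_coverage: float
    mean_spacing: float
    mean_gap: float
    min_link_len: int
    typical_link_len: int

    def report(self) -> dict:
        """Printed-precision view: coverages at 2 decimals, spacings as
        half-up integers, link lengths as computed."""
        return {
            "n_seeds": self.n_seeds,
            "seed_len": self.seed_len,
            "genome_size": self.genome_size,
            "fold_coverage": round_half_up_dp(self.fold_coverage, 2),
            "mean_spacing": round_half_up(self.mean_spacing),
            "mean_gap": round_half_up(self.mean_gap),
            "min_link_len": self.min_link_len,
            "typical_link_len": self.typical_link_len,
        }


def seed_stats(
    n_seeds: int,
    seed_len: int,
    genome_size: float,
    max_overlap_frac: float = 0.10,
) -> SeedStats:
    """Pure arithmetic over the seed-density model.

    fold_coverage = n_seeds * seed_len / genome_size
    mean_spacing  = genome_size / n_seeds
    mean_gap      = mean_spacing - seed_len
    min_link_len  = ceil(2 * seed_len - max_overlap_frac * seed_len)
    typical_link_len = round(mean_spacing + seed_len)
    """
    if n_seeds <= 0 or seed_len <= 0 or genome_size <= 0:
        raise ValueError("all inputs must be positive")
    if not (0 <= max_overlap_frac < 1):
        raise ValueError("max_overlap_frac must be in [0, 1)")
    mean_spacing = genome_size / n_seeds
    return SeedStats(
        n_seeds=n_seeds,
        seed_len=seed_len,
        genome_size=genome_size,
        fold_coverage=n_seeds * seed_len / genome_size,
        mean_spacing=mean_spacing,
        mean_gap=mean_spacing - seed_len,
        min_link_len=math.ceil(2 * seed_len - max_overlap_frac * seed_len),
        typical_link_len=round_half_up(mean_spacing + seed_len),
    )


def occurrence_cap_estimate(
    max_count: int,
    data_bp: float,
    merged_fraction: float,
    genome_size: float,
) -> float:
    """Genomic occurrence implied by a k-mer count cap.

    The merged fragments represent ``data_bp * merged_fraction`` of sequence,
    i.e. a fold coverage of the genome (rounded to the nearest integer);
    a k-mer seen ``max_count`` times in that data occurs about
    ``max_count / coverage`` times in the genome.
    """
    if min(max_count, data_bp, merged_fraction, genome_size) <= 0:
        raise ValueError("all inputs must be positive")
    coverage = round_half_up(data_bp * merged_fraction / genome_size)
    if coverage == 0:
        raise ValueError("merged data gives < 0.5-fold genome coverage")
    return max_count / coverage
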