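"""Assembly assessment: contiguity statistics, truth-based misjoin
accounting, k-mer spectrum comparison, and orthologue-count summaries.

``misjoin_report`` replaces whole-genome alignment for simulated data: since
the simulator records where every seed truly lies, each scaffold adjacency
can be checked directly for chromosome, order, orientation and distance
agreement.  ``spectrum_compare`` quantifies sequence-composition similarity
between assemblies as the Pearson correlation of log-scaled canonical k-mer
frequency vectors (k = 6 by default).  ``completeness_summary`` converts
externally produced orthologue counts (complete / fragmented / missing) into
the conventional percentage summary.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import canonical_kmer, round_half_up_dp
from .simplify import ScaffoldModel
from .simulate import SimTruth

__all__ = [
    "AssemblyStats",
    "CollinearityReport",
    "SpectrumComparison",
    "CompletenessSummary",
    "assembly_stats",
    "misjoin_report",
    "spectrum_compare",
    "completeness_summary",
]


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50: int
    max_len: int
    min_len: int
    n_over_1mb: int
    frac_in_over_1mb: float


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Contiguity statistics.  N50 is the length at which the cumulative sum
    of descending-sorted scaffold lengths first reaches half the total."""
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    half = total / 2
    cum = 0
    n50 = ordered[-1]
    for length in ordered:
        cum += length
        if cum >= half:
            n50 = length
            break
    over = [l for l in ordered if l > 1_000_000]
    return AssemblyStats(
        n_scaffolds=len(ordered),
        total_bp=total,
        n50=n50,
        max_len=ordered[0],
        min_len=ordered[-1],
        n_over_1mb=len(over),
        frac_in_over_1mb=sum(over) / total,
    )


@dataclass
class CollinearityReport:
    misjoins: int
    seeds_recovered_frac: float
    orientation_errors: int
    per_scaffold: dict[str, int] = field(default_factory=dict)


def misjoin_report(
    models: Sequence[ScaffoldModel],
    truth: SimTruth,
    seed_len: int,
    tolerance: float = 50.0,
    tolerance_frac: float = 0.2,
) -> CollinearityReport:
    """Check every scaffold adjacency against true seed placements.

    An adjacency (a -> b with gap g) asserts that walking ``seed_len + g``
    bp from a's start — forward if a's scaffold orientation matches its
    true strand, backward otherwise — lands on b's start, with b's relative
    orientation matching.  Violations of chromosome, direction, orientation
    or distance (beyond max(tolerance, tolerance_frac * asserted distance))
    are misjoins; orientation violations are additionally counted apart.
    """
    misjoins = 0
    orientation_errors = 0
    per_scaffold: dict[str, int] = {}
    for model in models:
        errors = 0
        for (a, oa, gap), (b, ob, _) in zip(model.placements, model.placements[1:]):
            if a not in truth.placements or b not in truth.placements:
                raise KeyError(f"seed {a if a not in truth.placements else b} not in truth")
            chrom_a, start_a, strand_a = truth.placements[a]
            chrom_b, start_b, strand_b = truth.placements[b]
            asserted = seed_len + (gap or 0)
            if chrom_a != chrom_b:
                errors += 1
                continue
            same_rel_scaffold = oa == ob
            same_rel_truth = strand_a == strand_b
            if same_rel_scaffold != same_rel_truth:
                orientation_errors += 1
                errors += 1
                continue
            observed = start_b - start_a if oa == strand_a else start_a - start_b
            if observed <= 0:
                errors += 1  # wrong relative order
                continue
            if abs(observed - asserted) > max(tolerance, tolerance_frac * asserted):
                errors += 1
        if errors:
            per_scaffold[model.scaffold_id] = errors
        misjoins += errors
    placed = {sid for m in models for sid in m.seed_ids()}
    recovered = len(placed & set(truth.placements)) / max(len(truth.placements), 1)
    return CollinearityReport(
        misjoins=misjoins,
        seeds_recovered_frac=recovered,
        orientation_errors=orientation_errors,
        per_scaffold=per_scaffold,
    )


@dataclass
class SpectrumComparison:
    k: int
    names: list[str]
    vectors: dict[str, np.ndarray]
    pearson: dict[tuple[str, str], float]

    def r(self, a: str, b: str) -> float:
        return self.pearson[(a, b) if (a, b) in self.pearson else (b, a)]


def _canonical_kmer_axis(k: int) -> list[str]:
    kmers = ("".join(p) for p in itertools.product("ACGT", repeat=k))
    return sorted({canonical_kmer(km) for km in kmers})


def spectrum_compare(
    sequence_sets: Mapping[str, Iterable[str]],
    k: int = 6,
) -> SpectrumComparison:
    """Pairwise Pearson correlation of log10(count + 1) canonical k-mer
    frequency vectors across two or more sequence sets."""
    if k > 8:
        raise ValueError("k must be <= 8 (dense vector bound)")
    if len(sequence_sets) < 2:
        raise ValueError("need at least two sequence sets")
    axis = _canonical_kmer_axis(k)
    axis_index = {km: i for i, km in enumerate(axis)}
    vectors: dict[str, np.ndarray] = {}
    for name, seqs in sequence_sets.items():
        counts = Counter()
        for seq in seqs:
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if "N" in window:
                    continue
                counts[canonical_kmer(window)] += 1
        vec = np.zeros(len(axis))
        for km, c in counts.items():
            vec[axis_index[km]] = c
        vectors[name] = np.log10(vec + 1)
    names = sorted(vectors)
    pearson = {}
    for a, b in itertools.combinations(names, 2):
        pearson[(a, b)] = float(np.corrcoef(vectors[a], vectors[b])[0, 1])
    for name in names:
        pearson[(name, name)] = 1.0
    return SpectrumComparison(k=k, names=names, vectors=vectors, pearson=pearson)


@dataclass
class CompletenessSummary:
    total_genes: int
    complete: int
    fragmented: int
    missing: int
    pct_complete: float
    pct_fragmented: float
    pct_missing: float


def completeness_summary(
    total: int, complete: int, fragmented: int
) -> CompletenessSummary:
    """Summarize orthologue recovery counts as half-up percentages (1 dp)."""
    if complete + fragmented > total:
        raise ValueError("complete + fragmented exceeds total")
    missing = total - complete - fragmented
    pct = lambda n: round_half_up_dp(100.0 * n / total, 1)
    return CompletenessSummary(
        total_genes=total,
        complete=complete,
        fragmented=fragmented,
        missing=missing,
        pct_complete=pct(complete),
        pct_fragmented=pct(fragmented),
        pct_missing=pct(missing),
    )
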