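"""Seed graph construction from long-read-to-seed alignments.

Long reads are aligned (externally) against the sparse seed reference; this
module consumes the resulting SAM, chains the seed hits of each read along
the read coordinate, and records a link between every pair of consecutively
co-aligning seeds.  Links live in a bidirected graph over *oriented* seeds:
a link (A,+) -> (B,+) asserts that moving forward past A's end one reaches
B's start after a signed gap; its mirror (B,-) -> (A,-) is the same assertion
read in the opposite direction and is stored simultaneously, sharing the same
observation lists, so reverse-complement symmetry holds by construction.

Each link carries every observed gap (signed bp, negative when the seeds
overlap on the read) and the supporting read ids; evidence is the number of
supporting reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from ._util import flip_orient, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "OrientedSeed",
    "SeedAlignment",
    "ReadChain",
    "Link",
    "SeedGraph",
    "GraphReport",
    "parse_sam",
    "build_graph",
    "graph_report",
]


@dataclass(frozen=True, order=True)
class OrientedSeed:
    seed_id: str
    orient: str  # '+' or '-'

    def flipped(self) -> "OrientedSeed":
        return OrientedSeed(self.seed_id, flip_orient(self.orient))

    def __str__(self) -> str:
        return f"{self.seed_id}{self.orient}"


@dataclass
class SeedAlignment:
    """One seed hit on one read, in read-forward coordinates (0-based,
    half-open).  ``strand`` is the seed's orientation relative to the read."""

    read_id: str
    seed_id: str
    read_start: int
    read_end: int
    strand: str
    seed_cov: float
    mapq: int
    score: float = 0.0


@dataclass
class ReadChain:
    """All retained seed hits of one read, sorted by read coordinate."""

    read_id: str
    read_len: int
    hits: list[SeedAlignment]


class Link:
    """Observations supporting one bidirected link."""

    __slots__ = ("gap_obs", "reads")

    def __init__(self) -> None:
        self.gap_obs: list[int] = []
        self.reads: list[str] = []

    @property
    def evidence(self) -> int:
        return len(self.reads)

    def mean_gap(self) -> float:
        return sum(self.gap_obs) / len(self.gap_obs)

    def add(self, gap: int, read_id: str) -> None:
        self.gap_obs.append(gap)
        self.reads.append(read_id)


LinkKey = tuple[OrientedSeed, OrientedSeed]


def mirror_key(key: LinkKey) -> LinkKey:
    u, v = key
    return (v.flipped(), u.flipped())


def canonical_key(key: LinkKey) -> LinkKey:
    return min(key, mirror_key(key))


class SeedGraph:
    """Bidirected graph over oriented seeds.

    Both directions of every link are stored and share one :class:`Link`
    object, so observation lists can never diverge between a link and its
    mirror.  ``removed`` is an append-only audit of simplification decisions.
    """

    def __init__(self, seed_len: int):
        self.seed_len = seed_len
        self._adj: dict[OrientedSeed, dict[OrientedSeed, Link]] = {}
        self.removed: list[tuple[LinkKey, Link, str]] = []
        self.n_skipped_overlap = 0

    # -- construction -----------------------------------------------------

    def add_observation(self, u: OrientedSeed, v: OrientedSeed, gap: int, read_id: str) -> None:
        link = self._adj.get(u, {}).get(v)
        if link is None:
            link = Link()
            self._adj.setdefault(u, {})[v] = link
            mu, mv = mirror_key((u, v))
            self._adj.setdefault(mu, {})[mv] = link
        link.add(gap, read_id)

    # -- queries ----------------------------------------------------------

    def out_links(self, u: OrientedSeed) -> dict[OrientedSeed, Link]:
        return self._adj.get(u, {})

    def in_degree(self, u: OrientedSeed) -> int:
        return len(self._adj.get(u.flipped(), {}))

    def out_degree(self, u: OrientedSeed) -> int:
        return len(self._adj.get(u, {}))

    def oriented_nodes(self) -> list[OrientedSeed]:
        return sorted(self._adj)

    def seed_ids(self) -> set[str]:
        ids = {u.seed_id for u in self._adj}
        ids.update(k[0].seed_id for k, _, _ in self.removed)
        ids.update(k[1].seed_id for k, _, _ in self.removed)
        return ids

    def iter_links(self) -> Iterator[tuple[LinkKey, Link]]:
        """Each bidirected link exactly once, canonically keyed and sorted."""
        seen: set[LinkKey] = set()
        for u in self._adj:
            for v in self._adj[u]:
                key = canonical_key((u, v))
                if key not in seen:
                    seen.add(key)
        for key in sorted(seen):
            u, v = key
            yield key, self._adj[u][v]

    def n_links(self) -> int:
        return sum(1 for _ in self.iter_links())

    def has_link(self, u: OrientedSeed, v: OrientedSeed) -> bool:
        return v in self._adj.get(u, {})

    # -- mutation ---------------------------------------------------------

    def remove_link(self, u: OrientedSeed, v: OrientedSeed, reason: str) -> None:
        link = self._adj[u].pop(v)
        if not self._adj[u]:
            del self._adj[u]
        mu, mv = mirror_key((u, v))
        if (mu, mv) != (u, v):
            self._adj[mu].pop(mv)
            if not self._adj[mu]:
                del self._adj[mu]
        self.removed.append((canonical_key((u, v)), link, reason))

    # -- integrity --------------------------------------------------------

    def check_symmetry(self) -> None:
        """Assert the mirror-link invariant over the whole graph."""
        for u, targets in self._adj.items():
            for v, link in targets.items():
                mu, mv = mirror_key((u, v))
                mlink = self._adj.get(mu, {}).get(mv)
                assert mlink is link, f"mirror of {u}->{v} missing or diverged"

    def canonical_state(self) -> list[tuple[LinkKey, tuple[tuple[int, str], ...]]]:
        """Order-insensitive fingerprint used for equality in tests and for
        deterministic serialization."""
        state = []
        for key, link in self.iter_links():
            state.append((key, tuple(sorted(zip(link.gap_obs, link.reads)))))
        return state


def parse_sam(
    path,
    min_seed_cov: float = 0.8,
    min_mapq: int = 1,
    seed_names: set[str] | None = None,
) -> list[ReadChain]:
    """Read a headered SAM/BAM of long reads aligned against seeds.

    Secondary and supplementary records are dropped; records below the seed
    coverage or MAPQ thresholds are dropped; if a read hits the same seed
    several times only the highest-scoring hit (AS tag, then aligned length)
    survives.  Hit coordinates are reported on the read's own forward strand
    regardless of alignment orientation.  When ``seed_names`` is given, a SAM
    whose references are not seeds is rejected outright rather than guessed
    at.
    """
    mode = "r" if str(path).endswith(".sam") or not str(path).endswith(".bam") else "rb"
    per_read: dict[str, dict[str, SeedAlignment]] = {}
    read_lens: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        ref_lens = dict(zip(sam.references, sam.lengths))
        if not ref_lens:
            raise ValueError("SAM has no @SQ header lines; cannot interpret references")
        if seed_names is not None:
            unknown = set(ref_lens) - seed_names
            if unknown:
                raise ValueError(
                    "SAM references are not seed ids (e.g. "
                    f"{sorted(unknown)[:3]}); expected seeds as references"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"record {rec.query_name}: missing CIGAR")
            if rec.reference_name not in ref_lens:
                raise ValueError(
                    f"record {rec.query_name}: unknown reference {rec.reference_name}"
                )
            read_len = rec.infer_read_length() or rec.query_length
            qs, qe = rec.query_alignment_start, rec.query_alignment_end
            if rec.is_reverse:
                read_start, read_end = read_len - qe, read_len - qs
                strand = "-"
            else:
                read_start, read_end = qs, qe
                strand = "+"
            seed_cov = (rec.reference_length or 0) / ref_lens[rec.reference_name]
            if seed_cov < min_seed_cov or rec.mapping_quality < min_mapq:
                continue
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else float(
                rec.reference_length or 0
            )
            hit = SeedAlignment(
                read_id=rec.query_name,
                seed_id=rec.reference_name,
                read_start=read_start,
                read_end=read_end,
                strand=strand,
                seed_cov=seed_cov,
                mapq=rec.mapping_quality,
                score=score,
            )
            best = per_read.setdefault(rec.query_name, {})
            prev = best.get(rec.reference_name)
            if prev is None or (hit.score, -hit.read_start) > (prev.score, -prev.read_start):
                best[rec.reference_name] = hit
            read_lens[rec.query_name] = max(read_lens.get(rec.query_name, 0), read_len)

    chains = []
    for read_id in sorted(per_read):
        hits = sorted(
            per_read[read_id].values(), key=lambda h: (h.read_start, h.read_end, h.seed_id)
        )
        chains.append(ReadChain(read_id=read_id, read_len=read_lens[read_id], hits=hits))
    return chains


def build_graph(
    chains: Iterable[ReadChain],
    seed_len: int,
    max_overlap_frac: float = 0.10,
) -> SeedGraph:
    """Record a link for every pair of consecutive seed hits in every chain.

    The gap is ``next.read_start - prev.read_end`` (signed); pairs implying an
    overlap deeper than ``max_overlap_frac * seed_len`` are skipped and
    counted.  Evidence and gap observations accumulate across reads; mirrors
    are recorded simultaneously.
    """
    graph = SeedGraph(seed_len)
    cap = max_overlap_frac * seed_len
    for chain in chains:
        for prev, nxt in zip(chain.hits, chain.hits[1:]):
            gap = nxt.read_start - prev.read_end
            if gap < -cap:
                graph.n_skipped_overlap += 1
                continue
            u = OrientedSeed(prev.seed_id, prev.strand)
            v = OrientedSeed(nxt.seed_id, nxt.strand)
            graph.add_observation(u, v, gap, chain.read_id)
    return graph


@dataclass
class GraphReport:
    """Histograms of link evidence and of mean link distance."""

    evidence_hist: Counter
    distance_hist: Counter

    def mean_evidence(self) -> float:
        n = sum(self.evidence_hist.values())
        return sum(e * c for e, c in self.evidence_hist.items()) / n if n else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\tcount\n")
            for ev in sorted(self.evidence_hist):
                fh.write(f"evidence\t{ev}\t{self.evidence_hist[ev]}\n")
            for d in sorted(self.distance_hist):
                fh.write(f"distance\t{d}\t{self.distance_hist[d]}\n")


def graph_report(graph: SeedGraph) -> GraphReport:
    """Distributions over the graph's links, each bidirected link counted
    once: evidence (read support) and mean inter-seed distance (half-up)."""
    evidence = Counter()
    distance = Counter()
    for _, link in graph.iter_links():
        evidence[link.evidence] += 1
        distance[round_half_up(link.mean_gap())] += 1
    return GraphReport(evidence_hist=evidence, distance_hist=distance)
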