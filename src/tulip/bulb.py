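"""Uncorrected scaffold sequence layout and per-scaffold read bundles.

A scaffold model is an ordered, oriented list of seeds with mean gaps; this
module attaches actual sequence.  Seeds contribute their own (short-read
derived, high-identity) sequence; each positive gap is patched with the
subsequence of one supporting long read — the *donor*, chosen as the read
whose observed gap is closest to the link's mean (ties broken by read id for
reproducibility).  Negative gaps trim the downstream seed by the overlap.
The result is deliberately uncorrected: per-base accuracy inside patches is
that of a single long read, and external consensus polishing is expected
downstream.  To feed that polishing, each scaffold can be exported together
with a FASTA *bundle* of all long reads supporting its links.

Per-base provenance (which seed or read produced every base) is tracked as
runs and exportable as BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import revcomp
from .graphbuild import OrientedSeed, ReadChain, mirror_key
from .seedselect import SeedSet
from .simplify import ScaffoldModel

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldSequence",
    "LinkObservation",
    "ScaffoldReadBundle",
    "index_link_observations",
    "fill_gaps",
    "bundle_reads",
    "export_bundles",
]


@dataclass
class ScaffoldSequence:
    """Laid-out scaffold sequence with per-base provenance runs
    (0-based, half-open, scaffold-relative)."""

    scaffold_id: str
    seq: str
    source_map: list[tuple[int, int, str]]  # (start, end, seed_id | read_id)


@dataclass
class LinkObservation:
    """One read's view of one link: the observed gap and where on the read
    the two flanking seed alignments end/start.  ``flipped`` is True when the
    read traverses the link opposite to the key's direction, in which case
    the excised patch must be reverse-complemented."""

    read_id: str
    gap: int
    excise_start: int
    excise_end: int
    flipped: bool


@dataclass
class ScaffoldReadBundle:
    scaffold_id: str
    read_ids: list[str]


LinkObsIndex = dict[tuple[OrientedSeed, OrientedSeed], list[LinkObservation]]


def index_link_observations(chains: Iterable[ReadChain]) -> LinkObsIndex:
    """Index every adjacent co-alignment by its oriented link key, under both
    the direct key and the mirror key (flagged flipped)."""
    index: LinkObsIndex = {}
    for chain in chains:
        for prev, nxt in zip(chain.hits, chain.hits[1:]):
            key = (
                OrientedSeed(prev.seed_id, prev.strand),
                OrientedSeed(nxt.seed_id, nxt.strand),
            )
            obs = LinkObservation(
                read_id=chain.read_id,
                gap=nxt.read_start - prev.read_end,
                excise_start=prev.read_end,
                excise_end=nxt.read_start,
                flipped=False,
            )
            index.setdefault(key, []).append(obs)
            mkey = mirror_key(key)
            if mkey != key:
                mobs = LinkObservation(
                    read_id=obs.read_id,
                    gap=obs.gap,
                    excise_start=obs.excise_start,
                    excise_end=obs.excise_end,
                    flipped=True,
                )
                index.setdefault(mkey, []).append(mobs)
    return index


def _oriented_seed_seq(seeds: Mapping[str, str], seed_id: str, orient: str) -> str:
    seq = seeds[seed_id]
    return seq if orient == "+" else revcomp(seq)


def fill_gaps(
    model: ScaffoldModel,
    seeds: SeedSet | Mapping[str, str],
    reads: Mapping[str, str],
    chains: Iterable[ReadChain] | LinkObsIndex,
) -> ScaffoldSequence:
    """Lay out one scaffold: oriented seed sequences joined by read-derived
    patches (positive gaps) or overlap trims of the downstream seed
    (negative gaps).

    The donor read for a positive gap is the supporting read whose observed
    gap is closest to the mean of all observations, ties to the
    lexicographically smallest read id.  Missing supporting reads are a hard
    error naming the read.
    """
    seed_seqs = seeds.sequences() if isinstance(seeds, SeedSet) else seeds
    index = chains if isinstance(chains, dict) else index_link_observations(chains)

    parts: list[str] = []
    runs: list[tuple[int, int, str]] = []
    pos = 0
    pending_trim = 0

    def emit(piece: str, source: str) -> None:
        nonlocal pos
        if not piece:
            return
        parts.append(piece)
        runs.append((pos, pos + len(piece), source))
        pos += len(piece)

    placements = model.placements
    for i, (sid, orient, gap) in enumerate(placements):
        seed_seq = _oriented_seed_seq(seed_seqs, sid, orient)
        if pending_trim:
            if pending_trim >= len(seed_seq):
                logger.warning(
                    "scaffold %s: overlap %d swallows seed %s entirely",
                    model.scaffold_id, pending_trim, sid,
                )
                seed_seq = ""
            else:
                seed_seq = seed_seq[pending_trim:]
            pending_trim = 0
        emit(seed_seq, sid)
        if gap is None:
            continue
        if gap <= 0:
            pending_trim = -gap
            continue
        nid, norient, _ = placements[i + 1]
        key = (OrientedSeed(sid, orient), OrientedSeed(nid, norient))
        observations = index.get(key, [])
        if not observations:
            raise ValueError(
                f"scaffold {model.scaffold_id}: no supporting read for link "
                f"{key[0]}->{key[1]}"
            )
        mean = sum(o.gap for o in observations) / len(observations)
        donor = min(observations, key=lambda o: (abs(o.gap - mean), o.read_id))
        if donor.read_id not in reads:
            raise KeyError(
                f"supporting read {donor.read_id} not present in the read store"
            )
        patch = reads[donor.read_id][donor.excise_start : donor.excise_end]
        if donor.flipped:
            patch = revcomp(patch)
        emit(patch, donor.read_id)

    return ScaffoldSequence(
        scaffold_id=model.scaffold_id, seq="".join(parts), source_map=runs
    )


def bundle_reads(
    model: ScaffoldModel,
    chains: Iterable[ReadChain] | LinkObsIndex,
) -> ScaffoldReadBundle:
    """All reads supporting at least one retained link of the scaffold,
    deduplicated and sorted."""
    index = chains if isinstance(chains, dict) else index_link_observations(chains)
    read_ids: set[str] = set()
    for (sid, orient, gap), (nid, norient, _) in zip(
        model.placements, model.placements[1:]
    ):
        key = (OrientedSeed(sid, orient), OrientedSeed(nid, norient))
        for obs in index.get(key, []):
            read_ids.add(obs.read_id)
    return ScaffoldReadBundle(scaffold_id=model.scaffold_id, read_ids=sorted(read_ids))


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def export_bundles(
    models: Sequence[ScaffoldModel],
    seeds: SeedSet | Mapping[str, str],
    reads: Mapping[str, str],
    chains: Iterable[ReadChain],
    outdir: str | Path,
    mode: str = "per-scaffold",
) -> dict[str, ScaffoldSequence]:
    """Write scaffold sequence and bundles.

    mode 'combined': one ``scaffolds.fa`` with every scaffold.
    mode 'per-scaffold': per scaffold ``<id>.scaffold.fa`` plus
    ``<id>.bundle.fa`` holding its supporting long reads.
    A provenance BED (``provenance.bed``) is written in both modes.
    """
    if mode not in ("combined", "per-scaffold"):
        raise ValueError(f"unknown mode {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = index_link_observations(chains)
    sequences: dict[str, ScaffoldSequence] = {}
    for model in models:
        sequences[model.scaffold_id] = fill_gaps(model, seeds, reads, index)

    try:
        if mode == "combined":
            with open(outdir / "scaffolds.fa", "w") as fh:
                for sid in sorted(sequences):
                    fh.write(f">{sid}\n{_wrap(sequences[sid].seq)}\n")
        else:
            for model in models:
                sid = model.scaffold_id
                with open(outdir / f"{sid}.scaffold.fa", "w") as fh:
                    fh.write(f">{sid}\n{_wrap(sequences[sid].seq)}\n")
                bundle = bundle_reads(model, index)
                with open(outdir / f"{sid}.bundle.fa", "w") as fh:
                    for rid in bundle.read_ids:
                        if rid not in reads:
                            raise KeyError(f"bundle read {rid} missing from read store")
                        fh.write(f">{rid}\n{_wrap(reads[rid])}\n")
        with open(outdir / "provenance.bed", "w") as fh:
            for sid in sorted(sequences):
                for start, end, source in sequences[sid].source_map:
                    kind = "seed" if source.startswith("seed") else "read"
                    fh.write(f"{sid}\t{start}\t{end}\t{source}\t0\t+\t{kind}\n")
    except OSError as exc:
        raise OSError(f"failed writing under {outdir}: {exc}") from exc
    return sequences
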