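"""Interchange formats: FASTA/FASTQ, GFA1, AGP v2.1, chain/audit TSV.

Sequence files go through Biopython; GFA and AGP writers are bespoke because
they carry pipeline-specific tags: GFA links store the full gap-observation
list (``go:B:i``) and read ids (``rd:Z``) so a graph round-trips losslessly,
and AGP gap lines are paired with a sidecar TSV of true signed gaps because
AGP itself cannot express overlapping components (negative gaps become 1-bp
``U`` records).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from ._util import round_half_up
from .graphbuild import Link, OrientedSeed, ReadChain, SeedAlignment, SeedGraph
from .seedselect import SeedSet
from .simplify import ScaffoldModel

__all__ = [
    "read_fasta",
    "read_reads",
    "write_fasta",
    "write_fastq",
    "write_seeds_fasta",
    "read_seeds_fasta",
    "write_gfa",
    "read_gfa",
    "write_chains_tsv",
    "read_chains_tsv",
    "write_agp",
    "read_agp",
    "write_removed_tsv",
    "write_json",
]


# -- sequences --------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> dict[str, str]:
    """Load a FASTA or FASTQ read store into memory (format by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fq", ".fastq")) else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(p, fmt)}


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in records:
            seq = records[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Mapping[str, str], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name in records:
            seq = records[name]
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_seeds_fasta(path: str | Path, seeds: SeedSet) -> None:
    write_fasta(path, dict(seeds.seeds))


def read_seeds_fasta(path: str | Path) -> SeedSet:
    records = read_fasta(path)
    lens = {len(s) for s in records.values()}
    if len(lens) != 1:
        raise ValueError(f"seeds FASTA has mixed lengths {sorted(lens)}")
    return SeedSet(seed_len=lens.pop(), seeds=list(records.items()))


# -- GFA1 -------------------------------------------------------------------


def write_gfa(
    path: str | Path,
    graph: SeedGraph,
    seeds: SeedSet | Mapping[str, str] | None = None,
) -> None:
    """Serialize the graph as GFA1: S-lines per seed, one L-line per
    bidirected link (canonical direction).  Negative gaps become an ``<n>M``
    overlap CIGAR; tags carry the mean gap (gp:f), evidence (ev:i), all gap
    observations (go:B:i) and supporting reads (rd:Z)."""
    seed_seqs: Mapping[str, str] = {}
    if isinstance(seeds, SeedSet):
        seed_seqs = seeds.sequences()
    elif seeds:
        seed_seqs = seeds
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid in sorted(graph.seed_ids()):
            seq = seed_seqs.get(sid, "*")
            fh.write(f"S\t{sid}\t{seq}\tLN:i:{graph.seed_len}\n")
        for (u, v), link in graph.iter_links():
            gap = link.mean_gap()
            cigar = f"{-round_half_up(gap)}M" if gap < 0 else "0M"
            go = ",".join(str(g) for g in link.gap_obs)
            rd = ",".join(link.reads)
            fh.write(
                f"L\t{u.seed_id}\t{u.orient}\t{v.seed_id}\t{v.orient}\t{cigar}"
                f"\tgp:f:{gap:.3f}\tev:i:{link.evidence}\tgo:B:i,{go}\trd:Z:{rd}\n"
            )


def read_gfa(path: str | Path) -> tuple[SeedGraph, dict[str, str]]:
    """Reconstruct a graph (and any stored seed sequences) from GFA1."""
    seed_len = None
    seqs: dict[str, str] = {}
    links: list[tuple[OrientedSeed, OrientedSeed, list[int], list[str]]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                sid, seq = fields[1], fields[2]
                if seq != "*":
                    seqs[sid] = seq
                for tag in fields[3:]:
                    if tag.startswith("LN:i:"):
                        seed_len = int(tag[5:])
            elif fields[0] == "L":
                u = OrientedSeed(fields[1], fields[2])
                v = OrientedSeed(fields[3], fields[4])
                gaps: list[int] = []
                reads: list[str] = []
                for tag in fields[6:]:
                    if tag.startswith("go:B:i,"):
                        gaps = [int(x) for x in tag[7:].split(",")]
                    elif tag.startswith("rd:Z:"):
                        reads = tag[5:].split(",") if tag[5:] else []
                links.append((u, v, gaps, reads))
    if seed_len is None:
        raise ValueError(f"{path}: no S-line with LN tag; cannot infer seed length")
    graph = SeedGraph(seed_len)
    for u, v, gaps, reads in links:
        if len(gaps) != len(reads):
            raise ValueError(f"{path}: link {u}->{v} has inconsistent go/rd tags")
        for gap, rid in zip(gaps, reads):
            graph.add_observation(u, v, gap, rid)
    return graph, seqs


# -- chains -----------------------------------------------------------------

_CHAIN_HEADER = "read_id\tread_len\tseed_id\tread_start\tread_end\tstrand\tseed_cov\tmapq\n"


def write_chains_tsv(path: str | Path, chains: Iterable[ReadChain]) -> None:
    with open(path, "w") as fh:
        fh.write(_CHAIN_HEADER)
        for chain in chains:
            for h in chain.hits:
                fh.write(
                    f"{chain.read_id}\t{chain.read_len}\t{h.seed_id}\t{h.read_start}"
                    f"\t{h.read_end}\t{h.strand}\t{h.seed_cov:.4f}\t{h.mapq}\n"
                )


def read_chains_tsv(path: str | Path) -> list[ReadChain]:
    per_read: dict[str, ReadChain] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, rlen, sid, rs, re, strand, cov, mapq = line.rstrip("\n").split("\t")
            chain = per_read.setdefault(rid, ReadChain(read_id=rid, read_len=int(rlen), hits=[]))
            chain.hits.append(
                SeedAlignment(
                    read_id=rid, seed_id=sid, read_start=int(rs), read_end=int(re),
                    strand=strand, seed_cov=float(cov), mapq=int(mapq),
                )
            )
    chains = []
    for rid in sorted(per_read):
        chain = per_read[rid]
        chain.hits.sort(key=lambda h: (h.read_start, h.read_end, h.seed_id))
        chains.append(chain)
    return chains


# -- AGP v2.1 ---------------------------------------------------------------


def write_agp(
    path: str | Path,
    models: Iterable[ScaffoldModel],
    seed_len: int,
    gaps_tsv: str | Path | None = None,
) -> None:
    """Scaffold models as AGP v2.1 with a sidecar TSV of true signed gaps.

    Positive gaps are N records (known size, linkage `paired-ends;map`);
    zero or negative gaps cannot be expressed in AGP and become 1-bp U
    records — the sidecar holds the authoritative signed value for every
    gap, keyed by scaffold and part number.
    """
    gaps_tsv = Path(gaps_tsv) if gaps_tsv else Path(str(path) + ".gaps.tsv")
    with open(path, "w") as agp, open(gaps_tsv, "w") as side:
        agp.write("##agp-version\t2.1\n")
        side.write("scaffold_id\tpart_number\tgap\n")
        for model in models:
            pos = 0
            part = 0
            for sid, orient, gap in model.placements:
                part += 1
                agp.write(
                    f"{model.scaffold_id}\t{pos + 1}\t{pos + seed_len}\t{part}\tW"
                    f"\t{sid}\t1\t{seed_len}\t{orient}\n"
                )
                pos += seed_len
                if gap is None:
                    continue
                part += 1
                if gap > 0:
                    agp.write(
                        f"{model.scaffold_id}\t{pos + 1}\t{pos + gap}\t{part}\tN"
                        f"\t{gap}\tscaffold\tyes\tpaired-ends;map\n"
                    )
                    pos += gap
                else:
                    agp.write(
                        f"{model.scaffold_id}\t{pos + 1}\t{pos + 1}\t{part}\tU"
                        f"\t1\tscaffold\tyes\tpaired-ends;map\n"
                    )
                    pos += 1
                side.write(f"{model.scaffold_id}\t{part}\t{gap}\n")


def read_agp(path: str | Path, gaps_tsv: str | Path | None = None) -> list[ScaffoldModel]:
    """Rebuild scaffold models from AGP plus its sidecar gap TSV."""
    gaps_tsv = Path(gaps_tsv) if gaps_tsv else Path(str(path) + ".gaps.tsv")
    side: dict[tuple[str, int], int] = {}
    if gaps_tsv.exists():
        with open(gaps_tsv) as fh:
            fh.readline()
            for line in fh:
                scf, part, gap = line.rstrip("\n").split("\t")
                side[(scf, int(part))] = int(gap)
    raw: dict[str, list[tuple[int, str, str, int | None]]] = {}
    seed_len = None
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            scf, part, ctype = f[0], int(f[3]), f[4]
            if scf not in raw:
                raw[scf] = []
                order.append(scf)
            if ctype == "W":
                seed_len = int(f[7])
                raw[scf].append((part, f[5], f[8], None))
            else:
                gap = side.get((scf, part), int(f[5]))
                if raw[scf]:
                    p, sid, orient, _ = raw[scf][-1]
                    raw[scf][-1] = (p, sid, orient, gap)
    if seed_len is None:
        raise ValueError(f"{path}: no component lines")
    models = []
    for scf in order:
        placements = [(sid, orient, gap) for _, sid, orient, gap in raw[scf]]
        est = seed_len * len(placements) + sum(
            g for _, _, g in placements if g is not None
        )
        models.append(ScaffoldModel(scaffold_id=scf, placements=placements, est_length=est))
    return models


# -- audits and reports -----------------------------------------------------


def write_removed_tsv(path: str | Path, graph: SeedGraph) -> None:
    with open(path, "w") as fh:
        fh.write("from\tfrom_orient\tto\tto_orient\tevidence\tmean_gap\treason\n")
        for (u, v), link, reason in graph.removed:
            fh.write(
                f"{u.seed_id}\t{u.orient}\t{v.seed_id}\t{v.orient}"
                f"\t{link.evidence}\t{round_half_up(link.mean_gap())}\t{reason}\n"
            )


def write_json(path: str | Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
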