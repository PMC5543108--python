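"""Synthetic genomes, seeds and nanopore-like reads with ground truth.

The simulator stands in for a real sequencing experiment so that the whole
scaffolding pipeline can be exercised hermetically: it emits a random genome,
a sparse set of genome-unique seeds, noisy long reads, and — crucially — a
*truth* SAM of seed-on-read alignment intervals computed from the introduced
edits, bypassing any external aligner.  Ground truth (seed placements, read
origins) supports misjoin accounting downstream.

The error model is i.i.d. per base: with probability (1 - identity) a base
suffers an event, split into mismatch / insertion / deletion by a
chemistry-specific ratio.  Nanopore chemistries differ chiefly in identity
(~75% for R7.3 2D, ~89% for R9 1D, up to ~94% for R9 2D); an optional extra
deletion rate inside homopolymers of length >= 4 approximates the platform's
characteristic homopolymer under-representation.  Chimeric reads join two
unrelated genomic fragments.  All randomness is derived from one seed with a
dedicated substream per stage, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import revcomp
from .graphbuild import ReadChain, SeedAlignment
from .seedselect import SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ChemistryPreset",
    "CHEMISTRIES",
    "SimTruth",
    "Simulation",
    "simulate_genome",
    "sample_seeds",
    "simulate_reads",
    "run_simulation",
    "truth_chains",
    "write_truth_sam",
]

UNIQUE_K = 25  # k-mer size defining seed uniqueness

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


@dataclass(frozen=True)
class ChemistryPreset:
    """Per-chemistry error profile: overall identity and how the error mass
    splits into mismatch:insertion:deletion (fractions summing to 1)."""

    identity: float
    mismatch: float
    insertion: float
    deletion: float

    def __post_init__(self):
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if abs(self.mismatch + self.insertion + self.deletion - 1.0) > 1e-9:
            raise ValueError("error ratio must sum to 1")


CHEMISTRIES: dict[str, ChemistryPreset] = {
    "r73-2d": ChemistryPreset(0.75, 0.40, 0.30, 0.30),
    "r9-1d": ChemistryPreset(0.89, 0.35, 0.30, 0.35),
    "r9-2d": ChemistryPreset(0.94, 0.35, 0.30, 0.35),
    "r94-1d": ChemistryPreset(0.89, 0.35, 0.30, 0.35),
    "perfect": ChemistryPreset(1.0, 0.35, 0.30, 0.35),
}


@dataclass
class SimConfig:
    """Study conditions for a simulated experiment.

    Defaults describe a desk-scale experiment: a 1 Mbp haploid genome, 285 nt
    seeds at one per ~700 bp, and 15-fold coverage in ~8 kbp reads — enough
    seeds per read (~10) for the graph to be richly connected, mirroring a
    sparse-seed regime rather than any particular dataset.
    """

    genome_len: int = 1_000_000
    n_chromosomes: int = 1
    gc: float = 0.42
    repeat_frac: float = 0.0
    repeat_unit_len: int = 500
    seed_len: int = 285
    seed_spacing_mean: int = 700
    coverage: float = 15.0
    read_len_mean: int = 8000
    read_len_sd: int = 4000
    chemistry: str = "r9-1d"
    chimera_rate: float = 0.0
    missed_hit_rate: float = 0.0
    homopolymer_del_factor: float = 2.0  # extra deletion rate in homopolymers >= 4
    rng_seed: int = 42

    def __post_init__(self):
        for frac in (self.gc, self.repeat_frac, self.chimera_rate, self.missed_hit_rate):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        for length in (self.genome_len, self.seed_len, self.seed_spacing_mean,
                       self.read_len_mean, self.repeat_unit_len):
            if length <= 0:
                raise ValueError("lengths must be positive")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")

    @property
    def preset(self) -> ChemistryPreset:
        return CHEMISTRIES[self.chemistry]


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    placements:   seed_id -> (chromosome, start, strand)
    read_origins: read_id -> [(chromosome, start, end, strand), ...]
                  (two entries for chimeric reads)
    hits:         read_id -> [(seed_id, read_start, read_end, strand_on_read)]
                  — truth seed-alignment intervals after edits, with
                  missed-hit dropout already applied
    read_lens:    read_id -> length
    repeats:      [(chromosome, start, end)] repeat-unit placements
    """

    placements: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    read_origins: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)
    hits: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)
    read_lens: dict[str, int] = field(default_factory=dict)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        with open(outdir / "truth_seeds.tsv", "w") as fh:
            fh.write("seed_id\tchrom\tstart\tstrand\n")
            for sid in sorted(self.placements):
                chrom, start, strand = self.placements[sid]
                fh.write(f"{sid}\t{chrom}\t{start}\t{strand}\n")
        with open(outdir / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\tchrom\tstart\tend\tstrand\n")
            for rid in sorted(self.read_origins):
                for chrom, start, end, strand in self.read_origins[rid]:
                    fh.write(f"{rid}\t{chrom}\t{start}\t{end}\t{strand}\n")

    @classmethod
    def placements_from_tsv(cls, path: str | Path) -> "SimTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                sid, chrom, start, strand = line.rstrip("\n").split("\t")
                truth.placements[sid] = (chrom, int(start), strand)
        return truth


@dataclass
class Simulation:
    """Everything one run produces, in memory."""

    config: SimConfig
    chromosomes: dict[str, str]
    seeds: SeedSet
    reads: dict[str, str]
    truth: SimTruth


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


_DECODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _DECODE[_b] = _i


def _to_codes(seq: str) -> np.ndarray:
    return _DECODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], SimTruth]:
    """Random i.i.d. genome at the target GC, with ``repeat_frac`` of the
    sequence overwritten by copies of a single repeat unit at random
    non-overlapping positions."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.rng_seed).spawn(3)[0]))
    truth = SimTruth()
    if cfg.repeat_frac > 0 and cfg.repeat_frac * cfg.genome_len < cfg.repeat_unit_len:
        raise ValueError("repeat_frac * genome_len smaller than one repeat unit")
    lens = [cfg.genome_len // cfg.n_chromosomes] * cfg.n_chromosomes
    lens[-1] += cfg.genome_len - sum(lens)
    chroms: dict[str, str] = {}
    unit = _random_bases(rng, cfg.repeat_unit_len, cfg.gc) if cfg.repeat_frac > 0 else None
    for i, clen in enumerate(lens):
        name = f"chr{i + 1}"
        codes = _random_bases(rng, clen, cfg.gc)
        if unit is not None:
            n_copies = int(round(cfg.repeat_frac * clen / cfg.repeat_unit_len))
            placed: list[tuple[int, int]] = []
            attempts = 0
            while len(placed) < n_copies and attempts < n_copies * 20:
                attempts += 1
                start = int(rng.integers(0, clen - cfg.repeat_unit_len + 1))
                end = start + cfg.repeat_unit_len
                if any(s < end and start < e for s, e in placed):
                    continue
                codes[start:end] = unit
                placed.append((start, end))
            for start, end in sorted(placed):
                truth.repeats.append((name, start, end))
        chroms[name] = _to_str(codes)
    return chroms, truth


def _unique_window_mask(chroms: dict[str, str], seed_len: int) -> dict[str, np.ndarray]:
    """For each chromosome, a boolean array over start positions: True where
    every canonical 25-mer of the window [p, p + seed_len) is genome-unique."""
    from ._util import canonical_kmer

    counts: dict[str, int] = {}
    for seq in chroms.values():
        for i in range(len(seq) - UNIQUE_K + 1):
            kmer = canonical_kmer(seq[i : i + UNIQUE_K])
            counts[kmer] = counts.get(kmer, 0) + 1
    masks: dict[str, np.ndarray] = {}
    w = seed_len - UNIQUE_K + 1  # k-mer windows per seed window
    for name, seq in chroms.items():
        n_kmers = len(seq) - UNIQUE_K + 1
        if n_kmers < w:
            masks[name] = np.zeros(0, dtype=bool)
            continue
        uniq = np.empty(n_kmers, dtype=np.int64)
        for i in range(n_kmers):
            uniq[i] = 1 if counts[canonical_kmer(seq[i : i + UNIQUE_K])] == 1 else 0
        cum = np.concatenate([[0], np.cumsum(uniq)])
        eligible = (cum[w:] - cum[:-w]) == w  # all k-mers in window unique
        masks[name] = eligible
    return masks


def sample_seeds(
    chroms: dict[str, str],
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> SeedSet:
    """Draw seed start positions uniformly from loci whose every 25-mer is
    genome-unique, rejecting overlapping picks, at a mean spacing of
    ``seed_spacing_mean``.  Seed strand is drawn uniformly; a '-' seed stores
    the reverse complement of the genome window."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.rng_seed).spawn(3)[1]))
    masks = _unique_window_mask(chroms, cfg.seed_len)
    # seeds must not touch repeat units at all (uniqueness of interior
    # 25-mers alone would still allow a < 25 bp graze at a repeat edge)
    for chrom, rstart, rend in truth.repeats:
        mask = masks[chrom]
        lo = max(rstart - cfg.seed_len + 1, 0)
        mask[lo:rend] = False
    placements: list[tuple[str, int]] = []
    for name in sorted(chroms):
        eligible = np.flatnonzero(masks[name])
        target = int(round(len(chroms[name]) / cfg.seed_spacing_mean))
        if len(eligible) < target:
            raise ValueError(
                f"only {len(eligible)} unique loci on {name} for {target} seeds; "
                "lower the seed density or repeat fraction"
            )
        order = rng.permutation(len(eligible))
        occupied = np.zeros(len(chroms[name]), dtype=bool)
        picked: list[int] = []
        for idx in order:
            start = int(eligible[idx])
            end = start + cfg.seed_len
            if occupied[start:end].any():
                continue
            occupied[start:end] = True
            picked.append(start)
            if len(picked) >= target:
                break
        if len(picked) < target:
            raise ValueError(
                f"could not place {target} non-overlapping seeds on {name} "
                f"({len(picked)} fit); lower the seed density"
            )
        for start in sorted(picked):
            placements.append((name, start))

    seeds: list[tuple[str, str]] = []
    strands = rng.random(len(placements)) < 0.5
    for i, ((chrom, start), minus) in enumerate(zip(placements, strands)):
        sid = f"seed_{i + 1}"
        window = chroms[chrom][start : start + cfg.seed_len]
        strand = "-" if minus else "+"
        seeds.append((sid, revcomp(window) if minus else window))
        truth.placements[sid] = (chrom, start, strand)
    return SeedSet(seed_len=cfg.seed_len, seeds=seeds)


def _apply_errors(
    codes: np.ndarray,
    preset: ChemistryPreset,
    hp_factor: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Introduce i.i.d. errors into a read-oriented fragment.

    Returns (read codes, posmap) where posmap[i] is the read coordinate of
    fragment base i and posmap[len] the read length, so fragment intervals
    project exactly onto the read.
    """
    n = len(codes)
    e = 1.0 - preset.identity
    if e <= 0:
        posmap = np.arange(n + 1)
        return codes, posmap
    p_mis = e * preset.mismatch
    p_del = np.full(n, e * preset.deletion)
    p_ins = e * preset.insertion
    if hp_factor > 1.0:
        # positions inside homopolymer runs of length >= 4 delete more often
        run_start = np.flatnonzero(np.concatenate([[True], codes[1:] != codes[:-1]]))
        run_len = np.diff(np.concatenate([run_start, [n]]))
        in_long_run = np.repeat(run_len >= 4, run_len)
        p_del[in_long_run] *= hp_factor
    u = rng.random(n)
    is_mis = u < p_mis
    is_del = (~is_mis) & (u < p_mis + p_del)
    is_ins = (~is_mis) & (~is_del) & (u < p_mis + p_del + p_ins)

    out = codes.copy()
    if is_mis.any():
        shift = rng.integers(1, 4, size=int(is_mis.sum()), dtype=np.uint8)
        out[is_mis] = (out[is_mis] + shift) % 4
    contrib = np.ones(n, dtype=np.int64)
    contrib[is_del] = 0
    contrib[is_ins] = 2  # the base plus one inserted base after it
    posmap = np.concatenate([[0], np.cumsum(contrib)])
    read = np.empty(posmap[-1], dtype=np.uint8)
    keep = ~is_del
    read[posmap[:-1][keep]] = out[keep]
    if is_ins.any():
        ins_pos = posmap[:-1][is_ins] + 1
        read[ins_pos] = rng.integers(0, 4, size=int(is_ins.sum()), dtype=np.uint8)
    # a deleted base maps to the position of the next surviving base, which
    # posmap already encodes (cumsum semantics)
    return read, posmap


def simulate_reads(
    chroms: dict[str, str],
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Sample reads at the target coverage, apply the chemistry error model,
    and record truth seed-alignment intervals (with missed-hit dropout)."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.rng_seed).spawn(3)[2]))
    preset = cfg.preset
    chrom_names = sorted(chroms)
    chrom_codes = {name: _to_codes(chroms[name]) for name in chrom_names}
    chrom_lens = np.array([len(chroms[n]) for n in chrom_names], dtype=np.float64)
    chrom_p = chrom_lens / chrom_lens.sum()

    # per-chromosome sorted seed starts for fast overlap lookup
    seeds_by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    for name in chrom_names:
        entries = sorted(
            (start, sid, strand)
            for sid, (chrom, start, strand) in truth.placements.items()
            if chrom == name
        )
        starts = np.array([s for s, _, _ in entries], dtype=np.int64)
        seeds_by_chrom[name] = (starts, [sid for _, sid, _ in entries],
                                [st for _, _, st in entries])

    n_reads = int(round(cfg.coverage * cfg.genome_len / cfg.read_len_mean))
    m, s = float(cfg.read_len_mean), float(max(cfg.read_len_sd, 1))
    sigma2 = np.log(1 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    lengths = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_reads)
    lengths = np.clip(lengths, 2 * cfg.seed_len, None).astype(np.int64)
    chimeric = rng.random(n_reads) < cfg.chimera_rate

    reads: dict[str, str] = {}

    def sample_fragment(frag_len: int):
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        name = chrom_names[ci]
        clen = int(chrom_lens[ci])
        frag_len = min(frag_len, clen)
        start = int(rng.integers(0, clen - frag_len + 1))
        strand = "-" if rng.random() < 0.5 else "+"
        frag = chrom_codes[name][start : start + frag_len]
        if strand == "-":
            frag = (3 - frag)[::-1]
        return name, start, start + frag_len, strand, frag

    for i in range(n_reads):
        rid = f"read_{i + 1}"
        frag_specs = []
        if chimeric[i]:
            half = max(int(lengths[i]) // 2, 2 * cfg.seed_len)
            frag_specs.append(sample_fragment(half))
            frag_specs.append(sample_fragment(half))
        else:
            frag_specs.append(sample_fragment(int(lengths[i])))

        read_parts: list[np.ndarray] = []
        hits: list[tuple[str, int, int, str]] = []
        offset = 0
        origins = []
        for name, gs, ge, strand, frag in frag_specs:
            read_frag, posmap = _apply_errors(frag, preset, cfg.homopolymer_del_factor, rng)
            origins.append((name, gs, ge, strand))
            starts, sids, sstrands = seeds_by_chrom[name]
            lo = np.searchsorted(starts, gs, side="left")
            hi = np.searchsorted(starts, ge - cfg.seed_len, side="right")
            for j in range(lo, hi):
                sstart = int(starts[j])
                o0 = sstart - gs
                o1 = o0 + cfg.seed_len
                if strand == "-":
                    o0, o1 = len(frag) - o1, len(frag) - o0
                rs, re = int(posmap[o0]), int(posmap[o1])
                if re - rs < 2:
                    continue  # seed erased by edits at this locus
                hit_strand = "+" if sstrands[j] == strand else "-"
                hits.append((sids[j], offset + rs, offset + re, hit_strand))
            read_parts.append(read_frag)
            offset += len(read_frag)

        read_codes = np.concatenate(read_parts) if len(read_parts) > 1 else read_parts[0]
        reads[rid] = _to_str(read_codes)
        truth.read_lens[rid] = len(read_codes)
        truth.read_origins[rid] = origins
        if cfg.missed_hit_rate > 0 and hits:
            keep = rng.random(len(hits)) >= cfg.missed_hit_rate
            hits = [h for h, k in zip(hits, keep) if k]
        hits.sort(key=lambda h: (h[1], h[2], h[0]))
        truth.hits[rid] = hits
    return reads


def truth_chains(truth: SimTruth, seed_len: int) -> list[ReadChain]:
    """Truth hits as ReadChains, equivalent to parsing the truth SAM."""
    chains = []
    for rid in sorted(truth.hits):
        hits = [
            SeedAlignment(
                read_id=rid,
                seed_id=sid,
                read_start=rs,
                read_end=re,
                strand=strand,
                seed_cov=1.0,
                mapq=60,
            )
            for sid, rs, re, strand in truth.hits[rid]
        ]
        if hits:
            chains.append(ReadChain(read_id=rid, read_len=truth.read_lens[rid], hits=hits))
    return chains


def write_truth_sam(path: str | Path, seeds: SeedSet, truth: SimTruth) -> None:
    """Emit the truth alignments as a valid SAM with seeds as references.

    Each record encodes the seed's interval on the read via soft clips and a
    centred insertion/deletion balancing the edit-induced length change; SEQ
    is '*' (read sequences live in the FASTQ).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for sid, _ in seeds.seeds:
            fh.write(f"@SQ\tSN:{sid}\tLN:{seeds.seed_len}\n")
        L = seeds.seed_len
        for rid in sorted(truth.hits):
            read_len = truth.read_lens[rid]
            for sid, rs, re, strand in truth.hits[rid]:
                span = re - rs
                d = span - L
                if strand == "-":
                    # SAM stores coordinates on the reverse-complemented query
                    rs_sam, re_sam = read_len - re, read_len - rs
                else:
                    rs_sam, re_sam = rs, re
                if d == 0:
                    mid = f"{L}M"
                elif d > 0:
                    a = L // 2
                    mid = f"{a}M{d}I{L - a}M"
                else:
                    a = span // 2
                    mid = f"{a}M{-d}D{span - a}M"
                cigar = ""
                if rs_sam:
                    cigar += f"{rs_sam}S"
                cigar += mid
                clip = read_len - re_sam
                if clip:
                    cigar += f"{clip}S"
                flag = 16 if strand == "-" else 0
                fh.write(f"{rid}\t{flag}\t{sid}\t1\t60\t{cigar}\t*\t0\t0\t*\t*\n")


def run_simulation(cfg: SimConfig) -> Simulation:
    """Run all stages with one RNG substream per stage."""
    children = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
    chroms, truth = simulate_genome(cfg, rngs[0])
    seeds = sample_seeds(chroms, cfg, truth, rngs[1])
    reads = simulate_reads(chroms, cfg, truth, rngs[2])
    return Simulation(config=cfg, chromosomes=chroms, seeds=seeds, reads=reads, truth=truth)
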