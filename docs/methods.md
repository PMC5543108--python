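# Methods

## Model

The scaffolder treats assembly as a layout problem over a sparse reference.
Short, accurate fragments (**seeds**) are assumed to be effectively unique
in the genome; long reads are aligned against them externally, and each
read induces an ordered chain of seed hits. Two seeds that co-align
*adjacently* on a read are presumed genomically close, at the signed
distance observed on the read. The resulting structure is a **bidirected
graph over oriented seeds**: every link `(A,o₁) → (B,o₂)` coexists with its
mirror `(B,¬o₂) → (A,¬o₁)`, and in this implementation both directions
share one underlying observation record, so reverse-complement symmetry
cannot be violated by construction (it is nevertheless asserted by a full
sweep in the tests). Gap observations are accumulated per link; *evidence*
is the number of distinct supporting reads.

Non-adjacent co-alignments within a chain are deliberately **not** turned
into links: they are retained per read and consulted only by the final
long-range joining pass. This keeps the initial graph sparse and the local
simplification decisions local.

## Graph simplification

Ambiguities (nodes with in- or out-degree above one) arise mainly from
missed seed alignments — a read that fails to hit one seed links its two
neighbours directly, producing a triangle — plus repetitive seeds and
spurious or chimeric alignments. Simplification proceeds in two stages:

1. **Span resolution.** A link `A → C` is removed (reason `spanned`) when
   some path `A → B₁ … B_k → C` over retained links explains its distance:
   `|gap(A→C) − (Σ path gaps + Σ len(Bᵢ))| ≤ max(50 bp, 0.2·gap(A→C))`,
   with `gap()` the arithmetic mean of the link's observations and
   `k ≤ max_lookahead` (default 3). Each sweep marks all such links first
   and removes them together, so the outcome is independent of node
   iteration order; sweeps repeat to a fixpoint, bounded at 10.
2. **Repeat severing.** At any side of a node that still branches, a link
   whose evidence is at least `min_evidence_ratio` (default 3.0) times every
   rival's wins and the rivals are dropped (reason `outvoted`); with no such
   winner the node is treated as repeat content and every link on that side
   is dropped (reason `repeat`). Because in-links of one orientation are
   the out-links of the other, a single pass over oriented nodes covers
   both sides. Under this rule the configured `max_branch` is never the
   deciding factor (a branch without an evidence winner is severed
   regardless); the parameter is kept for API stability.

Every removal is recorded `(link, reason)` in an audit list; retained and
removed links partition the initial link set exactly (asserted in tests).

After severing, every oriented node has degree ≤ 1 on both sides, and
maximal chains are read off as scaffold models. Each bidirected chain is
emitted once, oriented so the lexicographically smaller terminal seed comes
first. Circular components (possible in simulation) are linearised at the
link with the lowest evidence (ties by canonical key) — deterministic by
construction. Per-link gaps in the model are the half-up-rounded mean of
the observations (median available by flag).

## Long-range joining

Scaffolds whose terminal regions (outermost `max_lookahead` seeds) are
bridged by read co-alignments are merged when at least `min_join_evidence`
(default 2) distinct reads agree. Relative orientation is encoded in which
two scaffold ends face each other, so a candidate is orientation-consistent
by construction; its gap observations must lie within the span tolerance of
their mean. A join is applied only when neither end has a competing
surviving candidate — any end engaged twice voids all its candidates. The
inter-scaffold gap is the mean over supporting observations. Chains of
joins are walked deterministically; join cycles are broken at the
weakest join.

## Sequence layout

Scaffold sequence = oriented seed sequences joined gap by gap. For a
positive gap the patch is excised from the **donor** read — the supporting
read whose observed gap is closest to the link's mean, ties to the smallest
read id — between its two flanking seed alignments, reverse-complemented
when the read traverses the link backwards. A consensus of all supporting
reads would be the natural alternative; one donor keeps provenance exact
and leaves consensus to the downstream polishing step the bundles exist
for. For a non-positive gap the **downstream** seed is trimmed by the
overlap (the upstream seed is kept intact — an arbitrary but fixed
convention). Per-base provenance runs (seed id or donor read id) are
tracked and exported as BED; no quality strings are emitted, since
single-read nanopore-derived patches carry no meaningful per-base quality.

## Seed selection

Read pairs are merged at their longest exact terminal overlap of ≥ 15 nt
(a mismatch-tolerant mode exists but defaults off; exactness keeps the
operation verifiable against enumeration). Canonical 25-mers — the
lexicographic minimum of a k-mer and its reverse complement — are counted
across merged fragments in a streaming pass; counting is strand-collapsed
because seeds must be unique on both strands to serve as graph nodes.
Windows containing N are skipped, and fragments containing N are excluded
from candidacy outright. A fragment survives filtering iff every window's
count is ≤ 25 (strictly *over* 25 is removed); fragments of exactly the
configured seed length (270 or 285 nt) become seeds. When the table
outgrows a configurable bound, sorted partial tables spill to disk and are
merge-sorted; filtering against a spilled-scale table is out of scope for
this package (the TSV is the interchange artifact at that scale).

## Simulator

The simulator emulates: i.i.d. genome sequence at a target GC (default
0.42, a typical vertebrate value), optional interspersed copies of a single
repeat unit, seeds sampled uniformly from loci whose every 25-mer is
genome-unique (never overlapping each other or a repeat unit; strand
uniform), and reads with log-normal lengths, uniform strand, and an i.i.d.
per-base error model: with probability `1 − identity` a base suffers a
mismatch, insertion or deletion in chemistry-specific proportions.
Identities follow the published figures for nanopore chemistries (R7.3 2D
~0.75, R9 1D ~0.89, R9 2D ~0.94); R9.4 1D is set to 0.89 as no separate
figure is published. The mismatch:insertion:deletion splits (40:30:30 for
R7.3, 35:30:35 for R9/R9.4) are stated assumptions, config-overridable.
Deletion probability is doubled inside homopolymers of length ≥ 4
(default on), a coarse stand-in for the platform's homopolymer
under-representation. Chimeric reads join two unrelated fragments.

A **truth SAM** (seeds as references) is emitted directly from the edit
trace, bypassing any aligner: each record places the seed's post-edit
interval on the read via soft clips with a centred insertion or deletion
balancing the length change; `missed_hit_rate` randomly drops records to
model alignment failures. All randomness derives from one seed with one
PCG64 substream per stage (genome / seeds / reads), so every artifact is
bit-reproducible.

What the simulator does **not** model: diploidy and heterozygosity,
basecaller-specific error correlation, realistic read-length mixtures
across flow cells, and alignment mapping ambiguity (truth alignments are
perfect recall at the stated dropout rate). Passing tests therefore
demonstrate the graph algorithms' correctness under calibrated noise, not
end-to-end performance on real flow-cell data.

## Default study conditions

The bundled test conditions are a 1 Mbp single-chromosome genome, 285 nt
seeds at a mean spacing of 700 bp (~1 429 seeds), and 15× coverage in
log-normal reads of mean 8 kbp (sd 4 kbp). Under these conditions the
pipeline must recover exactly one scaffold with the true seed order and
orientation and zero misjoins from error-free reads, and ≥ 95 % of seeds
with zero misjoins at identity 0.89 with 15 % of seed alignments dropped
(both asserted in the test suite, fixed RNG seed 42). The acceptance
script runs a 200 kbp variant of the noisy condition so the whole
computation stays in seconds.

## Numerical conventions

- Coordinates are 0-based half-open throughout; gaps are signed and may
  reach `−seed_len`.
- Printed statistics: minimum link length uses ceiling; typical link
  length, mean spacing/gap and per-link gaps round half-up; coverages are
  reported at 2 decimals; orthologue percentages at 1 decimal, half-up.
- N50 is the length at which the descending cumulative length sum first
  reaches half the total (definitions vary in the literature; this one is
  stated in the CLI help and verified against exhaustive enumeration).
- Misjoin distance tolerance defaults to the simplification span tolerance
  (`max(50 bp, 20 %)`) for consistency.
- The overlap cap during graph construction (default 10 % of seed length)
  is configuration, not a constant: deeper overlaps can legitimately occur
  in production settings, so no default claims to bound the minimum
  scaffold length.

## Known limitations

- `join_long_range` considers only terminal regions; internally misplaced
  scaffold fragments are never re-split by the joining pass.
- The k-mer spill path bounds memory for counting but not for filtering.
- Spectrum comparison holds a dense `4^k/2` vector per input (hence
  `k ≤ 8`).
- Truth-based misjoin accounting requires simulator output; for real data
  an external whole-genome aligner remains necessary.
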