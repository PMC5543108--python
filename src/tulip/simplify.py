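"""Seed graph simplification and scaffold extraction.

The initial seed graph contains ambiguities — forks and joins — caused mostly
by missed seed alignments (a read that fails to align to one seed links its
two neighbours directly, creating a triangle), plus residual repetitive seeds
and spurious alignments.  Simplification proceeds in two stages:

1. ``resolve_spans`` removes a link when an alternative path through one or
   more intermediate seeds explains the same distance: the intermediate seeds
   "fit" inside the spanning link within a tolerance sized to long-read indel
   noise.
2. ``sever_repeats`` arbitrates nodes that still branch: a link whose
   evidence dominates every rival by a configurable ratio wins; otherwise the
   node looks repetitive and all links on that side are severed.

After simplification every oriented seed has in- and out-degree at most one,
so maximal chains can be read off directly as scaffold models
(``extract_paths``).  A final pass (``join_long_range``) merges scaffolds
whose terminal regions are bridged by unambiguous long-distance co-alignments
— read pairs of seed hits that were deliberately *not* turned into links at
graph construction time.

Every removal is recorded with a reason so decisions can be audited and
visualized in local neighbourhoods (``neighborhood``).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import flip_orient, round_half_up
from .graphbuild import (
    Link,
    LinkKey,
    OrientedSeed,
    ReadChain,
    SeedGraph,
    canonical_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimplifyConfig",
    "ScaffoldModel",
    "resolve_spans",
    "sever_repeats",
    "extract_paths",
    "join_long_range",
    "neighborhood",
    "simplify_graph",
    "partition_seeds",
]

MAX_SWEEPS = 10  # fixpoint bound for span resolution


@dataclass
class SimplifyConfig:
    """Thresholds governing graph simplification and scaffold joining.

    span_tolerance_*  — how well an intermediate path must explain a spanning
                        link's distance (the larger of the absolute and the
                        fractional bound applies);
    max_lookahead     — maximum number of intermediate seeds in such a path,
                        and the depth of a scaffold terminal region during
                        long-range joining;
    max_branch        — branching beyond which a node is treated as repeat
                        content outright;
    min_join_evidence — reads required to support a long-range join;
    min_evidence_ratio— dominance factor for evidence arbitration before a
                        branching node is severed.
    """

    span_tolerance_frac: float = 0.2
    span_tolerance_abs: int = 50
    max_lookahead: int = 3
    max_branch: int = 2
    min_join_evidence: int = 2
    min_evidence_ratio: float = 3.0
    gap_consensus: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if min(
            self.span_tolerance_frac,
            self.span_tolerance_abs,
            self.max_lookahead,
            self.max_branch,
            self.min_join_evidence,
            self.min_evidence_ratio,
        ) <= 0:
            raise ValueError("all SimplifyConfig thresholds must be positive")

    def consensus(self, values: Sequence[int]) -> float:
        if self.gap_consensus == "median":
            return statistics.median(values)
        return sum(values) / len(values)

    def span_tol(self, span: float) -> float:
        return max(self.span_tolerance_abs, self.span_tolerance_frac * span)


@dataclass
class ScaffoldModel:
    """An ordered, oriented seed arrangement with mean inter-seed gaps.

    ``placements`` holds ``(seed_id, orient, gap_after)`` triples where
    ``gap_after`` is the signed gap (bp, possibly negative for overlapping
    seeds) to the next seed, and ``None`` on the last placement.
    """

    scaffold_id: str
    placements: list[tuple[str, str, int | None]]
    est_length: int

    def seed_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.placements]

    def __len__(self) -> int:
        return len(self.placements)


def _mean_gap(link: Link, cfg: SimplifyConfig) -> float:
    return cfg.consensus(link.gap_obs)


def _spanning_paths_exist(
    graph: SeedGraph,
    u: OrientedSeed,
    v: OrientedSeed,
    gap_direct: float,
    cfg: SimplifyConfig,
) -> bool:
    """True if some path u -> B1 .. Bk -> v (1 <= k <= max_lookahead, simple,
    avoiding the direct link) explains gap_direct within tolerance."""
    tol = cfg.span_tol(gap_direct)
    seed_len = graph.seed_len
    # DFS over retained links; state = (node, implied distance, path seed set)
    stack = []
    for w, link in graph.out_links(u).items():
        if w == v or w.seed_id == u.seed_id or w.seed_id == v.seed_id:
            continue  # first step must reach an intermediate seed
        stack.append((w, _mean_gap(link, cfg), {u.seed_id, w.seed_id}))
    while stack:
        node, dist, seen = stack.pop()
        for w, link in graph.out_links(node).items():
            if w == v:
                # implied = sum of path gaps + lengths of the intermediates
                implied = dist + _mean_gap(link, cfg) + seed_len * (len(seen) - 1)
                if abs(gap_direct - implied) <= tol:
                    return True
                continue
            if w.seed_id in seen or w.seed_id == v.seed_id:
                continue
            if len(seen) - 1 >= cfg.max_lookahead:
                continue  # would exceed the intermediate budget
            stack.append((w, dist + _mean_gap(link, cfg), seen | {w.seed_id}))
    return False


def resolve_spans(graph: SeedGraph, cfg: SimplifyConfig | None = None) -> SeedGraph:
    """Remove links that span intermediate seeds which fit inside them.

    Each sweep marks every spanning link whose distance is explained by an
    alternative path of at most ``max_lookahead`` intermediate seeds, then
    removes all marks at once (so a sweep's outcome does not depend on node
    order).  Sweeps repeat to a fixpoint, bounded at ``MAX_SWEEPS``.
    """
    cfg = cfg or SimplifyConfig()
    for _ in range(MAX_SWEEPS):
        marks: set[LinkKey] = set()
        for u in graph.oriented_nodes():
            out = graph.out_links(u)
            if len(out) <= 1:
                continue
            for v, link in out.items():
                key = canonical_key((u, v))
                if key in marks:
                    continue
                if _spanning_paths_exist(graph, u, v, _mean_gap(link, cfg), cfg):
                    marks.add(key)
        if not marks:
            break
        for u, v in sorted(marks):
            graph.remove_link(u, v, "spanned")
    return graph


def sever_repeats(graph: SeedGraph, cfg: SimplifyConfig | None = None) -> SeedGraph:
    """Arbitrate or sever nodes that still branch after span resolution.

    At each oriented node with more than one outgoing link (in-sides are the
    out-sides of the mirror orientation and are visited likewise): if one link
    has evidence at least ``min_evidence_ratio`` times every rival it wins and
    the rivals are removed ("outvoted"); otherwise the node is treated as
    repeat content and every link on that side is removed ("repeat").
    """
    cfg = cfg or SimplifyConfig()
    for u in graph.oriented_nodes():
        out = graph.out_links(u)
        if len(out) <= 1:
            continue
        items = sorted(out.items())  # deterministic
        winner = None
        for v, link in items:
            if all(
                link.evidence >= cfg.min_evidence_ratio * other.evidence
                for w, other in items
                if w != v
            ):
                winner = v
                break
        if winner is not None:
            for v, _ in items:
                if v != winner:
                    graph.remove_link(u, v, "outvoted")
        else:
            for v, _ in items:
                graph.remove_link(u, v, "repeat")
    return graph


def simplify_graph(graph: SeedGraph, cfg: SimplifyConfig | None = None) -> SeedGraph:
    """resolve_spans to fixpoint, then sever_repeats."""
    cfg = cfg or SimplifyConfig()
    resolve_spans(graph, cfg)
    sever_repeats(graph, cfg)
    return graph


def _canonicalize(
    nodes: list[OrientedSeed], gaps: list[int]
) -> tuple[list[OrientedSeed], list[int]]:
    """Of a chain and its reverse-complement mirror, keep the representation
    whose terminal seed id is lexicographically smaller at the front."""
    if nodes[-1].seed_id < nodes[0].seed_id:
        nodes = [n.flipped() for n in reversed(nodes)]
        gaps = list(reversed(gaps))
    return nodes, gaps


def _to_model(
    nodes: list[OrientedSeed], gaps: list[int], seed_len: int
) -> tuple[list[tuple[str, str, int | None]], int]:
    placements: list[tuple[str, str, int | None]] = []
    for i, node in enumerate(nodes):
        gap = gaps[i] if i < len(gaps) else None
        placements.append((node.seed_id, node.orient, gap))
    est = seed_len * len(nodes) + sum(gaps)
    return placements, est


def extract_paths(
    graph: SeedGraph,
    cfg: SimplifyConfig | None = None,
    keep_singletons: bool = False,
    singleton_seeds: Iterable[str] | None = None,
) -> list[ScaffoldModel]:
    """Read maximal simple chains off a fully simplified graph.

    Requires every oriented node to have in- and out-degree at most one;
    residual branching is an invariant breach and fatal.  Each bidirected
    chain is emitted once, in canonical orientation.  Circular components are
    linearized at their weakest link (lowest evidence, ties by key), which is
    deterministic.  Isolated seeds become single-seed scaffolds only when
    ``keep_singletons`` is set (provide them via ``singleton_seeds``).
    """
    cfg = cfg or SimplifyConfig()
    for u in graph.oriented_nodes():
        if graph.out_degree(u) > 1:
            raise ValueError(f"node {u} still branches; graph not simplified")

    visited: set[str] = set()
    chains: list[tuple[list[OrientedSeed], list[int]]] = []

    # Linear chains: start where in-degree is 0.
    for u in graph.oriented_nodes():
        if u.seed_id in visited or graph.in_degree(u) != 0 or graph.out_degree(u) == 0:
            continue
        nodes, gaps = [u], []
        visited.add(u.seed_id)
        current = u
        while True:
            out = graph.out_links(current)
            if not out:
                break
            (nxt, link), = out.items()
            if nxt.seed_id in visited:
                raise ValueError(f"unexpected revisit of seed {nxt.seed_id}")
            gaps.append(round_half_up(cfg.consensus(link.gap_obs)))
            nodes.append(nxt)
            visited.add(nxt.seed_id)
            current = nxt
        chains.append(_canonicalize(nodes, gaps))

    # Remaining components with links are circles; break at the weakest link.
    for u in graph.oriented_nodes():
        if u.seed_id in visited or graph.out_degree(u) == 0:
            continue
        cycle_nodes = [u]
        cycle_links: list[tuple[LinkKey, Link]] = []
        current = u
        while True:
            (nxt, link), = graph.out_links(current).items()
            cycle_links.append(((current, nxt), link))
            if nxt == u:
                break
            cycle_nodes.append(nxt)
            current = nxt
        weakest_i = min(
            range(len(cycle_links)),
            key=lambda i: (cycle_links[i][1].evidence, canonical_key(cycle_links[i][0])),
        )
        logger.info(
            "breaking circular component at link %s->%s (evidence %d)",
            cycle_links[weakest_i][0][0],
            cycle_links[weakest_i][0][1],
            cycle_links[weakest_i][1].evidence,
        )
        n = len(cycle_nodes)
        order = [cycle_nodes[(weakest_i + 1 + j) % n] for j in range(n)]
        gaps = [
            round_half_up(cfg.consensus(cycle_links[(weakest_i + 1 + j) % n][1].gap_obs))
            for j in range(n - 1)
        ]
        for node in order:
            visited.add(node.seed_id)
        chains.append(_canonicalize(order, gaps))

    if keep_singletons and singleton_seeds is not None:
        for sid in sorted(set(singleton_seeds) - visited):
            chains.append(([OrientedSeed(sid, "+")], []))

    chains.sort(key=lambda c: c[0][0].seed_id)
    models = []
    for i, (nodes, gaps) in enumerate(chains):
        placements, est = _to_model(nodes, gaps, graph.seed_len)
        models.append(
            ScaffoldModel(scaffold_id=f"scaffold_{i + 1}", placements=placements, est_length=est)
        )
    return models


def partition_seeds(
    models: Sequence[ScaffoldModel],
    graph: SeedGraph,
    all_seeds: Iterable[str],
) -> dict[str, int]:
    """Account for every seed: scaffolded (in a multi-seed scaffold),
    singleton (no surviving links, none removed) or severed-isolated (all
    links removed during simplification)."""
    scaffolded = {sid for m in models for sid in m.seed_ids() if len(m) > 1}
    touched_by_removal = set()
    for (u, v), _, _ in graph.removed:
        touched_by_removal.add(u.seed_id)
        touched_by_removal.add(v.seed_id)
    counts = {"scaffolded": 0, "singleton": 0, "severed_isolated": 0}
    for sid in set(all_seeds):
        if sid in scaffolded:
            counts["scaffolded"] += 1
        elif sid in touched_by_removal:
            counts["severed_isolated"] += 1
        else:
            counts["singleton"] += 1
    return counts


# ---------------------------------------------------------------------------
# Long-range joining
# ---------------------------------------------------------------------------


def _positions(model: ScaffoldModel, seed_len: int) -> list[int]:
    starts, pos = [], 0
    for _, _, gap in model.placements:
        starts.append(pos)
        pos += seed_len + (gap if gap is not None else 0)
    return starts


def join_long_range(
    scaffolds: Sequence[ScaffoldModel],
    chains: Iterable[ReadChain],
    cfg: SimplifyConfig | None = None,
    seed_len: int = 285,
) -> list[ScaffoldModel]:
    """Merge scaffolds bridged by unambiguous long-distance co-alignments.

    A candidate join connects a terminal region (the outermost
    ``max_lookahead`` seeds) of one scaffold to a terminal region of another
    when at least ``min_join_evidence`` distinct reads co-align across them
    with mutually consistent orientation (encoded in which ends face each
    other) and gap (within span tolerance of their mean).  A join is applied
    only when neither participating scaffold end has any competing surviving
    candidate.  Applied joins merge models with the mean inter-scaffold gap.
    """
    cfg = cfg or SimplifyConfig()
    scaffolds = list(scaffolds)
    by_id = {m.scaffold_id: m for m in scaffolds}

    seed_loc: dict[str, tuple[str, int, str, int]] = {}  # seed -> (scf, idx, orient, start)
    for m in scaffolds:
        starts = _positions(m, seed_len)
        for idx, (sid, orient, _) in enumerate(m.placements):
            seed_loc[sid] = (m.scaffold_id, idx, orient, starts[idx])

    Port = tuple[str, str]  # (scaffold_id, 'head'|'tail')
    obs: dict[tuple[Port, Port], dict[str, int]] = {}

    for chain in chains:
        for i in range(len(chain.hits)):
            for j in range(i + 1, len(chain.hits)):
                h1, h2 = chain.hits[i], chain.hits[j]
                loc1, loc2 = seed_loc.get(h1.seed_id), seed_loc.get(h2.seed_id)
                if loc1 is None or loc2 is None:
                    continue
                s1, idx1, or1, start1 = loc1
                s2, idx2, or2, start2 = loc2
                if s1 == s2:
                    continue
                m1, m2 = by_id[s1], by_id[s2]
                end1 = "tail" if h1.strand == or1 else "head"
                end2 = "head" if h2.strand == or2 else "tail"
                # both seeds must sit in the terminal region facing the join
                if end1 == "tail" and len(m1) - 1 - idx1 >= cfg.max_lookahead:
                    continue
                if end1 == "head" and idx1 >= cfg.max_lookahead:
                    continue
                if end2 == "head" and idx2 >= cfg.max_lookahead:
                    continue
                if end2 == "tail" and len(m2) - 1 - idx2 >= cfg.max_lookahead:
                    continue
                off1 = (
                    m1.est_length - (start1 + seed_len) if end1 == "tail" else start1
                )
                off2 = (
                    start2 if end2 == "head" else m2.est_length - (start2 + seed_len)
                )
                gap = (h2.read_start - h1.read_end) - off1 - off2
                p1, p2 = (s1, end1), (s2, end2)
                key = (p1, p2) if p1 <= p2 else (p2, p1)
                obs.setdefault(key, {}).setdefault(chain.read_id, gap)

    # Survivors: enough distinct reads, internally consistent gaps.
    survivors: dict[tuple[Port, Port], tuple[float, int]] = {}
    for key, per_read in obs.items():
        gaps = sorted(per_read.values())
        if len(gaps) < cfg.min_join_evidence:
            continue
        mean = sum(gaps) / len(gaps)
        tol = cfg.span_tol(abs(mean))
        if all(abs(g - mean) <= tol for g in gaps):
            survivors[key] = (mean, len(gaps))

    # Ambiguity: a port engaged by more than one surviving candidate voids
    # every candidate touching it.
    port_use: dict[Port, int] = {}
    for (p1, p2) in survivors:
        port_use[p1] = port_use.get(p1, 0) + 1
        port_use[p2] = port_use.get(p2, 0) + 1
    applied = {
        key: val
        for key, val in survivors.items()
        if port_use[key[0]] == 1 and port_use[key[1]] == 1
    }

    # Break any cycle of joins at the weakest (then lexicographically first).
    joined_at: dict[Port, tuple[Port, float]] = {}
    for (p1, p2), (mean, ev) in sorted(
        applied.items(), key=lambda kv: (-kv[1][1], kv[0])
    ):
        joined_at[p1] = (p2, mean)
        joined_at[p2] = (p1, mean)
    # Detect cycles by walking components.
    adjacency: dict[str, list[Port]] = {}
    for (p1, p2) in applied:
        adjacency.setdefault(p1[0], []).append(p1)
        adjacency.setdefault(p2[0], []).append(p2)
    # A scaffold may use each port at most once by construction of `applied`.

    def other_end(port: Port) -> Port:
        return (port[0], "head" if port[1] == "tail" else "tail")

    # Walk components deterministically and emit merged models.
    merged_models: list[tuple[list[OrientedSeed], list[int]]] = []
    consumed: set[str] = set()

    def oriented_placements(m: ScaffoldModel, forward: bool):
        nodes = [OrientedSeed(sid, o) for sid, o, _ in m.placements]
        gaps = [g for _, _, g in m.placements[:-1]]
        if not forward:
            nodes = [n.flipped() for n in reversed(nodes)]
            gaps = list(reversed(gaps))
        return nodes, gaps

    for m in scaffolds:
        sid = m.scaffold_id
        if sid in consumed or sid not in adjacency:
            continue
        # find a free port in this component to start from
        component, frontier = set(), [sid]
        while frontier:
            s = frontier.pop()
            if s in component:
                continue
            component.add(s)
            for port in adjacency.get(s, []):
                partner, _ = joined_at[port]
                frontier.append(partner[0])
        starts = []
        for s in sorted(component):
            for end in ("head", "tail"):
                if (s, end) not in joined_at:
                    starts.append((s, end))
        if not starts:
            # pure cycle: break at the weakest join in the component
            weakest = min(
                (k for k in applied if k[0][0] in component),
                key=lambda k: (applied[k][1], k),
            )
            logger.info("breaking join cycle at %s (evidence %d)", weakest, applied[weakest][1])
            p1, p2 = weakest
            del joined_at[p1]
            del joined_at[p2]
            starts = [p1 if p1 <= p2 else p2]
        start_port = sorted(starts)[0]
        # orient the first scaffold so the free port is its head
        current_id, free_end = start_port
        forward = free_end == "head"
        nodes, gaps = oriented_placements(by_id[current_id], forward)
        consumed.add(current_id)
        while True:
            exit_port = (current_id, "tail" if forward else "head")
            if exit_port not in joined_at:
                break
            partner, mean_gap = joined_at[exit_port]
            next_id, entry_end = partner
            if next_id in consumed:
                break  # safety; should not happen after cycle breaking
            forward = entry_end == "head"
            nnodes, ngaps = oriented_placements(by_id[next_id], forward)
            gaps.append(round_half_up(mean_gap))
            gaps.extend(ngaps)
            nodes.extend(nnodes)
            consumed.add(next_id)
            current_id = next_id
        merged_models.append(_canonicalize(nodes, gaps))

    for m in scaffolds:
        if m.scaffold_id not in consumed:
            nodes = [OrientedSeed(sid, o) for sid, o, _ in m.placements]
            gaps = [g for _, _, g in m.placements[:-1]]
            merged_models.append((nodes, gaps))

    merged_models.sort(key=lambda c: c[0][0].seed_id)
    out = []
    for i, (nodes, gaps) in enumerate(merged_models):
        placements, est = _to_model(nodes, gaps, seed_len)
        out.append(
            ScaffoldModel(scaffold_id=f"scaffold_{i + 1}", placements=placements, est_length=est)
        )
    return out


# ---------------------------------------------------------------------------
# Neighbourhood extraction
# ---------------------------------------------------------------------------


@dataclass
class Neighborhood:
    """An induced local subgraph around a seed or scaffold, with removed
    links included and flagged by their recorded removal reason."""

    seeds: set[str]
    links: list[tuple[LinkKey, Link, str | None]]  # reason None = retained

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("from\tfrom_orient\tto\tto_orient\tevidence\tmean_gap\tstatus\n")
            for (u, v), link, reason in self.links:
                status = reason or "retained"
                fh.write(
                    f"{u.seed_id}\t{u.orient}\t{v.seed_id}\t{v.orient}"
                    f"\t{link.evidence}\t{round_half_up(link.mean_gap())}\t{status}\n"
                )


def neighborhood(
    graph: SeedGraph,
    target: str | ScaffoldModel,
    radius: int,
) -> Neighborhood:
    """Induced subgraph within ``radius`` links of a seed or of a scaffold's
    seeds, traversing retained and removed links alike."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if isinstance(target, ScaffoldModel):
        frontier = set(target.seed_ids())
    else:
        frontier = {target}

    edges: dict[LinkKey, tuple[Link, str | None]] = {}
    for key, link in graph.iter_links():
        edges[key] = (link, None)
    for key, link, reason in graph.removed:
        edges.setdefault(key, (link, reason))

    adj: dict[str, set[str]] = {}
    for (u, v), _ in edges.items():
        adj.setdefault(u.seed_id, set()).add(v.seed_id)
        adj.setdefault(v.seed_id, set()).add(u.seed_id)

    known = set(adj)
    unknown = frontier - known
    if unknown and not (isinstance(target, ScaffoldModel) and frontier & known):
        raise KeyError(f"unknown seed id(s): {sorted(unknown)[:3]}")

    seeds = set(frontier)
    for _ in range(radius):
        nxt = set()
        for sid in frontier:
            nxt.update(adj.get(sid, ()))
        nxt -= seeds
        if not nxt:
            break
        seeds.update(nxt)
        frontier = nxt

    links = [
        (key, link, reason)
        for key, (link, reason) in sorted(edges.items())
        if key[0].seed_id in seeds and key[1].seed_id in seeds
    ]
    return Neighborhood(seeds=seeds, links=links)
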