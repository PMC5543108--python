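"""Independent oracles used by the tests.

These deliberately avoid the library's own code paths: naive enumeration and
brute force only, so they can vouch for the optimized implementations.
"""

from __future__ import annotations


def naive_canonical_counts(fragments, k):
    """Dict of canonical k-mer counts by direct enumeration, skipping windows
    containing N."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    counts = {}
    for frag in fragments:
        seq = frag if isinstance(frag, str) else frag.seq
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            rc = "".join(comp[c] for c in reversed(window))
            kmer = min(window, rc)
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def naive_n50(lengths):
    """Largest L among the scaffold lengths such that scaffolds of length
    >= L sum to at least half the total (exhaustive over candidates)."""
    total = sum(lengths)
    feasible = [
        L for L in set(lengths) if sum(x for x in lengths if x >= L) >= total / 2
    ]
    return max(feasible)


def networkx_resolve_spans(graph, cfg):
    """Fixpoint span-removal via networkx all_simple_paths enumeration.

    Returns the set of canonical link keys an independent implementation
    would remove, leaving *graph* untouched.
    """
    import networkx as nx

    from tulip.graphbuild import canonical_key

    links = {}
    for key, link in graph.iter_links():
        u, v = key
        links[(u, v)] = link.mean_gap()
        links[(v.flipped(), u.flipped())] = link.mean_gap()

    removed = set()
    for _ in range(10):
        g = nx.DiGraph()
        for (u, v), gap in links.items():
            if canonical_key((u, v)) in removed:
                continue
            g.add_edge(u, v, gap=gap)
        marks = set()
        for u, v in g.edges:
            if g.out_degree(u) <= 1:
                continue
            direct = g.edges[u, v]["gap"]
            tol = max(cfg.span_tolerance_abs, cfg.span_tolerance_frac * direct)
            for path in nx.all_simple_paths(g, u, v, cutoff=cfg.max_lookahead + 1):
                if len(path) < 3:
                    continue
                intermediates = path[1:-1]
                if any(n.seed_id in (u.seed_id, v.seed_id) for n in intermediates):
                    continue
                if len({n.seed_id for n in path}) != len(path):
                    continue
                implied = sum(
                    g.edges[a, b]["gap"] for a, b in zip(path, path[1:])
                ) + graph.seed_len * len(intermediates)
                if abs(direct - implied) <= tol:
                    marks.add(canonical_key((u, v)))
                    break
        if not marks:
            break
        removed |= marks
    return removed


def naive_misjoins(models, truth, seed_len, tolerance=50.0, tolerance_frac=0.2):
    """Adjacency-by-adjacency misjoin count straight from the definitions."""
    errors = 0
    for model in models:
        for i in range(len(model.placements) - 1):
            a, oa, gap = model.placements[i]
            b, ob, _ = model.placements[i + 1]
            ca, sa, ta = truth.placements[a]
            cb, sb, tb = truth.placements[b]
            if ca != cb:
                errors += 1
                continue
            if (oa == ob) != (ta == tb):
                errors += 1
                continue
            step = seed_len + (gap or 0)
            delta = sb - sa if oa == ta else sa - sb
            if delta <= 0 or abs(delta - step) > max(tolerance, tolerance_frac * step):
                errors += 1
    return errors
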