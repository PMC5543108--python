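import random

import pytest

from tulip import (
    OrientedSeed,
    ReadChain,
    SeedAlignment,
    build_graph,
    graph_report,
    parse_sam,
)
from tulip.graphbuild import canonical_key


def make_hit(seed_id, start, end, strand="+", read_id="r1"):
    return SeedAlignment(
        read_id=read_id, seed_id=seed_id, read_start=start, read_end=end,
        strand=strand, seed_cov=1.0, mapq=60,
    )


def make_chain(read_id, read_len, hits):
    return ReadChain(read_id=read_id, read_len=read_len, hits=hits)


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:seed_A\tLN:285\n@SQ\tSN:seed_B\tLN:285\n"


def write_sam(tmp_path, records):
    path = tmp_path / "aln.sam"
    path.write_text(SAM_HEADER + "".join(r + "\n" for r in records))
    return path


class TestParseSam:
    def test_two_hit_chain_ordered_by_read_coordinate(self, tmp_path):
        path = write_sam(tmp_path, [
            "read_1\t0\t_B_\t1\t60\t500S285M15S\t*\t0\t0\t*\t*".replace("_B_", "seed_B"),
            "read_1\t0\tseed_A\t1\t60\t100S285M415S\t*\t0\t0\t*\t*",
        ])
        chains = parse_sam(path)
        assert len(chains) == 1
        chain = chains[0]
        assert chain.read_len == 800
        assert [(h.seed_id, h.read_start, h.read_end) for h in chain.hits] == [
            ("seed_A", 100, 385), ("seed_B", 500, 785),
        ]

    def test_reverse_strand_coordinates_on_read_forward(self, tmp_path):
        # reverse alignment: SAM soft clips refer to the reverse-complemented
        # query, so read-forward coordinates flip
        path = write_sam(tmp_path, [
            "read_1\t16\tseed_A\t1\t60\t100S285M415S\t*\t0\t0\t*\t*",
        ])
        (chain,) = parse_sam(path)
        (hit,) = chain.hits
        assert (hit.read_start, hit.read_end, hit.strand) == (415, 700, "-")

    def test_secondary_and_supplementary_dropped(self, tmp_path):
        path = write_sam(tmp_path, [
            "read_1\t0\tseed_A\t1\t60\t285M\t*\t0\t0\t*\t*",
            "read_1\t256\tseed_B\t1\t60\t285M\t*\t0\t0\t*\t*",
            "read_1\t2048\tseed_B\t1\t60\t285M\t*\t0\t0\t*\t*",
        ])
        (chain,) = parse_sam(path)
        assert [h.seed_id for h in chain.hits] == ["seed_A"]

    def test_low_coverage_and_mapq_filters(self, tmp_path):
        path = write_sam(tmp_path, [
            "read_1\t0\tseed_A\t1\t60\t100M685S\t*\t0\t0\t*\t*",   # 35% of seed
            "read_2\t0\tseed_A\t1\t0\t285M\t*\t0\t0\t*\t*",        # mapq 0
            "read_3\t0\tseed_A\t1\t60\t285M\t*\t0\t0\t*\t*",
        ])
        chains = parse_sam(path, min_seed_cov=0.8, min_mapq=1)
        assert [c.read_id for c in chains] == ["read_3"]

    def test_best_hit_per_seed_kept(self, tmp_path):
        path = write_sam(tmp_path, [
            "read_1\t0\tseed_A\t1\t60\t285M100S\t*\t0\t0\t*\t*\tAS:i:50",
            "read_1\t0\tseed_A\t1\t60\t100S285M\t*\t0\t0\t*\t*\tAS:i:280",
        ])
        (chain,) = parse_sam(path)
        assert [(h.seed_id, h.read_start) for h in chain.hits] == [("seed_A", 100)]

    def test_foreign_references_rejected(self, tmp_path):
        path = write_sam(tmp_path, [])
        with pytest.raises(ValueError, match="references"):
            parse_sam(path, seed_names={"other_1", "other_2"})

    def test_truth_sam_reproduces_simulator_chains(self, tmp_path, small_sim):
        from tulip import truth_chains, write_truth_sam

        sam = tmp_path / "truth.sam"
        write_truth_sam(sam, small_sim.seeds, small_sim.truth)
        parsed = parse_sam(sam)
        direct = truth_chains(small_sim.truth, small_sim.config.seed_len)
        assert len(parsed) == len(direct)
        for a, b in zip(parsed, direct):
            assert a.read_id == b.read_id
            assert [(h.seed_id, h.read_start, h.read_end, h.strand) for h in a.hits] == [
                (h.seed_id, h.read_start, h.read_end, h.strand) for h in b.hits
            ]


class TestBuildGraph:
    def test_positive_gap_link_and_mirror(self):
        chain = make_chain("r1", 800, [make_hit("S1", 100, 385), make_hit("S2", 500, 785)])
        g = build_graph([chain], seed_len=285)
        u, v = OrientedSeed("S1", "+"), OrientedSeed("S2", "+")
        link = g.out_links(u)[v]
        assert link.gap_obs == [115]
        assert link.evidence == 1
        mirror = g.out_links(OrientedSeed("S2", "-"))[OrientedSeed("S1", "-")]
        assert mirror is link
        g.check_symmetry()

    def test_small_overlap_within_cap_is_linked(self):
        chain = make_chain("r1", 800, [make_hit("S1", 100, 385), make_hit("S2", 360, 645)])
        g = build_graph([chain], seed_len=285, max_overlap_frac=0.10)
        link = g.out_links(OrientedSeed("S1", "+"))[OrientedSeed("S2", "+")]
        assert link.gap_obs == [-25]  # |−25| <= 28.5

    def test_deep_overlap_skipped(self):
        chain = make_chain("r1", 800, [make_hit("S1", 100, 385), make_hit("S2", 300, 585)])
        g = build_graph([chain], seed_len=285, max_overlap_frac=0.10)
        assert g.n_links() == 0
        assert g.n_skipped_overlap == 1

    def test_evidence_accumulates_across_reads(self):
        chains = [
            make_chain(f"r{i}", 800, [
                make_hit("S1", 100, 385, read_id=f"r{i}"),
                make_hit("S2", 500, 785, read_id=f"r{i}"),
            ])
            for i in range(3)
        ]
        g = build_graph(chains, seed_len=285)
        link = g.out_links(OrientedSeed("S1", "+"))[OrientedSeed("S2", "+")]
        assert link.evidence == 3
        assert sorted(link.reads) == ["r0", "r1", "r2"]

    def test_evidence_sum_equals_retained_adjacent_pairs(self, golden_result):
        g = golden_result.graph
        chains = golden_result.chains
        total_pairs = sum(max(len(c.hits) - 1, 0) for c in chains)
        evidence_sum = sum(link.evidence for _, link in g.iter_links())
        removed_sum = sum(link.evidence for _, link, _ in g.removed)
        assert evidence_sum + removed_sum + g.n_skipped_overlap == total_pairs

    def test_order_independent(self, small_sim):
        from tulip import truth_chains

        chains = truth_chains(small_sim.truth, small_sim.config.seed_len)
        g1 = build_graph(chains, small_sim.config.seed_len)
        shuffled = chains[:]
        random.Random(0).shuffle(shuffled)
        g2 = build_graph(shuffled, small_sim.config.seed_len)
        assert g1.canonical_state() == g2.canonical_state()

    def test_error_free_gaps_match_genomic_truth(self, golden_result):
        truth = golden_result.sim.truth
        seed_len = golden_result.sim.config.seed_len
        for (u, v), link in golden_result.graph.iter_links():
            start_u = truth.placements[u.seed_id][1]
            start_v = truth.placements[v.seed_id][1]
            true_gap = abs(start_v - start_u) - seed_len
            assert all(g == true_gap for g in link.gap_obs)


class TestGraphReport:
    def test_evidence_histogram(self):
        chains = []
        for i, (a, b) in enumerate([("S1", "S2"), ("S3", "S4"), ("S5", "S6")] ):
            n = 3 if i == 2 else 1
            for j in range(n):
                rid = f"r{i}_{j}"
                chains.append(make_chain(rid, 800, [
                    make_hit(a, 0, 285, read_id=rid), make_hit(b, 400, 685, read_id=rid),
                ]))
        report = graph_report(build_graph(chains, 285))
        assert dict(report.evidence_hist) == {1: 2, 3: 1}

    def test_empty_graph(self):
        report = graph_report(build_graph([], 285))
        assert not report.evidence_hist and not report.distance_hist
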