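"""Splice-graph construction, node typing and local path enumeration."""

import numpy as np
import pytest

from spliceplex.graph import (
    TranscriptModel,
    build_splice_graph,
    enumerate_event_paths,
)
from spliceplex.simulate import SimConfig, simulate_gene_models


def brute_force_partition(transcripts):
    """Independent oracle: cut the coordinate line at every exon boundary and
    keep the pieces covered by at least one exon."""
    cuts = sorted({c for t in transcripts for s, e in t.exons for c in (s, e)})
    pieces = []
    for a, b in zip(cuts, cuts[1:]):
        covered = any(
            s <= a and b <= e for t in transcripts for s, e in t.exons
        )
        if covered:
            pieces.append((a, b))
    return pieces


def test_cassette_collapse(cassette_graph):
    g = cassette_graph
    assert [(n.start, n.end) for n in g.nodes] == [(0, 100), (200, 300), (400, 500)]
    assert g.transcript_paths["t1"] == (1, 2, 3)
    assert g.transcript_paths["t2"] == (1, 3)
    # node 2 appears only in the inclusion isoform's path
    assert 2 not in g.transcript_paths["t2"]


def test_boundary_union_forces_split():
    t1 = TranscriptModel("g", "t1", "chr1", "+", ((0, 100), (300, 400)))
    t2 = TranscriptModel("g", "t2", "chr1", "+", ((0, 150), (300, 400)))
    g = build_splice_graph([t1, t2])
    assert [(n.start, n.end) for n in g.nodes] == [(0, 100), (100, 150), (300, 400)]
    # t2 reads through the split via an adjacency edge
    assert g.edges[(1, 2)] == "adjacency"
    assert g.transcript_paths["t2"] == (1, 2, 3)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_partition_matches_brute_force(seed):
    """Random transcripts over shared exon slots collapse to exactly the
    brute-force boundary partition of the exonic cover."""
    rng = np.random.default_rng(seed)
    slots = []
    pos = 0
    for _ in range(8):
        a = pos + int(rng.integers(0, 30))
        b = a + int(rng.integers(20, 120))
        slots.append((a, b))
        pos = b + int(rng.integers(0, 40))  # may touch or leave gaps
    txs = []
    for i in range(5):
        take = sorted(rng.choice(8, size=int(rng.integers(2, 7)), replace=False))
        exons = []
        for j in take:
            s, e = slots[j]
            if rng.random() < 0.4:  # jitter boundaries to create AA/AD splits
                s = s + int(rng.integers(0, max((e - s) // 3, 1)))
            exons.append((s, e))
        merged = []
        for s, e in sorted(exons):  # merge contiguous/overlapping picks
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        txs.append(
            TranscriptModel("g", f"t{i}", "chr1", "+", tuple(merged))
        )
    g = build_splice_graph(txs)
    assert [(n.start, n.end) for n in g.nodes] == brute_force_partition(txs)
    # each transcript exon is an exact concatenation of nodes
    for t in txs:
        path = g.transcript_paths[t.transcript_id]
        covered = sorted(g.node(i).interval for i in path)
        assert sum(e - s for s, e in covered) == sum(e - s for s, e in t.exons)


def test_graph_determinism_under_transcript_order(cassette_transcripts):
    g1 = build_splice_graph(cassette_transcripts)
    g2 = build_splice_graph(list(reversed(cassette_transcripts)))
    assert [(n.start, n.end, n.node_type) for n in g1.nodes] == [
        (n.start, n.end, n.node_type) for n in g2.nodes
    ]
    assert g1.edges == g2.edges


def test_mixed_strand_and_zero_length_rejected():
    t1 = TranscriptModel("g", "t1", "chr1", "+", ((0, 100),))
    t2 = TranscriptModel("g", "t2", "chr1", "-", ((0, 100),))
    with pytest.raises(ValueError, match="strand"):
        build_splice_graph([t1, t2])
    with pytest.raises(ValueError, match="zero-length"):
        TranscriptModel("g", "t", "chr1", "+", ((5, 5),))


class TestNodeTyping:
    def test_cassette_middle_is_core_exon(self, cassette_graph):
        assert cassette_graph.node(2).node_type == "CE"

    def test_retained_intron(self):
        t1 = TranscriptModel("g", "t1", "chr1", "+", ((0, 100), (200, 300)))
        t2 = TranscriptModel("g", "t2", "chr1", "+", ((0, 300),))
        g = build_splice_graph([t1, t2])
        assert g.node(2).interval == (100, 200)
        assert g.node(2).node_type == "RI"

    def test_alternative_first_exon(self):
        t1 = TranscriptModel("g", "t1", "chr1", "+", ((0, 50), (400, 500)))
        t2 = TranscriptModel("g", "t2", "chr1", "+", ((100, 200), (400, 500)))
        g = build_splice_graph([t1, t2])
        assert g.node(1).node_type == "AF"
        assert g.node(2).node_type == "AF"

    def test_alternative_acceptor_on_minus_strand(self):
        # '-' strand acceptor variation: the extension piece sits at the
        # genomic end of an internal exon (its transcriptional 5' side)
        t1 = TranscriptModel(
            "g", "t1", "chr1", "-", ((0, 100), (200, 320), (400, 500))
        )
        t2 = TranscriptModel(
            "g", "t2", "chr1", "-", ((0, 100), (200, 280), (400, 500))
        )
        g = build_splice_graph([t1, t2])
        ext = next(n for n in g.nodes if n.interval == (280, 320))
        assert ext.node_type == "AA"

    @pytest.mark.parametrize(
        "etype", ["CE", "AA", "AD", "RI", "AF", "AL", "TS", "TE"]
    )
    def test_simulator_round_trip(self, etype):
        """Every intended focal event appears in the built graph with the
        intended node type, on both strands."""
        cfg = SimConfig(seed=99, n_genes=24, event_mix={etype: 1.0})
        for sim in simulate_gene_models(cfg):
            g = build_splice_graph(sim.transcripts)
            node = next(
                n for n in g.nodes if (n.start, n.end) == sim.focal_interval
            )
            assert node.node_type == etype, (sim.gene_id, node)


class TestEnumerateEventPaths:
    def test_cassette_two_paths(self, cassette_graph):
        ev = enumerate_event_paths(cassette_graph, 2)
        assert ev.paths == [(1, 2, 3), (1, 3)]
        assert ev.contains_node == [True, False]
        assert not ev.truncated

    def test_single_transcript_gene_single_path(self):
        t = TranscriptModel("g", "t", "chr1", "+", ((0, 100), (200, 300)))
        g = build_splice_graph([t])
        for i in (1, 2):
            ev = enumerate_event_paths(g, i)
            assert ev.n_paths == 1
            assert ev.contains_node == [True]

    def test_matches_exhaustive_dfs_oracle(self):
        """Cassette plus an alternative acceptor on the downstream exon:
        enumeration equals exhaustive DFS over the local DAG."""
        t1 = TranscriptModel(
            "g", "t1", "chr1", "+", ((0, 100), (200, 300), (400, 520))
        )
        t2 = TranscriptModel("g", "t2", "chr1", "+", ((0, 100), (400, 520)))
        t3 = TranscriptModel(
            "g", "t3", "chr1", "+", ((0, 100), (200, 300), (450, 520))
        )
        g = build_splice_graph([t1, t2, t3])
        ev = enumerate_event_paths(g, 2)

        def oracle_paths(edges, start, end):
            out = []

            def walk(cur, acc):
                if cur == end:
                    out.append(tuple(acc))
                    return
                for (a, b) in sorted(edges):
                    if a == cur:
                        walk(b, acc + [b])

            walk(start, [start])
            return out

        # anchors: node 1 upstream; downstream anchor is the shared exon body
        assert ev.anchor_up == 1
        expected = oracle_paths(set(g.edges), ev.anchor_up, ev.anchor_down)
        assert sorted(ev.paths) == sorted(expected)

    def test_path_closure(self):
        """Every transcript's restriction to an event window is one of the
        enumerated paths."""
        cfg = SimConfig(seed=17, n_genes=30)
        for sim in simulate_gene_models(cfg):
            g = build_splice_graph(sim.transcripts)
            for node in g.nodes:
                ev = enumerate_event_paths(g, node.node_index)
                if ev.truncated:
                    continue
                window = {n for p in ev.paths for n in p}
                lo, hi = min(window), max(window)
                starts = {p[0] for p in ev.paths}
                ends = {p[-1] for p in ev.paths}
                for path in g.transcript_paths.values():
                    restr = tuple(n for n in path if lo <= n <= hi)
                    # only transcripts traversing the whole event region
                    if restr and restr[0] in starts and restr[-1] in ends:
                        assert restr in set(ev.paths), (sim.gene_id, node)

    def test_truncation_flag(self):
        """A ladder of many skippable exons explodes combinatorially and is
        flagged unquantifiable at the cap."""
        exons = tuple((200 * i, 200 * i + 100) for i in range(10))
        txs = [TranscriptModel("g", "t_full", "chr1", "+", exons)]
        for k in range(1, 9):
            txs.append(
                TranscriptModel(
                    "g", f"t_skip{k}", "chr1", "+",
                    tuple(e for j, e in enumerate(exons) if j != k),
                )
            )
        g = build_splice_graph(txs)
        ev = enumerate_event_paths(g, 5, max_paths=8)
        assert ev.truncated
        assert ev.n_paths <= 8
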