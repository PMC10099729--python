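"""Contiguous splice graphs (CSGs).

A gene's annotated transcripts are collapsed into non-overlapping exonic
*nodes* by cutting the exonic cover of the gene at every exon boundary seen
in any transcript. The contiguous splice graph connects nodes with two kinds
of edges: *adjacency* edges between genomically contiguous nodes that some
transcript reads through, and *junction* edges where a transcript splices
between non-contiguous nodes. Each annotated isoform is then a path through
the graph, and the alternative-splicing event of a node is the set of local
paths between the nearest anchors shared by every transcript overlapping the
node's region.

Coordinates are 0-based half-open throughout this module (GTF conversion
happens at the I/O layer). Node indices are 1..N in transcription order, so
"upstream" always means transcriptionally upstream (reverse of genomic order
on the '-' strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TranscriptModel",
    "SpliceNode",
    "SpliceGraph",
    "EventPaths",
    "build_splice_graph",
    "classify_node_type",
    "enumerate_event_paths",
    "NODE_TYPES",
]

NODE_TYPES = ("CE", "AA", "AD", "AF", "AL", "RI", "TE", "TS", "NONE")

ADJACENCY = "adjacency"
JUNCTION = "junction"


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform: an ordered set of genomic exon intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError(
                    f"{self.transcript_id}: zero-length exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass(frozen=True)
class SpliceNode:
    gene_id: str
    node_index: int  # 1-based, transcription order
    start: int
    end: int
    node_type: str = "NONE"

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpliceGraph:
    """Per-gene CSG: ordered nodes, typed edges, and transcript paths."""

    gene_id: str
    chrom: str
    strand: str
    nodes: list[SpliceNode]
    # (from_index, to_index) -> "adjacency" | "junction"; from < to in
    # transcription order
    edges: dict[tuple[int, int], str]
    transcript_paths: dict[str, tuple[int, ...]]

    def node(self, node_index: int) -> SpliceNode:
        if not 1 <= node_index <= len(self.nodes):
            raise KeyError(f"{self.gene_id}: no node {node_index}")
        return self.nodes[node_index - 1]

    def out_edges(self, node_index: int) -> list[tuple[int, str]]:
        return sorted(
            (v, kind) for (u, v), kind in self.edges.items() if u == node_index
        )

    def in_edges(self, node_index: int) -> list[tuple[int, str]]:
        return sorted(
            (u, kind) for (u, v), kind in self.edges.items() if v == node_index
        )

    def contiguous(self, u: int, v: int) -> bool:
        """True if nodes u and v (transcription order, v = u + 1) touch."""
        if v != u + 1:
            return False
        a, b = self.node(u), self.node(v)
        if self.strand == "+":
            return a.end == b.start
        return b.end == a.start

    def first_nodes(self) -> set[int]:
        return {path[0] for path in self.transcript_paths.values()}

    def last_nodes(self) -> set[int]:
        return {path[-1] for path in self.transcript_paths.values()}


@dataclass
class EventPaths:
    """All local paths through one node's AS event.

    Each path is the ordered node sequence from the event's upstream anchor
    to its downstream anchor; edges are recoverable from the graph. A path
    "contains" the event node when the node lies on it.
    """

    gene_id: str
    node_index: int
    anchor_up: int | None
    anchor_down: int | None
    paths: list[tuple[int, ...]]
    contains_node: list[bool]
    truncated: bool = False

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def path_edges(self, i: int) -> list[tuple[int, int]]:
        p = self.paths[i]
        return [(p[j], p[j + 1]) for j in range(len(p) - 1)]

    def event_edges(self) -> list[tuple[int, int]]:
        """Union of edges over all paths, sorted."""
        seen: set[tuple[int, int]] = set()
        for i in range(self.n_paths):
            seen.update(self.path_edges(i))
        return sorted(seen)


def _exonic_cover(transcripts: Sequence[TranscriptModel]) -> list[tuple[int, int]]:
    """Merged union of all exon intervals."""
    ivs = sorted(e for t in transcripts for e in t.exons)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_splice_graph(transcripts: Iterable[TranscriptModel]) -> SpliceGraph:
    """Collapse one gene's transcripts into nodes and build its CSG.

    Node boundaries are the union of all exon start/end coordinates
    projected onto the merged exonic cover; every transcript exon is an
    exact concatenation of nodes, and every transcript becomes a path.
    """
    txs = list(transcripts)
    if not txs:
        raise ValueError("build_splice_graph requires at least one transcript")
    gene_id = txs[0].gene_id
    chrom = txs[0].chrom
    strand = txs[0].strand
    for t in txs:
        if t.gene_id != gene_id:
            raise ValueError(f"mixed gene_ids: {gene_id} vs {t.gene_id}")
        if t.chrom != chrom:
            raise ValueError(f"{gene_id}: transcripts on mixed chromosomes")
        if t.strand != strand:
            raise ValueError(f"{gene_id}: transcripts on mixed strands")

    boundaries = sorted({c for t in txs for s, e in t.exons for c in (s, e)})
    cover = _exonic_cover(txs)

    # Partition the cover at every interior boundary -> genomic-order nodes.
    genomic: list[tuple[int, int]] = []
    for cs, ce in cover:
        cuts = [cs] + [b for b in boundaries if cs < b < ce] + [ce]
        genomic.extend((cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))

    order = genomic if strand == "+" else list(reversed(genomic))
    index_of = {iv: i + 1 for i, iv in enumerate(order)}
    nodes = [
        SpliceNode(gene_id=gene_id, node_index=i + 1, start=s, end=e)
        for i, (s, e) in enumerate(order)
    ]

    # Genomic lookup: node start -> interval, for mapping exons to node runs.
    starts = {s: (s, e) for s, e in genomic}

    edges: dict[tuple[int, int], str] = {}
    transcript_paths: dict[str, tuple[int, ...]] = {}
    for t in txs:
        path_genomic: list[list[tuple[int, int]]] = []
        for es, ee in t.exons:
            run: list[tuple[int, int]] = []
            pos = es
            while pos < ee:
                iv = starts.get(pos)
                if iv is None or iv[1] > ee:
                    raise ValueError(
                        f"{t.transcript_id}: exon [{es},{ee}) does not align "
                        "to the node partition"
                    )
                run.append(iv)
                pos = iv[1]
            path_genomic.append(run)
        flat = [iv for run in path_genomic for iv in run]
        if strand == "-":
            path_genomic = [list(reversed(run)) for run in reversed(path_genomic)]
            flat = [iv for run in path_genomic for iv in run]
        path = tuple(index_of[iv] for iv in flat)
        transcript_paths[t.transcript_id] = path
        # adjacency within exons, junctions between exons (zero-length
        # introns collapse to adjacency)
        k = 0
        for run in path_genomic:
            for j in range(len(run) - 1):
                u, v = path[k + j], path[k + j + 1]
                edges[(u, v)] = ADJACENCY
            k += len(run)
        offsets = [0]
        for run in path_genomic:
            offsets.append(offsets[-1] + len(run))
        for j in range(len(path_genomic) - 1):
            u = path[offsets[j + 1] - 1]
            v = path[offsets[j + 1]]
            if (u, v) not in edges:
                a, b = order[u - 1], order[v - 1]
                touch = a[1] == b[0] if strand == "+" else b[1] == a[0]
                edges[(u, v)] = ADJACENCY if touch else JUNCTION

    graph = SpliceGraph(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        nodes=nodes,
        edges=edges,
        transcript_paths=transcript_paths,
    )
    graph.nodes = [
        SpliceNode(
            gene_id=gene_id,
            node_index=n.node_index,
            start=n.start,
            end=n.end,
            node_type=classify_node_type(graph, n.node_index),
        )
        for n in graph.nodes
    ]
    return graph


def classify_node_type(graph: SpliceGraph, node_index: int) -> str:
    """Type a node with an ordered rule cascade (first match wins).

    Order: RI, AF, AL, TS, TE, AA, AD, CE; nodes that are read through by
    adjacency in every transcript and never skipped are NONE. The eight
    types follow the standard splice-graph vocabulary: retained intron,
    alternative first/last exon, tandem TSS/polyA extension, alternative
    acceptor/donor, core (cassette-like) exon.
    """
    graph.node(node_index)
    n = len(graph.nodes)

    in_edges = graph.in_edges(node_index)
    out_edges = graph.out_edges(node_index)
    junction_in = any(k == JUNCTION for _, k in in_edges)
    junction_out = any(k == JUNCTION for _, k in out_edges)

    # RI: node is read through contiguously by some transcript but lies
    # strictly inside an intron of another (a spliced-over contiguous run).
    adj_in = any(k == ADJACENCY and u == node_index - 1 for u, k in in_edges)
    adj_out = any(k == ADJACENCY and v == node_index + 1 for v, k in out_edges)
    spanned_by_junction = any(
        kind == JUNCTION and u < node_index < v
        for (u, v), kind in graph.edges.items()
    )
    if adj_in and adj_out and spanned_by_junction:
        if graph.contiguous(node_index - 1, node_index) and graph.contiguous(
            node_index, node_index + 1
        ):
            return "RI"

    is_first = node_index in graph.first_nodes()
    is_last = node_index in graph.last_nodes()

    if is_first and junction_out and len(graph.first_nodes()) >= 2:
        return "AF"
    if is_last and junction_in and len(graph.last_nodes()) >= 2:
        return "AL"
    if is_first and not junction_in and not junction_out and (in_edges or out_edges):
        return "TS"
    if is_last and not junction_in and not junction_out and (in_edges or out_edges):
        return "TE"

    # AA: contiguous extension at the transcriptional 5' side of the
    # downstream neighbour, which other transcripts reach directly by a
    # junction (bypassing this node).
    down = node_index + 1
    if down <= n and graph.contiguous(node_index, down):
        if (node_index, down) in graph.edges and any(
            kind == JUNCTION and v == down and u < node_index
            for (u, v), kind in graph.edges.items()
        ):
            return "AA"
    # AD: mirror image on the donor side.
    up = node_index - 1
    if up >= 1 and graph.contiguous(up, node_index):
        if (up, node_index) in graph.edges and any(
            kind == JUNCTION and u == up and v > node_index
            for (u, v), kind in graph.edges.items()
        ):
            return "AD"

    if junction_in or junction_out or spanned_by_junction:
        return "CE"
    return "NONE"


def _relevant_transcripts(graph: SpliceGraph, node_index: int) -> list[tuple[int, ...]]:
    """Transcript paths that contain the node or splice across its position."""
    rel = []
    for path in graph.transcript_paths.values():
        if node_index in path:
            rel.append(path)
        elif path[0] < node_index < path[-1] and any(
            a < node_index < b for a, b in zip(path, path[1:])
        ):
            rel.append(path)
    return rel


def enumerate_event_paths(
    graph: SpliceGraph, node_index: int, max_paths: int = 128
) -> EventPaths:
    """Enumerate all local paths through a node's AS event.

    The anchors are the nearest nodes up- and downstream of the event node
    that every transcript overlapping the node's region passes through;
    every distinct edge-path between the anchors is one splicing outcome.
    When a gene end lies inside the event, the corresponding anchor is open
    and paths start (end) at the transcript start (end) nodes instead.
    Enumeration stops, with ``truncated=True``, if more than ``max_paths``
    paths exist; such events are unquantifiable.
    """
    graph.node(node_index)
    if not graph.in_edges(node_index) and not graph.out_edges(node_index):
        if len(graph.nodes) > 1:
            raise ValueError(
                f"{graph.gene_id}: node {node_index} has no incident edges "
                "(inconsistent annotation)"
            )
        # single-node gene: the trivial one-path event
        return EventPaths(
            gene_id=graph.gene_id,
            node_index=node_index,
            anchor_up=None,
            anchor_down=None,
            paths=[(node_index,)],
            contains_node=[True],
        )

    rel = _relevant_transcripts(graph, node_index)
    if not rel:  # pragma: no cover - every node belongs to some transcript
        raise ValueError(f"{graph.gene_id}: node {node_index} unreachable")

    common: set[int] = set(rel[0])
    for path in rel[1:]:
        common &= set(path)
    ups = [i for i in common if i < node_index]
    downs = [i for i in common if i > node_index]
    u = max(ups) if ups else None
    v = min(downs) if downs else None

    starts = {u} if u is not None else {p[0] for p in rel}
    ends = {v} if v is not None else {p[-1] for p in rel}
    lo = min(starts)
    hi = max(ends)

    succ: dict[int, list[int]] = {}
    for (a, b), _ in graph.edges.items():
        if lo <= a and b <= hi:
            succ.setdefault(a, []).append(b)
    for lst in succ.values():
        lst.sort()

    paths: list[tuple[int, ...]] = []
    truncated = False

    def dfs(cur: int, acc: list[int]) -> bool:
        nonlocal truncated
        if cur in ends:
            if len(paths) >= max_paths:
                truncated = True
                return False
            paths.append(tuple(acc))
            return True
        for nxt in succ.get(cur, ()):
            if not dfs(nxt, acc + [nxt]):
                return False
        return True

    for s in sorted(starts):
        if not dfs(s, [s]):
            break

    contains = [node_index in p for p in paths]
    return EventPaths(
        gene_id=graph.gene_id,
        node_index=node_index,
        anchor_up=u,
        anchor_down=v,
        paths=paths,
        contains_node=contains,
        truncated=truncated,
    )
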