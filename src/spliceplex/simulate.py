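"""Synthetic data with recorded ground truth.

The generator emulates a multi-tissue, multi-species, multi-stage splicing
study on annotation alone: multi-isoform gene models instantiating each of
the eight event types; per-condition path abundances drawn from Dirichlet
distributions whose concentration controls splicing entropy (a mixture of a
concentrated and a flat regime reproduces the bimodal entropy landscape of
real tissues); multinomially sampled edge read counts at a configurable
depth; binary gain/loss histories of alternative splicing along a rooted
species tree; and developmental stage series with planted inclusion sweeps
(Dev events) or entropy sweeps at constant inclusion (entropy-dynamic
events). Every observable has a recorded truth, and every generator output
is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .development import StageQuant, StageSeries
from .evolution import PhyloTree
from .graph import EventPaths, TranscriptModel, build_splice_graph
from .quantify import (
    EdgeCounts,
    estimate_path_abundances,
    node_psi,
    splicing_entropy,
)

__all__ = [
    "SimConfig",
    "GeneSim",
    "DEFAULT_EVENT_MIX",
    "simulate_gene_models",
    "simulate_genome",
    "simulate_path_abundances",
    "simulate_edge_counts",
    "simulate_evolutionary_history",
    "simulate_stage_series",
    "three_path_event",
    "cassette_event",
    "simulate_divergent_entropies",
]

DEFAULT_EVENT_MIX = {
    "CE": 0.50, "AA": 0.10, "AD": 0.10, "RI": 0.10,
    "AF": 0.08, "AL": 0.08, "TS": 0.02, "TE": 0.02,
}


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    Defaults emulate a desk-scale version of a six-tissue, seven-species
    bulk study with a ten-stage developmental series: 200 genes of 4-9
    exons, 2-4 isoforms, the event-type mix above, and multinomial edge
    reads at depth 200 per event and condition. The Dirichlet concentration
    pair (0.08, 12.0) with a 50/50 regime mixture yields the two-peaked
    (low/high) splicing-entropy landscape seen in tissues.
    """

    seed: int
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 9)
    transcripts_per_gene: tuple[int, int] = (2, 4)
    event_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    tissues: tuple[str, ...] = (
        "brain", "cerebellum", "heart", "liver", "kidney", "testis",
    )
    n_stages: int = 10
    depth: int = 200
    gene_tpm: float = 50.0
    concentration_low: float = 0.08
    concentration_high: float = 12.0
    high_entropy_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not all(0 <= p <= 1 for p in self.event_mix.values()):
            raise ValueError("event mix proportions must be in [0,1]")
        if self.n_stages < 6:
            raise ValueError("developmental series needs >= 6 stages")


@dataclass
class GeneSim:
    gene_id: str
    transcripts: list[TranscriptModel]
    event_type: str
    focal_interval: tuple[int, int]  # genomic interval of the focal node


def _truncate_5p(exon: tuple[int, int], delta: int, strand: str) -> tuple[int, int]:
    s, e = exon
    return (s + delta, e) if strand == "+" else (s, e - delta)


def _truncate_3p(exon: tuple[int, int], delta: int, strand: str) -> tuple[int, int]:
    s, e = exon
    return (s, e - delta) if strand == "+" else (s + delta, e)


def _make_gene(
    gene_id: str,
    chrom: str,
    offset: int,
    event_type: str,
    rng: np.random.Generator,
    n_exons: int,
    n_extra_skips: int,
) -> tuple[GeneSim, int]:
    """One gene whose isoforms instantiate ``event_type`` at a focal node."""
    strand = "+" if rng.random() < 0.5 else "-"
    min_exons = {"CE": 3, "AA": 3, "AD": 3, "RI": 3, "AF": 3, "AL": 3,
                 "TS": 2, "TE": 2}[event_type]
    n_exons = max(n_exons, min_exons)

    # AF/AL reserve an extra genomic slot for the alternative terminal exon
    extra_slot = event_type in ("AF", "AL")
    n_slots = n_exons + (1 if extra_slot else 0)
    exons: list[tuple[int, int]] = []
    pos = offset
    for _ in range(n_slots):
        length = int(rng.integers(80, 260))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(120, 420))
    gene_end = pos

    def order(e: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(e))

    # transcription-order index of exon slots
    slots = exons if strand == "+" else list(reversed(exons))

    transcripts: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    focal: tuple[int, int]

    if event_type == "CE":
        k = int(rng.integers(1, n_exons - 1))
        full = slots
        skip = [e for j, e in enumerate(slots) if j != k]
        focal = slots[k]
        transcripts = [("t1", order(full)), ("t2", order(skip))]
    elif event_type in ("AA", "AD"):
        k = int(rng.integers(1, n_exons - 1))
        delta = int(rng.integers(20, min(60, slots[k][1] - slots[k][0] - 20)))
        trunc = (
            _truncate_5p(slots[k], delta, strand)
            if event_type == "AA"
            else _truncate_3p(slots[k], delta, strand)
        )
        short = list(slots)
        short[k] = trunc
        if event_type == "AA":
            focal = (
                (slots[k][0], trunc[0]) if strand == "+" else (trunc[1], slots[k][1])
            )
        else:
            focal = (
                (trunc[1], slots[k][1]) if strand == "+" else (slots[k][0], trunc[0])
            )
        transcripts = [("t1", order(slots)), ("t2", order(short))]
    elif event_type == "RI":
        k = int(rng.integers(0, n_exons - 1))
        a, b = sorted([slots[k], slots[k + 1]])
        merged = [e for j, e in enumerate(slots) if j not in (k, k + 1)]
        merged.append((a[0], b[1]))
        focal = (a[1], b[0])  # the retained intron
        transcripts = [("t1", order(slots)), ("t2", order(merged))]
    elif event_type in ("AF", "AL"):
        # slots, transcription order, has n_exons + 1 entries; the first two
        # (AF) or last two (AL) are the alternative terminal exons.
        if event_type == "AF":
            alt0, alt1 = slots[0], slots[1]
            body = slots[2:]
            t1 = [alt1] + list(body)
            t2 = [alt0] + list(body)
            focal = alt0
        else:
            alt0, alt1 = slots[-2], slots[-1]
            body = slots[:-2]
            t1 = list(body) + [alt0]
            t2 = list(body) + [alt1]
            focal = alt1
        transcripts = [("t1", order(t1)), ("t2", order(t2))]
    elif event_type in ("TS", "TE"):
        delta = int(
            rng.integers(
                20,
                min(
                    60,
                    (slots[0][1] - slots[0][0] if event_type == "TS"
                     else slots[-1][1] - slots[-1][0]) - 20,
                ),
            )
        )
        short = list(slots)
        if event_type == "TS":
            short[0] = _truncate_5p(slots[0], delta, strand)
            focal = (
                (slots[0][0], short[0][0]) if strand == "+"
                else (short[0][1], slots[0][1])
            )
        else:
            short[-1] = _truncate_3p(slots[-1], delta, strand)
            focal = (
                (short[-1][1], slots[-1][1]) if strand == "+"
                else (slots[-1][0], short[-1][0])
            )
        transcripts = [("t1", order(slots)), ("t2", order(short))]
    else:
        raise ValueError(f"unknown event type {event_type!r}")

    # optional extra isoforms: skip additional internal exons of t1 to raise
    # event complexity
    base = list(transcripts[0][1])
    internal = [
        j for j in range(1, len(base) - 1)
        if not (base[j][0] < focal[1] and focal[0] < base[j][1])
    ]
    internal = [int(j) for j in rng.permutation(internal)] if internal else []
    for x, j in enumerate(internal[:n_extra_skips]):
        variant = [e for jj, e in enumerate(base) if jj != j]
        transcripts.append((f"t{3 + x}", order(variant)))

    models = [
        TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.{tid}",
            chrom=chrom,
            strand=strand,
            exons=ex,
        )
        for tid, ex in transcripts
    ]
    sim = GeneSim(gene_id, models, event_type, focal)
    return sim, gene_end + int(rng.integers(300, 800))


def simulate_gene_models(config: SimConfig) -> list[GeneSim]:
    """Generate gene models realizing the configured event-type mix.

    Each gene carries one focal event; the realized splice graph is checked
    to contain a node matching the focal interval (round-trip check) and
    the gene is re-drawn (up to a few attempts) if boundary collisions
    break the intended structure.
    """
    rng = np.random.default_rng(config.seed)
    types = sorted(config.event_mix)
    probs = np.array([config.event_mix[t] for t in types], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("event mix must have positive total probability")
    probs = probs / probs.sum()

    genes: list[GeneSim] = []
    offset = 1000
    for i in range(config.n_genes):
        etype = str(rng.choice(types, p=probs))
        if etype == "RI" and config.transcripts_per_gene[1] < 2:
            raise ValueError("RI events require >= 2 transcripts per gene")
        # ranges are inclusive at both ends
        n_exons = int(
            rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1)
        )
        n_extra = max(
            0,
            int(
                rng.integers(
                    config.transcripts_per_gene[0],
                    config.transcripts_per_gene[1] + 1,
                )
            )
            - 2,
        )
        gene_id = f"g{i + 1:04d}"
        sim, offset = _make_gene(
            gene_id, "chr1", offset, etype, rng, n_exons, n_extra
        )
        graph = build_splice_graph(sim.transcripts)  # round-trip check
        match = [
            n for n in graph.nodes
            if (n.start, n.end) == sim.focal_interval
        ]
        if not match:
            raise AssertionError(
                f"{gene_id}: focal {etype} node missing after graph build"
            )
        genes.append(sim)
    return genes


_BASES = np.array(list("ACGT"))


def simulate_genome(
    genes: Sequence[GeneSim], seed: int, flank: int = 200
) -> dict[str, str]:
    """Random genome with canonical GT/AG dinucleotides planted at every
    annotated intron boundary (strand-aware)."""
    rng = np.random.default_rng(seed)
    length: dict[str, int] = {}
    for g in genes:
        for t in g.transcripts:
            length[t.chrom] = max(length.get(t.chrom, 0), t.span[1] + flank)
    genome: dict[str, np.ndarray] = {
        chrom: rng.choice(_BASES, size=n) for chrom, n in length.items()
    }
    for g in genes:
        for t in g.transcripts:
            for s, e in t.introns():
                seq = genome[t.chrom]
                if t.strand == "+":
                    seq[s], seq[s + 1] = "G", "T"
                    seq[e - 2], seq[e - 1] = "A", "G"
                else:
                    seq[s], seq[s + 1] = "C", "T"
                    seq[e - 2], seq[e - 1] = "A", "C"
    return {chrom: "".join(arr) for chrom, arr in genome.items()}


def simulate_path_abundances(
    rng: np.random.Generator, n_paths: int, concentration: float
) -> np.ndarray:
    """Symmetric Dirichlet path abundances; low concentration gives
    near-one-hot (low entropy) draws, high concentration near-uniform."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if n_paths == 1:
        return np.array([1.0])
    return rng.dirichlet(np.full(n_paths, concentration))


def simulate_edge_counts(
    event: EventPaths,
    psi: Sequence[float],
    depth: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> EdgeCounts:
    """Multinomial edge reads with intensity = summed abundance of the paths
    through each edge; total reads = ``depth`` (0 gives all-zero counts)."""
    psi = np.asarray(psi, dtype=float)
    if abs(psi.sum() - 1.0) > 1e-8:
        raise ValueError("abundances must be normalized")
    edges = event.event_edges()
    intensity = np.zeros(len(edges))
    eix = {e: j for j, e in enumerate(edges)}
    for i in range(event.n_paths):
        for e in event.path_edges(i):
            intensity[eix[e]] += psi[i]
    counts = {e: 0 for e in edges}
    if depth > 0 and intensity.sum() > 0:
        draw = rng.multinomial(depth, intensity / intensity.sum())
        counts = {e: int(k) for e, k in zip(edges, draw)}
    return EdgeCounts(sample_id=sample_id, gene_id=event.gene_id, counts=counts)


def simulate_evolutionary_history(
    tree: PhyloTree,
    gain_prob: float,
    loss_prob: float,
    rng: np.random.Generator,
    constrain_single_change: bool = False,
    root_state: str | None = None,
    max_tries: int = 10_000,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Binary gain/loss history along the tree.

    Returns (leaf states, flips) where flips lists every (branch clade
    name, direction) at which the A/C state changed. With
    ``constrain_single_change`` histories are rejection-sampled until at
    most one flip occurred.
    """
    for _ in range(max_tries):
        root = root_state or ("A" if rng.random() < 0.5 else "C")
        states: dict[str, str] = {}
        flips: list[tuple[str, str]] = []

        def walk(node, state: str) -> None:
            for child in node.child_nodes():
                s = state
                if state == "C" and rng.random() < gain_prob:
                    s = "A"
                elif state == "A" and rng.random() < loss_prob:
                    s = "C"
                if s != state:
                    clade = frozenset(
                        lf.taxon.label for lf in child.leaf_nodes()
                    )
                    flips.append(
                        (tree.clade_name(clade), "gain" if s == "A" else "loss")
                    )
                if child.is_leaf():
                    states[child.taxon.label] = s
                else:
                    walk(child, s)

        walk(tree.tree.seed_node, root)
        if not constrain_single_change or len(flips) <= 1:
            return states, flips
    raise RuntimeError("could not sample a single-change history")


# --- canonical toy events used by the stage/species panels -----------------

def cassette_event(gene_id: str = "toy") -> EventPaths:
    """Two-path cassette: inclusion (1-2-3, two junction edges) vs skip (1-3)."""
    return EventPaths(
        gene_id=gene_id,
        node_index=2,
        anchor_up=1,
        anchor_down=3,
        paths=[(1, 2, 3), (1, 3)],
        contains_node=[True, False],
    )


def three_path_event(gene_id: str = "toy3") -> EventPaths:
    """Three-path event on focal node 3: two inclusion routes (via node 2 or
    direct) plus a full skip; K2, max entropy log2(3)."""
    return EventPaths(
        gene_id=gene_id,
        node_index=3,
        anchor_up=1,
        anchor_down=5,
        paths=[(1, 2, 3, 5), (1, 3, 5), (1, 5)],
        contains_node=[True, True, False],
    )


def _logistic(t: float, t0: float, scale: float) -> float:
    return 1.0 / (1.0 + math.exp(-(t - t0) / scale))


def simulate_stage_series(
    rng: np.random.Generator,
    kind: str,
    n_stages: int = 10,
    depth: int = 200,
    amplitude: float = 0.3,
    tpm: float = 50.0,
    event_id: str = "ev",
) -> tuple[StageSeries, dict]:
    """Developmental stage series with recorded truth.

    kinds: ``null`` (constant abundances), ``dev`` (logistic node-Ψ sweep of
    the given amplitude), ``dynamic`` (entropy sweep > 0.5 bits at constant
    node Ψ). Reads are multinomial edge counts on the three-path toy event;
    per-stage entropy is re-estimated through the EM quantifier, and
    inclusion/exclusion counts summarize node-containing vs skipping paths.
    """
    if n_stages < 6:
        raise ValueError("stage series needs >= 6 stages")
    event = three_path_event(event_id)
    incl_edges = {(1, 2), (2, 3), (1, 3)}
    excl_edges = {(1, 5)}

    truth_psis: list[np.ndarray] = []
    for t in range(n_stages):
        if kind == "null":
            vec = np.array([0.30, 0.30, 0.40])
        elif kind == "dev":
            lo = 0.5 - amplitude / 2
            node = lo + amplitude * _logistic(t, 2.0, 0.7)
            vec = np.array([node / 2, node / 2, 1.0 - node])
        elif kind == "dynamic":
            # node Psi constant at 0.9; inclusion mass migrates between the
            # two inclusion routes, sweeping entropy by ~0.8 bits
            f = _logistic(t, 4.0, 1.0)
            p1 = 0.88 - 0.43 * f
            vec = np.array([p1, 0.9 - p1, 0.10])
        else:
            raise ValueError(f"unknown stage-series kind {kind!r}")
        truth_psis.append(vec)

    stages: list[StageQuant] = []
    for t, vec in enumerate(truth_psis):
        counts = simulate_edge_counts(event, vec, depth, rng, sample_id=f"s{t}")
        pa = estimate_path_abundances(event, counts)
        incl = sum(counts.get(e) for e in incl_edges)
        excl = sum(counts.get(e) for e in excl_edges)
        stages.append(
            StageQuant(
                stage=f"stage{t}",
                ordinal=t,
                incl=incl,
                excl=excl,
                entropy=splicing_entropy(pa.psi_paths),
                psi=node_psi(pa, event),
                reads=counts.total_event_reads(event),
                tpm=tpm,
            )
        )

    true_entropies = [splicing_entropy(v) for v in truth_psis]
    true_node_psi = [float(v[0] + v[1]) for v in truth_psis]
    truth = {
        "kind": kind,
        "dev": kind == "dev" and amplitude > 0,
        "entropy_dynamic": (max(true_entropies) - min(true_entropies)) >= 0.5,
        "true_entropies": true_entropies,
        "true_node_psi": true_node_psi,
    }
    return StageSeries(event_id=event_id, stages=stages), truth


def transcript_edge_intensity(
    graph, theta: Mapping[str, float]
) -> dict[tuple[int, int], float]:
    """Edge intensity = summed relative abundance of the transcripts whose
    paths traverse the edge."""
    intensity: dict[tuple[int, int], float] = {}
    for tid, path in graph.transcript_paths.items():
        w = float(theta.get(tid, 0.0))
        for a, b in zip(path, path[1:]):
            intensity[(a, b)] = intensity.get((a, b), 0.0) + w
    return intensity


def simulate_gene_edge_counts(
    graph,
    theta: Mapping[str, float],
    depth: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> EdgeCounts:
    """Multinomial edge reads over a whole gene from transcript abundances."""
    intensity = transcript_edge_intensity(graph, theta)
    edges = sorted(intensity)
    vals = np.array([intensity[e] for e in edges], dtype=float)
    counts = {e: 0 for e in edges}
    if depth > 0 and vals.sum() > 0:
        draw = rng.multinomial(depth, vals / vals.sum())
        counts = {e: int(k) for e, k in zip(edges, draw)}
    return EdgeCounts(sample_id=sample_id, gene_id=graph.gene_id, counts=counts)


def local_path_truth(
    event: EventPaths, graph, theta: Mapping[str, float]
) -> np.ndarray:
    """True relative path abundances of an event under transcript flux theta.

    Each transcript's restriction to the event window is one of the
    enumerated paths (path closure); the truth of a path is the normalized
    sum of the flux of transcripts restricting to it. Transcripts that do
    not reach the window contribute nothing.
    """
    window = {n for p in event.paths for n in p}
    lo, hi = min(window), max(window)
    weights = np.zeros(event.n_paths)
    index = {p: i for i, p in enumerate(event.paths)}
    for tid, path in graph.transcript_paths.items():
        restriction = tuple(n for n in path if lo <= n <= hi)
        i = index.get(restriction)
        if i is not None:
            weights[i] += float(theta.get(tid, 0.0))
    total = weights.sum()
    if total == 0:
        return np.full(event.n_paths, 1.0 / event.n_paths)
    return weights / total


def simulate_divergent_entropies(
    rng: np.random.Generator,
    base: Sequence[float],
    divergence_times: Sequence[float],
    scale: float = 0.005,
) -> np.ndarray:
    """Per-species entropy vectors drifting from a reference with divergence:
    species at time T gets N(0, scale*T) noise (clipped at 0). Rows follow
    ``divergence_times``."""
    base = np.asarray(base, dtype=float)
    out = np.empty((len(divergence_times), base.size))
    for i, t in enumerate(divergence_times):
        noise = rng.normal(0.0, math.sqrt(max(scale * t, 1e-12)), size=base.size)
        out[i] = np.clip(base + noise, 0.0, None)
    return out
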