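"""Event quantification: path abundances, Ψ, entropy, and complexity bins.

Path abundances are estimated from edge read counts by expectation-
maximization: each edge's reads are assigned to the paths containing that
edge in proportion to the current abundances, per-path totals are averaged
over the path's edge count (so a longer path is not over-weighted by having
more edges), and the result renormalized. The node-level inclusion Ψ is the
summed abundance of paths containing the node; splicing entropy is the
Shannon entropy of the path distribution in bits, and the complexity bin
K(n) = ceil(log2(number of paths)) bounds the entropy from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .graph import EventPaths

__all__ = [
    "EdgeCounts",
    "PathAbundance",
    "EventQuant",
    "estimate_path_abundances",
    "node_psi",
    "splicing_entropy",
    "complexity_bin",
    "event_filter",
    "downsample_counts",
    "quantify_event",
]

Edge = tuple[int, int]


@dataclass
class EdgeCounts:
    """Read counts on one gene's CSG edges for one sample."""

    sample_id: str
    gene_id: str
    counts: dict[Edge, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count on edge {e}")

    def get(self, edge: Edge) -> int:
        return self.counts.get(edge, 0)

    def total_event_reads(self, event: EventPaths) -> int:
        """Sum of counts on the edges strictly inside the event anchors."""
        return sum(self.get(e) for e in event.event_edges())


@dataclass
class PathAbundance:
    gene_id: str
    node_index: int
    psi_paths: np.ndarray
    converged: bool
    iterations: int
    no_data: bool = False

    def __post_init__(self) -> None:
        self.psi_paths = np.asarray(self.psi_paths, dtype=float)
        if np.any(self.psi_paths < 0):
            raise ValueError("negative path abundance")
        if abs(float(self.psi_paths.sum()) - 1.0) > 1e-9:
            raise ValueError("path abundances must sum to 1")


@dataclass
class EventQuant:
    """One event in one sample: Ψ, entropy (bits), complexity, filters."""

    sample_id: str
    gene_id: str
    node_index: int
    node_type: str
    psi: float
    entropy: float
    k_bin: int
    n_paths: int
    total_event_reads: int
    gene_tpm: float


def estimate_path_abundances(
    event: EventPaths,
    counts: EdgeCounts,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PathAbundance:
    """EM estimate of relative path abundances from edge counts.

    Initialization is uniform; convergence is declared when the L1 change
    of the abundance vector drops below ``tol``. With all-zero counts the
    uniform distribution is returned with ``no_data=True``.
    """
    if event.truncated:
        raise ValueError(
            f"{event.gene_id} node {event.node_index}: event truncated at "
            "enumeration; not quantifiable"
        )
    m = event.n_paths
    edges = event.event_edges()
    if m == 0:
        raise ValueError("event has no paths")

    edge_ix = {e: j for j, e in enumerate(edges)}
    member = np.zeros((m, max(len(edges), 1)), dtype=bool)
    n_edges = np.ones(m)
    for i in range(m):
        pe = event.path_edges(i)
        n_edges[i] = max(len(pe), 1)
        for e in pe:
            member[i, edge_ix[e]] = True
    c = np.array([counts.get(e) for e in edges], dtype=float)

    if len(edges) == 0 or c.sum() == 0:
        return PathAbundance(
            event.gene_id, event.node_index, np.full(m, 1.0 / m),
            converged=False, iterations=0, no_data=True,
        )

    psi = np.full(m, 1.0 / m)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        denom = member.T @ psi  # expected intensity per edge
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(denom > 0, c / denom, 0.0)
        assigned = (member * psi[:, None]) @ frac
        w = assigned / n_edges
        total = w.sum()
        if total <= 0:  # pragma: no cover - guarded by c.sum() > 0
            break
        new = w / total
        if np.abs(new - psi).sum() < tol:
            psi = new
            converged = True
            break
        psi = new
    psi = psi / psi.sum()
    return PathAbundance(
        event.gene_id, event.node_index, psi, converged=converged, iterations=it
    )


def node_psi(pa: PathAbundance, event: EventPaths) -> float:
    """Ψ of the node: summed abundance of the paths containing it."""
    contains = np.asarray(event.contains_node, dtype=bool)
    psi = float(pa.psi_paths[contains].sum())
    return min(max(psi, 0.0), 1.0)


def splicing_entropy(psi_paths) -> float:
    """Shannon entropy (bits) of a path abundance vector, 0·log2(0) = 0."""
    p = np.asarray(psi_paths, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) + 0.0 if p.size else 0.0


def complexity_bin(n_paths: int) -> int:
    """K(n) bin: smallest n with 2**n >= n_paths (a K(n) event has at most
    2**n outcomes); a single-path event is K0."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    return int(n_paths - 1).bit_length()


def event_filter(q: EventQuant, min_tpm: float = 1.0, min_reads: int = 10) -> bool:
    """Expression filter: host gene TPM >= 1 and >= 10 event-supporting reads."""
    return q.gene_tpm >= min_tpm and q.total_event_reads >= min_reads


def downsample_counts(
    counts: EdgeCounts, target_total: int, seed: int
) -> EdgeCounts:
    """Subsample reads to ``target_total`` without replacement (hypergeometric
    across edges); deterministic for a fixed seed."""
    edges = sorted(counts.counts)
    colors = np.array([counts.counts[e] for e in edges], dtype=np.int64)
    total = int(colors.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total {total}")
    if target_total == total:
        return EdgeCounts(counts.sample_id, counts.gene_id, dict(counts.counts))
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(colors, target_total)
    return EdgeCounts(
        counts.sample_id,
        counts.gene_id,
        {e: int(k) for e, k in zip(edges, drawn)},
    )


def quantify_event(
    event: EventPaths,
    counts: EdgeCounts,
    node_type: str,
    gene_tpm: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EventQuant:
    """Full per-event quantification: EM, node Ψ, entropy, K bin, filters."""
    pa = estimate_path_abundances(event, counts, tol=tol, max_iter=max_iter)
    ent = splicing_entropy(pa.psi_paths)
    kb = complexity_bin(event.n_paths)
    # numerical safety: entropy is bounded by log2(n_paths) <= k_bin
    ent = min(ent, math.log2(max(event.n_paths, 1)) if event.n_paths > 1 else 0.0)
    return EventQuant(
        sample_id=counts.sample_id,
        gene_id=event.gene_id,
        node_index=event.node_index,
        node_type=node_type,
        psi=node_psi(pa, event),
        entropy=ent,
        k_bin=kb,
        n_paths=event.n_paths,
        total_event_reads=counts.total_event_reads(event),
        gene_tpm=gene_tpm,
    )
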