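"""End-to-end analyses wiring the stages together.

These functions run complete synthetic studies: quantify every node of every
gene from simulated edge reads, classify events, assign splicing ages across
a species panel, and call developmental dynamics — returning both the
pipeline's outputs and the generator's recorded truth so recovery can be
checked. The CLI subcommands and the reproduction script are thin wrappers
around this module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import splicing_status
from .development import call_dev_events, dev_entropy_crosstab, entropy_dynamic_flag
from .evolution import (
    PhyloTree,
    age_group_summaries,
    assign_splicing_age,
    build_state_matrix,
)
from .graph import SpliceGraph, build_splice_graph, enumerate_event_paths
from .quantify import EdgeCounts, EventQuant, event_filter, quantify_event
from .simulate import (
    SimConfig,
    simulate_edge_counts,
    simulate_gene_models,
    simulate_stage_series,
    three_path_event,
)

__all__ = [
    "quantify_gene",
    "AgePanelResult",
    "run_species_age_analysis",
    "DevPanelResult",
    "run_dev_analysis",
    "simulate_study",
    "AGE_GROUP_ORDER",
]

# planted age groups, youngest to oldest, and the fraction of their events
# given the high-entropy regime
AGE_GROUP_ORDER = ("human_gain", "human-macaque_gain", "MCA", "VCA")
HIGH_ENTROPY_FRACTIONS = (0.10, 0.35, 0.65, 0.90)


def quantify_gene(
    graph: SpliceGraph,
    counts: EdgeCounts,
    gene_tpm: float,
    max_paths: int = 128,
) -> list[EventQuant]:
    """Quantify every node event of one gene in one sample.

    Truncated (path-explosion) events are skipped with no output row.
    """
    out = []
    for node in graph.nodes:
        event = enumerate_event_paths(graph, node.node_index, max_paths=max_paths)
        if event.truncated:
            continue
        out.append(quantify_event(event, counts, node.node_type, gene_tpm))
    return out


@dataclass
class AgePanelResult:
    summaries: pd.DataFrame  # per-group ratios from age_group_summaries
    assignments: dict[str, str]  # event -> inferred label
    truth_labels: dict[str, str]  # event -> planted label
    entropies: pd.DataFrame  # events x tissues (reference species)


def _states_for_label(label: str, tree: PhyloTree) -> dict[str, str]:
    mammals = tree.ingroup
    if label == "VCA":
        return {sp: "A" for sp in tree.leaves}
    if label == "MCA":
        return {sp: "A" if sp in mammals else "C" for sp in tree.leaves}
    if label.endswith("_gain"):
        name = label[: -len("_gain")]
        clade = next(c for c in tree.clades if tree.clade_name(c) == name)
        return {sp: "A" if sp in clade else "C" for sp in tree.leaves}
    raise KeyError(f"no planted state pattern for {label!r}")


def _alternative_abundance(rng: np.random.Generator, high: bool) -> np.ndarray:
    """Three-path abundances for an alternative tissue observation.

    High-entropy regime: near-uniform (entropy ~ log2(3)); low-entropy
    regime: one dominant inclusion route with a small skip fraction
    (entropy well below 1 bit).
    """
    if high:
        return rng.dirichlet((20.0, 20.0, 20.0))
    u = rng.uniform(0.80, 0.94)
    eps = 0.02
    return np.array([u * (1 - eps), u * eps, 1.0 - u])


def run_species_age_analysis(
    seed: int,
    n_events: int = 200,
    depth: int = 300,
    n_tissues: int = 6,
    gene_tpm: float = 50.0,
    reference_species: str = "human",
) -> AgePanelResult:
    """Simulate and analyze a seven-species orthologous-event panel.

    Events are planted into four splicing-age groups (young to old) with an
    increasing share of high-entropy splicing in the reference species;
    per-species, per-tissue edge reads are sampled, events re-quantified by
    EM, species states called from estimated Ψ, ages assigned by parsimony,
    and the per-group high-complexity ratios summarized.
    """
    rng = np.random.default_rng(seed)
    tree = PhyloTree.default()
    tissues = [f"tissue{j}" for j in range(n_tissues)]

    truth_labels: dict[str, str] = {}
    statuses: dict[str, dict[str, list[str]]] = {}
    ref_entropy: dict[str, dict[str, float]] = {}

    group_ix = rng.integers(0, len(AGE_GROUP_ORDER), size=n_events)
    for i in range(n_events):
        ev = f"ev{i:04d}"
        label = AGE_GROUP_ORDER[group_ix[i]]
        truth_labels[ev] = label
        high = rng.random() < HIGH_ENTROPY_FRACTIONS[group_ix[i]]
        states = _states_for_label(label, tree)
        event = three_path_event(ev)
        statuses[ev] = {}
        ref_entropy[ev] = {}
        for sp in tree.leaves:
            per_tissue = []
            for tis in tissues:
                if states[sp] == "A":
                    vec = _alternative_abundance(rng, high)
                else:
                    # constitutive: node always included, no skip flux
                    w = rng.uniform(0.75, 0.95)
                    vec = np.array([w, 1.0 - w, 0.0])
                counts = simulate_edge_counts(
                    event, vec, depth, rng, sample_id=f"{sp}_{tis}"
                )
                q = quantify_event(event, counts, "CE", gene_tpm)
                status = splicing_status(q.psi, event_filter(q))
                per_tissue.append(status)
                if sp == reference_species:
                    ref_entropy[ev][tis] = (
                        q.entropy if status != "excluded" else math.nan
                    )
            statuses[ev][sp] = per_tissue

    matrix = build_state_matrix(statuses)
    assignments = {
        ev: assign_splicing_age(matrix.loc[ev].to_dict(), tree, event_id=ev).label
        for ev in matrix.index
    }
    entropies = pd.DataFrame.from_dict(ref_entropy, orient="index")
    summaries = age_group_summaries(assignments, entropies)
    return AgePanelResult(summaries, assignments, truth_labels, entropies)


@dataclass
class DevPanelResult:
    crosstab: pd.DataFrame
    nondev_dynamic_ratio: float
    planted_fraction: float
    calls: list[tuple[str, str | None, bool]]  # (event, dev status, dynamic)
    truth: dict[str, dict]


def run_dev_analysis(
    seed: int,
    n_events: int = 300,
    dev_fraction: float = 0.5,
    dynamic_fraction: float = 0.12,
    n_stages: int = 10,
    depth: int = 200,
    amplitude: float = 0.3,
) -> DevPanelResult:
    """Simulate and call a developmental stage-series panel.

    A ``dev_fraction`` of events get an inclusion sweep (true Dev events);
    among the remaining null-inclusion events a ``dynamic_fraction`` get an
    entropy sweep at constant node Ψ. Events are called Dev/non-Dev from
    posterior ΔΨ against the first stage and flagged entropy-dynamic; the
    crosstab's non-Dev dynamic ratio estimates the planted fraction.
    """
    rng = np.random.default_rng(seed)
    calls: list[tuple[str, str | None, bool]] = []
    truth: dict[str, dict] = {}
    # stratified planting: the composition is exact, only assignment random
    n_dev = int(round(n_events * dev_fraction))
    n_rest = n_events - n_dev
    n_dyn = int(round(n_rest * dynamic_fraction))
    kinds = ["dev"] * n_dev + ["dynamic"] * n_dyn + ["null"] * (n_rest - n_dyn)
    kinds = [kinds[j] for j in rng.permutation(n_events)]
    planted = n_dyn / n_rest if n_rest else float("nan")
    for i in range(n_events):
        ev = f"dev{i:04d}"
        kind = kinds[i]
        series, t = simulate_stage_series(
            rng, kind, n_stages=n_stages, depth=depth,
            amplitude=amplitude, event_id=ev,
        )
        status, _ = call_dev_events(
            series, seed=int(rng.integers(0, 2**31 - 1))
        )
        dynamic = entropy_dynamic_flag(series)
        calls.append((ev, status, dynamic))
        truth[ev] = t
    table, ratio = dev_entropy_crosstab((s, d) for _, s, d in calls)
    return DevPanelResult(table, ratio, planted, calls, truth)


def simulate_study(config: SimConfig, outdir: str) -> dict:
    """Emit a full synthetic study to ``outdir`` and return a manifest dict.

    Files: annotation GTF, genome FASTA, species tree (newick), per-tissue
    edge-count TSV, gene TPM TSV, gene annotation TSV, ortholog-map TSV and
    a ground-truth JSON.
    """
    import os

    from . import io as spio
    from .evolution import DEFAULT_TREE_NEWICK
    from .simulate import simulate_genome, simulate_path_abundances

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = simulate_gene_models(config)
    genome = simulate_genome(genes, seed=config.seed + 1)

    gtf_path = os.path.join(outdir, "annotation.gtf")
    spio.write_gtf({g.gene_id: g.transcripts for g in genes}, gtf_path)
    spio.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(DEFAULT_TREE_NEWICK + "\n")

    from .quantify import splicing_entropy
    from .simulate import local_path_truth, simulate_gene_edge_counts

    graphs = {g.gene_id: build_splice_graph(g.transcripts) for g in genes}
    truth: dict[str, dict] = {}
    all_counts: list[EdgeCounts] = []
    tpms: dict[tuple[str, str], float] = {}
    for g in genes:
        graph = graphs[g.gene_id]
        focal = next(
            n.node_index for n in graph.nodes
            if (n.start, n.end) == g.focal_interval
        )
        event = enumerate_event_paths(graph, focal)
        truth[g.gene_id] = {
            "event_type": g.event_type,
            "focal_node": focal,
            "n_paths": event.n_paths,
            "psi": {},
            "entropy": {},
        }
        tids = sorted(graph.transcript_paths)
        for tis in config.tissues:
            # two-regime isoform flux: concentrated (one dominant isoform,
            # low entropy) vs flat (high entropy)
            high = rng.random() < config.high_entropy_fraction
            conc = (
                config.concentration_high if high else config.concentration_low
            )
            theta = dict(
                zip(tids, simulate_path_abundances(rng, len(tids), conc))
            )
            # total gene reads scale with the number of junctions covered
            gene_depth = config.depth * max(len(graph.edges), 1) // 3
            counts = simulate_gene_edge_counts(
                graph, theta, gene_depth, rng, sample_id=tis
            )
            all_counts.append(counts)
            tpms[(tis, g.gene_id)] = config.gene_tpm
            vec = local_path_truth(event, graph, theta)
            contains = np.asarray(event.contains_node, dtype=bool)
            truth[g.gene_id]["psi"][tis] = float(vec[contains].sum())
            truth[g.gene_id]["entropy"][tis] = splicing_entropy(vec)

    spio.write_node_table(graphs.values(), os.path.join(outdir, "nodes.tsv"))
    spio.write_edge_counts(all_counts, os.path.join(outdir, "edge_counts.tsv"))
    spio.write_gene_tpm(tpms, os.path.join(outdir, "gene_tpm.tsv"))

    # gene-level annotations (housekeeping flag, age, dN/dS, PPI degree,
    # per-tissue expression) for the gene-context analyses
    rows = []
    for g in genes:
        expr = rng.gamma(2.0, 25.0, size=len(config.tissues))
        rows.append(
            {
                "gene_id": g.gene_id,
                "housekeeping": bool(rng.random() < 0.25),
                "age_class": "old" if rng.random() < 0.8 else "young",
                "dnds": float(rng.lognormal(-2.5, 1.0)),
                "ppi_degree": int(rng.integers(1, 2000)),
                **{
                    f"tpm_{t}": float(v)
                    for t, v in zip(config.tissues, expr)
                },
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "gene_annotations.tsv"), sep="\t", index=False
    )

    # trivial self-map ortholog table (same annotation shared by species)
    from .evolution import SPECIES

    ortho = [
        {
            "event_id": f"{g.gene_id}:{truth[g.gene_id]['focal_node']}",
            "species": sp,
            "gene_id": g.gene_id,
            "node_index": truth[g.gene_id]["focal_node"],
        }
        for g in genes
        for sp in SPECIES
    ]
    pd.DataFrame(ortho).to_csv(
        os.path.join(outdir, "ortholog_map.tsv"), sep="\t", index=False
    )

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "tissues": list(config.tissues),
        "files": sorted(os.listdir(outdir)),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
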