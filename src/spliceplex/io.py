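"""Readers and writers for the pipeline's file formats.

GTF is 1-based inclusive on disk and converted to 0-based half-open
intervals in memory (and back on write). Edge counts, node tables, event
tables, gene annotations and ortholog maps are plain TSV; trees are newick;
genomes are FASTA.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph import SpliceGraph, TranscriptModel
from .quantify import EdgeCounts, EventQuant

__all__ = [
    "read_gtf",
    "write_gtf",
    "write_fasta",
    "read_fasta",
    "node_table",
    "write_node_table",
    "event_table",
    "write_event_table",
    "write_edge_counts",
    "read_edge_counts",
    "write_gene_tpm",
    "read_gene_tpm",
]


def read_gtf(path: str) -> dict[str, list[TranscriptModel]]:
    """Parse a GTF into per-gene transcript models (exon features only).

    Uses an in-memory gffutils database; requires gene_id and transcript_id
    attributes on exon lines. Raises ValueError naming the offending line on
    malformed input.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed GTF {path!r}: {exc}") from exc

    tx: dict[tuple[str, str], dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"{path}: exon at {feat.seqid}:{feat.start} missing {exc}"
            ) from exc
        key = (gene_id, transcript_id)
        rec = tx.setdefault(
            key, {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF 1-based inclusive -> 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))

    genes: dict[str, list[TranscriptModel]] = {}
    for (gene_id, transcript_id), rec in tx.items():
        exons = tuple(sorted(rec["exons"]))
        genes.setdefault(gene_id, []).append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
            )
        )
    for models in genes.values():
        models.sort(key=lambda t: t.transcript_id)
    return genes


def write_gtf(genes: Mapping[str, Sequence[TranscriptModel]], path: str) -> None:
    """Write transcript models as exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene_id in sorted(genes):
            for t in sorted(genes[gene_id], key=lambda t: t.transcript_id):
                for i, (s, e) in enumerate(t.exons, start=1):
                    attrs = (
                        f'gene_id "{t.gene_id}"; '
                        f'transcript_id "{t.transcript_id}"; '
                        f'exon_number "{i}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                "spliceplex",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True, build_index=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    # avoid leaving .fai files behind only if caller wants; keep (standard)
    return out


def node_table(graphs: Iterable[SpliceGraph]) -> pd.DataFrame:
    rows = []
    for g in graphs:
        for n in g.nodes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "node_index": n.node_index,
                    "chrom": g.chrom,
                    "start": n.start + 1,  # 1-based on disk
                    "end": n.end,
                    "strand": g.strand,
                    "node_type": n.node_type,
                }
            )
    return pd.DataFrame(rows)


def write_node_table(graphs: Iterable[SpliceGraph], path: str) -> None:
    node_table(graphs).to_csv(path, sep="\t", index=False)


def event_table(quants: Iterable[EventQuant], graphs: Mapping[str, SpliceGraph]) -> pd.DataFrame:
    rows = []
    for q in quants:
        g = graphs[q.gene_id]
        n = g.node(q.node_index)
        rows.append(
            {
                "Sample": q.sample_id,
                "Gene": q.gene_id,
                "Node": q.node_index,
                "Coord": f"{g.chrom}:{n.start + 1}-{n.end}",
                "Strand": g.strand,
                "Type": q.node_type,
                "Psi": round(q.psi, 6),
                "Total_Reads": q.total_event_reads,
                "Complexity": f"K{q.k_bin}",
                "Entropy": round(q.entropy, 6),
                "Gene_TPM": q.gene_tpm,
            }
        )
    return pd.DataFrame(rows)


def write_event_table(
    quants: Iterable[EventQuant], graphs: Mapping[str, SpliceGraph], path: str
) -> None:
    event_table(quants, graphs).to_csv(path, sep="\t", index=False)


def write_edge_counts(counts: Iterable[EdgeCounts], path: str) -> None:
    rows = []
    for ec in counts:
        for (u, v), c in sorted(ec.counts.items()):
            rows.append(
                {
                    "sample_id": ec.sample_id,
                    "gene_id": ec.gene_id,
                    "from_node": u,
                    "to_node": v,
                    "count": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_counts(path: str) -> dict[tuple[str, str], EdgeCounts]:
    """(sample_id, gene_id) -> EdgeCounts from the long TSV format."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "from_node", "to_node", "count"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: edge-count TSV missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[tuple[str, str], EdgeCounts] = {}
    for (sample, gene), sub in df.groupby(["sample_id", "gene_id"], sort=True):
        out[(str(sample), str(gene))] = EdgeCounts(
            sample_id=str(sample),
            gene_id=str(gene),
            counts={
                (int(r.from_node), int(r.to_node)): int(r.count)
                for r in sub.itertuples()
            },
        )
    return out


def write_gene_tpm(tpm: Mapping[tuple[str, str], float], path: str) -> None:
    rows = [
        {"sample_id": s, "gene_id": g, "tpm": v}
        for (s, g), v in sorted(tpm.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_tpm(path: str) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.sample_id), str(r.gene_id)): float(r.tpm)
        for r in df.itertuples()
    }
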