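"""Exon-context features and entropy regression.

A compact, documented feature set describes each core-exon event by its own
length and GC content, the lengths and GC of the transcriptionally up- and
downstream exons, the lengths, GC and pyrimidine content of the flanking
introns, the exon's rank in its host transcript, and position-weight-matrix
log-odds scores of the four splice sites bordering the event (donor: last 3
exonic + first 6 intronic bases; acceptor: last 20 intronic + first 3 exonic
bases). The PWMs are trained on the input annotation's own splice sites, so
feature extraction is self-contained. Cross-validated regressors (linear,
gradient-boosted trees, random forest, SVR) predict an event's mean splicing
entropy from these features; performance is summarized by Pearson and
Spearman correlation and R² on pooled held-out predictions, with permutation
feature importances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .graph import JUNCTION, SpliceGraph

__all__ = [
    "PositionWeightMatrix",
    "DONOR_EXONIC", "DONOR_INTRONIC", "ACCEPTOR_INTRONIC", "ACCEPTOR_EXONIC",
    "train_splice_site_pwms",
    "splice_site_strength",
    "extract_exon_features",
    "FEATURE_NAMES",
    "RegressionReport",
    "train_entropy_regressor",
    "SplicingEntropyModel",
    "SplicingEntropyResults",
]

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class PositionWeightMatrix:
    """Log-odds PWM against a uniform background; 'N' scores 0 anywhere."""

    def __init__(self, log_odds: np.ndarray):
        self.log_odds = np.asarray(log_odds, dtype=float)  # (width, 4)

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_sequences(
        cls, seqs: Sequence[str], pseudocount: float = 1.0
    ) -> "PositionWeightMatrix":
        if not seqs:
            raise ValueError("no training sequences")
        width = len(seqs[0])
        if any(len(s) != width for s in seqs):
            raise ValueError("training sequences differ in length")
        counts = np.full((width, 4), pseudocount)
        for s in seqs:
            for i, ch in enumerate(s.upper()):
                j = _BASES.find(ch)
                if j >= 0:
                    counts[i, j] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.log2(freqs / 0.25))

    def score(self, window: str) -> float:
        """Sum of per-position log-odds; non-ACGT bases contribute 0."""
        if len(window) != self.width:
            raise ValueError(
                f"window length {len(window)} != PWM width {self.width}"
            )
        total = 0.0
        for i, ch in enumerate(window.upper()):
            j = _BASES.find(ch)
            if j >= 0:
                total += self.log_odds[i, j]
        return float(total)

    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.log_odds.argmax(axis=1))


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str | None:
    """0-based half-open slice; None when off either end of the sequence."""
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        return None
    return str(seq[start:end]).upper()


def _donor_window(
    genome: Mapping[str, str], chrom: str, strand: str, exon_end_5p: int
) -> str | None:
    """Donor site window at an exon/intron boundary, transcript strand.

    ``exon_end_5p`` is the genomic coordinate where the exon meets the
    intron on the donor side (exon end on '+', exon start on '-').
    """
    if strand == "+":
        s = exon_end_5p - DONOR_EXONIC
        w = _fetch(genome, chrom, s, exon_end_5p + DONOR_INTRONIC)
        return w
    s = exon_end_5p - DONOR_INTRONIC
    w = _fetch(genome, chrom, s, exon_end_5p + DONOR_EXONIC)
    return _revcomp(w) if w is not None else None


def _acceptor_window(
    genome: Mapping[str, str], chrom: str, strand: str, exon_start_3p: int
) -> str | None:
    """Acceptor site window where the intron meets the exon."""
    if strand == "+":
        s = exon_start_3p - ACCEPTOR_INTRONIC
        return _fetch(genome, chrom, s, exon_start_3p + ACCEPTOR_EXONIC)
    s = exon_start_3p - ACCEPTOR_EXONIC
    w = _fetch(genome, chrom, s, exon_start_3p + ACCEPTOR_INTRONIC)
    return _revcomp(w) if w is not None else None


def _node_boundaries(graph: SpliceGraph, node_index: int) -> tuple[int, int]:
    """(5' boundary, 3' boundary) genomic coordinates in transcript sense."""
    node = graph.node(node_index)
    if graph.strand == "+":
        return node.start, node.end
    return node.end, node.start


def train_splice_site_pwms(
    graphs: Sequence[SpliceGraph],
    genome: Mapping[str, str],
    pseudocount: float = 1.0,
) -> tuple[PositionWeightMatrix, PositionWeightMatrix]:
    """(donor PWM, acceptor PWM) trained on the annotation's junction sites."""
    donors: list[str] = []
    acceptors: list[str] = []
    for g in graphs:
        for (u, v), kind in g.edges.items():
            if kind != JUNCTION:
                continue
            nu, nv = g.node(u), g.node(v)
            if g.strand == "+":
                dw = _donor_window(genome, g.chrom, "+", nu.end)
                aw = _acceptor_window(genome, g.chrom, "+", nv.start)
            else:
                dw = _donor_window(genome, g.chrom, "-", nu.start)
                aw = _acceptor_window(genome, g.chrom, "-", nv.end)
            if dw is not None:
                donors.append(dw)
            if aw is not None:
                acceptors.append(aw)
    if not donors or not acceptors:
        raise ValueError("annotation provides no complete splice-site windows")
    return (
        PositionWeightMatrix.from_sequences(donors, pseudocount),
        PositionWeightMatrix.from_sequences(acceptors, pseudocount),
    )


def splice_site_strength(
    window: str | None, kind: str, pwm: PositionWeightMatrix
) -> float:
    """Log-odds strength of one splice-site window (nan if off-sequence)."""
    if kind not in ("donor", "acceptor"):
        raise ValueError("kind must be 'donor' or 'acceptor'")
    if window is None:
        return math.nan
    return pwm.score(window)


def _gc(seq: str) -> float:
    if not seq:
        return math.nan
    n = sum(1 for c in seq if c in "GCgc")
    return n / len(seq)


def _pyrimidine(seq: str) -> float:
    if not seq:
        return math.nan
    n = sum(1 for c in seq if c in "CTct")
    return n / len(seq)


FEATURE_NAMES = (
    "exon_length", "exon_gc",
    "up_exon_length", "up_exon_gc",
    "down_exon_length", "down_exon_gc",
    "up_intron_length", "up_intron_gc", "up_intron_pyrimidine",
    "down_intron_length", "down_intron_gc", "down_intron_pyrimidine",
    "exon_rank",
    "acceptor_strength", "donor_strength",
    "up_exon_donor_strength", "down_exon_acceptor_strength",
)


def extract_exon_features(
    graph: SpliceGraph,
    genome: Mapping[str, str],
    node_index: int,
    donor_pwm: PositionWeightMatrix,
    acceptor_pwm: PositionWeightMatrix,
) -> dict[str, float]:
    """Deterministic, strand-aware feature vector for one internal CE node.

    The host transcript is the one (alphabetically first among the longest
    paths) whose path places the node internally with a spliced boundary on
    both sides; terminal nodes are rejected.
    """
    host = None
    for tid in sorted(
        graph.transcript_paths,
        key=lambda t: (-len(graph.transcript_paths[t]), t),
    ):
        path = graph.transcript_paths[tid]
        if node_index in path:
            i = path.index(node_index)
            if 0 < i < len(path) - 1:
                host = (tid, path, i)
                break
    if host is None:
        raise ValueError(
            f"{graph.gene_id} node {node_index}: terminal in every transcript; "
            "no flanking exons"
        )
    _, path, i = host

    # group the host path into exons (runs of adjacency edges)
    exons: list[list[int]] = [[path[0]]]
    for a, b in zip(path, path[1:]):
        if graph.edges.get((a, b)) == JUNCTION:
            exons.append([b])
        else:
            exons[-1].append(b)
    rank = next(j for j, ex in enumerate(exons) if node_index in ex)
    if rank == 0 or rank == len(exons) - 1:
        raise ValueError(
            f"{graph.gene_id} node {node_index}: lies in a terminal exon of "
            "its host transcript"
        )

    def exon_interval(ex: list[int]) -> tuple[int, int]:
        coords = [c for n in ex for c in graph.node(n).interval]
        return min(coords), max(coords)

    strand = graph.strand
    chrom = graph.chrom
    tgt = exon_interval(exons[rank])
    up = exon_interval(exons[rank - 1])
    down = exon_interval(exons[rank + 1])

    def intron_between(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
        lo, hi = (a, b) if a[1] <= b[0] else (b, a)
        return lo[1], hi[0]

    up_intron = intron_between(up, tgt)
    down_intron = intron_between(tgt, down)

    seq_tgt = _fetch(genome, chrom, *tgt) or ""
    seq_up = _fetch(genome, chrom, *up) or ""
    seq_down = _fetch(genome, chrom, *down) or ""
    seq_ui = _fetch(genome, chrom, *up_intron) or ""
    seq_di = _fetch(genome, chrom, *down_intron) or ""
    if strand == "-":
        # up/down assignments already follow transcription order; only the
        # sequences need reverse-complementing
        seq_tgt, seq_up, seq_down = map(_revcomp, (seq_tgt, seq_up, seq_down))
        seq_ui, seq_di = _revcomp(seq_ui), _revcomp(seq_di)

    # splice-site boundary coordinates in transcript sense
    if strand == "+":
        tgt_acc, tgt_don = tgt[0], tgt[1]
        up_don = up[1]
        down_acc = down[0]
    else:
        tgt_acc, tgt_don = tgt[1], tgt[0]
        up_don = up[0]
        down_acc = down[1]

    feats = {
        "exon_length": float(tgt[1] - tgt[0]),
        "exon_gc": _gc(seq_tgt),
        "up_exon_length": float(up[1] - up[0]),
        "up_exon_gc": _gc(seq_up),
        "down_exon_length": float(down[1] - down[0]),
        "down_exon_gc": _gc(seq_down),
        "up_intron_length": float(up_intron[1] - up_intron[0]),
        "up_intron_gc": _gc(seq_ui),
        "up_intron_pyrimidine": _pyrimidine(seq_ui),
        "down_intron_length": float(down_intron[1] - down_intron[0]),
        "down_intron_gc": _gc(seq_di),
        "down_intron_pyrimidine": _pyrimidine(seq_di),
        "exon_rank": float(rank + 1),
        "acceptor_strength": splice_site_strength(
            _acceptor_window(genome, chrom, strand, tgt_acc), "acceptor",
            acceptor_pwm,
        ),
        "donor_strength": splice_site_strength(
            _donor_window(genome, chrom, strand, tgt_don), "donor", donor_pwm
        ),
        "up_exon_donor_strength": splice_site_strength(
            _donor_window(genome, chrom, strand, up_don), "donor", donor_pwm
        ),
        "down_exon_acceptor_strength": splice_site_strength(
            _acceptor_window(genome, chrom, strand, down_acc), "acceptor",
            acceptor_pwm,
        ),
    }
    return feats


@dataclass
class RegressionReport:
    model: str
    pcc: float
    scc: float
    r2: float
    fold_pcc: list[float] = field(default_factory=list)
    importance: pd.Series | None = None
    n_events: int = 0


_FAMILIES = {
    "linear": lambda seed: make_pipeline(StandardScaler(), LinearRegression()),
    "gbt": lambda seed: HistGradientBoostingRegressor(random_state=seed),
    "random_forest": lambda seed: RandomForestRegressor(
        n_estimators=200, random_state=seed
    ),
    "svm": lambda seed: make_pipeline(StandardScaler(), SVR()),
}


def train_entropy_regressor(
    features: pd.DataFrame,
    target: Sequence[float],
    family: str = "gbt",
    folds: int = 5,
    seed: int = 0,
    min_events: int = 50,
) -> RegressionReport:
    """Cross-validated regression of mean splicing entropy on exon features.

    Missing feature values are median-imputed. Metrics are computed on the
    pooled held-out predictions of a seeded K-fold split; importances are
    permutation importances of a full-data refit. A constant target leaves
    the correlation metrics undefined.
    """
    if family not in _FAMILIES:
        raise KeyError(f"unknown model family {family!r}; choose from "
                       f"{sorted(_FAMILIES)}")
    X = features.apply(pd.to_numeric).astype(float)
    X = X.fillna(X.median())
    y = np.asarray(list(target), dtype=float)
    if len(X) != len(y):
        raise ValueError("features and target lengths differ")
    if len(y) < min_events:
        raise ValueError(f"need >= {min_events} events, got {len(y)}")
    if np.ptp(y) == 0:
        return RegressionReport(family, math.nan, math.nan, math.nan,
                                n_events=len(y))

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    fold_pcc = []
    for train_ix, test_ix in kf.split(X):
        est = _FAMILIES[family](seed)
        est.fit(X.iloc[train_ix], y[train_ix])
        p = est.predict(X.iloc[test_ix])
        pred[test_ix] = p
        if np.ptp(p) > 0 and np.ptp(y[test_ix]) > 0:
            fold_pcc.append(float(stats.pearsonr(y[test_ix], p).statistic))
        else:
            fold_pcc.append(math.nan)

    pcc = float(stats.pearsonr(y, pred).statistic)
    scc = float(stats.spearmanr(y, pred).statistic)
    r2 = float(r2_score(y, pred))

    full = _FAMILIES[family](seed)
    full.fit(X, y)
    imp = permutation_importance(
        full, X, y, n_repeats=5, random_state=seed, scoring="r2"
    )
    importance = pd.Series(
        imp.importances_mean, index=list(X.columns)
    ).sort_values(ascending=False)
    return RegressionReport(family, pcc, scc, r2, fold_pcc, importance, len(y))


class SplicingEntropyModel:
    """Entropy-from-features regression model (fit -> results object)."""

    def __init__(self, features: pd.DataFrame, entropy: Sequence[float]):
        self.features = features
        self.entropy = np.asarray(list(entropy), dtype=float)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, target_column: str = "mean_entropy"
    ) -> "SplicingEntropyModel":
        feats = table.drop(columns=[target_column])
        return cls(feats, table[target_column].to_numpy())

    def fit(
        self, family: str = "gbt", folds: int = 5, seed: int = 0
    ) -> "SplicingEntropyResults":
        report = train_entropy_regressor(
            self.features, self.entropy, family=family, folds=folds, seed=seed
        )
        return SplicingEntropyResults(self, report)


class SplicingEntropyResults:
    def __init__(self, model: SplicingEntropyModel, report: RegressionReport):
        self.model = model
        self.report = report

    @property
    def pcc(self) -> float:
        return self.report.pcc

    @property
    def scc(self) -> float:
        return self.report.scc

    @property
    def r2(self) -> float:
        return self.report.r2

    def summary(self) -> str:
        r = self.report
        lines = [
            "Splicing entropy regression",
            f"  model family : {r.model}",
            f"  events       : {r.n_events}",
            f"  PCC (held-out): {r.pcc:.4f}",
            f"  SCC (held-out): {r.scc:.4f}",
            f"  R2  (held-out): {r.r2:.4f}",
            "  top features  :",
        ]
        if r.importance is not None:
            for name, val in r.importance.head(5).items():
                lines.append(f"    {name:<28s} {val:+.4f}")
        return "\n".join(lines)
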