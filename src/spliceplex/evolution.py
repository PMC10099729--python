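"""Splicing-age inference and cross-species entropy summaries.

Orthologous exonic events are scored per species as alternative (A: spliced
alternatively in at least one tissue), constitutive (C: constitutively
included in all quantifiable tissues) or missing (NA). On a rooted species
tree, an event's A/C pattern across species is explained, when possible, by
a single gain or loss of alternative splicing on one branch (Dollo-style
single-change parsimony). Patterns alternative or constitutive in every
species get the conserved labels VCA / VCC; patterns splitting exactly at
the outgroup get the mammal-conserved labels MCA / MCC (each of which admits
both a gain and a loss reading); all remaining patterns are either a unique
"<clade>_gain" / "<clade>_loss" or "complex" when no single change explains
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy
from scipy import stats

__all__ = [
    "PhyloTree",
    "AgeAssignment",
    "DEFAULT_TREE_NEWICK",
    "SPECIES",
    "species_splicing_state",
    "build_state_matrix",
    "assign_splicing_age",
    "pairwise_entropy_correlation",
    "max_entropy_species",
    "monotonic_entropy_trend",
    "age_group_summaries",
]

SPECIES = (
    "human", "chimpanzee", "gorilla", "macaque", "mouse", "opossum", "chicken",
)

# Seven-species ladder with the bird outgroup; divergence times (Myr) are
# round TimeTree-style values and only the topology matters for parsimony.
DEFAULT_TREE_NEWICK = (
    "((((((human:6.7,chimpanzee:6.7):2.3,gorilla:9.0):20.0,macaque:29.0)"
    ":61.0,mouse:90.0):69.0,opossum:159.0):153.0,chicken:312.0);"
)


class PhyloTree:
    """Rooted species tree wrapper exposing the clades needed for parsimony.

    A *clade* here is the leaf set below one branch (the branch above each
    non-root node); the branch is named by its boundary leaves in tree
    order, e.g. ``human`` for a terminal branch or ``human-opossum`` for the
    stem of the clade spanning human through opossum.
    """

    def __init__(self, newick: str, outgroup: str | None = None):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.leaves: tuple[str, ...] = tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf names in tree")
        if outgroup is None:
            # the root child with the fewest leaves, by convention
            kids = self.tree.seed_node.child_nodes()
            if len(kids) < 2:
                raise ValueError("tree root must have >= 2 children")
            smallest = min(kids, key=lambda nd: len(nd.leaf_nodes()))
            og_leaves = [lf.taxon.label for lf in smallest.leaf_nodes()]
            if len(og_leaves) != 1:
                raise ValueError("cannot infer a single-leaf outgroup; pass one")
            outgroup = og_leaves[0]
        if outgroup not in self.leaves:
            raise ValueError(f"outgroup {outgroup!r} not a leaf")
        self.outgroup = outgroup
        self.clades: list[frozenset[str]] = []
        for nd in self.tree.preorder_node_iter():
            if nd is self.tree.seed_node:
                continue
            clade = frozenset(lf.taxon.label for lf in nd.leaf_nodes())
            if clade not in self.clades:
                self.clades.append(clade)

    @property
    def ingroup(self) -> frozenset[str]:
        return frozenset(self.leaves) - {self.outgroup}

    def clade_name(self, clade: frozenset[str]) -> str:
        ordered = [s for s in self.leaves if s in clade]
        if len(ordered) == 1:
            return ordered[0]
        return f"{ordered[0]}-{ordered[-1]}"

    @classmethod
    def default(cls) -> "PhyloTree":
        return cls(DEFAULT_TREE_NEWICK, outgroup="chicken")


@dataclass
class AgeAssignment:
    event_id: str
    label: str
    # every single-change explanation, as (branch clade name, direction)
    scenarios: list[tuple[str, str]] = field(default_factory=list)


def species_splicing_state(tissue_statuses: Iterable[str | None]) -> str:
    """Collapse per-tissue statuses into one species state.

    A if alternative in any tissue; C if at least one tissue is quantifiable
    and all quantifiable tissues are constitutive; NA otherwise.
    """
    statuses = [s for s in tissue_statuses if s not in (None, "excluded")]
    if any(s == "alternative" for s in statuses):
        return "A"
    if statuses and all(s == "constitutive" for s in statuses):
        return "C"
    return "NA"


def build_state_matrix(
    statuses: Mapping[str, Mapping[str, Iterable[str | None]]]
) -> pd.DataFrame:
    """events x species state matrix from nested per-tissue statuses."""
    rows = {
        ev: {sp: species_splicing_state(ts) for sp, ts in per_sp.items()}
        for ev, per_sp in statuses.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def assign_splicing_age(
    states: Mapping[str, str],
    tree: PhyloTree,
    event_id: str = "",
    require_complete: bool = True,
) -> AgeAssignment:
    """Single-change parsimony label for one event's A/C pattern.

    Enumerates every (branch, direction) scenario: a gain on branch b means
    the root is C and exactly the clade below b is A; a loss is symmetric.
    Uniform patterns are VCA/VCC; the outgroup-split patterns are MCA/MCC;
    a pattern with exactly one scenario is labeled by its branch; patterns
    with no scenario are complex. With ``require_complete=False`` missing
    species are ignored and scenarios are judged on the observed leaves
    only (non-canonical mode).
    """
    observed = {sp: states.get(sp, "NA") for sp in tree.leaves}
    missing = {sp for sp, st in observed.items() if st not in ("A", "C")}
    if missing and require_complete:
        return AgeAssignment(event_id, "unassignable", [])
    leaves = [sp for sp in tree.leaves if sp not in missing]
    if not leaves:
        return AgeAssignment(event_id, "unassignable", [])
    a_set = frozenset(sp for sp in leaves if observed[sp] == "A")
    c_set = frozenset(sp for sp in leaves if observed[sp] == "C")

    if not c_set:
        return AgeAssignment(event_id, "VCA", [])
    if not a_set:
        return AgeAssignment(event_id, "VCC", [])

    scenarios: list[tuple[str, str]] = []
    changed: list[frozenset[str]] = []
    for clade in tree.clades:
        obs_clade = frozenset(clade) - missing
        if not obs_clade or len(obs_clade) == len(leaves):
            continue
        if obs_clade == a_set:
            scenarios.append((tree.clade_name(clade), "gain"))
            changed.append(clade)
        if obs_clade == c_set:
            scenarios.append((tree.clade_name(clade), "loss"))
            changed.append(clade)

    if not scenarios:
        return AgeAssignment(event_id, "complex", [])

    ingroup = tree.ingroup - missing
    if a_set == ingroup and c_set == {tree.outgroup} - missing:
        return AgeAssignment(event_id, "MCA", scenarios)
    if c_set == ingroup and a_set == {tree.outgroup} - missing:
        return AgeAssignment(event_id, "MCC", scenarios)

    # prefer the scenario changing the smaller clade when several remain
    best = min(range(len(scenarios)), key=lambda i: len(changed[i]))
    name, direction = scenarios[best]
    return AgeAssignment(event_id, f"{name}_{direction}", scenarios)


def pairwise_entropy_correlation(
    entropy_a: Sequence[float] | pd.Series,
    entropy_b: Sequence[float] | pd.Series,
) -> tuple[float, int]:
    """Spearman rho of splicing entropy over shared orthologous events.

    Pairs with a missing value on either side are dropped; fewer than three
    shared events yields (nan, n).
    """
    a = pd.Series(entropy_a, dtype=float)
    b = pd.Series(entropy_b, dtype=float)
    if isinstance(entropy_a, pd.Series) and isinstance(entropy_b, pd.Series):
        a, b = a.align(b, join="inner")
    ok = a.notna() & b.notna()
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho), n


def max_entropy_species(
    entropies: Mapping[str, float], margin: float = 1.0
) -> str | None:
    """Species with the clearly highest entropy for one event.

    Returns the arg-max species only when it beats the runner-up by at
    least ``margin`` bits; ties or narrow gaps return None.
    """
    vals = [(v, sp) for sp, v in entropies.items() if v == v]  # drop NaN
    if len(vals) < 2:
        return None
    vals.sort(key=lambda t: -t[0])
    (top, sp_top), (second, _) = vals[0], vals[1]
    if top - second >= margin:
        return sp_top
    return None


def monotonic_entropy_trend(entropies: Sequence[float]) -> str:
    """'increase'/'decrease'/'none' for entropies ordered oldest -> reference.

    Increase means non-decreasing along the order with a positive total
    change toward the reference species; decrease is symmetric.
    """
    e = np.asarray(entropies, dtype=float)
    if e.size < 2 or np.any(np.isnan(e)):
        return "none"
    diffs = np.diff(e)
    if np.all(diffs >= 0) and e[-1] > e[0]:
        return "increase"
    if np.all(diffs <= 0) and e[-1] < e[0]:
        return "decrease"
    return "none"


def age_group_summaries(
    assignments: Mapping[str, str],
    entropies: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per age group: fraction of events with max-over-tissue entropy >=
    threshold, and fraction with cross-tissue entropy range >= threshold.

    ``entropies`` is events x tissues (NaN = unquantified); events with no
    quantified tissue are skipped. Empty groups are absent from the output.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for ev, label in assignments.items():
        groups.setdefault(label, []).append(ev)
    for label, evs in sorted(groups.items()):
        evs = [e for e in evs if e in entropies.index]
        sub = entropies.loc[evs]
        quantified = sub.notna().any(axis=1)
        sub = sub[quantified]
        if sub.empty:
            continue
        mx = sub.max(axis=1)
        rng = mx - sub.min(axis=1)
        rows.append(
            {
                "group": label,
                "n_events": len(sub),
                "frac_high_entropy": float((mx >= threshold).mean()),
                "frac_large_change": float((rng >= threshold).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame(
        columns=["n_events", "frac_high_entropy", "frac_large_change"]
    )
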