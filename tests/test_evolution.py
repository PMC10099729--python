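"""Species states, single-change parsimony ages and entropy summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spliceplex.evolution import (
    PhyloTree,
    age_group_summaries,
    assign_splicing_age,
    max_entropy_species,
    monotonic_entropy_trend,
    pairwise_entropy_correlation,
    species_splicing_state,
)
from spliceplex.simulate import (
    simulate_divergent_entropies,
    simulate_evolutionary_history,
)


@pytest.fixture(scope="module")
def tree():
    return PhyloTree.default()


class TestSpeciesState:
    def test_any_alternative_wins(self):
        assert species_splicing_state(
            ["alternative", "constitutive", "constitutive", None, None, None]
        ) == "A"

    def test_all_constitutive(self):
        assert species_splicing_state(["constitutive", "constitutive"]) == "C"

    def test_all_missing(self):
        assert species_splicing_state([None, "excluded", None]) == "NA"


def brute_force_single_change(states, tree):
    """Independent oracle: try every (branch, direction) on the tree and keep
    the ones whose implied leaf pattern equals the observation."""
    scenarios = []
    for clade in tree.clades:
        for direction, changed_state, base in (("gain", "A", "C"), ("loss", "C", "A")):
            implied = {
                sp: changed_state if sp in clade else base for sp in tree.leaves
            }
            if implied == states:
                scenarios.append((tree.clade_name(clade), direction))
    return scenarios


class TestAssignSplicingAge:
    def test_conserved_labels(self, tree):
        all_a = {sp: "A" for sp in tree.leaves}
        all_c = {sp: "C" for sp in tree.leaves}
        assert assign_splicing_age(all_a, tree).label == "VCA"
        assert assign_splicing_age(all_c, tree).label == "VCC"

    def test_mammal_conserved(self, tree):
        mca = {sp: "A" for sp in tree.leaves}
        mca["chicken"] = "C"
        asg = assign_splicing_age(mca, tree)
        assert asg.label == "MCA"
        # both the gain-in-mammals and the loss-in-chicken reading recorded
        assert set(asg.scenarios) == {
            ("human-opossum", "gain"), ("chicken", "loss"),
        }
        mcc = {sp: "C" for sp in tree.leaves}
        mcc["chicken"] = "A"
        assert assign_splicing_age(mcc, tree).label == "MCC"

    def test_species_specific_gain(self, tree):
        states = {sp: "C" for sp in tree.leaves}
        states["human"] = "A"
        assert assign_splicing_age(states, tree).label == "human_gain"

    def test_non_clade_pattern_is_complex(self, tree):
        states = {sp: "C" for sp in tree.leaves}
        states["human"] = "A"
        states["mouse"] = "A"  # human+mouse is not a clade
        assert assign_splicing_age(states, tree).label == "complex"

    def test_missing_data_unassignable(self, tree):
        states = {sp: "A" for sp in tree.leaves}
        states["gorilla"] = "NA"
        assert assign_splicing_age(states, tree).label == "unassignable"
        tolerant = assign_splicing_age(states, tree, require_complete=False)
        assert tolerant.label == "VCA"

    def test_exhaustive_pattern_oracle(self, tree):
        """All 2^7 complete A/C patterns agree with the brute-force
        single-change enumerator; non-complex labels are exactly the
        patterns whose A-set or C-set is a clade (or a uniform pattern)."""
        clades = {frozenset(c) for c in tree.clades}
        for bits in itertools.product("AC", repeat=len(tree.leaves)):
            states = dict(zip(tree.leaves, bits))
            asg = assign_splicing_age(states, tree)
            oracle = brute_force_single_change(states, tree)
            a_set = frozenset(s for s, v in states.items() if v == "A")
            c_set = frozenset(tree.leaves) - a_set
            if not a_set or not c_set:
                assert asg.label in ("VCA", "VCC")
                continue
            if oracle:
                assert asg.label != "complex"
                assert set(asg.scenarios) == set(oracle)
                assert a_set in clades or c_set in clades
            else:
                assert asg.label == "complex"
                assert a_set not in clades and c_set not in clades

    def test_gain_loss_symmetry(self, tree):
        """Swapping A and C maps gains to losses and VCA/MCA to VCC/MCC."""
        swap = {"A": "C", "C": "A"}
        pairs = {"VCA": "VCC", "VCC": "VCA", "MCA": "MCC", "MCC": "MCA"}
        for bits in itertools.product("AC", repeat=len(tree.leaves)):
            states = dict(zip(tree.leaves, bits))
            flipped = {sp: swap[v] for sp, v in states.items()}
            l1 = assign_splicing_age(states, tree).label
            l2 = assign_splicing_age(flipped, tree).label
            if l1 in pairs:
                assert l2 == pairs[l1]
            elif l1 == "complex":
                assert l2 == "complex"
            elif l1.endswith("_gain"):
                assert l2 == l1.replace("_gain", "_loss")
            else:
                assert l2 == l1.replace("_loss", "_gain")

    def test_parsimony_recovers_simulated_single_changes(self, tree, rng):
        """Histories constrained to at most one flip are recovered exactly."""
        for _ in range(200):
            states, flips = simulate_evolutionary_history(
                tree, gain_prob=0.15, loss_prob=0.15, rng=rng,
                constrain_single_change=True,
            )
            asg = assign_splicing_age(states, tree)
            if not flips:
                assert asg.label in ("VCA", "VCC")
                continue
            clade_name, direction = flips[0]
            if asg.label in ("MCA", "MCC"):
                assert (clade_name, direction) in asg.scenarios
            else:
                assert asg.label == f"{clade_name}_{direction}"


class TestEntropySummaries:
    def test_spearman_trivial_cases(self):
        rho, n = pairwise_entropy_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)
        rho, _ = pairwise_entropy_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)
        rho, n = pairwise_entropy_correlation([1.0, 2.0], [1.0, 2.0])
        assert np.isnan(rho) and n == 2

    def test_correlation_decays_with_divergence(self, rng):
        base = rng.uniform(0, 2, size=400)
        times = [6.7, 29.0, 90.0, 312.0]
        drifted = simulate_divergent_entropies(rng, base, times, scale=0.02)
        rhos = [
            pairwise_entropy_correlation(base, drifted[i])[0]
            for i in range(len(times))
        ]
        assert rhos == sorted(rhos, reverse=True)

    def test_max_entropy_species_margin(self):
        assert max_entropy_species(
            {"human": 2.2, "mouse": 1.0, "chicken": 0.8}
        ) == "human"
        assert max_entropy_species({"human": 2.2, "mouse": 1.5}) is None
        assert max_entropy_species({"human": 2.0, "mouse": 2.0}) is None
        assert max_entropy_species({"human": 2.0}) is None

    def test_monotonic_trend(self):
        assert monotonic_entropy_trend([0.2, 0.5, 0.9, 1.4]) == "increase"
        assert monotonic_entropy_trend([1.0, 1.0, 1.0]) == "none"
        assert monotonic_entropy_trend([1.4, 0.9, 1.0, 0.2]) == "none"
        assert monotonic_entropy_trend([1.4, 0.9, 0.9, 0.2]) == "decrease"

    def test_age_group_summaries(self):
        assignments = {"e1": "VCA", "e2": "VCA", "e3": "human_gain"}
        entropies = pd.DataFrame(
            {
                "brain": [2.0, 2.0, 0.3],
                "liver": [2.0, 0.5, np.nan],
            },
            index=["e1", "e2", "e3"],
        )
        out = age_group_summaries(assignments, entropies)
        assert out.loc["VCA", "frac_high_entropy"] == 1.0
        assert out.loc["VCA", "frac_large_change"] == 0.5
        # single-tissue event contributes zero range
        assert out.loc["human_gain", "frac_large_change"] == 0.0
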