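"""Ground-truth self-consistency and determinism of the generator."""

import numpy as np
import pytest

from spliceplex.evolution import PhyloTree
from spliceplex.graph import build_splice_graph
from spliceplex.quantify import estimate_path_abundances, node_psi, splicing_entropy
from spliceplex.simulate import (
    SimConfig,
    cassette_event,
    local_path_truth,
    simulate_edge_counts,
    simulate_evolutionary_history,
    simulate_gene_models,
    simulate_genome,
    simulate_path_abundances,
    simulate_stage_series,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, depth=-1)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_stages=3)
        with pytest.raises(ValueError):
            SimConfig(seed=1, event_mix={"CE": 1.5})


class TestGeneModels:
    def test_deterministic_for_seed(self):
        from spliceplex.io import write_gtf
        import os, tempfile

        outs = []
        for _ in range(2):
            genes = simulate_gene_models(SimConfig(seed=42, n_genes=15))
            with tempfile.TemporaryDirectory() as d:
                p = os.path.join(d, "x.gtf")
                write_gtf({g.gene_id: g.transcripts for g in genes}, p)
                outs.append(open(p, "rb").read())
        assert outs[0] == outs[1]

    def test_cassette_only_config(self):
        genes = simulate_gene_models(
            SimConfig(seed=7, n_genes=3, event_mix={"CE": 1.0},
                      transcripts_per_gene=(2, 2))
        )
        for g in genes:
            assert len(g.transcripts) == 2
            # isoforms differ by exactly one internal exon
            e1 = set(g.transcripts[0].exons)
            e2 = set(g.transcripts[1].exons)
            assert len(e1 ^ e2) == 1

    def test_genome_plants_splice_dinucleotides(self):
        genes = simulate_gene_models(SimConfig(seed=9, n_genes=10))
        genome = simulate_genome(genes, seed=10)
        for g in genes:
            for t in g.transcripts:
                seq = genome[t.chrom]
                for s, e in t.introns():
                    if t.strand == "+":
                        assert seq[s:s + 2] == "GT" and seq[e - 2:e] == "AG"
                    else:
                        assert seq[s:s + 2] == "CT" and seq[e - 2:e] == "AC"


class TestAbundances:
    def test_one_hot_limit(self, rng):
        psi = simulate_path_abundances(rng, 4, concentration=1e-4)
        assert splicing_entropy(psi) < 0.05

    def test_symmetric_dirichlet_mean_entropy(self, rng):
        """Dirichlet(10) on four paths concentrates near the 2-bit maximum."""
        ents = [
            splicing_entropy(simulate_path_abundances(rng, 4, 10.0))
            for _ in range(5000)
        ]
        assert np.mean(ents) == pytest.approx(1.93, abs=0.03)

    def test_two_regime_mixture_is_bimodal(self, rng):
        """The low/high concentration mixture produces the two-peaked
        entropy landscape: mass near 0 and near the maximum, little between."""
        cfg = SimConfig(seed=1)
        ents = []
        for _ in range(4000):
            conc = (
                cfg.concentration_low
                if rng.random() < cfg.high_entropy_fraction
                else cfg.concentration_high
            )
            ents.append(splicing_entropy(simulate_path_abundances(rng, 4, conc)))
        ents = np.asarray(ents)
        low = np.mean(ents < 0.4)
        mid = np.mean((ents > 0.8) & (ents < 1.4))
        high = np.mean(ents > 1.6)
        assert low > mid and high > mid


class TestLocalPathTruth:
    def test_transcript_flux_maps_to_path_truth(self, cassette_transcripts):
        from spliceplex.graph import enumerate_event_paths

        g = build_splice_graph(cassette_transcripts)
        ev = enumerate_event_paths(g, 2)
        psi = local_path_truth(ev, g, {"t1": 0.7, "t2": 0.3})
        order = {p: i for i, p in enumerate(ev.paths)}
        assert psi[order[(1, 2, 3)]] == pytest.approx(0.7)
        assert psi[order[(1, 3)]] == pytest.approx(0.3)


class TestEdgeCounts:
    def test_depth_conserved_and_zero(self, rng):
        ev = cassette_event()
        c = simulate_edge_counts(ev, [0.6, 0.4], 1000, rng)
        assert sum(c.counts.values()) == 1000
        c0 = simulate_edge_counts(ev, [0.6, 0.4], 0, rng)
        assert all(v == 0 for v in c0.counts.values())

    def test_seed_determinism(self):
        ev = cassette_event()
        a = simulate_edge_counts(ev, [0.6, 0.4], 500, np.random.default_rng(5))
        b = simulate_edge_counts(ev, [0.6, 0.4], 500, np.random.default_rng(5))
        assert a.counts == b.counts

    def test_law_of_large_numbers_em_recovery(self, rng):
        ev = cassette_event()
        c = simulate_edge_counts(ev, [0.6, 0.4], 1_000_000, rng)
        pa = estimate_path_abundances(ev, c)
        assert node_psi(pa, ev) == pytest.approx(0.6, abs=0.005)


class TestEvolutionaryHistory:
    def test_zero_probs_uniform(self, rng):
        tree = PhyloTree.default()
        states, flips = simulate_evolutionary_history(
            tree, 0.0, 0.0, rng, root_state="C"
        )
        assert flips == []
        assert set(states.values()) == {"C"}

    def test_single_change_bookkeeping(self, rng):
        tree = PhyloTree.default()
        for _ in range(100):
            states, flips = simulate_evolutionary_history(
                tree, 0.2, 0.2, rng, constrain_single_change=True
            )
            assert len(flips) <= 1
            if flips:
                name, direction = flips[0]
                clade = next(
                    c for c in tree.clades if tree.clade_name(c) == name
                )
                inside = {states[sp] for sp in clade}
                outside = {states[sp] for sp in tree.leaves if sp not in clade}
                assert inside == {"A" if direction == "gain" else "C"}
                assert outside == {"C" if direction == "gain" else "A"}

    def test_complex_fraction_matches_flip_bookkeeping(self, rng):
        """Unconstrained histories labeled complex by parsimony are exactly
        those whose realized leaf pattern is explained by no single change,
        which the recorded flip count predicts for effective histories."""
        from spliceplex.evolution import assign_splicing_age

        from oracles import single_change_explanations

        tree = PhyloTree.default()
        n_complex_parsimony = 0
        n_unexplainable = 0
        for _ in range(300):
            states, flips = simulate_evolutionary_history(tree, 0.25, 0.25, rng)
            label = assign_splicing_age(states, tree).label
            explained = bool(single_change_explanations(states, tree)) or (
                len(set(states.values())) == 1
            )
            assert (label == "complex") == (not explained)
            n_complex_parsimony += label == "complex"
            n_unexplainable += not explained
        assert n_complex_parsimony == n_unexplainable


class TestStageSeries:
    def test_truth_self_consistency(self, rng):
        """Stored truth flags are recomputable from the stored true values."""
        series, truth = simulate_stage_series(rng, "dynamic")
        assert truth["entropy_dynamic"] == (
            max(truth["true_entropies"]) - min(truth["true_entropies"]) >= 0.5
        )
        assert len(truth["true_entropies"]) == len(series.stages)
        # node Psi truth stays constant for an entropy-only sweep
        assert max(truth["true_node_psi"]) - min(truth["true_node_psi"]) < 1e-9

    def test_amplitude_zero_is_not_dev(self, rng):
        _, truth = simulate_stage_series(rng, "dev", amplitude=0.0)
        assert not truth["dev"]

    def test_kinds(self, rng):
        _, t_null = simulate_stage_series(rng, "null")
        assert not t_null["dev"] and not t_null["entropy_dynamic"]
        _, t_dyn = simulate_stage_series(rng, "dynamic")
        assert t_dyn["entropy_dynamic"] and not t_dyn["dev"]
        with pytest.raises(ValueError):
            simulate_stage_series(rng, "bogus")
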