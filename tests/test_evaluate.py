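"""Reference gene lists, scoring metrics, and the F-measure permutation test."""

from itertools import product

import numpy as np
import pytest

from mqtlnet import (build_rgl, compare_methods, evaluate_method, lod_sweep,
                     metabolite_wise_precision, permutation_test_f)
from mqtlnet.evaluate import empirical_p
from mqtlnet.simulate import ReactionGraph, SimulationConfig, simulate_all


def _chain_graph():
    # M1 -R1(E1)- M2 -R2(E2)- M3 -R3(E3)- M4
    return ReactionGraph(
        metabolites=["M1", "M2", "M3", "M4"],
        reactions={
            "R1": {"substrates": ["M1"], "products": ["M2"],
                   "enzymes": ["E1"], "pathway": "p1"},
            "R2": {"substrates": ["M2"], "products": ["M3"],
                   "enzymes": ["E2"], "pathway": "p1"},
            "R3": {"substrates": ["M3"], "products": ["M4"],
                   "enzymes": ["E3"], "pathway": "p2"},
        },
    )


def _random_graph(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 9))
    mets = [f"M{i}" for i in range(m)]
    reactions = {}
    for i in range(m - 1):
        reactions[f"R{i}"] = {
            "substrates": [mets[i]], "products": [mets[i + 1]],
            "enzymes": [f"E{i}a", f"E{i}b"][: int(rng.integers(1, 3))],
            "pathway": f"p{i // 3}",
        }
    for j in range(int(rng.integers(1, 4))):
        a, b = rng.choice(m, size=2, replace=False)
        reactions[f"X{j}"] = {
            "substrates": [mets[a]], "products": [mets[b]],
            "enzymes": [f"EX{j}"], "pathway": f"px{j % 2}",
        }
    return ReactionGraph(metabolites=mets, reactions=reactions)


def _bfs_oracle(graph, metabolite, max_step):
    """Independent breadth-first layering over the bipartite graph."""
    import networkx as nx

    g = graph.to_networkx()
    dist = nx.single_source_shortest_path_length(g, metabolite)
    # Reaction at bipartite distance 2k-1 is at reaction-step k.
    genes = set()
    for node, d in dist.items():
        if g.nodes[node].get("kind") == "reaction":
            step = (d + 1) // 2
            if step <= max_step:
                genes |= set(g.nodes[node]["enzymes"])
    return genes


class TestBuildRgl:
    def test_chain_hand_bfs(self):
        graph = _chain_graph()
        assert build_rgl(graph, "M2", 1) == {"E1", "E2"}
        assert build_rgl(graph, "M2", 2) == {"E1", "E2", "E3"}
        assert build_rgl(graph, "M1", 1) == {"E1"}
        # Pathway rule: M2's direct reactions lie in p1 only.
        assert build_rgl(graph, "M2", 4) == {"E1", "E2"}
        assert build_rgl(graph, "M4", 4) == {"E3"}

    def test_isolated_metabolite_levels_coincide(self):
        graph = ReactionGraph(
            metabolites=["M"],
            reactions={"R": {"substrates": ["M"], "products": [],
                             "enzymes": ["E1", "E2"], "pathway": "p"}},
        )
        assert build_rgl(graph, "M", 1) == build_rgl(graph, "M", 2) \
            == build_rgl(graph, "M", 3) == {"E1", "E2"}

    def test_matches_bfs_oracle_on_random_graphs(self):
        for seed in range(20):
            graph = _random_graph(seed)
            for met in graph.metabolites:
                for level in (1, 2, 3):
                    assert build_rgl(graph, met, level) == \
                        _bfs_oracle(graph, met, level)

    def test_levels_nest(self):
        for seed in range(20):
            graph = _random_graph(100 + seed)
            for met in graph.metabolites:
                r1 = build_rgl(graph, met, 1)
                r2 = build_rgl(graph, met, 2)
                r3 = build_rgl(graph, met, 3)
                assert r1 <= r2 <= r3

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(KeyError):
            build_rgl(_chain_graph(), "nope", 1)


class TestEvaluateMethod:
    def test_hand_computed_counts(self):
        graph = _chain_graph()
        preds = {"M1": {"E1"}, "M2": {"EX"}, "M3": {"E2", "EX"}, "M4": set()}
        rep = evaluate_method(preds, graph, level=1,
                              annotated_metabolites=graph.metabolites)
        assert (rep.na, rep.np_, rep.ncp) == (4, 3, 2)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f_measure == pytest.approx(4 / 7)

    def test_predictions_equal_to_rgls(self):
        graph = _chain_graph()
        preds = {m: build_rgl(graph, m, 1) for m in ["M1", "M2"]}
        rep = evaluate_method(preds, graph, 1,
                              annotated_metabolites=graph.metabolites)
        assert rep.precision == 1.0
        assert rep.recall == pytest.approx(rep.np_ / rep.na)

    def test_empty_predictions_flagged(self):
        graph = _chain_graph()
        rep = evaluate_method({m: set() for m in graph.metabolites}, graph, 1,
                              annotated_metabolites=graph.metabolites)
        assert rep.np_ == 0 and rep.precision == 0.0 and rep.f_measure == 0.0
        assert not rep.precision_defined

    def test_no_annotated_metabolites_rejected(self):
        with pytest.raises(ValueError, match="Na = 0"):
            evaluate_method({}, _chain_graph(), 1, annotated_metabolites=[])

    def test_f_is_harmonic_mean_identity(self):
        rng = np.random.default_rng(0)
        graph = _chain_graph()
        genes = ["E1", "E2", "E3", "X1", "X2"]
        for _ in range(25):
            preds = {m: set(rng.choice(genes, size=rng.integers(0, 4),
                                       replace=False))
                     for m in graph.metabolites}
            rep = evaluate_method(preds, graph, 2,
                                  annotated_metabolites=graph.metabolites)
            if rep.precision + rep.recall > 0:
                expected = (2 * rep.precision * rep.recall
                            / (rep.precision + rep.recall))
                assert rep.f_measure == pytest.approx(expected, abs=1e-12)
            else:
                assert rep.f_measure == 0.0


class TestMetaboliteWisePrecision:
    def test_direct_ratio(self):
        assert metabolite_wise_precision({"a", "b", "c", "d"}, {"a", "z"}) \
            == pytest.approx(0.25)

    def test_subset_and_disjoint(self):
        assert metabolite_wise_precision({"a"}, {"a", "b"}) == 1.0
        assert metabolite_wise_precision({"a"}, {"b"}) == 0.0

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            metabolite_wise_precision(set(), {"a"})


class TestCompareMethods:
    def test_identical_distributions_rarely_significant(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {m: rng.standard_normal(10).tolist()
                      for m in ("gwas", "network", "combined")}
            p, _, _ = compare_methods(groups)
            hits += p < 0.05
        assert hits <= 12

    def test_shifted_method_detected_by_both_corrections(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 15).tolist(),
                  "b": rng.normal(0, 1, 15).tolist(),
                  "c": (rng.normal(0, 1, 15) + 5).tolist()}
        p, bonf, tukey = compare_methods(groups)
        assert p < 1e-6
        sig_bonf = {tuple(sorted((r.method_a, r.method_b)))
                    for r in bonf.itertuples() if r.p_bonferroni < 0.01}
        assert sig_bonf == {("a", "c"), ("b", "c")}
        sig_tukey = {tuple(sorted((r.group1, r.group2)))
                     for r in tukey.itertuples() if r.reject}
        assert sig_tukey == sig_bonf

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            compare_methods({"a": [1.0], "b": [0.1, 0.2]})


class TestPermutationTestF:
    def test_worked_example_950_of_1000(self):
        # 950 permutations where the actual F exceeds the permuted F.
        ys = np.r_[np.zeros(950), np.ones(50)]
        assert empirical_p(0.5, ys) == pytest.approx(0.05)

    def test_degenerate_bounds(self):
        ys = np.array([0.1, 0.2, 0.3])
        assert empirical_p(0.0, ys) == 1.0
        assert empirical_p(0.99, ys) == 0.0

    def test_matches_enumerated_null_on_toy_universe(self):
        # Two metabolites, one predicted gene each, universe of 4 genes:
        # the null distribution of F is enumerable exactly.
        graph = ReactionGraph(
            metabolites=["M1", "M2"],
            reactions={
                "R1": {"substrates": ["M1"], "products": [],
                       "enzymes": ["E1"], "pathway": "p"},
                "R2": {"substrates": ["M2"], "products": [],
                       "enzymes": ["E2"], "pathway": "p"},
            },
        )
        universe = ["E1", "E2", "X1", "X2"]
        preds = {"M1": {"E1"}, "M2": {"X1"}}

        def f_of(p1, p2):
            ncp = int(p1 == "E1") + int(p2 == "E2")
            np_ = 2
            na = 2
            prec, rec = ncp / np_, ncp / na
            return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

        actual = f_of("E1", "X1")
        null = [f_of(a, b) for a, b in product(universe, universe)]
        exact_p = np.mean([actual <= y for y in null])

        k = 4000
        a, mu, sd, p = permutation_test_f(preds, graph, level=1,
                                          gene_universe=universe, k=k, seed=3)
        assert a == pytest.approx(actual)
        tol = 3 * np.sqrt(exact_p * (1 - exact_p) / k)
        assert abs(p - exact_p) <= tol

    def test_prediction_outside_universe_rejected(self):
        graph = _chain_graph()
        with pytest.raises(ValueError):
            permutation_test_f({"M1": {"E1"}}, graph, 1,
                               gene_universe=["X"], k=100)

    def test_list_permutation_scheme_preserves_sizes(self):
        graph = _chain_graph()
        preds = {"M1": {"E1", "E2"}, "M2": {"E3"}, "M3": set(), "M4": set()}
        a, mu, sd, p = permutation_test_f(
            preds, graph, 1, gene_universe=["E1", "E2", "E3"],
            k=200, seed=0, scheme="permute_lists")
        assert 0.0 <= p <= 1.0


@pytest.fixture(scope="module")
def sweep_inputs():
    from mqtlnet import compute_structure_pcs, mlm_scan, preprocess_traits

    cfg = SimulationConfig(n_accessions=100, n_snps=1000, n_genes=100,
                           n_metabolites=6, seed=23,
                           causal_variance_share=0.3,
                           n_trans_per_metabolite=0)
    study = simulate_all(cfg)
    K = study.truth.true_kinship
    Q = compute_structure_pcs(study.genotypes, 2)
    traits, _ = preprocess_traits(study.traits)
    assoc = {m: mlm_scan(traits[m], study.genotypes, K, Q)
             for m in traits.columns}
    return study, assoc


class TestLodSweep:
    def test_threshold_above_all_lods_gives_empty_row(self, sweep_inputs):
        study, assoc = sweep_inputs
        table = lod_sweep(assoc, [99.0], study.graph, study.annotation,
                          n_snps=study.genotypes.n_snps)
        assert (table["np"] == 0).all()
        assert (table["f_measure"] == 0).all()

    def test_recall_non_increasing_in_threshold(self, sweep_inputs):
        study, assoc = sweep_inputs
        table = lod_sweep(assoc, [2.0, 3.0, 4.0, 4.5, 5.3], study.graph,
                          study.annotation, n_snps=study.genotypes.n_snps)
        for level, grp in table.groupby("level"):
            rec = grp.sort_values("lod_threshold")["recall"].to_numpy()
            assert np.all(np.diff(rec) <= 1e-12)

    def test_unsorted_thresholds_rejected(self, sweep_inputs):
        study, assoc = sweep_inputs
        with pytest.raises(ValueError):
            lod_sweep(assoc, [5.0, 3.0], study.graph, study.annotation,
                      n_snps=study.genotypes.n_snps)
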