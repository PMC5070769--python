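"""Synthetic-data generators: determinism, structure, and ground-truth closure."""

import numpy as np
import pandas as pd
import pytest

from mqtlnet import SimulationConfig, simulate_all
from mqtlnet.simulate import (InvalidConfigError, ReactionGraph,
                              TIME_GRID_MINUTES, generate_annotation,
                              generate_external_qtl_calls, generate_genotypes,
                              generate_reaction_graph, generate_timecourse,
                              generate_traits, plant_edges, read_gff3,
                              write_gff3)


@pytest.mark.parametrize("field,value", [
    ("n_snps", 0),
    ("n_accessions", 0),
    ("heritability", 0.0),
    ("heritability", 1.0),
    ("fst_like_drift", 1.5),
    ("external_tp_rate", -0.1),
])
def test_config_rejects_invalid_values(field, value):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(InvalidConfigError):
        cfg.validate()


def test_config_rejects_fewer_snps_than_chromosomes():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_snps=3, n_chromosomes=5).validate()


def test_genotypes_are_deterministic_given_seed():
    cfg = SimulationConfig(n_accessions=50, n_snps=500, seed=7)
    g1, t1 = generate_genotypes(cfg)
    g2, t2 = generate_genotypes(cfg)
    assert np.array_equal(g1.dosages, g2.dosages)
    assert np.array_equal(g1.pos, g2.pos)
    assert t1.subpop_labels == t2.subpop_labels


def test_unstructured_population_has_near_zero_mean_kinship():
    cfg = SimulationConfig(n_accessions=100, n_snps=2000, n_subpops=1,
                           fst_like_drift=0.0, seed=1)
    geno, truth = generate_genotypes(cfg)
    K = truth.true_kinship
    off = K[~np.eye(K.shape[0], dtype=bool)]
    assert abs(off.mean()) < 0.02


def test_leading_pc_separates_subpopulations():
    # Oracle: recompute the PCA directly from the generated matrix and
    # score the separation of the true labels.
    from sklearn.metrics import silhouette_score

    cfg = SimulationConfig(n_accessions=90, n_snps=1500, n_subpops=3,
                           fst_like_drift=0.3, seed=3)
    geno, truth = generate_genotypes(cfg)
    X = geno.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pc1 = (U[:, :1] * s[:1])
    labels = [truth.subpop_labels[a] for a in geno.accessions]
    assert silhouette_score(pc1, labels) > 0


def test_snp_positions_sorted_and_one_based():
    cfg = SimulationConfig(n_accessions=20, n_snps=300, seed=2)
    geno, _ = generate_genotypes(cfg)
    for c in np.unique(geno.chrom):
        pos = geno.pos[geno.chrom == c]
        assert pos.min() >= 1
        assert np.all(np.diff(pos) > 0)


def test_annotation_tiles_disjoint_sorted_genes():
    cfg = SimulationConfig(n_genes=10, n_chromosomes=1, seed=0)
    ann = generate_annotation(cfg)
    g = ann.genes
    assert len(g) == 10
    assert (g["start"] <= g["end"]).all()
    assert (g["start"].values[1:] > g["end"].values[:-1]).all()


def test_causal_snps_lie_inside_their_gene_spans(small_study):
    geno = small_study.genotypes
    for met, entries in small_study.truth.causal_map.items():
        for gene, snp, _eff in entries:
            chrom, start, end = small_study.annotation.span(gene)
            j = geno.snp_index(snp)
            assert geno.chrom[j] == chrom
            assert start <= geno.pos[j] <= end


def test_gff3_round_trip_preserves_spans(tmp_path, small_study):
    path = tmp_path / "genes.gff3"
    write_gff3(small_study.annotation, path)
    back = read_gff3(path)
    pd.testing.assert_frame_equal(
        small_study.annotation.genes.reset_index(drop=True),
        back.genes.reset_index(drop=True),
    )
    # Independent reader cross-check.
    gffutils = pytest.importorskip("gffutils")
    db = gffutils.create_db(str(path), ":memory:")
    spans = {f.id: (int(f.seqid), f.start, f.end)
             for f in db.features_of_type("gene")}
    for r in small_study.annotation.genes.itertuples(index=False):
        assert spans[r.gene_id] == (r.chrom, r.start, r.end)


def test_reaction_graph_chain_degree():
    graph = ReactionGraph(
        metabolites=["M1", "M2", "M3"],
        reactions={
            "R1": {"substrates": ["M1"], "products": ["M2"],
                   "enzymes": ["E1"], "pathway": "p"},
            "R2": {"substrates": ["M2"], "products": ["M3"],
                   "enzymes": ["E2"], "pathway": "p"},
        },
    )
    assert graph.degree("M2") == 2
    assert graph.degree("M1") == 1


def test_reaction_graph_rejects_orphan_metabolite():
    with pytest.raises(ValueError, match="without any reaction"):
        ReactionGraph(
            metabolites=["M1", "M2"],
            reactions={"R1": {"substrates": ["M1"], "products": [],
                              "enzymes": ["E1"], "pathway": "p"}},
        )


def test_causal_genes_are_step_one_enzymes(small_study):
    from mqtlnet.evaluate import build_rgl

    for met, entries in small_study.truth.causal_map.items():
        rgl1 = build_rgl(small_study.graph, met, 1)
        assert {g for g, _s, _e in entries} <= rgl1


def test_every_metabolite_participates_in_a_reaction(small_study):
    for met in small_study.graph.metabolites:
        assert small_study.graph.degree(met) >= 1


def test_trait_heritability_limit_decorrelates_causal_snp():
    cfg = SimulationConfig(n_accessions=200, n_snps=500, n_genes=60,
                           n_metabolites=4, heritability=1e-6,
                           causal_variance_share=1e-7,
                           trans_variance_share=1e-7,
                           missing_fraction=0.0, seed=9)
    study = simulate_all(cfg)
    # Critical |r| at alpha=0.01, n=200.
    from scipy import stats

    t_crit = stats.t.isf(0.005, 198)
    r_crit = t_crit / np.sqrt(198 + t_crit**2)
    for met, entries in study.truth.causal_map.items():
        (gene, snp, _e), = entries
        x = study.genotypes.dosages[:, study.genotypes.snp_index(snp)]
        y = np.log(study.traits[met].to_numpy(float))
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < r_crit * 1.5  # headroom for 4 independent traits


def test_trait_variance_share_matches_configuration():
    # Oracle: in the generative model the causal SNP's standardized dosage
    # carries exactly `causal_variance_share` of the latent variance, so
    # the squared trait correlation should sit near that share.
    cfg = SimulationConfig(n_accessions=300, n_snps=600, n_genes=60,
                           n_metabolites=6, heritability=0.8,
                           causal_variance_share=0.4,
                           n_trans_per_metabolite=0,
                           missing_fraction=0.0, seed=13)
    study = simulate_all(cfg)
    shares = []
    for met, entries in study.truth.causal_map.items():
        (gene, snp, _e), = entries
        x = study.genotypes.dosages[:, study.genotypes.snp_index(snp)]
        y = np.log(study.traits[met].to_numpy(float))
        shares.append(np.corrcoef(x, y)[0, 1] ** 2)
    assert abs(np.mean(shares) - 0.4) < 0.15


def test_highly_missing_trait_removed_by_completeness_filter():
    from mqtlnet import preprocess_traits

    cfg = SimulationConfig(n_accessions=100, n_snps=400, n_genes=60,
                           n_metabolites=4, missing_fraction=0.7, seed=4)
    study = simulate_all(cfg)
    kept, report = preprocess_traits(study.traits, min_complete=0.40)
    assert kept.shape[1] == 0  # all traits ~30% complete


def test_time_grid_has_23_labels_including_extra_samples(small_study):
    grid = set(small_study.timecourse.time_grid)
    assert len(grid) == 23
    assert {0, 5, 10, 640, 1280} <= grid


def test_noise_free_planted_edge_has_unit_correlation():
    cfg = SimulationConfig(n_metabolites=2, n_genes=20, n_accessions=10,
                           n_snps=40, n_conditions=1,
                           timecourse_noise_sd=0.0, seed=1)
    edges = {("met000", "gene00003", 1), ("met001", "gene00007", -1)}
    tc = generate_timecourse(cfg, edges, ["met000", "met001"],
                             [f"gene{i:05d}" for i in range(20)])
    from mqtlnet.network import correlate

    pcc = correlate(tc, tc.conditions()[0], ["met000", "met001"])
    assert pcc.loc["met000", "gene00003"] == pytest.approx(1.0)
    assert pcc.loc["met001", "gene00007"] == pytest.approx(-1.0)


def test_planted_edge_with_unknown_feature_rejected():
    cfg = SimulationConfig(n_metabolites=2, n_conditions=1, seed=1)
    with pytest.raises(ValueError, match="unknown feature"):
        generate_timecourse(cfg, {("met000", "nope", 1)}, ["met000"], ["t1"])


def test_flat_metabolite_rarely_passes_anova():
    # Oracle: repeated simulation; a time-flat profile should be declared
    # significant at alpha=0.05 in roughly 5% of datasets.
    from scipy import stats

    hits = 0
    n_runs = 50
    for seed in range(n_runs):
        cfg = SimulationConfig(n_metabolites=2, n_genes=10, n_accessions=10,
                               n_snps=40, n_conditions=1,
                               flat_metabolite_fraction=1.0,
                               causal_edge_rate=0.0,
                               planted_edge_fraction=0.0, seed=seed)
        tc = generate_timecourse(cfg, set(), ["met000"], ["g0"])
        sub = tc.data[(tc.data["kind"] == "metabolite")]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("time")]
        hits += stats.f_oneway(*groups).pvalue < 0.05
    # Binomial(50, 0.05): 10+ hits would be wildly improbable.
    assert hits <= 8


def test_external_calls_exact_at_rate_extremes(small_study):
    cfg_full = SimulationConfig(**{**small_study.config.to_dict(),
                                   "external_tp_rate": 1.0,
                                   "external_fp_rate": 0.0})
    lists, intervals = generate_external_qtl_calls(
        small_study.truth, small_study.annotation, cfg_full)
    for met, per_method in lists.items():
        causal = {g for g, _s, _e in small_study.truth.causal_map[met]}
        for method, genes in per_method.items():
            assert genes == causal
    assert (intervals["start"] <= intervals["end"]).all()

    cfg_none = SimulationConfig(**{**small_study.config.to_dict(),
                                   "external_tp_rate": 0.0})
    lists0, _ = generate_external_qtl_calls(
        small_study.truth, small_study.annotation, cfg_none)
    for met, per_method in lists0.items():
        causal = {g for g, _s, _e in small_study.truth.causal_map[met]}
        for genes in per_method.values():
            assert not (genes & causal)


def test_external_recovery_fraction_near_tp_rate():
    cfg = SimulationConfig(n_metabolites=50, n_genes=200, n_accessions=60,
                           n_snps=1000, external_tp_rate=0.6,
                           external_fp_rate=0.0, seed=21)
    study = simulate_all(cfg)
    for method in ("RIL", "IL"):
        hits = total = 0
        for met, entries in study.truth.causal_map.items():
            causal = {g for g, _s, _e in entries}
            hits += len(causal & study.external_lists[met][method])
            total += len(causal)
        # Binomial(50, 0.6) 99% CI is roughly [21, 39] hits.
        assert 21 <= hits <= 39


def test_external_interval_contains_reported_gene(small_study):
    for r in small_study.external_intervals.itertuples(index=False):
        chrom, start, end = small_study.annotation.span(r.gene)
        assert r.chrom == chrom
        assert r.start <= start and end <= r.end


def test_simulated_study_identifiers_resolve(small_study):
    genes = set(small_study.annotation.gene_ids)
    mets = set(small_study.graph.metabolites)
    for met, entries in small_study.truth.causal_map.items():
        assert met in mets
        assert {g for g, _s, _e in entries} <= genes
    for met, tr, _sign in small_study.truth.planted_edges:
        assert met in mets and tr in genes
    for rec in small_study.graph.reactions.values():
        assert set(rec["enzymes"]) <= genes


def test_plant_edges_assigns_each_transcript_once(small_config):
    causal_map = {f"met{i:03d}": {(f"gene{i:05d}", f"snp{i:06d}", 0.3)}
                  for i in range(8)}
    transcripts = [f"gene{i:05d}" for i in range(100)]
    edges = plant_edges(small_config, causal_map, transcripts)
    planted_t = [t for _m, t, _s in edges]
    assert len(planted_t) == len(set(planted_t))
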