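"""Benchmarking predicted gene lists against reaction-distance references.

Reference gene lists (RGLs) grade how far an enzyme sits from a
metabolite in the bipartite metabolite-reaction graph: RGL1 collects
enzymes of directly catalyzing reactions (step 1), RGL2/RGL3 extend to
reactions within two/three steps, and RGL4 takes every enzyme in the
pathways the metabolite's direct reactions belong to.  Method quality is
summarized as

    precision = Ncp / Np,   recall = Ncp / Na,
    F = 2 * precision * recall / (precision + recall)

where Na counts annotated metabolites in the dataset, Np those with at
least one predicted gene, and Ncp those whose prediction intersects
their RGL.  A permutation test replaces each metabolite's prediction by
an equally sized random gene sample and compares the achieved F-measure
with the permuted distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .loci import call_loci
from .simulate import ReactionGraph

__all__ = [
    "EvaluationReport",
    "build_rgl",
    "evaluate_method",
    "metabolite_wise_precision",
    "compare_methods",
    "permutation_test_f",
    "lod_sweep",
]

RGL_LEVELS = (1, 2, 3, 4)


def _reaction_steps(graph: ReactionGraph, metabolite: str) -> dict:
    """Minimal reaction-step distance of every reachable reaction.

    Reactions touching the metabolite are step 1; reactions touching any
    metabolite of a step-k reaction are step k+1.
    """
    if metabolite not in set(graph.metabolites):
        raise KeyError(f"unknown metabolite {metabolite!r}")
    steps: dict = {}
    frontier_mets = {metabolite}
    seen_mets = set(frontier_mets)
    step = 1
    while frontier_mets:
        frontier_rxns = set()
        for m in frontier_mets:
            for rid in graph.reactions_of(m):
                if rid not in steps:
                    steps[rid] = step
                    frontier_rxns.add(rid)
        nxt = set()
        for rid in frontier_rxns:
            nxt |= graph.metabolites_of(rid)
        frontier_mets = nxt - seen_mets
        seen_mets |= nxt
        step += 1
    return steps


def build_rgl(graph: ReactionGraph, metabolite: str, level: int) -> set:
    """Reference gene list of a metabolite at the given level (1-4)."""
    if level not in RGL_LEVELS:
        raise ValueError(f"level must be one of {RGL_LEVELS}, got {level!r}")
    steps = _reaction_steps(graph, metabolite)
    if level <= 3:
        return {
            g for rid, s in steps.items() if s <= level
            for g in graph.enzymes(rid)
        }
    pathways = {graph.reactions[rid]["pathway"]
                for rid, s in steps.items() if s == 1}
    return {
        g for rid, rec in graph.reactions.items()
        if rec["pathway"] in pathways
        for g in graph.enzymes(rid)
    }


@dataclass
class EvaluationReport:
    """Metabolite-level scoring of one method against one RGL level."""

    method: str
    level: int
    na: int
    np_: int
    ncp: int
    precision: float
    recall: float
    f_measure: float
    precision_defined: bool
    correct_metabolites: list = field(default_factory=list)
    metabolite_wise_precision: dict = field(default_factory=dict)


def metabolite_wise_precision(predicted: set, rgl: set) -> float:
    """|predicted & rgl| / |predicted| for one metabolite."""
    if not predicted:
        raise ValueError("metabolite-wise precision undefined for an empty "
                         "prediction")
    return len(set(predicted) & set(rgl)) / len(predicted)


def evaluate_method(
    predictions: dict,
    graph: ReactionGraph,
    level: int,
    annotated_metabolites: list | None = None,
    method: str = "",
) -> EvaluationReport:
    """Score one method's per-metabolite predictions at one RGL level.

    ``predictions`` maps metabolite -> predicted gene set.  A metabolite
    is correctly predicted when at least one predicted gene lies in its
    RGL.  ``annotated_metabolites`` defaults to the graph's metabolites
    restricted to those appearing in ``predictions``' keys.
    """
    graph_mets = set(graph.metabolites)
    if annotated_metabolites is None:
        annotated = sorted(set(predictions) & graph_mets)
    else:
        stray = set(annotated_metabolites) - graph_mets
        if stray:
            raise ValueError(f"annotated metabolites not in graph: {sorted(stray)}")
        annotated = sorted(annotated_metabolites)
    na = len(annotated)
    if na == 0:
        raise ValueError("no annotated metabolites to evaluate (Na = 0)")

    predicted_mets = [m for m in annotated if predictions.get(m)]
    np_count = len(predicted_mets)
    correct = []
    mwp = {}
    for m in predicted_mets:
        rgl = build_rgl(graph, m, level)
        pred = set(predictions[m])
        if pred & rgl:
            correct.append(m)
        mwp[m] = metabolite_wise_precision(pred, rgl)
    ncp = len(correct)
    precision_defined = np_count > 0
    precision = ncp / np_count if precision_defined else 0.0
    recall = ncp / na
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return EvaluationReport(
        method=method, level=level, na=na, np_=np_count, ncp=ncp,
        precision=precision, recall=recall, f_measure=f,
        precision_defined=precision_defined,
        correct_metabolites=correct,
        metabolite_wise_precision=mwp,
    )


def compare_methods(precisions_by_method: dict, alpha: float = 0.05):
    """ANOVA plus Bonferroni pairwise and Tukey HSD across methods.

    ``precisions_by_method`` maps method -> list of metabolite-wise
    precision values (NaNs dropped).  Returns ``(anova_p, pairwise
    Bonferroni table, Tukey HSD table)``.
    """
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = {m: np.asarray([v for v in vals if np.isfinite(v)])
              for m, vals in precisions_by_method.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 methods")
    for m, g in groups.items():
        if g.size < 2:
            raise ValueError(f"method {m!r} has fewer than 2 values")
    anova_p = float(stats.f_oneway(*groups.values()).pvalue)

    pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        p_raw = float(stats.ttest_ind(groups[a], groups[b]).pvalue)
        rows.append({
            "method_a": a, "method_b": b, "p_raw": p_raw,
            "p_bonferroni": min(1.0, p_raw * len(pairs)),
        })
    bonf = pd.DataFrame(rows)

    values = np.concatenate([groups[m] for m in sorted(groups)])
    labels = np.concatenate([[m] * groups[m].size for m in sorted(groups)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova_p, bonf, tukey


def permutation_test_f(
    predictions: dict,
    graph: ReactionGraph,
    level: int,
    gene_universe: list,
    k: int = 10_000,
    seed: int = 0,
    annotated_metabolites: list | None = None,
    scheme: str = "resample",
):
    """Empirical p-value of the achieved F-measure under gene shuffling.

    Each of ``k`` iterations replaces every metabolite's predicted set by
    a uniformly random, equally sized, without-replacement sample from
    ``gene_universe`` (``scheme='resample'``), or permutes whole gene
    lists among the predicted metabolites (``scheme='permute_lists'``),
    then recomputes the F-measure y_k.  The reported p is the fraction of
    iterations with actual F <= y_k (the indicator is 0 only when the
    actual F strictly exceeds the permuted one).

    Returns ``(actual_f, permuted_mean, permuted_sd, p)``.
    """
    if k < 100:
        raise ValueError("k must be >= 100")
    if scheme not in ("resample", "permute_lists"):
        raise ValueError(f"unknown scheme {scheme!r}")
    universe = sorted(set(gene_universe))
    for m, genes in predictions.items():
        if set(genes) - set(universe):
            raise ValueError(f"predicted genes for {m} outside the universe")
        if len(genes) > len(universe):
            raise ValueError("predicted set larger than the gene universe")
    rng = np.random.default_rng(seed)
    actual = evaluate_method(predictions, graph, level,
                             annotated_metabolites=annotated_metabolites).f_measure

    if annotated_metabolites is None:
        annotated = sorted(set(predictions) & set(graph.metabolites))
    else:
        annotated = sorted(annotated_metabolites)
    na = len(annotated)
    rgls = {m: build_rgl(graph, m, level) for m in annotated}
    sizes = {m: len(predictions.get(m, ())) for m in annotated}
    nonempty = [m for m in annotated if sizes[m]]
    np_count = len(nonempty)
    uni = np.asarray(universe, dtype=object)

    def f_of(pred_sets: dict, mets: list) -> float:
        ncp = sum(1 for m in mets if pred_sets[m] & rgls[m])
        prec = ncp / np_count if np_count else 0.0
        rec = ncp / na
        return 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0

    ys = np.empty(k)
    for it in range(k):
        if scheme == "resample":
            shuffled = {
                m: set(uni[rng.choice(uni.size, size=sizes[m], replace=False)])
                for m in nonempty
            }
        else:
            perm = rng.permutation(np_count)
            shuffled = {m: set(predictions[nonempty[j]])
                        for m, j in zip(nonempty, perm)}
        ys[it] = f_of(shuffled, nonempty)
    p = float(np.mean(actual <= ys))
    return float(actual), float(ys.mean()), float(ys.std(ddof=1)), p


def empirical_p(actual_f: float, permuted_fs) -> float:
    """p = (1/n) sum_k 1[actual <= y_k] over a permuted F sample."""
    ys = np.asarray(permuted_fs, dtype=float)
    if ys.size == 0:
        raise ValueError("empty permutation sample")
    return float(np.mean(actual_f <= ys))


def lod_sweep(
    assoc_by_trait: dict,
    thresholds: list,
    graph: ReactionGraph,
    annotation,
    n_snps: int,
    genomewide_lod: float | None = None,
    flank_bp: int = 10_000,
    levels: tuple = RGL_LEVELS,
    annotated_metabolites: list | None = None,
) -> pd.DataFrame:
    """GWAS performance across a sweep of LOD thresholds.

    For each threshold, loci are re-called (the Bonferroni keep rule is
    relaxed to the sweep threshold itself when it lies below the
    genome-wide level), gene lists rebuilt, and metabolite-level metrics
    recomputed per RGL level.  Returns one row per (threshold, level).
    """
    from .loci import assign_candidate_genes, lod_threshold

    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    if genomewide_lod is None:
        genomewide_lod = lod_threshold(n_snps)
    rows = []
    for thr in thresholds:
        strict = thr >= genomewide_lod
        predictions = {}
        for trait, assoc in assoc_by_trait.items():
            loci = call_loci(assoc, lod_min=thr, n_snps_for_bonferroni=n_snps,
                             require_bonferroni=strict)
            genes = set()
            for loc in loci:
                genes |= set(assign_candidate_genes(loc, annotation, flank_bp))
            predictions[trait] = genes
        for level in levels:
            rep = evaluate_method(predictions, graph, level, method="GWAS",
                                  annotated_metabolites=annotated_metabolites)
            rows.append({
                "lod_threshold": thr, "level": level,
                "na": rep.na, "np": rep.np_, "ncp": rep.ncp,
                "precision": rep.precision, "recall": rep.recall,
                "f_measure": rep.f_measure,
            })
    return pd.DataFrame(rows)
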