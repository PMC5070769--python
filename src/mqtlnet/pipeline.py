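"""End-to-end orchestration: simulate -> gwas -> loci -> network ->
integrate -> evaluate, with deterministic per-stage seeds and a run
manifest recording config hash and output digests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import evaluate_method, permutation_test_f
from .gwas import compute_kinship, compute_structure_pcs, mlm_scan, preprocess_traits
from .integrate import candidate_table, collect_gene_lists, combine
from .loci import call_loci, common_loci, lod_threshold
from .network import (anova_select_metabolites, build_condition_network,
                      correlate, network_edge_table, permutation_pcc_threshold)
from .simulate import (SimulationConfig, simulate_all, write_external_calls_tsv,
                       write_gff3, write_ground_truth_json,
                       write_reaction_graph_json, write_timecourse_tsv,
                       write_traits_tsv, write_vcf)

__all__ = ["PipelineConfig", "PipelineResult", "RunManifest", "run_pipeline"]

STAGES = ("simulate", "gwas", "loci", "network", "integrate", "evaluate")


@dataclass
class PipelineConfig:
    """Single configuration object covering every stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_pcs: int = 3
    maf_min: float = 0.01
    min_complete: float = 0.40
    lod_min: float | None = None  # default: genome-wide log10(N)
    gap_bp: int = 10_000
    flank_bp: int = 10_000
    network_n_perm: int = 300
    network_fdr: float = 0.05
    anova_fdr: float = 0.05
    pcc_mode: str = "replicate_means"
    permutation_k: int = 1000
    rgl_levels: tuple = (1, 2, 3, 4)
    stages: tuple = STAGES

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["simulation"] = self.simulation.to_dict()
        d["rgl_levels"] = list(self.rgl_levels)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "rgl_levels" in d:
            d["rgl_levels"] = tuple(d["rgl_levels"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class RunManifest:
    config_hash: str
    stage_seeds: dict
    output_digests: dict
    version: str
    started: float
    finished: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: RunManifest
    study: object = None
    assoc_by_trait: dict = field(default_factory=dict)
    loci_by_trait: dict = field(default_factory=dict)
    common_loci_table: pd.DataFrame | None = None
    networks: list = field(default_factory=list)
    network_thresholds: dict = field(default_factory=dict)
    gene_lists: dict = field(default_factory=dict)
    candidates: pd.DataFrame | None = None
    evaluation: pd.DataFrame | None = None
    permutation: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base: int, k: int) -> int:
    return (int(base) * 1009 + k * 9973) % (2**31 - 1)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the requested stages in dependency order.

    A failing stage aborts with the stage name; outputs of completed
    stages are retained in the result (and on disk when ``out_dir`` is
    given).  Identical config gives identical results.
    """
    manifest = RunManifest(
        config_hash=_config_hash(config),
        stage_seeds={}, output_digests={},
        version=__version__, started=time.time(),
    )
    res = PipelineResult(config=config, manifest=manifest)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    seed = config.simulation.seed

    def write(name, fn):
        if out is None:
            return
        path = out / name
        fn(path)
        manifest.output_digests[name] = _digest(path)

    # --- simulate -----------------------------------------------------
    if any(s in stages for s in STAGES):
        try:
            manifest.stage_seeds["simulate"] = seed
            res.study = simulate_all(config.simulation)
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e
        if "simulate" in stages and out is not None:
            s = res.study
            write("genotypes.vcf", lambda p: write_vcf(s.genotypes, p))
            write("genes.gff3", lambda p: write_gff3(s.annotation, p))
            write("traits.tsv", lambda p: write_traits_tsv(s.traits, p))
            write("timecourse.tsv", lambda p: write_timecourse_tsv(s.timecourse, p))
            write("reaction_graph.json",
                  lambda p: write_reaction_graph_json(s.graph, p))
            write("external_calls.tsv",
                  lambda p: write_external_calls_tsv(s.external_intervals, p))
            write("ground_truth.json",
                  lambda p: write_ground_truth_json(s.truth, p))

    study = res.study
    n_snps = study.genotypes.n_snps
    lod_min = config.lod_min if config.lod_min is not None else lod_threshold(n_snps)

    # --- gwas ---------------------------------------------------------
    if "gwas" in stages:
        try:
            traits, _rep = preprocess_traits(study.traits, config.min_complete)
            K = compute_kinship(study.genotypes)
            Q = compute_structure_pcs(study.genotypes, config.n_pcs)
            for met in traits.columns:
                res.assoc_by_trait[met] = mlm_scan(
                    traits[met], study.genotypes, K, Q, maf_min=config.maf_min
                )
        except Exception as e:  # noqa: BLE001
            raise StageError("gwas", e) from e
        if out is not None:
            allassoc = pd.concat(res.assoc_by_trait.values(), ignore_index=True)
            write("associations.tsv",
                  lambda p: allassoc.to_csv(p, sep="\t", index=False))

    # --- loci ---------------------------------------------------------
    if "loci" in stages:
        if not res.assoc_by_trait:
            raise StageError("loci", RuntimeError("missing gwas output"))
        try:
            for met, assoc in res.assoc_by_trait.items():
                res.loci_by_trait[met] = call_loci(
                    assoc, lod_min=lod_min, n_snps_for_bonferroni=n_snps,
                    gap_bp=config.gap_bp,
                    require_bonferroni=lod_min >= lod_threshold(n_snps),
                )
            res.common_loci_table = common_loci(
                res.loci_by_trait, study.external_intervals,
                traits=list(study.traits.columns),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("loci", e) from e
        if out is not None:
            write("common_loci.tsv",
                  lambda p: res.common_loci_table.to_csv(p, sep="\t", index=False))

    # --- network ------------------------------------------------------
    if "network" in stages:
        try:
            conditions = study.timecourse.conditions()
            for i, cond in enumerate(conditions):
                selected, _tab = anova_select_metabolites(
                    study.timecourse, cond, fdr=config.anova_fdr
                )
                if not selected:
                    res.networks.append(build_condition_network(
                        pd.DataFrame(), None, cond))
                    res.network_thresholds[cond] = None
                    continue
                thr, _null = permutation_pcc_threshold(
                    study.timecourse, cond, selected,
                    n_perm=config.network_n_perm, fdr=config.network_fdr,
                    seed=_stage_seed(seed, 100 + i), mode=config.pcc_mode,
                )
                pcc = correlate(study.timecourse, cond, selected,
                                mode=config.pcc_mode)
                res.networks.append(build_condition_network(pcc, thr, cond))
                res.network_thresholds[cond] = thr
        except Exception as e:  # noqa: BLE001
            raise StageError("network", e) from e
        if out is not None:
            edges = network_edge_table(res.networks)
            write("network_edges.tsv",
                  lambda p: edges.to_csv(p, sep="\t", index=False))
            thr_tab = pd.DataFrame({
                "condition": list(res.network_thresholds),
                "pcc_threshold": list(res.network_thresholds.values()),
            })
            write("network_thresholds.tsv",
                  lambda p: thr_tab.to_csv(p, sep="\t", index=False))

    # --- integrate ----------------------------------------------------
    if "integrate" in stages:
        if not res.networks and "network" not in stages:
            raise StageError("integrate", RuntimeError("missing network output"))
        try:
            lists = collect_gene_lists(
                res.loci_by_trait, study.external_lists, res.networks,
                study.annotation, flank_bp=config.flank_bp,
            )
            res.gene_lists = combine(lists)
            res.candidates = candidate_table(
                res.gene_lists, res.loci_by_trait, res.networks,
                study.annotation, flank_bp=config.flank_bp,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("integrate", e) from e
        if out is not None:
            write("candidates.tsv",
                  lambda p: res.candidates.to_csv(p, sep="\t", index=False))

    # --- evaluate -----------------------------------------------------
    if "evaluate" in stages:
        if not res.gene_lists:
            raise StageError("evaluate", RuntimeError("missing integrate output"))
        try:
            annotated = list(study.graph.metabolites)
            rows = []
            for method in ("GWAS", "RIL", "IL", "network", "combined"):
                preds = {m: res.gene_lists[m].get(method, set())
                         for m in res.gene_lists}
                for level in config.rgl_levels:
                    rep = evaluate_method(preds, study.graph, level,
                                          annotated_metabolites=annotated,
                                          method=method)
                    rows.append({
                        "method": method, "level": level, "na": rep.na,
                        "np": rep.np_, "ncp": rep.ncp,
                        "precision": rep.precision, "recall": rep.recall,
                        "f_measure": rep.f_measure,
                    })
            res.evaluation = pd.DataFrame(rows)
            combined_preds = {m: res.gene_lists[m]["combined"]
                              for m in res.gene_lists}
            for level in config.rgl_levels:
                actual, mu, sd, p = permutation_test_f(
                    combined_preds, study.graph, level,
                    gene_universe=study.annotation.gene_ids,
                    k=config.permutation_k,
                    seed=_stage_seed(seed, 200 + level),
                    annotated_metabolites=annotated,
                )
                res.permutation[level] = {
                    "actual_f": actual, "permuted_mean": mu,
                    "permuted_sd": sd, "p": p,
                }
        except Exception as e:  # noqa: BLE001
            raise StageError("evaluate", e) from e
        if out is not None:
            write("evaluation.tsv",
                  lambda p: res.evaluation.to_csv(p, sep="\t", index=False))
            write("permutation_test.json",
                  lambda p: p.write_text(json.dumps(res.permutation, indent=1)))

    manifest.finished = time.time()
    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=1))
    return res
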