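"""Synthetic study generator with known ground truth.

Emulates the data structure of a metabolite GWAS in a selfing plant
population: structured inbred genotypes, metabolite traits driven by
planted causal enzyme genes, a KEGG-like bipartite metabolite-reaction
graph, dense time-course metabolite/transcript profiles under several
environmental conditions, and externally supplied mapping-population
(RIL/IL-style) mQTL calls.  Every generator is deterministic given the
configuration seed, and every identifier it emits resolves against the
generated annotation and reaction graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TIME_GRID_MINUTES",
    "SimulationConfig",
    "GenotypeMatrix",
    "GeneAnnotation",
    "ReactionGraph",
    "GroundTruth",
    "TimecourseDataset",
    "SimulatedStudy",
    "generate_genotypes",
    "generate_annotation",
    "generate_reaction_graph",
    "generate_traits",
    "generate_timecourse",
    "generate_external_qtl_calls",
    "simulate_all",
]

#: Eight environmental conditions (temperature-light combinations).
CONDITIONS = ("21-L", "21-D", "21-LL", "21-HL", "4-L", "4-D", "32-L", "32-D")

#: 23-point sampling grid in minutes: a 19-point linear series at 20-min
#: intervals (0..360) plus early/late samples at 5, 10, 640 and 1280 min.
TIME_GRID_MINUTES = tuple(sorted(set(range(0, 361, 20)) | {5, 10, 640, 1280}))

assert len(TIME_GRID_MINUTES) == 23


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Scales default to a desk-size analogue of a metabolite GWAS panel
    (hundreds of accessions, thousands of SNPs); the real study design the
    generator emulates is larger but structurally identical.
    """

    n_accessions: int = 200
    n_snps: int = 4000
    n_chromosomes: int = 5
    chrom_length_bp: int = 1_000_000
    n_subpops: int = 3
    fst_like_drift: float = 0.1
    n_genes: int = 300
    n_metabolites: int = 40
    n_causal_per_metabolite: int = 1
    heritability: float = 0.6
    n_conditions: int = 8
    n_timepoints: int = 23
    n_replicates: int = 3
    planted_edge_fraction: float = 0.2
    external_tp_rate: float = 0.6
    external_fp_rate: float = 0.5
    seed: int = 0
    # Generator knobs referenced by the operations but not part of the
    # core design grid.
    missing_fraction: float = 0.1
    causal_variance_share: float = 0.12
    n_trans_per_metabolite: int = 1
    trans_variance_share: float = 0.12
    causal_edge_rate: float = 0.75
    timecourse_noise_sd: float = 0.4
    flat_metabolite_fraction: float = 0.0

    def validate(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_subpops": self.n_subpops,
            "n_genes": self.n_genes,
            "n_metabolites": self.n_metabolites,
            "n_causal_per_metabolite": self.n_causal_per_metabolite,
            "n_conditions": self.n_conditions,
            "n_timepoints": self.n_timepoints,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise InvalidConfigError(f"{name} must be a count >= 1, got {value!r}")
        fractions = {
            "fst_like_drift": self.fst_like_drift,
            "planted_edge_fraction": self.planted_edge_fraction,
            "external_tp_rate": self.external_tp_rate,
            "external_fp_rate": self.external_fp_rate,
            "missing_fraction": self.missing_fraction,
            "causal_variance_share": self.causal_variance_share,
            "trans_variance_share": self.trans_variance_share,
            "causal_edge_rate": self.causal_edge_rate,
            "flat_metabolite_fraction": self.flat_metabolite_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.heritability < 1.0:
            raise InvalidConfigError(
                f"heritability must lie strictly in (0, 1), got {self.heritability!r}"
            )
        if self.n_trans_per_metabolite < 0:
            raise InvalidConfigError("n_trans_per_metabolite must be >= 0")
        genetic = self.causal_variance_share + (
            self.trans_variance_share if self.n_trans_per_metabolite else 0.0
        )
        if genetic > self.heritability:
            raise InvalidConfigError(
                "causal + trans variance shares cannot exceed heritability"
            )
        if self.n_snps < self.n_chromosomes:
            raise InvalidConfigError("n_snps must be >= n_chromosomes")
        if self.timecourse_noise_sd < 0:
            raise InvalidConfigError("timecourse_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # Independent deterministic stream per generation stage.
    return np.random.default_rng((int(config.seed), stage))


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs, 0/1 dosage (homozygous inbreds)."""

    dosages: np.ndarray  # (n_accessions, n_snps), int8
    accessions: list
    snp_ids: list
    chrom: np.ndarray  # int per SNP
    pos: np.ndarray  # 1-based bp per SNP

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0)
        return np.minimum(freq, 1.0 - freq)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)


@dataclass
class GeneAnnotation:
    """Gene models as non-overlapping 1-based inclusive spans."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> list:
        return list(self.genes["gene_id"])

    def span(self, gene_id: str) -> tuple:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return int(r["chrom"]), int(r["start"]), int(r["end"])


@dataclass
class ReactionGraph:
    """Bipartite metabolite <-> reaction graph.

    Each reaction carries an enzyme gene set, substrate/product metabolite
    sets and a pathway label.  Enzyme genes reference the gene annotation.
    """

    metabolites: list
    reactions: dict  # rid -> {"substrates", "products", "enzymes", "pathway"}

    def __post_init__(self) -> None:
        met_set = set(self.metabolites)
        touched = set()
        for rid, rec in self.reactions.items():
            mets = set(rec["substrates"]) | set(rec["products"])
            if not mets:
                raise ValueError(f"reaction {rid} touches no metabolite")
            if not rec["enzymes"]:
                raise ValueError(f"reaction {rid} carries no enzyme")
            if not rec.get("pathway"):
                raise ValueError(f"reaction {rid} has no pathway label")
            touched |= mets
        orphans = met_set - touched
        if orphans:
            raise ValueError(
                f"metabolites without any reaction: {sorted(orphans)}"
            )

    def reactions_of(self, metabolite: str) -> list:
        if metabolite not in set(self.metabolites):
            raise KeyError(f"unknown metabolite {metabolite!r}")
        return [
            rid
            for rid, rec in self.reactions.items()
            if metabolite in set(rec["substrates"]) | set(rec["products"])
        ]

    def metabolites_of(self, rid: str) -> set:
        rec = self.reactions[rid]
        return set(rec["substrates"]) | set(rec["products"])

    def enzymes(self, rid: str) -> set:
        return set(self.reactions[rid]["enzymes"])

    def degree(self, metabolite: str) -> int:
        return len(self.reactions_of(metabolite))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for m in self.metabolites:
            g.add_node(m, kind="metabolite")
        for rid, rec in self.reactions.items():
            g.add_node(rid, kind="reaction", pathway=rec["pathway"],
                       enzymes=sorted(rec["enzymes"]))
            for m in set(rec["substrates"]) | set(rec["products"]):
                g.add_edge(m, rid)
        return g


@dataclass
class GroundTruth:
    """Planted truth of the simulation."""

    causal_map: dict = field(default_factory=dict)  # met -> set[(gene, snp, effect)]
    trans_map: dict = field(default_factory=dict)  # met -> set[(gene, snp, effect)]
    planted_edges: set = field(default_factory=set)  # {(met, transcript, sign)}
    true_kinship: np.ndarray | None = None
    subpop_labels: dict = field(default_factory=dict)  # accession -> int


@dataclass
class TimecourseDataset:
    """Long-format time-course omics table over conditions.

    Columns: condition, kind (metabolite|transcript), feature, time
    (minutes), replicate, value.
    """

    data: pd.DataFrame
    time_grid: tuple = TIME_GRID_MINUTES
    n_replicates: int = 3

    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    def features(self, kind: str) -> list:
        return sorted(self.data.loc[self.data["kind"] == kind, "feature"].unique())

    def feature_matrix(self, condition: str, kind: str,
                       collapse_replicates: bool = True) -> pd.DataFrame:
        """Features x time points (replicate means) or x (time, replicate)."""
        sub = self.data[(self.data["condition"] == condition)
                        & (self.data["kind"] == kind)]
        if sub.empty:
            raise KeyError(f"no {kind} data for condition {condition!r}")
        if collapse_replicates:
            wide = sub.pivot_table(index="feature", columns="time",
                                   values="value", aggfunc="mean")
        else:
            wide = sub.pivot_table(index="feature", columns=["time", "replicate"],
                                   values="value")
        return wide.sort_index(axis=1)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(config: SimulationConfig):
    """Structured inbred genotypes under a Balding-Nichols-style model.

    Per-SNP ancestral frequencies are drawn uniformly; each subpopulation's
    frequency is a Beta draw around the ancestral value whose spread is
    controlled by ``fst_like_drift``; accessions are homozygous, so dosage
    is Bernoulli(subpop frequency).

    Returns ``(GenotypeMatrix, GroundTruth)`` with subpopulation labels and
    the realized (VanRaden-centered) kinship filled in.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    n, m = config.n_accessions, config.n_snps

    # SNP placement: near-even split across chromosomes, unique sorted
    # 1-based positions per chromosome.
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c, k in enumerate(per_chrom, start=1):
        if k > config.chrom_length_bp:
            raise InvalidConfigError(
                f"chromosome {c} too short for {k} distinct SNP positions"
            )
        p = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False) + 1)
        chrom.extend([c] * k)
        pos.extend(p.tolist())
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)

    ancestral = rng.uniform(0.1, 0.9, size=m)
    labels = np.arange(n) % config.n_subpops
    drift = config.fst_like_drift
    if config.n_subpops == 1 or drift == 0.0:
        subpop_freq = np.tile(ancestral, (config.n_subpops, 1))
    else:
        a = ancestral * (1.0 - drift) / drift
        b = (1.0 - ancestral) * (1.0 - drift) / drift
        subpop_freq = rng.beta(a, b, size=(config.n_subpops, m))
    dosages = (rng.random((n, m)) < subpop_freq[labels]).astype(np.int8)

    geno = GenotypeMatrix(
        dosages=dosages,
        accessions=[f"acc{i:04d}" for i in range(n)],
        snp_ids=[f"snp{i:06d}" for i in range(m)],
        chrom=chrom,
        pos=pos,
    )
    from .gwas import compute_kinship

    truth = GroundTruth(
        true_kinship=compute_kinship(geno),
        subpop_labels=dict(zip(geno.accessions, labels.tolist())),
    )
    return geno, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Tile non-overlapping gene models across the chromosomes."""
    config.validate()
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for c, g in enumerate(per_chrom, start=1):
        if g == 0:
            continue
        spacing = config.chrom_length_bp // g
        length = max(1, spacing // 2)
        if spacing < 2:
            raise InvalidConfigError(
                f"chromosome {c}: cannot tile {g} disjoint genes over "
                f"{config.chrom_length_bp} bp"
            )
        for i in range(g):
            start = i * spacing + 1
            end = start + length - 1
            if end > config.chrom_length_bp:
                raise InvalidConfigError(
                    f"gene span exceeds chromosome {c} length"
                )
            rows.append({
                "gene_id": f"gene{gid:05d}",
                "chrom": c,
                "start": start,
                "end": end,
                "strand": "+" if gid % 2 == 0 else "-",
            })
            gid += 1
    return GeneAnnotation(genes=pd.DataFrame(rows))


def _genes_with_snps(annotation: GeneAnnotation, genotypes: GenotypeMatrix) -> list:
    out = []
    for r in annotation.genes.itertuples(index=False):
        mask = (genotypes.chrom == r.chrom) & (genotypes.pos >= r.start) & (
            genotypes.pos <= r.end
        )
        if mask.any():
            out.append(r.gene_id)
    return out


# ---------------------------------------------------------------------------
# Reaction graph
# ---------------------------------------------------------------------------

def generate_reaction_graph(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    genotypes: GenotypeMatrix | None = None,
) -> ReactionGraph:
    """KEGG-like bipartite metabolite-reaction graph with pathway labels.

    A chain backbone guarantees every metabolite participates in at least
    one reaction; extra cross-reactions add realistic branching.  When
    ``genotypes`` is supplied, each metabolite's backbone reaction is
    guaranteed to carry at least ``n_causal_per_metabolite`` enzyme genes
    whose spans contain a SNP, so planted causal genes are recoverable at
    reaction-step distance 1.
    """
    config.validate()
    rng = _stage_rng(config, 2)
    mets = [f"met{i:03d}" for i in range(config.n_metabolites)]
    gene_ids = annotation.gene_ids
    eligible = _genes_with_snps(annotation, genotypes) if genotypes is not None else gene_ids
    if genotypes is not None and len(eligible) < config.n_metabolites * config.n_causal_per_metabolite:
        raise InvalidConfigError(
            "not enough SNP-containing genes to seed causal enzymes"
        )

    reactions: dict = {}
    rid = 0
    # Assign each metabolite a dedicated pool of candidate-causal enzymes.
    pool = list(rng.permutation(eligible))
    backbone_enzymes = {}
    for m in mets:
        backbone_enzymes[m], pool = (
            pool[: config.n_causal_per_metabolite],
            pool[config.n_causal_per_metabolite:],
        )

    def new_reaction(substrates, products, enzymes):
        nonlocal rid
        reactions[f"rxn{rid:03d}"] = {
            "substrates": sorted(map(str, substrates)),
            "products": sorted(map(str, products)),
            "enzymes": sorted({str(e) for e in enzymes}),
            "pathway": None,
        }
        rid += 1

    if len(mets) == 1:
        new_reaction([mets[0]], [], backbone_enzymes[mets[0]])
    else:
        # Chain backbone M_i -> M_{i+1}; reaction i carries the causal
        # enzymes of both endpoints so each metabolite's causal genes sit
        # at step 1.
        for i in range(len(mets) - 1):
            new_reaction(
                [mets[i]], [mets[i + 1]],
                backbone_enzymes[mets[i]] + backbone_enzymes[mets[i + 1]],
            )
    # Branching cross-reactions, each with its own enzyme.
    n_extra = max(1, len(mets) // 6)
    for _ in range(n_extra):
        a, b = rng.choice(len(mets), size=2, replace=False)
        enz = [str(rng.choice(gene_ids))]
        new_reaction([mets[a]], [mets[b]], enz)

    # Pathway labels: chunk the reaction list into pathways of ~6 reactions.
    rids = sorted(reactions)
    for i, r in enumerate(rids):
        reactions[r]["pathway"] = f"path{i // 6:02d}"

    return ReactionGraph(metabolites=mets, reactions=reactions)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def generate_traits(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    graph: ReactionGraph,
    config: SimulationConfig,
):
    """Metabolite traits with planted causal SNPs.

    Each trait is the sum of (i) a biochemical causal component from SNPs
    inside step-1 enzyme genes of the metabolite (variance share
    ``causal_variance_share``), (ii) a trans-regulatory component from
    SNPs in random non-enzyme genes (share ``trans_variance_share``;
    these loci are mappable but their genes are not pathway enzymes,
    which is what limits GWAS precision in real metabolite panels),
    (iii) a polygenic term with covariance proportional to the realized
    kinship (share = heritability minus the causal shares), and (iv)
    white noise.  Values are exponentiated so intensities are strictly
    positive (downstream preprocessing log-transforms them back), and a
    ``missing_fraction`` of entries is masked at random.

    Returns ``(TraitTable as DataFrame, GroundTruth with causal_map and
    trans_map)``.
    """
    config.validate()
    rng = _stage_rng(config, 3)
    n = genotypes.n_accessions
    maf = genotypes.maf

    # Polygenic factor from the realized kinship.
    from .gwas import compute_kinship

    K = compute_kinship(genotypes)
    w, V = np.linalg.eigh(K)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    h2 = config.heritability
    c_share = config.causal_variance_share
    t_share = config.trans_variance_share if config.n_trans_per_metabolite else 0.0
    p_share = h2 - c_share - t_share

    gene_snps = {}
    for r in annotation.genes.itertuples(index=False):
        mask = (genotypes.chrom == r.chrom) & (genotypes.pos >= r.start) & (
            genotypes.pos <= r.end
        )
        idx = np.flatnonzero(mask)
        if idx.size:
            gene_snps[r.gene_id] = idx

    def standardize(v):
        s = v.std()
        if s == 0:
            return np.zeros_like(v, dtype=float)
        return (v - v.mean()) / s

    def snp_component(genes, total_share):
        entries = set()
        part = np.zeros(n)
        per_snp_share = total_share / max(1, len(genes))
        for g in genes:
            idx = gene_snps[g]
            # Prefer a common SNP inside the gene so the signal is mappable.
            best = idx[np.argmax(maf[idx])]
            x = standardize(genotypes.dosages[:, best].astype(float))
            effect = np.sqrt(per_snp_share)
            part = part + effect * x
            entries.add((str(g), genotypes.snp_ids[best], float(effect)))
        return part, entries

    causal_map = {}
    trans_map = {}
    values = {}
    used_causal: set = set()
    for met in graph.metabolites:
        step1 = set()
        for rid in graph.reactions_of(met):
            step1 |= graph.enzymes(rid)
        candidates = [g for g in sorted(step1) if g in gene_snps]
        # Prefer enzymes not already causal for another metabolite so each
        # causal transcript tracks a single metabolite's trajectory.
        fresh = [g for g in candidates if g not in used_causal]
        if len(fresh) >= config.n_causal_per_metabolite:
            candidates = fresh
        if len(candidates) < config.n_causal_per_metabolite:
            raise InvalidConfigError(
                f"metabolite {met}: only {len(candidates)} step-1 enzymes "
                f"contain SNPs, need {config.n_causal_per_metabolite}"
            )
        chosen = list(rng.choice(candidates, size=config.n_causal_per_metabolite,
                                 replace=False))
        used_causal.update(map(str, chosen))
        causal_part, causal_map[met] = snp_component(chosen, c_share)

        trans_part = np.zeros(n)
        trans_map[met] = set()
        if config.n_trans_per_metabolite:
            trans_pool = [g for g in gene_snps if g not in step1]
            trans_genes = list(rng.choice(
                sorted(trans_pool), size=config.n_trans_per_metabolite,
                replace=False))
            trans_part, trans_map[met] = snp_component(trans_genes, t_share)

        poly = standardize(L @ rng.standard_normal(n)) * np.sqrt(p_share)
        noise = rng.standard_normal(n) * np.sqrt(1.0 - h2)
        latent = causal_part + trans_part + poly + noise
        y = np.exp(latent)
        if config.missing_fraction > 0:
            mask = rng.random(n) < config.missing_fraction
            y = y.astype(float)
            y[mask] = np.nan
        values[met] = y

    traits = pd.DataFrame(values, index=genotypes.accessions)
    truth = GroundTruth(causal_map=causal_map, trans_map=trans_map)
    return traits, truth


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------

def _latent_curve(rng: np.random.Generator, n_points: int,
                  phi: float = 0.3) -> np.ndarray:
    """Latent trajectory shared by a planted pair: AR(1), z-scored.

    The autocorrelation is kept mild (phi = 0.3) on purpose: the
    downstream network-threshold calibration shuffles each metabolite's
    time order and treats the shuffled correlations as the null, which is
    only honest when unrelated profiles are close to exchangeable in
    time.  Strongly smooth latents (e.g. smoothed random walks) carry so
    much low-frequency power that two independent curves correlate
    heavily by chance, which the shuffled null cannot represent.  Planted
    pairs share the whole trajectory, so their correlation does not
    depend on its smoothness.
    """
    x = np.empty(n_points)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_points):
        x[t] = phi * x[t - 1] + innov_sd * rng.standard_normal()
    sd = x.std()
    if sd == 0:
        return np.zeros(n_points)
    return (x - x.mean()) / sd


def plant_edges(
    config: SimulationConfig,
    causal_map: dict,
    transcripts: list,
) -> set:
    """Choose the metabolite-transcript pairs that share a latent trajectory.

    Each metabolite's causal-gene transcript is planted with probability
    ``causal_edge_rate`` (transcriptional co-variation with the metabolite
    is not guaranteed in real data); in addition a
    ``planted_edge_fraction`` of the transcript universe is attached to
    random metabolites as co-regulated partners with random sign.
    """
    rng = _stage_rng(config, 4)
    edges = set()
    mets = sorted(causal_map)
    tset = set(transcripts)
    taken: set = set()
    # The time-course study is a single fixed dataset, so the fraction of
    # causal genes that co-vary transcriptionally is treated as a design
    # fraction: exactly round(rate * n) pairs are planted (random subset).
    candidates = []
    for met in mets:
        for gene, _snp, _eff in sorted(causal_map[met]):
            if gene in tset and gene not in taken:
                candidates.append((met, gene))
                taken.add(gene)
    n_plant = int(round(config.causal_edge_rate * len(candidates)))
    if n_plant:
        picked = rng.choice(len(candidates), size=n_plant, replace=False)
        for j in picked:
            met, gene = candidates[int(j)]
            edges.add((met, gene, 1))
    taken = {g for _m, g, _s in edges}
    n_extra = int(round(config.planted_edge_fraction * len(transcripts)))
    taken = {t for _m, t, _s in edges}
    free = sorted(tset - taken)
    n_extra = min(n_extra, len(free))
    if n_extra and mets:
        extra_t = rng.choice(free, size=n_extra, replace=False)
        for t in extra_t:
            met = mets[int(rng.integers(len(mets)))]
            sign = 1 if rng.random() < 0.5 else -1
            edges.add((met, str(t), sign))
    return edges


def generate_timecourse(
    config: SimulationConfig,
    planted_edges: set,
    metabolites: list,
    transcripts: list,
) -> TimecourseDataset:
    """Per-condition time-course profiles with planted correlations.

    Planted (metabolite, transcript, sign) pairs share a smooth latent
    trajectory per condition, observed with i.i.d. Gaussian replicate
    noise of sd ``timecourse_noise_sd``; unplanted transcripts are
    time-stationary noise; a ``flat_metabolite_fraction`` of unplanted
    metabolites has no time trend at all (removed downstream by the ANOVA
    filter); the remaining metabolites follow their own latent curves.
    """
    config.validate()
    rng = _stage_rng(config, 5)
    known = set(metabolites) | set(transcripts)
    for met, tr, sign in planted_edges:
        if met not in set(metabolites) or tr not in set(transcripts):
            raise ValueError(f"planted edge references unknown feature: {(met, tr)}")
        if sign not in (-1, 1):
            raise ValueError(f"planted edge sign must be +/-1, got {sign!r}")
    del known

    if config.n_timepoints == 23:
        grid = TIME_GRID_MINUTES
    else:
        grid = tuple(int(t) for t in np.arange(config.n_timepoints) * 20)
    conditions = CONDITIONS[: config.n_conditions]
    T, R = len(grid), config.n_replicates
    noise = config.timecourse_noise_sd

    planted_by_met: dict = {}
    for met, tr, sign in planted_edges:
        planted_by_met.setdefault(met, []).append((tr, sign))
    planted_transcripts = {tr for _, lst in planted_by_met.items() for tr, _ in lst}

    unplanted_mets = [m for m in metabolites if m not in planted_by_met]
    n_flat = int(round(config.flat_metabolite_fraction * len(metabolites)))
    flat_mets = set(unplanted_mets[:n_flat])

    transcript_profile = {}  # transcript -> (metabolite, sign)
    for m, lst in planted_by_met.items():
        for tr, sign in lst:
            if tr in transcript_profile and transcript_profile[tr][0] != m:
                raise ValueError(
                    f"transcript {tr!r} planted against two metabolites; "
                    "each transcript can follow only one latent trajectory"
                )
            transcript_profile[tr] = (m, sign)

    frames = []
    times = np.asarray(grid)
    reps = np.arange(R)
    for cond in conditions:
        # Latents per metabolite (shared with its planted transcripts).
        met_latent = {
            m: (np.zeros(T) if m in flat_mets else _latent_curve(rng, T))
            for m in metabolites
        }
        blocks = []
        for kind, features in (("metabolite", metabolites),
                               ("transcript", transcripts)):
            vals = np.empty((len(features), T, R))
            for i, f in enumerate(features):
                if kind == "metabolite":
                    base = met_latent[f][:, None]
                    vals[i] = base + noise * rng.standard_normal((T, R))
                elif f in transcript_profile:
                    m, sign = transcript_profile[f]
                    base = sign * met_latent[m][:, None]
                    vals[i] = base + noise * rng.standard_normal((T, R))
                else:
                    # Time-stationary expression noise.
                    vals[i] = rng.standard_normal((T, R))
            blocks.append(pd.DataFrame({
                "condition": cond,
                "kind": kind,
                "feature": np.repeat(features, T * R),
                "time": np.tile(np.repeat(times, R), len(features)),
                "replicate": np.tile(reps, len(features) * T),
                "value": vals.ravel(),
            }))
        frames.extend(blocks)

    df = pd.concat(frames, ignore_index=True)
    return TimecourseDataset(data=df, time_grid=grid, n_replicates=R)


# ---------------------------------------------------------------------------
# External mapping-population calls
# ---------------------------------------------------------------------------

def generate_external_qtl_calls(
    truth: GroundTruth,
    annotation: GeneAnnotation,
    config: SimulationConfig,
    methods: tuple = ("RIL", "IL"),
    flank_bp: int = 5000,
):
    """Emulated RIL/IL-style mQTL gene calls with support intervals.

    Each true causal gene is reported with probability
    ``external_tp_rate``; per metabolite and method, up to three decoy
    genes are added, each with probability ``external_fp_rate``.  Every
    reported gene carries a 1-based inclusive interval containing it.

    Returns ``(gene_lists, intervals)`` where ``gene_lists`` maps
    metabolite -> method -> set of genes and ``intervals`` is a DataFrame
    (metabolite, method, gene, chrom, start, end).
    """
    config.validate()
    rng = _stage_rng(config, 6)
    gene_ids = annotation.gene_ids
    lists: dict = {}
    rows = []
    mets = sorted(truth.causal_map)
    # Each emulated mapping dataset is a single fixed set of published
    # calls, so its recall is treated as a design fraction: for each
    # method, exactly round(tp_rate * n) of the causal (met, gene) pairs
    # are reported (random subset).
    reported: dict = {}
    for method in methods:
        pairs = [(m, g) for m in mets
                 for g in sorted({g for g, _s, _e in truth.causal_map[m]})]
        n_tp = int(round(config.external_tp_rate * len(pairs)))
        hit = set()
        if n_tp:
            picked = rng.choice(len(pairs), size=n_tp, replace=False)
            hit = {pairs[int(j)] for j in picked}
        reported[method] = hit
    for met in mets:
        lists[met] = {}
        causal_genes = sorted({g for g, _s, _e in truth.causal_map[met]})
        for method in methods:
            chosen = {g for g in causal_genes if (met, g) in reported[method]}
            n_decoys = int(rng.binomial(4, config.external_fp_rate))
            if n_decoys:
                decoys = rng.choice(gene_ids, size=n_decoys, replace=False)
                chosen |= {str(d) for d in decoys if d not in causal_genes}
            lists[met][method] = chosen
            for g in sorted(chosen):
                chrom, start, end = annotation.span(g)
                rows.append({
                    "metabolite": met, "method": method, "gene": g,
                    "chrom": chrom,
                    "start": max(1, start - flank_bp),
                    "end": end + flank_bp,
                })
    intervals = pd.DataFrame(
        rows, columns=["metabolite", "method", "gene", "chrom", "start", "end"]
    )
    return lists, intervals


# ---------------------------------------------------------------------------
# Orchestration + writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """All pipeline inputs plus the planted ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    annotation: GeneAnnotation
    graph: ReactionGraph
    traits: pd.DataFrame
    timecourse: TimecourseDataset
    external_lists: dict
    external_intervals: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator in dependency order under one seed."""
    config.validate()
    genotypes, truth = generate_genotypes(config)
    annotation = generate_annotation(config)
    graph = generate_reaction_graph(config, annotation, genotypes)
    traits, trait_truth = generate_traits(genotypes, annotation, graph, config)
    truth.causal_map = trait_truth.causal_map
    truth.trans_map = trait_truth.trans_map
    transcripts = annotation.gene_ids
    truth.planted_edges = plant_edges(config, truth.causal_map, transcripts)
    timecourse = generate_timecourse(
        config, truth.planted_edges, graph.metabolites, transcripts
    )
    external_lists, external_intervals = generate_external_qtl_calls(
        truth, annotation, config
    )
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        annotation=annotation,
        graph=graph,
        traits=traits,
        timecourse=timecourse,
        external_lists=external_lists,
        external_intervals=external_intervals,
        truth=truth,
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF v4.2 (homozygous 0/0 / 1/1 calls)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mqtlnet-simulate\n")
        for c in sorted(set(genotypes.chrom.tolist())):
            length = int(genotypes.pos[genotypes.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.accessions) + "\n")
        for j in range(genotypes.n_snps):
            calls = "\t".join(
                "1/1" if d else "0/0" for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}"
                f"\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_gff3(annotation: GeneAnnotation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tmqtlnet\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t."
                f"\tID={r.gene_id}\n"
            )


def read_gff3(path) -> GeneAnnotation:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "gene_id": attrs["ID"], "chrom": int(f[0]),
                "start": int(f[3]), "end": int(f[4]), "strand": f[6],
            })
    return GeneAnnotation(genes=pd.DataFrame(rows))


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF of homozygous biallelic calls into 0/1 dosages.

    Heterozygous calls (unexpected in inbred panels) count as carrying
    the alternate allele; missing calls count as reference.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    snp_ids, chrom, pos, rows = [], [], [], []
    for i, v in enumerate(vcf):
        snp_ids.append(v.ID if v.ID else f"snp{i:06d}")
        chrom.append(int(v.CHROM))
        pos.append(int(v.POS))
        rows.append(np.isin(v.gt_types, (1, 3)).astype(np.int8))
    return GenotypeMatrix(
        dosages=np.asarray(rows, dtype=np.int8).T,
        accessions=accessions, snp_ids=snp_ids,
        chrom=np.asarray(chrom), pos=np.asarray(pos),
    )


def write_traits_tsv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="accession")


def read_traits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def read_timecourse_tsv(path) -> TimecourseDataset:
    df = pd.read_csv(path, sep="\t")
    grid = tuple(sorted(df["time"].unique()))
    n_reps = int(df["replicate"].nunique())
    return TimecourseDataset(data=df, time_grid=grid, n_replicates=n_reps)


def read_external_calls_tsv(path):
    """Load external mQTL calls; returns (gene lists, intervals table)."""
    intervals = pd.read_csv(path, sep="\t")
    lists: dict = {}
    for r in intervals.itertuples(index=False):
        lists.setdefault(r.metabolite, {}).setdefault(r.method, set()).add(r.gene)
    return lists, intervals


def write_timecourse_tsv(tc: TimecourseDataset, path) -> None:
    tc.data.to_csv(path, sep="\t", index=False)


def write_reaction_graph_json(graph: ReactionGraph, path) -> None:
    payload = {"metabolites": list(graph.metabolites),
               "reactions": graph.reactions}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_reaction_graph_json(path) -> ReactionGraph:
    payload = json.loads(Path(path).read_text())
    return ReactionGraph(metabolites=payload["metabolites"],
                         reactions=payload["reactions"])


def write_external_calls_tsv(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "causal_map": {
            met: sorted([list(e) for e in entries])
            for met, entries in truth.causal_map.items()
        },
        "trans_map": {
            met: sorted([list(e) for e in entries])
            for met, entries in truth.trans_map.items()
        },
        "planted_edges": sorted([list(e) for e in truth.planted_edges]),
        "subpop_labels": truth.subpop_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
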