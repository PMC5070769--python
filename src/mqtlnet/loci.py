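"""Locus identification and locus interrogation.

Converts per-SNP association results into candidate loci: SNPs above the
LOD threshold are grouped when consecutive same-chromosome SNPs lie less
than 10 kb apart, groups without a Bonferroni-significant SNP are
discarded, and genes overlapping the (flanked) locus span become
candidates.  Also provides pairwise LD, haplotype clustering with
Ward's minimum-variance method, and cross-method locus overlap tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .simulate import GeneAnnotation

__all__ = [
    "Locus",
    "HaplotypeReport",
    "lod_threshold",
    "call_loci",
    "assign_candidate_genes",
    "ld_r2",
    "haplotype_analysis",
    "common_loci",
    "loci_to_bed",
]


def lod_threshold(n_snps: int) -> float:
    """Genome-wide LOD threshold -log10(1/N) = log10(N)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return float(np.log10(n_snps))


@dataclass
class Locus:
    """A group of associated SNPs for one trait."""

    trait: str
    chrom: int
    start: int
    end: int
    snp_ids: list
    lead_snp: str
    lead_lod: float
    contains_bonferroni_snp: bool
    candidate_genes: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


def call_loci(
    results: pd.DataFrame,
    lod_min: float,
    n_snps_for_bonferroni: int,
    gap_bp: int = 10_000,
    alpha: float = 0.05,
    require_bonferroni: bool = True,
) -> list:
    """Group threshold-passing SNPs into loci.

    SNPs with LOD strictly above ``lod_min`` are retained; consecutive
    retained SNPs on a chromosome are merged while their distance is
    strictly less than ``gap_bp``; each group must contain at least one
    SNP with Bonferroni-corrected p < ``alpha`` (p * N < alpha) unless
    ``require_bonferroni`` is False, in which case the LOD threshold
    itself is the keep rule (used for suggestive-threshold sweeps).
    The lead SNP is the member with maximal LOD, ties broken by smaller
    position.
    """
    traits = results["trait"].unique()
    if len(traits) != 1:
        raise ValueError(f"call_loci expects one trait, got {list(traits)}")
    trait = traits[0]
    hits = results[results["lod"] > lod_min].sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    loci: list = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            block = grp.iloc[s:e + 1]
            has_bonf = bool((block["p"] * n_snps_for_bonferroni < alpha).any())
            if require_bonferroni and not has_bonf:
                continue
            best_lod = block["lod"].max()
            leads = block[block["lod"] == best_lod].sort_values("pos")
            lead = leads.iloc[0]
            loci.append(Locus(
                trait=trait,
                chrom=int(chrom),
                start=int(block["pos"].min()),
                end=int(block["pos"].max()),
                snp_ids=list(block["snp"]),
                lead_snp=str(lead["snp"]),
                lead_lod=float(best_lod),
                contains_bonferroni_snp=has_bonf,
            ))
    return loci


def assign_candidate_genes(
    locus: Locus, annotation: GeneAnnotation, flank_bp: int = 10_000
) -> list:
    """Genes overlapping the locus extended by ``flank_bp`` on both sides.

    Overlap is on 1-based inclusive intervals, so a gene exactly abutting
    the flanked boundary is included.
    """
    genes = annotation.genes
    if locus.chrom not in set(genes["chrom"].unique()):
        raise KeyError(f"chromosome {locus.chrom} absent from annotation")
    lo = locus.start - flank_bp
    hi = locus.end + flank_bp
    sub = genes[(genes["chrom"] == locus.chrom)
                & (genes["start"] <= hi) & (genes["end"] >= lo)]
    return list(sub["gene_id"])


def ld_r2(dosage_a, dosage_b):
    """Squared Pearson correlation of two dosage vectors plus its p-value.

    Missing entries are removed pairwise.  A zero-variance vector makes
    the statistic undefined; (nan, nan) is returned rather than 0.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need >= 3 complete genotype pairs")
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r * r), float(p)


@dataclass
class HaplotypeReport:
    """Haplotype enumeration, Ward clusters and trait contrasts."""

    haplotypes: pd.DataFrame  # haplotype, count, informative, cluster
    accession_clusters: pd.Series  # cluster label per accession (informative only)
    anova_p: float
    pairwise: pd.DataFrame  # cluster_a, cluster_b, p_raw, p_bonferroni, significant
    cluster_summary: pd.DataFrame  # cluster, n, mean, sd


def haplotype_analysis(
    gene_dosages: pd.DataFrame,
    trait: pd.Series,
    n_clusters: int,
    informative_min: int = 3,
    alpha: float = 0.01,
) -> HaplotypeReport:
    """Cluster gene haplotypes and test trait differences between clusters.

    ``gene_dosages`` is accessions x SNPs (0/1).  Accessions with any
    missing genotype are excluded.  Haplotypes carried by at least
    ``informative_min`` accessions (i.e. more than two at the default) are
    informative and are clustered with Ward's minimum-variance method on
    Hamming distances between allele strings; the trait is compared
    between clusters by one-way ANOVA with Bonferroni-corrected pairwise
    contrasts at ``alpha``.
    """
    complete = gene_dosages.dropna(axis=0)
    trait = trait.reindex(complete.index).dropna()
    complete = complete.loc[trait.index]
    hap_strings = complete.astype(int).astype(str).agg("".join, axis=1)
    counts = hap_strings.value_counts()
    if len(counts) < 2:
        raise ValueError("fewer than 2 distinct haplotypes; nothing to cluster")
    informative = counts[counts >= informative_min]
    if n_clusters > len(informative):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {len(informative)} informative haplotypes"
        )

    hap_mat = np.array([[int(ch) for ch in h] for h in informative.index])
    if len(informative) == n_clusters:
        labels = np.arange(1, n_clusters + 1)
    else:
        d = pdist(hap_mat, metric="hamming")
        Z = linkage(d, method="ward")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    hap_cluster = dict(zip(informative.index, labels.tolist()))

    hap_table = pd.DataFrame({
        "haplotype": counts.index,
        "count": counts.values,
        "informative": counts.values >= informative_min,
    })
    hap_table["cluster"] = hap_table["haplotype"].map(hap_cluster).astype("Int64")

    acc_clusters = hap_strings.map(hap_cluster).dropna().astype(int)
    groups = [trait.loc[acc_clusters[acc_clusters == c].index].to_numpy()
              for c in sorted(acc_clusters.unique())]
    if len(groups) < 2:
        raise ValueError("fewer than 2 populated clusters")
    anova_p = float(stats.f_oneway(*groups).pvalue)

    cluster_ids = sorted(acc_clusters.unique())
    pairs = list(combinations(cluster_ids, 2))
    rows = []
    for a, b in pairs:
        ga = trait.loc[acc_clusters[acc_clusters == a].index]
        gb = trait.loc[acc_clusters[acc_clusters == b].index]
        if len(ga) < 2 or len(gb) < 2:
            p_raw = float("nan")
        else:
            p_raw = float(stats.ttest_ind(ga, gb).pvalue)
        p_adj = min(1.0, p_raw * len(pairs)) if np.isfinite(p_raw) else float("nan")
        rows.append({
            "cluster_a": a, "cluster_b": b, "p_raw": p_raw,
            "p_bonferroni": p_adj,
            "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
        })
    summary = pd.DataFrame({
        "cluster": cluster_ids,
        "n": [len(g) for g in groups],
        "mean": [float(np.mean(g)) for g in groups],
        "sd": [float(np.std(g, ddof=1)) if len(g) > 1 else float("nan")
               for g in groups],
    })
    return HaplotypeReport(
        haplotypes=hap_table,
        accession_clusters=acc_clusters,
        anova_p=anova_p,
        pairwise=pd.DataFrame(rows),
        cluster_summary=summary,
    )


def common_loci(
    gwas_loci: dict,
    external_intervals: pd.DataFrame,
    traits: list | None = None,
) -> pd.DataFrame:
    """Cross-method locus support table.

    ``gwas_loci`` maps trait -> list of ``Locus``.  A locus is confirmed
    by an external method when any of that method's 1-based inclusive
    intervals for the same trait overlaps it.  When a trait universe is
    supplied, external traits outside it raise an error listing the
    mismatches.
    """
    if traits is not None:
        unknown = sorted(set(external_intervals["metabolite"]) - set(traits))
        if unknown:
            raise ValueError(f"external traits not matching any GWAS trait: {unknown}")
    methods = sorted(external_intervals["method"].unique())
    rows = []
    for trait, loci in sorted(gwas_loci.items()):
        ext = external_intervals[external_intervals["metabolite"] == trait]
        for loc in loci:
            row = {
                "trait": trait, "chrom": loc.chrom,
                "start": loc.start, "end": loc.end, "width": loc.width,
                "n_snps": len(loc.snp_ids), "lead_snp": loc.lead_snp,
                "gwas": True,
            }
            for method in methods:
                mi = ext[ext["method"] == method]
                hit = bool(((mi["chrom"] == loc.chrom)
                            & (mi["start"] <= loc.end)
                            & (mi["end"] >= loc.start)).any())
                row[method.lower()] = hit
            rows.append(row)
    cols = ["trait", "chrom", "start", "end", "width", "n_snps", "lead_snp",
            "gwas"] + [m.lower() for m in methods]
    return pd.DataFrame(rows, columns=cols)


def loci_table(loci_by_trait: dict, annotation: GeneAnnotation | None = None,
               flank_bp: int = 10_000) -> pd.DataFrame:
    """Flat loci table, one row per locus, with candidate genes attached."""
    rows = []
    for trait, loci in sorted(loci_by_trait.items()):
        for loc in loci:
            genes = (assign_candidate_genes(loc, annotation, flank_bp)
                     if annotation is not None else loc.candidate_genes)
            rows.append({
                "trait": trait, "chrom": loc.chrom, "start": loc.start,
                "end": loc.end, "width": loc.width,
                "n_snps": len(loc.snp_ids), "lead_snp": loc.lead_snp,
                "lead_lod": loc.lead_lod,
                "bonferroni": loc.contains_bonferroni_snp,
                "genes": ",".join(genes),
            })
    return pd.DataFrame(rows, columns=["trait", "chrom", "start", "end",
                                       "width", "n_snps", "lead_snp",
                                       "lead_lod", "bonferroni", "genes"])


def read_loci_table(path) -> dict:
    """Load a loci table back into trait -> list of Locus."""
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    for r in df.itertuples(index=False):
        genes = [] if pd.isna(r.genes) or not r.genes else str(r.genes).split(",")
        out.setdefault(r.trait, []).append(Locus(
            trait=r.trait, chrom=int(r.chrom), start=int(r.start),
            end=int(r.end), snp_ids=[], lead_snp=str(r.lead_snp),
            lead_lod=float(r.lead_lod),
            contains_bonferroni_snp=bool(r.bonferroni),
            candidate_genes=list(genes),
        ))
    return out


def loci_to_bed(loci: list) -> pd.DataFrame:
    """Loci as BED intervals (0-based half-open: start-1, end)."""
    return pd.DataFrame({
        "chrom": [l.chrom for l in loci],
        "start": [l.start - 1 for l in loci],
        "end": [l.end for l in loci],
        "name": [f"{l.trait}:{l.lead_snp}" for l in loci],
        "score": [l.lead_lod for l in loci],
    })
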