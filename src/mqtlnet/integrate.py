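"""Cross-method assembly of per-metabolite candidate gene lists.

The combined strategy predicts a gene for a metabolite only when it is a
network neighbor AND appears in at least one mapping method's list
(GWAS, RIL or IL) for that metabolite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .loci import assign_candidate_genes

__all__ = ["collect_gene_lists", "combine", "candidate_table"]

MAPPING_METHODS = ("GWAS", "RIL", "IL")


def collect_gene_lists(
    loci_by_trait: dict,
    external_lists: dict,
    networks: list,
    annotation,
    flank_bp: int = 10_000,
) -> dict:
    """Per-metabolite gene lists for every method.

    GWAS = union of candidate genes over the trait's loci; network =
    union of transcript neighbors over all condition networks; RIL/IL
    lists are passed through.  Every gene id must resolve against the
    annotation.

    Returns metabolite -> {method -> set of gene ids}.
    """
    universe = set(annotation.gene_ids)
    mets = sorted(set(loci_by_trait) | set(external_lists)
                  | {m for n in networks for m in n.metabolites()})
    out: dict = {}
    for met in mets:
        entry = {m: set() for m in MAPPING_METHODS}
        entry["network"] = set()
        for loc in loci_by_trait.get(met, []):
            entry["GWAS"] |= set(assign_candidate_genes(loc, annotation, flank_bp))
        for method, genes in external_lists.get(met, {}).items():
            entry[method] = set(genes)
        for n in networks:
            entry["network"] |= n.neighbors(met)
        for method, genes in entry.items():
            stray = genes - universe
            if stray:
                raise ValueError(
                    f"{method} list for {met} contains unknown genes: "
                    f"{sorted(stray)[:5]}"
                )
        out[met] = entry
    return out


def combine(lists: dict) -> dict:
    """Fill the 'combined' list: network AND at least one mapping method."""
    out = {}
    for met, entry in lists.items():
        entry = {k: set(v) for k, v in entry.items()}
        network = entry.get("network", set())
        mapping = set()
        for m in MAPPING_METHODS:
            mapping |= entry.get(m, set())
        entry["combined"] = network & mapping
        out[met] = entry
    return out


def candidate_table(
    lists: dict,
    loci_by_trait: dict,
    networks: list,
    annotation,
    flank_bp: int = 10_000,
) -> pd.DataFrame:
    """One row per supported (metabolite, gene) pair.

    Columns: metabolite, gene, lod (lead-SNP LOD of a GWAS locus whose
    candidate genes include the gene; NaN when GWAS-unsupported), T/F
    support flags per method, n_methods, and one signed PCC column per
    condition (0 when the pair is below that condition's threshold, NaN
    when the gene is not a network neighbor at all).
    """
    conditions = [n.condition for n in networks]
    rows = []
    for met in sorted(lists):
        entry = lists[met]
        supported = set()
        for m in (*MAPPING_METHODS, "network"):
            supported |= entry.get(m, set())
        for gene in sorted(supported):
            flags = {m: gene in entry.get(m, set())
                     for m in ("GWAS", "network", "RIL", "IL")}
            lod = np.nan
            if flags["GWAS"]:
                for loc in loci_by_trait.get(met, []):
                    if gene in set(assign_candidate_genes(loc, annotation,
                                                          flank_bp)):
                        lod = max(loc.lead_lod, lod) if np.isfinite(lod) \
                            else loc.lead_lod
            row = {
                "metabolite": met, "gene": gene, "lod": lod,
                "gwas": flags["GWAS"], "network": flags["network"],
                "ril": flags["RIL"], "il": flags["IL"],
                "n_methods": int(sum(flags.values())),
            }
            for n in networks:
                if not flags["network"]:
                    row[n.condition] = np.nan
                else:
                    row[n.condition] = n.edges.get((met, gene), 0.0)
            rows.append(row)
    cols = ["metabolite", "gene", "lod", "gwas", "network", "ril", "il",
            "n_methods", *conditions]
    return pd.DataFrame(rows, columns=cols)
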