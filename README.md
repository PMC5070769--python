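# mqtlnet

Integrative candidate-gene discovery for plant primary metabolism:
mixed-model metabolite GWAS, metabolite–transcript correlation networks,
external mapping-population evidence, and a reaction-graph benchmarking
framework — exercised end-to-end on a synthetic study generator with
known ground truth.

## The problem

Genome-wide association mapping of metabolite levels (mQTL mapping) in
inbred plant panels readily finds loci, but rarely pinpoints the causal
gene: loci span many genes, and a large share of mQTL are regulatory
("trans") loci far from any pathway enzyme. Correlation networks between
metabolites and transcripts across dense environmental time courses
suggest functional links, but co-expression alone is also noisy. This
package implements a combined strategy: **predict a gene for a
metabolite only when it is a network neighbor of the metabolite AND
falls inside a mapped locus of at least one quantitative-genetics
method** (GWAS, recombinant inbred lines, introgression lines), and a
benchmarking framework that scores every method against reference gene
lists derived from a metabolic reaction graph.

## Methods at a glance

**Association scan.** Per SNP, the mixed linear model

    y = μ + Qγ + xβ + u + e,   u ~ N(0, σg² K),   e ~ N(0, σe² I)

with VanRaden kinship `K`, principal-component covariates `Q`, the
variance ratio δ = σg²/σe² estimated once per trait by REML on the
spectral decomposition of `K` and reused for every SNP (P3D), and a
Wald test on β. SNPs with LOD = −log10(p) above the genome-wide level
log10(N) are grouped into loci when consecutive SNPs lie < 10 kb apart;
groups are kept only if they contain a Bonferroni-significant SNP, and
genes overlapping the locus ± 10 kb become candidates.

**Networks.** Per environmental condition, metabolites with a
significant time effect (one-way ANOVA, Benjamini–Hochberg FDR < 0.05)
are correlated (Pearson, over replicate-mean time points) against the
full transcript universe; edges require |PCC| above a
permutation-calibrated threshold controlling the edge FDR below 5%.

**Evaluation.** Reference gene lists RGL1–RGL3 collect enzymes within
1–3 reaction steps of a metabolite in a bipartite metabolite–reaction
graph; RGL4 collects all enzymes of the pathways its direct reactions
belong to. With `Na` annotated metabolites, `Np` metabolites that have
predictions and `Ncp` whose prediction intersects their RGL:

    precision = Ncp / Np,  recall = Ncp / Na,  F = 2PR / (P + R)

A permutation test replaces each metabolite's prediction by an equally
sized random gene draw and reports `p = (1/k) Σ 1[F_actual ≤ F_perm]`.

## Worked example

```python
from mqtlnet import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=0), permutation_k=200)
res = run_pipeline(cfg)
print(res.evaluation.pivot(index="level", columns="method", values="f_measure").round(3))
print(res.permutation[2])
```

prints

```
method   GWAS    IL    RIL  combined  network
level
1       0.603  0.60  0.658     0.829    0.795
2       0.603  0.65  0.658     0.829    0.795
3       0.603  0.65  0.658     0.829    0.821
4       0.630  0.65  0.658     0.829    0.821
{'actual_f': 0.8285714285714285, 'permuted_mean': 0.01885714285714286,
 'permuted_sd': 0.02403975785970047, 'p': 0.0}
```

Each row is a reference-list level, each column a prediction method.
The combined strategy attains the highest F-measure at every level:
intersecting network neighbors with mapped loci removes the spurious
members that drag down each single method, at a modest cost in recall.
The permutation line shows that the achieved combined F-measure (0.83)
is far beyond what equally sized random gene lists reach (0.019 ±
0.024), giving an empirical p of 0 at k = 200.

The same stages are available from the shell:

```bash
mqtlnet simulate --out sim --seed 1               # VCF/GFF3/TSV/JSON inputs
mqtlnet gwas --vcf sim/genotypes.vcf --traits sim/traits.tsv --out g
mqtlnet loci --assoc g/associations.tsv --gff sim/genes.gff3 --out l
mqtlnet network --timecourse sim/timecourse.tsv --seed 1 --out n
mqtlnet integrate --loci l/loci.tsv --gff sim/genes.gff3 \
    --external sim/external_calls.tsv --edges n/network_edges.tsv --out i
mqtlnet evaluate --loci l/loci.tsv --gff sim/genes.gff3 \
    --external sim/external_calls.tsv --edges n/network_edges.tsv \
    --graph sim/reaction_graph.json --out e
mqtlnet run --out run_out --seed 1                # all of the above at once
mqtlnet lod-threshold 199455                      # genome-wide LOD: 5.2998
```

The same subcommands accept real data in the same formats (VCF
genotypes, TSV trait and time-course tables, TSV external mQTL calls,
JSON reaction graph).

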