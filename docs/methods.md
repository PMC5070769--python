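# Methods

This note documents the models, the synthetic-study generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Mixed-model association scan

Traits are filtered to ≥ 40% completeness (boundary kept) and
natural-log transformed; the log base only rescales effect estimates,
never p-values. Missing trait values are dropped pairwise per trait —
no imputation.

Kinship is the VanRaden cross-product of frequency-centered dosages
scaled by Σ 2p(1−p), computed over polymorphic SNPs; if numerical noise
makes the matrix indefinite, a minimal diagonal ridge restores positive
semi-definiteness. Population structure enters as the first three
principal components of the centered dosage matrix (three is the common
default of GWAS toolchains; configurable). Both corrections are needed:
under a three-subpopulation null the uncorrected scan inflates the
genomic-control λ well above 1, while the corrected scan stays in
[0.85, 1.15] (tested).

The variance ratio δ = σg²/σe² is estimated once per trait under the
null model by REML, profiling the restricted likelihood on the spectral
decomposition of K over a log-spaced grid in [1e−5, 1e5] followed by
bounded refinement to 1e−6 — then held fixed for every SNP (the P3D
approximation). Accession-compression variants of the mixed model are
purely a speed device at biobank scale and are not implemented; at desk
scale the plain P3D scan is exact and fast. After rotating by the
eigenvectors of K and whitening with 1/(δλᵢ+1), the per-SNP Wald test
reduces to weighted least squares; covariates are projected out once by
QR, so the scan over all SNPs is a single matrix product. SNPs whose
residualized dosage has (numerically) zero variance are flagged
`collinear` and their p-value is recorded as missing, never fabricated.
SNPs with MAF ≤ 0.01 on the analysis subset are excluded.

## Locus identification

The genome-wide LOD threshold is −log10(1/N) = log10(N) for N tested
SNPs. SNPs above the threshold are grouped per chromosome while the
distance between consecutive retained SNPs is strictly less than 10 kb
(the boundary reading of "less than"; configurable), and a group
survives only if it contains a SNP with Bonferroni-corrected p < 0.05.
For suggestive-threshold sweeps below the genome-wide level the
Bonferroni keep-rule would empty every extra locus, so it is relaxed to
the sweep threshold itself — the relaxation is explicit
(`require_bonferroni=False`) and only `lod_sweep` uses it
automatically. Candidate genes are all genes overlapping the locus
extended by a 10-kb flank (1-based inclusive intervals); the flank
reuses the grouping scale because no separate value is canonical, and
it is configurable. Lead-SNP ties break toward the smaller coordinate
so outputs are deterministic. Haplotype interrogation enumerates allele
strings over a gene's SNPs, calls a haplotype informative when at least
three accessions carry it, clusters informative haplotypes by Ward's
minimum-variance linkage on Hamming distances, and compares trait means
across clusters by one-way ANOVA with Bonferroni-corrected pairwise
t-tests.

## Condition networks

Within each condition, metabolites are screened by one-way ANOVA with
time point as factor over replicate values and Benjamini–Hochberg FDR
across metabolites; transcripts are deliberately not screened (the full
transcript universe enters the correlation step). Pearson correlations
are computed over replicate-mean time points (n = 23 on the default
grid); an all-samples mode exists because the weighting convention
(replicate means vs all samples) is genuinely open — replicate means
are the default since replicate noise would otherwise inflate the
effective sample size.

The |PCC| edge threshold is calibrated by permutation: each
metabolite's time order is shuffled independently (transcripts fixed),
the full |PCC| set recomputed, and for thresholds t on a 0.01 grid
FDR(t) = (mean permuted count ≥ t) / (observed count ≥ t); the smallest
t with FDR(t) < 0.05 is chosen. If no threshold qualifies — e.g. on
pure noise, where observed and permuted counts coincide — no network is
built for that condition (threshold `None`), which is the correct
conservative outcome rather than an arbitrary cutoff. The estimator and
scheme are the package's choices; replicate-block permutation is
available for the all-samples mode.

This permutation null is only honest when unrelated profiles are close
to exchangeable in time. That constraint shaped the generator (below)
and is the main caveat for real data: strongly autocorrelated
transcriptome dynamics make time-shuffling anti-conservative, and a
rotation-based null would be the appropriate extension.

## Integration and evaluation

Per metabolite: the GWAS list is the union of candidate genes over its
loci; the network list the union of transcript neighbors over all
condition networks; RIL/IL lists come from the external tables; the
combined list is network ∩ (GWAS ∪ RIL ∪ IL). The candidate table
mirrors this with per-method flags, the lead-SNP LOD where
GWAS-supported, and per-condition PCCs (0 = below that condition's
threshold, missing = not a network neighbor at all).

Reference gene lists are built by breadth-first layering over the
bipartite metabolite–reaction graph: reactions touching the metabolite
are step 1, reactions touching any metabolite of a step-k reaction are
step k+1; RGL_L (L ≤ 3) unions the enzymes of reactions at step ≤ L,
and RGL4 unions the enzymes of every reaction sharing a pathway label
with a step-1 reaction. A metabolite counts as correctly predicted when
at least one predicted gene lies in its RGL; precision, recall and
F-measure follow from the Na/Np/Ncp counts, and metabolite-wise
precision is |predicted ∩ RGL| / |predicted| (undefined and excluded,
not zero, for empty predictions).

The permutation test replaces every metabolite's prediction with an
equally sized without-replacement draw from the gene universe
(k = 10,000 by default; the pipeline uses smaller k since the permuted
F distribution is extremely tight at desk scale) and reports
p = (1/k) Σ 1[F_actual ≤ F_perm]. The alternative reading of
"shuffling" — permuting whole gene lists among metabolites — is
implemented as `scheme="permute_lists"`; the same-size-random-draw
reading is the default because it matches the stated construction
("the same number of randomly selected genes for each metabolite").
Evaluation is restricted to metabolites present in the reaction graph,
mirroring the restriction of benchmarking to pathway-annotated
compounds.

## The synthetic study generator

The generator emulates the data structure of a metabolite GWAS in a
selfing plant panel, scaled to desk size: 200 homozygous accessions ×
4,000 SNPs on 5 chromosomes (0/1 dosages), 300 genes, 40 metabolites,
8 environmental conditions × 23 time points × 3 replicates, and two
emulated bi-parental mapping datasets. All generators share one seed
and are fully deterministic.

*Genotypes* follow a Balding–Nichols-style model: per-SNP ancestral
frequencies are uniform on [0.1, 0.9] and each of 3 subpopulations
draws its frequency from a Beta distribution whose spread is one drift
parameter (0.1 by default); with one subpopulation or zero drift the
panel is unstructured. SNPs are placed uniformly at unique sorted
positions. There is deliberately no local LD beyond what structure
induces — realistic LD decay is out of scope, and causal-SNP recovery
is therefore assessed by physical distance, not tagging.

*Traits* decompose the latent (log-scale) variance into: a causal SNP
inside a step-1 enzyme gene of the metabolite (share 0.12), a trans
locus in a random non-enzyme gene (share 0.12), a kinship-correlated
polygenic term (share 0.36), and white noise (0.40) — heritability 0.6
in total. The trans component is essential realism: without it a
desk-scale GWAS is perfect and no integration strategy could improve
on it, whereas real metabolite panels are dominated by regulatory loci
whose genes are not pathway enzymes. Intensities are exponentiated (so
strictly positive, log-normal-like) and 10% of entries are masked.

*Reaction graph*: a substrate–product chain over all metabolites
guarantees connectivity and places each metabolite's causal gene on a
directly catalyzing reaction (so truth is recoverable at RGL1), plus a
handful of single-enzyme cross-reactions for branching; pathway labels
chunk the chain. Reactions carry only their own enzymes — bystander
gene padding would silently widen every RGL and blur the evaluation.

*Time courses*: planted (metabolite, transcript) pairs share a latent
AR(1) trajectory (φ = 0.3, z-scored) per condition, observed with
Gaussian replicate noise (sd 0.4); unplanted transcripts are
time-stationary noise; optionally a fraction of metabolites is
time-flat (to exercise the ANOVA filter). The mild autocorrelation is
a deliberate compromise: it gives every metabolite a genuine time
effect while keeping unrelated profiles nearly exchangeable, so the
time-shuffling permutation null is calibrated (realized edge FDR ≈
0.06 at nominal 0.05, pooled over 50 datasets). Smooth random-walk
trajectories look more like real kinetics but carry so much
low-frequency power that independent curves correlate heavily by
chance, which the shuffled null cannot represent — with such latents
the realized FDR reached 0.2–0.6. Passing FDR tests here therefore
say nothing about strongly autocorrelated real data (see the caveat
above). 75% of causal genes are planted as network edges (transcript
co-variation with the metabolite level is common but not guaranteed
for primary-metabolism enzymes), and 20% of the transcript universe is
attached to random metabolites as co-regulated but pathway-unrelated
partners — the false-positive pressure on the network method.

*External RIL/IL calls*: each method reports 60% of the true causal
(metabolite, gene) pairs and adds up to four random decoy genes per
metabolite (each with probability 0.5), every report wrapped in a ±5 kb
interval. The 60/50 setting encodes moderate transferability of
bi-parental evidence to a natural panel and the coarse, partly wrong
gene content of linkage intervals. Because the emulated external
tables and the time-course study stand for single fixed datasets, their
recall rates are implemented as stratified design fractions (exactly
round(rate·N) successes at random positions) rather than i.i.d.
Bernoulli draws: a published mapping table does not re-randomize its
recall between analyses.

Under these defaults the combined strategy's F-measure matches or
exceeds every single method on RGL2–RGL4 in ≈ 85–90% of simulated
studies — the desk-scale analogue of the integration argument — while
the network method alone wins occasionally, consistent with it being
the strongest single method.

## Numerical choices and degenerate inputs

- REML grid 61 points on log δ ∈ [−5, 5]·ln10, bounded refinement,
  xatol 1e−6; an identity-spectrum K short-circuits to OLS.
- PC scores are sign-fixed (largest-magnitude score positive).
- Zero-variance features: LD r² returns (nan, nan), never 0; constant
  metabolites are flagged degenerate by the ANOVA screen; zero-variance
  correlation partners yield missing PCCs excluded from thresholding.
- Threshold grid resolution 0.01; the smallest qualifying threshold is
  chosen; all permutation draws are seeded.
- Problem sizes throughout the tests and the acceptance script (200 ×
  4,000 default panel, 40 metabolites, 25-seed dominance check, 50-seed
  FDR pooling) were chosen so the full suite completes in a few minutes
  while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- No local LD, no epistasis, no genotype imputation; fine-mapping is
  out of scope.
- The reaction graph is a stylized chain-plus-branches, far sparser
  than a real metabolic network; absolute F-measures are not
  comparable to values obtained against curated pathway databases.
- GC–MS signal processing and raw linkage mapping are upstream of this
  package: it consumes trait tables and external call lists.
- The permutation-FDR calibration result is conditional on weak
  autocorrelation, as discussed above.
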