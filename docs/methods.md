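# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `stressstates`, in the order the pipeline runs.

## Count model and synthetic data

All statistics assume overdispersed count data. The generator realises the
model they assume: per-gene baseline means μ_g ~ LogNormal(ln 4, 1)
(counts/cell), per-cell size factors s_c ~ LogNormal(0, 0.3), and counts
X_cg ~ NB(mean μ_g·s_c, size r) with Var = m + m²/r and a shared size
r = 5 by default. With 2,000 genes these defaults give ~13k counts per
cell — above the 10k QC threshold and comparable to real per-cell depths
of probe-based single-cell chemistry — with a realistic right-skewed
mean distribution. No public per-gene dispersion estimates exist for this
assay class, so r = 5 (moderate overdispersion) was chosen for testability
rather than fitted realism.

Treatments are responsive subpopulations: a Bernoulli(f) subset of each
treatment's cells multiplies the NB *mean* of every targeted-signature
gene by 2^l2fc, keeping counts in the NB family (no post-hoc count
scaling). Responder status is drawn once per cell, so the targeted
programme switches on coherently — matching how ER stressors activate
whole gene programmes in a subpopulation; a per-gene-independent mode
exists behind a flag. Ground truth (responder flags, per-gene effects,
state labels) is recorded for recovery tests.

The default screen layout is 7 chemicals × 3 rising concentrations with
responsive fractions 0.05/0.2/0.5 and a vehicle pool 4× a treatment group
(large shared DMSO populations are the norm in such screens, and the FGT
null needs well-estimated control moments — see below). The generator does
NOT emulate ambient RNA, doublets, batch effects, UMI-level noise or
per-gene dispersion trends; tests passing on it validate the estimators
under their stated model, not robustness to those artifacts.

Signature libraries for simulation share an `overlap_fraction·size` core
across all sets (placed first in the ranking so truncation preserves it),
making every pairwise overlap exact rather than random.

## QC and normalisation

Cells must have **more than** 10,000 counts and 1,000 detected genes
(strict inequalities); both thresholds are configurable. Normalisation is
counts-per-10k followed by log2(x+1); provenance flags enforce the
filter → normalise → log order. HVG selection ranks genes by variance
standardised against a mean-expression trend in 20 equal-occupancy bins
using median/MAD within each bin — a deliberate simplification of the
loess-trend estimators common in single-cell toolkits, chosen because HVGs
feed only visualisation here, with robustness (MAD) so the highly variable
genes do not inflate their own bin's scale. Batch correction is an
optional no-op hook; stratified per-treatment sampling prepares balanced
embedding inputs. All sampling is deterministic under a seed with
documented tie-breaks (gene id ascending).

## FGT1+ (fraction of responsive cells)

Per gene and condition: T = mean(control)·2^L2FC0; k = #{treated > T}
(strict); f₀ = k/n₁. The control null is fitted by method of moments with
ddof = 1 variance: NB(r = m²/(v−m), p = m/v) when v > m, Poisson(m) when
0 < v ≤ m (the NB inversion is undefined under equidispersion), degenerate
when v = 0; an all-zero control with L2FC0 ≠ 0 is unscorable and reported
with missing p. π = P(X > ⌊T⌋) via the survival function; p-value
P(Binom(n₁, π) ≥ k), defined as 1 when k = 0. The binomial tail uses ≥ k
("at least as many"). A mirrored downregulation variant (FGT1−, threshold
μ·2^−L2FC0, counting values strictly below) is provided behind a flag as
an extension. BH q-values are computed within each (chemical,
concentration) stratum; the default reporting threshold is p < 0.1 with
responsive-fraction cutoffs 0.05/0.1/0.2.

**Data layer.** FGT1+ operates on raw counts. We measured the
alternatives on simulated nulls: per-cell rescaling (counts-per-10k or
rescaling to the mean library size) turns the data into a mixture of
differently-scaled NBs whose tail the moment-matched integer-lattice NB
underestimates, roughly doubling to tripling the nominal type-I error.
Raw counts leave depth variation to enter treated and control
symmetrically, where the moment fit absorbs it as overdispersion. A
`target_depth` option remains for designs with depth imbalance between
groups.

**Calibration.** The plug-in binomial p-value treats the estimated π as
known. Its noise — dominated by the moment dispersion estimate — inflates
the type-I error when the control population is small: on exact-NB nulls
(r = 5) the fraction of genes with p < 0.05 is ≈ 0.10 with 500 control
cells, ≈ 0.05 with 2,000, and slightly conservative (≈ 0.04) with 7,000.
Shared per-cell depth factors additionally correlate gene-level errors
within a dataset, widening run-to-run spread. Practical guidance: pool
controls; treat p-values from control pools under ~2,000 cells as
approximate. The acceptance script reports the measured type-I error at
both 500 and 2,000 control cells.

## Pseudo-bulk differential expression

Each treatment's cells are partitioned into n_reps = 3 disjoint random
subsets of ⌊n/3⌋ cells ("33.33% without replacement" read as a partition,
avoiding replicate overlap; an independent-subsample mode exists) and raw
counts are summed. Size factors are median-of-ratios to the geometric-mean
reference over genes positive in all samples, rescaled to geometric
mean 1. The per-gene test is a two-group NB GLM with log link and
size-factor offsets, solved in closed form: with only a group indicator
the MLE satisfies Σ(y_j − s_j·m)/(1 + α·s_j·m) = 0 per group, solved by a
damped fixed point from the moment start Σy/Σs; the Wald variance is
1/I_ctrl + 1/I_treat with I = Σ μ/(1+αμ). Dispersion α is method-of-
moments on normalised counts, pooled across the two groups and floored at
1e-8. bL2FC = β/ln 2; two-sided normal p; BH q-values. This is a
deliberately simple estimator — no dispersion shrinkage across genes, no
outlier filtering, no fold-change shrinkage; `export_deseq2` writes
counts + coldata CSVs for users who want a full bulk DE engine. Genes
all-zero in both groups are reported missing; genes expressed in only one
group get infinite bL2FC with missing p (no finite Wald test exists).

Under a mixture response (fraction f of cells at 2^L), the expected
linear-scale ratio is 1 + f·(2^L − 1), so bL2FC ≈ log2(1 + f·(2^L − 1)) —
the quantity the recovery tests assert (f = 0.5, L = 2 → log2 2.5 ≈ 1.32).

## nPMI signatures

nPMI = ln(p_gt/(p_g·p_t)) / (−ln p_gt) with natural logs (the base cancels
in the ratio; natural log is fixed so oracles match). n_gt = 0 is reported
as −1; a pair present in every document is undefined (missing). Genes with
nPMI > 0.2 are ranked by co-occurrence count, then nPMI, then gene id
(count-first per the convention that frequency is the primary evidence;
a flag swaps the order), truncated to sizes 50/100/150/200 with the prefix
property. Abstract mining is out of scope: the module consumes a prepared
`gene,term,n_gene,n_term,n_pair,N` CSV, and the simulator can fabricate
one with planted associations.

## Connectivity scoring

Cells are standardised gene-wise against the DMSO population (ddof = 1;
genes constant in control are excluded and listed). Z200 takes the 200
largest strictly-positive and 200 smallest strictly-negative z genes (ties
by gene id). The generalized Jaccard score of a Z200 against a signature
with signed genes S⁺/S⁻ is

    gj = (|U∩S⁺| + |D∩S⁻| − |U∩S⁻| − |D∩S⁺|) / |U ∪ D ∪ S|  ∈ [−1, 1].

The binary signed-set form is normative here; a weighted variant
(numerator Σ sign-agreement·min(|a|,|b|), denominator Σ max(|a|,|b|), with
z-weights clipped to [−1,1]) is available behind a flag. Signatures are
unsigned (+1) unless a GMT provides weights. Raw scores are standardised
per (pathway, size) against the control cells' scores (ddof = 1), so
z_gj = 1 means one control-SD above the control mean.

ANOVA: per (chemical, pathway), an additive OLS z ~ conc + length with
both factors numeric, concentration on its raw μM scale with the control
entering every chemical's model at conc = 0 (a log10(conc + pseudocount)
mode exists); sequential (type-I) sums of squares in the order (conc,
length); η² = SS_factor/SS_total with bands 0.01/0.06/0.14
(small/medium/large); slopes are the fitted coefficients.

## States, groups, transitions

Clustering operates on standardised scores at signature size 200 (raw-
score mode behind a flag). k-means uses k-means++ with 10 restarts;
k = 25 by default, with `scan_k` reporting silhouette, Calinski-Harabasz
and Davies-Bouldin over a range (on real-like data these indices decline
smoothly in k — the states form a continuum, and k is an interpretability
choice, not an optimum). Cluster summaries report per-(cluster, pathway)
mean score and the fraction of member cells above the global per-pathway
mean + 1 population SD.

Phenotypic groups: Ward/Euclidean agglomeration of centroids, cut into 5
branches, labelled I…V by ascending mean total activation (unweighted mean
over member clusters; a size-weighted mode exists), so Group I is basal.
The grouping is a deterministic automation of what is usually a manual
call; a manual override map is accepted.

CSTG: (a) dendrogram edges — merges processed in height order, each merge
contributing the closest centroid pair across the two subtrees (ties by
lexicographic id pair), one edge per merge, giving a k−1-edge spanning
tree ("iteratively connecting leaves within subtrees" operationalised as a
deterministic rule); (b) each cluster linked to its 2 nearest centroids
(Euclidean, ties toward lower id). The union is tagged
dendrogram/knn/both; it is simple, connected (contains the tree) and has
min degree ≥ 2. The graph is undirected and carries no rates — transitions
are putative. Note that a knn edge may be longer than a node's dendrogram
edges; no ordering between the two edge sets is asserted. Layout is
seeded Fruchterman-Reingold; export is GraphML + edge-list CSV.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — 2,000–4,000 genes,
500–7,500 cells, 5,000 score-space cells — as a stand-in for a ~22.5k-gene,
~34k-cell experiment; every stochastic step takes an explicit seed and
fixed seeds reproduce outputs byte-identically. The pipeline writes a
manifest (config hash, seeds, version) with every run.

## Known limitations

- The FGT1+ p-value is plug-in and anti-conservative for small control
  pools (quantified above); no dispersion shrinkage is attempted.
- The simplified NB Wald DE will not numerically match shrinkage-based
  bulk DE tools, only agree in expectation on clean designs.
- The generalized Jaccard form is fixed by its stated properties (range,
  overlap-based, direction-aware); other direction-aware overlap scores
  exist and would rank similarly but not identically.
- Group assignment automates a judgement call; on real data the 5-branch
  cut may split differently than an expert would.
- The generator's realism gaps (no batch effects, doublets, ambient RNA)
  bound what green tests imply about real screens.
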