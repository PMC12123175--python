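# Methods

This note documents the models, rules and numerical choices behind each
`subpheno` stage, the assumptions of the synthetic-data generators, and
the limits of what passing tests demonstrate about real cohort data.

## Growth classification

Measurements are standardized against reference tables of per-sex,
per-age means and SDs; means and SDs are **linearly interpolated** in age
within sex, and ages up to 3 months outside the tabulated range are
clamped to the nearest row (beyond that, an error — a silently
extrapolated growth reference is worse than a refusal). Percentiles come
from the standard normal CDF applied to the z-score; reference files may
instead supply empirical percentile columns, which then take precedence.

Cutoffs are applied as strict inequalities exactly as conventionally
printed: macrocephaly means head-circumference z strictly above 1.5 SD,
somatic overgrowth (SO) means both head-circumference and height
percentiles strictly above 90, and disproportionate macrocephaly (DMac)
means a height-to-head-circumference percentile ratio strictly below 0.7.
Three choices deserve a note:

* **SO is evaluated before the ratio rule.** The ratio rules alone would
  double-assign probands who satisfy both; checking SO first makes
  {SO, DMac, RM} a partition of the macrocephalic probands, which the
  test suite asserts on 10,000 random percentile pairs.
* **Ratio exactly 0.7 is assigned RM**, the complement class, since the
  DMac rule is a strict `< 0.7`.
* **The 1.5 SD cutoff corresponds to the 93.3rd percentile** under
  normality, although it is often glossed as "the 90th". The SD rule is
  primary here; the exact percentile is reported alongside so users can
  see both conventions.

The cerebral-volume-to-height ratio for the megalencephaly call uses
height in centimetres by default; the unit is configurable because
published ratio references differ.

An expression-outlier helper (`zscore_outlier`, default threshold 3 SD
above the population mean, sample SD with `ddof=1`) supports
per-individual over-expression calls against a cohort.

## Trio variant filtering

Variants are reduced to a canonical key (chrom:pos:ref:alt) by splitting
multiallelic records, right-trimming/left-trimming shared bases, and —
when a reference context is supplied — left-aligning indels with the
standard extend-left-while-suffix-matches loop. De novo detection then
compares keys: the proband must carry the alternate allele and **both**
parents must be genotyped and not carry it. Sites with a missing parental
genotype are excluded (conservative; matches treating probands without
parental data as a separate, dbSNP-based analysis arm). A verbatim
string-matching mode is retained behind a flag for fidelity with
pipelines that filter on raw VCF lines, but normalized-key matching is
the default because raw string comparison misses representation
differences.

The rarity rule is strict: AF < 0.2% in *all five* continental reference
populations (AFR/AMR/EAS/EUR/SAS); a population absent from the
annotation is treated as frequency 0 and logged. Consequence classes come
from the input annotation table — no re-annotation is attempted. CNVs are
included when flagged precise and exonic and impacting at most two genes.
Candidate-gene aggregation counts **distinct probands** (recurrence), so
two variants in one proband count once; a multi-gene variant or CNV
credits every listed gene and is flagged. Constraint is flagged at
pLI > 0.9.

Burden comparisons use a 1-df two-proportion chi-squared without Yates
correction by default (toggle provided) and a two-sided Fisher's exact
test; both echo the contingency table used, and zero-margin tables return
p = 1 with a warning rather than NaN.

## Network expansion and enrichment

The edge table is undirected with integer combined scores in [0, 1000]
(STRING `protein.links` dialect accepted); a minimum-score cutoff is
available (the conventional "medium confidence" 400) but defaults to 0 so
the caller controls stringency explicitly. Per seed, the top-k (k = 10)
neighbors by score are taken, with ties broken lexicographically by gene
symbol so results are deterministic; expansion is therefore invariant to
seed iteration order, which a test asserts. Term enrichment is the
hypergeometric upper tail P(X ≥ overlap) within a caller-supplied
background universe, BH-adjusted across terms. A conservative variant
that reduces the observed overlap by one (the EASE convention) is
available by flag; the plain hypergeometric is the default. Term pooling
(grouping related terms) is driven by an explicit user-supplied mapping —
no automatic semantic grouping is attempted.

## Morphometrics and qPCR

Group comparisons are two-sided Wilcoxon rank-sum tests. Method choice:
exact null when both groups have ≤ 25 observations and the pooled sample
is tie-free; **exhaustive midrank permutation** when ties are present and
the pooled size is ≤ 16 (C(16,8) = 12,870 arrangements, cheap and exact);
otherwise the tie-corrected normal approximation. Two-sided p is twice
the smaller tail, capped at 1 (the R convention). Fold change is the
median ratio (robust and consistent with a rank test; a mean-ratio flag
exists because "fold change" is often left undefined). Bonferroni family
size defaults to the number of features compared in one experiment
(e.g. four gross features; two brain areas), configurable; stars are
≤ 0.05 `*`, ≤ 0.01 `**`, ≤ 0.001 `***` on the adjusted p, thresholds
inclusive.

ΔΔCt quantification uses group-mean Ct values: FC = 2^−ΔΔCt. Replicate
level fold changes (each test replicate against the control-group mean
ΔCt) are also returned so downstream tests have per-sample values;
Monte-Carlo error propagation is deliberately not applied by default
since no error model for Ct values is assumed.

## Single-cell stage

QC removes cells with mitochondrial **or** ribosomal percentage above 5,
fewer than 200 detected features (strict), more features than the
per-sample pre-filter mean + 2 SD, or a precomputed doublet flag.
Normalization scales each cell to the median total count and applies
natural log1p; the most variable genes (default 5,000) are ranked by the
variance of this normalized expression and used only for PCA/clustering.
A regularized variance-stabilizing transform is intentionally **not**
reimplemented: the downstream result surface (rank-sum DE, Fisher
enrichment, fold-change shift tests) depends only weakly on the
variance-stabilization flavor, and a simple documented normalization
keeps the stage auditable. Optional per-gene linear residualization on
mito/ribo percentages approximates covariate regression.

Clustering: PCA (full SVD, deterministic; the sign of each component is
fixed by forcing its largest-magnitude loading positive), Euclidean
distances on the first 30 components, Ward linkage (the unstated-default
choice; complete/average available), tree cut into k flat clusters
(k = 10 broad, k = 18 for brain subsets by default).

Downsampling matches the test group to the control **total** while
preserving the test group's own cluster proportions (largest-remainder
allocation, per-cluster `min(available, target)`, sampling without
replacement under a caller seed). The alternative reading — matching
control *per-cluster* counts — is available as a mode.

DE: genes detected (normalized value > 0) in ≥ 1% of cells of either
group, with |log2 FC| ≥ 0.1 where
log2FC = log2((mean(expm1 x_test)+ε)/(mean(expm1 x_ctl)+ε)), ε = 1e−9,
are tested by midrank rank-sum and BH-adjusted over the tested genes.
Marker finding is the positive one-vs-rest variant (detection floor 20%,
raw-p return threshold 0.01). The detection floor for DE testing (1% of
cells) and the expression floor for the fold-change shift analysis
(0.01% of cells, i.e. fraction 1e−4) are deliberately distinct knobs:
both conventions circulate and they serve different steps.

Target-set enrichment crosses DEG status (BH p ≤ 0.05) with target
membership over the expressed background in a two-sided Fisher test; the
BH family for this enrichment is a caller-supplied list of companion
p-values (e.g. the two models), since the correct family is a study-level
decision. Per-gene average log2 fold changes (computed with the DE-style
group-mean ratio — the within-cell averaging alternative is noted but not
used) feed a paired t-test between models over shared target genes and
unpaired t-tests of target vs non-target genes within a model.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under a seed and emit machine-readable
truth tables.

* **Growth cohort** (default n = 1847 probands, the scale of a large
  simplex-collection cohort): z-scores bivariate normal with
  configurable head-height correlation (default 0.3); a planted
  macrocephalic fraction (default 0.36, chosen so the overall call rate
  lands near the ~40% reported in large autism cohorts once the natural
  6.7% tail is added) draws its head-circumference z from the truncated
  tail above 1.5 SD. Reference curves are smooth synthetic standards
  shaped like published growth references (ages 4–17 y).
* **Trios** (default 6 families × 5,000 inherited + 50 de novo):
  inherited variants are Mendelian-consistent with Bernoulli(½)
  transmission from a heterozygous parent; de novos are proband-only.
  Allele frequencies are Beta-distributed with a point mass at 0 (both
  rare-filter branches exercised); LGD consequences are planted at a
  configurable fraction (default 0.2). Genotypes are error-free, so
  perfect de novo precision/recall is the *correctness* bar for the
  matching logic, not a claim about real WGS data with genotyping error
  or parental mosaicism.
* **Edges/terms/morphometrics**: an Erdős–Rényi-style graph at mean
  degree 6 with scores uniform on [150, 999]; one planted term composed
  predominantly of seed genes (so its enrichment in the expanded network
  is structural); larval features log-normal around plausible 3-dpf
  baselines with multiplicative group effects (defaults 0.95–0.97 on
  size features, 1.0 on head-trunk angle) and a 2% coefficient of
  variation, typical of clutch-matched morphometrics, at n = 35 per
  group.
* **Single cell** (default 500 cells/condition × 2,000 genes): log-normal
  gene means (mean count ≈ 1 per gene per cell, i.e. ≈ 3,000 counts per
  cell — a realistic droplet/combinatorial-indexing depth), cluster
  identity via 8× boosted disjoint marker blocks, negative-binomial
  counts via the gamma–Poisson mixture with dispersion 0.5 (typical
  droplet-scale overdispersion), log-normal cell size factors (σ = 0.25),
  and a multiplicative downshift (default 0.8×) on a 50-gene target set
  in the overexpression-analog condition. Planted QC violators cover all
  four removal rules; the truth table records both the planted set and
  the full rule-derived removal set (the mean + 2 SD feature ceiling can
  legitimately catch a few unplanted cells).

None of the generators model batch effects, ambient RNA, doublet
structure, genotyping error, linkage, or real ontology topology — so
green tests certify the pipeline's logic and calibration under its stated
assumptions, not performance on raw cohort data.

## Problem sizes and reproducibility

The bundled demo pipeline (`subpheno run`) uses a reduced workspace
(600 probands, 2 families × 520 variants, 250 cells/condition × 600
genes) so an end-to-end run completes in seconds; stage entry points
accept full-size inputs. The acceptance script uses the generator
defaults (10,000-proband calibration cohorts, 6 × 5,050-variant trios,
20 single-cell replicates at 500 cells/condition × 2,000 genes) —
deliberate choices balancing statistical resolution against a
single-CPU run of a few minutes. Every output carries the resolved
configuration hash and per-file checksums; reruns under a fixed seed are
byte-identical, which both the test suite and the acceptance script
verify.

## Known limitations

* Percentiles assume normality of the reference distribution unless
  empirical percentile columns are provided; real growth references are
  skewed (LMS-style fits are out of scope).
* Consequence annotation, phasing, and read-level validation are
  upstream concerns; the filter chain trusts its annotation table.
* The hypergeometric enrichment treats genes as exchangeable — no
  gene-length or expression-level bias correction.
* The single-cell normalization is a simple depth/log transform; results
  sensitive to variance stabilization subtleties (e.g. very shallow
  cells) should be interpreted accordingly.
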