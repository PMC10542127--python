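# Methods

This note documents the statistical procedures, the synthetic-data
generator that exercises them, the numerical choices, and what the test
suite does and does not establish.

## Quality control and normalization

Droplets are kept when the mitochondrial UMI fraction is strictly below
0.20 and the number of unique genes detected strictly exceeds 300 (solid
tissue: heart, tumor, adjacent normal) or 400 (blood). The mitochondrial
fraction uses a fixed 13-gene list (MT-ND6, MT-CO2, MT-CYB, MT-ND2,
MT-ND5, MT-CO1, MT-ND3, MT-ND4, MT-ND1, MT-ATP6, MT-CO3, MT-ND4L,
MT-ATP8), regardless of other MT- features in the annotation. "Unique
genes" counts all annotated features with nonzero UMIs. Normalized
expression is logCPM = ln(1 + 10⁵ · c/total), natural log; zeros map to
zeros so sparsity is preserved. Pseudobulk units are exact integer sums
of UMI counts per sample × cluster; units with no cells do not exist.

## Differential abundance

Per subset, the mixed-effects logistic model `cluster ~ 1 + outcome +
(1|donor)` is fit on donor-level binomial counts — an exact collapse of
the cell-level Bernoulli likelihood, valid because the random effect and
the covariate are donor-constant, and orders of magnitude faster. The
marginal likelihood per donor,
∫ Binomial(y_d | n_d, logistic(β₀ + β₁x_d + u)) φ(u; 0, σ²) du,
is evaluated by adaptive Gauss–Hermite quadrature: the integrand's mode
is found by Newton iteration per donor, nodes are centred there and
scaled by the local curvature, 25 nodes. Optimization is L-BFGS-B over
(β₀, β₁, σ) with σ ≥ 0. When σ̂ hits the boundary the fit is repeated as
a plain logistic (BFGS on the σ = 0 likelihood), whose log-likelihood
enters the LRT, so boundary cases degrade gracefully to the fixed-effect
model. Standard errors come from the inverse observed information
(central finite differences; the σ row is dropped at the boundary).
Complete separation (one group all-zero or all-full) flags the result
`unstable`; estimates are still reported. The LRT statistic is clamped
at 0 (tolerance 1e-6) and referred to χ²₁; BH correction runs across the
tested subsets with an FDR < 0.10 significance rule. The fit matches
lme4's `glmer` with nAGQ = 25 to ≈1e-4 on a frozen fixture.

The χ²₁ reference is asymptotic in the number of donors: at the default
cohort size (12 case, 8 control) the measured type-I error at α = 0.05
is ≈ 0.06–0.07 — mildly anticonservative, a property of the test itself,
not of the implementation.

Severity regression is OLS of ln(troponin) on ln(subset fraction),
two-sided t on the slope with n − 2 df. Samples with troponin measured
more than 2 days from tissue collection, zero fractions, and non-positive
troponin values are excluded; fewer than 3 usable samples yields an
undefined result with a reason string; a constant response returns slope
0 with p = 1.

## Marker genes

AUROC is computed from the rank-sum statistic with mid-rank ties,
within the analyzed lineage; it is invariant to monotone transforms of
expression. The one-versus-all moderated t fits, per gene, an unweighted
linear model on log2(CPM + 0.5)-transformed pseudobulk (precision
weighting deliberately omitted for parsimony). The variance prior
(d₀, s₀²) is estimated per scan by matching the mean and variance of
log sample variances to the log-F distribution they follow under a
scaled-inverse-χ² prior (trigamma inversion by Newton iteration);
non-positive excess dispersion returns the d₀ = ∞ sentinel with s₀² the
geometric mean variance. Posterior variances are
(d₀s₀² + d·s²)/(d₀ + d); t̃ is referred to t with d + d₀ df (normal when
d₀ = ∞). Markers: AUROC ≥ 0.75, or FDR < 0.05 with positive log2FC.

## Case-control differential expression

A deliberately lean pseudobulk negative-binomial Wald test: per gene, a
log-link NB GLM `gene ~ case` with median-of-ratios size factors as
offsets (total-count ratios as a logged fallback when no gene is nonzero
everywhere). Dispersions are estimated per gene by Cox–Reid adjusted
profile maximum likelihood — the adjustment (−½ logdet X'WX) removes the
downward bias of plain profile ML that made the null test markedly
liberal in development testing — then shrunk on the log scale toward the
20%-trimmed mean with a weight computed from the excess spread of the
gene-wise estimates over an approximate sampling variance 2/(n−2);
dispersion floor 1e-8. Wald z uses a two-sided normal reference; BH FDR
with a < 0.1 rule. No outlier replacement, independent filtering or
fold-change shrinkage. Like any median-of-ratios workflow, fold-change
estimates are attenuated when a large fraction (≳20%) of genes is DE in
one direction; calibration simulations use the 12 + 8-unit design.

## TCR-β repertoire

Clone identity is `v_gene|CDR3` with the nucleotide junction by default
and the amino-acid junction as fallback (`key_on="aa"` forces aa-level
matching across platforms). Expansion: frequency strictly > 0.005 AND
count ≥ 2, counts being reads (bulk) or cells (single-cell). Enrichment
candidates are the expanded clones of the tissue of interest; each gets
a 2×2 of its counts vs the remainder in tissue and control, a one-sided
(greater-in-tissue) Fisher exact p — enrichment is directional; the
two-sided p is also available — and BH correction over candidates with
FDR < 5%. The plotted normalized ratio divides tissue frequency by
control frequency with a 0.5/total pseudo-frequency when the clone is
absent from control; the test itself always uses the true zero.

Hill diversity: qD = (Σ pᵢ^q)^{1/(1−q)}, with the exp-Shannon limit
taken exactly at q = 1 (the formula is numerically stable elsewhere,
continuous at q = 1 to < 1e-3 on the default grid). Samples below 100
sequences are refused. Optional rarefaction resamples multinomially at a
fixed depth, 200 seeded bootstraps by default, and averages the profile.

Sharing: a blood cell is flagged (`myo_clone`) when its clone key is in
the union of its own donor's bulk- and single-cell-expanded heart sets;
cross-donor matches are never flagged. Per donor and subset, the
fixed-effect logistic `in_subset ~ 1 + myo_clone` is fit in closed form
from its sufficient 2×2 (the MLE is the log odds ratio; the LRT is the
binomial deviance difference), matching a cell-level logistic fit to
1e-6 when all four cells are positive. Zero cells produce ±∞ slopes
flagged `unstable`, with the LRT still defined. BH runs across a donor's
subsets (FDR < 5%); the fatal-outcome association is a two-sided Fisher
test on the donor-level 2×2. Heart-side mapping of shared clones flags
donors with ≤ 10 qualifying cells as low-evidence.

## Receptor-ligand interactions

The statistic for (ligand, receptor, sender, receiver) is the mean of
the sender's mean ligand logCPM and the receiver's mean receptor logCPM,
computed only when both genes are expressed in > 10% (strict) of their
cluster's cells and both clusters have ≥ 20 cells. The null shuffles
cluster labels over cells; the same B permutations (default 1000) are
shared across all tuples, making the table bit-reproducible under a
fixed seed. Empirical p = (1 + #{T_b ≥ T_obs})/(1 + B) — the add-one
estimator never returns 0, and with B = 999 the best attainable p is
exactly 0.001, which fails the strict < 0.001 rule; B must exceed 999.
Final calls additionally require a DE ligand or receptor (FDR < 0.1), an
abundance-enriched sender or receiver, and membership in the mandatory
curated pair list. Case and control cell sets are scored in separate
runs. Heteromeric receptor complexes are not supported — pairs only.

## Serum and density statistics

Serum analytes are compared on ln(x + 1) with a Welch two-sided t-test
per analyte (Student's pooled variant by flag); flagging is raw
p < 0.05 with no multiplicity adjustment, recorded in the output
metadata. Degenerate comparisons (both groups constant) report p = 1.
Density comparisons report the ratio of region means (cells per 10⁵
total cells) and a one-sided Welch t; a zero denominator mean yields an
undefined ratio with a reason.

BH adjustment is shared by all modules: step-up, monotone, capped at 1,
NaNs passed through without counting toward the number of tests.

## Synthetic cohort generator

The generator emulates the data structure of a multi-compartment ICI
myocarditis cohort; its defaults are the study conditions the analyses
are exercised under:

- **Cohort**: 12 case and 8 control donors (heart comparison), 4 fatal
  cases; case heart samples labelled pre-corticosteroid.
- **Composition**: per donor per cluster, independent Gaussian random
  intercepts (SD 0.5) added to baseline logits; the case effect defaults
  to ln 4 on cluster 0. Drawing intercepts per donor *per cluster* makes
  each per-cluster logistic fit exactly correctly specified. Cells are
  multinomial given the softmax of the logits; 1000 cells per donor.
- **Expression**: NB2 counts (dispersion 0.5) around log-normal gene
  base means, with 10 marker genes per cluster (8-fold) and a planted
  case effect (log2FC 1) on the last 20 genes in cluster 0; log-normal
  library-size factors (σ = 0.3) independent of cluster, isolating
  abundance from depth effects. QC covariates (mito fraction, unique
  genes) are simulated at full-transcriptome scale and a configured 5%
  of cells each is overwritten to fail the mito or gene filters — counts
  are never altered, keeping the count model clean.
- **Repertoires**: 4 donors carry matched heart/tumor/control-tissue
  repertoires; control tissue is a truncated power law (300 clones,
  rank-frequency exponent 1 — a modelling choice, as repertoire shape is
  conventionally power-law-like), and heart/tumor boost their enriched
  clones (19 heart, 28 tumor, 5 shared across donors) into a 1–3%
  frequency band; 5000 reads per specimen. Remaining case donors get
  heart-only power-law repertoires. Blood cells (1000 per case donor,
  6 subsets) carry their own donor's heart-expanded keys at rate 0.15
  (fatal) vs 0.01 (non-fatal) inside the designated subset and at half
  the non-fatal rate elsewhere.
- **Serum**: 71 log-normal analytes (log-SD 0.5), 16 shifted by 1.0 on
  the log scale in cases.
- **Troponin**: log-linear in the designated cluster's expected
  proportion (slope 1, noise SD 0.5). The expected proportion — computed
  from the donor's own intercepts — is used because cohort generation
  precedes cell generation; at zero noise the link is exactly affine.

Identical configs (including seed) give bit-identical output; each stage
derives its own seed stream so stages are individually reproducible.
What the generator does **not** emulate: V(D)J sequence realism, doublets,
ambient RNA, batch effects, compartment-specific depth differences, or
clone-frequency correlations between tissues beyond the planted
enrichment. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean, correctly specified world — not
robustness to the artefacts of real single-cell data.

## Problem sizes and numerical choices

Simulation-based checks use desk-scale sizes chosen to keep the full
suite fast while leaving the asymptotics honest: 1000 null replicates
(12 + 8 donors, 500 cells each) for LRT calibration; 200 replicates
(20 + 20 donors, 1000 cells) for effect recovery; 100 donor-repertoires
for enrichment recovery; 300-gene pseudobulk panels for DE calibration.
Quadrature uses 25 Hermite nodes (near-exact for binomial
random-intercept integrands); Newton mode-finding tolerance 1e-10;
finite-difference step 1e-4 relative for observed information; dispersion
search bounded in [1e-8, 100] with 1e-2 log-scale tolerance.

## Known limitations

- The NB Wald test is not DESeq2: no Cook's-distance outlier handling,
  no independent filtering, no apeglm shrinkage; exact numerical
  agreement with DESeq2 outputs is out of scope.
- Wald CIs for odds ratios are symmetric on the log scale and can be
  very wide under near-separation; profile-likelihood CIs are not
  implemented.
- The per-donor sharing model is the printed fixed-effect logistic; a
  pooled donor-random-intercept variant can be assembled from
  `BinomialMixedModel` but is not wired into the pipeline stage.
- The sidedness of the enrichment Fisher test is a documented choice
  (one-sided greater); the two-sided option is exposed.
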