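# Methods

## Overview

`cellpool` covers the two bespoke computational stages of a pooled
single-cell challenge study: (i) assigning every droplet back to its
donor by two independent modalities — hashtag counts and SNP allele
counts — and keeping only cells on which both agree, and (ii) testing
allergen-challenge effects on immune-cell cluster frequencies with an
overdispersed binomial mixed model. A synthetic-data generator with
emitted ground truth stands in for the study's raw data; every accuracy
claim in the test suite is scored against that truth.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: several
encapsulation runs, each pooling `donors_per_run` (default 15) barcoded
donors.

* **Hashtag counts.** On the log10(count+1) scale, a cell's own hashtag
  is drawn from the signal component Normal(mu_hi, sigma_hi) and every
  other hashtag from the noise component Normal(mu_lo, sigma_lo); draws
  are mapped back to integers by round(10^x − 1). Defaults mu_lo = 1.0,
  mu_hi = 2.5, sigma = 0.2 give the clearly separated bimodal
  per-hashtag histograms the demultiplexer is designed for. A fraction
  `doublet_rate` (default 0.05) of droplets carry two distinct donors
  and receive signal draws on both hashtags. Doublets are exactly
  two-donor; higher-order multiplets are rare enough at realistic
  loading to ignore. The noise component is drawn independently per
  non-own hashtag; there is no cross-cell ambient contamination model.
* **Genotypes and allele counts.** Per SNP, an alt-allele frequency is
  uniform in [maf_low, maf_high] (defaults 0.1–0.5) and each donor's
  dosage is Binomial(2, f). Per cell and SNP, depth ~
  Poisson(depth_mean) and the alt count ~ Binomial(depth, q_g) with
  q_0 = eps, q_1 = 1/2, q_2 = 1 − eps (default eps = 0.01); doublets
  mix their two donors' q with equal weight.
* **QC metrics.** UMI counts are log10-normal (mean 3.1, sd 0.25) and
  mitochondrial fractions Beta(2, 25); 5% of cells emulate dead or
  degraded droplets (low UMI, high mito), so the QC filter has real
  work to do.
* **Cluster counts.** For sample s of donor v, count ~ Binomial(n_s,
  logistic(beta0 + beta1·challenge + u_v + e_s)) with u_v ~ N(0,
  sigma_u²) and e_s ~ N(0, sigma_e²); totals are Poisson(total mean)
  truncated at 1. The realized random effects are emitted with the
  truth so recovery tests can condition on them.

All randomness flows from one integer seed through named substreams
(`SeedSequence` keyed by stage tags): regenerating with the same config
and seed is bit-exact, and adding a stage never perturbs another stage's
draws.

What the generator does **not** emulate — ambient hashtag contamination
correlated across cells, UMI saturation, sequencing-depth variation
between runs, linkage disequilibrium between SNPs, multiplets beyond
two donors, non-logit-normal overdispersion — bounds what passing tests
show: they certify the algorithms under the stated generative
assumptions, not performance on any particular real dataset.

## QC filter

A cell is retained iff min_umi ≤ UMI ≤ max_umi and mito ≤ max_mito
(defaults 200, 4000, 0.25). Removal inequalities are strict, so the
boundary values themselves are kept. Removal reasons are tallied per
cell (a cell may count toward several). The filter takes the
mitochondrial fraction as an input rather than computing it from gene
names, keeping the module data-agnostic.

## Hashtag demultiplexing

Per hashtag, a two-component univariate Gaussian mixture is fitted to
log10(count+1) over all provided cells of a run by EM. Initialization is
deterministic and tailored to minority-signal mixtures: noise mean at
the 25th percentile, signal mean at the 95th, both sds at half the
pooled sd, signal weight 0.1. Components are relabeled after fitting so
mu_hi ≥ mu_lo; sds are floored at 1e-3 to prevent collapse; convergence
is declared when the log-likelihood change drops below `tol` (1e-6),
and the EM log-likelihood is monotone by construction. Inputs with
fewer than 20 observations or zero variance raise a degenerate-input
error.

A hashtag is positive for a cell when the mixing-proportion-weighted
posterior odds pi·N(x; hi) / ((1−pi)·N(x; lo)) reach `ratio_threshold`
(default 3, inclusive). The pi-weighting reflects that any one donor's
cells are a minority of the pool; the unweighted density ratio is
available via `weighted=False`. The log transform's base cancels in the
odds. Cells with exactly one positive hashtag are assigned; zero or ≥2
positives give status "negative"/"multiplet" with a null call, so
positivity histograms and multiplet rates remain reportable.

## Genotype demultiplexing

* **Panel selection.** Positions are kept when the pooled pileup has
  depth ≥ 50 and pooled alt fraction in [0.05, 0.95] — a minimal
  pooled-polymorphism reading of "positions likely to differ between
  donors". Monomorphic positions drop out by construction.
* **Genotype calling.** Per (sample, SNP) with depth ≥ `min_call_depth`
  (default 5), the call is the dosage maximizing Binomial(alt; depth,
  q_g), ties broken toward heterozygous (the only way an exact tie
  arises is symmetric evidence). Below the depth floor the genotype is
  missing. The three-state {eps, 1/2, 1−eps} model is the standard
  minimal model for expressed-SNP deconvolution.
* **Concordance.** For a sample pair, the fraction of co-called SNPs
  with equal genotype (undefined at zero co-called SNPs). Same-donor
  pairs across runs should separate completely from cross-donor pairs;
  `pool_donor_genotypes` can validate its linking against that
  separation and warns when a link's concordance falls below the
  cross-donor ceiling.
* **Per-cell assignment.** Each cell is scored against every donor by
  the summed per-SNP binomial log-likelihood, restricted to SNPs called
  in *all* donors so every donor is scored on the same loci. The best
  donor is called only when it beats the runner-up by `min_margin`
  (2 natural-log units) and at least `min_informative` (3) covered SNPs
  contributed; otherwise null. The margin and floor guard against
  spurious calls on shallow cells. Doublet genotype mixtures are not
  modeled; doublets are expected to be flagged by the hashtag stage or
  fail the margin.

## Consensus

A cell's final donor is set only when hashtag and genotype calls agree
("consistent"). Conflicts, single-modality calls and doubly uncalled
cells keep distinct statuses, and the hashtag × genotype cross-tab
carries the diagonal (consensus), edges (single-modality) and
off-diagonal (disagreement) counts. Cells called by one modality only
are excluded from the final set — the strict reading of "consistently
assigned by both" — but never discarded from the report.

## Cluster-frequency model

For each cluster and each subject group separately:

    y_s ~ Binomial(n_s, p_s)
    logit(p_s) = beta0 + beta1 * [timepoint = after] + u_donor(s) + e_s
    u_v ~ N(0, sigma_u^2),  e_s ~ N(0, sigma_e^2)

The binomial denominator n_s (total CD45+ or mononuclear cells) does
the cell-number weighting; the sample-level effect e_s absorbs
extra-binomial variation, without which replicate scatter at totals in
the thousands would overwhelm a plain binomial fit.

**Estimation.** The exact marginal likelihood is maximized. Both random
effects are integrated by adaptive Gauss–Hermite quadrature: the inner
(sample-effect) integral per observation uses 20 nodes recentred and
rescaled at the integrand's mode (found by closed-form Newton steps on
the concave log-integrand); the outer (donor-effect) integral uses 15
nodes per donor, recentred at the donor mode. The outer curvature uses
the marginal information E[n p (1−p)] − Var(y − n p) under the inner
posterior — the variance correction is essential, since marginalizing
e flattens the likelihood by an order of magnitude at large totals.
The quadrature was verified against brute-force nested adaptive
quadrature (agreement ~1e-10) and the full fit against glmmTMB's
Laplace fit (estimates and SE agree to four decimals on matched data).
Optimization is L-BFGS-B over (beta0, beta1, sigma_u, sigma_e) with
sigmas bounded at 0 and a Nelder-Mead fallback; variance estimates
below 1e-4 are reported as 0 with a boundary flag rather than an
error. All counts 0 or all counts equal to totals raise a separation
error. At least 4 donors with both timepoints are required.

**Inference.** The Wald SE of beta1 comes from the observed information
of the marginal likelihood in (beta0, beta1) at the variance estimates
(the usual mixed-model convention; including the variance parameters in
the information matrix was checked and changes nothing at balanced
designs). With one two-level fixed factor, the estimated-marginal-means
contrast after−before equals beta1 with that SE. The default p value
uses a t reference with df = (donors with both timepoints − 1):
calibration measured at the study's scale (30 donors, totals ≈ 2000,
sigma_u = 0.5, sigma_e = 0.3; 600 null replicates) gives type-I error
5.2% for the t reference versus 6.2% for the asymptotic normal, and
95%-interval coverage 94% versus 92%. The normal reference remains
available (`reference="normal"`).

**Multiplicity.** Benjamini–Hochberg step-up across clusters within a
(group, contrast) family — one p per cluster, groups fitted separately —
with adjusted p < 0.1 flagged significant (statsmodels' `fdr_bh`,
verified exactly against the step-up definition). Clusters whose fit
fails (separation, too few paired donors) are excluded from the family
and reported with a note.

**Nonparametric tests.** The paired signed-rank test discards zero
differences, uses the exact tabulated null for ≤ 25 untied differences,
enumerates all 2^n sign patterns of the (mid-)ranks when magnitudes are
tied and n ≤ 13, and otherwise applies the tie-corrected normal
approximation. The Mann–Whitney test is exact for untied samples up to
n = 25 per arm and tie-corrected asymptotic otherwise. All tests are
two-sided; an all-zero difference vector is reported as undefined
rather than an error.

## Pipeline and formats

Stages run in the order simulate → QC → hashtag → genotype → consensus →
abundance; the consensus stage refuses to run without both
demultiplexing stages. The genotype stage takes its provisional
per-sample grouping (cells of one donor in one run) from the hashtag
calls, mirroring how the two modalities bootstrap each other on real
data. TSV is the canonical interchange; hashtag matrices round-trip
through MatrixMarket triplets, SNP panels through a minimal sites-only
biallelic VCF. Readers validate counts, shapes and id uniqueness and
name offending lines. Cell ids are opaque strings. Two runs with the
same config and seed produce byte-identical outputs.

## Problem sizes

The test suite runs the demultiplexing accuracy checks at 15 donors ×
1000 cells (one run) and the concordance/consensus checks at 2 runs of
15 × 150 cells with 200 SNPs at depth 20; the GLMM calibration uses
100 replicates for interval coverage and 500 for type-I error at the
30-donor design. The acceptance script uses a 2-run, 15-donor × 300-cell
study and 100/300 GLMM replicates. These sizes were chosen as the
smallest at which the binomial/quadrature noise floors sit well below
the thresholds being asserted.

## Known limitations

* The hashtag mixture is fitted per run on all provided cells;
  pre-filtering presumed empty droplets would sharpen the noise
  component but is left to the caller.
* The genotype stage assumes biallelic SNPs and reads supporting either
  ref or alt only; multi-allelic sites are rejected at the panel
  boundary.
* No probabilistic fusion of the two modalities' likelihoods — the
  consensus is deliberately conservative set intersection.
* The GLMM fits each cluster independently; compositional coupling
  between clusters (one cluster growing forces others' proportions
  down) is not modeled.
* Between-group interactions are out of scope; groups are fitted
  separately, matching the separate-model design.
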