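# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It is the package's own
account of its science; every empirical claim here is computed by the test
suite or by `scripts/acceptance.py`.

## Mixed-model association

The phenotype model is `y = Xb + g + e` with `g ~ N(0, σ²_g K)` and
`e ~ N(0, σ²_e I)`. `X` contains an intercept, treatment-coded sex and
batch factors (first level as reference) and carcass weight as a covariate.

Two kinship weightings are offered. `raw` is mean identity-by-state,
`K_ij = mean_snps(1 − |g_i − g_j|/2)` with missing genotypes
pairwise-deleted; raw IBS matrices can be indefinite, so negative
eigenvalues are clipped at zero before fitting. `frequency` (the default) is
the allele-frequency-standardised relationship matrix `ZZ'/m` with
`Z = (G − 2p)/√(2p(1−p))` and missing dosages imputed at `2p`; it is
positive semidefinite by construction and weights rare alleles up, which is
the usual choice for polygenic covariance.

REML estimation is a single bounded 1-D optimisation of the heritability
ratio `h = σ²_g/(σ²_g+σ²_e)` on the eigenbasis of `K`, with the total
variance profiled out analytically; the `h → 0` boundary (pure OLS) is
always evaluated and preferred when at least as likely. Per-variant tests
are score tests against this null fit: `U = x'Py`, `χ² = U²/(x'Px)`,
`β = U/(x'Px)`, with `P` the inverse fitted covariance projected orthogonal
to the fixed effects. With `σ²_g = 0` and `K = I` this is exactly the OLS
Wald test computed with the null residual variance; the suite checks the
statistic against an explicit dense-matrix oracle. Two properties of score
tests are worth keeping in mind when reading output: χ² saturates near `n`
under a perfect fit instead of diverging, and β estimates under strong
signals are computed at the null variance (adequate here; exact per-SNP
refits are out of scope).

Conditional scans append the conditioning columns (e.g. CNV copy number) to
the fixed effects while reusing the null variance components — the standard
two-step approximation. A tested SNP collinear with the conditioning columns
is flagged rather than tested. Missing dosages are mean-imputed per SNP;
after QC, missingness is a few percent and the effect on the score test is
negligible relative to per-SNP sample dropping.

LOD is defined as `−log10(P)` everywhere. P-values are clamped into
`(0, 1]` at the smallest positive float so LOD stays finite on noiseless
toys.

## Meta-analysis

Per-population 1-df χ² values are summed per variant; the degrees of freedom
equal the number of populations actually contributing that variant (a
variant absent from one population's array simply contributes fewer df).
Combination is permutation-invariant and monotone in every input;
significance is Bonferroni `α/n` over tested variants.

## Quality control

Samples with call rate below 95% are removed first; SNP statistics are then
recomputed on the retained samples, and SNPs fail on call rate < 95%,
MAF < 1%, or exact-test Hardy-Weinberg `P < 1e-6` (boundary values kept,
filters applied in that order of precedence). The Hardy-Weinberg test is the
exact conditional test — the sum of probabilities of all heterozygote
configurations no more probable than the observed one given the allele
counts — because the χ² approximation is unreliable at the `1e-6` tail where
the filter operates. It is implemented in log-space with `gammaln` and
verified exhaustively against an exact rational-arithmetic enumeration for
all configurations up to n = 50.

## Confidence intervals and refinement

Step 1 takes the positional min–max span of SNPs with `r² > 0.8`
(strict, as a printed threshold; `r²` is the squared Pearson correlation of
dosages with pairwise deletion) to the peak; using the span rather than the
SNP set lets interior low-LD SNPs participate in step 2. Step 2 keeps SNPs
with `LOD > peak − 2` inside the span and returns their span. The peak is
always contained; when no SNP passes the LD threshold the interval
degenerates to the peak position with a warning. Coordinates are 1-based
inclusive internally; BED output is 0-based half-open, converted only at the
I/O boundary.

A caveat the synthetic experiments make visible: the 2-LOD drop-off is
calibrated only when the peak sits in a dense, near-saturated LD block. With
moderate tagging (inter-tag `r² ≈ 0.95`), the observed peak's
winner's-curse inflation is itself on the order of 2 LOD, the drop-off
retains little more than the peak, and coverage of the causal position falls
well below nominal. The generator's defaults therefore place the causal
variant in a saturated block (see below), which is also where the original
analysis operated; on sparser maps the interval should be read as
optimistic.

## Haplotype sharing

Phasing is consumed, not performed. Shared segments are maximal runs of
consecutive SNPs at which all carrier chromosomes agree; a missing allele
breaks a run (conservative default; a permissive mode lets missing match
anything). Segments are reported at the outermost matching SNPs — lengths
are therefore conservative by up to the inter-SNP spacing relative to the
(unknowable) recombination breakpoints. A segment is carrier-exclusive when
no control chromosome reproduces the carrier consensus across it. Haplotype
phenotype effects are estimated by OLS on per-sample haplotype-copy counts
plus covariates; least-square means are predictions for two-copy carriers at
covariate means, and pairwise contrasts are t-tests on coefficient
differences.

## Read-depth CNV calling

Per-base depth is divided by the track median, then by the median of its GC
bin (bin width 0.02; a degenerate bin falls back to the global median with a
warning). Windows of 20 bp slide by 1 bp; a window is variant when ≥ 18
bases pass the gain (ratio ≥ 1.4) or loss (≤ 0.6) threshold. Same-type
variant windows are unioned; unions separated by ≤ 200 bp (`merge_gap`,
configurable) merge; each region is emitted with its mean ratio and
`copies = round(2 × mean ratio)`. A copy-neutral track cannot satisfy either
threshold, so no two-copy call can be emitted by construction. Output
equals an independent brute-force per-window scan on every track the suite
throws at it. Junction support counts soft-clip positions within a tolerance
of either boundary; alignment itself is out of scope — the caller consumes
per-base depth (bedGraph), not BAM.

## Copy-number quantification

qPCR uses comparative Ct: `ΔCt = mean Ct_target − mean Ct_reference` over
replicates, `ΔΔCt` subtracts the two-copy calibrator's `ΔCt`, and
`copies = 2·2^−ΔΔCt`. The reference locus is assumed present at exactly two
copies. ddPCR uses single-dye Poisson occupancy per channel,
`λ = −ln(negatives/total)`, and `copies = 2·λ_t/λ_r`; a saturated channel
(zero negatives) is an error advising dilution, and the estimator's relative
bias is below 1% at 10⁶ droplets. Copies map to genotype classes by
half-up rounding: 2 → wild (−/−), 3 → het (+/−), ≥ 4 → hom (+/+) — animals
carrying two multi-copy alleles (six copies) still class as hom — and < 2
flags a loss. Amplification-efficiency correction (Pfaffl) is a non-goal.

## CNV association, interaction, eQTL

The CNV association is the fixed-effects linear model with RQ (or copies) as
a quantitative covariate — matching the written association equation — with
an optional polygenic mode through the same score-test machinery; variance
explained is `(V_reduce − V_full)/V_reduce` on residual variances of the
models without/with the term. The two-locus interaction is an F-test of the
full factor-by-factor model against the additive one; under an additive
simulation its type-I error is the nominal 5%.

Expression values (`2^−ΔΔCt`, multiplicative) are modelled on the log2 scale
by default and pre-adjusted for sex and batch with a Huber M-estimator
(tuning constant 1.345, via iteratively reweighted least squares). Kinship
enters the subsequent mixed-model eQTL scan, not the robust pre-adjustment —
adjusting for it twice would double-count relatedness. The CNV competes in
the scan as a shifted dosage (copies − 2) alongside the tag SNPs, with
Bonferroni over all tests.

Genotype concordance canonicalises both inputs (copies via the rounding map;
labels qq/Qq/QQ, −/−, +/−, +/+ via a fixed dictionary) and reports the
fraction of agreeing samples, making the measure symmetric and
relabelling-invariant.

## The synthetic-data generator

LD blocks come from a latent Gaussian AR(1) copula: each haplotype draws an
autocorrelated chain per block and thresholds it at the per-SNP
allele-frequency quantile. This gives phased haplotypes, exact control of
marginal frequencies, and adjacent-SNP `r²` tunable through the latent
correlation `ld_rho`, without coalescent machinery. One allele frequency is
drawn per block — SNPs tagging one haplotype share a frequency, without
which within-block `r²` is capped well below useful levels. Blocks are
independent of each other, so `block_size=1` yields independent SNPs.

The causal duplication is one extra latent site in the centre of the middle
block (its physical position falls between the flanking SNPs), with
Hardy-Weinberg diploid copies `2 + a₁ + a₂`. Carrier chromosomes
additionally inherit a single founder haplotype across the causal block —
identity by descent, as for a duplication that arose once — which is the
structure haplotype-sharing analysis exploits and which population LD alone
does not create. The default `ld_rho = 0.99999` makes the causal block
effectively saturated (tag `r²` to the CNV ≈ 0.99); as discussed above,
that is the regime in which the 2-LOD drop-off interval is calibrated. The
expression-eQTL experiment instead uses `ld_rho = 0.97`, giving tag `r²`
of ~0.85–0.9, so the CNV-versus-proxy ranking is genuinely contested.

Phenotypes follow the additive model with sex (12 cm²), batch (4 cm² per
level), carcass weight (0.6 cm²/kg), 15 cm² per extra copy, and a polygenic
plus residual variance of 100 cm⁴ split by `h² = 0.3`, the polygenic part
drawn against the realised kinship. Effect sizes in copy units are not
published quantities; these defaults are chosen for testability at desk
scale, not to mimic pig biology.

Depth tracks are negative binomial (variance `μ + 0.02·μ²` by default;
Poisson as dispersion → 0) around `mean_depth × gc_bias × copies/2`, with a
unimodal quadratic GC-efficiency curve peaking at 0.45 and a smooth random
GC track with ~100-bp correlation length. The canonical caller experiment
plants a 1-kb duplication in a 10-kb track: a duplication that is a large
fraction of its track contaminates the GC-bin medians (bins dominated by
in-CNV bases absorb the signal), biasing the ratio low — visible if the CNV
is made 20% of the track, and absent in genome-scale use where CNVs are a
vanishing fraction. ddPCR wells are binomial with Poisson occupancy
`λ_t = λ_ref·copies/2`; qPCR Ct values are Gaussian around
`Ct_ref − log2(copies/2)`; expression is log-normal around
`baseline·fold^(copies−2)`.

What the generator does **not** emulate: real array ascertainment and
genotyping error, pedigree structure of an actual F₂ cross (kinship is
population-style, not family blocks), read-level artefacts (mappability,
duplicates, insert-size effects), qPCR efficiency drift, or ddPCR droplet
volume variation. Passing tests demonstrate the algorithms implement their
definitions and are calibrated under these idealised conditions; they do not
certify performance on real livestock data.

## Determinism and numerics

Every generator takes a seed and is bit-reproducible; derived seeds are
produced with `SeedSequence` spawning. Eigendecompositions use `eigh` on
symmetrised matrices; the REML search tolerance is `1e-8` on `h`;
window-count comparisons use half-integer thresholds to avoid
floating-point equality; degenerate inputs (all-missing SNP columns,
monomorphic SNPs, zero-variance phenotypes, saturated ddPCR wells, empty GC
bins) raise or flag explicitly rather than propagate NaNs.

## Problem sizes

The shipped experiments use 500 samples × 600 SNPs for fine-mapping
replicates, 5 × (300 samples × 2000 SNPs) for null calibration, 200
replicates at n = 400 for effect recovery, 500 replicates for the
interaction type-I rate, and 100 seeds for caller accuracy — sizes at which
every calibration property is measured with useful precision on a single
CPU in well under a minute.
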