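# Methods

## Scope and data model

`linevar` analyses a *multi-line cohort*: L ≥ 1 closed populations ("lines")
genotyped at one shared index of biallelic variants. Genotypes are
alternative-allele dosages in [0, 2] (imputed data are the norm; hard calls
are the special case of integer dosage). A variant that does not appear in a
line's input VCF is *absent* (not called) in that line — stored as NaN and
distinct from a dosage of 0, which is a call of homozygous reference.
Coordinates are 1-based inclusive at the VCF boundary and converted to
0-based half-open internally; all windows are half-open. Missing
per-individual genotypes are a hard error at load time (the analyses assume
fully imputed data); a config flag enables per-line mean imputation instead.

## Per-site statistics

For each line, the alternative-allele frequency is p̂ = mean(dosage)/2. A
variant *segregates* in a line when 0 < p̂ < 1; its prevalence level k is
the number of segregating lines. Wright's fixation index is computed among
the segregating lines only (a "called" mode includes lines fixed for either
allele, for sensitivity analysis):

    F_ST = (H_T − H_S) / H_T,   H_T = 2 p̄ (1 − p̄),   H_S = mean_l 2 p_l (1 − p_l),

with unweighted line means (the population-level definition carries no
sample-size weights; Hudson-style weighting is available behind a config
switch, off by default). Under unweighted means H_T ≥ H_S by Jensen's
inequality, so F_ST ∈ [0, 1]; this is asserted, not clamped, and values
within 1e-15 of zero are snapped to exactly zero so that "equal frequencies
give F_ST = 0" holds in floating point.

**Small-L bias (important).** This per-site estimator uses the mean of the
L *observed* line frequencies for H_T. Its expectation under an
island-model divergence with parameter F is approximately
F(1 − 1/L)/(1 − F/L), below F for finite L (and the per-variant ratio form
is lower still). At L = 3 and F = 0.4 the expected estimate is ≈ 0.23–0.31,
not 0.4. The estimator is kept exactly as defined — it is the quantity the
downstream stratified tables report — but parameter-recovery claims about
the generator should use many lines or the closed form above, not the raw
estimate at small L.

Windowed density statistics count variants (overall and by prevalence
class) in the non-overlapping 1-Mb windows of the recombination map;
density is count divided by the true window length (final partial windows
retained). The density–recombination association is the Pearson correlation
on raw densities, with a two-sided p-value; degenerate series (fewer than 3
windows or zero spread) yield no correlation rather than NaN.

## Consequence classification

The severity scale follows the conventional most-to-least-severe ordering
of Sequence Ontology terms: splice acceptor/donor, stop-gain, stop-loss,
start-loss (together the LOF group), frameshift indel, in-frame indel,
missense, splice region, synonymous, promoter/5′UTR, 3′UTR, non-coding
transcript exon, intronic, upstream, downstream, intergenic. Frameshift
indels are never folded into LOF: in stratified population data they behave
unlike the other LOF classes, so they are quantified separately. A variant
with several transcript annotations resolves to its most severe category;
unknown SO terms are errors, never silently binned.

Upstream-of-gene variants within 500 bp of the TSS *on the transcribed
strand* are reclassified as promoter/5′UTR. The distance is inclusive
(≤ 500, and a variant at the TSS base itself qualifies) — the boundary
convention is stated here because no external convention fixes it. Missing
TSS leaves the category unchanged with a log entry. Missense variants split
by SIFT score: < 0.05 deleterious, ≥ 0.05 tolerated, absent score
unclassified. Relative transcript position is linear in transcript
coordinates, 0 at the transcription start (the high reference coordinate
for minus-strand transcripts) and 1 at the end.

## Allele load

Per (category × prevalence) cell and individual: the count and percentage
of the cell's variants carried heterozygous and homozygous-alternative,
with dosages hard-called by nearest-integer rounding ([0, 0.5) hom-ref,
[0.5, 1.5] het, (1.5, 2] hom-alt). Categories above 50,000 variants are
down-sampled uniformly without replacement (seeded); the tolerated-missense
category instead keeps the 50,000 highest-SIFT variants, ties broken by
variant key order, so that the "most clearly tolerated" subset is measured.
Sampling is per consequence category with prevalence tallied inside the
sample. Cohort-level means and SDs accompany the per-individual table.

## Mixed-model association

The scan fits y = 1μ + x_i β_i + u + e per variant, u ~ N(0, σ²_u K), e
white noise, K the VanRaden method-1 GRM (centred dosage cross-products
over 2Σp(1−p)). K is eigendecomposed once; the variance *ratio*
δ = σ²_e/σ²_u is estimated once per trait by REML (1-D bounded optimisation
of the profiled restricted likelihood in log δ over the rotated data) and
fixed for the scan. Each variant test is then a weighted least-squares
solve in the rotated basis with the residual *scale* profiled per variant
and a Wald t-test on n − p degrees of freedom. This is numerically
identical to a dense feasible-GLS solve with covariance σ²_u K + σ²_e I
(as statsmodels implements it), reduces exactly to OLS when K = I, and has
exact finite-sample type-I calibration for Gaussian traits — the reason the
scale is profiled rather than frozen at the null value. When K's
eigenvalue spectrum is flat the two components are not separately
identifiable; the fit is flagged and only the total variance is meaningful.
Monomorphic variants get an absent p-value and are never significant.
Significance is p ≤ 10⁻⁶ by default. Per-variant explained variance is
100 · 2p(1−p)β̂²/σ̂²_y with σ̂²_y the empirical variance of the analysed
trait vector; it is 0 by continuity at fixed sites and invariant to allele
relabelling. Dosages are used as-is by default; a hard-call flag rounds
them first. No covariates are fitted beyond the intercept unless supplied.

## Haplotype blocks and candidates

For every variant pair within 5 Mb, haplotype frequencies are estimated by
EM over the 3×3 unphased genotype table (double heterozygotes split by the
current coupling/repulsion odds; ≤ 1000 iterations, non-convergence makes
the pair uninformative) or read directly from phased input. The likelihood
of |D′| is evaluated on a 101-point grid in [0, 1] with allele frequencies
held at their sample values and the sign of D fixed at the EM estimate; the
90% interval spans the 5th–95th percentiles of the normalised likelihood
mass. Pairs classify as strong LD (lower bound > 0.7 and upper bound
≥ 0.9), strong recombination (upper bound < 0.7), else uninformative.
Blocks are intervals of ≥ 2 variants whose informative pairs are ≥ 90%
strong-LD (at least one informative pair required); overlaps are resolved
greedily longest-span-first, ties to the leftmost start — a deterministic
rule chosen because the block definition itself does not dictate conflict
resolution. Candidates are selected among a block's *significant* members
(a flag widens to all members): most severe category, then lowest p-value,
then lowest position. Enrichment per category cell is
ln[(nSign/nNotSign)_category / (nSign/nNotSign)_total]; natural log
throughout (recorded in output metadata; base changes are a constant
factor). Zero significant or zero non-significant counts produce signed
infinities reported as absent with their count context. F_ST enrichment of
candidates is ln(median F_ST of candidates / median F_ST of category).

## Synthetic data generator

The generator reproduces the structure the analyses assume, with ground
truth for every variant:

* **Line divergence** — shared variants draw per-line frequencies from the
  Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F) around an
  ancestral frequency p; chosen over forward simulation because the
  variance Var(p_l) = F·p(1−p) gives an analytic recovery target.
* **Prevalence spectrum** — a fraction of variants (default 0.28) is
  injected into a single line with a low-frequency Beta(0.5, 10) spectrum
  (mean ≈ 0.045); direct injection, rather than line-specific mutation
  histories, gives exact control of the prevalence mix. Together with the
  rare-skewed ancestral spectrum Beta(0.3, 1.2), mean allele frequency
  rises monotonically with prevalence level.
* **Purifying selection** — generating frequencies of LOF categories
  (×0.3) and deleterious missense (×0.25) are multiplicatively down-shifted,
  which depletes their allele frequencies and homozygous-alternative load.
* **Genome structure** — 1-Mb windows with Gamma(2, 0.6) recombination
  rates (cM/Mb, mean 1.2); variant placement intensity 1 + 2·rate.
* **Defaults** — 5 lines × 100 individuals × 20,000 variants, F = 0.2, mean
  coverage 4.1× with 1% high-depth outliers at 5× — a desk-scale cohort
  whose category *proportions* follow a realistic genome-wide composition.
  Because that composition leaves coding categories nearly empty at 20k
  variants, `coding_enriched_mixture()` provides an alternative used by
  category-level tests and the acceptance script; it changes cell counts,
  not the selection or divergence mechanics.
* **Genotypes** — Binomial(2, p_l) per individual (linkage equilibrium) by
  default; a haplotype-copying mode samples each individual as two
  haplotypes from a per-line pool of size m, producing LD that strengthens
  as m shrinks (used for the block analyses, since binomial sampling has no
  LD by construction).
* **Phenotypes** — y = Σ x_c β_c + g + e with each β_c solved so that
  β_c²·Var(x_c) meets its target share of unit total variance, polygenic g
  built from N(0,1) effects on a random marker subset and rescaled to the
  target background variance, and the remainder white noise. Realized
  components are recorded alongside the targets.

What the generator does *not* emulate: coalescent or pedigree structure,
selective sweeps and hitchhiking, imputation error, sequencing noise, and
realistic LD decay along the chromosome (the haplotype-pool LD is
exchangeable within a line, not distance-structured beyond the 5-Mb pair
window). Tests passing on these cohorts therefore validate the estimators
and the pipeline's bookkeeping — not robustness to those real-data
complications.

## Numerical choices and problem sizes

REML optimises log δ on [−12, 12] with 1e-8 tolerance; GRM input must
contain a polymorphic marker; kinship eigenvalues are floored at 0 and a
substantially negative eigenvalue is an error. The EM tolerance is 1e-12.
F_ST values within 1e-15 of 0 snap to 0. Output floats are written with 6
significant digits.

The test-suite simulations use desk-scale sizes chosen to make each
statistical check decisive at comfortable margins: 20,000 variants for
frequency-spectrum properties, 10⁵ null tests at n = 500 for scan
calibration (threshold 10⁻³, expectation 100 hits, checked within 3
Poisson SEs), 100 trait replicates at n = 2,000 for power against a
3%-variance causal variant, 200 random instances of ≤ 15 variants for the
block-finding oracle, and 500 replicates at n = 1,000 for the D′
confidence-interval behaviour under independence. The acceptance script
runs three seeded stages (population statistics, GWAS, fine-mapping/blocks)
in about 15 seconds total. In the fine-mapping stage every variant of the
5-Mb region lies in the span of the small haplotype pool, so a polygenic
term built from the same region would absorb the causal effect entirely
("proximal contamination"); that stage therefore scans with an identity
kinship, i.e. plain least squares.

## Known limitations

* The per-site F_ST estimator is biased downward at small numbers of
  segregating lines (see above); stratified F_ST tables are comparable
  within a fixed k but k-levels are not directly comparable to each other
  or to the island-model parameter.
* The D′ confidence interval fixes allele frequencies at their sample
  values (profile over D′ only), the standard shortcut of block-definition
  software; at very small samples the interval is slightly narrow.
* Block finding is exact for the stated greedy rule but O(m³) per
  chromosome in the number of variants considered; restrict to regions of
  interest for dense data.
* The load accounting drops variants not called in the analysed line from
  the category denominator; with very small sampled categories the
  percentages can be noisy.
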