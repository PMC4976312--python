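# Methods

## The genetic model

The CNV is multi-allelic: a chromosome carries k ∈ {1,2,3} tandem copies of
the segment, and two flanking SNPs (rs183211, rs17698176) define a
haploallele.  A *haplotype* is the pair (haploallele, k).  Genotyping
observes only the diploid copy total c ∈ {2,…,6} and, per SNP, an
unordered allele pair; the partition of c into (k₁, k₂) and the SNP phase
are latent.  Compatible diploid partitions are 2→(1,1), 3→(1,2),
4→(1,3)|(2,2), 5→(2,3), 6→(3,3); SNP phase contributes a second,
independent source of ambiguity for multiple heterozygous loci.

### EM haplotype frequency estimation

Under Hardy-Weinberg equilibrium the probability of an unordered haplotype
pair {h₁,h₂} is f(h₁)f(h₂), doubled when h₁ ≠ h₂.  The observed-data
likelihood of a genotype is the sum over its compatible pairs.  The EM:

- **Seeding** — every individual spreads unit weight uniformly over its
  compatible pairs; accumulated weights, normalized, form the initial
  frequency table.  This realizes "seed from genotype counts"
  deterministically: unambiguous individuals (total 2 copies, ≤1
  heterozygous locus) contribute their full weight to their only pair.
- **E-step** — posterior weight of pair {h₁,h₂} ∝ m·f(h₁)f(h₂), m = 2 for
  heterozygous pairs; expected haplotype counts accumulate.
- **M-step** — f(h) = expected count / 2N.
- **Convergence** — max per-haplotype |Δf| < 1e-5 ("stable to five decimal
  places"); cap 200 iterations, with a `converged` flag and the
  log-likelihood trace in the output.  On cohorts of ~400 individuals drawn
  from the reference table, convergence typically occurs within 10-20
  iterations.

Haplotypes supported by the allele sets but absent from the data are kept
in the output at frequency 0 so the table schema is stable.  The haploid
copy support {1,2,3} is configurable.  HWE is assumed, not tested — with
unphasable genotypes there is no model-free test, and copy-dosage effects
depend on the total anyway.

Properties asserted by the test-suite on every run: the observed-data
log-likelihood is non-decreasing across iterations; frequencies sum to 1
after every M-step; with no ambiguity the EM equals direct counting in one
iteration; on small cohorts it matches a multi-start Nelder-Mead maximizer
over the simplex within 1e-4.

### LD and the haploallele-copy screen

For haplotype classes A (on alleles) and B (on copies): D = f_AB − f_A·f_B
and r² = D²/(f_A(1−f_A)f_B(1−f_B)).  On the reference frequency table the
GT haploallele vs the one-copy class gives r² = 0.609 → 0.61.  The
chi-square screen builds the 2×2 table of expected haplotype counts
(frequencies × 2N); because those are EM expectations rather than observed
chromosomes, its p-value is labelled approximate and is not treated as an
exact test (for a 2×2 the statistic reduces to 2N·r², which the tests use
as a closed-form oracle).

## qPCR copy-number model

Ct falls by one cycle per E-fold increase in starting template, E =
10^(−1/slope) from the dilution standard curve (E = 2 is perfect doubling;
the assays modelled here run at E = 1.94).  With ΔCt = Ct_target −
Ct_reference and ΔΔCt = ΔCt_sample − ΔCt_calibrator(2 copies), the copy
estimate is 2·E^(−ΔΔCt).  Replicates are averaged on the Ct scale
(arithmetic mean, with a configurable spread flag — whether the original
assays applied such a QC rule is unknown, so none is applied by default).
The estimate snaps to the nearest integer in [2,6] when within 0.3 copies,
else the sample is discarded as ambiguous; 0.3 is a default (the practice
of discarding is documented for the assays modelled, the threshold is
not).  The single 2-copy calibrator anchors the computation; calibrators
3-6 are re-called each run as concordance controls.  Boundary
delimitation classifies an amplicon inside the CNV when its calls vary
across samples and agree sample-by-sample with an internal-control
amplicon, outside when constantly 2; per-sample discordance between
co-varying amplicons is flagged.

## Association statistics

Rows are (case, control), columns (low {2,3}, high {4,5,6}); the low set
is configurable (the {2,3,4} sensitivity split included).  The 2×2 exact
p is two-tailed by the "probability at most observed" rule; both the
sample OR (ad/bc, Woolf CI) and the conditional-MLE OR (noncentral
hypergeometric likelihood, via `scipy.stats.contingency.odds_ratio`) are
reported because they answer slightly different questions and differ in
the third decimal at these sample sizes.  The five-category 2×K test
enumerates all margin-fixed tables when their number is within a 2×10⁶
budget (counted first by dynamic programming), otherwise estimates the
p-value by multivariate-hypergeometric Monte-Carlo sampling with 10⁶
draws and reports the binomial standard error.  Logistic adjustment fits
status ~ low-copy + covariates by ML and fails loudly on separation or
zero-variance covariates.  Onset analyses: Mann-Whitney U on the lapse
(years) between first use and dependence, low vs high copies; and a
one-tailed exact test on early (<1 y) vs late (≥1 y), with exactly 1.0
year counted late.  Cases missing the lapse are dropped from onset
analyses only.  No multiple-testing correction is applied anywhere,
matching the source analyses.

## Expression dosage

rel_expr = E^−(Ct_target − mean(Ct_ref1, Ct_ref2)), i.e. normalization to
the geometric mean of the two reference-gene quantities (the combination
rule is a package choice; the source does not state one).  Per transcript:
Kruskal-Wallis across copy groups with ≥2 samples, low/high Mann-Whitney,
fold change as mean(high)/mean(low) (medians via flag — the fold-change
central tendency is likewise unstated upstream), Spearman ρ with
average-rank ties and t-approximation p, and the OLS slope on copies.
Statistics whose group requirements fail are reported as None rather than
aborting the rest.

## Synthetic cohort generator

What it emulates: haplotype draws i.i.d. from a frequency table with HWE
pairing (phase then discarded); prospective case sampling,
P(case) = logistic(β₀ + β·1[low copies]); Gaussian ages per arm;
log-normal onset lapse (right-skewed, as the observed lapse distribution
is) with the low-copy median shifted; Ct values inverting the ΔΔCt model
with independent Gaussian cycle noise on every replicate of both target
and reference amplicons and noise-free calibrators; expression linear in
diploid copies with Gaussian noise and zero slope outside the CNV.

Key defaults (the cohort-like scenario, `data/default_scenario.yaml`):

| parameter | default | why |
|---|---|---|
| haplotype table | nine reference frequencies (normalized; printed values sum to 1.0001) | the estimated population table |
| n_individuals | 1792 | pooled case-control size |
| low_copy_log_or | ln 1.459 | pooled point estimate |
| case intercept β₀ | −0.325 | yields overall case fraction ≈ 867/1792 given the table's low-copy mass (0.69) |
| ages | cases 35.6 ± 7.9, controls 52.4 ± 16.8 y | cohort demographics |
| onset lapse | log-normal, high-copy median 1.5 y, log-sd 1.0, shift −0.5 y, 25% missing | only medians and skewness are known; values chosen to put a realistic mass below the 1-year cut |
| Ct noise | sd 0.1 cycles, triplicates, E = 1.94 | typical SYBR replicate scatter; the shared assay efficiency |
| expression slopes | 1.0 with intercepts −0.963 / 0.940 (internal), 0 (external) | solved so high/low group-mean ratios are 2.1 and 1.5 under the default copy distribution |

What it does **not** emulate: genomic coordinates, read- or
intensity-level data, population stratification, genotyping error in the
SNPs, plate effects, correlated replicate noise, or retrospective
(outcome-dependent) sampling.  Passing tests therefore show the
*statistical machinery* is correct under the stated model, not that real
cohorts satisfy the model.

## Numerical choices and degenerate inputs

Exact-test enumeration compares log-probabilities with a relative 1e-9
slack so ties are included as in classical implementations.  A zero cell
makes the sample OR 0/∞ and the Woolf CI undefined (flagged, not raised).
Monomorphic classes make r² undefined and raise.  EM individuals whose
compatible pairs all hit zero frequency (possible only by underflow) fall
back to uniform weights for that step.  Estimates outside [2−tol, 6+tol]
are ambiguous by construction.  All randomness descends from one root
seed; each generator stage derives an independent stream, so stages are
reproducible in isolation and end-to-end reports are byte-identical
modulo the timestamp.

## Problem sizes

Test and analysis runs use the study's own scales where they are known —
n = 1792 (association), 407 (EM/LD), 174 (delimitation), 652
(onset-reporting cases), 45 (expression donors) — and 10,000 for the
frequency-recovery property; seed-sweep calibrations use 25-100
replicates, chosen to keep the whole suite under a minute while leaving
the binomial error of the calibrated rates well below the asserted
margins.

## Known limitations

- The chi-square haploallele-copy screen treats EM expectations as counts;
  its p-values are optimistic and labelled approximate.
- The conditional-MLE and sample OR agree only to ~2 decimals at these n;
  published point estimates rounded from percentages can differ in the
  third decimal from either.
- The EM's likelihood surface can be multi-modal for pathological tiny
  cohorts; the deterministic seeding makes results reproducible but global
  optimality is only verified on the tested instances.
- The 2×K Monte-Carlo p-value is an estimate; its standard error is
  reported and should be checked against decision thresholds.
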