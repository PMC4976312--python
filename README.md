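# nsfcnv

Analysis pipeline for a highly polymorphic copy number variant (CNV)
spanning the first 13 exons of the human *NSF* gene, built for case-control
studies of substance dependence.  Each chromosome carries 1-3 tandem copies
of the ~734 kb segment, so diploid genotypes range from 2 to 6 total copies
and neither SNP phase nor the haploid copy partition is directly
observable.  The package implements the four analyses such a study needs,
plus a synthetic cohort generator so the entire pipeline is testable
without clinical data:

1. **qPCR copy-number calling** (`nsfcnv.qpcr`) — standard-curve
   amplification efficiency E = 10^(−1/slope); comparative ΔΔCt
   quantification against a 2-copy calibrator, estimate = 2·E^(−ΔΔCt);
   integer calling with an ambiguity tolerance (estimates between integers
   are discarded, not force-called); CNV boundary delimitation from
   per-amplicon call patterns.
2. **Case-control association** (`nsfcnv.association`) — low {2,3} vs high
   {4,5,6} copy dichotomization; Fisher's exact test (2×2 and margin-fixed
   2×K with complete enumeration or Monte-Carlo); sample odds ratio ad/bc
   with Woolf 95% CI, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), and the
   conditional-MLE odds ratio; age-adjusted logistic regression; onset-lapse
   analyses (Mann-Whitney U; early <1 y vs late ≥1 y one-tailed exact test).
3. **SNP-CNV haplotype EM and LD** (`nsfcnv.haplotypes`) — the core
   algorithm: maximum-likelihood estimation of joint (SNP haploallele ×
   haploid copy count) haplotype frequencies from unphased genotypes under
   Hardy-Weinberg equilibrium.  The E-step weights each individual's
   compatible haplotype pairs by f(h₁)f(h₂) (×2 if heterozygous); the
   M-step divides expected counts by 2N; iteration stops when every
   frequency is stable to five decimals.  LD between haplotype classes is
   r² = D²/(f_A(1−f_A)f_B(1−f_B)) with D = f_AB − f_A·f_B.
4. **Expression dosage trends** (`nsfcnv.expression`) — two-reference-gene
   ΔCt normalization; Kruskal-Wallis across copy groups, low/high
   Mann-Whitney, fold change, Spearman ρ and OLS slope per transcript.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort drawn from the reference haplotype frequency table:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_case_control_association.py --seed 1
python analysis/04_haplotype_em_ld.py
```

which prints (abridged):

```
simulated n=1792 (cases 841, controls 951)
diploid copy totals: {2: 579, 3: 689, 4: 368, 5: 139, 6: 17}
discovery    low-copy 72% cases vs 63% controls; OR 1.51 [1.10-2.07], CMLE 1.510, P = 0.013
replication  low-copy 69% cases vs 61% controls; OR 1.42 [1.10-1.83], CMLE 1.422, P = 0.0071
pooled       low-copy 71% cases vs 62% controls; OR 1.46 [1.20-1.78], CMLE 1.461, P = 0.00018
simulated     OR 1.40 [1.14-1.72], P = 0.0015; 5-category exact P = 0.016 (monte_carlo)
EM on n=407 (rs183211/rs17698176): converged in 10 iterations
LD r2 (GT vs 1 copy): estimated 0.642, reference table 0.609
```

The first block re-analyzes the published low/high contingency counts
(cases are enriched for 2-3 copies, OR ≈ 1.5); the second shows the same
effect recovered from a cohort the generator built with that odds ratio;
the EM block estimates the nine haplotype frequencies from unphased data
and finds the risk haploallele GT in strong LD with the one-copy CNV
allele (r² ≈ 0.61 on the reference table).

The same stages are available as a CLI (`nsf-cnv run-all --seed 1
--out-dir results/run`) or through `nsfcnv.pipeline.run_pipeline`, which
emits a schema-validated JSON report.

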