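# Methods

This note documents the statistical procedures, the synthetic-data
generator that stands in for subject-level study data, the numerical
choices, and the known limitations.

## Association model

Each cisSNP/transcript pair is fit by OLS of preprocessed expression on
minor-allele dosage with covariates. Design choices:

- **Cis window.** 1-based inclusive coordinates; a SNP is cis to a probe
  iff it shares the chromosome and `gene_start − w ≤ pos ≤ gene_end + w`
  with `w = 100 kb` by default; the window test is inclusive at both ends.
- **Covariates.** Plate enters as indicator contrasts (first level as
  reference); RIN enters linearly and as `(RIN − mean RIN)²` with the mean
  recomputed on each analysis set; diagnosis (AD = 1) enters only in
  combined-cohort analyses; eigenvector columns (`ev*`) are used when
  present. Rank-deficient designs drop aliased columns with a warning.
- **Replicates.** Subjects measured on several plates enter the
  regressions once, via their first-plate measurement; the replicates are
  reserved for the ICC.
- **SNP QC.** Empirical MAF ≥ 0.01 and Hardy–Weinberg p > 1e-7 on the
  analysis subjects, both exposed as options.
- **Missing data.** Complete-case per pair. When the matrices are
  complete, a vectorized Frisch–Waugh path (residualize expression and
  dosage on the covariate design once; each pair then reduces to a simple
  regression with n − rank(X) − 1 residual df) computes betas, SEs and
  p-values identical to the full per-pair OLS; the test suite verifies
  agreement with statsmodels to 1e-8.

**Genomic control.** λ = median(χ²₁)/0.45494. Statistics are divided by λ
only when λ > 1 (no deflation), then converted back to p-values. Applied
per analysis (cohort × tissue) before q-values.

**Storey q-values.** π₀ is estimated by the smoother method:
π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid 0.05…0.95, smoothed with a cubic
polynomial fit and read off at λ = 0.95, clamped to (0, 1]. (The canonical
implementation uses a df = 3 smoothing spline; a cubic fit is the closest
closed-form smoother available with numpy/scipy alone and agrees closely
on well-behaved p-value distributions.) With π₀ = 1 the q-values equal
Benjamini–Hochberg exactly. For n < 2, π₀ is fixed at 1.

**Best cisSNP.** Per probe, minimal genomic-control-adjusted p; ties by
larger |β|, then lexicographically smaller SNP id.

## Two-stage evidence

Discovery requires q < 0.05 in both cohorts of the discovery tissue.
Validation computes K = number of discovery pairs testable in the
validation tissue and declares a pair validated iff `p_validation · K < α`
(α = 0.05). The "study-wide" denominator is the testable-discovery count,
not the validated count. The counting identity
`discovery = validated + failed + untestable` holds by construction.
Either tissue may serve as discovery.

## Variance decomposition

**ICC.** One-way random-effects ANOVA method of moments with subject as
the grouping factor (plate/day are not separate strata): σ²𝓌 = MSW,
σ²ᵦ = (MSB − MSW)/n₀ truncated at zero, with n₀ the unbalanced-design
effective replicate count. A probe with zero total variance is reported as
ICC 0 with a `degenerate` flag. Note the ratio estimator carries a small
negative bias (≈0.02 at 15 subjects) even though the variance components
themselves are unbiased.

**Sequential R².** Three nested OLS fits — technical only; + biological
covariates; + best-SNP dosage — give non-negative increments summing to
the full model's R² (unadjusted coefficient of determination, matching the
"proportion of variance" reading). Adjusted values divide each increment
by (1 − R²technical), i.e. the increment as a share of the non-technical
variance. This rule reproduces the published adjusted best-SNP fractions
of the four worked-example probes to ±0.001; one probe (MTRR) lands at the
band edge (0.808 vs printed 0.809), consistent with the printed inputs
being rounded.

## Westfall–Young permutation

Max-T stepdown on the absolute residual correlation (a monotone transform
of the OLS |t|). "Maintaining the covariate structure" is implemented
Freedman–Lane style: expression and dosage are residualized on the
covariate design once; each permutation shuffles whole residual-expression
rows jointly across probes (preserving inter-probe correlation) and
re-residualizes the permuted rows on the design so permuted and observed
statistics live in the same (n − rank X)-dimensional space — without the
re-residualization the family-wise error is visibly inflated. Empirical
p-values use +1 smoothing, so the floor is 1/(B + 1); stepdown
monotonicity is enforced along decreasing significance, and adjusted ≥ raw
always. Perfectly duplicated probes receive identical adjusted p-values.
The default B is configurable; the calibration test uses B = 500 and
observes family-wise error within Monte-Carlo error of 0.05.

## Catalog enrichment

The catalog is filtered to rows whose SNP field is a single rs number
(haplotypes, multi-SNP and non-rs entries dropped), gated at reported
p ≤ 1e-5, and de-duplicated to (SNP, trait) pairs. The test statistic is
the unique-SNP overlap between the significant set and the catalog. The
null redraws SNP sets from the tested universe without replacement,
matched to the significant set's per-bin counts over ten MAF bins
(half-open [0, 0.05), …, last bin closed at 0.5). Because each bin's draw
is a uniform without-replacement subset, the per-bin overlap is exactly
hypergeometric and the total is a sum of independent hypergeometric
variables; the default path samples those counts directly, which makes
10⁶ simulations cheap, while `method="sets"` draws explicit SNP sets and
is cross-checked against the count path in the tests. Empirical p uses
+1 smoothing; fold = observed/null mean (0 when both are 0).

## Synthetic-study generator

The generator emulates the statistical structure of an autopsy eGWAS:

- **Genotypes.** Dosage ~ Binomial(2, MAF) per subject (HWE, no LD). MAFs
  uniform on a configurable range so all ten enrichment bins are
  populated.
- **Layout.** Genes spaced 250 kb apart across a few chromosomes (wider
  than gene length + 2 × window, so cis windows are disjoint); SNPs are
  assigned round-robin to genes and placed inside their cis windows.
- **Expression.** Per measurement:
  μ_probe + Σ β·g + plate(probe, plate) + γ'x + subject(probe, subject) + ε,
  with plate effects N(0, σ²_plate) per probe-plate cell, a between-subject
  random effect shared across a subject's replicate measurements, and
  independent noise. Defaults: σ_noise = 1, σ_subject = 1, σ_plate = 0.3,
  modest covariate coefficients (e.g. RIN 0.2 per unit). RIN ~ N(8, 0.5²)
  truncated to [5, 10]; plates round-robin; APOE ε4 enriched in cases.
- **Cohorts/tissues.** 374 subjects (fraction of cases 197/374) by
  default; two tissues re-draw all stochastic terms with shared true
  effects; options decouple effects per cohort or tissue to exercise the
  replication filter's rejection path.
- **Replicates.** 15 subjects × 5 measurements on distinct plates, for the
  ICC.
- **Detection.** Bernoulli per measurement with a probe-level rate; by
  default 10% of probes get rate 0.5 (filtered out at the >75% cut) and
  the rest 0.995.
- **Catalog.** Single-rs rows drawn MAF-bin-balanced so the expected
  in-significant-set fraction is `factor × |sig|/|universe|` per bin
  (fractional expected counts resolved with a Bernoulli coin, keeping the
  expectation exact), plus decoy rows (multi-SNP, non-rs, weak-p) that the
  filter must remove.

What the generator does **not** emulate: linkage disequilibrium, bead-array
background/noise models, cell-composition effects, batch-by-probe
interactions beyond plate, and real MAF/effect-size spectra. Passing tests
therefore certify the statistical machinery (calibration, recovery,
counting identities), not performance on real array data.

## Problem sizes used by the test suite

Chosen to make every calibration check statistically meaningful while the
whole suite stays fast: false-discovery control uses 50 null studies of
200 subjects × 2,000 cis pairs; effect recovery uses 40 planted effects at
n = 200, σ = 1; family-wise calibration uses 200 seeds × 100 correlated
probes at B = 500; ICC recovery uses 15 × 5 replicates over 500 probes;
enrichment exactness uses a 10-SNP universe against exhaustive
enumeration at 10⁵ draws.

The planted-enrichment power check runs at one fifth of a realistic study
scale (significant set 520, catalog 850, universe 40,000). An a priori
power calculation fixed this size: at one twentieth scale the null overlap
mean is ≈2.8 against a planted observed mean of ≈6.6 with sd ≥ 1.5, so an
empirical p < 0.01 is reached in only ~30–50% of seeds no matter how the
catalog is drawn — the fold estimate is unbiased at any scale, but the
*detection* of a 2.4-fold excess needs larger sets; at one fifth scale the
separation is comfortable.

## Known limitations

- Without LD, the "best cisSNP" is almost always the causal one; on real
  data it is a tag, and the variance attributed to it is a lower bound.
- The log2 VST is a monotone stand-in for the model-based
  variance-stabilizing transform of bead arrays; rank-based downstream
  statistics are unaffected, absolute effect sizes on the transformed
  scale are not comparable to lumi's.
- Quantile normalization is exactly idempotent only for tie-free data;
  tied values receive averaged quantile targets.
- The π₀ smoother can dip below 1 on null data (mild anti-conservatism of
  single-analysis q-values); the dual-cohort intersection rule is what
  controls false discoveries in the two-stage design.
- The enrichment test treats significant SNPs as exchangeable within MAF
  bins; with LD-clustered significant sets the null would need clumping
  first.
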