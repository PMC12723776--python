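# Methods

## Model

`asevar` quantifies, per gene, how much a population's gene expression varies
because of common genetic regulatory variation, using haplotype-aggregated
allele-specific expression (ASE).  For individual *i* at gene *g*, let
*a*, *b* be the read counts assigned to the two phased haplotypes and
*n = a + b* the total.  The latent **log allelic fold change**
δ = log(e_A / e_B) — the natural-log ratio of the two haplotypes' expression
dosages — is modeled as Normal across individuals, and reads as binomial
around it:

    δ_gi ~ Normal(0, sd_g(g)^2)
    a_gi | δ_gi ~ Binomial(n_gi, logistic(δ_gi))

a binomial-logit-normal (BLN) compound law.  `sd_g` is the gene's regulatory
variability in log allelic fold change; `vg = sd_g^2 / 2` (the per-haplotype
variance convention) is emitted alongside for interoperability with external
reference tables — the loader's `vg_convention` flag converts two-column
legacy tables on read.

Because aggregation sums reads over all phased heterozygous sites of a gene,
there is no per-site linkage structure left to model: a single BLN component
with mean zero suffices.  The zero mean reflects that haplotype A/B labels
are arbitrary per individual, so the marginal law of the allelic ratio is
symmetric; estimates are invariant to swapping (a, b) labels of any subset of
individuals (asserted in tests).

The same law drives the **dosage outlier test (DOT)**: given a reference
`sd_g` for the gene (from a matched reference cohort), a sample's observed
count pair is assigned a two-sided tail probability under
BLN(n, 0, ref_sd_g), p-values are Benjamini–Hochberg adjusted within the
sample over the gene universe (conventionally protein-coding + lncRNA), and
genes at q ≤ α are outliers.

## Numerics

The BLN pmf has no closed form.  It is computed by mode-centered (adaptive)
Gauss–Hermite quadrature: the integrand in δ is a single log-concave bump
whose width shrinks like n^(-1/2), so plain σ-scaled nodes undersample it at
large n — recentering at the mode (a damped-Newton solve, fixed iteration
count for determinism and exact x ↔ n−x symmetry) and rescaling by the local
curvature keeps a fixed order accurate uniformly in n.  The default order is
61; with mode centering the normalization error Σ_x Pr(x) − 1 stays below
1e-12 out to n = 1000 and the pmf is finite to n ≥ 1e5.  All arithmetic is
in log space (log-gamma binomial coefficients, log-sum-exp over nodes).

Tail probabilities integrate the binomial CDF against the latent normal with
plain Gauss–Hermite.  Here the integrand is a smoothed step of width
~1/√(npq) in δ, so the node count grows as ⌈16 σ² n⌉ (capped at 20001) to
keep the node spacing below the transition width; agreement with summed
adaptive-quadrature pmfs is ~1e-12 at n = 2000 and asserted to 1e-8 in tests.

Two-sided p-values double the smaller tail, include the observed point, and
clamp at 1: p = min(1, 2·min(Pr(X ≤ x), Pr(X ≥ x))).  On a discrete support
this construction is deliberately conservative — see Calibration below.

**Estimation.** Per gene, sd_g maximizes Σ_i log BLN(a_i; n_i, 0, σ) over
σ ∈ [1e-3, 5] (log allelic fold change units) by bounded Brent search on
log σ (xatol 1e-3, i.e. 0.1% in σ — far below statistical error).  Estimates
at a search bound are flagged `at_bound` (balanced data legitimately sits at
the lower bound).  Individuals with total < 10 are excluded from the
likelihood, matching the outlier test's coverage threshold; a gene is
eligible for estimation only with ≥ 6 individuals at total ≥ 30.

**Bootstrap.** CIs are parametric-bootstrap percentile intervals that
condition on the observed totals n_i — coverage is ancillary to regulatory
variance — resampling counts from the fitted law and refitting B times
(B = 1000 by default; the acceptance studies use B = 200).  Refits run
through a compiled kernel (identical adaptive-quadrature likelihood at order
21, fixed 19-step golden section on log σ, bracket < 1e-2 on log σ); the
kernel is asserted equivalent to the reference path in tests.  The emitted
interval is clipped to bracket the point estimate so `ci_low ≤ sd_g ≤
ci_high` always holds; measured empirical coverage at B = 200, N = 600,
sd_g = 0.2 sits inside [0.90, 0.98].

## Calibration of the outlier test

Under a matched null (data generated and tested at the same sd_g, totals
log-uniform on [30, 3000]) the p-values are *valid but conservative*:
F(t) ≤ t everywhere, with P(p = 1) ≈ 0.03 because the doubled, observed-
point-inclusive tail of a discrete symmetric law equals 1 at the median
count.  The Kolmogorov distance from uniform measures ≈ 0.05–0.06,
concentrated at moderate-to-large t; the fraction of p ≤ 0.05 is ≈ 0.045 and
no anti-conservatism occurs anywhere, so FDR control is preserved — the cost
is a small power loss at shallow coverage.  A mid-p construction would
roughly meet KS ≈ 0.02 but breaks the closed-form tail identities this
package documents and tests; the conservative convention is kept.  At totals
≥ 300 the discrete effect fades (KS ≈ 0.014).

## Synthetic data

The generator (`asevar.simulate`) emulates exactly the model above plus
planted structure, so every downstream module is testable without real data:

- per-gene sd_g from a fixed value, a cycled grid, or a log-normal across
  genes;
- totals log-uniform on [30, 3000] by default — spanning the eligibility
  threshold through deep coverage — or negative-binomial;
- planted outliers in a configurable fraction of (gene, individual) cells,
  either a fixed |δ*| with random sign or complete monoallelic expression;
- rare-variant carrier tables with per-consequence-class base rates and an
  elevated carrier rate given a planted outlier.

What it does **not** emulate: reference-mapping bias, phasing errors,
double-counted overlapping reads, imprinting, cross-gene count correlation,
and cohort structure (relatedness, ancestry admixture).  Passing tests
therefore certify the statistics conditional on correct haplotype counts,
not robustness to upstream artifacts — those are the province of the
upstream ASE pipeline.

## Downstream screens

**False-positive-prone genes.**  Per gene, with k outlier calls in m tested
samples, the exact (Clopper–Pearson) two-sided 95% interval on the outlier
rate is computed from beta quantiles; genes with lower bound > 1% are
flagged and written to an exclusion list.  A two-sided exact binomial
p-value against the threshold rate is reported for information only — the
flag is solely the lower-bound rule.  The CI level (0.95) is configurable;
the threshold rate defaults to 0.01.

**Rare-variant enrichment.**  Tested (individual, gene) pairs — restricted
by default to genes outlying in ≥ 1 individual — are labeled
outlier/non-outlier and carrier/non-carrier per consequence class (absent
annotation means non-carrier; MAF filtering and the gene window are upstream
of the table this module consumes).  The primary statistic is the risk
ratio rr = (a/(a+b)) / (c/(c+d)) with a Katz log-normal 95% CI; the sampling
odds ratio is emitted alongside.  Any zero cell triggers Haldane–Anscombe
+0.5 on all four cells, recorded in the output.  Stratification by q-value
threshold recomputes outlier labels per threshold, so stricter-threshold
outlier sets are nested within looser ones.

**Cross-population comparison.**  For populations p, q the similarity
S[p, q] is the fraction of common genes (intersection of gene sets) whose
sd_g 95% CIs intersect; intervals are closed, so touching endpoints overlap
(the binary rule needs a boundary convention and the closed choice is the
conservative one).  D = 1 − S feeds average-linkage hierarchical clustering,
provided for visualization only — linkage choice is not part of the tested
contract.  The cross-population DOT matrix tests each population's ASE
against every population's reference and records the median per-sample
outlier count, with fold change relative to the matched diagonal; under a
calibrated synthetic null the matched diagonal is ~0 (BH makes null
discoveries rare), so the fold is reported NaN there rather than inflated.

## Study sizes and tolerances

The simulation studies the test suite and `scripts/acceptance.py` run use:
estimator recovery at N = 600 individuals, 50 replicate genes per true
sd_g ∈ {0.05, 0.1, 0.2, 0.4} (median relative error < 10%, |bias| < 0.02);
bootstrap coverage at 200 replicates × B = 200; calibration at 10^5
matched-null tests; power on complete-monoallelic plants at totals ≥ 100
with reference sd_g ≤ 0.2 (≥ 0.9 at q ≤ 0.05).  Monte-Carlo cross-checks of
the quadrature use 10^6 draws and 3-standard-error bands at support points
with probability > 1e-4.  These sizes were chosen so each study resolves its
tolerance comfortably on a single CPU.

## Known limitations

- μ is fixed at 0; systematic reference bias (which shifts the allelic mean)
  must be corrected upstream.
- The conservative two-sided p-value costs power at shallow coverage
  (totals near the 10-read threshold).
- sd_g at the search bounds (1e-3, 5) is flagged, not resolved; genes with
  essentially no regulatory variance are reported at the lower bound.
- The variance convention of external V^G tables cannot be auto-detected;
  supplying the wrong `vg_convention` silently rescales the null.
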