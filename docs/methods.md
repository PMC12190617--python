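# Methods

`pqtlmr` implements a proteome-wide two-sample Mendelian randomization
(MR) workflow for drug-target discovery, of the kind used to screen
circulating-protein panels (e.g. UK Biobank-scale pQTL atlases) against a
disease GWAS, here modelled on a psoriasis case-control design. This note
records the statistical model, the defaults and why they were chosen,
what the simulator does and does not emulate, and the numerical decisions
a maintainer would want to know.

## Causal model and estimands

For each protein, cis variants near the encoding gene serve as
instrumental variables. With harmonized per-allele effects
(`beta_x`, `se_x`) on the protein (SD units) and (`beta_y`, `se_y`) on
the disease (log odds), the estimand is the causal log-odds effect
`theta` of a 1-SD increase in protein level.

- **Wald ratio** (single instrument): `theta_hat = beta_y / beta_x`,
  `se = se_y / |beta_x|` (first-order delta method). A second-order
  expansion was considered and rejected as a default: at the instrument
  strength enforced here (F > 10, in practice F in the hundreds) the
  correction is far below the Monte-Carlo noise floor.
- **IVW**: weighted regression of `beta_y` on `beta_x` through the
  origin with weights `1/se_y^2`. For n ≤ 3 instruments the fixed-effect
  SE is used; for n > 3 the SE is inflated by `max(1, sqrt(Q/df))`
  (multiplicative random effects). The switch point is a package
  decision (the heterogeneity scale is barely estimable below 4
  instruments); the model used is recorded in every result.
- **MR-Egger**: the same regression with a free intercept, instruments
  orientated so `beta_x >= 0`; the intercept estimates directional
  pleiotropy. SEs carry the residual scale `max(1, sqrt(RSS_w/(n-2)))`
  and p-values use a t reference with n − 2 df, appropriate at the small
  instrument counts where Egger is typically run.
- **Weighted median**: ratio estimates ordered and the weighted
  empirical CDF (midpoint convention `s_j = cum_j − w_j/2`, linear
  interpolation at 0.5) evaluated; weights are inverse-variance weights
  of the per-SNP ratios. The SE comes from a parametric bootstrap
  (default 1,000 draws, explicit seed carried in the result); the
  estimator is consistent while valid instruments hold ≥ 50% of weight.
- **Cochran's Q**: `Q = Σ w_j (theta_j − theta_IVW)^2` with first-order
  weights `w_j = (beta_x_j/se_y_j)^2`, referred to chi-square(n − 1).
- **SMR**: at a single lead variant,
  `T = z_x^2 z_y^2 / (z_x^2 + z_y^2) ~ chi2(1)` under the null of no
  mediated effect. Only the single-variant statistic is implemented; the
  HEIDI LD-heterogeneity companion test is out of scope (it requires a
  reference LD panel and is not part of this workflow's decision rules).

## Instrument selection

Cis window 1 Mb from the gene body (the convention when no TSS is
available in the annotation; measured from gene-body boundaries, both
ends). Association threshold defaults to 1.7e-11 — a genome-wide 5e-8
Bonferroni-corrected over a 2,923-protein assay panel; for other panel
sizes use `bonferroni_threshold(5e-8, n_proteins)`. Variants associated
with three or more proteins at the instrument threshold are excluded as
classically pleiotropic (the count is made at the instrument threshold;
a genome-wide-only count would be a different, laxer rule — this choice
is deliberate and configurable via the map passed in). Instrument
strength uses `R² = 2·EAF·(1−EAF)·beta²` and `F = R²(N−2)/(1−R²)` with
F ≥ 10. Greedy LD clumping at r² < 0.001 runs last before
harmonization, restricted to the cis region; the F filter precedes
clumping so weak variants never shadow strong ones. Ties in the lead /
clump ordering break by larger F, then lexicographic SNP id, making
selection invariant to input order.

## Harmonization

Inner join on SNP id; outcome coding aligned to the exposure's effect
allele directly, by strand complement, or by swap (negating `beta_y` and
complementing the frequency). Palindromic pairs (A/T, C/G) are
orientated by allele frequency only when both minor-allele frequencies
are below 0.42, and dropped otherwise — the conservative two-sample MR
convention, chosen here as a package policy since no single standard
exists. Every drop is categorized in the returned report.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors,
`lABF = 0.5(log(1−r) + r z²)` with `r = W/(W + se²)`, prior effect SD
0.15 for the quantitative protein and 0.2 for the binary disease
(field-standard defaults; recorded in every result). Per-SNP priors
p1 = p2 = 1e-4, p12 = 1e-5 with a 5e-6 sensitivity re-evaluation that
reuses the Bayes factors. All hypothesis sums use log-sum-exp; the H3
(distinct variants) term is the log-difference
`log(Σe^{l1} Σe^{l2} − Σe^{l1+l2})`, exactly −inf for single-SNP regions.
Calls: "robust" when PPH4 > 0.9 at p12 = 1e-5, "supported" when
PPH4 > 0.8 at p12 = 5e-6. Colocalization regions default to gene
± 500 kb, distinct from the 1 Mb instrument window; both are
configurable. The single-causal-variant assumption is inherent to the
method; multi-signal regions should be interpreted with caution.

## Pipeline decision rules

- **Discovery**: Wald ratio at the lead cis-pQTL, Bonferroni over the
  proteins that actually had a usable instrument.
- **Replication**: per-dataset IVW (Wald with one instrument); a dataset
  "passes" at p < 0.05 **and** direction concordant with discovery.
  Concordance is required by default to forbid sign-flipped
  replications; it can be switched off.
- **Reverse MR**: disease as exposure with genome-wide-significant
  (p < 5e-8), strong, clumped instruments (a cis restriction is
  undefined for a disease). A protein is flagged as reverse-causal only
  when IVW and Egger are both significant; a significant IVW with a null
  Egger is annotated and not flagged. With fewer than 3 instruments
  Egger is unavailable and IVW alone flags at low confidence. The
  IVW-only reading is available behind `require_egger_concordance=False`;
  Q is reported alongside in all cases.
- **Pleiotropy scan**: variants in LD (r² > 0.8) with the lead pQTL are
  listed; every other panel protein whose gene overlaps the cis region
  is MR-tested against the disease using its own cis instruments at
  p < 5e-8 (selection cascade including clumping, so the confounder MR
  is itself valid); confounders are those with p < 0.05.
- **Tiers** (total and mutually exclusive, in order): no replication
  data → Tier 3; replication available, zero passes → Tier 4; ≥ 2
  passes and robust colocalization → Tier 1; otherwise Tier 2. The
  single-pass case falls to Tier 2 — a boundary the source evidence
  grading never exercises, fixed here by decision.

## Synthetic cohorts

The summary-statistic sampler is exact under a standardized-genotype,
standardized-trait model: with AR(1) LD (`r_ij = rho^|i−j|`, default
rho 0.9, a realistic decay for a dense cis region) and one causal
variant per trait per region, true marginal standardized effects are the
LD column times the causal effect, and estimates are one multivariate
normal draw with covariance `r/N`. Per-allele effects and SEs follow by
the `sqrt(2f(1−f))` scale, reproducing `se = 1/sqrt(2f(1−f)N)` exactly.
EAFs are Uniform(0.05, 0.5); alleles are assigned from non-palindromic
pairs so harmonization is exercised without ambiguity drops. Scenarios
H0–H4 mirror the colocalization hypotheses; under H4 the disease effect
at the shared variant is `theta·b_protein + direct_effect`. H2/H3
disease signals reuse the same magnitude so scenarios differ only in
variant sharing, not power. Defaults are the emulated study design:
54,219 proteomics participants; 10,312 cases / 397,564 controls
(effective N ≈ 40,200, the standard `4ab/(a+b)`); `b_protein = 0.15` SD
per allele (a strong cis-pQTL, F ≈ 1,200); `theta = 0.2`.

Not emulated: sample overlap between exposure and outcome, confounding,
multi-causal regions, haplotype-level (coalescent) structure,
genotyping error, and imputation quality. Calibration and recovery
results on these simulations therefore certify the estimators and
decision rules under their stated assumptions, not robustness to those
real-data pathologies.

Single-cell counts are negative binomial (variance `mu + phi·mu²`,
default dispersion phi 0.5) with lognormal relative gene abundances and
a planted fold-change per DE gene in one (cell type, condition) stratum.
It does not emulate batch effects, ambient RNA, doublets, or
per-sample depth variation; sample ids exist for reporting only.

## Single-cell screen

QC keeps genes seen in ≥ 3 cells, then cells with ≥ 200 detected genes
(gene-then-cell order; the filter is idempotent). Normalization is
CP10K-log1p. DE is the two-sided Wilcoxon rank-sum test with tie
correction and normal approximation; log2 fold changes use natural-scale
means (`expm1` of normalized values) with a 1e-9 pseudocount.
Significance: log2FC > 0.5 and Bonferroni p < 0.05, the correction
spanning genes × comparisons within a call. Cell-type specificity in a
condition requires the one-vs-rest contrast to be significant in that
condition and not in the other. Groups under 3 cells yield results
flagged unreliable rather than errors.

## Problem sizes and determinism

All randomness flows from integer seeds through named NumPy generators;
no global RNG state is touched. Reported simulation studies use
panel/replicate sizes chosen to make Monte-Carlo error comfortably
smaller than the tested margins (2,000 proteins for null calibration,
200 replicates for bias/coverage, 100 seeds per colocalization
scenario); the full pipeline on a fixed seed is byte-identical across
runs, including the bootstrap SE of the weighted median (seed carried in
the result). Degenerate inputs fail loudly: zero exposure effect in a
ratio, empty instrument sets, regions with no shared SNPs, zero-total
cells in normalization; the one deliberate soft path is the pipeline's
"unconfirmable" status when no instrument survives selection, which is a
reportable outcome rather than an exception.
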