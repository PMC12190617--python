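# pqtlmr

Proteome-wide cis-pQTL Mendelian randomization for drug-target
discovery, with Bayesian colocalization, reverse-MR adjudication,
LD-based pleiotropy scanning, evidence tiering, and a single-cell
candidate-gene expression screen — plus a summary-statistic simulator so
every stage can be exercised and calibrated without access to real
cohort data.

## Who it is for

Genetic epidemiologists screening circulating-protein panels against a
disease GWAS to nominate drug targets. Protein levels are the exposures,
instrumented by cis protein quantitative trait loci (cis-pQTLs:
variants within 1 Mb of the encoding gene); the disease is the outcome.
The package works entirely from GWAS summary statistics (TSV) and an LD
matrix — no individual-level data.

## The statistics

For harmonized per-allele effects β̂_x (protein, SD units) and β̂_y
(disease, log odds), the causal log-odds effect θ per SD of protein is
estimated by:

- **Wald ratio** θ̂ = β̂_y/β̂_x with se(θ̂) = se_y/|β̂_x| (one instrument);
- **IVW** — weighted regression of β̂_y on β̂_x through the origin,
  weights 1/se_y²; multiplicative random effects inflate the SE by
  max(1, √(Q/df)) when instruments are heterogeneous;
- **MR-Egger** (free intercept, tests directional pleiotropy) and the
  **weighted median** (robust to <50% invalid weight), with **Cochran's
  Q** for heterogeneity;
- **SMR** at the lead variant: T = z_x²z_y²/(z_x²+z_y²) ~ χ²(1).

Instruments pass p ≤ 5×10⁻⁸/n_proteins, associate with fewer than three
proteins, have F = R²(N−2)/(1−R²) > 10 with R² = 2·EAF(1−EAF)β², and
survive greedy LD clumping at r² < 0.001.

Colocalization uses per-SNP Wakefield approximate Bayes factors,
log ABF = ½(log(1−r) + r·z²) with r = W/(W+se²), combined under priors
p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵ (sensitivity 5×10⁻⁶) into posteriors
PPH0–PPH4; PPH4 > 0.9 is robust evidence of a shared causal variant.

Discovery-significant proteins are tiered: **1** replicated (≥2
datasets, p < 0.05, concordant direction) and colocalized; **2**
replicated but not colocalized (or only one pass); **3** no replication
data; **4** replication attempted, none passed. Reverse causation is
flagged only when disease→protein IVW *and* Egger are both significant.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
python examples/simulate_and_mr.py
```

simulates one cis region where the protein truly raises disease risk
(θ = 0.2 log-odds per SD) and prints:

```
truth: shared causal variant rs_R1_168, theta = 0.2
instruments after selection cascade: 1 (log: {'input_cis': 200, 'removed_p_threshold': 167, 'removed_cross_protein': 0, 'removed_weak_f': 0, 'removed_clump': 32, 'removed_harmonization': 0, 'retained': 1})
IVW: beta = 0.180 (SE 0.033), p = 3.94e-08, OR 1.20 (1.12–1.28)
SMR at lead rs_R1_168: p = 5.68e-08
```

The selection log shows 200 cis variants reduced to one independent
instrument (the causal variant itself); the IVW estimate 0.180 ± 0.033
covers the true θ = 0.2, and the odds ratio 1.20 (1.12–1.28) is the
per-SD effect a target-validation table would report. The other
examples cover colocalization (`examples/colocalization.py`), the full
panel-to-tier workflow (`examples/full_pipeline.py`) and the
single-cell screen (`examples/single_cell_screen.py`).

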