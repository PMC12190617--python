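"""Synthetic GWAS/pQTL summary statistics and single-cell counts with
known ground truth.

The summary-statistic sampler works on the standardized-genotype,
standardized-trait scale: with an AR(1) LD correlation matrix ``r`` and a
single causal variant ``j`` of effect ``b``, the true marginal
(standardized) effects are ``r[:, j] * b`` and the estimated effects are a
single multivariate-normal draw with covariance ``r / N``.  Per-allele
effects and standard errors follow by dividing by ``sqrt(2 f (1 - f))``,
which reproduces the analytic ``se = 1 / sqrt(2 f (1 - f) N)`` exactly.
No individual-level genotypes are simulated.

Five causal scenarios mirror the colocalization hypotheses: H0 neither
trait has a signal, H1 protein only, H2 disease only, H3 both but at
distinct variants, H4 a single shared variant.  Under H4 the disease's
causal (log-odds) effect at the shared variant is
``theta * b_protein + direct_effect`` — the protein-mediated path plus an
optional pleiotropic path — so ``theta`` is the estimand of every MR
estimator downstream.

Default sample sizes are those of the emulated study design: 54,219
proteomics participants for the protein GWAS and a 10,312-case /
397,564-control disease GWAS (effective N ~= 40,200).

Single-cell counts are negative binomial per gene with a common
dispersion; differential genes have their mean multiplied by
``2**log2_effect`` in one (cell type, condition) stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .gwas_io import GeneAnnotation, SummaryStatsTable, effective_n
from .instruments import LDMatrix
from .sc import SparseCountMatrix

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "SimulatedStudy",
    "make_ld_matrix",
    "simulate_region",
    "replicate_study",
    "simulate_panel",
    "simulate_counts",
]

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")

# non-palindromic allele pairs assigned cyclically to variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated cis region."""

    n_snps: int = 200
    ld_rho: float = 0.9
    n_exposure: int = 54_219
    n_case: int = 10_312
    n_control: int = 397_564
    causal_scenario: str = "H4"
    b_protein: float = 0.15
    theta: float = 0.2
    direct_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.causal_scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.causal_scenario!r}")
        if min(self.n_exposure, self.n_case, self.n_control) < 2:
            raise ValueError("sample sizes must be >= 2")

    @property
    def n_eff(self) -> float:
        return effective_n(self.n_case, self.n_control)


@dataclass(frozen=True)
class TruthRecord:
    causal_snp_protein: str | None
    causal_snp_disease: str | None
    theta: float
    scenario: str


@dataclass
class SimulatedStudy:
    protein_stats: SummaryStatsTable
    disease_stats: SummaryStatsTable
    ld: LDMatrix
    truth: TruthRecord
    gene: GeneAnnotation


def make_ld_matrix(n_snps: int, rho: float, snp_ids=None) -> LDMatrix:
    """AR(1) LD: r[i, j] = rho ** |i - j|, always symmetric PSD."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return LDMatrix(snp_ids, r)


def _stats_table(
    trait_id, trait_type, snp_ids, chrom, pos, ea, oa, eaf, beta_std_hat, n,
    n_case=None, n_control=None,
) -> SummaryStatsTable:
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    z = beta_std_hat * math.sqrt(n)
    df = pd.DataFrame({
        "snp": snp_ids, "chrom": chrom, "pos": pos, "ea": ea, "oa": oa,
        "eaf": eaf,
        "beta": beta_std_hat / scale,
        "se": 1.0 / (scale * math.sqrt(n)),
        "p": np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0),
        "n": float(n),
    })
    return SummaryStatsTable(
        trait_id=trait_id, trait_type=trait_type, df=df,
        n_case=n_case, n_control=n_control,
    )


def simulate_region(config: ScenarioConfig, region_tag: str = "R1") -> SimulatedStudy:
    """Draw one cis region's protein and disease summary statistics.

    Deterministic given ``config.seed``; the two traits use independent
    noise draws (no sample overlap).  ``region_tag`` namespaces SNP and
    gene identifiers so panel regions never collide.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    snp_ids = [f"rs_{region_tag}_{i + 1}" for i in range(m)]
    chrom = region_tag
    gene = GeneAnnotation(f"GENE_{region_tag}", f"PROT_{region_tag}", chrom, 5_000_000, 5_010_000)

    step = max(1, min(10_000, 1_800_000 // max(m, 1)))
    pos = 5_005_000 + (np.arange(m) - m // 2) * step
    alleles = [_ALLELE_PAIRS[i % 4] for i in range(m)]
    ea = np.array([a[0] for a in alleles])
    oa = np.array([a[1] for a in alleles])
    eaf = rng.uniform(0.05, 0.5, size=m)

    ld = make_ld_matrix(m, config.ld_rho, snp_ids)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))

    j_prot = j_dis = None
    scen = config.causal_scenario
    if scen in ("H1", "H3", "H4"):
        j_prot = int(rng.integers(m))
    if scen == "H4":
        j_dis = j_prot
    elif scen in ("H2", "H3"):
        j_dis = int(rng.integers(m))
        while scen == "H3" and j_dis == j_prot:
            j_dis = int(rng.integers(m))

    mu_prot = np.zeros(m)
    if j_prot is not None:
        mu_prot = ld.r[:, j_prot] * config.b_protein
    mu_dis = np.zeros(m)
    b_dis = config.theta * config.b_protein + config.direct_effect
    if j_dis is not None:
        mu_dis = ld.r[:, j_dis] * b_dis

    n_eff = config.n_eff
    hat_prot = mu_prot + chol @ rng.standard_normal(m) / math.sqrt(config.n_exposure)
    hat_dis = mu_dis + chol @ rng.standard_normal(m) / math.sqrt(n_eff)

    protein = _stats_table(
        gene.protein_id, "quantitative", snp_ids, chrom, pos, ea, oa, eaf,
        hat_prot, config.n_exposure,
    )
    disease = _stats_table(
        "disease", "binary", snp_ids, chrom, pos, ea, oa, eaf,
        hat_dis, n_eff, n_case=config.n_case, n_control=config.n_control,
    )
    truth = TruthRecord(
        causal_snp_protein=None if j_prot is None else snp_ids[j_prot],
        causal_snp_disease=None if j_dis is None else snp_ids[j_dis],
        theta=config.theta if scen == "H4" else 0.0,
        scenario=scen,
    )
    return SimulatedStudy(protein, disease, ld, truth, gene)


def replicate_study(study: SimulatedStudy, config: ScenarioConfig, seed: int) -> SimulatedStudy:
    """Fresh summary statistics for an existing region's truth.

    Reuses the region's variants, frequencies, LD and causal configuration
    and redraws only the estimation noise (optionally at the new sample
    sizes in ``config``) — an external replication cohort for the same
    underlying biology.
    """
    rng = np.random.default_rng(seed)
    pdf = study.protein_stats.df
    m = len(pdf)
    snp_ids = pdf["snp"].tolist()
    eaf = pdf["eaf"].to_numpy()
    idx = {s: i for i, s in enumerate(snp_ids)}
    chol = np.linalg.cholesky(study.ld.r + 1e-10 * np.eye(m))

    mu_prot = np.zeros(m)
    if study.truth.causal_snp_protein is not None:
        mu_prot = study.ld.r[:, idx[study.truth.causal_snp_protein]] * config.b_protein
    mu_dis = np.zeros(m)
    if study.truth.causal_snp_disease is not None:
        b_dis = config.theta * config.b_protein + config.direct_effect
        mu_dis = study.ld.r[:, idx[study.truth.causal_snp_disease]] * b_dis

    n_eff = config.n_eff
    hat_prot = mu_prot + chol @ rng.standard_normal(m) / math.sqrt(config.n_exposure)
    hat_dis = mu_dis + chol @ rng.standard_normal(m) / math.sqrt(n_eff)
    common = (snp_ids, pdf["chrom"].iloc[0], pdf["pos"].to_numpy(),
              pdf["ea"].to_numpy(), pdf["oa"].to_numpy(), eaf)
    protein = _stats_table(
        study.gene.protein_id, "quantitative", *common, hat_prot, config.n_exposure)
    disease = _stats_table(
        "disease", "binary", *common, hat_dis, n_eff,
        n_case=config.n_case, n_control=config.n_control)
    return SimulatedStudy(protein, disease, study.ld, study.truth, study.gene)


def simulate_panel(
    n_proteins: int,
    frac_causal: float,
    base_config: ScenarioConfig = ScenarioConfig(),
    seed: int = 0,
) -> tuple[list[SimulatedStudy], pd.DataFrame]:
    """Simulate a protein panel of independent cis regions.

    ``ceil(frac_causal * n_proteins)`` randomly chosen proteins follow the
    shared-variant scenario (H4, protein causal for disease at
    ``base_config.theta``); the rest have a protein signal but a null
    disease region (H1).  Returns the studies and a truth table.
    """
    if not 0 <= frac_causal <= 1:
        raise ValueError("frac_causal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_causal = math.ceil(frac_causal * n_proteins)
    causal = np.zeros(n_proteins, dtype=bool)
    causal[rng.choice(n_proteins, size=n_causal, replace=False)] = True

    studies, rows = [], []
    for i in range(n_proteins):
        scen = "H4" if causal[i] else "H1"
        cfg = replace(
            base_config,
            causal_scenario=scen,
            theta=base_config.theta if causal[i] else 0.0,
            seed=int(rng.integers(2**31)),
        )
        study = simulate_region(cfg, region_tag=f"R{i + 1}")
        studies.append(study)
        rows.append({
            "protein_id": study.gene.protein_id,
            "scenario": scen,
            "theta": cfg.theta if causal[i] else 0.0,
            "causal_snp_protein": study.truth.causal_snp_protein,
            "causal_snp_disease": study.truth.causal_snp_disease,
        })
    return studies, pd.DataFrame(rows)


def simulate_counts(
    n_genes: int,
    cells_per_type: dict[str, int],
    de_genes: dict[str, tuple[str, str, float]] | None = None,
    dispersion: float = 0.5,
    depth: float = 5_000.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("case", "control"),
    n_samples_per_condition: int = 2,
) -> tuple[SparseCountMatrix, pd.DataFrame]:
    """Negative-binomial single-cell counts with planted DE effects.

    ``cells_per_type`` gives cells per cell type in each condition;
    ``de_genes`` maps a gene id (``G0001``-style) to (cell_type,
    condition, log2 effect): that gene's mean is multiplied by
    ``2**effect`` in that stratum.  Variance is mu + dispersion * mu^2;
    ``depth`` is the expected total counts per cell.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    de_genes = de_genes or {}
    for eff in de_genes.values():
        if not np.isfinite(eff[2]):
            raise ValueError("DE effects must be finite")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    rel = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    rel /= rel.sum()
    base_mu = depth * rel  # expected counts per gene per cell

    barcodes, cond_l, type_l, sample_l, cols = [], [], [], [], []
    k = 0
    for cond in conditions:
        for ct, n_cells in cells_per_type.items():
            mu = base_mu.copy()
            for g, (ect, econd, eff) in de_genes.items():
                if ect == ct and econd == cond:
                    mu[gene_index[g]] *= 2.0**eff
            size = 1.0 / dispersion  # NB shape parameter
            p = size / (size + mu)
            draws = rng.negative_binomial(size, p[:, None], size=(n_genes, n_cells))
            cols.append(sparse.csc_matrix(draws))
            for c in range(n_cells):
                barcodes.append(f"CELL{k + 1:06d}")
                cond_l.append(cond)
                type_l.append(ct)
                sample_l.append(f"{cond}_s{(c % n_samples_per_condition) + 1}")
                k += 1
    x = sparse.hstack(cols, format="csr")
    ann = pd.DataFrame({
        "barcode": barcodes, "condition": cond_l,
        "cell_type": type_l, "sample_id": sample_l,
    })
    return SparseCountMatrix(genes, barcodes, x), ann
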