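"""End-to-end drug-target discovery workflow.

Stages, in order: proteome-wide discovery screen (Wald ratio at the lead
cis-pQTL, Bonferroni over proteins tested) -> multi-instrument confirmation
(IVW, MR-Egger, weighted median, Cochran's Q on the clumped set) ->
replication against external datasets (p < 0.05 with direction
concordance) -> reverse MR (disease as exposure, to rule out reverse
causation) -> Bayesian colocalization at the primary and sensitivity
priors -> LD-based pleiotropy scan of neighbouring proteins -> tier
classification:

    Tier 3  no replication data available
    Tier 4  replication available but no dataset passes
    Tier 1  >= 2 replication passes and robust colocalization (PPH4 > 0.9)
    Tier 2  otherwise

The final report is one wide row per discovery-significant protein with
the full evidence trail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from .coloc import ColocPriors, ColocResult
from .gwas_io import SummaryStatsTable, cis_region, extract_region, harmonize
from .instruments import (
    Instrument,
    InstrumentSet,
    LDMatrix,
    SelectionConfig,
    build_instrument_set,
    clump,
    f_statistic,
)
from .mr import (
    HeterogeneityResult,
    MRResult,
    bonferroni_threshold,
    cochran_q,
    format_or_ci,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)

__all__ = [
    "PipelineConfig",
    "ProteinData",
    "DiscoveryResult",
    "ConfirmationResult",
    "ReplicationResult",
    "ReverseMRResult",
    "PleiotropyScanResult",
    "TierAssignment",
    "lead_instrument",
    "discovery_screen",
    "confirm_multi_instrument",
    "replicate",
    "adjudicate_reverse",
    "reverse_mr",
    "pleiotropy_scan",
    "assign_tier",
    "compile_report",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches for the whole workflow."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    replication_alpha: float = 0.05
    require_direction_concordance: bool = True
    reverse_p_instrument: float = 5e-8
    #: flag reverse causation only when IVW *and* Egger agree (p < 0.05);
    #: False reproduces the looser IVW-only reading
    require_egger_concordance: bool = True
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    coloc_p12_sensitivity: float = 5e-6
    coloc_window: int = 500_000
    pleiotropy_r2: float = 0.8
    pleiotropy_p_instrument: float = 5e-8
    n_boot: int = 1000
    seed: int = 0


@dataclass
class ProteinData:
    """One protein's region-level inputs to the pipeline."""

    protein_id: str
    protein_stats: SummaryStatsTable
    disease_stats: SummaryStatsTable
    gene: "object"
    ld: LDMatrix

    @classmethod
    def from_study(cls, study) -> "ProteinData":
        return cls(study.gene.protein_id, study.protein_stats,
                   study.disease_stats, study.gene, study.ld)


@dataclass
class DiscoveryResult:
    protein_id: str
    wald: MRResult | None
    lead_snp: str | None
    significant: bool
    threshold: float


@dataclass
class ConfirmationResult:
    protein_id: str
    ivw: MRResult | None
    egger: MRResult | None
    wmedian: MRResult | None
    q: HeterogeneityResult | None
    instruments: InstrumentSet | None
    confirmable: bool


@dataclass
class ReplicationResult:
    protein_id: str
    results: dict[str, MRResult]
    passes: dict[str, bool]
    available: bool

    @property
    def n_pass(self) -> int:
        return sum(self.passes.values())


@dataclass
class ReverseMRResult:
    protein_id: str
    ivw: MRResult | None
    egger: MRResult | None
    q: HeterogeneityResult | None
    flagged: bool
    annotation: str


@dataclass
class PleiotropyScanResult:
    protein_id: str
    neighbor_snps: list[str]
    cis_proteins_tested: list[str]
    significant_confounders: list[tuple[str, MRResult]]

    @property
    def clean(self) -> bool:
        return not self.significant_confounders


@dataclass
class TierAssignment:
    protein_id: str
    tier: int
    rationale: dict


def lead_instrument(item: ProteinData, config: PipelineConfig) -> Instrument | None:
    """Lead cis-pQTL harmonized to the disease outcome, or None."""
    from .instruments import lead_cis_pqtl

    cis = extract_region(item.protein_stats, cis_region(item.gene, config.selection.cis_window))
    lead = lead_cis_pqtl(item.protein_stats, item.gene, config.selection)
    if lead is None:
        return None
    pairs, _ = harmonize(cis.subset(cis.df["snp"] == lead.snp_id), item.disease_stats)
    if pairs.empty:
        return None
    row = pairs.iloc[0]
    lead.beta_y, lead.se_y = float(row["beta_y"]), float(row["se_y"])
    return lead


def discovery_screen(
    panel: list[ProteinData], config: PipelineConfig = PipelineConfig()
) -> list[DiscoveryResult]:
    """Wald-ratio screen at each protein's lead cis-pQTL.

    Bonferroni correction spans only the proteins with a usable lead
    instrument (n_tested).
    """
    if not panel:
        raise ValueError("empty panel")
    leads: dict[str, Instrument] = {}
    for item in panel:
        inst = lead_instrument(item, config)
        if inst is not None:
            leads[item.protein_id] = inst
    n_tested = len(leads)
    threshold = bonferroni_threshold(config.alpha, max(n_tested, 1))
    out = []
    for item in panel:
        inst = leads.get(item.protein_id)
        if inst is None:
            out.append(DiscoveryResult(item.protein_id, None, None, False, threshold))
        else:
            res = wald_ratio(inst)
            out.append(DiscoveryResult(
                item.protein_id, res, inst.snp_id, res.p < threshold, threshold))
    return out


def confirm_multi_instrument(
    item: ProteinData, config: PipelineConfig = PipelineConfig()
) -> ConfirmationResult:
    """IVW (primary) plus Egger/weighted median (>= 3 instruments) and
    Cochran's Q on the clumped instrument set."""
    insts = build_instrument_set(
        item.protein_stats, item.disease_stats, item.gene, item.ld, config.selection)
    if len(insts) == 0:
        return ConfirmationResult(item.protein_id, None, None, None, None, insts, False)
    res_ivw = ivw(insts)
    egger = wmed = q = None
    if len(insts) >= 3:
        egger = mr_egger(insts)
        wmed = weighted_median(insts, n_boot=config.n_boot, seed=config.seed)
    if len(insts) >= 2:
        q = cochran_q(insts)
    return ConfirmationResult(item.protein_id, res_ivw, egger, wmed, q, insts, True)


def replicate(
    protein_id: str,
    discovery_beta: float,
    replication_datasets: dict[str, ProteinData],
    config: PipelineConfig = PipelineConfig(),
    p_instrument: float | None = None,
) -> ReplicationResult:
    """Per-dataset IVW (Wald for one instrument) replication.

    A dataset passes when p < replication_alpha and, if configured, the
    effect direction matches discovery.  ``p_instrument`` overrides the
    instrument threshold for replication panels with fewer proteins.
    """
    sel = config.selection
    if p_instrument is not None:
        sel = replace(sel, p_instrument=p_instrument)
    results: dict[str, MRResult] = {}
    passes: dict[str, bool] = {}
    available = False
    for name, item in replication_datasets.items():
        insts = build_instrument_set(
            item.protein_stats, item.disease_stats, item.gene, item.ld, sel)
        if len(insts) == 0:
            continue
        available = True
        res = ivw(insts)
        ok = res.p < config.replication_alpha
        if config.require_direction_concordance:
            ok = ok and np.sign(res.beta) == np.sign(discovery_beta)
        results[name] = res
        passes[name] = bool(ok)
    return ReplicationResult(protein_id, results, passes, available)


def _disease_instruments(
    disease_stats: SummaryStatsTable,
    protein_stats: SummaryStatsTable,
    ld: LDMatrix,
    config: PipelineConfig,
) -> InstrumentSet:
    """Genome-wide-significant, strong, clumped disease instruments
    harmonized to the protein outcome."""
    df = disease_stats.df
    sig = disease_stats.subset(df["p"] < config.reverse_p_instrument)
    if len(sig):
        fs = np.array([
            f_statistic(e, b, n)[1]
            for e, b, n in zip(sig.df["eaf"], sig.df["beta"], sig.df["n"])
        ])
        sig = sig.subset(fs >= config.selection.f_min)
    if len(sig):
        retained = clump(dict(zip(sig.df["snp"], sig.df["p"])), ld, config.selection.clump_r2)
        sig = sig.subset(sig.df["snp"].isin(retained))
    pairs, _ = harmonize(sig, protein_stats)
    instruments = [
        Instrument(snp_id=r.snp, beta_x=r.beta_x, se_x=r.se_x, eaf=r.eaf_x,
                   n_x=r.n_x, p_x=r.p_x, beta_y=r.beta_y, se_y=r.se_y)
        for r in pairs.itertuples(index=False)
    ]
    return InstrumentSet(disease_stats.trait_id, protein_stats.trait_id, instruments)


def adjudicate_reverse(
    ivw_p: float,
    egger_p: float | None,
    require_egger_concordance: bool = True,
) -> tuple[bool, str]:
    """Decide whether a disease->protein MR signals reverse causation.

    Returns (flagged, annotation).  A significant IVW whose Egger test is
    null is annotated and not flagged under the concordance rule; without
    an Egger result (too few instruments) a significant IVW flags at low
    confidence.
    """
    ivw_sig = ivw_p < 0.05
    if egger_p is None:
        return ivw_sig, "low-confidence (Egger unavailable)" if ivw_sig else ""
    if not require_egger_concordance:
        return ivw_sig, ""
    flagged = ivw_sig and egger_p < 0.05
    if ivw_sig and not flagged:
        return False, (
            f"not considered reverse causal (IVW p={ivw_p:.3g}, Egger p={egger_p:.3g})"
        )
    return flagged, ""


def reverse_mr(
    disease_stats: SummaryStatsTable,
    protein_stats: SummaryStatsTable,
    ld: LDMatrix,
    config: PipelineConfig = PipelineConfig(),
    protein_id: str | None = None,
) -> ReverseMRResult:
    """Disease-as-exposure MR against the protein, to detect reverse
    causation.

    With Egger available, a protein is flagged only when both IVW and
    Egger reach p < 0.05 (a significant IVW with a null Egger is annotated
    and not flagged).  With fewer than 3 instruments, Egger is unavailable
    and a significant IVW alone flags at low confidence.
    """
    pid = protein_id or protein_stats.trait_id
    insts = _disease_instruments(disease_stats, protein_stats, ld, config)
    if len(insts) == 0:
        return ReverseMRResult(pid, None, None, None, False, "no disease instruments")
    res_ivw = ivw(insts)
    egger = q = None
    if len(insts) >= 2:
        q = cochran_q(insts)
    if len(insts) >= 3:
        egger = mr_egger(insts)

    flagged, note = adjudicate_reverse(
        res_ivw.p, None if egger is None else egger.p, config.require_egger_concordance)
    return ReverseMRResult(pid, res_ivw, egger, q, flagged, note)


def pleiotropy_scan(
    item: ProteinData,
    panel: list[ProteinData],
    config: PipelineConfig = PipelineConfig(),
) -> PleiotropyScanResult:
    """Scan the cis region for proteins that could confound the signal.

    Step 1: cis variants in LD (r^2 > 0.8) with the lead pQTL.  Step 2:
    other panel proteins whose gene overlaps this protein's cis region.
    Step 3: MR of each such protein (its own cis-pQTLs at p < 5e-8, F >=
    10, clumped) against the disease; confounders are those significant at
    p < 0.05.
    """
    lead = lead_instrument(item, config)
    if lead is None:
        raise ValueError(f"{item.protein_id}: no lead instrument")
    region = cis_region(item.gene, config.selection.cis_window)
    cis = extract_region(item.protein_stats, region).df
    neighbors = [
        s for s in cis["snp"]
        if s in item.ld and lead.snp_id in item.ld
        and item.ld.r2(lead.snp_id, s) > config.pleiotropy_r2
    ]

    tested, confounders = [], []
    scan_sel = replace(config.selection, p_instrument=config.pleiotropy_p_instrument)
    for other in panel:
        if other.protein_id == item.protein_id:
            continue
        g = other.gene
        overlaps = g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
        if not overlaps:
            continue
        tested.append(other.protein_id)
        insts = build_instrument_set(
            other.protein_stats, other.disease_stats, other.gene, other.ld, scan_sel)
        if len(insts) == 0:
            continue
        res = ivw(insts)
        if res.p < 0.05:
            confounders.append((other.protein_id, res))
    return PleiotropyScanResult(item.protein_id, neighbors, tested, confounders)


def assign_tier(
    discovery: DiscoveryResult,
    replication: ReplicationResult,
    coloc: ColocResult | None,
    config: PipelineConfig = PipelineConfig(),
) -> TierAssignment:
    """Evidence-tier classification of a discovery-significant protein.

    The rules are total and mutually exclusive: no replication data ->
    tier 3; replication available but zero passes -> tier 4; >= 2 passes
    with robust colocalization (PPH4 > 0.9 at the primary prior) -> tier
    1; anything else -> tier 2.
    """
    if not discovery.significant:
        raise ValueError("tiers are assigned only to discovery-significant proteins")
    pph4 = coloc.pph4 if coloc is not None else 0.0
    rationale = {
        "replication_available": replication.available,
        "n_pass": replication.n_pass,
        "coloc_robust": pph4 > 0.9,
        "pph4": pph4,
    }
    if not replication.available:
        tier = 3
    elif replication.n_pass == 0:
        tier = 4
    elif replication.n_pass >= 2 and pph4 > 0.9:
        tier = 1
    else:
        tier = 2
    return TierAssignment(discovery.protein_id, tier, rationale)


def compile_report(
    discoveries: list[DiscoveryResult],
    confirmations: dict[str, ConfirmationResult],
    replications: dict[str, ReplicationResult],
    reverses: dict[str, ReverseMRResult],
    colocs: dict[str, list[ColocResult]],
    tiers: dict[str, TierAssignment],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, str]:
    """One wide row per discovery-significant protein plus a provenance
    JSON blob (thresholds, priors, seed)."""
    rows = []
    for d in sorted(discoveries, key=lambda d: d.protein_id):
        if not d.significant:
            continue
        pid = d.protein_id
        conf = confirmations.get(pid)
        rep = replications.get(pid)
        rev = reverses.get(pid)
        cres = colocs.get(pid, [])
        pph4s = "/".join(f"{c.pph4:.3f}" for c in cres) if cres else "NA"
        row = {
            "protein": pid,
            "lead_snp": d.lead_snp,
            "p_discovery": d.wald.p,
            "or_discovery": format_or_ci(d.wald.beta, d.wald.se),
            "p_ivw": conf.ivw.p if conf and conf.ivw else np.nan,
            "p_reverse": rev.ivw.p if rev and rev.ivw else np.nan,
            "reverse_flagged": rev.flagged if rev else False,
            "pph4": pph4s,
            "tier": tiers[pid].tier if pid in tiers else np.nan,
        }
        if rep:
            for name, res in sorted(rep.results.items()):
                row[f"or_{name}"] = format_or_ci(res.beta, res.se)
                row[f"p_{name}"] = res.p
            row["n_replication_pass"] = rep.n_pass
        rows.append(row)
    report = pd.DataFrame(rows)
    provenance = json.dumps({
        "alpha": config.alpha,
        "p_instrument": config.selection.p_instrument,
        "clump_r2": config.selection.clump_r2,
        "f_min": config.selection.f_min,
        "coloc_p12": [config.coloc_priors.p12, config.coloc_p12_sensitivity],
        "seed": config.seed,
    }, sort_keys=True)
    return report, provenance


def run_pipeline(
    panel: list[ProteinData],
    config: PipelineConfig = PipelineConfig(),
    replication_datasets: dict[str, dict[str, ProteinData]] | None = None,
) -> dict:
    """Run every stage over a panel and compile the tier report.

    ``replication_datasets`` maps dataset name -> {protein_id:
    ProteinData} for external validation; proteins absent from every
    dataset go down the tier-3 path.
    """
    replication_datasets = replication_datasets or {}
    discoveries = discovery_screen(panel, config)
    by_id = {item.protein_id: item for item in panel}

    confirmations, replications, reverses, colocs, tiers = {}, {}, {}, {}, {}
    for d in discoveries:
        if not d.significant:
            continue
        item = by_id[d.protein_id]
        confirmations[d.protein_id] = confirm_multi_instrument(item, config)

        per_protein = {
            name: ds[d.protein_id]
            for name, ds in replication_datasets.items()
            if d.protein_id in ds
        }
        rep = replicate(d.protein_id, d.wald.beta, per_protein, config)
        replications[d.protein_id] = rep

        reverses[d.protein_id] = reverse_mr(
            item.disease_stats, item.protein_stats, item.ld, config, d.protein_id)

        coloc_cis = extract_region(item.protein_stats, cis_region(item.gene, config.coloc_window))
        coloc_dis = extract_region(item.disease_stats, cis_region(item.gene, config.coloc_window))
        pairs, _ = harmonize(coloc_cis, coloc_dis)
        if len(pairs):
            colocs[d.protein_id] = coloc_mod.sensitivity(
                pairs,
                [config.coloc_priors.p12, config.coloc_p12_sensitivity],
                config.coloc_priors,
            )
        primary = colocs.get(d.protein_id, [None])[0]
        tiers[d.protein_id] = assign_tier(d, rep, primary, config)

    report, provenance = compile_report(
        discoveries, confirmations, replications, reverses, colocs, tiers, config)
    return {
        "discoveries": discoveries,
        "confirmations": confirmations,
        "replications": replications,
        "reverse_mr": reverses,
        "coloc": colocs,
        "tiers": tiers,
        "report": report,
        "provenance": provenance,
    }
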