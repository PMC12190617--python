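"""cis-pQTL instrument selection.

Instruments for a protein exposure are its cis variants (within a window of
the encoding gene) passing a Bonferroni-style association threshold, not
associated with too many proteins (classic horizontal pleiotropy), strong
(first-stage F above a cutoff), mutually independent after greedy LD
clumping, and harmonizable to the outcome GWAS.

Instrument strength uses the standard single-SNP formulas
``R^2 = 2 * EAF * (1 - EAF) * beta^2`` and
``F = R^2 * (N - 2) / (1 - R^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gwas_io import GeneAnnotation, SummaryStatsTable, cis_region, extract_region, harmonize

__all__ = [
    "SelectionConfig",
    "LDMatrix",
    "Instrument",
    "InstrumentSet",
    "f_statistic",
    "lead_cis_pqtl",
    "cross_protein_filter",
    "clump",
    "build_instrument_set",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow the discovery analysis: 1 Mb cis window, association
    threshold 1.7e-11 (5e-8 Bonferroni-corrected over 2923 assayed
    proteins), variants associated with fewer than three proteins kept
    (``max_proteins_per_snp=2``), clumping at r^2 < 0.001, F > 10.
    """

    cis_window: int = 1_000_000
    p_instrument: float = 1.7e-11
    max_proteins_per_snp: int = 2
    clump_r2: float = 0.001
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_instrument <= 1):
            raise ValueError("p_instrument must be in (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.cis_window < 0 or self.f_min < 0 or self.max_proteins_per_snp < 0:
            raise ValueError("negative threshold")


class LDMatrix:
    """Pairwise allelic correlations (r, not r^2) for an ordered SNP set.

    The matrix must be symmetric with unit diagonal and (numerically)
    positive semi-definite.
    """

    def __init__(self, snp_ids, r: np.ndarray):
        self.snp_ids = list(snp_ids)
        r = np.asarray(r, dtype=float)
        if r.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("LD matrix must be symmetric with unit diagonal")
        self.r = r
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def submatrix(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(snp_ids, self.r[np.ix_(idx, idx)])


@dataclass
class Instrument:
    """A harmonized exposure/outcome effect pair with strength statistics.

    ``beta_y``/``se_y`` are NaN until the variant is harmonized to an
    outcome table.
    """

    snp_id: str
    beta_x: float
    se_x: float
    eaf: float
    n_x: float
    p_x: float
    beta_y: float = math.nan
    se_y: float = math.nan
    r2_explained: float = 0.0
    f_stat: float = 0.0

    def __post_init__(self) -> None:
        if not self.r2_explained and self.beta_x:
            self.r2_explained, self.f_stat = f_statistic(self.eaf, self.beta_x, self.n_x)


@dataclass
class InstrumentSet:
    """Instruments surviving all selection filters for one exposure/outcome
    pair, plus a log of how many variants each filter removed."""

    protein_id: str
    outcome_id: str
    instruments: list[Instrument]
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as aligned vectors."""
        bx = np.array([i.beta_x for i in self.instruments])
        sx = np.array([i.se_x for i in self.instruments])
        by = np.array([i.beta_y for i in self.instruments])
        sy = np.array([i.se_y for i in self.instruments])
        return bx, sx, by, sy


def f_statistic(eaf: float, beta: float, n: float) -> tuple[float, float]:
    """Variance explained and first-stage F for one variant.

    R^2 = 2*eaf*(1-eaf)*beta^2;  F = R^2*(n-2)/(1-R^2).
    """
    if not 0 < eaf < 1:
        raise ValueError("eaf must be in (0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1:
        raise ValueError(f"R^2 = {r2:.3g} >= 1: beta is not on a standardized-trait scale")
    return r2, r2 * (n - 2) / (1.0 - r2)


def _candidate_order(df) -> np.ndarray:
    """Stable ordering: ascending p, then descending F, then snp id."""
    f = np.array([f_statistic(e, b, n)[1] for e, b, n in zip(df["eaf"], df["beta"], df["n"])])
    return np.lexsort((df["snp"].to_numpy(), -f, df["p"].to_numpy()))


def lead_cis_pqtl(
    protein_stats: SummaryStatsTable,
    gene: GeneAnnotation,
    config: SelectionConfig = SelectionConfig(),
) -> Instrument | None:
    """The strongest cis association for a protein, or None.

    Among cis variants with p <= ``p_instrument`` and F >= ``f_min``,
    returns the smallest-p variant; ties broken by larger F, then
    lexicographic snp id.
    """
    cis = extract_region(protein_stats, cis_region(gene, config.cis_window)).df
    cis = cis[cis["p"] <= config.p_instrument]
    if cis.empty:
        return None
    fs = np.array([f_statistic(e, b, n) for e, b, n in zip(cis["eaf"], cis["beta"], cis["n"])])
    cis = cis[fs[:, 1] >= config.f_min]
    if cis.empty:
        return None
    row = cis.iloc[_candidate_order(cis)[0]]
    return Instrument(
        snp_id=row["snp"], beta_x=row["beta"], se_x=row["se"],
        eaf=row["eaf"], n_x=row["n"], p_x=row["p"],
    )


def cross_protein_filter(
    snp_protein_map: dict[str, set], config: SelectionConfig = SelectionConfig()
) -> set:
    """SNPs to exclude because they instrument too many proteins.

    A SNP associated (at the instrument threshold) with more than
    ``max_proteins_per_snp`` proteins is excluded — "fewer than three" at
    the default of 2.
    """
    return {s for s, prots in snp_protein_map.items() if len(prots) > config.max_proteins_per_snp}


def clump(candidates, ld: LDMatrix, r2_max: float) -> list[str]:
    """Greedy LD clumping.

    ``candidates`` maps snp id -> p-value (a dict or pandas Series).
    Repeatedly retain the smallest-p unclaimed variant and discard every
    unclaimed variant with r^2 >= ``r2_max`` to it.  Ties broken
    lexicographically by snp id, so the output is independent of input
    order.
    """
    items = dict(candidates)
    for s in items:
        if s not in ld:
            raise KeyError(f"variant {s} missing from LD matrix")
    order = sorted(items, key=lambda s: (items[s], s))
    retained: list[str] = []
    claimed: set = set()
    for s in order:
        if s in claimed:
            continue
        retained.append(s)
        claimed.add(s)
        for t in order:
            if t not in claimed and ld.r2(s, t) >= r2_max:
                claimed.add(t)
    return retained


def build_instrument_set(
    protein_stats: SummaryStatsTable,
    disease_stats: SummaryStatsTable,
    gene: GeneAnnotation,
    ld: LDMatrix,
    config: SelectionConfig = SelectionConfig(),
    snp_protein_map: dict[str, set] | None = None,
) -> InstrumentSet:
    """Apply the full selection cascade and harmonize to the outcome.

    Order: cis restriction -> p threshold -> cross-protein filter -> F
    filter -> LD clumping -> harmonization.  ``selection_log`` counts the
    variants each step removed.
    """
    log: dict[str, int] = {}
    cis = extract_region(protein_stats, cis_region(gene, config.cis_window))
    log["input_cis"] = len(cis)

    sig = cis.subset(cis.df["p"] <= config.p_instrument)
    log["removed_p_threshold"] = len(cis) - len(sig)

    if snp_protein_map:
        excluded = cross_protein_filter(snp_protein_map, config)
        kept = sig.subset(~sig.df["snp"].isin(excluded))
    else:
        kept = sig
    log["removed_cross_protein"] = len(sig) - len(kept)

    if len(kept):
        fs = np.array([
            f_statistic(e, b, n)[1]
            for e, b, n in zip(kept.df["eaf"], kept.df["beta"], kept.df["n"])
        ])
        strong = kept.subset(fs >= config.f_min)
    else:
        strong = kept
    log["removed_weak_f"] = len(kept) - len(strong)

    if len(strong):
        pvals = dict(zip(strong.df["snp"], strong.df["p"]))
        retained_ids = clump(pvals, ld, config.clump_r2)
        clumped = strong.subset(strong.df["snp"].isin(retained_ids))
    else:
        clumped = strong
    log["removed_clump"] = len(strong) - len(clumped)

    pairs, harm_report = harmonize(clumped, disease_stats)
    log["removed_harmonization"] = len(clumped) - len(pairs)
    log["retained"] = len(pairs)

    instruments = [
        Instrument(
            snp_id=r.snp, beta_x=r.beta_x, se_x=r.se_x, eaf=r.eaf_x,
            n_x=r.n_x, p_x=r.p_x, beta_y=r.beta_y, se_y=r.se_y,
        )
        for r in pairs.itertuples(index=False)
    ]
    return InstrumentSet(
        protein_id=gene.protein_id,
        outcome_id=disease_stats.trait_id,
        instruments=instruments,
        selection_log={**log, "harmonization": harm_report},
    )
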