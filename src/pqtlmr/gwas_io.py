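"""Reading, validation, harmonization and region extraction for GWAS/pQTL
summary statistics.

Summary statistics are exchanged as tab-delimited tables with the header
``SNP CHR POS EA OA EAF BETA SE P N`` (case-insensitive, any column order;
``N_CASE``/``N_CONTROL`` optional for binary traits).  Internally a table is
a :class:`SummaryStatsTable`: a validated, (chrom, pos)-sorted pandas
DataFrame plus trait metadata.  Coordinates are 1-based inclusive
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "Region",
    "GeneAnnotation",
    "SummaryStatsTable",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_annotations",
    "effective_n",
    "cis_region",
    "extract_region",
    "harmonize",
]

#: canonical internal column names, in on-disk order
COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_HEADER = {
    "snp": "snp", "chr": "chrom", "chrom": "chrom", "pos": "pos", "bp": "pos",
    "ea": "ea", "oa": "oa", "eaf": "eaf", "beta": "beta", "se": "se",
    "p": "p", "pval": "p", "n": "n", "n_case": "n_case",
    "n_control": "n_control",
}

_SNV_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates linking a protein to its encoding gene."""

    gene_id: str
    protein_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class SummaryStatsTable:
    """Per-variant association records for one trait.

    ``df`` holds the canonical columns of :data:`COLUMNS`; rows are sorted by
    (chrom, pos) and snp ids are unique.  ``trait_type`` is ``"quantitative"``
    (protein levels, beta in SD units) or ``"binary"`` (disease, beta on the
    log-odds scale).  For binary traits ``n`` stores the effective sample
    size ``4 * n_case * n_control / (n_case + n_control)``.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    n_case: int | None = None
    n_control: int | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SummaryStatsTable":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True), report={})


def effective_n(n_case: int, n_control: int) -> float:
    """Effective sample size of a case-control study, 4ab/(a+b)."""
    return 4.0 * n_case * n_control / (n_case + n_control)


def _valid_mask(df: pd.DataFrame) -> pd.Series:
    ea = df["ea"].astype(str).str.upper()
    oa = df["oa"].astype(str).str.upper()
    return (
        ea.isin(_SNV_ALLELES)
        & oa.isin(_SNV_ALLELES)
        & (ea != oa)
        & (df["eaf"] > 0) & (df["eaf"] < 1)
        & (df["se"] > 0)
        & (df["p"] > 0) & (df["p"] <= 1)
        & (df["n"] > 0)
        & df[["pos", "eaf", "beta", "se", "p", "n"]].notna().all(axis=1)
    )


def read_summary_stats(path, trait_type: str, trait_id: str | None = None) -> SummaryStatsTable:
    """Read and validate a tab-delimited summary-statistics file.

    Rows violating the per-variant invariants (non-SNV or identical alleles,
    frequency outside (0,1), non-positive SE, p outside (0,1], missing
    fields) are dropped; counts are recorded in the returned table's
    ``report``.  A missing mandatory column or an empty file is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str}, thousands=",")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_HEADER)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    n_case = n_control = None
    if "n_case" in df.columns and "n_control" in df.columns:
        n_case = int(df["n_case"].iloc[0])
        n_control = int(df["n_control"].iloc[0])

    df = df[COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    for c in ("eaf", "beta", "se", "p", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

    ok = _valid_mask(df)
    n_dropped = int((~ok).sum())
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df = df.drop_duplicates("snp").sort_values(["chrom", "pos"], kind="stable")
    df = df.reset_index(drop=True)

    if trait_type == "binary" and n_case is not None:
        df["n"] = effective_n(n_case, n_control)
    return SummaryStatsTable(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        df=df,
        n_case=n_case,
        n_control=n_control,
        report={"n_read": int(ok.size), "n_dropped": n_dropped, "n_kept": len(df)},
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical TSV layout at full double precision."""
    out = table.df.rename(columns={c: c.upper() for c in COLUMNS})
    out = out.rename(columns={"CHROM": "CHR"})
    if table.n_case is not None:
        out["N_CASE"] = table.n_case
        out["N_CONTROL"] = table.n_control
    # shortest-repr float formatting round-trips doubles exactly
    out.to_csv(path, sep="\t", index=False)


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with header GENE PROTEIN CHR START END."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    df.columns = [c.strip().lower() for c in df.columns]
    need = ["gene", "protein", "chr", "start", "end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        GeneAnnotation(r.gene, r.protein, str(r.chr), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def cis_region(gene: GeneAnnotation, window: int = 1_000_000) -> Region:
    """Gene body extended by ``window`` bp on each side, clamped at 1."""
    if window < 0:
        raise ValueError("window must be >= 0")
    return Region(gene.chrom, max(1, gene.start - window), gene.end + window)


def extract_region(table: SummaryStatsTable, region: Region) -> SummaryStatsTable:
    """Subset a table to variants inside a region, preserving order."""
    df = table.df
    mask = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] <= region.end)
    )
    return table.subset(mask)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    maf_threshold: float = 0.42,
) -> tuple[pd.DataFrame, dict]:
    """Align outcome effect alleles to the exposure's.

    Inner join on snp id.  For each pair: identical allele coding (directly
    or after strand complement) is kept as-is; swapped coding negates the
    outcome beta and complements its frequency; palindromic pairs (A/T or
    C/G) are orientated by allele frequency when both minor-allele
    frequencies are below ``maf_threshold`` and dropped otherwise;
    incompatible alleles are dropped.  Returns the aligned pair table
    (columns ``snp chrom pos ea oa eaf_x beta_x se_x p_x n_x eaf_y beta_y
    se_y p_y n_y``) and a report categorizing every drop.
    """
    x = exposure.df.rename(columns={c: c + "_x" for c in ("eaf", "beta", "se", "p", "n")})
    y = outcome.df.rename(
        columns={c: c + "_y" for c in ("eaf", "beta", "se", "p", "n")}
    )[["snp", "ea", "oa", "eaf_y", "beta_y", "se_y", "p_y", "n_y"]]
    merged = x.merge(y, on="snp", suffixes=("", "_out"))

    report = {
        "n_exposure": len(exposure.df), "n_outcome": len(outcome.df),
        "n_shared": len(merged), "kept": 0, "flipped": 0,
        "dropped_palindromic_ambiguous": 0, "dropped_incompatible": 0,
    }
    keep_rows = []
    for row in merged.itertuples(index=False):
        ea_x, oa_x = row.ea, row.oa
        ea_y, oa_y = row.ea_out, row.oa_out
        beta_y, eaf_y = row.beta_y, row.eaf_y

        if _is_palindromic(ea_x, oa_x):
            if _is_palindromic(ea_y, oa_y) and {ea_y, oa_y} == {ea_x, oa_x}:
                maf_x = min(row.eaf_x, 1 - row.eaf_x)
                maf_y = min(eaf_y, 1 - eaf_y)
                if maf_x >= maf_threshold or maf_y >= maf_threshold:
                    report["dropped_palindromic_ambiguous"] += 1
                    continue
                # frequency alignment: effect alleles agree iff frequencies
                # fall on the same side of 0.5
                same_side = (row.eaf_x < 0.5) == (eaf_y < 0.5)
                if ea_y == ea_x and same_side or ea_y == oa_x and not same_side:
                    report["kept"] += 1
                else:
                    beta_y, eaf_y = -beta_y, 1 - eaf_y
                    report["flipped"] += 1
            else:
                report["dropped_incompatible"] += 1
                continue
        elif (ea_y, oa_y) == (ea_x, oa_x):
            report["kept"] += 1
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1 - eaf_y
            report["flipped"] += 1
        elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (ea_x, oa_x):
            report["kept"] += 1
        elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1 - eaf_y
            report["flipped"] += 1
        else:
            report["dropped_incompatible"] += 1
            continue

        keep_rows.append({
            "snp": row.snp, "chrom": row.chrom, "pos": row.pos,
            "ea": ea_x, "oa": oa_x,
            "eaf_x": row.eaf_x, "beta_x": row.beta_x, "se_x": row.se_x,
            "p_x": row.p_x, "n_x": row.n_x,
            "eaf_y": eaf_y, "beta_y": beta_y, "se_y": row.se_y,
            "p_y": row.p_y, "n_y": row.n_y,
        })

    cols = ["snp", "chrom", "pos", "ea", "oa",
            "eaf_x", "beta_x", "se_x", "p_x", "n_x",
            "eaf_y", "beta_y", "se_y", "p_y", "n_y"]
    pairs = pd.DataFrame(keep_rows, columns=cols)
    return pairs, report
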