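"""Single-cell candidate-gene expression screen.

Counts are genes x cells sparse integer matrices exchanged as MatrixMarket
triplets with ``features.tsv``/``barcodes.tsv`` sidecars.  The screen
applies minimal QC (genes seen in >= 3 cells, cells with >= 200 detected
genes), CP10K-log1p normalization, and two-sided Wilcoxon rank-sum
differential expression (tie-corrected normal approximation) with
Bonferroni correction.  A candidate is called cell-type specific in a
condition when its one-vs-rest test in that condition clears log2FC > 0.5
and Bonferroni p < 0.05 while the same contrast in the other condition
does not.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats

__all__ = [
    "SparseCountMatrix",
    "DEResult",
    "read_mtx",
    "write_mtx",
    "read_cell_annotation",
    "qc_filter",
    "normalize",
    "wilcoxon_de",
    "candidate_screen",
]

_PSEUDO = 1e-9


@dataclass
class SparseCountMatrix:
    """Genes x cells sparse matrix with row/column identifiers.

    ``x`` holds raw nonnegative integer counts, or floats after
    normalization.
    """

    genes: list[str]
    cells: list[str]
    x: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.x = sparse.csr_matrix(self.x)
        if self.x.shape != (len(self.genes), len(self.cells)):
            raise ValueError("matrix shape does not match gene/cell ids")
        if len(set(self.genes)) != len(self.genes) or len(set(self.cells)) != len(self.cells):
            raise ValueError("gene/cell ids must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape


@dataclass
class DEResult:
    """One gene's differential-expression record for one comparison."""

    gene: str
    group_a: str
    group_b: str
    log2fc: float
    p: float
    p_bonf: float
    pct_a: float
    pct_b: float
    reliable: bool = True

    @property
    def significant(self) -> bool:
        return self.reliable and self.log2fc > 0.5 and self.p_bonf < 0.05


def write_mtx(m: SparseCountMatrix, outdir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv."""
    os.makedirs(outdir, exist_ok=True)
    coo = m.x.tocoo()
    order = np.lexsort((coo.row, coo.col))
    spio.mmwrite(
        os.path.join(outdir, "matrix.mtx"),
        sparse.coo_matrix((coo.data[order], (coo.row[order], coo.col[order])), shape=m.x.shape),
        field="integer" if np.issubdtype(m.x.dtype, np.integer) else "real",
    )
    with open(os.path.join(outdir, "features.tsv"), "w") as fh:
        fh.write("\n".join(m.genes) + "\n")
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(m.cells) + "\n")


def read_mtx(indir) -> SparseCountMatrix:
    """Read a MatrixMarket directory written by :func:`write_mtx`."""
    x = sparse.csr_matrix(spio.mmread(os.path.join(indir, "matrix.mtx")))
    with open(os.path.join(indir, "features.tsv")) as fh:
        genes = fh.read().split()
    with open(os.path.join(indir, "barcodes.tsv")) as fh:
        cells = fh.read().split()
    return SparseCountMatrix(genes, cells, x)


def read_cell_annotation(path) -> pd.DataFrame:
    """Read a cell annotation TSV (barcode, condition, cell_type, sample)."""
    ann = pd.read_csv(path, sep="\t")
    ann.columns = [c.strip().lower() for c in ann.columns]
    need = ["barcode", "condition", "cell_type"]
    missing = [c for c in need if c not in ann.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return ann


def qc_filter(
    m: SparseCountMatrix, min_cells: int = 3, min_features: int = 200
) -> tuple[SparseCountMatrix, dict]:
    """Drop rarely seen genes, then shallow cells.

    Genes expressed (count > 0) in at least ``min_cells`` cells are
    retained; then cells with at least ``min_features`` retained genes are
    kept.  The report records before/after dimensions.
    """
    report = {"genes_before": len(m.genes), "cells_before": len(m.cells)}
    gene_cells = (m.x > 0).sum(axis=1).A1
    gmask = gene_cells >= min_cells
    x = m.x[gmask]
    feat_per_cell = (x > 0).sum(axis=0).A1
    cmask = feat_per_cell >= min_features
    x = x[:, cmask]
    out = SparseCountMatrix(
        [g for g, k in zip(m.genes, gmask) if k],
        [c for c, k in zip(m.cells, cmask) if k],
        x,
    )
    report.update(genes_after=len(out.genes), cells_after=len(out.cells))
    if len(out.genes) == 0 or len(out.cells) == 0:
        raise ValueError(f"matrix empty after QC: {report}")
    return out, report


def normalize(m: SparseCountMatrix, target_sum: float = 1e4) -> SparseCountMatrix:
    """CP10K-log1p: per cell, x -> ln(1 + target_sum * x / total counts)."""
    totals = np.asarray(m.x.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise ValueError("cell with zero total counts (run qc_filter first)")
    x = m.x.tocsc(copy=True).astype(float)
    x.data *= target_sum / np.repeat(totals, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return replace(m, x=x.tocsr())


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all values identical: no evidence either way
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_de(
    expr: SparseCountMatrix,
    mask_a,
    mask_b,
    genes: list[str] | None = None,
    group_names: tuple[str, str] = ("A", "B"),
    n_comparisons: int = 1,
) -> list[DEResult]:
    """Per-gene two-sided Wilcoxon rank-sum tests between two cell groups.

    ``expr`` is a normalized matrix; log2 fold changes are computed on
    natural-scale means (expm1 of the normalized values) with a tiny
    pseudocount.  Bonferroni correction spans the genes tested times
    ``n_comparisons``.  Groups with fewer than 3 cells yield results
    flagged unreliable.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    gene_idx = (
        range(len(expr.genes))
        if genes is None
        else [expr.genes.index(g) for g in genes]
    )
    gene_idx = list(gene_idx)
    n_tests = len(gene_idx) * n_comparisons
    reliable = mask_a.sum() >= 3 and mask_b.sum() >= 3
    xa_all = expr.x[:, mask_a]
    xb_all = expr.x[:, mask_b]

    out = []
    for gi in gene_idx:
        a = xa_all[gi].toarray().ravel()
        b = xb_all[gi].toarray().ravel()
        p = _rank_sum_p(a, b)
        with np.errstate(divide="ignore", over="ignore"):
            mean_a = float(np.mean(np.expm1(a)))
            mean_b = float(np.mean(np.expm1(b)))
            log2fc = float(np.log2((mean_a + _PSEUDO) / (mean_b + _PSEUDO)))
        out.append(
            DEResult(
                gene=expr.genes[gi], group_a=group_names[0], group_b=group_names[1],
                log2fc=log2fc, p=p, p_bonf=min(1.0, p * n_tests),
                pct_a=float(np.mean(a > 0)), pct_b=float(np.mean(b > 0)),
                reliable=reliable,
            )
        )
    return out


def candidate_screen(
    expr: SparseCountMatrix,
    ann: pd.DataFrame,
    candidate_genes: list[str],
    raw: SparseCountMatrix | None = None,
) -> pd.DataFrame:
    """Screen candidate genes for condition-level DE and cell-type
    specificity.

    For each candidate: detection flags per condition (any nonzero count),
    a case-vs-control test, and within each condition a one-vs-rest test
    per cell type.  The gene is called "specific" to a cell type in a
    condition when the one-vs-rest contrast is significant there
    (log2FC > 0.5, Bonferroni p < 0.05) and not in the other condition.
    Candidates absent from the matrix get a row with detected = False.
    Detection uses ``raw`` counts when supplied, else ``expr``.
    """
    ann = ann.set_index("barcode").loc[expr.cells].reset_index()
    cond = ann["condition"].to_numpy()
    ctype = ann["cell_type"].to_numpy()
    conditions = ("case", "control")
    cell_types = sorted(set(ctype))
    detect_m = (raw or expr).x

    present = [g for g in candidate_genes if g in expr.genes]
    n_onevsrest = len(cell_types) * len(conditions)

    cond_de = {
        r.gene: r
        for r in wilcoxon_de(
            expr, cond == "case", cond == "control",
            genes=present, group_names=("case", "control"),
        )
    }
    ovr: dict[tuple[str, str], dict[str, DEResult]] = {}
    for c in conditions:
        for t in cell_types:
            in_c = cond == c
            mask_a = in_c & (ctype == t)
            mask_b = in_c & (ctype != t)
            if mask_a.sum() == 0 or mask_b.sum() == 0:
                continue
            res = wilcoxon_de(
                expr, mask_a, mask_b, genes=present,
                group_names=(t, "rest"), n_comparisons=n_onevsrest,
            )
            ovr[(c, t)] = {r.gene: r for r in res}

    rows = []
    for g in candidate_genes:
        if g not in expr.genes:
            rows.append({
                "gene": g, "detected_case": False, "detected_control": False,
                "log2fc_case_vs_control": np.nan, "p_bonf_case_vs_control": np.nan,
                "de_case_vs_control": False, "specific": "",
            })
            continue
        gi = expr.genes.index(g)
        grow = detect_m[gi].toarray().ravel()
        det = {c: bool(np.any(grow[cond == c] > 0)) for c in conditions}
        cd = cond_de[g]
        spec_flags = []
        for t in cell_types:
            sig = {
                c: ovr.get((c, t), {}).get(g) is not None and ovr[(c, t)][g].significant
                for c in conditions
            }
            for c in conditions:
                other = conditions[1 - conditions.index(c)]
                if sig[c] and not sig[other]:
                    spec_flags.append(f"{t}:{c}")
        rows.append({
            "gene": g,
            "detected_case": det["case"], "detected_control": det["control"],
            "log2fc_case_vs_control": cd.log2fc,
            "p_bonf_case_vs_control": cd.p_bonf,
            "de_case_vs_control": abs(cd.log2fc) > 0.5 and cd.p_bonf < 0.05,
            "specific": ";".join(spec_flags),
        })
    return pd.DataFrame(rows)
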