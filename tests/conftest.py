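import numpy as np
import pandas as pd
import pytest

from pqtlmr.gwas_io import SummaryStatsTable
from pqtlmr.instruments import Instrument, InstrumentSet


def make_table(rows, trait_id="prot", trait_type="quantitative", **kw) -> SummaryStatsTable:
    """Build a SummaryStatsTable from a list of dicts with defaults filled."""
    defaults = dict(chrom="1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=1e-9, n=50_000.0)
    recs = []
    for i, r in enumerate(rows):
        rec = {**defaults, "snp": f"rs{i + 1}", "pos": 1000 * (i + 1), **r}
        recs.append(rec)
    df = pd.DataFrame(recs)[
        ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
    ]
    return SummaryStatsTable(trait_id=trait_id, trait_type=trait_type, df=df, **kw)


def make_instrument_set(bx, sy, by=None, sx=None, theta=0.2, protein="P", outcome="D"):
    """InstrumentSet from effect vectors; by defaults to theta * bx."""
    bx = np.asarray(bx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    by = theta * bx if by is None else np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.005) if sx is None else np.asarray(sx, dtype=float)
    insts = [
        Instrument(
            snp_id=f"rs{i + 1}", beta_x=float(bx[i]), se_x=float(sx[i]),
            eaf=0.3, n_x=50_000.0, p_x=1e-12,
            beta_y=float(by[i]), se_y=float(sy[i]),
        )
        for i in range(len(bx))
    ]
    return InstrumentSet(protein, outcome, insts)


@pytest.fixture
def tmp_tsv(tmp_path):
    """Write a summary-stats TSV and return its path."""

    def _write(text, name="stats.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
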