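"""Bundled reference data: the published TRAP-client signal-peptide tables.

The package ships a transcription of two published tables of signal peptides:
putative TRAP clients identified by the differential-abundance screen
(table "1") and possible/non-clients used for validation (table "3", which
includes two mutagenized SP variants). Each row carries the sequence as
printed, the printed GP content and hydrophobicity values, and flags for
overlap with the Sec61-depletion screen, independent validation, and OST
membership.

Some printed rows are internally inconsistent: recomputing GP content from
the printed sequence does not reproduce the printed GP value (the source
table text is corrupted for a handful of sequences, and one value reflects
double rounding). `gp_consistency` exposes that check so the discrepancies
stay visible instead of being silently reconciled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import seqfeatures
from .io import SignalPeptideRecord


def load_published_sp_tables() -> pd.DataFrame:
    """Return the bundled SP reference table as a DataFrame."""
    ref = resources.files("trapclient.data") / "published_sp_tables.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"table": str})
    return df


def published_sp_records(table: str | None = None) -> list[SignalPeptideRecord]:
    """Bundled rows as SignalPeptideRecord objects (features recomputed)."""
    df = load_published_sp_tables()
    if table is not None:
        df = df[df["table"] == table]
    return [
        SignalPeptideRecord(
            protein_id=row.protein_id, gene=row.gene, sequence=row.sequence,
            kind=row.kind, tm_flag=bool(row.tm), nglyc_flag=bool(row.nglyc),
        )
        for row in df.itertuples()
    ]


def _printed_decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def gp_consistency(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check recomputed GP content against the printed values.

    A row is consistent when the recomputed value agrees with the printed one
    to within half a unit in the printed last decimal place (inclusive, so
    values the source truncated rather than rounded still count as matches).
    """
    if df is None:
        df = load_published_sp_tables()
    out = df.copy()
    out["gp_computed"] = [seqfeatures.gp_content(s) for s in out["sequence"]]
    printed_str = out["gp_printed"].astype(str)
    out["gp_printed"] = printed_str.astype(float)
    tol = [0.5 * 10.0 ** -_printed_decimals(p) + 1e-9 for p in printed_str]
    out["gp_consistent"] = (out["gp_computed"] - out["gp_printed"]).abs() <= tol
    return out
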