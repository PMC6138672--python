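"""Domain types and TSV/FASTA readers and writers.

The pipeline's interchange formats are deliberately minimal: tab-separated
tables (UTF-8, header row) for intensity matrices, sample designs, annotations
and every result table, and FASTA only for sequences. Intensities follow
MaxQuant LFQ conventions: a stored 0 means "not quantified" and is converted
to an explicit missing marker (NaN) on load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import seqfeatures
from .errors import ParseError, StateError, ValidationError

logger = logging.getLogger(__name__)

#: Tokens treated as missing in intensity tables (besides numeric 0).
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")

LINEAR, LOG2 = "linear", "log2"


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity grid with explicit missingness.

    `values` is a float DataFrame (rows = proteins, columns = samples) where
    NaN marks a missing measurement. `scale` records whether values are raw
    (linear) intensities or log2-transformed.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)
        if self.scale == LINEAR:
            present = self.values.to_numpy()
            if np.nanmin(present, initial=np.inf) <= 0:
                raise ValidationError(
                    "linear-scale matrix contains non-positive intensities; "
                    "zeros must be encoded as missing"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.scale)

    def require_scale(self, scale: str, op: str) -> None:
        if self.scale != scale:
            raise StateError(f"{op} requires a {scale}-scale matrix, got {self.scale}")


@dataclass
class SampleDesign:
    """Sample -> (group, replicate) map with one designated control group."""

    table: pd.DataFrame  # index: sample_id; columns: group, replicate
    control: str

    def __post_init__(self) -> None:
        if not {"group", "replicate"}.issubset(self.table.columns):
            raise ValidationError("design table needs 'group' and 'replicate' columns")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        if self.control not in set(self.table["group"]):
            raise ValidationError(f"control group {self.control!r} not present in design")
        counts = self.table.groupby("group").size()
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"groups with <2 replicates cannot be tested: {list(small.index)}"
            )

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def targeting_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control]

    def samples_of(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def validate_against(self, matrix: AbundanceMatrix) -> None:
        design_samples = set(self.table.index)
        matrix_samples = set(matrix.sample_ids)
        if design_samples != matrix_samples:
            raise ValidationError(
                f"design/matrix sample mismatch: only in design "
                f"{sorted(design_samples - matrix_samples)}, only in matrix "
                f"{sorted(matrix_samples - design_samples)}"
            )


@dataclass
class SignalPeptideRecord:
    """One SP (or N-terminal TMH) sequence with computed feature scores."""

    protein_id: str
    gene: str
    sequence: str
    kind: str = "SP"  # SP | TMH
    tm_flag: bool = False
    nglyc_flag: bool = False
    gp_percent: float = field(init=False)
    hydrophobicity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("SP", "TMH"):
            raise ValidationError(f"kind must be SP or TMH, got {self.kind!r}")
        self.sequence = self.sequence.upper()
        self.gp_percent = seqfeatures.gp_content(self.sequence)
        self.hydrophobicity = seqfeatures.hydrophobicity(self.sequence)


@dataclass
class AnnotationTable:
    """Protein -> binary category memberships from a declared vocabulary."""

    table: pd.DataFrame  # index: protein_id; boolean columns = categories

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate protein ids in annotation table")
        self.table = self.table.astype(bool)

    @property
    def categories(self) -> list[str]:
        return list(self.table.columns)

    def members(self, category: str) -> set[str]:
        if category not in self.table.columns:
            raise ValidationError(f"unknown category {category!r}")
        return set(self.table.index[self.table[category]])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path, missing_tokens=DEFAULT_MISSING_TOKENS, scale: str = LINEAR
) -> AbundanceMatrix:
    """Read a proteins-x-samples TSV of intensities.

    First column holds protein ids, header row holds sample ids. The declared
    missing tokens map to missing; in linear scale (the MaxQuant convention)
    numeric 0 additionally maps to missing, while log2-scale input keeps
    every numeric value.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if len(cols) < 2 or any(c == "" for c in cols[1:]):
        raise ParseError(f"{path}:1: malformed header {header!r}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate protein ids {dups}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    token_set = set(missing_tokens)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw in token_set:
                values.iloc[i, j] = np.nan
                continue
            try:
                v = float(raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell at protein {df.index[i]!r}, "
                    f"sample {col!r}: {raw!r}"
                ) from exc
            values.iloc[i, j] = np.nan if (v == 0 and scale == LINEAR) else v
    return AbundanceMatrix(values, scale=scale)


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_design(path, control: str | None = None) -> SampleDesign:
    """Read a sample design TSV with columns sample_id, group, replicate.

    An optional `control` column of 0/1 may declare the control group inside
    the file; otherwise pass `control` explicitly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: design table needs a sample_id column")
    df = df.set_index("sample_id")
    if control is None:
        if "control" not in df.columns:
            raise ValidationError(f"{path}: no control group declared")
        ctrl_groups = sorted(set(df.loc[df["control"].astype(bool), "group"]))
        if len(ctrl_groups) != 1:
            raise ValidationError(f"{path}: exactly one control group required, got {ctrl_groups}")
        control = ctrl_groups[0]
    return SampleDesign(df[["group", "replicate"]], control=control)


def write_design(design: SampleDesign, path) -> None:
    df = design.table.copy()
    df["control"] = (df["group"] == design.control).astype(int)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


_SP_COLUMNS = ["id", "gene", "sequence", "kind", "tm", "nglyc"]


def _flag(token) -> bool:
    return str(token).strip() in ("1", "+", "True", "true", "yes")


def read_sp_table(path) -> list[SignalPeptideRecord]:
    """Read SP/TMH records from TSV (columns id, gene, sequence, kind, tm,
    nglyc) or FASTA (header fields 'id|gene|kind|tm|nglyc').

    GP content and hydrophobicity are computed on load; sequences outside the
    20-letter alphabet are rejected.
    """
    path = Path(path)
    records: list[SignalPeptideRecord] = []
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.description.split("|")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: FASTA header {rec.description!r} needs "
                    "'id|gene|kind|tm|nglyc'"
                )
            records.append(
                SignalPeptideRecord(
                    protein_id=fields[0], gene=fields[1], sequence=str(rec.seq),
                    kind=fields[2], tm_flag=_flag(fields[3]), nglyc_flag=_flag(fields[4]),
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _SP_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        for _, row in df.iterrows():
            records.append(
                SignalPeptideRecord(
                    protein_id=row["id"], gene=row["gene"], sequence=row["sequence"],
                    kind=row["kind"], tm_flag=_flag(row["tm"]), nglyc_flag=_flag(row["nglyc"]),
                )
            )
    if not records:
        logger.warning("no sequence records read from %s", path)
    return records


def write_sp_table(records, path) -> None:
    rows = [
        {
            "id": r.protein_id, "gene": r.gene, "sequence": r.sequence,
            "kind": r.kind, "tm": int(r.tm_flag), "nglyc": int(r.nglyc_flag),
            "gp_percent": f"{r.gp_percent:.6g}",
            "hydrophobicity": f"{r.hydrophobicity:.6g}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SP_COLUMNS + ["gp_percent", "hydrophobicity"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AnnotationTable(df)


def write_annotations(annotations: AnnotationTable, path) -> None:
    df = annotations.table.astype(int).copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> pd.DataFrame:
    """Write each result table as `<name>.tsv` under out_dir.

    Returns a manifest DataFrame listing file names, row counts and content
    hashes. Column order is taken from each table as-is, so repeated runs on
    identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        tables[name].to_csv(fpath, sep="\t", index=False, na_rep="NA")
        entries.append(
            {"file": fname, "n_rows": len(tables[name]), "sha256": sha256_file(fpath)}
        )
    manifest = pd.DataFrame(entries, columns=["file", "n_rows", "sha256"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
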