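"""Tabular interchange formats: expression TSV, GMT gene sets, clinical TSV,
and a minimal MAF-like mutation table.

All tabular files are tab-separated UTF-8 with a header line; lines starting
with ``#`` are comments and are ignored on read. Missing values are encoded
as ``NA``. Expression scale is always declared by the caller (``linear`` or
``log2p1``), never inferred: upstream cohorts mix TPM with log2/RMA-normalized
arrays, and silent inference of the scale is a classic source of silent
corruption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "MAFTable",
    "NONSYNONYMOUS_CLASSES",
    "SYNONYMOUS_CLASSES",
    "RESPONSE_LEVELS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
]

#: MAF variant classes counted as nonsynonymous (the TMB vocabulary).
NONSYNONYMOUS_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Translation_Start_Site",
)

#: Variant classes accepted but excluded from TMB.
SYNONYMOUS_CLASSES = (
    "Silent",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "IGR",
    "RNA",
)

#: Ordered ICB response labels, worst to best.
RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")

_PROVENANCE_PREFIX = "# tlsig"


def _provenance_line(what: str) -> str:
    from . import __version__

    return f"{_PROVENANCE_PREFIX} {__version__} {what}"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix with a declared scale.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. ``scale`` is ``"linear"`` (e.g. TPM) or ``"log2p1"``
    (log2(value + 1)).
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2p1"):
            raise ValidationError(f"unknown expression scale: {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale == "linear" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value under linear scale at gene {idx[g]!r}, "
                f"sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2p1(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(v + 1) scale (no-op if already there)."""
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2p1")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(
            np.power(2.0, self.values) - 1.0, scale="linear"
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> unique gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample follow-up time, event indicator, and covariates.

    ``data`` is indexed by sample id, carries float ``time`` (> 0) and int
    ``event`` (0 censored / 1 event) columns, and preserves any additional
    covariate columns. ``response``, when present, holds ordered ICB labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        for col in ("time", "event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if df["time"].isna().any() or df["event"].isna().any():
            bad = df.index[df["time"].isna() | df["event"].isna()].tolist()
            raise ValidationError(f"missing time/event for samples {bad}")
        bad = df.index[df["time"] <= 0].tolist()
        if bad:
            raise ValidationError(f"non-positive follow-up time for samples {bad}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])].tolist()
            raise ValidationError(f"event indicator outside {{0,1}} for {bad}")
        if "response" in df.columns:
            vals = df["response"].dropna()
            unknown = sorted(set(vals) - set(RESPONSE_LEVELS))
            if unknown:
                raise ValidationError(f"unknown response labels: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class MAFTable:
    """Minimal mutation table: (sample_id, gene_id, variant_classification)."""

    records: pd.DataFrame

    _COLS = ("sample_id", "gene_id", "variant_classification")

    def __post_init__(self) -> None:
        for col in self._COLS:
            if col not in self.records.columns:
                raise FormatError(f"MAF table missing column {col!r}")
        self.records = self.records.loc[:, list(self._COLS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique().tolist())


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", comment="#", dtype=str, na_values=["NA"],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_expression_matrix(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column = gene ids, header = samples).

    The scale of the stored values must be declared by the caller.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected gene-id column plus >=1 sample")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene rows: {dup}")
    body = raw.drop(columns=[gene_col])
    mat = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: non-numeric cell at gene {genes.iloc[i]!r}, "
                f"sample {col!r}: {body[col].iloc[i]!r}"
            )
        mat[:, j] = converted.to_numpy(float)
    df = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                      columns=body.columns)
    return ExpressionMatrix(df, scale=scale)


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(f"expression scale={em.scale}") + "\n")
        em.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (MSigDB dialect): name, description, genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"gene set {name!r}: duplicate genes de-duplicated",
                    stacklevel=2,
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with mandatory sample_id, time, event columns."""
    raw = _read_tsv(path)
    for col in ("sample_id", "time", "event"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df = raw.set_index("sample_id")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype("Int64")
    # numeric covariates come back as strings; convert where possible
    for col in df.columns:
        if col in ("time", "event"):
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().sum() == df[col].notna().sum():
            df[col] = converted
    df["event"] = df["event"].astype(int)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("clinical") + "\n")
        table.data.to_csv(fh, sep="\t", index_label="sample_id", na_rep="NA")


def read_maf(
    path,
    nonsyn_vocabulary: Iterable[str] = NONSYNONYMOUS_CLASSES,
) -> MAFTable:
    """Read a 3-column MAF-like TSV (sample, gene, variant classification).

    Header matching is case-insensitive and tolerant of the full MAF spellings
    (``Tumor_Sample_Barcode``, ``Hugo_Symbol``, ``Variant_Classification``).
    Records whose class is outside the declared vocabulary are kept with class
    ``"other"`` and a warning; fully duplicated records collapse to one.
    """
    raw = _read_tsv(path)
    aliases = {
        "sample_id": {"sample", "sample_id", "tumor_sample_barcode"},
        "gene_id": {"gene", "gene_id", "hugo_symbol"},
        "variant_classification": {"variant_classification", "class"},
    }
    rename = {}
    lowered = {c.lower(): c for c in raw.columns}
    for target, names in aliases.items():
        found = [lowered[n] for n in names if n in lowered]
        if not found:
            raise FormatError(f"{path}: missing column for {target!r}")
        rename[found[0]] = target
    df = raw.rename(columns=rename)[list(aliases)]
    vocab = set(nonsyn_vocabulary) | set(SYNONYMOUS_CLASSES)
    unknown = ~df["variant_classification"].isin(vocab)
    if unknown.any():
        bad = sorted(df.loc[unknown, "variant_classification"].unique())
        warnings.warn(
            f"unknown variant classes retained as 'other': {bad}", stacklevel=2
        )
        df.loc[unknown, "variant_classification"] = "other"
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(
            f"{n_before - len(df)} fully duplicated MAF records collapsed",
            stacklevel=2,
        )
    return MAFTable(df.reset_index(drop=True))


def write_maf(maf: MAFTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("maf") + "\n")
        maf.records.to_csv(fh, sep="\t", index=False)
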