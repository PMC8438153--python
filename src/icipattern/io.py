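"""Domain containers and readers/writers for the formats the pipeline touches.

Expression travels as genes x samples tables (TSV or GCT 1.2), gene sets as
GMT, clinical and mutation tables as tab-delimited text. All containers are
thin, validated wrappers around pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "FPKM", "TPM", "log2TPM1")

CLINICAL_COLUMNS = ("sample_id", "os_time", "os_event", "batch")
MUTATION_COLUMNS = ("sample_id", "gene_symbol", "variant_class")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene symbols), samples in columns.
    unit : str
        One of ``counts``, ``FPKM``, ``TPM``, ``log2TPM1``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            gene = self.values.index[np.isnan(arr).any(axis=1)][0]
            raise ValueError(f"missing expression values (first offending gene: {gene})")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite expression values")
        if self.unit in ("FPKM", "TPM") and (arr < 0).any():
            raise ValueError(f"negative values are not valid {self.unit}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.unit)


@dataclass
class SignatureMatrix:
    """Cell-type reference profiles: genes x cell types."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("signature matrix needs at least 2 cell types")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell-type ids in signature matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("signature matrix has non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: order-free, descriptions discarded)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def restrict_to(self, genes: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe; error if a set empties."""
        universe = set(genes)
        out = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in universe]
            if not kept:
                raise ValueError(f"gene set {name!r} shares no genes with the expression matrix")
            out[name] = kept
        return GeneSetCollection(out)


@dataclass
class ClinicalTable:
    """Per-sample outcome table: overall survival, event flag, batch, optional response."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing required columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.table["os_time"] <= 0).any():
            bad = self.table.loc[self.table["os_time"] <= 0, "sample_id"].tolist()
            raise ValueError(f"non-positive overall-survival times for samples {bad[:5]}")
        if not self.table["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0 or 1")
        if "response" in self.table.columns:
            ok = self.table["response"].isin(["CR", "PR", "SD", "PD"]) | self.table["response"].isna()
            if not ok.all():
                raise ValueError("response values must be CR/PR/SD/PD")

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")


@dataclass
class MutationTable:
    """Long-format mutation records plus the set of samples covered by sequencing.

    TMB is defined only for covered samples: a covered sample with no records has
    TMB 0, an uncovered sample has *undefined* (not zero) TMB.
    """

    records: pd.DataFrame
    covered_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing required columns: {missing}")
        if not self.covered_samples:
            self.covered_samples = sorted(self.records["sample_id"].unique().tolist())
        uncovered = set(self.records["sample_id"]) - set(self.covered_samples)
        if uncovered:
            raise ValueError(f"mutation records for samples not declared covered: {sorted(uncovered)[:5]}")

    def tmb(self) -> pd.Series:
        """Per-sample mutation count over covered samples (raw count, not per-Mb)."""
        counts = self.records.groupby("sample_id").size()
        return counts.reindex(self.covered_samples, fill_value=0).astype(int).rename("tmb")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # duplicate symbols keep the per-gene maximum in every sample
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).max()
    return df


def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    try:
        out = df.astype(float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at gene {row!r}, sample {col!r}"
                ) from exc
        raise FormatError(f"{path}: non-numeric values") from exc
    return out


def read_expression(path: str | Path, format: str = "tsv", unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes-in-rows expression table (TSV or GCT 1.2).

    Duplicate gene symbols are collapsed by per-gene maximum. The declared
    unit is recorded on the returned matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, float_precision="round_trip")
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        else:  # GCT 1.2 mandates a description column even if unnamed
            df = df.drop(columns=df.columns[0])
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT dimension line says {(n_genes, n_samples)}, body is {df.shape}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if df.index.isna().any() or any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError(f"{path}: malformed header (missing gene or sample ids)")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    df = _validate_numeric(df, str(path))
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, unit)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        m.values.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            body = m.values.copy()
            body.insert(0, "Description", "na")
            body.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(Path(path), "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(Path(path), sep="\t"))


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.table.to_csv(Path(path), sep="\t", index=False)


def read_mutations(path: str | Path, covered_samples: Sequence[str] | None = None) -> MutationTable:
    records = pd.read_csv(Path(path), sep="\t")
    return MutationTable(records, list(covered_samples) if covered_samples else [])


def write_mutations(m: MutationTable, path: str | Path) -> None:
    m.records.to_csv(Path(path), sep="\t", index=False)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    return SignatureMatrix(df.astype(float))


def write_signature_matrix(s: SignatureMatrix, path: str | Path) -> None:
    s.values.to_csv(Path(path), sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Cohort merging
# ---------------------------------------------------------------------------


def intersect_cohorts(
    matrices: Sequence[ExpressionMatrix],
    batch_labels: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Merge cohorts on their common genes; samples are concatenated.

    All inputs must already be on the ``log2TPM1`` scale. Returns the merged
    matrix and a per-sample batch series recording each sample's source cohort.
    """
    if len(matrices) == 0:
        raise ValueError("no cohorts to merge")
    units = {m.unit for m in matrices}
    if units != {"log2TPM1"}:
        raise ValueError(f"cohorts must share the log2TPM1 unit before merging, got {sorted(units)}")
    if batch_labels is None:
        batch_labels = [f"batch{i}" for i in range(len(matrices))]
    if len(batch_labels) != len(matrices):
        raise ValueError("one batch label per cohort required")

    common: set[str] = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    genes = [g for g in matrices[0].genes if g in common]

    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.samples)
    if len(set(all_samples)) != len(all_samples):
        seen: set[str] = set()
        dups = [s for s in all_samples if s in seen or seen.add(s)]
        raise ValueError(f"duplicate sample ids across cohorts: {dups[:5]}")

    merged = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    batches = pd.Series(
        np.repeat(list(batch_labels), [len(m.samples) for m in matrices]),
        index=all_samples,
        name="batch",
    )
    return ExpressionMatrix(merged, "log2TPM1"), batches
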