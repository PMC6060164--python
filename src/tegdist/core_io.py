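"""Domain containers and TSV input/output.

The package works with three kinds of matrices and one clinical table:

* :class:`ExpressionMatrix` — gene × sample expression on a linear scale
  (RSEM-like abundances for RNA-seq, intensities for microarrays), with
  per-sample annotations (tissue type, tumor/normal flag, cohort).
* :class:`MethylationMatrix` — gene × sample methylation beta values in
  ``[0, 1]``.
* :class:`ClinicalTable` — per-patient overall survival, grade/stage and
  the categorical/continuous covariates used for association tables.
* :class:`GeneSet` — an ordered, duplicate-free list of gene ids (for
  instance a liver-enriched gene set).

All files are plain TSV, UTF-8, ``.`` decimal separator, ``NA`` as the
missing-value sentinel, no quoting of identifiers.  Matrix files carry a
``gene_id`` first column and one column per sample; metadata files carry
``sample_id, tissue_type, is_tumor, cohort``.

Expression matrices carry an explicit scale flag (``"linear"`` or
``"log2"``) so that transforming twice, or feeding a log-scale matrix to
an operation that needs linear values, is a detectable error instead of
silent corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA_SENTINEL = "NA"

GRADE_LEVELS = ("G1", "G2", "G3/4")
STAGE_LEVELS = ("I", "II", "III/IV")

#: ordinal codings used everywhere a grade/stage enters a rank statistic
GRADE_CODES = {g: i + 1 for i, g in enumerate(GRADE_LEVELS)}
STAGE_CODES = {s: i + 1 for i, s in enumerate(STAGE_LEVELS)}

CLINICAL_COLUMNS = [
    "os_time_days",
    "os_event",
    "grade",
    "stage",
    "afp_high",
    "gender",
    "vascular_invasion",
    "child_pugh",
    "inflammation",
    "age",
    "patient_weight",
    "tumor_weight",
]

META_COLUMNS = ["tissue_type", "is_tumor", "cohort"]


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups.index[:5]))}")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  Linear
        scale values must be non-negative and finite.
    sample_meta
        DataFrame indexed by sample id with columns ``tissue_type``,
        ``is_tumor`` (bool) and ``cohort``, covering every sample.
    scale
        ``"linear"`` or ``"log2"``.
    centered
        True once the genes have been median-centered.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "linear"
    centered: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(
                "samples missing from metadata: " + ", ".join(map(str, missing[:5]))
            )
        # align metadata to the column order of the matrix
        self.sample_meta = self.sample_meta.loc[self.values.columns, META_COLUMNS].copy()
        self.sample_meta["is_tumor"] = self.sample_meta["is_tumor"].astype(bool)
        arr = self.values.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear":
            neg = np.argwhere(arr < 0)
            if len(neg):
                g, s = neg[0]
                raise ValueError(
                    f"negative expression value at gene "
                    f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)].copy())

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values[list(samples)].copy(),
            sample_meta=self.sample_meta.loc[list(samples)].copy(),
        )

    def tumor_subset(self) -> "ExpressionMatrix":
        keep = self.sample_meta.index[self.sample_meta["is_tumor"]]
        return self.subset_samples(list(keep))

    def normal_subset(self) -> "ExpressionMatrix":
        keep = self.sample_meta.index[~self.sample_meta["is_tumor"]]
        return self.subset_samples(list(keep))


@dataclass
class MethylationMatrix:
    """Gene × sample methylation beta values with sample annotations."""

    beta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "gene ids")
        _check_unique(self.beta.columns, "sample ids")
        missing = [s for s in self.beta.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(
                "samples missing from metadata: " + ", ".join(map(str, missing[:5]))
            )
        self.sample_meta = self.sample_meta.loc[self.beta.columns, META_COLUMNS].copy()
        self.sample_meta["is_tumor"] = self.sample_meta["is_tumor"].astype(bool)
        arr = self.beta.to_numpy(dtype=float)
        ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
        if not ok.all():
            g, s = np.argwhere(~ok)[0]
            raise ValueError(
                f"beta value outside [0, 1] at gene {self.beta.index[g]!r}, "
                f"sample {self.beta.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class ClinicalTable:
    """Per-patient clinical annotations keyed by sample id.

    ``data`` is indexed by sample id and has the columns listed in
    :data:`CLINICAL_COLUMNS`.  ``os_time_days`` is non-negative;
    ``os_event`` is boolean (True = death observed); ``grade`` ∈
    {G1, G2, G3/4, NaN} and ``stage`` ∈ {I, II, III/IV, NaN}.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        missing = [c for c in ("os_time_days", "os_event") if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        for col in CLINICAL_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        t = self.data["os_time_days"].to_numpy(dtype=float)
        if np.nanmin(t) < 0:
            raise ValueError("os_time_days must be non-negative")
        self.data["os_event"] = self.data["os_event"].astype(bool)
        bad_grade = self.data["grade"].dropna().loc[
            lambda s: ~s.isin(GRADE_LEVELS)
        ]
        if len(bad_grade):
            raise ValueError(f"unknown grade label {bad_grade.iloc[0]!r}")
        bad_stage = self.data["stage"].dropna().loc[
            lambda s: ~s.isin(STAGE_LEVELS)
        ]
        if len(bad_stage):
            raise ValueError(f"unknown stage label {bad_stage.iloc[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free gene id list."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene set must contain at least one gene")
        _check_unique(self.genes, f"genes in set {self.name!r}")
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def n(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[NA_SENTINEL],
                     keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    _check_unique(df["gene_id"], "gene ids")
    df = df.set_index("gene_id")
    return df.astype(float)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_SENTINEL],
                       keep_default_na=False)
    required = ["sample_id"] + META_COLUMNS
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    _check_unique(meta["sample_id"], "sample ids in metadata")
    meta = meta.set_index("sample_id")
    meta["is_tumor"] = meta["is_tumor"].map({"0": False, "1": True, "False": False,
                                             "True": True})
    if meta["is_tumor"].isna().any():
        raise ValueError(f"{path}: is_tumor must be 0/1")
    return meta


def read_expression_matrix(path: str | Path, meta_path: str | Path,
                           scale: str = "linear") -> ExpressionMatrix:
    """Read an expression matrix TSV plus its sample metadata TSV."""
    values = _read_matrix_tsv(path)
    meta = read_sample_meta(meta_path)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(
            "samples in matrix missing from metadata: " + ", ".join(missing[:5])
        )
    return ExpressionMatrix(values=values, sample_meta=meta, scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            meta_path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL, float_format="%.6f")
    meta = m.sample_meta.copy()
    meta["is_tumor"] = meta["is_tumor"].astype(int)
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(meta_path, sep="\t", index=False, na_rep=NA_SENTINEL)


def read_methylation_matrix(path: str | Path, meta_path: str | Path) -> MethylationMatrix:
    beta = _read_matrix_tsv(path)
    meta = read_sample_meta(meta_path)
    return MethylationMatrix(beta=beta, sample_meta=meta)


def write_methylation_matrix(m: MethylationMatrix, path: str | Path,
                             meta_path: str | Path) -> None:
    out = m.beta.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL, float_format="%.6f")
    meta = m.sample_meta.copy()
    meta["is_tumor"] = meta["is_tumor"].astype(int)
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(meta_path, sep="\t", index=False, na_rep=NA_SENTINEL)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_SENTINEL],
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    _check_unique(df["sample_id"], "sample ids in clinical table")
    df = df.set_index("sample_id")
    for col in ("os_time_days", "age", "patient_weight", "tumor_weight"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "os_event" in df.columns:
        df["os_event"] = df["os_event"].map(
            {"0": False, "1": True, "False": False, "True": True}
        )
    if "afp_high" in df.columns:
        df["afp_high"] = df["afp_high"].map(
            {"0": False, "1": True, "False": False, "True": True}
        )
    return ClinicalTable(df)


def write_clinical_table(c: ClinicalTable, path: str | Path) -> None:
    df = c.data.copy()
    df["os_event"] = df["os_event"].astype(int)
    if "afp_high" in df.columns:
        df["afp_high"] = df["afp_high"].map(
            lambda v: NA_SENTINEL if pd.isna(v) else int(bool(v))
        )
    df.insert(0, "sample_id", df.index)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set stored one gene id per line."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneSet(name=name or Path(path).stem, genes=tuple(genes))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.genes) + "\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(value + pseudocount)`` of a linear-scale matrix.

    Raises
    ------
    ScaleError
        If the matrix is already log-scale.
    ValueError
        If any value is 0 and the pseudocount is 0 (log2 undefined).
    """
    if m.scale == "log2":
        raise ScaleError("matrix is already log2-transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    arr = m.values.to_numpy(dtype=float)
    if pseudocount == 0 and np.nanmin(arr) <= 0:
        raise ValueError("zero value with pseudocount 0: log2 undefined")
    out = pd.DataFrame(np.log2(arr + pseudocount), index=m.values.index,
                       columns=m.values.columns)
    return replace(m, values=out, scale="log2", centered=False)


def median_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's median; requires a log2-scale matrix."""
    if m.scale != "log2":
        raise ScaleError("median centering expects a log2-scale matrix")
    med = m.values.median(axis=1, skipna=True)
    if med.isna().any():
        gene = med.index[med.isna()][0]
        raise ValueError(f"gene {gene!r} has no observed values")
    out = m.values.sub(med, axis=0)
    return replace(m, values=out, centered=True)
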