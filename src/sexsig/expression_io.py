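"""Reading, validating and subsetting expression matrices and sample annotations.

Expression values are assumed to be log2-normalised intensities unless declared
linear, in which case downstream code log-transforms them after adding a
pseudocount.  Two on-disk dialects are supported: a plain tab-separated table
(first column gene/probe ids, header row of sample ids) and GCT 1.2.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError, VocabularyError

logger = logging.getLogger(__name__)

Scale = Literal["log2", "linear"]
Sex = Literal["male", "female"]
Condition = Literal["non_failing", "failing", "other"]

_SEX_TOKENS: Mapping[str, str] = {
    "male": "male", "m": "male", "female": "female", "f": "female",
}
_CONDITIONS = ("non_failing", "failing", "other")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of expression values.

    ``data`` is indexed by gene (or probe) id with one column per sample.
    ``scale_flag`` declares whether values are log2 intensities (the default
    convention for normalised microarray matrices) or linear.
    """

    data: pd.DataFrame
    scale_flag: Scale = "log2"

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.shape[1] and np.isnan(values).all(axis=1).any():
            bad = self.data.index[np.isnan(values).all(axis=1)].tolist()
            raise ValidationError(f"entirely-missing rows: {bad[:10]}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale view; linear input gets log2(x + pseudocount)."""
        if self.scale_flag == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), "log2")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: sex, disease condition and (optional) age in years."""

    sample_id: str
    sex: str
    condition: str
    age: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample_id")
        if self.sex not in ("male", "female"):
            raise VocabularyError(f"unknown sex {self.sex!r} for {self.sample_id}")
        if self.condition not in _CONDITIONS:
            raise VocabularyError(
                f"unknown condition {self.condition!r} for {self.sample_id}"
            )
        if self.age is not None and self.age < 0:
            raise ValidationError(f"negative age for {self.sample_id}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, format: Literal["series_matrix_tsv", "gct"] = "series_matrix_tsv",
    scale_flag: Scale = "log2",
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV or GCT 1.2 file.

    Blank and ``NA``/``NaN`` cells become missing values.  Duplicate gene or
    sample ids and GCT dimension mismatches are rejected.
    """
    if format == "series_matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="!",
                         float_precision="round_trip")
        if df.index.name is None and df.empty:
            raise FormatError(f"{path}: empty expression table")
        df.index = df.index.astype(str).str.strip()
        df.columns = [str(c).strip() for c in df.columns]
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
        return ExpressionMatrix(df, scale_flag)
    if format == "gct":
        return _read_gct(path, scale_flag)
    raise ValidationError(f"unknown expression format {format!r}")


def _read_gct(path, scale_flag: Scale) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path} line 1: expected '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2 or not all(t.lstrip("-").isdigit() for t in dims):
            raise FormatError(f"{path} line 2: expected '<n_genes> <n_samples>'")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t",
                     float_precision="round_trip")
    if df.columns[:2].tolist() != ["Name", "Description"]:
        raise FormatError(f"{path} line 3: header must start 'Name\\tDescription'")
    if len(df) != n_genes or df.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path} line 2: header declares {n_genes} x {n_samples} but file has "
            f"{len(df)} x {df.shape[1] - 2}"
        )
    out = df.drop(columns="Description").set_index("Name")
    out.index = out.index.astype(str).str.strip()
    out.index.name = None
    out.columns = [str(c).strip() for c in out.columns]
    try:
        out = out.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(out, scale_flag)


def write_expression_matrix(
    matrix: ExpressionMatrix, path,
    format: Literal["series_matrix_tsv", "gct"] = "series_matrix_tsv",
) -> None:
    """Write a matrix in the dialect `read_expression_matrix` reads back."""
    df = matrix.data
    if format == "series_matrix_tsv":
        out = df.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            gct = df.copy()
            gct.insert(0, "Description", "na")
            gct.index.name = "Name"
            gct.to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValidationError(f"unknown expression format {format!r}")


def read_sample_annotations(path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (sample_id, sex, condition[, age]).

    Sex tokens are matched case-insensitively against {male, m, female, f}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: list[SampleAnnotation] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ValidationError(f"{path} row {i + 2}: duplicate sample_id {sid!r}")
        seen.add(sid)
        sex_token = str(row["sex"]).strip().lower()
        if sex_token not in _SEX_TOKENS:
            raise VocabularyError(
                f"{path} row {i + 2}: unknown sex token {row['sex']!r}"
            )
        cond = str(row["condition"]).strip().lower()
        if cond not in _CONDITIONS:
            raise VocabularyError(
                f"{path} row {i + 2}: unknown condition {row['condition']!r}"
            )
        age: float | None = None
        if "age" in df.columns:
            raw = row["age"]
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                age = float(raw)
        out.append(SampleAnnotation(sid, _SEX_TOKENS[sex_token], cond, age))
    return out


def write_sample_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    rows = [
        {"sample_id": a.sample_id, "sex": a.sex, "condition": a.condition,
         "age": "" if a.age is None else a.age}
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# subsetting and probe collapse
# ---------------------------------------------------------------------------

def filter_samples(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    condition: str,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Keep only samples annotated with `condition`, preserving matrix order.

    Samples present in the matrix but lacking an annotation are dropped with
    a warning; an empty result is an error.
    """
    by_id = {a.sample_id: a for a in annotations}
    unannotated = [s for s in matrix.sample_ids if s not in by_id]
    if unannotated:
        logger.warning(
            "%d matrix samples lack annotation and are dropped (e.g. %s)",
            len(unannotated), unannotated[:5],
        )
    keep = [s for s in matrix.sample_ids
            if s in by_id and by_id[s].condition == condition]
    if not keep:
        raise ValidationError(f"no samples match condition {condition!r}")
    sub = ExpressionMatrix(matrix.data[keep], matrix.scale_flag)
    return sub, [by_id[s] for s in keep]


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_gene_map: Mapping[str, str],
    method: Literal["max_mean", "median"] = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``max_mean`` keeps, for each gene, the probe with greatest mean expression
    (the usual microarray convention); ``median`` takes the per-sample median
    across a gene's probes.  Unmapped probes are dropped with a logged count.
    """
    if not probe_gene_map:
        raise ValidationError("empty probe-to-gene mapping")
    mapped = [p for p in matrix.gene_ids if p in probe_gene_map]
    n_dropped = matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probes", n_dropped)
    if not mapped:
        raise ValidationError("no probe in the matrix is covered by the mapping")
    df = matrix.data.loc[mapped]
    genes = pd.Series({p: probe_gene_map[p] for p in mapped})
    if method == "max_mean":
        means = df.mean(axis=1)
        # first occurrence wins ties, keeping output deterministic
        best = means.groupby(genes).idxmax()
        out = df.loc[best]
        out.index = best.index
    elif method == "median":
        out = df.groupby(genes).median()
    else:
        raise ValidationError(f"unknown collapse method {method!r}")
    out.index.name = None
    return ExpressionMatrix(out.sort_index(), matrix.scale_flag)
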