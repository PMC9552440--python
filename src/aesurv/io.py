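"""Reading, writing and sample alignment of omics and clinical tables.

File dialect
------------
Omics matrices are TSV with features as rows and samples as columns: the
header row holds sample ids, the first column holds feature ids.  Clinical
tables are TSV with one row per sample and named columns
(``sample_id``, ``time``, ``event``, plus covariates such as ``age``,
``gender``, ``grade``, ``tumor_type``, ``idh_status``).

In memory an omics matrix is a :class:`pandas.DataFrame` indexed by feature
id with sample ids as columns; a clinical table is a DataFrame indexed by
sample id.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError

#: format used for all floating-point values written to TSV (6 significant
#: digits, enough for lossless round-trips at the precision the pipeline uses)
FLOAT_FORMAT = "%.6g"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()[:5]
        raise ParseError(f"{path}: duplicate {what} id(s): {dup}")


def read_omics(path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix.

    Raises :class:`ParseError` on duplicate feature/sample ids or
    non-numeric cells, naming the offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: malformed TSV: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    _check_unique(df.index, "feature", path)
    _check_unique(df.columns, "sample", path)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ParseError(f"{path}: missing values in rows {rows}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_omics(m: pd.DataFrame, path) -> None:
    """Write a feature-by-sample matrix in the package TSV dialect."""
    path = Path(path)
    m.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature_id")


REQUIRED_CLINICAL = ("time", "event")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV table indexed by ``sample_id``.

    Validates that survival times are positive and the event indicator
    is 0/1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    for col in REQUIRED_CLINICAL:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample", path)
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()[:5]
        raise ParseError(f"{path}: non-positive survival time for samples {bad}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])].tolist()[:5]
        raise ParseError(f"{path}: event indicator not in {{0,1}} for samples {bad}")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def align_samples(
    omics: list[pd.DataFrame], clinical: pd.DataFrame
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Restrict all tables to the intersection of their sample ids.

    The canonical order is the order of appearance in the first omics
    matrix.  Warns with the number of samples dropped from each source;
    raises :class:`AlignmentError` if the intersection is empty.
    """
    if not omics:
        raise AlignmentError("no omics matrices given")
    common = set(clinical.index)
    for m in omics:
        common &= set(m.columns)
    order = [s for s in omics[0].columns if s in common]
    if not order:
        raise AlignmentError("empty sample intersection between omics and clinical")
    for i, m in enumerate(omics):
        dropped = m.shape[1] - len(order)
        if dropped:
            warnings.warn(f"align_samples: dropped {dropped} sample(s) from omics[{i}]")
    dropped = len(clinical) - len(order)
    if dropped:
        warnings.warn(f"align_samples: dropped {dropped} sample(s) from clinical")
    return [m.loc[:, order] for m in omics], clinical.loc[order]
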