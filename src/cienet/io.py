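"""Reading and writing the pipeline's delimited-text formats.

Expression matrices are TSV with the probeset id in the first column and
sample ids in the header; annotations and drinking records are CSV. All
writers use a fixed decimal precision so that a write/read round trip is
exact at that precision and reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

EXPR_DECIMALS = 6


class FormatError(ValueError):
    """Malformed input file."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probesets-by-samples log2 expression TSV.

    Raises FormatError naming the offending row/column on duplicate ids,
    missing cells, or non-numeric values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probeset ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dup}")
    try:
        values = df.astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric cell in expression matrix: {e}") from e
    if values.isna().any().any():
        bad = values.columns[values.isna().any(axis=0)].tolist()
        raise FormatError(f"missing values (unsupported) in columns: {bad}")
    values.index.name = "probeset"
    return values


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=f"%.{EXPR_DECIMALS}f", index_label="probeset")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path)
    needed = {"sample_id", "vapor", "drinking"}
    if not needed.issubset(ann.columns):
        raise FormatError(f"annotation missing columns {needed - set(ann.columns)}")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in annotation: {dup}")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index=False)


def read_drinking(path: str | Path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    needed = {"mouse_id", "session", "phase", "intake_gkg"}
    if not needed.issubset(rec.columns):
        raise FormatError(f"drinking record missing columns {needed - set(rec.columns)}")
    if (rec["intake_gkg"] < 0).any():
        raise FormatError("negative intake values")
    return rec


def write_drinking(rec: pd.DataFrame, path: str | Path) -> None:
    rec.to_csv(path, index=False, float_format="%.4f")


def write_table(df: pd.DataFrame, path: str | Path, decimals: int = 6) -> None:
    """Write a generic stage-output TSV at fixed precision."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{decimals}g")


def check_matching(expr: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Align annotation to the expression columns; error if any sample lacks a row."""
    ann = ann.set_index("sample_id")
    missing = [s for s in expr.columns if s not in ann.index]
    if missing:
        raise FormatError(f"samples without annotation: {missing}")
    out = ann.loc[list(expr.columns)].reset_index()
    return out
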