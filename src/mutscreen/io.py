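"""Plain-text (TSV/JSON) readers and writers for pipeline artifacts.

All writers use a fixed float format so reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .variants import MutationCategory, MutationMatrix

FLOAT_FORMAT = "%.8g"

__all__ = [
    "read_count_matrix", "write_count_matrix",
    "read_survival_table", "write_survival_table",
    "read_mutation_matrix", "write_mutation_matrix",
    "write_size_factors", "write_frame",
]


def read_count_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV (first column = gene symbol, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene symbols in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table {path} missing columns: {sorted(missing)}")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def write_survival_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_mutation_matrix(path, category="disruptive") -> MutationMatrix:
    """Rows = patients, columns = genes, values 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all()
    if bad.any():
        raise ValueError(f"non-binary entries in mutation matrix columns "
                         f"{list(df.columns[bad])}")
    return MutationMatrix(indicator=df.astype("int8"),
                          category=MutationCategory(category))


def write_mutation_matrix(matrix: MutationMatrix, path) -> None:
    matrix.indicator.to_csv(path, sep="\t", index_label="patient_id")


def write_size_factors(sf: pd.Series, path) -> None:
    sf.rename("size_factor").to_csv(path, sep="\t", index_label="sample_id",
                                    float_format=FLOAT_FORMAT)


def write_frame(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
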