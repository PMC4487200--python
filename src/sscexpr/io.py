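"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices are plain tab-delimited tables (first column = probe or
gene identifier, header row = sample identifiers) or the GCT dialect
(two-line ``#1.2`` header).  Gene sets travel as GMT.  All expression data
are represented in memory as :class:`pandas.DataFrame` with row index =
feature identifiers and columns = sample identifiers, on a log2(ratio)
scale with NaN marking missing entries.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "read_cls",
    "read_clinical_long",
    "read_clinical_wide",
    "validate_matrix",
]

#: accepted missing-value sentinels (case-insensitive), besides empty fields
_NA_VALUES = ["", "NA", "NaN", "nan", "na", "NAN"]


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionMatrix invariants: unique row and column identifiers."""
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate row identifiers: {dupes} ...")
    if m.columns.has_duplicates:
        dupes = m.columns[m.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample identifiers: {dupes} ...")
    return m


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix from TSV, auto-detecting the GCT dialect.

    GCT files begin with a ``#1.2`` version line followed by a
    ``<n_rows>\\t<n_cols>`` count line; the data table then carries NAME and
    Description columns before the samples.  Plain TSV has the identifier in
    the first column and samples in the rest.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#1.2"):
            fh.readline()  # dimension line; trusted but not required
            df = pd.read_csv(
                fh, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
            )
            # drop the GCT Description column if present
            if df.columns[0].lower() == "description":
                df = df.drop(columns=df.columns[0])
        else:
            fh.seek(0)
            df = pd.read_csv(
                fh, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
            )
    df = df.apply(pd.to_numeric)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_matrix(df)


def write_expression(m: pd.DataFrame, path: str | Path, gct: bool = False) -> None:
    path = Path(path)
    if gct:
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            out = m.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        m.to_csv(path, sep="\t", index_label="id")


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column probe→gene-symbol table; ``#`` lines are comments.

    Probes with an empty or missing symbol are treated as unmapped and left
    out of the returned mapping.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            probe = parts[0].strip()
            symbol = parts[1].strip() if len(parts) > 1 else ""
            if not probe:
                continue
            if probe in mapping and mapping[probe] != symbol:
                raise ValueError(f"probe {probe!r} maps to multiple symbols")
            if symbol and symbol.upper() not in ("NA", "NAN"):
                mapping[probe] = symbol
    return mapping


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id,label CSV (header optional)."""
    df = pd.read_csv(path, header=None, dtype=str)
    if df.iloc[0, 0].lower() in ("sample_id", "sample", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_cls(path: str | Path) -> dict[str, str]:
    """Read a CLS categorical class file and return sample-order labels.

    Format: ``<n> <k> 1`` / ``# nameA nameB`` / space-separated labels, one
    per sample in matrix column order.  Returns a list-like mapping of
    positional index (as str) to class name; callers zip it with the
    matrix columns.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError("malformed CLS file")
    names = lines[1].lstrip("#").split()
    tokens = lines[2].split()
    out: dict[str, str] = {}
    for i, tok in enumerate(tokens):
        if tok in names:
            out[str(i)] = tok
        else:
            out[str(i)] = names[int(tok)]
    return out


_CLINICAL_REQUIRED = ["patient_id", "arm", "visit_day", "mrss"]


def read_clinical_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format clinical table: one row per patient-visit.

    Required columns: patient_id, arm, visit_day, mrss.  Everything else
    (disease_duration, covariates, expression sample links) is carried along.
    """
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    df["visit_day"] = pd.to_numeric(df["visit_day"])
    df["mrss"] = pd.to_numeric(df["mrss"])
    return df


def read_clinical_wide(path: str | Path, visit_days: list[int] | None = None) -> pd.DataFrame:
    """Read a wide clinical table (one row per patient, mrss_d<k> columns)
    and return it in long format."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    mrss_cols = [c for c in df.columns if c.startswith("mrss_d")]
    if not mrss_cols:
        raise ValueError("wide clinical table has no mrss_d<day> columns")
    id_cols = [c for c in df.columns if c not in mrss_cols]
    long = df.melt(id_vars=id_cols, value_vars=mrss_cols, var_name="visit", value_name="mrss")
    long["visit_day"] = long["visit"].str.removeprefix("mrss_d").astype(int)
    long = long.drop(columns="visit")
    long["patient_id"] = long["patient_id"].astype(str)
    return long.sort_values(["patient_id", "visit_day"]).reset_index(drop=True)
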