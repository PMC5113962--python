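"""Readers and writers for the three-table dataset layout.

The pipeline starts from the identified-metabolite stage: a samples x
metabolites abundance table plus sample and metabolite annotation tables.
CSV and TSV are auto-detected from the file extension; the first column is
the ID column and a header row is required. Empty cells are missing values
(NaN in memory) — distinct from an explicit 0.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from csfmet.datatypes import (
    Dataset,
    MetaboliteMatrix,
    ValidationError,
    validate_dataset,
)

_SEPS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _sep_for(path: os.PathLike | str) -> str:
    ext = Path(path).suffix.lower()
    try:
        return _SEPS[ext]
    except KeyError:
        raise ValidationError(
            f"cannot infer table format from extension {ext!r} of {path}"
        ) from None


def _fingerprint_to_str(fp) -> str:
    if fp is None or (np.isscalar(fp) and pd.isna(fp)):
        return ""
    return "".join("1" if b else "0" for b in np.asarray(fp))


def _fingerprint_from_str(s) -> object:
    if s is None or (np.isscalar(s) and pd.isna(s)) or s == "":
        return np.nan
    if set(str(s)) - {"0", "1"}:
        raise ValidationError(f"fingerprint string {s!r} contains non-binary chars")
    return np.array([int(c) for c in str(s)], dtype=np.uint8)


def _set_to_str(xs) -> str:
    if xs is None or (np.isscalar(xs) and pd.isna(xs)):
        return ""
    return ";".join(sorted(xs))


def _set_from_str(s) -> frozenset:
    if s is None or (np.isscalar(s) and pd.isna(s)) or s == "":
        return frozenset()
    return frozenset(str(s).split(";"))


def read_dataset(matrix_path, samples_path, metabolites_path) -> Dataset:
    """Read and cross-validate the (matrix, samples, metabolites) triple.

    Raises
    ------
    ValidationError
        On dimension mismatches, duplicate or unmatched IDs, or unknown
        category tokens; the message names the offending row or column.
    """
    mat = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0,
                      float_precision="round_trip")
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    matrix = MetaboliteMatrix(mat)

    samples = pd.read_csv(samples_path, sep=_sep_for(samples_path), index_col=0,
                          float_precision="round_trip")
    samples.index = samples.index.astype(str)

    mets = pd.read_csv(
        metabolites_path, sep=_sep_for(metabolites_path), index_col=0, dtype=str
    )
    mets.index = mets.index.astype(str)
    if "fingerprint" in mets.columns:
        mets["fingerprint"] = mets["fingerprint"].map(_fingerprint_from_str)
    for col in ("pathways", "rpair_partners"):
        if col in mets.columns:
            mets[col] = mets[col].map(_set_from_str)

    return validate_dataset(Dataset(matrix, samples, mets))


def write_dataset(ds: Dataset, dir_path, fmt: str = "tsv") -> dict[str, Path]:
    """Write the triple to ``dir_path``; returns the three file paths.

    Numeric cells round-trip to full precision, categorical fields
    bit-identically; missing values are written as empty cells.
    """
    if ds.matrix.n_metabolites == 0:
        raise ValidationError("refusing to write a dataset with no metabolites")
    validate_dataset(ds)
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"matrix.{fmt}",
        "samples": out / f"samples.{fmt}",
        "metabolites": out / f"metabolites.{fmt}",
    }
    ds.matrix.values.to_csv(paths["matrix"], sep=sep, index_label="sample_id",
                            float_format="%.17g")
    ds.samples.to_csv(paths["samples"], sep=sep, index_label="sample_id",
                      float_format="%.17g")

    mets = ds.metabolites.copy()
    if "fingerprint" in mets.columns:
        mets["fingerprint"] = mets["fingerprint"].map(_fingerprint_to_str)
    for col in ("pathways", "rpair_partners"):
        if col in mets.columns:
            mets[col] = mets[col].map(_set_to_str)
    mets.to_csv(paths["metabolites"], sep=sep, index_label="metabolite_id")
    return paths
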