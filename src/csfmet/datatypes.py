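"""Core domain types and validation for CSF metabolomics tables.

The central quantitative object is the :class:`MetaboliteMatrix`, a
samples x metabolites table of GC-MS peak heights. Missing values (censored
non-detects) are encoded as NaN and are distinct from zero, which is a
legitimate reported abundance. Sample and metabolite annotations are plain
pandas DataFrames indexed by ID, validated against closed category sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

#: Study design groups: healthy controls and the three demyelinating diseases.
GROUPS = ("CTRL", "MS", "NMOSD", "ITM")

#: Clinical status of a patient sample; controls carry NONE.
STATUSES = ("NONE", "REMISSION", "RELAPSE")

#: Closed chemical-class vocabulary for identified metabolites.
CHEM_CLASSES = (
    "sugar",
    "sugar_alcohol",
    "amino_acid",
    "fatty_acid",
    "organic_acid",
    "amine",
    "phosphate",
    "misc",
)

#: Clinical covariates carried in the sample annotation.
COVARIATES = ("edss", "ocb", "protein", "wbc", "igg_index")

SAMPLE_COLUMNS = ("group", "status") + COVARIATES
METABOLITE_COLUMNS = ("name", "chem_class", "fingerprint", "compound_id",
                      "pathways", "rpair_partners")


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance table.

    Parameters
    ----------
    values : pandas.DataFrame
        Float matrix, rows indexed by sample ID, columns by metabolite ID.
        NaN marks a missing (censored) measurement; all present values must
        be non-negative peak heights.
    """

    values: pd.DataFrame = field()

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
        self.values = v.astype(float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "metabolite")
        arr = self.values.to_numpy()
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at sample {self.values.index[i]!r}, "
                f"metabolite {self.values.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def present(self) -> pd.DataFrame:
        """Boolean mask of present (non-missing) cells."""
        return self.values.notna()

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.values.copy())

    def __eq__(self, other: object) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, MetaboliteMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)
        )


class Dataset(NamedTuple):
    """A validated triple of matrix + sample and metabolite annotations."""

    matrix: MetaboliteMatrix
    samples: pd.DataFrame
    metabolites: pd.DataFrame


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample annotation table (index = sample ID).

    Enforces the closed group/status vocabularies, the control => NONE rule,
    EDSS on the 0-10 half-point grid, binary OCB, and non-negative protein,
    WBC and IgG index. Missing covariates are allowed (NaN).
    """
    _check_unique(samples.index, "sample")
    for col in ("group", "status"):
        if col not in samples.columns:
            raise ValidationError(f"sample annotation lacks column {col!r}")
    bad = samples.loc[~samples["group"].isin(GROUPS)]
    if len(bad):
        raise ValidationError(
            f"unknown group {bad['group'].iloc[0]!r} for sample {bad.index[0]!r}"
        )
    bad = samples.loc[~samples["status"].isin(STATUSES)]
    if len(bad):
        raise ValidationError(
            f"unknown status {bad['status'].iloc[0]!r} for sample {bad.index[0]!r}"
        )
    ctrl = samples["group"] == "CTRL"
    bad = samples.loc[ctrl & (samples["status"] != "NONE")]
    if len(bad):
        raise ValidationError(
            f"control sample {bad.index[0]!r} must have status NONE"
        )
    if "edss" in samples.columns:
        e = pd.to_numeric(samples["edss"], errors="raise")
        present = e.notna()
        ok = ((e[present] * 2) % 1 == 0) & (e[present] >= 0) & (e[present] <= 10)
        if not ok.all():
            sid = e[present].index[~ok.to_numpy()][0]
            raise ValidationError(
                f"EDSS for sample {sid!r} not on the 0-10 half-point grid"
            )
    if "ocb" in samples.columns:
        o = samples["ocb"].dropna()
        if not o.isin([0, 1, 0.0, 1.0]).all():
            sid = o.index[~o.isin([0, 1])][0]
            raise ValidationError(f"OCB for sample {sid!r} is not binary")
    for col in ("protein", "wbc", "igg_index"):
        if col in samples.columns:
            v = pd.to_numeric(samples[col], errors="raise").dropna()
            if (v < 0).any():
                sid = v.index[v < 0][0]
                raise ValidationError(f"negative {col} for sample {sid!r}")
    return samples


def validate_metabolites(metabolites: pd.DataFrame) -> pd.DataFrame:
    """Validate a metabolite annotation table (index = metabolite ID).

    Fingerprints are numpy uint8 0/1 vectors (or NaN when absent) and must
    all share one length; chem_class comes from the closed vocabulary.
    """
    _check_unique(metabolites.index, "metabolite")
    if "chem_class" not in metabolites.columns:
        raise ValidationError("metabolite annotation lacks column 'chem_class'")
    bad = metabolites.loc[~metabolites["chem_class"].isin(CHEM_CLASSES)]
    if len(bad):
        raise ValidationError(
            f"unknown chem_class {bad['chem_class'].iloc[0]!r} "
            f"for metabolite {bad.index[0]!r}"
        )
    if "fingerprint" in metabolites.columns:
        length = None
        for mid, fp in metabolites["fingerprint"].items():
            if fp is None or (np.isscalar(fp) and pd.isna(fp)):
                continue
            fp = np.asarray(fp)
            if not np.isin(fp, (0, 1)).all():
                raise ValidationError(
                    f"fingerprint for metabolite {mid!r} is not binary"
                )
            if length is None:
                length = fp.size
            elif fp.size != length:
                raise ValidationError(
                    f"fingerprint length mismatch for metabolite {mid!r}: "
                    f"{fp.size} != {length}"
                )
    return metabolites


def validate_dataset(ds: Dataset) -> Dataset:
    """Cross-validate the triple: IDs must match one-to-one across tables."""
    ds.matrix.validate()
    validate_samples(ds.samples)
    validate_metabolites(ds.metabolites)
    mat_samples = set(ds.matrix.sample_ids)
    ann_samples = set(ds.samples.index)
    for sid in sorted(mat_samples - ann_samples):
        raise ValidationError(f"sample {sid!r} in matrix but not in annotation")
    for sid in sorted(ann_samples - mat_samples):
        raise ValidationError(f"sample {sid!r} annotated but absent from matrix")
    mat_mets = set(ds.matrix.metabolite_ids)
    ann_mets = set(ds.metabolites.index)
    for mid in sorted(mat_mets - ann_mets):
        raise ValidationError(f"metabolite {mid!r} in matrix but not annotated")
    for mid in sorted(ann_mets - mat_mets):
        raise ValidationError(f"metabolite {mid!r} annotated but absent from matrix")
    return ds


def rpair_table(metabolites: pd.DataFrame) -> list[tuple[str, str]]:
    """Reaction-pair edge list from the ``rpair_partners`` annotation column.

    Returns unordered unique pairs (a < b lexicographically). Partners that
    are not themselves annotated metabolites are kept (the network builder
    decides whether to warn and skip).
    """
    pairs: set[tuple[str, str]] = set()
    if "rpair_partners" not in metabolites.columns:
        return []
    for mid, partners in metabolites["rpair_partners"].items():
        if partners is None or (np.isscalar(partners) and pd.isna(partners)):
            continue
        for p in partners:
            if p == mid:
                continue
            pairs.add((min(mid, p), max(mid, p)))
    return sorted(pairs)
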