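"""Per-metabolite two-group statistics and fold changes.

The contrast statistic is the two-sided pooled-variance (Student) t-test on
present values of the sum-normalised, unlogged matrix; the fold change is
the ratio of arithmetic group means (case / reference). Groups may be
unions, e.g. all three diseases against the controls. No multiple-testing
correction is applied by default (raw p < alpha), with Benjamini-Hochberg
available behind a flag; the result records which was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from csfmet.datatypes import MetaboliteMatrix, ValidationError


@dataclass
class ContrastResult:
    """Per-metabolite statistics for one two-group contrast."""

    contrast: str
    table: pd.DataFrame  # columns: p_value, fold_change, direction, significant, testable
    alpha: float
    adjusted: bool

    def __post_init__(self) -> None:
        t = self.table
        ok = t["testable"]
        up = t.loc[ok, "fold_change"] > 1
        assert ((t.loc[ok, "direction"] == "up") == up).all()


def _group_mask(samples: pd.DataFrame, groups, by: str = "group") -> pd.Series:
    if isinstance(groups, str):
        groups = (groups,)
    return samples[by].isin(groups)


def contrast_stats(
    m: MetaboliteMatrix,
    samples: pd.DataFrame,
    reference,
    case,
    alpha: float = 0.05,
    welch: bool = False,
    adjust: bool = False,
    by: str = "group",
) -> ContrastResult:
    """Two-group contrast over all metabolites.

    Parameters
    ----------
    reference, case : str or sequence of str
        Design group(s) forming each side; unions are allowed
        (e.g. ``case=("MS", "NMOSD", "ITM")`` for all diseases).
    welch : bool
        Use the unequal-variance (Welch) t-test instead of the pooled
        Student test.
    adjust : bool
        Apply Benjamini-Hochberg across metabolites before calling
        significance.

    A metabolite with fewer than two present values on either side is
    flagged untestable and excluded from the significance list.
    """
    samples = samples.loc[m.values.index]
    ref_mask = _group_mask(samples, reference, by).to_numpy()
    case_mask = _group_mask(samples, case, by).to_numpy()
    if not ref_mask.any() or not case_mask.any():
        raise ValidationError("empty reference or case group")
    if (ref_mask & case_mask).any():
        raise ValidationError("reference and case groups overlap")

    rows = []
    for mid in m.values.columns:
        col = m.values[mid].to_numpy()
        a = col[case_mask]
        b = col[ref_mask]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append((np.nan, np.nan, "ns", False))
            continue
        if b.mean() == 0:
            rows.append((np.nan, np.nan, "ns", False))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        fc = a.mean() / b.mean()
        p = min(float(p), 1.0) if np.isfinite(p) else 1.0
        p = max(p, np.finfo(float).tiny)  # p in (0, 1]
        rows.append((p, fc, "up" if fc > 1 else "down", True))

    table = pd.DataFrame(
        rows,
        index=m.values.columns,
        columns=["p_value", "fold_change", "direction", "testable"],
    )
    p_for_sig = table["p_value"].copy()
    if adjust:
        ok = table["testable"]
        p_for_sig.loc[ok] = _bh_adjust(table.loc[ok, "p_value"].to_numpy())
    table["p_adjusted"] = p_for_sig if adjust else np.nan
    table["significant"] = table["testable"] & (p_for_sig < alpha)
    name = _contrast_name(reference, case)
    return ContrastResult(contrast=name, table=table, alpha=alpha, adjusted=adjust)


def _contrast_name(reference, case) -> str:
    def fmt(g):
        return g if isinstance(g, str) else "+".join(g)

    return f"{fmt(reference)}_vs_{fmt(case)}"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significant_set(result: ContrastResult, alpha: float | None = None) -> list[str]:
    """Metabolites passing the significance threshold, ascending by p."""
    t = result.table
    alpha = result.alpha if alpha is None else alpha
    p = t["p_adjusted"] if result.adjusted else t["p_value"]
    sig = t.loc[t["testable"] & (p < alpha)]
    return list(sig["p_value"].sort_values(kind="stable").index)
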