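"""Normalisation, occurrence filtering, imputation and scaling.

The processing order mirrors standard GC-MS practice: per-sample sum
normalisation (total identified-peak intensity), a per-design-group 50%
occurrence filter, half-minimum imputation of censored values, then a
natural-log transform with unit-variance autoscaling for the latent models.
Univariate statistics run on the sum-normalised, unlogged scale so fold
changes stay ratios of relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from csfmet.datatypes import MetaboliteMatrix, ValidationError


def sum_normalize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each sample by its total present intensity, rescaled to the
    cohort-median total so magnitudes stay in the original range.

    Missing values stay missing. Idempotent: row totals are equal afterwards,
    so a second application changes nothing.
    """
    v = m.values
    totals = v.sum(axis=1, skipna=True)
    if (totals == 0).any() or v.notna().sum(axis=1).eq(0).any():
        sid = v.index[(v.notna().sum(axis=1) == 0) | (totals == 0)][0]
        raise ValidationError(f"sample {sid!r} has no present intensity")
    target = float(np.median(totals))
    return MetaboliteMatrix(v.mul(target / totals, axis=0))


def occurrence_filter(
    m: MetaboliteMatrix, samples: pd.DataFrame, min_frac: float = 0.5
) -> MetaboliteMatrix:
    """Keep a metabolite iff present in at least ``min_frac`` of the samples
    of at least one design group. Presence = non-missing (zero counts)."""
    if not 0 <= min_frac <= 1:
        raise ValidationError("min_frac must be in [0, 1]")
    present = m.present()
    groups = samples.loc[m.values.index, "group"]
    keep = pd.Series(False, index=m.values.columns)
    for _, idx in groups.groupby(groups).groups.items():
        frac = present.loc[idx].mean(axis=0)
        keep |= frac >= min_frac
    return MetaboliteMatrix(m.values.loc[:, keep[keep].index])


def impute_missing(m: MetaboliteMatrix, strategy: str = "half_min") -> MetaboliteMatrix:
    """Replace missing values.

    ``half_min`` substitutes half the per-metabolite minimum present value
    (a standard stand-in for below-LOD censoring); ``none`` leaves the matrix
    untouched (the univariate stage tolerates missing values; the latent
    stage requires complete data).
    """
    if strategy == "none":
        return m.copy()
    if strategy != "half_min":
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    v = m.values.copy()
    mins = v.min(axis=0, skipna=True)
    if mins.isna().any():
        mid = mins.index[mins.isna()][0]
        raise ValidationError(f"metabolite {mid!r} is entirely missing")
    return MetaboliteMatrix(v.fillna(mins / 2.0))


@dataclass
class ScalingState:
    """Per-metabolite centering/dispersion constants on the transformed scale,
    stored so held-out samples are scaled with the training moments."""

    center: pd.Series
    scale: pd.Series
    transform: str  # "log" | "none"
    mode: str       # "uv" | "pareto" | "none"

    def apply(self, m: MetaboliteMatrix) -> pd.DataFrame:
        v = m.values.reindex(columns=self.center.index)
        if v.isna().any().any():
            raise ValidationError("scaling requires a complete matrix")
        if self.transform == "log":
            if (v <= 0).any().any():
                raise ValidationError("log transform requires positive values")
            v = np.log(v)
        return (v - self.center) / self.scale


def autoscale(
    m: MetaboliteMatrix, transform: str = "log", mode: str = "uv"
) -> tuple[pd.DataFrame, ScalingState]:
    """Transform and scale a complete matrix for latent modelling.

    ``transform='log'`` applies the natural log first. ``mode`` is ``uv``
    (unit variance: mean 0, sd 1), ``pareto`` (divide by sqrt(sd)) or
    ``none`` (centering only). Returns the scaled matrix and the state to
    apply to held-out samples.
    """
    if transform not in ("log", "none"):
        raise ValidationError(f"unknown transform {transform!r}")
    if mode not in ("uv", "pareto", "none"):
        raise ValidationError(f"unknown scaling mode {mode!r}")
    v = m.values
    if v.isna().any().any():
        raise ValidationError("autoscale requires a complete (imputed) matrix")
    if transform == "log":
        if (v <= 0).any().any():
            raise ValidationError("log transform requires positive values")
        v = np.log(v)
    center = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    if (sd == 0).any():
        mid = sd.index[sd == 0][0]
        raise ValidationError(f"zero-variance metabolite {mid!r}")
    scale = {"uv": sd, "pareto": np.sqrt(sd), "none": pd.Series(1.0, index=sd.index)}[mode]
    state = ScalingState(center=center, scale=scale, transform=transform, mode=mode)
    return (v - center) / scale, state


def unscale(scaled: pd.DataFrame, state: ScalingState) -> MetaboliteMatrix:
    """Invert :func:`autoscale` (up to floating point)."""
    v = scaled * state.scale + state.center
    if state.transform == "log":
        v = np.exp(v)
    return MetaboliteMatrix(v)
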