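"""Shared-and-unique-structures (SUS) screening of remission/relapse shifts.

Two one-predictive-component OPLS-DA models sharing the control class —
control vs. remission and control vs. relapse — give each metabolite a pair
of p(corr) coordinates. Metabolites on the diagonal move equally in both
statuses; metabolites above the diagonal increase gradually
(control < remission < relapse); metabolites hugging an axis are specific to
one status. Region calls are confirmed by K-means on standardised profiles,
and the merged screen additionally requires univariate relapse-vs-remission
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from csfmet.datatypes import MetaboliteMatrix, ValidationError
from csfmet.latent import OPLS
from csfmet.univariate import contrast_stats

logger = logging.getLogger(__name__)

REGIONS = (
    "shared_up_gradual", "shared_up", "shared_down",
    "relapse_specific", "remission_specific", "null",
)

DISEASES = ("MS", "NMOSD", "ITM")


@dataclass
class SusCoordinates:
    """Per-metabolite p(corr) pair and (after classification) region label."""

    table: pd.DataFrame  # columns: pcorr_remission, pcorr_relapse [, region]
    disease: str
    thresholds: dict[str, float] = field(default_factory=dict)


def _pre_treatment_mask(samples: pd.DataFrame) -> pd.Series:
    if "pre_treatment" in samples.columns:
        return samples["pre_treatment"].fillna(False).astype(bool)
    logger.warning(
        "no pre_treatment annotation; including all samples in the SUS analysis"
    )
    return pd.Series(True, index=samples.index)


def _status_pcorr(X: pd.DataFrame, samples: pd.DataFrame, mask_disease, status, a_orth):
    """p(corr) from the control-vs-one-status OPLS-DA, oriented so the
    disease class has the positive mean predictive score."""
    is_ctrl = samples["group"] == "CTRL"
    sel = is_ctrl | (mask_disease & (samples["status"] == status))
    sub = X.loc[sel.to_numpy()]
    y = np.where(is_ctrl[sel.to_numpy()], "CTRL", status)
    if (y == status).sum() == 0:
        raise ValidationError(f"no {status} samples in the selected disease set")
    res = OPLS(sub.to_numpy(), y, feature_names=list(X.columns)).fit(1, a_orth)
    t1 = res.scores[:, 0]
    flip = t1[y == status].mean() < t1[y == "CTRL"].mean()
    pc = res.pcorr()
    return -pc if flip else pc


def sus_coordinates(
    X: pd.DataFrame,
    samples: pd.DataFrame,
    disease: str = "ALL",
    a_orth: int = 1,
) -> SusCoordinates:
    """SUS coordinates for one disease (or statuses pooled over ``ALL``).

    Only pre-treatment samples enter the two models (the annotation flag is
    honoured when present). The X axis is p(corr) from control-vs-remission,
    the Y axis from control-vs-relapse.
    """
    samples = samples.loc[X.index]
    pre = _pre_treatment_mask(samples)
    if disease == "ALL":
        mask_disease = samples["group"].isin(DISEASES) & pre
    elif disease in DISEASES:
        mask_disease = (samples["group"] == disease) & pre
    else:
        raise ValidationError(f"unknown disease {disease!r}")
    if "status" not in samples.columns:
        raise ValidationError("sample annotation lacks status labels")
    x = _status_pcorr(X, samples, mask_disease, "REMISSION", a_orth)
    y = _status_pcorr(X, samples, mask_disease, "RELAPSE", a_orth)
    return SusCoordinates(
        table=pd.DataFrame({"pcorr_remission": x, "pcorr_relapse": y}),
        disease=disease,
    )


def classify_regions(
    coords: SusCoordinates,
    c_contrib: float = 0.3,
    c_axis: float = 0.08,
    c_diag: float = 0.08,
) -> SusCoordinates:
    """Deterministic region call from the coordinate pair.

    With x = p(corr) control-vs-remission and y = control-vs-relapse:

    * ``relapse_specific``   iff |x| < c_axis and y >= c_contrib
    * ``remission_specific`` iff |y| < c_axis and x >= c_contrib
    * ``shared_up_gradual``  iff x > c_axis and y > x + c_diag
    * ``shared_up``          iff x, y >= c_contrib and |y - x| <= c_diag
    * ``shared_down``        iff x, y <= -c_contrib
    * ``null`` otherwise.

    The thresholds are configuration, recorded on the result.
    """
    t = coords.table.copy()

    def region(x: float, y: float) -> str:
        if abs(x) < c_axis and y >= c_contrib:
            return "relapse_specific"
        if abs(y) < c_axis and x >= c_contrib:
            return "remission_specific"
        if x > c_axis and y > x + c_diag:
            return "shared_up_gradual"
        if x >= c_contrib and y >= c_contrib and abs(y - x) <= c_diag:
            return "shared_up"
        if x <= -c_contrib and y <= -c_contrib:
            return "shared_down"
        return "null"

    t["region"] = [
        region(x, y) for x, y in zip(t["pcorr_remission"], t["pcorr_relapse"])
    ]
    return SusCoordinates(
        table=t,
        disease=coords.disease,
        thresholds={"c_contrib": c_contrib, "c_axis": c_axis, "c_diag": c_diag},
    )


def kmeans_confirm(
    X: pd.DataFrame,
    samples: pd.DataFrame,
    candidates,
    k: int | None = None,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means confirmation of candidate expression patterns.

    Clusters the candidate metabolites on their per-metabolite standardised
    profiles (pattern, not magnitude) with seeded multi-restart K-means, and
    reports per cluster the mean abundance by status plus whether the
    monotone control < remission < relapse pattern holds.

    Returns (assignment: metabolite -> cluster, cluster report).
    """
    candidates = list(candidates)
    if k is None:
        k = max(2, min(len(candidates), 2))
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(candidates):
        raise ValidationError("k exceeds the number of candidate metabolites")
    prof = X[candidates].to_numpy().T  # metabolites x samples
    sd = prof.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    prof = (prof - prof.mean(axis=1, keepdims=True)) / sd[:, None]
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(prof)
    assign = pd.Series(labels, index=candidates, name="cluster")

    status = samples.loc[X.index, "status"].replace({"NONE": "CONTROL"})
    rows = []
    for c in range(k):
        mets = assign.index[assign == c]
        means = X[mets].mean(axis=1).groupby(status.to_numpy()).mean()
        ctrl = means.get("CONTROL", np.nan)
        rem = means.get("REMISSION", np.nan)
        rel = means.get("RELAPSE", np.nan)
        rows.append(
            {
                "cluster": c,
                "n_metabolites": len(mets),
                "mean_control": ctrl,
                "mean_remission": rem,
                "mean_relapse": rel,
                "monotone_up": bool(ctrl < rem < rel),
                "inertia": float(km.inertia_),
            }
        )
    return assign, pd.DataFrame(rows).set_index("cluster")


def merged_gradual_screen(
    X: pd.DataFrame,
    matrix: MetaboliteMatrix,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    a_orth: int = 1,
    c_contrib: float = 0.3,
    c_axis: float = 0.08,
    c_diag: float = 0.08,
) -> list[str]:
    """Merged (disease-pooled) screen for gradual relapse metabolites.

    Classifies SUS regions on the pooled remission/relapse models, keeps the
    ``shared_up_gradual`` metabolites, and confirms each by the univariate
    relapse-vs-remission test (p < alpha and fold change > 1) on the
    sum-normalised matrix restricted to pre-treatment patient samples.
    """
    coords = classify_regions(
        sus_coordinates(X, samples, "ALL", a_orth),
        c_contrib=c_contrib, c_axis=c_axis, c_diag=c_diag,
    )
    gradual = list(coords.table.index[coords.table["region"] == "shared_up_gradual"])
    if not gradual:
        return []
    sub_samples = samples.loc[matrix.values.index]
    pre = _pre_treatment_mask(sub_samples)
    disease = sub_samples["group"].isin(DISEASES) & pre
    sub = MetaboliteMatrix(matrix.values.loc[disease.to_numpy(), gradual])
    res = contrast_stats(
        sub, sub_samples.loc[disease.to_numpy()],
        reference="REMISSION", case="RELAPSE", alpha=alpha, by="status",
    )
    t = res.table
    confirmed = t.index[t["significant"] & (t["fold_change"] > 1)]
    return [m for m in gradual if m in set(confirmed)]


def hcluster_order(
    X_subset: pd.DataFrame, metric: str = "spearman", link: str = "average"
):
    """Agglomerative leaf ordering of metabolites for heatmap export.

    Distance is 1 - Spearman rank correlation between metabolite profiles
    (columns of ``X_subset``); linkage is average by default. Metabolites
    with constant profiles (undefined correlation) are flagged and placed
    last. Returns (leaf order, linkage matrix, dropped metabolites).
    """
    mets = list(X_subset.columns)
    if len(mets) < 2:
        raise ValidationError("need at least 2 metabolites to cluster")
    prof = X_subset.to_numpy().T
    const = prof.std(axis=1, ddof=0) == 0
    dropped = [m for m, c in zip(mets, const) if c]
    kept = [m for m, c in zip(mets, const) if not c]
    if len(kept) < 2:
        return kept + dropped, None, dropped
    sub = prof[~const]
    if metric == "spearman":
        rho = spearmanr(sub, axis=1)[0]
        if np.isscalar(rho):  # spearmanr collapses the 2-row case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        dist = 1.0 - rho
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=link)
    order = [kept[i] for i in leaves_list(Z)]
    return order + dropped, Z, dropped
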