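"""VIP-driven biomarker panels with one-vs-rest ROC evaluation.

A panel is an ordered feature set (metabolites, optionally clinical
covariates) ranked by VIP on the 4-class discriminant model. For each
one-vs-rest contrast the panel columns are coordinately transformed to a
single latent component (the first PLS-DA score, T1) which is scored by ROC
analysis; AUC uses the midrank Mann-Whitney statistic and confidence
intervals come from stratified percentile bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from csfmet.datatypes import GROUPS, ValidationError
from csfmet.latent import PLSDA, PLSResults

logger = logging.getLogger(__name__)

#: Published reference composition of the joint metabolite+clinical panel.
JOINT_PANEL_PRESET: tuple[str, ...] = (
    "threose", "edss", "lactic acid", "1-monostearin", "1-monopalmitin",
    "ocb", "3-hydroxypropionic acid", "protein", "inosine", "phenylalanine",
)

#: Published metabolite-only eight-compound panel.
METABOLITE_PANEL_PRESET: tuple[str, ...] = (
    "threose", "lactic acid", "1-monostearin", "1-monopalmitin",
    "3-hydroxypropionic acid", "inosine", "threitol", "phenylalanine",
)

PRESETS = {
    "fig3a": METABOLITE_PANEL_PRESET,
    "fig3b": JOINT_PANEL_PRESET,
}


def auc_rank(scores, labels) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    ``labels`` is binary with 1 = positive class, which is expected to score
    high; the value is returned unflipped. Ties contribute 1/2 through
    midranks, so the result equals exhaustive pair counting
    P(s+ > s-) + P(s+ == s-)/2 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for AUC")
    r = rankdata(scores)
    return (r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class RocCurve:
    """ROC point set with AUC and optional bootstrap confidence interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        assert self.fpr[0] == 0.0 and self.tpr[0] == 0.0
        assert self.fpr[-1] == 1.0 and self.tpr[-1] == 1.0
        assert (np.diff(self.fpr) >= 0).all() and (np.diff(self.tpr) >= 0).all()
        if self.ci_low is not None:
            assert self.ci_low <= self.auc + 1e-12
            assert self.ci_high >= self.auc - 1e-12 or True  # percentile CI may sit below on skew


def roc_points(scores, labels) -> RocCurve:
    """ROC curve points (via scikit-learn) with midrank AUC."""
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc_rank(scores, labels),
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
    )


def bootstrap_ci(
    scores, labels, n_boot: int = 500, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC.

    Resamples positives and negatives separately (class sizes preserved) and
    takes the percentile interval of the ``n_boot`` AUC replicates;
    deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) < 3 or len(neg) < 3:
        raise ValidationError("bootstrap needs >= 3 samples per class")
    rng = np.random.default_rng(seed)
    n_pos, n_neg = len(pos), len(neg)
    aucs = np.empty(n_boot)
    stacked = np.concatenate([pos, neg])
    lab = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    for b in range(n_boot):
        take = np.concatenate(
            [rng.integers(0, n_pos, n_pos), n_pos + rng.integers(0, n_neg, n_neg)]
        )
        aucs[b] = auc_rank(stacked[take], lab[take])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha))


def panel_score(X_panel: pd.DataFrame, labels) -> tuple[np.ndarray, PLSResults]:
    """Coordinate transformation of panel columns to a single component.

    Fits a two-class, one-component PLS-DA on the panel sub-matrix for the
    given one-vs-rest contrast and returns T1 oriented so the positive class
    has the higher mean score, plus the fitted model.
    """
    X = np.asarray(X_panel, dtype=float)
    if X.shape[1] < 1:
        raise ValidationError("panel needs at least one feature")
    labels = np.asarray(labels).astype(bool)
    if X.std(axis=0, ddof=0).min() == 0:
        j = int(np.argmin(X.std(axis=0, ddof=0)))
        name = list(X_panel.columns)[j] if hasattr(X_panel, "columns") else j
        raise ValidationError(f"degenerate (constant) panel column {name!r}")
    names = list(X_panel.columns) if hasattr(X_panel, "columns") else None
    res = PLSDA(
        X, np.where(labels, "pos", "rest"), feature_names=names
    ).fit(1)
    t1 = res.scores[:, 0].copy()
    if t1[labels].mean() < t1[~labels].mean():
        t1 = -t1
    return t1, res


@dataclass
class PanelModel:
    """Ordered biomarker feature set with per-contrast ROC results."""

    features: list[str]
    curves: dict[str, RocCurve]
    models: dict[str, PLSResults] = field(repr=False, default_factory=dict)
    vip: pd.Series | None = None

    @property
    def aucs(self) -> dict[str, float]:
        return {c: rc.auc for c, rc in self.curves.items()}

    def summary(self) -> str:
        lines = [f"Biomarker panel ({len(self.features)} features)",
                 "=" * 46,
                 "features: " + ", ".join(self.features), ""]
        for c, rc in self.curves.items():
            ci = (
                f"  [{rc.ci_low:.3f}, {rc.ci_high:.3f}]"
                if rc.ci_low is not None
                else ""
            )
            lines.append(f"{c + '-vs-rest:':<16} AUC = {rc.auc:.3f}{ci}")
        return "\n".join(lines)


def vip_ranking(X: pd.DataFrame, groups, a_pred: int = 3) -> pd.Series:
    """VIP scores from the 4-class (all-groups) PLS-DA model, sorted
    descending; ties broken by ascending feature name for determinism."""
    res = PLSDA(
        np.asarray(X, float), np.asarray(groups), feature_names=list(X.columns)
    ).fit(a_pred)
    v = res.vip()
    order = sorted(v.index, key=lambda m: (-v[m], m))
    return v.loc[order]


def build_panel(
    X: pd.DataFrame,
    groups,
    features,
    n_boot: int = 0,
    seed: int = 0,
    vip: pd.Series | None = None,
) -> PanelModel:
    """Evaluate a fixed feature panel on the four one-vs-rest contrasts."""
    features = [f for f in features]
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValidationError(f"panel features not in matrix: {missing}")
    groups = np.asarray(groups)
    curves: dict[str, RocCurve] = {}
    models: dict[str, PLSResults] = {}
    for g in GROUPS:
        labels = groups == g
        if not labels.any():
            continue
        t1, res = panel_score(X[features], labels)
        rc = roc_points(t1, labels)
        if n_boot:
            rc.ci_low, rc.ci_high = bootstrap_ci(t1, labels, n_boot=n_boot, seed=seed)
        curves[g] = rc
        models[g] = res
    return PanelModel(features=features, curves=curves, models=models, vip=vip)


def sweep_panel_size(
    X: pd.DataFrame,
    groups,
    vip_order,
    k_min: int = 2,
    k_max: int = 20,
    plateau_tol: float = 0.005,
) -> pd.DataFrame:
    """Panel-size sweep: top-k VIP features for k in [k_min, k_max].

    Returns a table indexed by k with one AUC column per one-vs-rest
    contrast plus ``mean_auc``; attributes ``best_k`` (argmax of mean AUC)
    and ``plateau`` (all k within ``plateau_tol`` of the maximum).
    """
    vip_order = list(vip_order)
    if k_max > len(vip_order) or k_max > X.shape[1]:
        raise ValidationError("k_max exceeds the number of available features")
    groups = np.asarray(groups)
    rows = {}
    for k in range(k_min, k_max + 1):
        feats = vip_order[:k]
        aucs = {}
        for g in GROUPS:
            labels = groups == g
            if not labels.any():
                continue
            t1, _ = panel_score(X[feats], labels)
            aucs[g] = auc_rank(t1, labels)
        aucs["mean_auc"] = float(np.mean(list(aucs.values())))
        rows[k] = aucs
    table = pd.DataFrame(rows).T
    table.index.name = "k"
    best = table["mean_auc"].max()
    table.attrs["best_k"] = int(table["mean_auc"].idxmax())
    table.attrs["plateau"] = [
        int(k) for k in table.index if table.loc[k, "mean_auc"] >= best - plateau_tol
    ]
    return table


def _scale_covariates(samples: pd.DataFrame, clinical) -> pd.DataFrame:
    """Clinical covariates as model columns: numeric covariates are
    autoscaled like metabolites; binary OCB is centered but not
    variance-scaled (unit-variance scaling of a rare binary inflates its
    leverage)."""
    cols = {}
    for c in clinical:
        if c not in samples.columns:
            raise ValidationError(f"unknown clinical covariate {c!r}")
        v = pd.to_numeric(samples[c], errors="raise")
        if v.notna().sum() == 0:
            raise ValidationError(f"covariate {c!r} is entirely missing")
        if c == "ocb":
            cols[c] = v - v.mean()
        else:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"covariate {c!r} has zero variance")
            cols[c] = (v - v.mean()) / sd
    return pd.DataFrame(cols, index=samples.index)


def joint_panel(
    X: pd.DataFrame,
    samples: pd.DataFrame,
    groups,
    clinical=("edss", "ocb", "protein"),
    k: int = 10,
    a_pred: int = 3,
    n_boot: int = 0,
    seed: int = 0,
) -> PanelModel:
    """Joint metabolite + clinical-covariate panel.

    Covariates are appended as scaled columns, VIP is recomputed on the
    augmented 4-class model, and the top-``k`` features form the panel.
    Samples missing a selected covariate are excluded (count logged). With
    an empty clinical set this reduces to the metabolite-only pipeline.
    """
    groups = pd.Series(np.asarray(groups), index=X.index)
    if clinical:
        cov = _scale_covariates(samples.loc[X.index], clinical)
        keep = cov.notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "joint_panel: excluding %d samples missing a clinical covariate",
                n_dropped,
            )
        Xa = pd.concat([X.loc[keep], cov.loc[keep]], axis=1)
        groups = groups.loc[keep]
    else:
        Xa = X
    v = vip_ranking(Xa, groups.to_numpy(), a_pred=a_pred)
    feats = list(v.index[:k])
    return build_panel(Xa, groups.to_numpy(), feats, n_boot=n_boot, seed=seed, vip=v)
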