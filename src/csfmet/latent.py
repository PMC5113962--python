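"""NIPALS latent-variable models: PLS-DA, OPLS(-DA), VIP, p(corr), Q2.

The models follow the statsmodels convention: a model object is constructed
from data and ``fit()`` returns a results object carrying scores, loadings,
fit statistics and diagnostics.

* :class:`PLSDA` — NIPALS PLS2 on one-hot class dummies (or a numeric
  response matrix, giving ordinary PLS regression).
* :class:`OPLS` — orthogonal projections to latent structures: structured
  X-variation uncorrelated with the response is filtered into orthogonal
  components before the predictive components are fitted.
* :func:`q2_cv` — cross-validated predictive ability Q2 = 1 - PRESS/SSY with
  scaling re-estimated inside each training fold.
* VIP (variable importance in the projection) and p(corr) (score-variable
  correlation) hang off the results objects.

Sign convention: every component is flipped so the variable with the largest
absolute weight has a positive weight, making score plots reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_MAX_ITER = 2000
_TOL = 1e-9


class FitError(RuntimeError):
    """Raised when NIPALS fails to converge or a component is degenerate."""


def _as_response(y, classes=None):
    """Return (Y matrix, class list or None). Labels become one-hot dummies."""
    y = np.asarray(y)
    if y.ndim == 1 and (y.dtype.kind in "OUSb" or classes is not None):
        cls = list(classes) if classes is not None else sorted(set(y.tolist()))
        if len(cls) < 2:
            raise ValueError("need at least 2 classes for a discriminant model")
        Y = np.column_stack([(y == c).astype(float) for c in cls])
        return Y, cls
    Y = y.astype(float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, None


def _nipals_component(X, Y):
    """One NIPALS PLS2 component on centered X, Y.

    Returns (w, t, c, p) with ``w`` unit-norm, ``t = X w``,
    ``c = Y't/(t't)``, ``p = X't/(t't)``.
    """
    ss = (Y**2).sum(axis=0)
    u = Y[:, int(np.argmax(ss))].copy()
    if not u.any():
        raise FitError("response has no variance")
    t = np.zeros(X.shape[0])
    for _ in range(_MAX_ITER):
        w = X.T @ u / (u @ u)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise FitError("zero weight vector: X has no covariance with Y")
        w /= nw
        t_new = X @ w
        c = Y.T @ t_new / (t_new @ t_new)
        u = Y @ c / (c @ c)
        if np.linalg.norm(t_new - t) <= _TOL * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    else:
        raise FitError(f"NIPALS did not converge in {_MAX_ITER} iterations")
    # sign convention: largest-|weight| variable positive
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w, t, c = -w, -t, -c
    p = X.T @ t / (t @ t)
    return w, t, c, p


def _fit_pls(X, Y, n_components):
    """NIPALS PLS2 with deflation; returns dict of matrices and statistics."""
    Xd, Yd = X.copy(), Y.copy()
    ssy_total = (Y**2).sum()
    W, T, C, P, ssy = [], [], [], [], []
    for a in range(n_components):
        if not np.any(np.abs(Xd) > 1e-12):
            raise FitError(f"X rank exhausted before component {a + 1}")
        try:
            w, t, c, p = _nipals_component(Xd, Yd)
        except FitError as e:
            raise FitError(f"component {a + 1}: {e}") from None
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, c)
        W.append(w)
        T.append(t)
        C.append(c)
        P.append(p)
        ssy.append((t @ t) * (c @ c))
    return {
        "W": np.column_stack(W),
        "T": np.column_stack(T),
        "C": np.column_stack(C),
        "P": np.column_stack(P),
        "ssy_explained": np.array(ssy),
        "r2y_cum": 1.0 - (Yd**2).sum() / ssy_total,
    }


def _pls_coef(W, P, C):
    """Regression coefficients B with Yhat = X B (centered spaces)."""
    return W @ np.linalg.solve(P.T @ W, C.T)


class _BaseResults:
    """Shared accessors for fitted latent models."""

    def vip(self) -> pd.Series:
        """Variable importance in the projection over predictive components.

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
        per-component weights; mean squared VIP is exactly 1.
        """
        W = self.weights
        ssy = self.ssy_explained
        p = W.shape[0]
        num = (W**2 * ssy[None, :]).sum(axis=1)
        v = np.sqrt(p * num / ssy.sum())
        return pd.Series(v, index=self.feature_names, name="VIP")

    def pcorr(self, X=None) -> pd.Series:
        """Correlation of each (scaled) X column with the first predictive
        score T1; the coordinate of S- and SUS-plots. Requires a model with
        exactly one predictive component."""
        if self.n_pred != 1:
            raise ValueError(
                f"p(corr) is defined for 1 predictive component, "
                f"model has {self.n_pred}"
            )
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        t = self.scores[:, 0]
        Xc = X - X.mean(axis=0)
        sx = Xc.std(axis=0, ddof=0)
        if np.any(sx == 0):
            j = int(np.where(sx == 0)[0][0])
            raise ValueError(f"zero-variance column {self.feature_names[j]!r}")
        r = (Xc.T @ (t - t.mean())) / (len(t) * sx * t.std(ddof=0))
        return pd.Series(r, index=self.feature_names, name="pcorr")

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            "=" * 46,
            f"n samples:              {self.model.X.shape[0]}",
            f"n variables:            {self.model.X.shape[1]}",
            f"predictive components:  {self.n_pred}",
        ]
        if getattr(self, "n_orth", 0):
            lines.append(f"orthogonal components:  {self.n_orth}")
        r2a = self.ssy_explained / self.model._ssy_total
        for a in range(self.n_pred):
            lines.append(f"  R2Y component {a + 1}:      {r2a[a]:.4f}")
        lines.append(f"R2Y (cumulative):       {self.r2y_cum:.4f}")
        if self.q2 is not None:
            lines.append(f"Q2  (cross-validated):  {self.q2:.4f}")
        if self.classes is not None:
            lines.append(f"classes:                {', '.join(map(str, self.classes))}")
        return "\n".join(lines)


class PLSResults(_BaseResults):
    """Fitted PLS(-DA) model state."""

    def __init__(self, model, parts, n_pred):
        self.model = model
        self.weights = parts["W"]
        self.scores = parts["T"]
        self.y_loadings = parts["C"]
        self.loadings = parts["P"]
        self.ssy_explained = parts["ssy_explained"]
        self.r2y_cum = parts["r2y_cum"]
        self.n_pred = n_pred
        self.n_orth = 0
        self.q2 = None
        self.classes = model.classes
        self.feature_names = model.feature_names

    def predict(self, X) -> np.ndarray:
        """Predicted response matrix for new (identically scaled) samples."""
        X = np.asarray(X, dtype=float)
        B = _pls_coef(self.weights, self.loadings, self.y_loadings)
        return (X - self.model._x_mean) @ B * self.model._y_sd + self.model._y_mean

    def predict_classes(self, X) -> np.ndarray:
        if self.classes is None:
            raise ValueError("not a discriminant model")
        Yhat = self.predict(X)
        return np.array([self.classes[i] for i in Yhat.argmax(axis=1)])

    def transform(self, X) -> np.ndarray:
        """Predictive scores for new samples."""
        X = np.asarray(X, dtype=float) - self.model._x_mean
        R = self.weights @ np.linalg.inv(self.loadings.T @ self.weights)
        return X @ R


class OPLSResults(_BaseResults):
    """Fitted OPLS(-DA) model state: predictive + orthogonal parts."""

    def __init__(self, model, parts, n_pred, orth):
        self.model = model
        self.weights = parts["W"]
        self.scores = parts["T"]
        self.y_loadings = parts["C"]
        self.loadings = parts["P"]
        self.ssy_explained = parts["ssy_explained"]
        self.r2y_cum = parts["r2y_cum"]
        self.n_pred = n_pred
        W_o, T_o, P_o = orth
        self.orth_weights = W_o
        self.orth_scores = T_o
        self.orth_loadings = P_o
        self.n_orth = 0 if W_o is None else W_o.shape[1]
        self.q2 = None
        self.classes = model.classes
        self.feature_names = model.feature_names

    def _filter(self, X) -> np.ndarray:
        """Remove the fitted orthogonal variation from (centered) X."""
        Xf = np.asarray(X, dtype=float) - self.model._x_mean
        for k in range(self.n_orth):
            t_o = Xf @ self.orth_weights[:, k]
            Xf -= np.outer(t_o, self.orth_loadings[:, k])
        return Xf

    def predict(self, X) -> np.ndarray:
        B = _pls_coef(self.weights, self.loadings, self.y_loadings)
        return self._filter(X) @ B * self.model._y_sd + self.model._y_mean

    def predict_classes(self, X) -> np.ndarray:
        if self.classes is None:
            raise ValueError("not a discriminant model")
        Yhat = self.predict(X)
        return np.array([self.classes[i] for i in Yhat.argmax(axis=1)])

    def transform(self, X) -> np.ndarray:
        Xf = self._filter(X)
        R = self.weights @ np.linalg.inv(self.loadings.T @ self.weights)
        return Xf @ R


class PLSDA:
    """NIPALS PLS2 discriminant model (or PLS regression for numeric y).

    Parameters
    ----------
    X : array-like, samples x variables
        Scaled data matrix (see :func:`csfmet.preprocess.autoscale`); it is
        re-centered internally so prediction is well-defined.
    y : array-like
        Class labels (one-hot dummy coding, column-centered) or a numeric
        response vector/matrix.
    """

    def __init__(self, X, y, feature_names=None, classes=None, y_scale=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        Y, cls = _as_response(y, classes)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different sample counts")
        self._x_mean = X.mean(axis=0)
        self.X = X - self._x_mean
        self._y_mean = Y.mean(axis=0)
        # Discriminant responses are unit-variance scaled by default (the
        # convention of the standard chemometrics packages): with unbalanced
        # classes, centering alone would let the majority-class dummies
        # dominate the fit and the VIP, burying minority-class contrasts.
        if y_scale is None:
            y_scale = cls is not None
        self._y_sd = (
            np.where((sd := (Y - self._y_mean).std(axis=0, ddof=1)) > 0, sd, 1.0)
            if y_scale
            else np.ones(Y.shape[1])
        )
        self.Y = (Y - self._y_mean) / self._y_sd
        self._ssy_total = (self.Y**2).sum()
        self.classes = cls
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

    def fit(self, n_components: int) -> PLSResults:
        if not 1 <= n_components <= min(self.X.shape):
            raise ValueError(f"n_components must be in [1, {min(self.X.shape)}]")
        parts = _fit_pls(self.X, self.Y, n_components)
        return PLSResults(self, parts, n_components)


class OPLS(PLSDA):
    """Orthogonal PLS: response-orthogonal X-variation is filtered into
    orthogonal components, then predictive components are fitted.

    For each orthogonal component the X-loading of the current predictive
    direction is projected onto the orthogonal complement of the X-response
    covariance span, so every orthogonal score is exactly uncorrelated with
    every response column. With zero orthogonal components the fit reduces
    to :class:`PLSDA`.
    """

    def fit(self, a_pred: int = 1, a_orth: int = 0) -> OPLSResults:
        if a_orth < 0:
            raise ValueError("a_orth must be >= 0")
        if a_pred + a_orth > min(self.X.shape):
            raise ValueError("a_pred + a_orth exceeds the rank bound of X")
        Xf = self.X.copy()
        W_o, T_o, P_o = [], [], []
        for k in range(a_orth):
            w, t, c, p = _nipals_component(Xf, self.Y)
            V = Xf.T @ self.Y                      # X-response covariance span
            Q, R = np.linalg.qr(V)
            keep = np.abs(np.diag(R)) > 1e-12
            Q = Q[:, keep]
            w_o = p - Q @ (Q.T @ p)
            n_wo = np.linalg.norm(w_o)
            if n_wo < 1e-10:
                raise FitError(
                    f"orthogonal component {k + 1}: residual X rank exhausted"
                )
            w_o /= n_wo
            j = int(np.argmax(np.abs(w_o)))
            if w_o[j] < 0:
                w_o = -w_o
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf -= np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
        parts = _fit_pls(Xf, self.Y, a_pred)
        orth = (
            (np.column_stack(W_o), np.column_stack(T_o), np.column_stack(P_o))
            if W_o
            else (None, None, None)
        )
        return OPLSResults(self, parts, a_pred, orth)


# --------------------------------------------------------------------------
# functional interface
# --------------------------------------------------------------------------

def fit_plsda(X, labels, a_pred, feature_names=None, classes=None) -> PLSResults:
    """Fit a PLS-DA model; thin wrapper over :class:`PLSDA`."""
    return PLSDA(X, labels, feature_names=feature_names, classes=classes).fit(a_pred)


def fit_opls(X, y, a_pred=1, a_orth=0, feature_names=None, classes=None) -> OPLSResults:
    """Fit an OPLS(-DA) model; thin wrapper over :class:`OPLS`."""
    return OPLS(X, y, feature_names=feature_names, classes=classes).fit(a_pred, a_orth)


def _fold_assignment(y, folds, seed, sample_ids=None, stratify=True):
    """Deterministic (optionally stratified) fold labels.

    Samples are keyed by sorted sample ID (row index by default) before the
    seeded shuffle, so the assignment is invariant to row order.
    """
    n = len(y)
    ids = np.asarray(sample_ids if sample_ids is not None else np.arange(n))
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if stratify:
        strata = [np.where(np.asarray(y) == c)[0] for c in sorted(set(np.asarray(y).tolist()))]
    else:
        strata = [np.arange(n)]
    for idx in strata:
        order = idx[np.argsort(ids[idx])]
        order = order[rng.permutation(len(order))]
        fold[order] = np.arange(len(order)) % folds
    return fold


def q2_cv(
    X,
    y,
    a_pred,
    a_orth=0,
    folds=7,
    seed=0,
    sample_ids=None,
    scale=True,
    classes=None,
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/SSY.

    PRESS accumulates squared held-out prediction errors over the folds;
    SSY accumulates squared held-out deviations from the training-fold
    response mean (the null model). Column scaling of X is re-estimated
    inside each training fold. Discriminant responses are stratified by
    class; a fold that would lose an entire class raises.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    Y, cls = _as_response(y, classes)
    stratify = cls is not None
    fold = _fold_assignment(
        np.asarray(y) if stratify else np.zeros(len(X)),
        folds, seed, sample_ids, stratify,
    )
    press = ssy = 0.0
    for f in range(folds):
        te = fold == f
        if not te.any():
            continue
        tr = ~te
        if stratify and len(set(np.asarray(y)[tr].tolist())) < len(cls):
            raise ValueError(f"fold {f} loses an entire class from training")
        Xtr, Xte = X[tr], X[te]
        mu = Xtr.mean(axis=0)
        if scale:
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
        else:
            sd = np.ones(X.shape[1])
        model = OPLS((Xtr - mu) / sd, Y[tr])
        res = model.fit(a_pred, a_orth)
        Yhat = res.predict((Xte - mu) / sd)
        press += ((Y[te] - Yhat) ** 2).sum()
        ssy += ((Y[te] - Y[tr].mean(axis=0)) ** 2).sum()
    return 1.0 - press / ssy


def select_components(X, y, max_components=10, min_gain=0.01, **cv_kw):
    """Forward selection of predictive components: add while cross-validated
    Q2 improves by more than ``min_gain``. Returns (n_components, q2)."""
    best_a, best_q2 = 1, q2_cv(X, y, 1, **cv_kw)
    for a in range(2, max_components + 1):
        try:
            q2 = q2_cv(X, y, a, **cv_kw)
        except (FitError, np.linalg.LinAlgError):
            break
        if q2 - best_q2 > min_gain:
            best_a, best_q2 = a, q2
        else:
            break
    return best_a, best_q2


def y_related_profile(
    X, edss, feature_names=None, a_orth=1, class_order=None
) -> pd.DataFrame:
    """Response-related variable profile of an OPLS regression on EDSS.

    Fits a one-predictive-component OPLS with ``edss`` as the single
    response, and returns per-variable predictive weights plus p(corr) for
    the loading scatter. ``class_order`` (variable -> structural class) is
    used to re-order the profile by chemical similarity when given.
    """
    edss = np.asarray(edss, dtype=float)
    if np.isnan(edss).all():
        raise ValueError("EDSS is entirely missing")
    if np.isnan(edss).any():
        raise ValueError("EDSS must be present for all included samples")
    res = fit_opls(X, edss, 1, a_orth, feature_names=feature_names)
    prof = pd.DataFrame(
        {"weight": res.weights[:, 0], "pcorr": res.pcorr().to_numpy()},
        index=pd.Index(res.feature_names, name="variable"),
    )
    if class_order is not None:
        key = pd.Series({v: class_order.get(v, "") for v in prof.index})
        prof = prof.loc[key.sort_values(kind="stable").index]
    return prof


def pca_scores(X, n_comp=2):
    """Principal-component scores via eigen-decomposition of the covariance.

    Returns (scores, explained_variance_ratio). Component signs follow the
    largest-|loading| convention.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(len(X) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_comp]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    total = np.trace(cov)
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    return Xc @ evecs, ratio


def vip(results) -> pd.Series:
    """Functional alias for :meth:`_BaseResults.vip`."""
    return results.vip()


def pcorr(results, X=None) -> pd.Series:
    """Functional alias for :meth:`_BaseResults.pcorr`."""
    return results.pcorr(X)
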