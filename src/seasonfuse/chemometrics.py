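"""Supervised latent-variable modelling for metabolomics matrices.

Implements Pareto scaling, PLS-DA via the NIPALS algorithm, OPLS-DA
(orthogonal signal correction before a predictive component), stratified
cross-validated fit statistics (R2X, R2Y, Q2), permutation validation of the
class model, VIP (variable importance in projection) scoring and top-k
selection, and a thin hierarchical-clustering wrapper.

Conventions follow the standard chemometrics formulation: X is an n x p
matrix of samples by variables, class labels are one-hot encoded into Y and
column-centered, and all fit statistics are fractions of centered sums of
squares.  Q2 = 1 - PRESS/SS with predictions taken from held-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold

DEFAULT_N_FOLDS = 7
DEFAULT_N_PERMUTATIONS = 100
DEFAULT_TOP_K = 15
_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def _as_array(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(c) for c in m.columns]
    arr = np.asarray(m, dtype=float)
    return arr, [str(j) for j in range(arr.shape[1])]


def pareto_scale(m):
    """Mean-center and divide by the square root of the column SD.

    Pareto scaling sits between mean-centering and unit-variance scaling: it
    damps the dominance of intense variables without blowing up noise.
    Constant columns map to all-zero columns.
    """
    arr, _ = _as_array(m)
    if arr.shape[0] < 2:
        raise ValueError("Pareto scaling needs >= 2 samples")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    root = np.sqrt(sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(root > 0, (arr - mean) / root, 0.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(scaled, index=m.index, columns=m.columns)
    return scaled


def one_hot(labels) -> tuple[np.ndarray, list]:
    """One-hot encode labels; classes in sorted order."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    y = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        y[labels == cls, k] = 1.0
    return y, classes


@dataclass
class LatentModel:
    """Fitted PLS-DA / OPLS-DA model.

    Predictive parts: X-weights ``weights`` (p x A), X-loadings ``loadings``,
    X-scores ``scores`` (n x A), Y-loadings ``y_loadings`` (c x A).  For
    OPLS-DA the orthogonal triplet (``orth_weights``, ``orth_loadings``,
    ``orth_scores``) is populated.  ``ssy`` holds the Y sum of squares
    explained per predictive component, used by VIP.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    classes: list
    variable_ids: list[str]
    r2x: float
    r2y: float
    r2x_per_component: np.ndarray
    ssy: np.ndarray
    orth_weights: np.ndarray | None = None
    orth_loadings: np.ndarray | None = None
    orth_scores: np.ndarray | None = None
    q2: float | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def _correct(self, x: np.ndarray) -> np.ndarray:
        """Center and strip orthogonal variation from new data."""
        xc = np.asarray(x, dtype=float) - self.x_mean
        if self.orth_weights is not None:
            for a in range(self.orth_weights.shape[1]):
                w_o = self.orth_weights[:, a]
                p_o = self.orth_loadings[:, a]
                t_o = xc @ w_o
                xc = xc - np.outer(t_o, p_o)
        return xc

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Predictive scores for new samples (orthogonal variation removed)."""
        xc = self._correct(x)
        w, p = self.weights, self.loadings
        # R = W (P'W)^-1 gives scores consistent with NIPALS deflation.
        r = w @ np.linalg.pinv(p.T @ w)
        return xc @ r

    def predict_y(self, x: np.ndarray) -> np.ndarray:
        """Continuous Y prediction (one column per class for PLS-DA)."""
        t = self.transform(x)
        return t @ self.y_loadings.T + self.y_mean

    def predict_class(self, x: np.ndarray) -> list:
        yhat = self.predict_y(x)
        return [self.classes[k] for k in np.argmax(yhat, axis=1)]


def _nipals_component(x: np.ndarray, y: np.ndarray):
    """One NIPALS PLS component on centered X (n x p) and Y (n x c)."""
    u = y[:, int(np.argmax(y.var(axis=0)))].copy()
    if not np.any(u):
        u = y[:, 0].copy()
    w = np.zeros(x.shape[1])
    for _ in range(_NIPALS_MAX_ITER):
        w_new = x.T @ u
        norm = np.linalg.norm(w_new)
        if norm == 0:
            break
        w_new /= norm
        t = x @ w_new
        tt = t @ t
        if tt == 0:
            w = w_new
            break
        q = y.T @ t / tt
        qq = q @ q
        u_new = y @ q / qq if qq > 0 else u
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            u = u_new
            break
        w, u = w_new, u_new
    t = x @ w
    tt = t @ t
    p = x.T @ t / tt if tt > 0 else np.zeros(x.shape[1])
    q = y.T @ t / tt if tt > 0 else np.zeros(y.shape[1])
    return w, t, p, q


def fit_plsda(X, labels, n_components: int = 2) -> LatentModel:
    """Fit a PLS-DA model by NIPALS with X- and Y-deflation.

    Labels are one-hot encoded and column-centered; score vectors from
    successive components are mutually orthogonal.
    """
    x, variable_ids = _as_array(X)
    y, classes = one_hot(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs >= 2 classes")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")

    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    ssx_total = float(np.sum(xc ** 2))
    ssy_total = float(np.sum(yc ** 2))

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((y.shape[1], n_components))
    r2x_comp = np.zeros(n_components)
    ssy_comp = np.zeros(n_components)
    for a in range(n_components):
        w, t, pl, q = _nipals_component(xc, yc)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pl, q
        r2x_comp[a] = float(np.sum(np.outer(t, pl) ** 2)) / ssx_total if ssx_total else 0.0
        ssy_before = float(np.sum(yc ** 2))
        xc = xc - np.outer(t, pl)
        yc = yc - np.outer(t, q)
        ssy_comp[a] = ssy_before - float(np.sum(yc ** 2))
    r2y = float(ssy_comp.sum() / ssy_total) if ssy_total else 0.0
    return LatentModel(W, P, T, Q, x_mean, y_mean, classes, variable_ids,
                       r2x=float(r2x_comp.sum()), r2y=r2y,
                       r2x_per_component=r2x_comp, ssy=ssy_comp)


def fit_oplsda(X, labels, n_components: int = 1, n_orth: int = 1) -> LatentModel:
    """Fit an OPLS-DA model for a binary contrast.

    Class-orthogonal variation is estimated and removed from X before the
    predictive component(s) are extracted, so the predictive scores carry the
    between-class separation and the orthogonal scores the within-class
    structure; corr(t_pred, t_orth) ~ 0 by construction.
    """
    x, variable_ids = _as_array(X)
    y2, classes = one_hot(labels)
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA requires exactly 2 groups, got {len(classes)}")
    x_mean = x.mean(axis=0)
    xc = x - x_mean
    # Single numeric response: membership of the second class, centered.
    yv = y2[:, 1]
    y_mean_scalar = yv.mean()
    yc = yv - y_mean_scalar
    n, p = x.shape
    ssx_total = float(np.sum(xc ** 2))

    w = xc.T @ yc / (yc @ yc)
    w /= np.linalg.norm(w)
    W_o = np.zeros((p, n_orth))
    P_o = np.zeros((p, n_orth))
    T_o = np.zeros((n, n_orth))
    for a in range(n_orth):
        t = xc @ w
        pl = xc.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            W_o = W_o[:, :a]
            P_o = P_o[:, :a]
            T_o = T_o[:, :a]
            break
        w_o /= norm
        t_o = xc @ w_o
        p_o = xc.T @ t_o / (t_o @ t_o)
        xc = xc - np.outer(t_o, p_o)
        W_o[:, a], T_o[:, a], P_o[:, a] = w_o, t_o, p_o

    # Predictive components on the orthogonality-filtered X.
    yc2 = yc.reshape(-1, 1)
    ssy_total = float(np.sum(yc2 ** 2))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((2, n_components))
    r2x_comp = np.zeros(n_components)
    ssy_comp = np.zeros(n_components)
    for a in range(n_components):
        wp, t, pl, q = _nipals_component(xc, yc2)
        # Map the scalar response loading back onto the two one-hot columns
        # ((-q, q) reproduces centered one-hot predictions for both classes).
        W[:, a], T[:, a], P[:, a] = wp, t, pl
        Q[:, a] = np.array([-q[0], q[0]])
        r2x_comp[a] = float(np.sum(np.outer(t, pl) ** 2)) / ssx_total if ssx_total else 0.0
        ssy_before = float(np.sum(yc2 ** 2))
        xc = xc - np.outer(t, pl)
        yc2 = yc2 - np.outer(t, q)
        ssy_comp[a] = ssy_before - float(np.sum(yc2 ** 2))
    r2y = float(ssy_comp.sum() / ssy_total) if ssy_total else 0.0
    y_mean2 = np.array([1.0 - y_mean_scalar, y_mean_scalar])
    return LatentModel(W, P, T, Q, x_mean, y_mean2, classes, variable_ids,
                       r2x=float(r2x_comp.sum()), r2y=r2y,
                       r2x_per_component=r2x_comp, ssy=ssy_comp,
                       orth_weights=W_o if W_o.size else None,
                       orth_loadings=P_o if P_o.size else None,
                       orth_scores=T_o if T_o.size else None)


def cross_validate(X, labels, n_components: int = 2,
                   n_folds: int = DEFAULT_N_FOLDS, seed: int = 0,
                   kind: str = "plsda", n_orth: int = 1) -> tuple[float, float, float]:
    """Stratified k-fold cross-validation; returns (R2X, R2Y, Q2).

    R2X and R2Y come from the full-data fit; Q2 = 1 - PRESS/SS with the
    prediction error summed over held-out folds against the one-hot response.
    """
    x, _ = _as_array(X)
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class size ({counts.min()}); "
            "stratified folds are impossible")
    fit = fit_plsda if kind == "plsda" else (
        lambda xx, ll, a: fit_oplsda(xx, ll, a, n_orth=n_orth))
    full = fit(x, labels, n_components)
    y_full, _ = one_hot(labels)

    press = 0.0
    ss = 0.0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, labels):
        model = fit(x[train], labels[train], n_components)
        y_test = np.zeros((len(test), len(model.classes)))
        for k, cls in enumerate(model.classes):
            y_test[labels[test] == cls, k] = 1.0
        yhat = model.predict_y(x[test])
        press += float(np.sum((y_test - yhat) ** 2))
        ss += float(np.sum((y_test - y_full[train].mean(axis=0)) ** 2))
    q2 = 1.0 - press / ss if ss > 0 else np.nan
    return full.r2x, full.r2y, q2


@dataclass
class PermutationResult:
    """Outcome of a label-permutation validation of a class model."""

    observed_r2y: float
    observed_q2: float
    permuted: pd.DataFrame  # columns: correlation, r2y, q2
    r2y_intercept: float
    q2_intercept: float
    valid: bool


def _label_correlation(perm_y: np.ndarray, true_y: np.ndarray) -> float:
    """|Pearson r| between permuted and true centered one-hot assignments."""
    a = (perm_y - perm_y.mean(axis=0)).ravel()
    b = (true_y - true_y.mean(axis=0)).ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(abs(a @ b) / denom) if denom > 0 else 0.0


def permutation_test(X, labels, n_components: int = 2,
                     n_permutations: int = DEFAULT_N_PERMUTATIONS, seed: int = 0,
                     n_folds: int = DEFAULT_N_FOLDS, kind: str = "plsda",
                     n_orth: int = 1) -> PermutationResult:
    """Validate a class model by repeatedly permuting the labels.

    For each permutation the model is refitted and cross-validated; R2Y and
    Q2 are regressed (least squares, over the permuted points plus the
    observed point at correlation 1) against the absolute correlation between
    permuted and true labels.  The model is flagged valid when the Q2
    regression intercept is negative and the observed Q2 exceeds every
    permuted Q2.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x, _ = _as_array(X)
    labels = np.asarray(labels)
    true_y, _ = one_hot(labels)
    rng = np.random.default_rng(seed)

    _, r2y_obs, q2_obs = cross_validate(x, labels, n_components, n_folds, seed,
                                        kind=kind, n_orth=n_orth)
    rows = []
    for i in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_labels = labels[perm]
        perm_y, _ = one_hot(perm_labels)
        corr = _label_correlation(perm_y, true_y)
        try:
            _, r2y_p, q2_p = cross_validate(x, perm_labels, n_components,
                                            n_folds, seed, kind=kind, n_orth=n_orth)
        except ValueError:
            # Permutation degraded a class below the fold count (cannot
            # happen for plain permutations, which preserve class sizes).
            continue
        rows.append((corr, r2y_p, q2_p))
    permuted = pd.DataFrame(rows, columns=["correlation", "r2y", "q2"])

    corr_all = np.append(permuted["correlation"].to_numpy(), 1.0)
    design = np.column_stack([np.ones_like(corr_all), corr_all])
    r2y_fit = np.linalg.lstsq(design, np.append(permuted["r2y"], r2y_obs), rcond=None)[0]
    q2_fit = np.linalg.lstsq(design, np.append(permuted["q2"], q2_obs), rcond=None)[0]
    valid = bool(q2_fit[0] < 0 and q2_obs > permuted["q2"].max())
    return PermutationResult(r2y_obs, q2_obs, permuted,
                             float(r2y_fit[0]), float(q2_fit[0]), valid)


def vip_scores(model: LatentModel) -> pd.DataFrame:
    """Variable importance in projection for a fitted model.

    VIP_j = sqrt( p * sum_a [ (w_ja/||w_a||)^2 * SSY_a ] / sum_a SSY_a ),
    over the predictive components; mean(VIP^2) = 1 by construction.  Returns
    a table with columns variable_id, vip, rank (1 = most important).
    """
    w = model.weights
    p = w.shape[0]
    wnorm2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    ssy = model.ssy
    denom = ssy.sum()
    vip = np.sqrt(p * (wnorm2 @ ssy) / denom) if denom > 0 else np.zeros(p)
    table = pd.DataFrame({"variable_id": model.variable_ids, "vip": vip})
    order = np.lexsort((np.arange(p), -vip))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    table["rank"] = ranks
    return table


def top_k_vip(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """The k highest-VIP variables; boundary ties broken by input order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(f"k={k} exceeds the {len(table)} available variables; "
                      "returning all", stacklevel=2)
        k = len(table)
    order = np.lexsort((np.arange(len(table)), -table["vip"].to_numpy()))
    return table.iloc[order[:k]].reset_index(drop=True)


def hierarchical_cluster(m, method: str = "ward", metric: str = "euclidean") -> np.ndarray:
    """Agglomerative clustering of samples; returns the scipy linkage matrix."""
    arr, _ = _as_array(m)
    if arr.shape[0] < 2:
        raise ValueError("clustering needs >= 2 samples")
    try:
        return _scipy_linkage(pdist(arr, metric=metric), method=method)
    except ValueError as exc:
        raise ValueError(f"unknown linkage/metric: {exc}") from exc


def per_season_top_vip(X, labels, k: int = DEFAULT_TOP_K,
                       n_orth: int = 1) -> dict[str, pd.DataFrame]:
    """One-vs-rest OPLS-DA per season with its top-k VIP table.

    The union of these per-season lists is the pool of season-discriminant
    variable candidates across all contrasts.
    """
    labels = np.asarray(labels)
    out: dict[str, pd.DataFrame] = {}
    for season in sorted(set(labels.tolist())):
        binary = np.where(labels == season, season, "rest")
        model = fit_oplsda(X, binary, 1, n_orth)
        out[season] = top_k_vip(vip_scores(model), k)
    return out


def most_scattered_season(scores: np.ndarray, labels) -> str:
    """The class whose samples lie farthest from the overall score centroid.

    In a score plot the "scattered" group is the one that both spreads out
    and breaks away from the tight cluster formed by the remaining samples;
    the mean squared distance of a class's samples to the overall centroid
    captures displacement plus spread in one number.  Used to pick the
    one-vs-rest OPLS-DA contrast (most scattered season versus all others).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    centroid = scores.mean(axis=0)
    best, best_val = None, -np.inf
    for cls in sorted(set(labels.tolist())):
        pts = scores[labels == cls]
        val = float(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        if val > best_val:
            best, best_val = cls, val
    return best
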