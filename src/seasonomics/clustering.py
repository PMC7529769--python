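"""Discovery of the major seasonal patterns.

Significant analytes' fitted annual curves (days 1..365, z-scored per
feature) are clustered with fuzzy C-means; the number of clusters is
chosen by the average silhouette width of the hardened partition, with
within-cluster dispersion reported for the elbow view. New data
streams — clinical labs, meteorology, pollen counts — are *projected*
onto the learned centroids: their fuzzy membership is computed against
fixed centroids, giving each stream a 0..1 affinity to every seasonal
pattern without refitting the clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .seasonal import SeasonalFit

log = logging.getLogger(__name__)

_TOL = 1e-9
_MAX_ITER = 1000


class ClusteringError(ValueError):
    pass


class EmptySelection(ClusteringError):
    """No feature passed the seasonality filter."""


@dataclass
class CurveMatrix:
    """Standardized annual curves of the seasonality-significant features."""

    feature_ids: list[str]
    matrix: np.ndarray          # (n_features, 365), rows mean 0 / sd 1
    excluded: list[str]         # degenerate (constant-curve) features

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass
class ClusterModel:
    """Fuzzy C-means solution over curve space."""

    k: int
    m: float
    centroids: np.ndarray       # (k, 365)
    membership: np.ndarray      # (n, k), rows sum to 1
    objective: float
    seed: int | None
    n_restarts: int


@dataclass
class KSelectionReport:
    ks: list[int]
    silhouette: list[float]
    dispersion: list[float]     # within-cluster sum of squares (elbow)
    chosen_k: int
    models: dict[int, ClusterModel]


def standardize_curve(curve: np.ndarray) -> np.ndarray:
    """z-score one curve across days; raises on a constant curve."""
    c = np.asarray(curve, dtype=float)
    sd = c.std()
    if sd < 1e-12:
        raise ClusteringError("constant curve cannot be standardized")
    return (c - c.mean()) / sd


def standardize_curves(
    fits: dict[str, SeasonalFit] | list[SeasonalFit],
    p_threshold: float = 0.05,
) -> CurveMatrix:
    """Filter fits by seasonality p <= threshold and z-score the curves.

    Constant fitted curves (zero variance across days) are excluded and
    logged. Raises :class:`EmptySelection` if nothing passes.
    """
    items = fits.values() if isinstance(fits, dict) else fits
    ids, rows, excluded = [], [], []
    for fit in items:
        if fit.pvalue is None or fit.pvalue > p_threshold:
            continue
        try:
            rows.append(standardize_curve(fit.fitted_curve))
        except ClusteringError:
            excluded.append(fit.feature_id or "?")
            log.info("excluding %s: constant fitted curve", fit.feature_id)
            continue
        ids.append(fit.feature_id or f"feature{len(ids)}")
    if not ids:
        raise EmptySelection(f"no feature passed p <= {p_threshold}")
    return CurveMatrix(feature_ids=ids, matrix=np.vstack(rows), excluded=excluded)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (n, k); exact-hit rows
    get a unit vector on (the first of) their zero-distance centroids."""
    n, k = d2.shape
    U = np.zeros((n, k))
    zero = d2 <= 1e-300
    hit = zero.any(axis=1)
    if hit.any():
        first = np.argmax(zero[hit], axis=1)
        U[np.flatnonzero(hit), first] = 1.0
    ok = ~hit
    if ok.any():
        power = 1.0 / (m - 1.0)
        inv = d2[ok] ** -power
        U[ok] = inv / inv.sum(axis=1, keepdims=True)
    return U


def _objective(d2: np.ndarray, U: np.ndarray, m: float) -> float:
    return float(((U ** m) * d2).sum())


def fuzzy_cmeans(
    curves: CurveMatrix | np.ndarray,
    k: int,
    m: float = 2.0,
    seed: int | None = 0,
    n_restarts: int = 10,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> ClusterModel:
    """Bezdek fuzzy C-means, best of ``n_restarts`` seeded restarts.

    Alternates the membership update u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1))
    with membership^m-weighted centroid means until the objective
    changes by less than ``tol``.
    """
    X = curves.matrix if isinstance(curves, CurveMatrix) else np.asarray(curves, float)
    n = len(X)
    if k < 1:
        raise ClusteringError("k must be >= 1")
    if m <= 1.0:
        raise ClusteringError("fuzzifier m must be > 1")
    if k > n:
        raise ClusteringError(f"k={k} exceeds the {n} available curves")
    if k == 1:
        C = X.mean(axis=0, keepdims=True)
        d2 = ((X - C) ** 2).sum(axis=1, keepdims=True)
        return ClusterModel(k=1, m=m, centroids=C, membership=np.ones((n, 1)),
                            objective=float(d2.sum()), seed=seed, n_restarts=1)

    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(n_restarts):
        C = X[rng.choice(n, size=k, replace=False)].copy()
        prev = np.inf
        for _it in range(max_iter):
            d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            U = _memberships(d2, m)
            W = U ** m
            C = (W.T @ X) / W.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            U = _memberships(d2, m)
            obj = _objective(d2, U, m)
            if prev - obj < tol:
                break
            prev = obj
        if best is None or obj < best.objective:
            best = ClusterModel(k=k, m=m, centroids=C, membership=U,
                                objective=obj, seed=seed, n_restarts=n_restarts)
    return best


def project_membership(new_curve: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Fuzzy membership of a standardized curve against fixed centroids.

    Returns a length-k vector summing to 1; a curve coinciding with a
    centroid gets membership 1 there.
    """
    x = np.asarray(new_curve, dtype=float)
    if x.shape != (model.centroids.shape[1],):
        raise ClusteringError("curve length does not match the centroids")
    d2 = ((model.centroids - x) ** 2).sum(axis=1)[None, :]
    return _memberships(d2, model.m)[0]


def hard_labels(model: ClusterModel) -> np.ndarray:
    return model.membership.argmax(axis=1)


def _dispersion(X: np.ndarray, model: ClusterModel) -> float:
    lab = hard_labels(model)
    return float(((X - model.centroids[lab]) ** 2).sum())


def select_k(
    curves: CurveMatrix | np.ndarray,
    k_range=range(2, 11),
    m: float = 2.0,
    seed: int | None = 0,
    n_restarts: int = 10,
) -> KSelectionReport:
    """Scan k, score each hardened partition by average silhouette width.

    Silhouette needs at least two clusters, so the scan starts at k=2;
    a k whose hardened partition collapses to a single label scores -1.
    The chosen k is the silhouette argmax; within-cluster dispersion is
    reported alongside for the elbow view.
    """
    X = curves.matrix if isinstance(curves, CurveMatrix) else np.asarray(curves, float)
    ks, sils, wss, models = [], [], [], {}
    if len(list(k_range)) == 0:
        raise ClusteringError(
            f"empty k range: {len(X)} curves support at most k = {len(X) - 1}")
    for k in k_range:
        if not 2 <= k <= len(X) - 1:
            raise ClusteringError(f"k={k} outside [2, n-1]")
        model = fuzzy_cmeans(X, k, m=m, seed=seed, n_restarts=n_restarts)
        lab = hard_labels(model)
        if len(np.unique(lab)) < 2:
            sil = -1.0
            log.info("k=%d hardened to a single cluster", k)
        else:
            sil = float(silhouette_score(X, lab, metric="euclidean"))
        ks.append(k)
        sils.append(sil)
        wss.append(_dispersion(X, model))
        models[k] = model
    chosen = ks[int(np.argmax(sils))]
    return KSelectionReport(ks=ks, silhouette=sils, dispersion=wss,
                            chosen_k=chosen, models=models)


def pca_summary(
    curves: CurveMatrix | np.ndarray,
    labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of the curve matrix.

    Returns (scores, variance_fractions): 2-D scores per feature (with
    hard cluster labels when given) and the per-component explained
    variance fractions (non-increasing, summing to 1).
    """
    cm = curves if isinstance(curves, CurveMatrix) else None
    X = cm.matrix if cm is not None else np.asarray(curves, float)
    if len(X) < 3:
        raise ClusteringError("PCA summary needs at least 3 curves")
    pca = PCA()
    scores = pca.fit_transform(X - X.mean(axis=0))
    frac = pca.explained_variance_ratio_
    out = pd.DataFrame({
        "feature_id": cm.feature_ids if cm is not None else np.arange(len(X)),
        "pc1": scores[:, 0], "pc2": scores[:, 1]})
    if labels is not None:
        out["cluster"] = labels
    return out, frac
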