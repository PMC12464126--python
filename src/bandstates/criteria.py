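"""Cluster-number selection criteria on the polarity-invariant distance.

All criteria operate on the dissimilarity ``d(u, v) = 1 - corr(u, v)^2``
between average-referenced, unit-norm topographies, so a map and its
negation are identical — the invariance microstate clustering requires.
Seven criteria are provided (Davies-Bouldin, Gamma, Silhouette, robust
Dunn, Point-Biserial, Krzanowski-Lai, and the microstate cross-validation
criterion); each votes for an optimal K by its own convention and the modal
vote wins, smaller K breaking ties.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import silhouette_score

__all__ = [
    "pairwise_distance",
    "davies_bouldin",
    "gamma_index",
    "silhouette",
    "dunn_robust",
    "point_biserial",
    "within_dispersion",
    "krzanowski_lai",
    "cross_validation",
    "CRITERION_DIRECTIONS",
]

#: criterion name -> +1 (maximise) or -1 (minimise)
CRITERION_DIRECTIONS = {
    "davies_bouldin": -1,
    "gamma": +1,
    "silhouette": +1,
    "dunn_robust": +1,
    "point_biserial": +1,
    "krzanowski_lai": +1,
    "cross_validation": -1,
}


def _unit_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def pairwise_distance(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """``1 - corr^2`` between rows of ``x`` and rows of ``y`` (or ``x``)."""
    xu = _unit_rows(x)
    yu = xu if y is None else _unit_rows(y)
    c = np.clip(xu @ yu.T, -1.0, 1.0)
    return 1.0 - c**2


def davies_bouldin(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Davies-Bouldin index (minimise)."""
    ks = np.unique(labels)
    if len(ks) < 2:
        return np.nan
    d_to_c = pairwise_distance(x, centroids)
    scatter = np.array([d_to_c[labels == k, k].mean() for k in ks])
    sep = pairwise_distance(centroids)
    ratios = np.full(len(ks), -np.inf)
    for i, ki in enumerate(ks):
        for j, kj in enumerate(ks):
            if i == j or sep[ki, kj] <= 0:
                continue
            ratios[i] = max(ratios[i], (scatter[i] + scatter[j]) / sep[ki, kj])
    if not np.all(np.isfinite(ratios)):
        return np.nan
    return float(ratios.mean())


def _within_between(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = pairwise_distance(x)
    iu = np.triu_indices(len(x), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    dv = d[iu]
    return dv[same], dv[~same]


def gamma_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Baker-Hubert Gamma: concordance of within vs between distances (maximise)."""
    w, b = _within_between(x, labels)
    if len(w) == 0 or len(b) == 0:
        return np.nan
    b_sorted = np.sort(b)
    # for each within distance: concordant pairs have b > w, discordant b < w
    s_plus = float(np.sum(len(b) - np.searchsorted(b_sorted, w, side="right")))
    s_minus = float(np.sum(np.searchsorted(b_sorted, w, side="left")))
    if s_plus + s_minus == 0:
        return np.nan
    return (s_plus - s_minus) / (s_plus + s_minus)


def silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on the polarity-invariant distance (maximise)."""
    if len(np.unique(labels)) < 2:
        return np.nan
    d = pairwise_distance(x)
    np.fill_diagonal(d, 0.0)
    return float(silhouette_score(d, labels, metric="precomputed"))


def dunn_robust(x: np.ndarray, labels: np.ndarray) -> float:
    """Robust Dunn index (maximise).

    Uses average rather than extreme linkages: separation is the minimum
    mean between-cluster distance over cluster pairs, diameter the maximum
    mean within-cluster distance — less sensitive to single outlying maps
    than the classical min/max form.
    """
    ks = np.unique(labels)
    if len(ks) < 2:
        return np.nan
    d = pairwise_distance(x)
    diam = 0.0
    for k in ks:
        idx = np.flatnonzero(labels == k)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            diam = max(diam, sub[np.triu_indices(len(idx), k=1)].mean())
    sep = np.inf
    for i, ki in enumerate(ks):
        for kj in ks[i + 1:]:
            sep = min(sep, d[np.ix_(labels == ki, labels == kj)].mean())
    if diam <= 0 or not np.isfinite(sep):
        return np.nan
    return float(sep / diam)


def point_biserial(x: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation between distances and cluster separation
    indicator (maximise)."""
    w, b = _within_between(x, labels)
    if len(w) == 0 or len(b) == 0:
        return np.nan
    dvec = np.concatenate([w, b])
    ind = np.concatenate([np.zeros(len(w)), np.ones(len(b))])
    if dvec.std() == 0:
        return np.nan
    return float(np.corrcoef(dvec, ind)[0, 1])


def within_dispersion(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Total within-cluster dispersion ``sum d(x, centroid)`` (for KL)."""
    d = pairwise_distance(x, centroids)
    return float(d[np.arange(len(x)), labels].sum())


def krzanowski_lai(w_by_k: dict[int, float], k: int, p: int) -> float:
    """Krzanowski-Lai index at ``k`` from within-dispersions (maximise).

    ``DIFF(K) = (K-1)^{2/p} W_{K-1} - K^{2/p} W_K``;
    ``KL(K) = |DIFF(K)| / |DIFF(K+1)|``.  Needs K-1 and K+1 in ``w_by_k``;
    ``p`` is the effective dimensionality of the maps.
    """
    if (k - 1) not in w_by_k or (k + 1) not in w_by_k:
        return np.nan

    def diff(kk: int) -> float:
        return (kk - 1) ** (2 / p) * w_by_k[kk - 1] - kk ** (2 / p) * w_by_k[kk]

    denom = abs(diff(k + 1))
    if denom == 0:
        return np.nan
    return abs(diff(k)) / denom


def cross_validation(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Microstate cross-validation criterion (minimise).

    ``CV = sigma^2 * ((C-1)/(C-1-K))^2`` where ``sigma^2`` is the mean
    residual variance of the samples after projecting out the assigned
    map.  Undefined (NaN) when K >= C-1.
    """
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    n, c = x.shape
    k = centroids.shape[0]
    if c - 1 - k <= 0:
        return np.nan
    a = _unit_rows(centroids)
    proj = np.einsum("ij,ij->i", x, a[labels])
    resid = np.einsum("ij,ij->i", x, x) - proj**2
    sigma2 = resid.sum() / (n * (c - 1))
    return float(sigma2 * ((c - 1) / (c - 1 - k)) ** 2)
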