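"""GFP computation, polarity-invariant K-means, K selection and labeling.

This is the two-level topographic clustering at the heart of microstate
analysis: per recording, scalp maps at the local maxima of the Global Field
Power (GFP) — moments of maximal topographic signal-to-noise — are reduced
to a handful of dominant topographies; pooled across subjects, a second
clustering yields the group microstate maps, with the number of states
chosen by a battery of seven criteria and maps labelled against canonical
templates (A-G).

Polarity is ignored throughout: a topography and its negation are the same
microstate, so assignment uses squared spatial correlation and centroids
are principal components of their assigned maps rather than means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import criteria as crit
from .recording import Recording

__all__ = [
    "GFPSeries",
    "MicrostateModel",
    "compute_gfp",
    "find_gfp_peaks",
    "modified_kmeans",
    "individual_topographies",
    "group_cluster",
    "choose_k",
    "compute_gev",
    "label_maps",
    "canonical_templates",
    "CANONICAL_LABELS",
]

CANONICAL_LABELS = ["A", "B", "C", "D", "E", "F", "G"]


@dataclass
class GFPSeries:
    """Per-sample Global Field Power (cross-channel SD, microvolts)."""

    values: np.ndarray
    fs: float


@dataclass
class MicrostateModel:
    """A set of microstate maps with its fit statistics.

    ``maps`` is ``(K, n_channels)``, rows average-referenced and unit-norm;
    ``gev`` is the GFP^2-weighted fraction of topographic variance the model
    explains on its training samples, ``cluster_gev`` the per-cluster
    contributions, and ``labels`` the canonical names once assigned.
    """

    maps: np.ndarray
    gev: float
    cluster_gev: np.ndarray | None = None
    labels: list[str] | None = None
    band: str = ""

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def compute_gfp(rec: Recording) -> GFPSeries:
    """Global Field Power: the cross-channel standard deviation per sample.

    ``GFP(t) = sqrt( sum_i (V_i(t) - Vbar(t))^2 / N )`` over the N
    electrodes of an average-referenced map.
    """
    if rec.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GFPSeries(values=values, fs=rec.fs)


def find_gfp_peaks(gfp: GFPSeries) -> np.ndarray:
    """Indices of local GFP maxima.

    A peak rises strictly from the left and does not rise to the right
    (``v[t-1] < v[t] >= v[t+1]``), so plateaus contribute their first
    sample and endpoints are never peaks.
    """
    v = np.asarray(gfp.values)
    if len(v) < 3:
        return np.array([], dtype=np.int64)
    t = np.arange(1, len(v) - 1)
    mask = (v[t - 1] < v[t]) & (v[t] >= v[t + 1])
    return t[mask]


def _unit_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _principal_map(x: np.ndarray) -> np.ndarray:
    """First principal component of a set of maps (polarity-proof centroid)."""
    cov = x.T @ x
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise RuntimeError("degenerate cluster: zero principal map")
    v = v / n
    # deterministic sign: largest-magnitude channel positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def compute_gev(
    maps: np.ndarray | MicrostateModel,
    samples: np.ndarray,
    gfp_at_samples: np.ndarray | None = None,
    return_parts: bool = False,
):
    """Global Explained Variance of ``maps`` on ``samples``.

    ``GEV = sum_t GFP_t^2 corr^2(x_t, a_{assign(t)}) / sum_t GFP_t^2`` with
    each sample assigned to its best map by squared spatial correlation.
    ``gfp_at_samples`` defaults to the samples' own cross-channel SD.
    """
    a = maps.maps if isinstance(maps, MicrostateModel) else maps
    samples = np.asarray(samples, dtype=np.float64)
    if gfp_at_samples is None:
        centered = samples - samples.mean(axis=1, keepdims=True)
        gfp_at_samples = np.sqrt(np.mean(centered**2, axis=1))
    gfp2 = np.asarray(gfp_at_samples, dtype=np.float64) ** 2
    total = gfp2.sum()
    if total <= 0:
        raise ValueError("total GFP is zero; GEV undefined")
    xu = _unit_rows(samples)
    au = _unit_rows(a)
    corr2 = (xu @ au.T) ** 2
    assign = np.argmax(corr2, axis=1)
    best = corr2[np.arange(len(xu)), assign]
    gev = float((gfp2 * best).sum() / total)
    if return_parts:
        cluster_gev = np.array([
            (gfp2[assign == k] * best[assign == k]).sum() / total
            for k in range(a.shape[0])
        ])
        return gev, cluster_gev, assign
    return gev


def modified_kmeans(
    samples: np.ndarray,
    k: int,
    n_init: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> MicrostateModel:
    """Polarity-invariant (modified) K-means on topographies.

    Samples are assigned to the centroid with maximal squared spatial
    correlation; each centroid is updated to the first principal component
    of its assigned maps, so sign flips in the data are irrelevant.  The
    best of ``n_init`` restarts by GEV is returned.  Initial centroids are
    random smooth directions drawn from ``seed`` only, which makes the
    result invariant to the ordering of the input rows.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n, c = samples.shape
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    rng = np.random.default_rng(seed)
    xu = _unit_rows(samples)
    centered = samples - samples.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=1))
    gfp2 = gfp**2
    gfp2_total = gfp2.sum()
    if gfp2_total <= 0:
        raise ValueError("all samples have zero field power")

    best_model: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        a = _unit_rows(rng.standard_normal((k, c)))
        assign = np.full(n, -1)
        for _ in range(max_iter):
            corr2 = (xu @ a.T) ** 2
            new_assign = np.argmax(corr2, axis=1)
            best_fit = corr2[np.arange(n), new_assign]
            for kk in range(k):
                if not np.any(new_assign == kk):
                    # re-seed empty cluster from the worst-fitted sample
                    worst = int(np.argmin(best_fit))
                    a[kk] = xu[worst]
                    new_assign[worst] = kk
                    best_fit[worst] = 1.0
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            a = np.array([
                _principal_map(xu[assign == kk]) for kk in range(k)
            ])
        corr2 = (xu @ a.T) ** 2
        assign = np.argmax(corr2, axis=1)
        best_fit = corr2[np.arange(n), assign]
        gev = float((gfp2 * best_fit).sum() / gfp2_total)
        if best_model is None or gev > best_model[0]:
            best_model = (gev, a.copy(), assign.copy())

    gev, a, assign = best_model
    cluster_gev = np.array([
        (gfp2[assign == kk] * (xu[assign == kk] @ a[kk]) ** 2).sum() / gfp2_total
        for kk in range(k)
    ])
    return MicrostateModel(maps=a, gev=gev, cluster_gev=cluster_gev)


def individual_topographies(
    rec: Recording,
    n_maps: int = 7,
    n_init: int = 10,
    seed: int = 0,
    return_model: bool = False,
):
    """Dominant topographies of one recording (default seven).

    Clusters the scalp maps at GFP peaks (artifact-masked samples excluded)
    with polarity-invariant K-means and returns the ``n_maps`` centroids
    ordered by descending per-cluster explained variance, as an
    ``(n_maps, n_channels)`` array (or the ordered
    :class:`MicrostateModel` when ``return_model`` is set).
    """
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp)
    peaks = peaks[~rec.artifact_mask[peaks]]
    if len(peaks) < n_maps:
        raise ValueError(
            f"only {len(peaks)} usable GFP peaks for {n_maps} clusters")
    peak_maps = rec.data[:, peaks].T
    model = modified_kmeans(peak_maps, n_maps, n_init=n_init, seed=seed)
    order = np.argsort(-model.cluster_gev)
    ordered = MicrostateModel(maps=model.maps[order], gev=model.gev,
                              cluster_gev=model.cluster_gev[order])
    return ordered if return_model else ordered.maps


def choose_k(
    models: dict[int, MicrostateModel],
    samples: np.ndarray,
) -> tuple[int, dict]:
    """Pick the number of microstates by seven-criterion modal vote.

    For each candidate K the Davies-Bouldin, Gamma, Silhouette, robust
    Dunn, Point-Biserial, Krzanowski-Lai and cross-validation criteria are
    evaluated on the polarity-invariant distance; each criterion votes for
    its own optimum (minimising or maximising per its convention), the
    modal K wins, and ties go to the smaller K.  Returns ``(k, details)``
    where ``details`` holds the criterion tables and votes.
    """
    ks = sorted(models)
    if len(ks) < 2:
        if len(ks) == 1:
            return ks[0], {"votes": {}, "values": {}}
        raise ValueError("need at least one candidate model")
    samples = np.asarray(samples, dtype=np.float64)
    xu = _unit_rows(samples)
    n_channels = samples.shape[1]

    assigns, w_by_k = {}, {}
    for k in ks:
        corr2 = (xu @ _unit_rows(models[k].maps).T) ** 2
        assigns[k] = np.argmax(corr2, axis=1)
        w_by_k[k] = crit.within_dispersion(samples, assigns[k], models[k].maps)

    values: dict[str, dict[int, float]] = {name: {} for name in crit.CRITERION_DIRECTIONS}
    for k in ks:
        labels, a = assigns[k], models[k].maps
        effective = len(np.unique(labels))
        if effective < 2:
            for name in values:
                values[name][k] = np.nan
            continue
        values["davies_bouldin"][k] = crit.davies_bouldin(samples, labels, a)
        values["gamma"][k] = crit.gamma_index(samples, labels)
        values["silhouette"][k] = crit.silhouette(samples, labels)
        values["dunn_robust"][k] = crit.dunn_robust(samples, labels)
        values["point_biserial"][k] = crit.point_biserial(samples, labels)
        values["krzanowski_lai"][k] = crit.krzanowski_lai(w_by_k, k, n_channels - 1)
        values["cross_validation"][k] = crit.cross_validation(samples, labels, a)

    votes: dict[str, int] = {}
    for name, direction in crit.CRITERION_DIRECTIONS.items():
        vals = {k: v for k, v in values[name].items() if np.isfinite(v)}
        if not vals:
            continue
        keyed = sorted(vals.items(), key=lambda kv: (-direction * kv[1], kv[0]))
        votes[name] = keyed[0][0]

    if not votes:
        return ks[0], {"votes": votes, "values": values}
    counts = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    winner = min(k for k, c in counts.items() if c == top)
    return winner, {"votes": votes, "values": values}


def group_cluster(
    pooled: np.ndarray,
    k_range: tuple[int, ...] | range,
    seed: int = 0,
    n_init: int = 20,
    band: str = "",
) -> MicrostateModel:
    """Group-level clustering of pooled individual topographies.

    Runs polarity-invariant K-means for each K in ``k_range`` and returns
    the model whose K wins the seven-criterion vote (:func:`choose_k`).
    """
    pooled = np.asarray(pooled, dtype=np.float64)
    ks = sorted(set(int(k) for k in k_range))
    models = {k: modified_kmeans(pooled, k, n_init=n_init, seed=seed) for k in ks}
    k_star, details = choose_k(models, pooled)
    model = models[k_star]
    model.band = band
    model.selection = details  # type: ignore[attr-defined]
    return model


def canonical_templates(positions: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Synthetic canonical microstate templates A-G on a given montage.

    Idealised stand-ins for the literature's canonical topographies, built
    analytically from electrode positions (head coordinates: +x right,
    +y anterior, +z superior): A left-anterior/right-posterior diagonal,
    B the mirrored right-anterior diagonal, C an anterior-posterior
    gradient, D a fronto-central versus occipital/lateral pattern, E its
    centro-occipital counterpart, F a left-lateralised and G a
    right-lateralised extremum.  Average-referenced, unit-norm.
    """
    pos = np.asarray(positions, dtype=np.float64)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    fields = [
        -x + y,          # A
        x + y,           # B
        y,               # C
        z + 0.5 * y,     # D
        z - 0.5 * y,     # E
        -x + 0.3 * z,    # F
        x + 0.3 * z,     # G
    ]
    maps = np.array([f - f.mean() for f in fields])
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps, list(CANONICAL_LABELS)


def label_maps(
    model: MicrostateModel,
    reference: np.ndarray,
    reference_names: list[str],
) -> MicrostateModel:
    """Assign canonical names to model maps and order them canonically.

    Solves the one-to-one assignment of model maps to reference templates
    that maximises the total absolute spatial correlation (exact, Hungarian
    algorithm), attaches the winning names, and reorders the maps by name.
    Also usable for cross-band alignment with another model's maps as the
    reference.
    """
    if model.K > len(reference_names):
        raise ValueError("more model maps than reference templates")
    absc = np.abs(_unit_rows(model.maps) @ _unit_rows(np.asarray(reference)).T)
    rows, cols = linear_sum_assignment(-absc)
    names = [reference_names[c] for c in cols]
    order = np.argsort(names)
    cluster_gev = (model.cluster_gev[order]
                   if model.cluster_gev is not None else None)
    return MicrostateModel(
        maps=model.maps[order],
        gev=model.gev,
        cluster_gev=cluster_gev,
        labels=[names[i] for i in order],
        band=model.band,
    )


def _assignment_score(absc: np.ndarray, perm: tuple[int, ...]) -> float:
    return float(sum(absc[i, p] for i, p in enumerate(perm)))


def brute_force_labeling(absc: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Exhaustive best one-to-one assignment (reference oracle, K <= 8)."""
    k, r = absc.shape
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(r), k):
        s = _assignment_score(absc, perm)
        if s > best_score:
            best, best_score = perm, s
    return best, best_score
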