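"""Back-fitting group maps onto recordings and temporal metrics.

Every sample is assigned to the group microstate map it correlates with
best in absolute value; samples whose best correlation stays below the 0.7
threshold remain unassigned (transient noise frames), labels are smoothed
with an iterative windowed (Besag) criterion, segments shorter than three
frames are dissolved, and per-state mean duration (ms), occurrence (Hz)
and coverage are computed from the resulting segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import MicrostateModel
from .recording import Recording

__all__ = [
    "UNASSIGNED",
    "Segmentation",
    "spatial_correlation",
    "fit_labels",
    "smooth_labels",
    "reject_short",
    "apply_segment_threshold",
    "temporal_metrics",
    "segments_of",
]

#: label value for samples not assigned to any microstate
UNASSIGNED = -1


@dataclass
class Segmentation:
    """Per-sample microstate labels at a known sampling rate.

    ``labels[t]`` is a state index into the model's maps or ``UNASSIGNED``;
    ``corr`` holds the per-sample per-map absolute spatial correlations the
    smoothing stage re-uses; ``mask`` marks artifact samples excluded from
    analysis; ``state_names`` carries the canonical names for reporting.
    """

    labels: np.ndarray
    fs: float
    corr: np.ndarray | None = None
    mask: np.ndarray | None = None
    state_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.mask is None:
            self.mask = np.zeros(len(self.labels), dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two scalp maps across channels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps must have the same channel count")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map has no spatial correlation")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _abs_corr_matrix(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """|Pearson corr| of every sample (column of data) with every map."""
    x = data - data.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(x, axis=0)
    xn[xn == 0] = np.inf  # flat samples correlate with nothing
    a = maps - maps.mean(axis=1, keepdims=True)
    an = np.linalg.norm(a, axis=1)
    if np.any(an == 0):
        raise ValueError("model contains a zero-variance map")
    c = (a @ x) / (an[:, None] * xn[None, :])
    return np.abs(np.clip(c, -1.0, 1.0)).T  # (n_samples, K)


def fit_labels(
    rec: Recording,
    model: MicrostateModel,
    threshold: float = 0.7,
) -> Segmentation:
    """Assign every sample to its best-correlated map (polarity ignored).

    Samples whose best absolute correlation is below ``threshold`` and
    artifact-masked samples are ``UNASSIGNED``.  Ties go to the lowest
    state index.
    """
    if rec.n_channels != model.n_channels:
        raise ValueError("recording and model channel counts differ")
    corr = _abs_corr_matrix(rec.data, model.maps)
    labels = np.argmax(corr, axis=1).astype(np.int64)
    best = corr[np.arange(len(labels)), labels]
    labels[best < threshold] = UNASSIGNED
    labels[rec.artifact_mask] = UNASSIGNED
    return Segmentation(labels=labels, fs=rec.fs, corr=corr,
                        mask=rec.artifact_mask.copy(),
                        state_names=model.labels)


def smooth_labels(
    seg: Segmentation,
    gfp: np.ndarray | None = None,
    half_window: int = 3,
    besag: float = 10.0,
    max_iter: int = 50,
) -> Segmentation:
    """Iterative windowed label smoothing (Besag-style).

    Implements the standard microstate segmentation smoothing: each
    assigned sample's label is re-chosen to minimise its residual misfit
    minus ``besag`` times the count of equal labels among the assigned
    samples within ``+/- half_window``, iterated to convergence or
    ``max_iter`` sweeps.  The misfit of map ``k`` at sample ``t`` is
    ``GFP_t^2 (1 - corr_tk^2)`` scaled by twice the mean residual of the
    current labelling, so moments of low field power — where the topography
    carries little evidence — defer to their temporal neighbourhood while
    strongly expressed topographies resist relabelling.  Unassigned samples
    are never modified and do not contribute to the neighbourhood counts.
    ``gfp`` defaults to flat weighting.
    """
    if half_window < 1 or besag < 0:
        raise ValueError("half_window must be >= 1 and besag >= 0")
    if seg.corr is None:
        raise ValueError("segmentation lacks the correlation matrix")
    labels = seg.labels.copy()
    if besag == 0:
        return Segmentation(labels=labels, fs=seg.fs, corr=seg.corr,
                            mask=seg.mask.copy(), state_names=seg.state_names)
    n, k = seg.corr.shape
    gfp2 = np.ones(n) if gfp is None else np.asarray(gfp, dtype=np.float64) ** 2
    resid = gfp2[:, None] * (1.0 - seg.corr**2)  # (n, k) misfit of each map
    idx = np.flatnonzero(labels != UNASSIGNED)
    kernel = np.ones(2 * half_window + 1)
    for _ in range(max_iter):
        sigma2 = max(resid[idx, labels[idx]].mean(), 1e-12)
        onehot = np.zeros((n, k))
        onehot[idx, labels[idx]] = 1.0
        counts = np.empty_like(onehot)
        for kk in range(k):
            counts[:, kk] = np.convolve(onehot[:, kk], kernel, mode="same")
        # a sample's own current label is excluded from its support
        counts[idx, labels[idx]] -= 1.0
        score = -resid / (2.0 * sigma2) + besag * counts
        new_labels = labels.copy()
        new_labels[idx] = np.argmax(score[idx], axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return Segmentation(labels=labels, fs=seg.fs, corr=seg.corr,
                        mask=seg.mask.copy(), state_names=seg.state_names)


def segments_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as ``(state, start, end)`` with half-open ``[start, end)``."""
    out = []
    n = len(labels)
    t = 0
    while t < n:
        s = int(labels[t])
        start = t
        while t < n and labels[t] == s:
            t += 1
        out.append((s, start, t))
    return out


def reject_short(seg: Segmentation, min_frames: int = 3) -> Segmentation:
    """Dissolve assigned segments shorter than ``min_frames``.

    Each sample of a short segment is reassigned to whichever neighbouring
    segment's map correlates better with it at that sample (edge segments
    merge inward); the pass repeats until no short assigned segment
    remains.  A short segment with no assigned neighbour becomes
    ``UNASSIGNED``.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    labels = seg.labels.copy()
    corr = seg.corr
    n = len(labels)
    for _ in range(n + 1):  # each pass strictly shrinks the short-run set
        runs = segments_of(labels)
        changed = False
        for i, (state, start, end) in enumerate(runs):
            if state == UNASSIGNED or end - start >= min_frames:
                continue
            # read neighbours from the live label array so merges made
            # earlier in this pass are respected
            left = int(labels[start - 1]) if start > 0 else UNASSIGNED
            right = int(labels[end]) if end < n else UNASSIGNED
            if state in (left, right):
                continue  # already contiguous with a neighbour; re-run pass
            for t in range(start, end):
                cand = [s for s in (left, right) if s != UNASSIGNED]
                if not cand:
                    new = UNASSIGNED
                elif len(cand) == 1 or corr is None:
                    new = cand[0]
                else:
                    new = max(cand, key=lambda s: (corr[t, s], -s))
                if new != labels[t]:
                    labels[t] = new
                    changed = True
        if not changed:
            break
    return Segmentation(labels=labels, fs=seg.fs, corr=corr,
                        mask=seg.mask.copy(), state_names=seg.state_names)


def apply_segment_threshold(
    seg: Segmentation,
    gfp: np.ndarray | None = None,
    threshold: float = 0.7,
) -> Segmentation:
    """Unassign whole segments whose fit stays below ``threshold``.

    A segment's fit is the GFP^2-weighted mean absolute correlation of its
    samples with its map, so brief low-power moments inside a well-fitting
    segment do not split it, while genuinely noisy stretches — whose
    correlation is poor even at their strongest samples — are excluded.
    """
    if seg.corr is None:
        raise ValueError("segmentation lacks the correlation matrix")
    labels = seg.labels.copy()
    w = np.ones(len(labels)) if gfp is None else np.asarray(gfp, float) ** 2
    for state, start, end in segments_of(labels):
        if state == UNASSIGNED:
            continue
        ww = w[start:end]
        tot = ww.sum()
        fit = (seg.corr[start:end, state] * ww).sum() / tot if tot > 0 \
            else seg.corr[start:end, state].mean()
        if fit < threshold:
            labels[start:end] = UNASSIGNED
    return Segmentation(labels=labels, fs=seg.fs, corr=seg.corr,
                        mask=seg.mask.copy(), state_names=seg.state_names)


def temporal_metrics(seg: Segmentation, n_states: int | None = None) -> pd.DataFrame:
    """Per-state mean duration (ms), occurrence (Hz) and coverage.

    Mean duration is the average length of the state's segments times
    ``1000/fs``; occurrence is its segment count divided by the analysed
    time in seconds; coverage its labelled samples over the analysed
    samples.  Analysed time excludes artifact-masked samples but includes
    unassigned ones, so ``occurrence * mean_duration / 1000 == coverage``
    holds exactly for every state.  Absent states get occurrence and
    coverage 0 and missing (NaN) duration.
    """
    labels = seg.labels
    analyzed = ~seg.mask
    n_analyzed = int(analyzed.sum())
    if n_analyzed == 0:
        raise ValueError("no analysed samples")
    analyzed_s = n_analyzed / seg.fs

    if n_states is None:
        present = labels[analyzed]
        n_states = int(present.max()) + 1 if np.any(present != UNASSIGNED) else 0

    seg_count = np.zeros(n_states, dtype=np.int64)
    seg_samples = np.zeros(n_states, dtype=np.int64)
    for state, start, end in segments_of(labels):
        if state == UNASSIGNED:
            continue
        # count only the analysed part of the run
        n_in = int(analyzed[start:end].sum())
        if n_in == 0:
            continue
        seg_count[state] += 1
        seg_samples[state] += n_in

    rows = []
    for k in range(n_states):
        if seg_count[k] > 0:
            mean_len = seg_samples[k] / seg_count[k]
            duration = mean_len * 1000.0 / seg.fs
            occurrence = seg_count[k] / analyzed_s
            coverage = seg_samples[k] / n_analyzed
        else:
            duration, occurrence, coverage = np.nan, 0.0, 0.0
        name = (seg.state_names[k] if seg.state_names is not None
                and k < len(seg.state_names) else str(k))
        rows.append((k, name, duration, occurrence, coverage))
    return pd.DataFrame(
        rows, columns=["state", "state_name", "mean_duration", "occurrence",
                       "coverage"])
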