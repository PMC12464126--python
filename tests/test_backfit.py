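"""Back-fitting, smoothing, segment rejection and temporal metrics."""

import numpy as np
import pandas as pd
import pytest

from bandstates.backfit import (UNASSIGNED, Segmentation,
                                apply_segment_threshold, fit_labels,
                                reject_short, segments_of, smooth_labels,
                                spatial_correlation, temporal_metrics)
from bandstates.clustering import MicrostateModel, compute_gfp
from bandstates.recording import Recording


# ---------------------------------------------------------------------------
# spatial correlation

def test_spatial_correlation_limits_and_hand_value():
    a = np.array([1.0, 2.0, -1.0, 0.5])
    assert spatial_correlation(a, a) == pytest.approx(1.0)
    assert spatial_correlation(a, -a) == pytest.approx(-1.0)
    b = np.array([0.0, 1.0, 1.0, -2.0])
    ac, bc = a - a.mean(), b - b.mean()
    expected = (ac @ bc) / (np.linalg.norm(ac) * np.linalg.norm(bc))
    assert spatial_correlation(a, b) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        spatial_correlation(a, np.full(4, 2.0))
    with pytest.raises(ValueError):
        spatial_correlation(a, b[:3])


# ---------------------------------------------------------------------------
# fitting

def test_fit_labels_recovers_planted(clean_recording, templates6):
    rec, labels = clean_recording
    model = MicrostateModel(maps=templates6.maps, gev=1.0)
    seg = fit_labels(rec, model)
    assigned = seg.labels != UNASSIGNED
    assert assigned.mean() >= 0.99
    assert (seg.labels[assigned] == labels[assigned]).mean() >= 0.99


def test_fit_labels_noise_is_unassigned(templates6):
    rng = np.random.default_rng(0)
    noise = rng.normal(size=(64, 500))
    # remove any component inside the span of the model maps
    proj = np.linalg.pinv(templates6.maps) @ (templates6.maps @ noise)
    rec = Recording(data=noise - proj, fs=128.0)
    model = MicrostateModel(maps=templates6.maps, gev=1.0)
    seg = fit_labels(rec, model)
    assert (seg.labels == UNASSIGNED).mean() >= 0.99


def test_fit_labels_tie_goes_to_lowest_index():
    maps = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
    sample = (maps[0] + maps[1])[:, None]  # equally correlated with both
    rec = Recording(data=sample, fs=10.0)
    seg = fit_labels(rec, MicrostateModel(maps=maps, gev=1.0), threshold=0.5)
    assert seg.labels[0] == 0


def test_fit_labels_masked_samples_unassigned(clean_recording, templates6):
    rec, _ = clean_recording
    mask = np.zeros(rec.n_samples, dtype=bool)
    mask[100:200] = True
    masked = rec.copy_with(artifact_mask=mask)
    seg = fit_labels(masked, MicrostateModel(maps=templates6.maps, gev=1.0))
    assert np.all(seg.labels[100:200] == UNASSIGNED)


def test_fit_labels_channel_mismatch(templates6):
    rec = Recording(data=np.zeros((32, 10)), fs=128.0)
    with pytest.raises(ValueError):
        fit_labels(rec, MicrostateModel(maps=templates6.maps, gev=1.0))


# ---------------------------------------------------------------------------
# smoothing

def _toy_segmentation(labels, corr, fs=128.0):
    return Segmentation(labels=np.asarray(labels), fs=fs,
                        corr=np.asarray(corr, dtype=float))


def test_smoothing_fixed_point_on_smooth_segmentation():
    labels = np.repeat([0, 1, 0], 10)
    corr = np.full((30, 2), 0.4)
    corr[np.arange(30), labels] = 0.9
    seg = _toy_segmentation(labels, corr)
    out = smooth_labels(seg)
    assert np.array_equal(out.labels, labels)


def test_smoothing_absorbs_single_sample_intrusion():
    """A 1-sample weakly supported intrusion inside a long run is relabelled;
    brute-force evaluation of the smoothing objective confirms the flip
    lowers it."""
    labels = np.array([0] * 4 + [1] + [0] * 4)
    corr = np.full((9, 2), 0.5)
    corr[np.arange(9), labels] = 0.6  # weak fit difference
    seg = _toy_segmentation(labels, corr)
    out = smooth_labels(seg, half_window=3, besag=10.0)
    assert np.array_equal(out.labels, np.zeros(9))

    def objective(lab):
        resid = 1.0 - seg.corr[np.arange(9), lab] ** 2
        sigma2 = resid.mean()
        total = 0.0
        for t in range(9):
            lo, hi = max(0, t - 3), min(9, t + 4)
            nb = np.sum(lab[lo:hi] == lab[t]) - 1
            total += resid[t] / (2 * sigma2) - 10.0 * nb
        return total

    assert objective(np.zeros(9, dtype=int)) < objective(labels)


def test_smoothing_besag_zero_is_identity(planted_recording, templates6):
    rec, _ = planted_recording
    seg = fit_labels(rec, MicrostateModel(maps=templates6.maps, gev=1.0))
    out = smooth_labels(seg, besag=0.0)
    assert np.array_equal(out.labels, seg.labels)


def test_smoothing_never_touches_unassigned():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 3, size=200)
    labels[rng.random(200) < 0.2] = UNASSIGNED
    corr = rng.random((200, 3))
    seg = _toy_segmentation(labels, corr)
    out = smooth_labels(seg)
    was_unassigned = labels == UNASSIGNED
    assert np.array_equal(out.labels[was_unassigned],
                          labels[was_unassigned])


# ---------------------------------------------------------------------------
# short-segment rejection

def test_reject_short_keeps_long_segments():
    labels = np.repeat([0, 1, 2], 5)
    corr = np.random.default_rng(0).random((15, 3))
    seg = _toy_segmentation(labels, corr)
    assert np.array_equal(reject_short(seg, 3).labels, labels)


def test_reject_short_dissolves_intrusion():
    labels = np.array([0] * 5 + [1] + [0] * 5)
    corr = np.random.default_rng(1).random((11, 2))
    out = reject_short(_toy_segmentation(labels, corr), 3)
    assert np.array_equal(out.labels, np.zeros(11))


def test_reject_short_isolated_segment_becomes_unassigned():
    labels = np.array([2, 2])
    corr = np.random.default_rng(2).random((2, 3))
    out = reject_short(_toy_segmentation(labels, corr), 3)
    assert np.all(out.labels == UNASSIGNED)


def test_reject_short_never_leaves_short_segments():
    rng = np.random.default_rng(6)
    for _ in range(30):
        n = int(rng.integers(10, 120))
        labels = rng.integers(-1, 3, size=n)
        corr = rng.random((n, 3))
        out = reject_short(_toy_segmentation(labels, corr), 3)
        for state, start, end in segments_of(out.labels):
            if state != UNASSIGNED:
                assert end - start >= 3


def test_segment_threshold_drops_poor_segments():
    labels = np.array([0] * 10 + [1] * 10)
    corr = np.zeros((20, 2))
    corr[:10, 0] = 0.9   # good fit
    corr[10:, 1] = 0.3   # poor fit
    seg = _toy_segmentation(labels, corr)
    out = apply_segment_threshold(seg, threshold=0.7)
    assert np.all(out.labels[:10] == 0)
    assert np.all(out.labels[10:] == UNASSIGNED)


# ---------------------------------------------------------------------------
# temporal metrics

def test_metrics_arithmetic_oracle():
    """4 segments of 8 frames at 128 Hz in an 8-s recording:
    duration 62.5 ms, occurrence 0.5 Hz, coverage 1/32."""
    n = 8 * 128
    labels = np.full(n, UNASSIGNED)
    for i in range(4):
        start = i * 200
        labels[start:start + 8] = 0
    seg = Segmentation(labels=labels, fs=128.0)
    row = temporal_metrics(seg, 1).iloc[0]
    assert row["mean_duration"] == pytest.approx(62.5)
    assert row["occurrence"] == pytest.approx(0.5)
    assert row["coverage"] == pytest.approx(0.03125)


def test_metrics_single_label_block():
    labels = np.zeros(1280, dtype=int)  # 10 s at 128 Hz
    row = temporal_metrics(Segmentation(labels=labels, fs=128.0), 1).iloc[0]
    assert row["mean_duration"] == pytest.approx(10_000.0)
    assert row["occurrence"] == pytest.approx(0.1)
    assert row["coverage"] == pytest.approx(1.0)


def test_metrics_absent_state_reported_missing():
    labels = np.zeros(100, dtype=int)
    table = temporal_metrics(Segmentation(labels=labels, fs=128.0), 3)
    absent = table[table["state"] == 2].iloc[0]
    assert np.isnan(absent["mean_duration"])
    assert absent["occurrence"] == 0.0 and absent["coverage"] == 0.0


def test_metrics_identity_occurrence_duration_coverage():
    """occurrence * duration / 1000 == coverage on random segmentations."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(30, 300))
        labels = rng.integers(-1, 4, size=n)
        mask = rng.random(n) < 0.15
        seg = Segmentation(labels=labels, fs=float(rng.choice([100, 128, 256])),
                           mask=mask)
        if (~mask).sum() == 0:
            continue
        table = temporal_metrics(seg, 4).dropna(subset=["mean_duration"])
        lhs = table["occurrence"] * table["mean_duration"] / 1000.0
        assert np.allclose(lhs, table["coverage"], atol=1e-12)


def test_metrics_exclude_masked_time():
    labels = np.zeros(200, dtype=int)
    mask = np.zeros(200, dtype=bool)
    mask[:100] = True
    row = temporal_metrics(Segmentation(labels=labels, fs=100.0, mask=mask),
                           1).iloc[0]
    # only 1 s of analysed time remains
    assert row["occurrence"] == pytest.approx(1.0)
    assert row["coverage"] == pytest.approx(1.0)
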