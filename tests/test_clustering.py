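"""GFP, polarity-invariant K-means, K selection, GEV and labeling."""

import itertools

import numpy as np
import pytest

from bandstates.clustering import (brute_force_labeling, canonical_templates,
                                   choose_k, compute_gev, compute_gfp,
                                   find_gfp_peaks, group_cluster,
                                   individual_topographies, label_maps,
                                   modified_kmeans, GFPSeries,
                                   MicrostateModel)
from bandstates.recording import Recording


# ---------------------------------------------------------------------------
# GFP

def test_gfp_is_cross_channel_sd():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(16, 50))
    rec = Recording(data=data, fs=128.0)
    gfp = compute_gfp(rec)
    oracle = np.std(data, axis=0)  # population SD, two-pass
    assert np.allclose(gfp.values, oracle, atol=1e-12)


def test_gfp_examples_and_homogeneity():
    rec = Recording(data=np.array([[1.0, 2.0], [-1.0, 2.0]]), fs=10.0)
    gfp = compute_gfp(rec)
    assert gfp.values[0] == pytest.approx(1.0)  # (+1, -1) sample
    assert gfp.values[1] == pytest.approx(0.0)  # equal channels
    scaled = compute_gfp(Recording(data=-3.0 * rec.data, fs=10.0))
    assert np.allclose(scaled.values, 3.0 * gfp.values)
    with pytest.raises(ValueError):
        compute_gfp(Recording(data=np.ones((1, 5)), fs=10.0))


def test_gfp_peaks_brute_force():
    series = GFPSeries(values=np.array([1.0, 3.0, 1.0, 5.0, 1.0]), fs=1.0)
    assert list(find_gfp_peaks(series)) == [1, 3]
    assert len(find_gfp_peaks(GFPSeries(np.arange(10.0), 1.0))) == 0
    assert len(find_gfp_peaks(GFPSeries(np.ones(10), 1.0))) == 0
    # plateau reports its first sample
    assert list(find_gfp_peaks(GFPSeries(np.array([0.0, 2.0, 2.0, 1.0]), 1.0))) == [1]
    # brute-force scan oracle on random series
    rng = np.random.default_rng(3)
    v = rng.random(200)
    got = set(find_gfp_peaks(GFPSeries(v, 1.0)))
    expected = {t for t in range(1, 199) if v[t - 1] < v[t] >= v[t + 1]}
    assert got == expected


# ---------------------------------------------------------------------------
# modified K-means

def _planted_samples(templates, n_per=40, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    k, c = templates.shape
    rows, labels = [], []
    for i in range(k):
        for _ in range(n_per):
            s = rng.choice([-1.0, 1.0])
            x = s * templates[i] + noise * rng.normal(size=c)
            x -= x.mean()
            rows.append(x)
            labels.append(i)
    order = rng.permutation(len(rows))
    return np.array(rows)[order], np.array(labels)[order]


def test_kmeans_recovers_planted_maps(templates6):
    samples, _ = _planted_samples(templates6.maps, seed=1)
    model = modified_kmeans(samples, 6, n_init=10, seed=0)
    corr = np.abs(model.maps @ templates6.maps.T)
    assert corr.max(axis=0).min() >= 0.99
    assert model.gev > 0.95  # bounded by the injected channel noise


def test_kmeans_k_equals_n_gives_unit_gev():
    rng = np.random.default_rng(4)
    samples = rng.normal(size=(5, 12))
    model = modified_kmeans(samples, 5, n_init=3, seed=0)
    assert model.gev >= 1.0 - 1e-9


def test_kmeans_polarity_invariance(templates6):
    samples, _ = _planted_samples(templates6.maps, seed=2)
    a = modified_kmeans(samples, 6, n_init=5, seed=9)
    b = modified_kmeans(-samples, 6, n_init=5, seed=9)
    assert np.array_equal(a.maps, b.maps)  # PCA centroids ignore sign exactly
    assert a.gev == b.gev


def test_kmeans_validates_k():
    samples = np.random.default_rng(0).normal(size=(10, 8))
    with pytest.raises(ValueError):
        modified_kmeans(samples, 0)
    with pytest.raises(ValueError):
        modified_kmeans(samples, 11)


# ---------------------------------------------------------------------------
# individual topographies

def test_individual_topographies_contract(clean_recording, templates6):
    rec, _ = clean_recording
    maps = individual_topographies(rec, n_maps=7, n_init=5, seed=0)
    assert maps.shape == (7, 64)
    corr = np.abs(maps @ templates6.maps.T)
    matched = (corr.max(axis=0) >= 0.95).sum()
    assert matched >= 6  # at least the six planted states
    # rows ordered by descending explained variance
    model = individual_topographies(rec, n_maps=7, n_init=5, seed=0,
                                    return_model=True)
    assert np.all(np.diff(model.cluster_gev) <= 1e-12)


def test_individual_topographies_needs_enough_peaks(templates6):
    tiny = Recording(data=np.random.default_rng(0).normal(size=(64, 8)),
                     fs=128.0)
    with pytest.raises(ValueError):
        individual_topographies(tiny, n_maps=7)


# ---------------------------------------------------------------------------
# K selection and group clustering

def test_choose_k_planted_four_clusters():
    from bandstates.synthetic import make_template_maps

    templates = make_template_maps(4, 64, seed=5).maps
    samples, _ = _planted_samples(templates, n_per=30, noise=0.05, seed=6)
    models = {k: modified_kmeans(samples, k, n_init=10, seed=0)
              for k in range(2, 9)}
    k, details = choose_k(models, samples)
    assert k == 4
    assert details["votes"]["silhouette"] == 4


def test_group_cluster_recovers_planted(templates6):
    samples, _ = _planted_samples(templates6.maps, n_per=28, noise=0.03, seed=7)
    model = group_cluster(samples, range(2, 9), seed=0, n_init=10)
    assert model.K == 6
    corr = np.abs(model.maps @ templates6.maps.T)
    assert corr.max(axis=0).min() >= 0.99


def test_group_cluster_singleton_range(templates6):
    samples, _ = _planted_samples(templates6.maps, n_per=10, seed=8)
    model = group_cluster(samples, [4], seed=0, n_init=5)
    assert model.K == 4


def test_group_cluster_row_order_invariant(templates6):
    samples, _ = _planted_samples(templates6.maps, n_per=12, noise=0.05, seed=9)
    m1 = group_cluster(samples, range(4, 8), seed=3, n_init=5)
    perm = np.random.default_rng(1).permutation(len(samples))
    m2 = group_cluster(samples[perm], range(4, 8), seed=3, n_init=5)
    assert m1.K == m2.K
    # same maps up to row order
    match = np.abs(m1.maps @ m2.maps.T).max(axis=1)
    assert match.min() >= 1.0 - 1e-9


# ---------------------------------------------------------------------------
# GEV

def test_gev_limits(templates6):
    rng = np.random.default_rng(10)
    signs = rng.choice([-1.0, 1.0], size=50)
    samples = templates6.maps[0][None, :] * signs[:, None]
    assert compute_gev(templates6.maps, samples) == pytest.approx(1.0)
    # samples orthogonal to every map
    basis = np.linalg.svd(templates6.maps, full_matrices=True)[2]
    ortho = basis[10:20]  # rows orthogonal to the 6-map span
    ortho = ortho - ortho.mean(axis=1, keepdims=True)
    gev = compute_gev(templates6.maps, ortho)
    assert gev < 0.05


def test_gev_hand_computed_two_samples():
    maps = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    samples = np.array([[2.0, -2.0, 0.0], [1.0, 1.0, -2.0]])
    gfp = np.std(samples, axis=1)
    xu = samples - samples.mean(axis=1, keepdims=True)
    xu = xu / np.linalg.norm(xu, axis=1, keepdims=True)
    corr2 = (xu @ maps.T) ** 2
    best = corr2.max(axis=1)
    expected = (gfp**2 * best).sum() / (gfp**2).sum()
    assert compute_gev(maps, samples, gfp) == pytest.approx(expected, abs=1e-12)


def test_gev_monotone_in_model_size(templates6):
    rng = np.random.default_rng(11)
    samples = rng.normal(size=(80, 64))
    gevs = [compute_gev(templates6.maps[:k], samples) for k in range(1, 7)]
    assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))


def test_gev_zero_power_fails(templates6):
    with pytest.raises(ValueError):
        compute_gev(templates6.maps, np.zeros((5, 64)))


# ---------------------------------------------------------------------------
# canonical labeling

def test_label_maps_recovers_shuffled_reference(templates6):
    ref, names = canonical_templates(templates6.channel_positions)
    rng = np.random.default_rng(12)
    order = rng.permutation(6)
    signs = rng.choice([-1.0, 1.0], size=6)
    model = MicrostateModel(maps=ref[order] * signs[:, None], gev=0.9,
                            cluster_gev=np.linspace(0.3, 0.1, 6))
    labelled = label_maps(model, ref, names)
    assert labelled.labels == sorted(np.array(names)[order])
    for row, name in zip(labelled.maps, labelled.labels):
        assert abs(row @ ref[names.index(name)]) >= 0.999


def test_label_maps_matches_enumeration_oracle(templates6):
    ref, names = canonical_templates(templates6.channel_positions)
    model = MicrostateModel(maps=templates6.maps, gev=0.8)
    labelled = label_maps(model, ref, names)
    mu = model.maps - model.maps.mean(axis=1, keepdims=True)
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    absc = np.abs(mu @ ref.T)
    _, best_score = brute_force_labeling(absc)
    # score of the returned assignment equals the exhaustive optimum
    score = 0.0
    for row, name in zip(labelled.maps, labelled.labels):
        r = row - row.mean()
        r /= np.linalg.norm(r)
        score += abs(r @ ref[names.index(name)])
    assert score == pytest.approx(best_score, abs=1e-9)


def test_label_maps_requires_enough_references(templates6):
    ref, names = canonical_templates(templates6.channel_positions)
    model = MicrostateModel(maps=np.vstack([templates6.maps, ref[:2]]), gev=0.5)
    with pytest.raises(ValueError):
        label_maps(model, ref[:4], names[:4])


def test_polarity_invariant_individual_maps(planted_recording):
    rec, _ = planted_recording
    flipped = rec.copy_with(data=-rec.data)
    a = individual_topographies(rec, n_maps=7, n_init=5, seed=1)
    b = individual_topographies(flipped, n_maps=7, n_init=5, seed=1)
    assert np.array_equal(a, b)
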