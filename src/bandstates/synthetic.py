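"""Synthetic EEG with planted microstate dynamics.

The generator emulates the structure microstate analysis assumes: a hidden
sequence of quasi-stable scalp topographies (mean segment durations in the
60-120 ms range), each expressed through a band-limited oscillatory carrier
and embedded in spatially correlated noise, for a multi-subject crossover
study (24 subjects x 3 conditions x 4 sessions: pre, post1-post3).  Every
quantity the analysis estimates — per-state mean duration, occurrence and
coverage — is therefore known exactly, including planted condition x
session effects and a tunable pre/post correlation used to exercise the
coupling-corrected baseline-vs-change test.

The segment-length law is geometric (memoryless) with mean matched to the
target duration; successive segments never repeat a label, and the next
label is drawn proportionally to per-state occurrence weights.  These are
modelling stand-ins chosen for analytic tractability, not claims about real
EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .bands import CANONICAL_BANDS, BandDefinition
from .recording import Recording, load_standard_montage

__all__ = [
    "TemplateMaps",
    "StateSequenceParams",
    "PlantedEffect",
    "StudyDesign",
    "make_template_maps",
    "simulate_state_sequence",
    "sequence_expectations",
    "synthesize_eeg",
    "make_study",
    "simulate_metrics_table",
]


@dataclass
class TemplateMaps:
    """Planted microstate topographies.

    ``maps`` is ``(K, n_channels)``: each row is average-referenced (sums
    to zero) with unit Euclidean norm, and distinct rows have pairwise
    absolute spatial correlation at most ``max_corr`` by construction.
    """

    maps: np.ndarray
    channel_positions: np.ndarray
    ch_names: list[str] = field(default_factory=list)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def _dipole_field(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scalp potential of a random interior dipole — smooth by construction."""
    # dipole location strictly inside the unit sphere
    loc = rng.normal(size=3)
    loc *= rng.uniform(0.2, 0.7) / np.linalg.norm(loc)
    ori = rng.normal(size=3)
    ori /= np.linalg.norm(ori)
    diff = pos - loc[None, :]
    dist = np.linalg.norm(diff, axis=1)
    return (diff @ ori) / dist**3


def make_template_maps(
    n_maps: int,
    n_channels: int,
    seed: int,
    max_corr: float = 0.7,
    max_tries: int = 500,
) -> TemplateMaps:
    """Draw ``n_maps`` smooth dipolar template topographies.

    Each candidate map is the scalp field of one or two random interior
    dipoles, average-referenced and normalised; candidates are rejected
    until all pairwise absolute correlations are at most ``max_corr``.
    Deterministic given ``seed``.
    """
    if not 2 <= n_maps <= n_channels:
        raise ValueError("need 2 <= n_maps <= n_channels")
    names, pos = load_standard_montage(n_channels)
    rng = np.random.default_rng(seed)

    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < n_maps:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not satisfy pairwise |corr| <= {max_corr} after "
                f"{max_tries} candidate maps"
            )
        tries += 1
        field_ = _dipole_field(pos, rng)
        if rng.uniform() < 0.5:
            field_ = field_ + _dipole_field(pos, rng)
        field_ = field_ - field_.mean()
        norm = np.linalg.norm(field_)
        if norm < 1e-12:
            continue
        field_ = field_ / norm
        if all(abs(float(field_ @ m)) <= max_corr for m in maps):
            maps.append(field_)
    return TemplateMaps(maps=np.array(maps), channel_positions=pos, ch_names=names)


@dataclass
class StateSequenceParams:
    """Parameters of the hidden semi-Markov label sequence."""

    mean_duration_ms: np.ndarray  # per state, > 0
    weights: np.ndarray  # occurrence weights, >= 0, not all zero
    fs: float = 128.0
    total_duration_s: float = 240.0
    seed: int = 0
    min_frames: int = 2  # refractory floor added to the geometric tail

    def __post_init__(self) -> None:
        self.mean_duration_ms = np.asarray(self.mean_duration_ms, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mean_duration_ms.shape != self.weights.shape:
            raise ValueError("mean_duration_ms and weights must align")
        if np.any(self.mean_duration_ms <= 0):
            raise ValueError("mean durations must be positive")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 and not all zero")

    @property
    def n_states(self) -> int:
        return len(self.weights)


def simulate_state_sequence(params: StateSequenceParams) -> np.ndarray:
    """Generate the hidden per-sample state labels.

    Segment lengths are ``min_frames`` plus a geometric draw, with the
    total mean matched to ``mean_duration_ms * fs / 1000``: microstates
    are quasi-stable, so segments have a short refractory floor and a
    memoryless tail.  The next state is drawn proportionally to the
    occurrence weights with the current state excluded, so successive
    segments never share a label.
    """
    n_samples = int(round(params.total_duration_s * params.fs))
    if n_samples < 1:
        raise ValueError("total duration is shorter than one sample")
    if np.count_nonzero(params.weights > 0) < 2:
        raise ValueError(
            "at least two states need positive occurrence weight: no distinct "
            "successor exists otherwise"
        )
    rng = np.random.default_rng(params.seed)
    mean_samp = params.mean_duration_ms * params.fs / 1000.0
    tail_mean = np.maximum(mean_samp - params.min_frames, 1.0)
    p = np.minimum(1.0, 1.0 / tail_mean)

    labels = np.empty(n_samples, dtype=np.int64)
    w = params.weights / params.weights.sum()
    state = int(rng.choice(params.n_states, p=w))
    t = 0
    while t < n_samples:
        seg = params.min_frames + int(rng.geometric(p[state]))
        labels[t : t + seg] = state
        t += seg
        w_next = params.weights.copy()
        w_next[state] = 0.0
        state = int(rng.choice(params.n_states, p=w_next / w_next.sum()))
    return labels


def sequence_expectations(params: StateSequenceParams) -> pd.DataFrame:
    """Exact long-run duration/occurrence/coverage implied by the generator.

    The label chain has transition probabilities proportional to the
    occurrence weights with the current state excluded; its stationary
    distribution ``pi`` gives, per state ``k`` with mean segment length
    ``d_k`` (s): occurrence_k = pi_k / sum_j pi_j d_j and coverage_k =
    pi_k d_k / sum_j pi_j d_j.
    """
    k = params.n_states
    w = params.weights
    trans = np.zeros((k, k))
    for i in range(k):
        w_next = w.copy()
        w_next[i] = 0.0
        tot = w_next.sum()
        if tot > 0:
            trans[i] = w_next / tot
    # stationary distribution restricted to reachable states
    active = w > 0
    sub = trans[np.ix_(active, active)]
    vals, vecs = np.linalg.eig(sub.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi_sub = np.real(vecs[:, idx])
    pi_sub = np.abs(pi_sub) / np.abs(pi_sub).sum()
    pi = np.zeros(k)
    pi[active] = pi_sub

    mean_samp = params.mean_duration_ms * params.fs / 1000.0
    mean_len_samples = params.min_frames + np.maximum(mean_samp - params.min_frames, 1.0)
    d_s = mean_len_samples / params.fs
    cycle = float(pi @ d_s)
    occurrence = pi / cycle
    coverage = pi * d_s / cycle
    return pd.DataFrame(
        {
            "state": np.arange(k),
            "mean_duration": mean_len_samples * 1000.0 / params.fs,
            "occurrence": occurrence,
            "coverage": coverage,
        }
    )


def _spatial_noise_chol(pos: np.ndarray, length_scale: float = 0.5) -> np.ndarray:
    """Cholesky factor of a squared-exponential covariance on the sphere.

    ``length_scale`` is in radians of great-circle angle; this mimics the
    spatial blurring of volume conduction without a head model.
    """
    ang = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    cov = np.exp(-(ang**2) / (2.0 * length_scale**2))
    cov += 1e-8 * np.eye(len(pos))
    return np.linalg.cholesky(cov)


def _carrier(band: BandDefinition, n_samples: int, fs: float,
             rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid centred in ``band``, unit RMS."""
    t = np.arange(n_samples) / fs
    f_c = 0.5 * (band.low + band.high)
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    x = env * np.sin(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi))
    return x / np.sqrt(np.mean(x**2))


def _correlated_noise(n_channels: int, n_samples: int, fs: float,
                      chol: np.ndarray, rng: np.random.Generator,
                      band: BandDefinition | None = None) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    noise = chol @ white
    if band is not None and band.high < fs / 2:
        sos = _signal.butter(4, [band.low, band.high], btype="bandpass",
                             fs=fs, output="sos")
        noise = _signal.sosfiltfilt(sos, noise, axis=1)
    return noise


def _compose(maps: TemplateMaps, band_labels: dict[BandDefinition, np.ndarray],
             snr: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Sum per-band microstate signals and add spatially correlated noise."""
    n_samples = len(next(iter(band_labels.values())))
    sig = np.zeros((maps.n_channels, n_samples))
    for band, labels in band_labels.items():
        carrier = _carrier(band, n_samples, fs, rng)
        sig += maps.maps[labels].T * carrier[None, :]
    chol = _spatial_noise_chol(maps.channel_positions)
    noise_band = BandDefinition("noise", 1.0, min(40.0, 0.45 * fs))
    noise = _correlated_noise(maps.n_channels, n_samples, fs, chol, rng, noise_band)
    p_sig = float(np.mean(sig**2))
    p_noise = float(np.mean(noise**2))
    noise *= np.sqrt(p_sig / (snr * p_noise))
    out = sig + noise
    return out - out.mean(axis=0, keepdims=True)


def synthesize_eeg(
    maps: TemplateMaps,
    labels: np.ndarray,
    band: str | BandDefinition = "broadband",
    snr: float = 5.0,
    fs: float = 128.0,
    seed: int = 0,
    **meta,
) -> Recording:
    """Render a label sequence as an EEG recording.

    ``signal(t) = maps[label(t)] * carrier(t) + noise(t)`` with the carrier
    an amplitude-modulated sinusoid centred in ``band`` and the noise
    spatially correlated Gaussian scaled so signal power / noise power =
    ``snr``.  The output is average-referenced.  Deterministic given
    ``seed``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    band_def = CANONICAL_BANDS[band] if isinstance(band, str) else band
    if not 0 < band_def.low < band_def.high < fs / 2:
        raise ValueError(f"band ({band_def.low}, {band_def.high}) Hz invalid at fs={fs}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    data = _compose(maps, {band_def: labels}, snr, fs, rng)
    return Recording(
        data=data,
        fs=fs,
        ch_names=list(maps.ch_names),
        positions=maps.channel_positions,
        band=band_def.name,
        **meta,
    )


@dataclass
class PlantedEffect:
    """Additive shift on one generator parameter in specific cells.

    ``parameter`` is ``"mean_duration_ms"`` (shift in ms) or
    ``"occurrence_weight"`` (shift on the state's occurrence weight).
    """

    condition: str
    sessions: tuple[str, ...]
    band: str
    state: int
    parameter: str
    shift: float


@dataclass
class StudyDesign:
    """A pre/post crossover study with planted effects.

    Defaults mirror the emulated experiment: 24 subjects, three stimulation
    conditions, one pre and three post sessions of 4-minute 64-channel
    recordings at 128 Hz, six hidden states with 80 ms mean segment
    duration, SNR 5, and a 0.5 pre/post correlation of the subject-level
    parameters.
    """

    n_subjects: int = 24
    conditions: tuple[str, ...] = ("iTBS", "cTBS", "sham")
    sessions: tuple[str, ...] = ("pre", "post1", "post2", "post3")
    bands: tuple[str, ...] = ("broadband",)
    n_states: int = 6
    mean_duration_ms: float = 80.0
    duration_between_sd_ms: float = 8.0
    weight_between_sd_log: float = 0.2
    duration_noise_sd_ms: float = 3.0
    occurrence_noise_sd_hz: float = 0.1
    pre_post_correlation: float = 0.5
    snr: float = 5.0
    fs: float = 128.0
    total_duration_s: float = 240.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pre_post_correlation <= 1.0:
            raise ValueError("pre_post_correlation must be in [0, 1]")
        for eff in self.planted_effects:
            if eff.condition not in self.conditions:
                raise ValueError(f"planted effect references unknown condition {eff.condition!r}")
            if eff.band not in self.bands:
                raise ValueError(f"planted effect references unknown band {eff.band!r}")
            if not 0 <= eff.state < self.n_states:
                raise ValueError(f"planted effect references unknown state {eff.state}")
            for s in eff.sessions:
                if s not in self.sessions:
                    raise ValueError(f"planted effect references unknown session {s!r}")
            if eff.parameter not in ("mean_duration_ms", "occurrence_weight"):
                raise ValueError(f"unknown planted parameter {eff.parameter!r}")


def _draw_subject_params(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level generator parameters for every study cell.

    Per (subject, condition, band, state), pre and post values of the
    duration (ms) and latent log-weight are drawn jointly Gaussian with
    correlation ``pre_post_correlation``; planted shifts are then added in
    their target cells.  Returns one row per (subject, condition, session,
    band, state) with columns ``mean_duration_ms`` and ``weight``.
    """
    rho = design.pre_post_correlation
    rows = []
    for subj in range(design.n_subjects):
        sid = f"S{subj + 1:02d}"
        for cond in design.conditions:
            for band in design.bands:
                b_dur = rng.normal(0.0, design.duration_between_sd_ms, design.n_states)
                b_w = rng.normal(0.0, design.weight_between_sd_log, design.n_states)
                for sess in design.sessions:
                    if sess == "pre":
                        dur_dev, w_dev = b_dur, b_w
                    else:
                        e_dur = rng.normal(0.0, design.duration_between_sd_ms,
                                           design.n_states)
                        e_w = rng.normal(0.0, design.weight_between_sd_log,
                                         design.n_states)
                        dur_dev = rho * b_dur + np.sqrt(1 - rho**2) * e_dur
                        w_dev = rho * b_w + np.sqrt(1 - rho**2) * e_w
                    dur = design.mean_duration_ms + dur_dev
                    weight = np.exp(w_dev)
                    for eff in design.planted_effects:
                        if (eff.condition == cond and sess in eff.sessions
                                and eff.band == band):
                            if eff.parameter == "mean_duration_ms":
                                dur = dur.copy()
                                dur[eff.state] += eff.shift
                            else:
                                weight = weight.copy()
                                weight[eff.state] = max(
                                    weight[eff.state] + eff.shift, 1e-6)
                    dur = np.maximum(dur, 20.0)  # keep segments physical
                    for k in range(design.n_states):
                        rows.append((sid, cond, sess, band, k,
                                     float(dur[k]), float(weight[k])))
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "session", "band", "state",
                 "mean_duration_ms", "weight"],
    )


def _params_to_truth(params: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Exact per-cell duration/occurrence/coverage implied by the parameters."""
    out = []
    group_cols = ["subject", "condition", "session", "band"]
    for keys, grp in params.groupby(group_cols, sort=False):
        grp = grp.sort_values("state")
        seq_params = StateSequenceParams(
            mean_duration_ms=grp["mean_duration_ms"].to_numpy(),
            weights=grp["weight"].to_numpy(),
            fs=design.fs,
            total_duration_s=design.total_duration_s,
        )
        exp = sequence_expectations(seq_params)
        for col, val in zip(group_cols, keys):
            exp[col] = val
        out.append(exp)
    truth = pd.concat(out, ignore_index=True)
    return truth[["subject", "condition", "session", "band", "state",
                  "mean_duration", "occurrence", "coverage"]]


def make_study(
    design: StudyDesign,
    maps: TemplateMaps | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate every recording of a study plus its ground-truth metrics.

    Each (subject, condition, session) yields one recording whose signal is
    the sum over the design's bands of a hidden label sequence rendered
    through that band's carrier; band-specific dynamics are therefore
    recoverable by band-pass filtering.  The ground-truth table holds the
    exact expected mean duration (ms), occurrence (Hz) and coverage for
    every (subject, condition, session, band, state).
    """
    if maps is None:
        maps = make_template_maps(design.n_states, 64, seed=design.seed)
    if maps.n_maps != design.n_states:
        raise ValueError("template map count must equal design.n_states")
    master = np.random.default_rng(design.seed)
    params = _draw_subject_params(design, master)
    truth = _params_to_truth(params, design)

    recordings = []
    for (subj, cond, sess), grp in params.groupby(
            ["subject", "condition", "session"], sort=False):
        band_labels = {}
        for band in design.bands:
            band_def = CANONICAL_BANDS[band]
            sub = grp[grp["band"] == band].sort_values("state")
            seq_params = StateSequenceParams(
                mean_duration_ms=sub["mean_duration_ms"].to_numpy(),
                weights=sub["weight"].to_numpy(),
                fs=design.fs,
                total_duration_s=design.total_duration_s,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            band_labels[band_def] = simulate_state_sequence(seq_params)
        rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        data = _compose(maps, band_labels, design.snr, design.fs, rng)
        recordings.append(Recording(
            data=data,
            fs=design.fs,
            ch_names=list(maps.ch_names),
            positions=maps.channel_positions,
            band="broadband",
            subject=subj,
            condition=cond,
            session=sess,
        ))
    return recordings, truth


def simulate_metrics_table(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Draw an observed metrics table directly from the parameter model.

    Skips EEG synthesis and segmentation: observed mean duration and
    occurrence are the exact cell expectations plus Gaussian measurement
    noise (``duration_noise_sd_ms``, ``occurrence_noise_sd_hz``).  Useful
    for statistical power and type-I-error simulations at scale.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = _draw_subject_params(design, rng)
    truth = _params_to_truth(params, design)
    obs = truth.copy()
    obs["mean_duration"] = truth["mean_duration"] + rng.normal(
        0.0, design.duration_noise_sd_ms, len(truth))
    obs["occurrence"] = np.maximum(
        truth["occurrence"] + rng.normal(0.0, design.occurrence_noise_sd_hz,
                                         len(truth)), 0.0)
    obs["coverage"] = np.clip(
        obs["occurrence"] * obs["mean_duration"] / 1000.0, 0.0, 1.0)
    return obs
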