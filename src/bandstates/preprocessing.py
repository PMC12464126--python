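"""Filtering, referencing, resampling and channel repair.

All filters are zero-phase (forward-backward second-order sections) so the
timing of scalp topographies — the quantity microstate analysis segments —
is not shifted by the filtering stage.  Channel repair uses the Perrin
spherical-spline interpolation standard in EEG work.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .bands import BandDefinition
from .recording import Recording

__all__ = [
    "notch_filter",
    "bandpass",
    "average_reference",
    "downsample",
    "interpolate_channels",
    "band_split",
]

#: default Butterworth order for band-pass designs
DEFAULT_ORDER = 4


def notch_filter(rec: Recording, freq: float = 50.0, width: float = 4.0,
                 order: int = 4) -> Recording:
    """Remove power-line interference with a zero-phase band-stop filter.

    The stop band is ``freq +/- width/2`` (default 48-52 Hz), applied
    forward-backward so the net phase response is zero.
    """
    nyq = rec.fs / 2
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz is not below Nyquist {nyq} Hz")
    lo, hi = freq - width / 2, freq + width / 2
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def bandpass(rec: Recording, band: BandDefinition, order: int = DEFAULT_ORDER) -> Recording:
    """Zero-phase Butterworth band-pass to ``band`` and tag the result."""
    if order < 1:
        raise ValueError("filter order must be >= 1")
    band.validate_for(rec.fs)
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out, band=band.name)


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: each sample's channel mean -> 0."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=out)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Resample to ``target_fs`` with anti-alias filtering.

    Integer decimation factors use polyphase resampling with the default
    anti-aliasing low-pass; ``target_fs == fs`` is the identity.
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if target_fs > rec.fs:
        raise ValueError("downsample cannot increase the sampling rate")
    if target_fs == rec.fs:
        return rec.copy_with()
    # rational resampling: fs * up / down == target_fs
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1)
    n_out = out.shape[1]
    # carry the artifact mask to the new grid by nearest-sample lookup
    idx = np.minimum((np.arange(n_out) * down) // up, rec.n_samples - 1)
    mask = rec.artifact_mask[idx]
    return rec.copy_with(data=out, fs=float(target_fs), artifact_mask=mask)


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos angle)."""
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.zeros_like(cosang, dtype=np.float64)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return out / (4 * np.pi)


def interpolate_channels(rec: Recording, bad: list[str], m: int = 4,
                         n_terms: int = 50, reg: float = 1e-5) -> Recording:
    """Replace ``bad`` channels by spherical-spline estimates.

    Uses the Perrin interpolation (order ``m`` = 4, 50 Legendre terms,
    ridge regularisation ``reg`` on the kernel matrix).  Good channels are
    returned unchanged.
    """
    if not bad:
        return rec.copy_with()
    if rec.positions is None:
        raise ValueError("channel positions are required for interpolation")
    unknown = set(bad) - set(rec.ch_names)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    bad_idx = np.array([rec.ch_names.index(ch) for ch in bad])
    good_idx = np.array([i for i in range(rec.n_channels) if i not in set(bad_idx)])
    if len(good_idx) < 4:
        raise ValueError("at least 4 good channels are required")

    pos = rec.positions / np.linalg.norm(rec.positions, axis=1, keepdims=True)
    g_gg = _spline_g(pos[good_idx] @ pos[good_idx].T, m, n_terms)
    g_bg = _spline_g(pos[bad_idx] @ pos[good_idx].T, m, n_terms)

    n_good = len(good_idx)
    # spline system with the zero-sum constraint on the weights
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + reg * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, rec.n_samples))
    rhs[:n_good] = rec.data[good_idx]
    sol = np.linalg.solve(a, rhs)
    weights, const = sol[:n_good], sol[n_good]

    out = rec.data.copy()
    out[bad_idx] = g_bg @ weights + const
    return rec.copy_with(data=out)


def band_split(rec: Recording, bands: dict[str, BandDefinition],
               order: int = DEFAULT_ORDER) -> dict[str, Recording]:
    """Band-pass a recording into each requested band; returns name -> Recording."""
    return {name: bandpass(rec, band, order=order) for name, band in bands.items()}
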