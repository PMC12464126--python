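"""Core data containers and I/O for multichannel EEG recordings.

A :class:`Recording` is the unit every pipeline stage consumes and returns:
a channels x samples matrix in microvolts plus the metadata (sampling rate,
channel names/positions, band tag, subject/condition/session) needed to keep
a multi-subject, multi-band study organised.  Readers for EDF and
BrainVision go through MNE; a minimal EDF writer is provided so synthetic
studies can be exported in the field's exchange format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "load_standard_montage",
    "write_edf",
    "read_edf",
    "read_brainvision",
]


@dataclass
class Recording:
    """Multichannel EEG block with study metadata.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    ch_names
        One name per channel row.
    positions
        ``(n_channels, 3)`` unit-sphere electrode coordinates, or ``None``
        when unknown (required only for spherical-spline interpolation).
    band
        Frequency-band tag (``"broadband"``, ``"alpha"``, ...).
    subject, condition, session
        Study coordinates; free-form strings.
    artifact_mask
        Boolean per sample, ``True`` marking samples to exclude from
        analysis (artifact epochs).  Defaults to all-clean.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None
    band: str = "broadband"
    subject: str = ""
    condition: str = ""
    session: str = ""
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"CH{i:02d}" for i in range(self.n_channels)]
        if len(self.ch_names) != self.n_channels:
            raise ValueError("ch_names length does not match channel count")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.float64)
            if self.positions.shape != (self.n_channels, 3):
                raise ValueError("positions must be (n_channels, 3)")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.n_samples, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.n_samples,):
                raise ValueError("artifact_mask length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with ``changes`` applied (data is copied)."""
        kwargs = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        kwargs["data"] = self.data.copy()
        kwargs["artifact_mask"] = self.artifact_mask.copy()
        kwargs.update(changes)
        return Recording(**kwargs)


def load_standard_montage(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Return channel names and unit-sphere positions of the bundled layout.

    The layout is a 64-electrode extension of the international 10-20
    system; for ``n_channels < 64`` the first ``n_channels`` entries are
    returned (sufficient for toy examples).
    """
    with resources.files("bandstates.data").joinpath("montage64.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    if n_channels > len(table):
        raise ValueError(f"bundled montage has only {len(table)} channels")
    table = table.iloc[:n_channels]
    names = table["channel"].tolist()
    pos = table[["x", "y", "z"]].to_numpy(dtype=np.float64)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return names, pos


# ---------------------------------------------------------------------------
# EDF I/O.  Reading is delegated to MNE; writing uses a minimal EDF encoder
# (16-bit integers, one data record per second) because no EDF-writing
# library is part of the runtime environment.

def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a plain EDF file (16-bit, 1-s data records)."""
    path = Path(path)
    data = np.asarray(rec.data, dtype=np.float64)
    n_ch = rec.n_channels
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    spr = fs  # samples per record (1-s records)
    n_rec = int(np.ceil(data.shape[1] / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : data.shape[1]] = data

    phys_min = np.floor(padded.min(axis=1) - 1.0)
    phys_max = np.ceil(padded.max(axis=1) + 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def fix(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            fix("0", 8),
            fix(f"sub {rec.subject}" if rec.subject else "X", 80),
            fix(f"bandstates {rec.condition} {rec.session}".strip(), 80),
            fix("01.01.00", 8),
            fix("00.00.00", 8),
            fix(str(256 * (1 + n_ch)), 8),
            fix("", 44),
            fix(str(n_rec), 8),
            fix("1", 8),
            fix(str(n_ch), 4),
        ]
    )
    header += b"".join(fix(n, 16) for n in rec.ch_names)
    header += b"".join(fix("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(fix("uV", 8) for _ in range(n_ch))
    header += b"".join(fix(f"{phys_min[i]:g}", 8) for i in range(n_ch))
    header += b"".join(fix(f"{phys_max[i]:g}", 8) for i in range(n_ch))
    header += b"".join(fix(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(fix(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(fix("", 80) for _ in range(n_ch))
    header += b"".join(fix(str(spr), 8) for _ in range(n_ch))
    header += b"".join(fix("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def _from_mne_raw(raw, **meta) -> Recording:
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        **meta,
    )


def read_edf(path: str | Path, **meta) -> Recording:
    """Read an EDF file into a :class:`Recording` (channels in file order)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw, **meta)


def read_brainvision(path: str | Path, **meta) -> Recording:
    """Read a BrainVision ``.vhdr`` file into a :class:`Recording`."""
    import mne

    raw = mne.io.read_raw_brainvision(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw, **meta)
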