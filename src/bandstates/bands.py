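"""Canonical frequency-band definitions for band-specific microstate analysis.

The five named narrow bands follow the conventional resting-state split
(delta 1-4, theta 4-8, alpha 8-12, beta 15-30, gamma 30-40 Hz) with a
deliberate 12-15 Hz gap between alpha and beta; ``broadband`` spans 1-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDefinition", "CANONICAL_BANDS", "get_band"]


@dataclass(frozen=True)
class BandDefinition:
    """A named pass-band ``[low, high]`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz not below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


CANONICAL_BANDS: dict[str, BandDefinition] = {
    "broadband": BandDefinition("broadband", 1.0, 40.0),
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 40.0),
}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name."""
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {sorted(CANONICAL_BANDS)}"
        ) from None
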