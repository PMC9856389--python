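"""Frequency-band definitions for the band-wise decomposition.

The six canonical resting-state EEG bands used throughout the package:
delta (0.5-4), theta (4-8), low alpha (8-10), high alpha (10-12),
beta (13-30) and gamma (30-45 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval in Hz, 0 < low < high."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidParameterError(
                f"band {self.name!r}: need 0 < low < high, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Raise if the band is not representable at sampling rate ``fs``."""
        if self.high_hz >= fs / 2:
            raise InvalidParameterError(
                f"band {self.name!r} upper edge {self.high_hz} Hz >= Nyquist "
                f"({fs / 2} Hz at fs={fs})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 10.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


def bands_by_name(names=None) -> tuple[BandDefinition, ...]:
    """Return the default bands, optionally restricted to ``names`` (ordered)."""
    if names is None:
        return DEFAULT_BANDS
    table = {b.name: b for b in DEFAULT_BANDS}
    missing = [n for n in names if n not in table]
    if missing:
        raise InvalidParameterError(f"unknown band names: {missing}")
    return tuple(table[n] for n in names)
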