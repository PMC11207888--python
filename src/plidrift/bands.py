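"""Canonical EEG frequency bands.

The delta band is nominally 0.5-4 Hz, but the preprocessing chain
high-passes the data at 1 Hz, so the effective delta edge implemented
here is 1 Hz; the nominal edge is kept as metadata (``nominal_low``).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float
    nominal_low: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def check_nyquist(self, sampling_rate: float) -> None:
        if self.high > sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds the "
                f"Nyquist frequency {sampling_rate / 2} Hz"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0, nominal_low=0.5),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 31.0, 45.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known bands: {BAND_ORDER}")
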