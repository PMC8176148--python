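"""Canonical frequency bands used throughout the pipeline.

The seven bands cover 1-150 Hz and are non-overlapping and ordered.  A
band's power statistic is always the *mean* spectral density over the
bins whose centre falls inside [f_lo, f_hi], which keeps values
comparable across bands of unequal width.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named frequency interval [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band limits ({self.f_lo}, {self.f_hi})")

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


CANONICAL_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 3.0),
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 14.0),
    Band("beta", 15.0, 30.0),
    Band("lowgamma1", 30.0, 55.0),
    Band("lowgamma2", 65.0, 80.0),
    Band("highgamma", 80.0, 150.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> Band:
    """Look up a canonical band by name.

    Raises ``KeyError`` with the list of valid names for anything else,
    so configuration typos fail early.
    """
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; canonical bands are {list(BAND_NAMES)}"
        ) from None
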