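"""Four-region reflectance coding and the orange/red dichotomy.

The 300-700 nm spectrum is divided into four 100-nm regions (UV, blue,
green, red). Each region is coded ``+`` when reflectance exceeds a
threshold (default 10%) somewhere in its interior, ``-`` when it never
does, and ``/`` when the threshold is exceeded only in a trailing window
at the region's upper boundary while reflectance stays high into the next
region — i.e. ``/`` marks a rising edge sitting on a region boundary.
Flowers coded ``UV-b-g-r+`` or ``UV-b-g/r+`` form the orange/red group;
everything else is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ReflectanceSpectrum

#: (name, lower_nm, upper_nm); upper bound exclusive except for the red region
REGIONS = (
    ("uv", 300.0, 400.0),
    ("b", 400.0, 500.0),
    ("g", 500.0, 600.0),
    ("r", 600.0, 700.0),
)

DEFAULT_THRESHOLD_PCT = 10.0
DEFAULT_BOUNDARY_WINDOW_NM = 25.0


@dataclass(frozen=True)
class RegionCode:
    """Per-region reflectance symbols, each one of '+', '-', '/'."""

    uv: str
    b: str
    g: str
    r: str

    def __post_init__(self) -> None:
        for sym in (self.uv, self.b, self.g, self.r):
            if sym not in "+-/":
                raise ValueError(f"invalid region symbol {sym!r}")
        if self.r == "/":
            # no successor region exists for a red-edge code
            raise ValueError("'/' is not a valid code for the red region")

    def as_string(self) -> str:
        return f"UV{self.uv}b{self.b}g{self.g}r{self.r}"


ORANGE_RED = "orange_red"
OTHER = "other"


def code_regions(
    s: ReflectanceSpectrum,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    boundary_window_nm: float = DEFAULT_BOUNDARY_WINDOW_NM,
) -> RegionCode:
    """Code each of the four spectral regions as '+', '-' or '/'.

    '+'  reflectance strictly above `threshold_pct` at some wavelength in
         the region outside its trailing `boundary_window_nm`;
    '/'  above threshold only within the trailing window, and still above
         threshold at the start of the next region (rising boundary edge);
    '-'  otherwise.  The red region has no successor, so any
         super-threshold red reflectance codes '+'.
    """
    wl = s.wavelengths_nm
    refl = s.reflectance_pct
    symbols: list[str] = []
    for i, (name, lo, hi) in enumerate(REGIONS):
        last = i == len(REGIONS) - 1
        in_region = (wl >= lo) & (wl < hi) if not last else (wl >= lo) & (wl <= hi)
        above = in_region & (refl > threshold_pct)
        if not above.any():
            symbols.append("-")
            continue
        if last:
            symbols.append("+")
            continue
        outside_window = above & (wl < hi - boundary_window_nm)
        if outside_window.any():
            symbols.append("+")
        elif s.value_at(hi) > threshold_pct:
            symbols.append("/")
        else:
            # an isolated bump confined to the trailing window that dies
            # before the next region is not a boundary edge
            symbols.append("-")
    return RegionCode(*symbols)


def classify_orange_red(code: RegionCode) -> str:
    """Orange/red iff the code is exactly UV-b-g-r+ or UV-b-g/r+."""
    if (code.uv, code.b, code.r) == ("-", "-", "+") and code.g in "-/":
        return ORANGE_RED
    return OTHER
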