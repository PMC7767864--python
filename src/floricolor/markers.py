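"""Marker points and their fit to pollinator hue-discrimination optima.

A marker point is the wavelength at the midpoint of a steep reflectance
transition — the spectral feature color-vision systems discriminate best.
The spectrum is split into maximal monotone segments between local
extrema of the smoothed curve; segments whose amplitude exceeds a change
threshold (default 20 percentage points of reflectance) each contribute
one marker at the half-amplitude crossing.

Fit to a visual system is summarized by two distances to that system's
discrimination optima (bee: 400, 500 nm; hummingbird: 460, 540, 600 nm):
MAD, the mean over marker points of the distance to the nearest optimum,
and minAD, the per-optimum distance to the nearest marker point. Small
values mean the flower's spectral edges sit where the pollinator
discriminates hue best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import ReflectanceSpectrum

DEFAULT_CHANGE_THRESHOLD_PP = 20.0

#: adjacent extrema closer than this in reflectance over this span are a plateau
PLATEAU_DELTA_PP = 0.5
PLATEAU_SPAN_NM = 10.0

BEE_OPTIMA_NM = (400.0, 500.0)
HUMMINGBIRD_OPTIMA_NM = (460.0, 540.0, 600.0)


@dataclass(frozen=True)
class MarkerPoint:
    wavelength_nm: float
    segment_lo_nm: float
    segment_hi_nm: float
    amplitude_pp: float


@dataclass
class MarkerPointSet:
    """The steep-transition wavelengths of one spectrum (typically 1-3)."""

    sample_id: str
    part: str
    points: list[MarkerPoint] = field(default_factory=list)

    @property
    def points_nm(self) -> list[float]:
        return [p.wavelength_nm for p in self.points]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DiscriminationOptima:
    system: str
    optima_nm: tuple[float, ...]


BEE_OPTIMA = DiscriminationOptima("bee", BEE_OPTIMA_NM)
HUMMINGBIRD_OPTIMA = DiscriminationOptima("hummingbird", HUMMINGBIRD_OPTIMA_NM)


class UndefinedStatistic(ValueError):
    """No marker points: MAD/minAD undefined; sample excluded from group means."""


def _segment_breakpoints(values: np.ndarray, wavelengths: np.ndarray) -> list[int]:
    """Indices of local extrema delimiting maximal monotone segments.

    Includes both endpoints. Plateau wobble (|dR| < 0.5 pp within 10 nm
    between consecutive candidate extrema) is merged away so smoothing
    artifacts do not split genuine transitions.
    """
    n = len(values)
    diffs = np.diff(values)
    sign = np.sign(diffs)
    # carry the previous non-zero slope through exact flats
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    breaks = [0]
    for i in range(1, len(sign)):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            breaks.append(i)
    breaks.append(n - 1)

    # merge plateau wobble: a segment bounded by two interior extrema whose
    # amplitude is < 0.5 pp over <= 10 nm is noise, not a transition. If the
    # flanking segments run the same way, drop both extrema (fusing one
    # monotone run); if they oppose, keep a single extremum at the wobble's
    # own extreme point (a noisy peak/trough plateau).
    changed = True
    while changed:
        changed = False
        for j in range(1, len(breaks) - 2):
            lo, hi = breaks[j], breaks[j + 1]
            if (
                abs(values[hi] - values[lo]) < PLATEAU_DELTA_PP
                and wavelengths[hi] - wavelengths[lo] <= PLATEAU_SPAN_NM
            ):
                rising_in = values[lo] >= values[breaks[j - 1]]
                rising_out = values[breaks[j + 2]] >= values[hi]
                if rising_in == rising_out:
                    del breaks[j : j + 2]
                else:
                    seg = values[lo : hi + 1]
                    apex = lo + int(np.argmax(seg) if rising_in else np.argmin(seg))
                    breaks[j : j + 2] = [apex]
                changed = True
                break
    return breaks


def find_marker_points(
    s: ReflectanceSpectrum,
    change_threshold_pp: float = DEFAULT_CHANGE_THRESHOLD_PP,
) -> MarkerPointSet:
    """Locate half-amplitude midpoints of steep monotone reflectance segments.

    The input should be a smoothed spectrum; monotone segments are taken
    between local extrema, segments with amplitude above
    `change_threshold_pp` are kept, and each marker is the linearly
    interpolated wavelength where reflectance crosses the segment's
    mid-value. Multiple crossings (noise) resolve to the one nearest the
    segment's wavelength midpoint. Slopes truncated at 300/700 nm count
    as segments if their in-range amplitude exceeds the threshold.
    """
    wl = s.wavelengths_nm
    refl = s.reflectance_pct
    breaks = _segment_breakpoints(refl, wl)
    if len(breaks) > 11:
        warnings.warn(
            f"{len(breaks) - 1} candidate segments in {s.sample_id!r}; "
            "input looks unsmoothed — consider smooth_spectrum() first",
            stacklevel=2,
        )
    points: list[MarkerPoint] = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        seg_wl = wl[lo : hi + 1]
        seg_r = refl[lo : hi + 1]
        amp = float(seg_r.max() - seg_r.min())
        if amp <= change_threshold_pp:
            continue
        mid = (seg_r.max() + seg_r.min()) / 2.0
        crossings = []
        for i in range(len(seg_r) - 1):
            a, b = seg_r[i], seg_r[i + 1]
            if (a - mid) * (b - mid) <= 0 and a != b:
                t = (mid - a) / (b - a)
                if 0.0 <= t <= 1.0:
                    crossings.append(seg_wl[i] + t * (seg_wl[i + 1] - seg_wl[i]))
        if not crossings:
            continue
        center = (seg_wl[0] + seg_wl[-1]) / 2.0
        marker = min(crossings, key=lambda c: abs(c - center))
        points.append(
            MarkerPoint(
                wavelength_nm=float(marker),
                segment_lo_nm=float(seg_wl[0]),
                segment_hi_nm=float(seg_wl[-1]),
                amplitude_pp=amp,
            )
        )
    points.sort(key=lambda p: p.wavelength_nm)
    return MarkerPointSet(sample_id=s.sample_id, part=s.part, points=points)


def mean_absolute_deviation(m: MarkerPointSet, o: DiscriminationOptima) -> float:
    """MAD: mean over marker points of |point - nearest optimum| (nm)."""
    if len(m) == 0:
        raise UndefinedStatistic(f"sample {m.sample_id!r} has no marker points")
    return float(
        np.mean([min(abs(p - v) for v in o.optima_nm) for p in m.points_nm])
    )


def minimum_absolute_deviation(m: MarkerPointSet, optimum_nm: float) -> float:
    """minAD: distance from one optimum to its nearest marker point (nm)."""
    if len(m) == 0:
        raise UndefinedStatistic(f"sample {m.sample_id!r} has no marker points")
    return float(min(abs(p - optimum_nm) for p in m.points_nm))
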