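"""Reflectance spectra: reading, resampling, smoothing, replicate averaging.

Spectra are % reflectance curves measured between 300 and 700 nm. All
downstream analyses (region coding, visual models, marker points) assume a
common wavelength grid, so every spectrum is linearly interpolated onto a
fixed 1-nm grid at load time. Smoothing is locally weighted linear
regression (LOWESS) with a tricube kernel, the standard treatment for
spectrophotometer output before feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

GRID_MIN_NM = 300.0
GRID_MAX_NM = 700.0
DEFAULT_GRID_STEP_NM = 1.0

#: fraction of [300, 700] a sample must cover to be usable
MIN_COVERAGE_FRACTION = 0.8


class SpectrumFormatError(ValueError):
    """Raised when an input table lacks required columns or has duplicate keys."""


class CoverageError(ValueError):
    """Raised when a sample's measured wavelengths cover too little of the range."""


def standard_grid(step_nm: float = DEFAULT_GRID_STEP_NM) -> np.ndarray:
    """The common wavelength grid, 300-700 nm inclusive (401 points at 1 nm)."""
    n = int(round((GRID_MAX_NM - GRID_MIN_NM) / step_nm))
    return GRID_MIN_NM + step_nm * np.arange(n + 1)


@dataclass
class ReflectanceSpectrum:
    """One sample/part reflectance curve on a wavelength grid.

    Parameters
    ----------
    sample_id : str
        Sample identifier (one flower accession).
    part : str
        Flower part measured: ``"whole"``, ``"lobe"`` or ``"tube"``.
    wavelengths_nm : ndarray
        Strictly increasing wavelength grid in nm.
    reflectance_pct : ndarray
        Percent reflectance (0-100 scale); small negative instrument noise
        is tolerated before smoothing and clipped afterwards.
    """

    sample_id: str
    part: str
    wavelengths_nm: np.ndarray
    reflectance_pct: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.reflectance_pct.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if len(self.wavelengths_nm) != len(self.reflectance_pct):
            raise ValueError("wavelengths and reflectance differ in length")
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.part)

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated reflectance at an arbitrary wavelength."""
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.reflectance_pct))


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one wavelength grid, keyed by (sample_id, part)."""

    spectra: dict[tuple[str, str], ReflectanceSpectrum] = field(default_factory=dict)

    def add(self, s: ReflectanceSpectrum) -> None:
        if s.key in self.spectra:
            raise SpectrumFormatError(f"duplicate spectrum key {s.key}")
        if self.spectra:
            grid = next(iter(self.spectra.values())).wavelengths_nm
            if not np.array_equal(grid, s.wavelengths_nm):
                raise ValueError("all members of a SpectrumSet must share one grid")
        self.spectra[s.key] = s

    def __iter__(self):
        return iter(self.spectra.values())

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, key: tuple[str, str]) -> ReflectanceSpectrum:
        return self.spectra[key]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample_id, part, wavelength_nm, reflectance_pct."""
        rows = []
        for s in self:
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "part": s.part,
                        "wavelength_nm": s.wavelengths_nm,
                        "reflectance_pct": s.reflectance_pct,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["sample_id", "part", "wavelength_nm", "reflectance_pct"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_wide(self) -> pd.DataFrame:
        """Wide matrix: rows = wavelengths, one column per (sample_id, part)."""
        frame = self.to_frame()
        return frame.pivot_table(
            index="wavelength_nm",
            columns=["sample_id", "part"],
            values="reflectance_pct",
        )


REQUIRED_COLUMNS = ("sample_id", "wavelength_nm", "reflectance_pct")


def load_spectra(
    path,
    grid_step_nm: float = DEFAULT_GRID_STEP_NM,
    sep: str | None = None,
) -> SpectrumSet:
    """Read a long-format delimited file of reflectance measurements.

    The file must carry columns ``sample_id``, ``wavelength_nm`` and
    ``reflectance_pct``; a ``part`` column is optional (defaults to
    ``"whole"``). Each (sample, part) series is linearly interpolated onto
    the common grid; input wavelengths outside [300, 700] nm are dropped
    first. A series covering less than 80% of the range raises
    :class:`CoverageError` naming the offending sample.
    """
    frame = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectrumFormatError(f"missing required column(s): {', '.join(missing)}")
    if "part" not in frame.columns:
        frame = frame.assign(part="whole")
    frame["part"] = frame["part"].fillna("whole")

    dup = frame.duplicated(subset=["sample_id", "part", "wavelength_nm"])
    if dup.any():
        bad = frame.loc[dup, ["sample_id", "part", "wavelength_nm"]].iloc[0]
        raise SpectrumFormatError(
            f"duplicate record for sample={bad['sample_id']!r} part={bad['part']!r} "
            f"wavelength={bad['wavelength_nm']}"
        )

    grid = standard_grid(grid_step_nm)
    out = SpectrumSet()
    for (sample_id, part), sub in frame.groupby(["sample_id", "part"], sort=True):
        sub = sub.sort_values("wavelength_nm")
        wl = sub["wavelength_nm"].to_numpy(dtype=float)
        refl = sub["reflectance_pct"].to_numpy(dtype=float)
        keep = (wl >= GRID_MIN_NM) & (wl <= GRID_MAX_NM)
        wl, refl = wl[keep], refl[keep]
        if len(wl) < 2:
            raise CoverageError(f"sample {sample_id!r} ({part}) has too few in-range points")
        coverage = (wl[-1] - wl[0]) / (GRID_MAX_NM - GRID_MIN_NM)
        if coverage < MIN_COVERAGE_FRACTION:
            raise CoverageError(
                f"sample {sample_id!r} ({part}) covers only {coverage:.0%} of "
                f"[{GRID_MIN_NM:.0f}, {GRID_MAX_NM:.0f}] nm"
            )
        out.add(
            ReflectanceSpectrum(
                sample_id=str(sample_id),
                part=str(part),
                wavelengths_nm=grid,
                reflectance_pct=np.interp(grid, wl, refl),
            )
        )
    return out


def write_spectra(spectra: SpectrumSet, path, sep: str = ",") -> None:
    """Write a SpectrumSet back to the long delimited format `load_spectra` reads."""
    spectra.to_frame().to_csv(path, sep=sep, index=False)


def smooth_spectrum(s: ReflectanceSpectrum, span: float = 0.25) -> ReflectanceSpectrum:
    """LOWESS-smooth a spectrum with window fraction `span` (default 0.25).

    Tricube-weighted local linear regression over the nearest
    ``ceil(span * n)`` grid points; constants and straight lines pass
    through unchanged. Negative fitted values (instrument noise) are
    clipped to zero after smoothing.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(s.wavelengths_nm) < 10:
        raise ValueError("need at least 10 grid points to smooth")
    frac = math.ceil(span * len(s.wavelengths_nm)) / len(s.wavelengths_nm)
    fitted = lowess(
        s.reflectance_pct,
        s.wavelengths_nm,
        frac=frac,
        it=0,
        return_sorted=False,
    )
    return replace(s, reflectance_pct=np.clip(fitted, 0.0, None))


def average_replicates(
    members: list[ReflectanceSpectrum], by_part: bool = False
) -> list[ReflectanceSpectrum]:
    """Pointwise mean of replicate measurements of one sample.

    With ``by_part`` set, lobe and tube measurements are averaged
    separately, giving one spectrum per part; otherwise everything is
    pooled into a single ``"whole"`` spectrum. All replicates carry equal
    weight.
    """
    if not members:
        raise ValueError("no spectra to average")
    ids = {m.sample_id for m in members}
    if len(ids) > 1:
        raise KeyError(f"mixed sample_ids in replicate set: {sorted(ids)}")
    grid = members[0].wavelengths_nm
    for m in members[1:]:
        if not np.array_equal(m.wavelengths_nm, grid):
            raise ValueError("replicates must share one wavelength grid")

    def _mean(group: list[ReflectanceSpectrum], part: str) -> ReflectanceSpectrum:
        stacked = np.vstack([g.reflectance_pct for g in group])
        return ReflectanceSpectrum(
            sample_id=group[0].sample_id,
            part=part,
            wavelengths_nm=grid,
            reflectance_pct=stacked.mean(axis=0),
        )

    if by_part:
        parts: dict[str, list[ReflectanceSpectrum]] = {}
        for m in members:
            parts.setdefault(m.part, []).append(m)
        return [_mean(group, part) for part, group in sorted(parts.items())]
    return [_mean(members, "whole")]
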