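"""Lamp emission spectra and the region over which a lamp emits light.

A street lamp's spectrum arrives as a two-column spectrometer export
(wavelength nm, relative irradiance).  The emission range is the set of
wavelengths where the baseline-corrected irradiance stays above a small
fraction of the corrected peak; nearby intervals are merged and the single
contiguous span between the outermost endpoints is the default region used
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, FormatError, ValidationError
from .pigments import default_grid

logger = logging.getLogger(__name__)

LAMP_TYPES = ("LPS", "HPS", "LED", "MH", "custom")

#: "Emits light" threshold: fraction of the baseline-corrected peak.
DEFAULT_REL_THRESHOLD = 0.01
#: Intervals separated by less than this many nm are merged.
DEFAULT_GAP_MERGE = 5.0


@dataclass(frozen=True)
class LampSpectrum:
    """Relative spectral irradiance of one lamp on a wavelength grid."""

    lamp_type: str
    grid: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self):
        if self.lamp_type not in LAMP_TYPES:
            raise ValidationError(f"unknown lamp type {self.lamp_type!r}")
        grid = np.asarray(self.grid, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if grid.shape != irr.shape or grid.ndim != 1:
            raise ValidationError("grid and irradiance must be 1-D and equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("lamp spectrum grid must be strictly increasing")
        if np.any(irr < 0):
            raise ValidationError("irradiance must be non-negative")
        if not np.any(irr > 0):
            raise ValidationError("spectrum must have at least one positive value")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "irradiance", irr)


@dataclass(frozen=True)
class EmissionRange:
    """Disjoint emission intervals and their contiguous span, in nm."""

    intervals: tuple[tuple[float, float], ...]
    threshold: float = DEFAULT_REL_THRESHOLD

    def __post_init__(self):
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        if not ivs:
            raise ValidationError("emission range needs >= 1 interval")
        for a, b in ivs:
            if not a < b:
                raise ValidationError(f"empty emission interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 <= b0:
                raise ValidationError("emission intervals must be sorted and disjoint")
        object.__setattr__(self, "intervals", ivs)

    @property
    def span(self) -> tuple[float, float]:
        return (self.intervals[0][0], self.intervals[-1][1])

    @property
    def span_width(self) -> float:
        lo, hi = self.span
        return hi - lo


def read_spectrum(path, lamp_type: str = "custom",
                  grid: np.ndarray | None = None) -> LampSpectrum:
    """Read a two-column spectrometer text/CSV file and resample it onto the
    package wavelength grid by linear interpolation.

    ``#``-prefixed lines are comments.  Values outside the file's wavelength
    support become 0.  Malformed rows raise :class:`FormatError` with the
    offending line number.
    """
    wavelengths: list[float] = []
    irradiances: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"expected two columns, got {len(parts)}", line=lineno)
            try:
                wl, irr = float(parts[0]), float(parts[1])
            except ValueError:
                raise FormatError(f"non-numeric value in {line!r}", line=lineno) from None
            if wavelengths and wl <= wavelengths[-1]:
                raise FormatError(
                    f"wavelengths must increase: {wl} after {wavelengths[-1]}",
                    line=lineno)
            if irr < 0:
                raise FormatError(f"negative irradiance {irr}", line=lineno)
            wavelengths.append(wl)
            irradiances.append(irr)

    if len(wavelengths) < 10:
        raise FormatError(f"spectrum has only {len(wavelengths)} points (< 10)")

    if grid is None:
        grid = default_grid()
    resampled = np.interp(grid, np.asarray(wavelengths), np.asarray(irradiances),
                          left=0.0, right=0.0)
    return LampSpectrum(lamp_type=lamp_type, grid=grid, irradiance=resampled)


def emission_range(spectrum: LampSpectrum,
                   rel_threshold: float = DEFAULT_REL_THRESHOLD,
                   gap_merge: float = DEFAULT_GAP_MERGE) -> EmissionRange:
    """Intervals where the lamp emits light.

    The dark offset (1st percentile of the irradiance) is subtracted and the
    result floored at zero; intervals are where the corrected irradiance is
    at or above ``rel_threshold`` times the corrected peak, with edges placed
    by linear interpolation and intervals closer than ``gap_merge`` nm
    merged.  Both the threshold and the merge distance are relative /
    geometric, so the result is invariant to rescaling the irradiance.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ValidationError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    grid = spectrum.grid
    corrected = spectrum.irradiance - np.percentile(spectrum.irradiance, 1.0)
    np.clip(corrected, 0.0, None, out=corrected)
    peak = float(np.max(corrected))
    if peak <= 0:
        raise DegenerateSpectrumError(
            f"{spectrum.lamp_type} spectrum is all zero after baseline correction")

    level = rel_threshold * peak
    above = corrected >= level

    intervals: list[list[float]] = []
    idx = np.nonzero(above)[0]
    if idx.size == 0:  # cannot happen: the peak itself is above
        raise DegenerateSpectrumError("no samples above the emission threshold")

    # contiguous runs of above-threshold samples, edges interpolated
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    for s, e in zip(starts, ends):
        if s > 0:
            v0, v1 = corrected[s - 1], corrected[s]
            lo = float(grid[s - 1] + (level - v0) / (v1 - v0) * (grid[s] - grid[s - 1]))
        else:
            lo = float(grid[0])
        if e < len(grid) - 1:
            v0, v1 = corrected[e], corrected[e + 1]
            hi = float(grid[e] + (level - v0) / (v1 - v0) * (grid[e + 1] - grid[e]))
        else:
            hi = float(grid[-1])
        if hi <= lo:  # single-sample spike narrower than the grid step
            continue
        intervals.append([lo, hi])

    if not intervals:
        raise DegenerateSpectrumError("emission support narrower than the grid step")

    merged: list[list[float]] = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo - merged[-1][1] < gap_merge:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    if len(merged) < len(intervals):
        logger.debug("%s: merged %d raw intervals into %d (gap < %g nm)",
                     spectrum.lamp_type, len(intervals), len(merged), gap_merge)
    return EmissionRange(tuple((a, b) for a, b in merged), threshold=rel_threshold)
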