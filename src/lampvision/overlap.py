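"""The percent-of-visual-range-stimulated index and the species x lamp table.

For each species the visually detectable interval (half-maximum range) is
intersected with the lamp's emission region; the index is the intersected
length as a percentage of the species' interval length.  It is purely
range-based — irradiance inside the emission region is not weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .lamps import EmissionRange, LampSpectrum, emission_range
from .pigments import SpeciesEntry, VisualRange, species_visual_range

logger = logging.getLogger(__name__)

OVERLAP_COLUMNS = ["species_id", "class", "lamp_type", "min_lambda_half_nm",
                   "max_lambda_half_nm", "lamp_span_lo_nm", "lamp_span_hi_nm",
                   "percent_stimulated"]


@dataclass(frozen=True)
class OverlapResult:
    species_id: str
    taxon_class: str
    lamp_type: str
    percent_stimulated: float

    def __post_init__(self):
        if not (0.0 <= self.percent_stimulated <= 100.0):
            raise ValidationError(
                f"percent_stimulated {self.percent_stimulated} outside [0, 100]")


def _intersection_length(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def percent_range_stimulated(visual: VisualRange, emission: EmissionRange,
                             mode: str = "span") -> float:
    """Percentage of the visual interval overlapped by the lamp's emission.

    ``mode="span"`` (default) intersects with the single contiguous emission
    span; ``mode="union"`` sums intersections over the disjoint emission
    intervals, a sensitivity-analysis variant that can only be smaller.
    """
    width = visual.width
    if width <= 0:
        raise ValidationError("zero-length visual range")
    v = visual.as_tuple()
    if mode == "span":
        overlap = _intersection_length(v, emission.span)
    elif mode == "union":
        overlap = sum(_intersection_length(v, iv) for iv in emission.intervals)
    else:
        raise ValidationError(f"unknown emission mode {mode!r}")
    return float(min(100.0, max(0.0, 100.0 * overlap / width)))


def overlap_table(species: Sequence[SpeciesEntry],
                  lamps: Iterable[LampSpectrum],
                  mode: str = "span",
                  rel_threshold: float | None = None,
                  gap_merge: float | None = None,
                  grid=None,
                  droplet_slope: float | None = None) -> pd.DataFrame:
    """One row per species x lamp with ranges, lamp span and the index.

    A species whose range computation fails is reported (with its id) and
    skipped rather than aborting the whole table.
    """
    lamps = list(lamps)
    if not lamps:
        raise ValidationError("need at least one lamp spectrum")

    er_kwargs = {}
    if rel_threshold is not None:
        er_kwargs["rel_threshold"] = rel_threshold
    if gap_merge is not None:
        er_kwargs["gap_merge"] = gap_merge
    emissions = [(lamp.lamp_type, emission_range(lamp, **er_kwargs)) for lamp in lamps]

    rows = []
    for entry in species:
        try:
            vr = species_visual_range(entry, grid=grid, droplet_slope=droplet_slope)
        except Exception as exc:  # keep the fleet running, report the species
            logger.error("species %s skipped: %s", entry.species_id, exc)
            continue
        for lamp_type, er in emissions:
            pct = percent_range_stimulated(vr, er, mode=mode)
            lo, hi = er.span
            rows.append((entry.species_id, entry.taxon_class, lamp_type,
                         vr.min_lambda_half, vr.max_lambda_half, lo, hi, pct))

    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


def write_overlap_csv(table: pd.DataFrame, path, config_echo: str = "") -> None:
    """Write the overlap table with the run configuration echoed in a
    ``#`` header comment, so every output is traceable to its settings."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in config_echo.splitlines():
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)
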