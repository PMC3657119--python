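"""Visual-pigment absorbance modelling and half-maximum sensitivity ranges.

A photoreceptor's visual pigment is summarized by the wavelength of its peak
absorbance, lambda_max.  The standard A1 pigment template reconstructs the
full absorbance spectrum from lambda_max alone as the sum of a main alpha band
and a short-wavelength beta band.  The wavelengths at which the (normalized)
curve crosses half its maximum — min lambda_0.5 and max lambda_0.5 — bound the
region where the receptor is more than half maximally sensitive; the envelope
of these intervals over all of a species' receptors is taken as the species'
visually detectable range.

The template's alpha band is ``1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)``
with ``x = lambda_max / lambda`` and published constants; the beta band is a
Gaussian whose centre and width are linear in lambda_max.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateCurveError, ValidationError

logger = logging.getLogger(__name__)

#: Modelling window in nm: templates are evaluated across this range.
DEFAULT_WINDOW: tuple[float, float] = (200.0, 750.0)

#: Default wavelength grid step in nm.  Half-maximum crossings move by far
#: less than 0.1 nm when the step is refined further, well below biological
#: meaning; the brute-force test oracle uses 0.01 nm.
DEFAULT_STEP: float = 0.1

#: Valid lambda_max bounds (nm) — covers all A1-range pigments in scope and
#: the template's calibration range.
LAMBDA_MAX_BOUNDS: tuple[float, float] = (300.0, 700.0)

# A1 template constants: alpha-band exponential coefficients and the
# beta-band amplitude / centre / width relations.
_ALPHA_A = 69.7
_ALPHA_B = 28.0
_ALPHA_C = -14.9
_ALPHA_D = 0.674
_ALPHA_b = 0.922
_ALPHA_c = 1.104
_BETA_AMPLITUDE = 0.26

TAXON_CLASSES = frozenset({"Arachnida", "Insecta", "Aves", "Reptilia", "Mammalia"})


def default_grid(step: float = DEFAULT_STEP,
                 window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Uniform wavelength grid (nm) spanning the modelling window inclusive."""
    lo, hi = window
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _check_grid(grid: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ConfigurationError("wavelength grid must be a 1-D array with >= 2 points")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        raise ConfigurationError("wavelength grid must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ConfigurationError("wavelength grid must have a uniform step")
    lo, hi = window
    if grid[0] > lo + 1e-9 or grid[-1] < hi - 1e-9:
        raise ConfigurationError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] nm does not cover the modelling "
            f"window [{lo:g}, {hi:g}] nm")
    return grid


@dataclass(frozen=True)
class AbsorbanceCurve:
    """A relative absorbance (or transmittance) spectrum on a uniform grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape:
            raise ValidationError("grid and values must have identical shape")
        steps = np.diff(grid)
        if grid.size < 2 or np.any(steps <= 0) or not np.allclose(steps, steps[0],
                                                                  rtol=0, atol=1e-6):
            raise ValidationError("grid must be strictly increasing with uniform step")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def normalized(self) -> "AbsorbanceCurve":
        """Rescale so the maximum equals exactly 1."""
        peak = float(np.max(self.values))
        if peak <= 0:
            raise DegenerateCurveError("cannot normalize an all-zero curve")
        return AbsorbanceCurve(self.grid, self.values / peak)

    def value_at(self, wavelength: float) -> float:
        """Linear interpolation at an arbitrary wavelength inside the grid."""
        return float(np.interp(wavelength, self.grid, self.values))


@dataclass(frozen=True)
class VisualRange:
    """[min lambda_0.5, max lambda_0.5] interval in nm."""

    min_lambda_half: float
    max_lambda_half: float

    def __post_init__(self):
        if not self.min_lambda_half < self.max_lambda_half:
            raise ValidationError(
                f"visual range must have min < max, got "
                f"({self.min_lambda_half}, {self.max_lambda_half})")

    @property
    def width(self) -> float:
        return self.max_lambda_half - self.min_lambda_half

    def as_tuple(self) -> tuple[float, float]:
        return (self.min_lambda_half, self.max_lambda_half)


@dataclass
class Pigment:
    """One photoreceptor's visual pigment.

    Parameters
    ----------
    lambda_max
        Peak absorbance wavelength in nm; must lie in [300, 700].
    receptor_label
        Free-text receptor name, e.g. ``"UVS"``, ``"SWS"``, ``"MWS"``,
        ``"LWS"``.  Labels containing ``UV`` route around oil-droplet
        filtering (UV cones carry clear droplets).
    oil_droplet
        Optional :class:`~lampvision.ocular_filters.OilDroplet`.
    """

    lambda_max: float
    receptor_label: str = ""
    oil_droplet: object | None = None

    def __post_init__(self):
        lo, hi = LAMBDA_MAX_BOUNDS
        if not (lo <= self.lambda_max <= hi):
            raise ValidationError(
                f"lambda_max {self.lambda_max} nm outside valid bounds [{lo}, {hi}]")

    @property
    def is_uv(self) -> bool:
        return "UV" in self.receptor_label.upper()


@dataclass
class SpeciesEntry:
    """A species' photoreceptor complement."""

    species_id: str
    taxon_class: str
    pigments: list[Pigment] = field(default_factory=list)
    diurnal: bool = True

    def __post_init__(self):
        if self.taxon_class not in TAXON_CLASSES:
            raise ValidationError(
                f"{self.species_id}: unknown class {self.taxon_class!r}; "
                f"expected one of {sorted(TAXON_CLASSES)}")
        if not self.pigments:
            raise ValidationError(f"{self.species_id}: species must have >= 1 pigment")


def template_absorbance(lambda_max: float, grid: np.ndarray,
                        window: tuple[float, float] = DEFAULT_WINDOW,
                        normalize: bool = True) -> AbsorbanceCurve:
    """Model a pigment's absorbance spectrum from lambda_max on ``grid``.

    The curve is the alpha band plus the beta band, renormalized (by default)
    so its maximum is exactly 1 — half-maximum crossings are relative to the
    pigment's own peak.

    Raises
    ------
    ValidationError
        lambda_max outside [300, 700] nm.
    ConfigurationError
        ``grid`` does not cover the modelling window.
    """
    lo, hi = LAMBDA_MAX_BOUNDS
    if not (lo <= lambda_max <= hi):
        raise ValidationError(
            f"lambda_max {lambda_max} nm outside valid bounds [{lo}, {hi}]")
    grid = _check_grid(grid, window)

    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(_ALPHA_A * (a - x))
                   + np.exp(_ALPHA_B * (_ALPHA_b - x))
                   + np.exp(_ALPHA_C * (_ALPHA_c - x))
                   + _ALPHA_D)

    beta_centre = 189.0 + 0.315 * lambda_max
    beta_width = -40.5 + 0.195 * lambda_max
    beta = _BETA_AMPLITUDE * np.exp(-(((grid - beta_centre) / beta_width) ** 2))

    curve = AbsorbanceCurve(grid, alpha + beta)
    return curve.normalized() if normalize else curve


def half_max_crossings(curve: AbsorbanceCurve, level: float = 0.5) -> VisualRange:
    """Outermost wavelengths where ``curve`` crosses ``level``.

    Crossing positions are located by linear interpolation between the
    bracketing grid points.  If the curve is still at or above ``level`` at a
    grid edge, a boundary warning is logged and the edge wavelength is
    returned.  Interior dips below ``level`` between the outermost crossings
    are logged but do not split the interval: the reported range is the
    single outermost-min to outermost-max interval.

    Raises
    ------
    DegenerateCurveError
        The curve never attains ``level``, or the above-level region has
        zero width.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    v = curve.values
    grid = curve.grid
    above = v >= level
    if not np.any(above):
        raise DegenerateCurveError(
            f"curve peaks at {np.max(v):.4f}, never reaching level {level}")

    idx = np.nonzero(above)[0]
    first, last = int(idx[0]), int(idx[-1])

    if first == 0:
        logger.warning("curve >= %g at lower grid edge %.1f nm; returning edge",
                       level, grid[0])
        lo = float(grid[0])
    else:
        # interpolate between the last below-level point and the first above
        v0, v1 = v[first - 1], v[first]
        lo = float(grid[first - 1] + (level - v0) / (v1 - v0) * (grid[first] - grid[first - 1]))

    if last == len(grid) - 1:
        logger.warning("curve >= %g at upper grid edge %.1f nm; returning edge",
                       level, grid[-1])
        hi = float(grid[-1])
    else:
        v0, v1 = v[last], v[last + 1]
        hi = float(grid[last] + (level - v0) / (v1 - v0) * (grid[last + 1] - grid[last]))

    if not lo < hi:
        raise DegenerateCurveError(
            f"above-level region at level {level} has zero width (at {lo:.2f} nm)")

    interior = ~above[first:last + 1]
    if np.any(interior):
        logger.info("curve dips below %g inside [%.1f, %.1f] nm "
                    "(%d grid points); reporting the outermost interval",
                    level, lo, hi, int(np.sum(interior)))
    return VisualRange(lo, hi)


def pigment_visual_range(pigment: Pigment, grid: np.ndarray | None = None,
                         window: tuple[float, float] = DEFAULT_WINDOW,
                         droplet_slope: float | None = None,
                         apply_droplet: bool = True) -> VisualRange:
    """Half-maximum range of one pigment, with oil-droplet filtering applied
    when the pigment carries a (non-clear) droplet."""
    from . import ocular_filters  # local import to avoid cycle

    if grid is None:
        grid = default_grid(window=window)
    curve = template_absorbance(pigment.lambda_max, grid, window=window)
    droplet = pigment.oil_droplet
    if apply_droplet and droplet is not None and not droplet.clear:
        trans = ocular_filters.droplet_transmittance(droplet, grid,
                                                     default_slope=droplet_slope)
        curve = ocular_filters.apply_filter(curve, trans)
    return half_max_crossings(curve)


def species_visual_range(entry: SpeciesEntry, grid: np.ndarray | None = None,
                         window: tuple[float, float] = DEFAULT_WINDOW,
                         droplet_slope: float | None = None) -> VisualRange:
    """Enveloping half-maximum interval over all of a species' pigments.

    min lambda_0.5 is the minimum over pigments of the per-pigment minimum,
    max lambda_0.5 the maximum of the per-pigment maximum: a single interval
    even when per-pigment ranges are disjoint.
    """
    from .ocular_filters import droplet_applies

    if not entry.pigments:
        raise ValidationError(f"{entry.species_id}: species has no pigments")
    ranges = [pigment_visual_range(
                  p, grid=grid, window=window, droplet_slope=droplet_slope,
                  apply_droplet=droplet_applies(entry.taxon_class, entry.diurnal,
                                                p.receptor_label))
              for p in entry.pigments]
    return VisualRange(min(r.min_lambda_half for r in ranges),
                       max(r.max_lambda_half for r in ranges))


# ---------------------------------------------------------------------------
# Species-table ingest
# ---------------------------------------------------------------------------

SPECIES_CSV_COLUMNS = ["species_id", "class", "receptor_label", "lambda_max_nm",
                       "oil_lambda_cut_nm", "oil_lambda_mid_nm", "diurnal"]


@dataclass
class IngestReport:
    """What the species-table reader kept, excluded and merged."""

    n_rows: int = 0
    n_species: int = 0
    excluded_missing_lambda_max: list[str] = field(default_factory=list)
    deduplicated_sex: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def read_species_table(path, dedupe_sex: bool = False) -> tuple[list[SpeciesEntry], IngestReport]:
    """Read a species photoreceptor CSV (one row per photoreceptor).

    Required header: ``species_id, class, receptor_label, lambda_max_nm,
    oil_lambda_cut_nm, oil_lambda_mid_nm, diurnal``.  Empty oil fields mean
    no droplet.  An optional ``sex`` column enables, with
    ``dedupe_sex=True``, the convention for sex-specific insect data: keep
    the sex with more characterized pigments, and on a tie keep the female.

    A species with any photoreceptor row missing ``lambda_max_nm`` is
    excluded from the returned entries and flagged in the report — never
    silently dropped.
    """
    from .ocular_filters import OilDroplet
    from .errors import FormatError

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("species CSV is empty", line=1)
        missing = [c for c in SPECIES_CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"species CSV missing columns {missing}", line=1)
        rows = list(reader)

    report = IngestReport(n_rows=len(rows))

    # group rows by (species_id, sex) preserving order
    groups: dict[tuple[str, str], list[dict]] = {}
    for row in rows:
        key = (row["species_id"], (row.get("sex") or "").strip())
        groups.setdefault(key, []).append(row)

    if dedupe_sex:
        by_species: dict[str, list[tuple[str, list[dict]]]] = {}
        for (sid, sex), g in groups.items():
            by_species.setdefault(sid, []).append((sex, g))
        groups = {}
        for sid, variants in by_species.items():
            if len(variants) > 1:
                # more pigments wins; tie -> female kept (male omitted)
                def rank(v):
                    sex, g = v
                    return (len(g), 1 if sex.lower().startswith("f") else 0)
                variants.sort(key=rank, reverse=True)
                kept_sex = variants[0][0]
                report.deduplicated_sex.append(f"{sid} (kept {kept_sex or 'unsexed'})")
            groups[(sid, variants[0][0])] = variants[0][1]

    entries: list[SpeciesEntry] = []
    for (sid, _sex), g in groups.items():
        if any(not (row["lambda_max_nm"] or "").strip() for row in g):
            report.excluded_missing_lambda_max.append(sid)
            logger.warning("species %s excluded: missing lambda_max for a "
                           "known photoreceptor", sid)
            continue
        pigments = []
        diurnal = True
        for row in g:
            cut = (row["oil_lambda_cut_nm"] or "").strip()
            mid = (row["oil_lambda_mid_nm"] or "").strip()
            droplet = None
            if cut or mid:
                droplet = OilDroplet(lambda_cut=float(cut) if cut else None,
                                     lambda_mid=float(mid) if mid else None)
            diurnal = (row["diurnal"] or "").strip().lower() not in ("0", "false", "no", "n")
            pigments.append(Pigment(lambda_max=float(row["lambda_max_nm"]),
                                    receptor_label=row["receptor_label"].strip(),
                                    oil_droplet=droplet))
        entries.append(SpeciesEntry(species_id=sid, taxon_class=g[0]["class"].strip(),
                                    pigments=pigments, diurnal=diurnal))

    report.n_species = len(entries)
    return entries, report
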