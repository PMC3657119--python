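"""Synthetic species tables and archetype lamp spectra.

Real compilations of photoreceptor peak sensitivities are scattered across
the literature, and measured street-lamp spectra are instrument- and
installation-specific.  This module generates stand-ins with the same
structure so the whole pipeline can run, and be tested, from a seed:

* a species table drawn from per-class receptor profiles — UV-sensitive
  arachnids, insects and reptiles; birds whose sensitivity reaches less far
  into the UV and whose single cones carry long-pass oil droplets (as do
  diurnal reptiles); dichromatic mammals with no sub-400 nm pigment — sized
  by default to a fleet of 213 species (7 arachnids, 112 insects, 16 birds,
  32 reptiles, 46 mammals);
* four lamp archetypes built from Gaussian emission lines plus a smooth
  continuum: LPS (narrow sodium doublet, no UV), HPS and LED (broad,
  no UV, nearly coincident emission spans) and MH (broadest, emitting
  below 400 nm).

Profiles and archetypes are configurable (YAML/JSON); the defaults encode
the qualitative class and lamp structure above, not any published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .lamps import LampSpectrum
from .ocular_filters import OilDroplet, droplet_applies, lambda_cut_to_mid
from .pigments import (Pigment, SpeciesEntry, SPECIES_CSV_COLUMNS,
                       default_grid)


@dataclass
class ReceptorProfile:
    """Distribution of one receptor's lambda_max within a class, with an
    optional oil-droplet rule (cut-off offset below lambda_max)."""

    label: str
    mean: float
    sd: float
    lo: float
    hi: float
    droplet_offset_mean: float | None = None  # lambda_max - lambda_cut, nm
    droplet_offset_sd: float = 3.0
    droplet_param: str = "cut"  # which published value is reported: cut | mid

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("receptor sd must be >= 0")
        if not self.lo < self.hi:
            raise ValidationError("receptor bounds must satisfy lo < hi")


@dataclass
class ClassProfile:
    taxon_class: str
    n_species: int
    receptors: list[ReceptorProfile]
    oil_droplets: bool = False   # birds / diurnal-reptile policy
    diurnal_fraction: float = 1.0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if not (0.0 <= self.diurnal_fraction <= 1.0):
            raise ValidationError("diurnal_fraction must be in [0, 1]")


@dataclass
class LampArchetype:
    """Gaussian emission lines plus an optional smooth continuum.

    ``lines`` are (centre nm, sd nm, height); ``continuum`` is
    (lo nm, hi nm, height, edge nm) — a plateau with raised-cosine tapers of
    width ``edge`` at both ends.
    """

    lamp_type: str
    lines: list[tuple[float, float, float]] = field(default_factory=list)
    continuum: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        for c, w, h in self.lines:
            if not (300.0 <= c <= 750.0):
                raise ValidationError(f"line centre {c} nm outside [300, 750]")
            if h <= 0 or w <= 0:
                raise ValidationError("line height and width must be > 0")


def default_class_profiles() -> list[ClassProfile]:
    """Fleet of 213 species across five classes (defaults, all configurable)."""
    return [
        ClassProfile("Arachnida", 7, [
            ReceptorProfile("UVS", 360, 12, 330, 392),
            ReceptorProfile("MWS", 520, 16, 478, 562),
        ]),
        ClassProfile("Insecta", 112, [
            ReceptorProfile("UVS", 350, 12, 320, 386),
            ReceptorProfile("SWS", 440, 15, 400, 482),
            ReceptorProfile("MWS", 530, 16, 488, 572),
        ]),
        ClassProfile("Aves", 16, [
            ReceptorProfile("UVS", 372, 6, 358, 390),
            ReceptorProfile("SWS", 450, 8, 430, 472,
                            droplet_offset_mean=22, droplet_param="mid"),
            ReceptorProfile("MWS", 505, 8, 483, 527, droplet_offset_mean=12),
            ReceptorProfile("LWS", 563, 6, 545, 580, droplet_offset_mean=5),
        ], oil_droplets=True),
        ClassProfile("Reptilia", 32, [
            ReceptorProfile("UVS", 365, 10, 340, 392),
            ReceptorProfile("SWS", 440, 12, 408, 472, droplet_offset_mean=20),
            ReceptorProfile("MWS", 495, 12, 463, 527, droplet_offset_mean=12),
            ReceptorProfile("LWS", 560, 10, 528, 582, droplet_offset_mean=5),
        ], oil_droplets=True, diurnal_fraction=0.5),
        ClassProfile("Mammalia", 46, [
            ReceptorProfile("SWS", 430, 12, 405, 465),
            ReceptorProfile("LWS", 545, 12, 505, 567),
        ]),
    ]


def default_lamp_archetypes() -> list[LampArchetype]:
    """Four archetypes mirroring the lamp categories: narrow no-UV (LPS),
    broad no-UV with near-identical spans (HPS, LED), broad with UV (MH)."""
    return [
        LampArchetype("LPS", lines=[(568.8, 1.5, 0.04), (589.0, 1.5, 1.0),
                                    (589.6, 1.5, 0.9), (615.4, 1.5, 0.03)]),
        LampArchetype("HPS",
                      lines=[(498, 4, 0.12), (569, 5, 0.5), (589, 8, 1.0),
                             (616, 6, 0.45)],
                      continuum=(435, 685, 0.35, 40)),
        LampArchetype("LED",
                      lines=[(460, 6, 0.85)],
                      continuum=(470, 670, 0.6, 60)),
        LampArchetype("MH",
                      lines=[(385, 4, 0.6), (405, 5, 0.6), (436, 5, 0.8),
                             (546, 6, 1.0), (577, 6, 0.7)],
                      continuum=(368, 700, 0.5, 45)),
    ]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, label: str, retries: int = 100) -> float:
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValidationError(f"{label}: mean {mean} outside bounds [{lo}, {hi}]")
        return mean
    for _ in range(retries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError(
        f"{label}: no lambda_max draw inside [{lo}, {hi}] after {retries} tries")


def generate_species_table(profiles: list[ClassProfile] | None = None,
                           seed: int = 0) -> tuple[list[SpeciesEntry], pd.DataFrame]:
    """Draw a reproducible species table from the class profiles.

    Returns both the in-memory entries and an equivalent data frame in the
    species-CSV column layout (one row per photoreceptor).  Each species
    appears exactly once — the one-entry-per-species discipline that, for
    real data, covers conventions like treating polymorphic primates as
    uniformly trichromatic.
    """
    if profiles is None:
        profiles = default_class_profiles()
    rng = np.random.default_rng(seed)

    entries: list[SpeciesEntry] = []
    rows: list[dict] = []
    for profile in profiles:
        cls = profile.taxon_class
        for i in range(profile.n_species):
            sid = f"{cls[:3].lower()}_{i + 1:03d}"
            diurnal = True
            if profile.diurnal_fraction < 1.0:
                diurnal = bool(rng.random() < profile.diurnal_fraction)
            pigments = []
            for rec in profile.receptors:
                lmax = _truncated_normal(rng, rec.mean, rec.sd, rec.lo, rec.hi,
                                         label=f"{sid}/{rec.label}")
                droplet = None
                cut_val = mid_val = None
                if (profile.oil_droplets and rec.droplet_offset_mean is not None
                        and droplet_applies(cls, diurnal, rec.label)):
                    offset = max(0.0, rng.normal(rec.droplet_offset_mean,
                                                 rec.droplet_offset_sd))
                    cut = lmax - offset
                    if rec.droplet_param == "mid":
                        mid_val = round(lambda_cut_to_mid(cut), 1)
                        droplet = OilDroplet(lambda_mid=mid_val)
                    else:
                        cut_val = round(cut, 1)
                        droplet = OilDroplet(lambda_cut=cut_val)
                lmax = round(lmax, 1)
                pigments.append(Pigment(lambda_max=lmax, receptor_label=rec.label,
                                        oil_droplet=droplet))
                rows.append({
                    "species_id": sid, "class": cls, "receptor_label": rec.label,
                    "lambda_max_nm": lmax,
                    "oil_lambda_cut_nm": "" if cut_val is None else cut_val,
                    "oil_lambda_mid_nm": "" if mid_val is None else mid_val,
                    "diurnal": int(diurnal),
                })
            entries.append(SpeciesEntry(species_id=sid, taxon_class=cls,
                                        pigments=pigments, diurnal=diurnal))

    return entries, pd.DataFrame(rows, columns=SPECIES_CSV_COLUMNS)


def _continuum_values(grid: np.ndarray,
                      continuum: tuple[float, float, float, float]) -> np.ndarray:
    lo, hi, height, edge = continuum
    v = np.zeros_like(grid)
    inside = (grid >= lo) & (grid <= hi)
    v[inside] = height
    ramp_in = inside & (grid < lo + edge)
    v[ramp_in] = height * 0.5 * (1 - np.cos(np.pi * (grid[ramp_in] - lo) / edge))
    ramp_out = inside & (grid > hi - edge)
    v[ramp_out] = height * 0.5 * (1 - np.cos(np.pi * (hi - grid[ramp_out]) / edge))
    return v


def generate_lamp_spectrum(archetype: LampArchetype, grid: np.ndarray | None = None,
                           seed: int = 0, noise_level: float = 1e-4) -> LampSpectrum:
    """Sum of Gaussian lines, optional continuum, and a small non-negative
    noise floor (emulating a spectrometer's dark noise, well below the
    emission threshold)."""
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    irr = np.zeros_like(grid)
    for centre, width, height in archetype.lines:
        irr += height * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    if archetype.continuum is not None:
        irr += _continuum_values(grid, archetype.continuum)
    if noise_level > 0:
        irr += noise_level * np.max(irr) * rng.random(grid.size)
    return LampSpectrum(lamp_type=archetype.lamp_type, grid=grid, irradiance=irr)


def generate_lamp_fleet(archetypes: list[LampArchetype] | None = None,
                        grid: np.ndarray | None = None,
                        seed: int = 0) -> list[LampSpectrum]:
    """All archetype spectra, with per-lamp seeds derived from ``seed``."""
    if archetypes is None:
        archetypes = default_lamp_archetypes()
    return [generate_lamp_spectrum(a, grid=grid, seed=(seed + 7919 * k) % (2 ** 31))
            for k, a in enumerate(archetypes)]


def write_lamp_spectrum(spectrum: LampSpectrum, path) -> None:
    """Two-column spectrometer-style text export (re-readable by
    :func:`lampvision.lamps.read_spectrum`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic {spectrum.lamp_type} lamp spectrum\n")
        fh.write("# wavelength_nm relative_irradiance\n")
        for wl, irr in zip(spectrum.grid, spectrum.irradiance):
            fh.write(f"{wl:.1f} {irr:.6e}\n")


def profiles_to_dict(profiles: list[ClassProfile]) -> list[dict]:
    return [asdict(p) for p in profiles]


def profiles_from_dict(data: list[dict]) -> list[ClassProfile]:
    out = []
    for p in data:
        p = dict(p)
        recs = [ReceptorProfile(**r) for r in p.pop("receptors")]
        out.append(ClassProfile(receptors=recs, **p))
    return out


def archetypes_from_dict(data: list[dict]) -> list[LampArchetype]:
    out = []
    for a in data:
        a = dict(a)
        a["lines"] = [tuple(line) for line in a.get("lines", [])]
        if a.get("continuum") is not None:
            a["continuum"] = tuple(a["continuum"])
        out.append(LampArchetype(**a))
    return out


def load_generator_config(path) -> tuple[list[ClassProfile], list[LampArchetype]]:
    """Read class profiles and lamp archetypes from a YAML or JSON file with
    top-level keys ``profiles`` and/or ``archetypes``; missing keys fall
    back to the package defaults."""
    import json

    import yaml

    text = open(path, encoding="utf-8").read()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    profiles = (profiles_from_dict(data["profiles"]) if "profiles" in data
                else default_class_profiles())
    archetypes = (archetypes_from_dict(data["archetypes"]) if "archetypes" in data
                  else default_lamp_archetypes())
    return profiles, archetypes
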