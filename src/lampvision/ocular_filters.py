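"""Oil-droplet transmittance modelling for bird and diurnal-reptile cones.

Pigmented oil droplets sit in front of the visual pigment in the single
cones of birds and many diurnal reptiles and act as long-pass spectral
filters, shifting the short-wavelength limb of the receptor's sensitivity
toward longer wavelengths.  A droplet is characterized by lambda_cut (the
wavelength where the tangent at the half-transmittance point intercepts zero
transmittance) and lambda_mid (the wavelength of half-maximal
transmittance).  UV cones, and all photoreceptors of nocturnal reptiles,
carry clear droplets with no spectral effect.

The transmittance edge is a Gompertz-type double exponential,

    T(lambda) = exp(-ln2 * exp(-k (lambda - lambda_mid))),   k = 2 B_mid / ln2,

parameterized so that T(lambda_mid) = 0.5 exactly and the slope of T at
lambda_mid equals B_mid (nm^-1).  lambda_cut and lambda_mid are
interconvertible through the tangent-line relation

    lambda_mid = lambda_cut + 0.5 / B_mid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pigments import AbsorbanceCurve

#: Default edge slope B_mid (nm^-1) used when published data give only
#: lambda_cut and no measured slope; corresponds to a 10 nm gap between
#: lambda_cut and lambda_mid, typical of measured cone droplets.
DEFAULT_SLOPE: float = 0.05

_LN2 = math.log(2.0)


@dataclass
class OilDroplet:
    """Long-pass oil-droplet filter parameters.

    Exactly one of: ``clear=True`` (identity filter), or at least one of
    ``lambda_cut`` / ``lambda_mid`` given (filtering droplet).
    """

    lambda_cut: float | None = None
    lambda_mid: float | None = None
    slope: float | None = None  # B_mid in nm^-1; None -> package default
    clear: bool = False

    def __post_init__(self):
        has_param = self.lambda_cut is not None or self.lambda_mid is not None
        if self.clear and has_param:
            raise ValidationError("clear droplet must not carry cut/mid wavelengths")
        if not self.clear and not has_param:
            raise ValidationError("non-clear droplet needs lambda_cut or lambda_mid")
        if self.slope is not None and self.slope <= 0:
            raise ValidationError("droplet edge slope must be > 0")

    def effective_lambda_mid(self, default_slope: float | None = None) -> float:
        """lambda_mid, converting from lambda_cut when only that is known."""
        if self.clear:
            raise ValidationError("clear droplet has no lambda_mid")
        if self.lambda_mid is not None:
            return self.lambda_mid
        b = self.slope or default_slope or DEFAULT_SLOPE
        return self.lambda_cut + 0.5 / b


def lambda_cut_to_mid(lambda_cut: float, slope: float = DEFAULT_SLOPE) -> float:
    """Tangent-line conversion lambda_cut -> lambda_mid."""
    return lambda_cut + 0.5 / slope


def droplet_transmittance(droplet: OilDroplet, grid: np.ndarray,
                          default_slope: float | None = None) -> AbsorbanceCurve:
    """Monotone long-pass transmittance curve of a (non-clear) droplet.

    T(lambda_mid) = 0.5 exactly; T -> 1 at long wavelengths and falls
    doubly-exponentially below lambda_cut.
    """
    grid = np.asarray(grid, dtype=float)
    if droplet.clear:
        # callers should route clear droplets to the identity; returning the
        # identity keeps the operation total anyway
        return AbsorbanceCurve(grid, np.ones_like(grid))
    b = droplet.slope or default_slope or DEFAULT_SLOPE
    mid = droplet.effective_lambda_mid(default_slope=default_slope)
    k = 2.0 * b / _LN2
    values = np.exp(-_LN2 * np.exp(-k * (grid - mid)))
    return AbsorbanceCurve(grid, values)


def apply_filter(pigment_curve: AbsorbanceCurve, transmittance: AbsorbanceCurve,
                 renormalize: bool = True) -> AbsorbanceCurve:
    """Pointwise product of pigment absorbance and droplet transmittance.

    The product is renormalized to peak 1 by default so half-maximum
    crossings of the filtered receptor remain relative to its own maximum.
    """
    if pigment_curve.grid.shape != transmittance.grid.shape or \
            not np.allclose(pigment_curve.grid, transmittance.grid, rtol=0, atol=1e-9):
        raise ValidationError("pigment and transmittance curves must share one grid")
    out = AbsorbanceCurve(pigment_curve.grid,
                          pigment_curve.values * transmittance.values)
    return out.normalized() if renormalize else out


def droplet_applies(taxon_class: str, diurnal: bool, receptor_label: str) -> bool:
    """Routing rule: droplets filter only non-UV receptors of birds and of
    diurnal reptiles; everything else (UV cones, nocturnal reptiles, all
    other classes) bypasses."""
    if "UV" in receptor_label.upper():
        return False
    if taxon_class == "Aves":
        return True
    if taxon_class == "Reptilia" and diurnal:
        return True
    return False
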