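"""Shared fixtures and independent oracles.

The oracle functions here are deliberately written as a second, scalar-math
transcription of the pigment template and droplet edge (plus a dense-grid
scan with no interpolation), independent of the package's vectorized
implementation, so tests compare two separately coded routes.
"""

import math

import numpy as np
import pytest

import lampvision as lv


# --- independent template transcription (scalar math, no numpy broadcast) --

def oracle_template_value(lambda_max: float, wavelength: float) -> float:
    """Absorbance (alpha + beta, unnormalized) at one wavelength."""
    x = lambda_max / wavelength
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (math.exp(69.7 * (a - x))
                   + math.exp(28.0 * (0.922 - x))
                   + math.exp(-14.9 * (1.104 - x))
                   + 0.674)
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * math.exp(-(((wavelength - lam_beta) / b_beta) ** 2))
    return alpha + beta


def oracle_droplet_transmittance(lambda_mid: float, slope: float,
                                 wavelength: float) -> float:
    """Gompertz long-pass edge, scalar transcription."""
    ln2 = math.log(2.0)
    k = 2.0 * slope / ln2
    return math.exp(-ln2 * math.exp(-k * (wavelength - lambda_mid)))


def oracle_half_max_scan(lambda_max: float, step: float = 0.01,
                         lambda_mid: float | None = None,
                         slope: float = 0.05) -> tuple[float, float]:
    """Brute-force half-maximum range: evaluate the (optionally droplet-
    filtered) template on a dense grid and return the outermost grid points
    at or above half the maximum.  No interpolation — the dense step bounds
    the error."""
    lam = 200.0 + step * np.arange(int(round(550.0 / step)) + 1)
    vals = np.array([oracle_template_value(lambda_max, w) for w in lam])
    if lambda_mid is not None:
        vals = vals * np.array([oracle_droplet_transmittance(lambda_mid, slope, w)
                                for w in lam])
    vals = vals / vals.max()
    idx = np.nonzero(vals >= 0.5)[0]
    return float(lam[idx[0]]), float(lam[idx[-1]])


@pytest.fixture(scope="session")
def grid():
    return lv.default_grid()


@pytest.fixture(scope="session")
def synthetic_fleet():
    """Default synthetic study inputs: 213 species, 4 archetype lamps."""
    entries, table = lv.generate_species_table(seed=1)
    lamps = lv.generate_lamp_fleet(seed=1)
    return entries, table, lamps


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-condition pipeline run shared across tests."""
    return lv.run_pipeline(lv.RunConfig(seed=1))
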