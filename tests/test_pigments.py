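"""Pigment template, half-maximum crossings and species ranges."""

import math

import numpy as np
import pytest

import lampvision as lv
from lampvision.errors import (ConfigurationError, DegenerateCurveError,
                               ValidationError)

from conftest import oracle_half_max_scan, oracle_template_value

# frozen dense-grid (0.01 nm) brute-force oracle outputs
FROZEN_RANGE_500 = (444.26, 545.73)
FROZEN_TETRACHROMAT = {370: (312.75, 399.81), 445: (393.68, 485.07),
                       508: (451.50, 554.50), 565: (502.74, 616.83)}


class TestTemplate:
    def test_peak_normalization(self, grid):
        curve = lv.template_absorbance(500, grid)
        assert curve.values.max() == 1.0
        assert curve.value_at(500.0) == pytest.approx(1.0, abs=1e-5)

    def test_far_red_tail(self, grid):
        assert lv.template_absorbance(500, grid).value_at(750.0) < 0.01

    @pytest.mark.parametrize("wavelength",
                             [330, 380, 420, 470, 510, 545, 560, 600, 650, 720])
    def test_matches_independent_transcription(self, grid, wavelength):
        """Pointwise agreement with a second, scalar transcription of the
        template at spot wavelengths (lambda_max = 560)."""
        raw = lv.template_absorbance(560, grid, normalize=False)
        expected = oracle_template_value(560, float(wavelength))
        assert raw.value_at(wavelength) == pytest.approx(expected, abs=1e-9)

    def test_lambda_max_bounds_rejected(self, grid):
        for bad in (299.9, 700.1, 0.0):
            with pytest.raises(ValidationError):
                lv.template_absorbance(bad, grid)
        with pytest.raises(ValidationError):
            lv.Pigment(lambda_max=250)

    def test_grid_must_cover_window(self):
        short = 300 + 0.1 * np.arange(1000)
        with pytest.raises(ConfigurationError):
            lv.template_absorbance(500, short)

    def test_monotone_shift_of_crossings(self, grid):
        """Increasing lambda_max strictly shifts both half-max crossings
        redward across the alpha-band-dominated range."""
        ranges = [lv.half_max_crossings(lv.template_absorbance(lm, grid))
                  for lm in range(400, 601, 50)]
        for r0, r1 in zip(ranges, ranges[1:]):
            assert r1.min_lambda_half > r0.min_lambda_half
            assert r1.max_lambda_half > r0.max_lambda_half


class TestHalfMaxCrossings:
    def test_gaussian_closed_form(self):
        """Half-max of a unit Gaussian lies at centre +/- sigma*sqrt(2 ln 2)."""
        g = 200 + 0.1 * np.arange(5501)
        curve = lv.AbsorbanceCurve(g, np.exp(-0.5 * ((g - 500) / 30) ** 2))
        vr = lv.half_max_crossings(curve)
        half_width = 30 * math.sqrt(2 * math.log(2))
        assert vr.min_lambda_half == pytest.approx(500 - half_width, abs=0.05)
        assert vr.max_lambda_half == pytest.approx(500 + half_width, abs=0.05)

    def test_monotone_ramp_interpolation(self):
        """A linear 0->1 ramp crosses 0.5 exactly halfway; the curve is still
        above level at the upper grid edge, so the edge is returned."""
        g = 400 + 0.1 * np.arange(2001)
        curve = lv.AbsorbanceCurve(g, (g - 400) / 200.0)
        vr = lv.half_max_crossings(curve)
        assert vr.min_lambda_half == pytest.approx(500.0, abs=1e-9)
        assert vr.max_lambda_half == pytest.approx(600.0)

    def test_never_reaching_level_is_degenerate(self):
        g = 200 + 0.1 * np.arange(5501)
        curve = lv.AbsorbanceCurve(g, np.full_like(g, 0.3))
        with pytest.raises(DegenerateCurveError):
            lv.half_max_crossings(curve)

    def test_bad_level_rejected(self, grid):
        curve = lv.template_absorbance(500, grid)
        with pytest.raises(ValidationError):
            lv.half_max_crossings(curve, level=1.5)

    def test_frozen_dense_grid_regression(self, grid):
        vr = lv.half_max_crossings(lv.template_absorbance(500, grid))
        assert vr.min_lambda_half == pytest.approx(FROZEN_RANGE_500[0], abs=0.05)
        assert vr.max_lambda_half == pytest.approx(FROZEN_RANGE_500[1], abs=0.05)

    def test_pipeline_matches_brute_force_scan(self, grid):
        """0.1 nm pipeline crossings agree with the 0.01 nm dense scan."""
        rng = np.random.default_rng(42)
        for lmax in rng.uniform(330, 620, size=10):
            vr = lv.half_max_crossings(lv.template_absorbance(lmax, grid))
            lo, hi = oracle_half_max_scan(lmax)
            assert vr.min_lambda_half == pytest.approx(lo, abs=0.05)
            assert vr.max_lambda_half == pytest.approx(hi, abs=0.05)


class TestSpeciesRange:
    def test_single_pigment_identity(self, grid):
        entry = lv.SpeciesEntry("sp1", "Insecta", [lv.Pigment(500, "MWS")])
        vr = lv.species_visual_range(entry, grid=grid)
        single = lv.half_max_crossings(lv.template_absorbance(500, grid))
        assert vr.as_tuple() == single.as_tuple()

    def test_envelope_of_intervals(self):
        """Species range is the envelope (350,450) u (440,560) -> (350,560)."""
        a = lv.VisualRange(350, 450)
        b = lv.VisualRange(440, 560)
        env = lv.VisualRange(min(a.min_lambda_half, b.min_lambda_half),
                             max(a.max_lambda_half, b.max_lambda_half))
        assert env.as_tuple() == (350, 560)

    def test_tetrachromat_matches_oracle_composition(self, grid):
        """Envelope of the four per-pigment dense-scan ranges."""
        lmaxes = sorted(FROZEN_TETRACHROMAT)
        entry = lv.SpeciesEntry("tetra", "Reptilia",
                                [lv.Pigment(lm) for lm in lmaxes], diurnal=False)
        vr = lv.species_visual_range(entry, grid=grid)
        lo = min(v[0] for v in FROZEN_TETRACHROMAT.values())
        hi = max(v[1] for v in FROZEN_TETRACHROMAT.values())
        assert vr.min_lambda_half == pytest.approx(lo, abs=0.05)
        assert vr.max_lambda_half == pytest.approx(hi, abs=0.05)

    def test_envelope_contains_every_pigment_range(self, grid):
        entry = lv.SpeciesEntry("sp", "Insecta",
                                [lv.Pigment(lm) for lm in (350, 440, 530)])
        vr = lv.species_visual_range(entry, grid=grid)
        for p in entry.pigments:
            pr = lv.pigment_visual_range(p, grid=grid)
            assert vr.min_lambda_half <= pr.min_lambda_half
            assert vr.max_lambda_half >= pr.max_lambda_half

    def test_empty_pigments_rejected(self):
        with pytest.raises(ValidationError):
            lv.SpeciesEntry("sp", "Insecta", [])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            lv.SpeciesEntry("sp", "Pisces", [lv.Pigment(500)])


class TestIngest:
    HEADER = ("species_id,class,receptor_label,lambda_max_nm,"
              "oil_lambda_cut_nm,oil_lambda_mid_nm,diurnal\n")

    def test_round_trip_and_missing_flagging(self, tmp_path):
        path = tmp_path / "species.csv"
        path.write_text(self.HEADER +
                        "a,Insecta,UVS,350,,,1\n"
                        "a,Insecta,MWS,530,,,1\n"
                        "b,Aves,LWS,565,558,,1\n"
                        "c,Insecta,UVS,,,,1\n")
        entries, report = lv.read_species_table(path)
        assert [e.species_id for e in entries] == ["a", "b"]
        assert report.excluded_missing_lambda_max == ["c"]
        assert entries[1].pigments[0].oil_droplet.lambda_cut == 558.0

    def test_sex_deduplication_prefers_more_pigments_then_female(self, tmp_path):
        header = self.HEADER.rstrip("\n") + ",sex\n"
        path = tmp_path / "species.csv"
        path.write_text(header +
                        "moth,Insecta,UVS,350,,,1,female\n"
                        "moth,Insecta,MWS,530,,,1,female\n"
                        "moth,Insecta,MWS,528,,,1,male\n"
                        "bee,Insecta,UVS,344,,,1,female\n"
                        "bee,Insecta,UVS,345,,,1,male\n")
        entries, report = lv.read_species_table(path, dedupe_sex=True)
        moth = next(e for e in entries if e.species_id == "moth")
        assert len(moth.pigments) == 2          # female kept (more pigments)
        bee = next(e for e in entries if e.species_id == "bee")
        assert bee.pigments[0].lambda_max == 344  # tie -> male omitted
        assert len(report.deduplicated_sex) == 2

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species_id,class\na,Insecta\n")
        with pytest.raises(lv.FormatError):
            lv.read_species_table(path)
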