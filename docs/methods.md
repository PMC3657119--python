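# Methods

## Pigment absorbance model

Visual pigments are modelled with the standard A1 chromophore template.
With `x = λ_max/λ`, the α-band is

    S_α(x) = 1 / ( exp[69.7 (a − x)] + exp[28 (0.922 − x)]
                   + exp[−14.9 (1.104 − x)] + 0.674 ),
    a = 0.8795 + 0.0459 · exp[ −(λ_max − 300)² / 11940 ],

and the β-band is the Gaussian `0.26 · exp[ −((λ − λ_mβ)/b_β)² ]` with
`λ_mβ = 189 + 0.315 λ_max` and `b_β = −40.5 + 0.195 λ_max` (all in nm).
The curve is the sum of the two bands. λ_max must lie in 300–700 nm, the
template's calibration range and the span of all A1-type pigments handled
here; values outside are rejected, not clamped.

The raw α+β sum can peak marginally above 1 and marginally off λ_max, so
curves are renormalized to a maximum of exactly 1 before any half-maximum
extraction — "half maximum" is always relative to the pigment's own peak.
`template_absorbance(..., normalize=False)` exposes the raw sum for anyone
wanting the alternative convention.

## Grid and crossing extraction

Curves are evaluated on a uniform 0.1 nm grid over 200–750 nm (both
configurable). The half-maximum crossings are located by linear
interpolation between the bracketing grid points; refining the step to
0.01 nm moves crossings by well under 0.05 nm, far below any biological
meaning, which is why 0.1 nm is the default and the test oracle uses a
0.01 nm brute-force scan. If a curve is still at or above the level at a
window edge the edge is returned with a logged warning; a curve that never
attains the level (or attains it at a single point) raises a
degenerate-curve error. When a curve dips below the level between its
outermost crossings (possible when a β-band shoulder clears 0.5), the
reported range is still the single outermost interval and the interior gap
is logged — the species-level quantity of interest is the enveloping
detectable region.

A species' visual range is the envelope over its receptors: the minimum of
the per-pigment minima to the maximum of the per-pigment maxima.

## Oil droplets

Droplet transmittance is a monotone long-pass Gompertz-type double
exponential

    T(λ) = exp( −ln2 · exp[ −k (λ − λ_mid) ] ),   k = 2 B_mid / ln 2,

parameterized so that T(λ_mid) = 0.5 exactly and the slope of T at λ_mid is
B_mid (nm⁻¹). λ_cut is the wavelength where the tangent at λ_mid intercepts
zero transmittance, giving the conversion `λ_mid = λ_cut + 0.5/B_mid` used
when only λ_cut is published. The default slope is B_mid = 0.05 nm⁻¹
(a 10 nm λ_cut→λ_mid gap), inside the range measured for cone droplets;
it is a package-level config value because per-species slopes are rarely
tabulated. Filtered curves (pigment × transmittance) are renormalized to
peak 1 before crossing extraction, with a flag to disable.

Routing: droplets filter only non-UV receptors of birds and of diurnal
reptiles. Receptors whose label contains "UV", all receptors of nocturnal
reptiles, and all receptors of mammals, insects and arachnids bypass
filtering even if droplet columns are present in the input. Lens/cornea
absorption is not modelled.

## Lamp emission range

Spectra are ingested from two-column text (wavelength nm, relative
irradiance), resampled to the package grid by linear interpolation with
zeros outside the file's support. "Emits light" is operationalized as:
subtract the dark offset (1st percentile of irradiance), floor at zero,
then take the region(s) at or above 1% of the corrected peak, merging
intervals closer than 5 nm. Both threshold and merge distance are exposed
in config and echoed into outputs; the definition is scale-invariant.
Downstream overlap uses the contiguous span between the outermost endpoints
by default; a union-of-intervals mode (never larger) is available for
sensitivity analysis.

## Overlap index

`% λ_0.5 range = 100 · |visual ∩ emission| / |visual|`, computed with exact
continuous interval arithmetic (no grid counting), clipped to [0, 100]. The
index is range-based by design: irradiance within the emission region is
not weighted.

## Bayesian comparison

Group means and differences come from the normal linear model with an
improper flat prior on coefficients and inverse-gamma(ε/2, ε/2), ε = 0.001,
on the error variance — the vague conjugate defaults of the standard MCMC
regression routines. The Gibbs sampler alternates the conjugate full
conditionals, discards 1000 burn-in iterations and retains 10 000 draws
(iterations 1001:11000), seeded per analysis stage. Group means use the
zero-intercept cell-means design (one indicator per class × lamp level);
pairwise differences refit with a fitted intercept and each level in turn
as treatment-coding baseline, the non-baseline coefficient being exactly
that pair's difference. Intervals are equal-tailed 2.5/97.5% posterior
quantiles; an interval excluding zero is flagged credible. Percent
responses are analysed untransformed on the 0–100 scale, and no
multiple-testing adjustment is applied. Reported uncertainties are always
the explicit quantiles, never a symmetric ±half-width.

Monte-Carlo standard errors (batch means) back the tests that compare
posterior means against closed-form least-squares oracles.

## Synthetic study conditions

The generator emulates the *structure* of a literature compilation of
photoreceptor λ_max values, not any real species. Defaults: 213 species —
7 arachnids (UV ≈ 360, green ≈ 520 nm), 112 insects (≈ 350/440/530), 16
birds (≈ 372/450/505/563, droplets on the three single-cone types), 32
reptiles (≈ 365/440/495/560, half diurnal with droplets) and 46 mammals
(dichromats, ≈ 430/545, no λ_max below 400 nm). λ_max values are truncated
normal draws; bird/diurnal-reptile droplet cut-offs sit a receptor-specific
offset below λ_max, some reported as λ_cut and some as λ_mid to exercise
both input paths.

The four lamp archetypes are Gaussian emission lines plus a raised-cosine
continuum with a small seeded noise floor: LPS is the sodium doublet at
589 nm with its weak 569/615 nm satellites (narrow, no UV); HPS and LED are
broad with deliberately near-coincident ~440–680 nm emission spans (they
represent the same "broad, no UV" category and should be statistically
indistinguishable); MH is broadest, emitting below 400 nm. Both profiles
and archetypes were fixed once, at design time, to embody this qualitative
category structure, and are fully configurable.

What passing tests on these conditions show — and what they do not: they
demonstrate that the pipeline recovers the qualitative ordering (LPS lowest
and MH highest in every class; mammals gaining most under broad lamps;
broad lamps amplifying between-class differences) whenever the underlying
class sensitivity structure has the described form. They do not certify
numeric agreement with any published per-class means, which depend on the
actual species compilation and measured lamp spectra; real analyses should
ingest real CSVs and spectrometer files through the same interfaces.

## Numerical and design choices

- Linear interpolation everywhere a sub-grid position is needed (crossings,
  emission edges, resampling); ties and plateaus resolve to the outermost
  bracketing points.
- Overlap arithmetic is continuous; grids only discretize curve evaluation.
- Problem sizes in the test suite and the reproduction script are the full
  default conditions (213 species × 4 lamps, 11 000 MCMC iterations per
  fit); the whole pipeline runs in a few seconds on one core. The sampler
  calibration check uses 200 replicate simulations at n = 30 with shorter
  chains (200 burn-in, 1500 retained), which is ample for interval-coverage
  assessment.
- A failing species in the batch table is logged with its id and skipped;
  ingest excludes (and reports) species with missing λ_max for a known
  receptor rather than silently dropping rows. An optional sex
  de-duplication rule for sex-specific entries keeps the sex with more
  characterized pigments, omitting the male on ties.

## Known limitations

- Only the A1 template is implemented; A2/porphyropsin pigments, screening
  pigments and receptor-noise colour discrimination models are out of
  scope.
- The droplet edge slope default is a single package constant; species with
  measured slopes should pass them per droplet.
- The index treats the emission region as binary; two lamps with identical
  ranges but different spectral power distributions score identically.
- Posterior intervals are reproducible in distribution across seeds, not
  digit-for-digit.
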