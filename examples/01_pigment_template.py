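"""Model visual-pigment absorbance curves and half-maximum ranges.

Builds the absorbance template for the three human cone pigments
(lambda_max ~ 420, 530, 560 nm), extracts each pigment's half-maximum
interval and the enveloping visual range of the trichromat.
"""

import lampvision as lv

grid = lv.default_grid()  # 200-750 nm at 0.1 nm

print("pigment   min_l0.5   max_l0.5   (nm)")
for lmax in (420, 530, 560):
    vr = lv.half_max_crossings(lv.template_absorbance(lmax, grid))
    print(f"  {lmax:3d}     {vr.min_lambda_half:7.1f}    {vr.max_lambda_half:7.1f}")

human = lv.SpeciesEntry("Homo sapiens", "Mammalia",
                        [lv.Pigment(420, "SWS"), lv.Pigment(530, "MWS"),
                         lv.Pigment(560, "LWS")])
vr = lv.species_visual_range(human, grid=grid)
print(f"\nspecies visual range: {vr.min_lambda_half:.1f} - "
      f"{vr.max_lambda_half:.1f} nm (width {vr.width:.1f} nm)")
# The species range is the envelope over receptors: the region of the
# spectrum where at least one pigment absorbs more than half its maximum.
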