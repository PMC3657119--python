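"""Oil-droplet filtering of a bird long-wavelength cone.

Bird (and diurnal reptile) single cones sit behind pigmented oil droplets —
long-pass filters that push the short-wavelength limb of the receptor's
sensitivity redward.  Here an LWS pigment (lambda_max 565 nm) is filtered
by a droplet with half-maximal transmittance at 560 nm.
"""

import lampvision as lv

grid = lv.default_grid()
pigment = lv.template_absorbance(565, grid)
unfiltered = lv.half_max_crossings(pigment)

droplet = lv.OilDroplet(lambda_mid=560)
trans = lv.droplet_transmittance(droplet, grid)
filtered = lv.half_max_crossings(lv.apply_filter(pigment, trans))

print(f"droplet transmittance at lambda_mid (560 nm): {trans.value_at(560):.3f}")
print(f"unfiltered half-max range: {unfiltered.min_lambda_half:.1f} - "
      f"{unfiltered.max_lambda_half:.1f} nm")
print(f"filtered   half-max range: {filtered.min_lambda_half:.1f} - "
      f"{filtered.max_lambda_half:.1f} nm")
print(f"short limb shifted redward by "
      f"{filtered.min_lambda_half - unfiltered.min_lambda_half:.1f} nm")
# The long limb barely moves: a long-pass filter only reshapes the blue side.
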