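"""How much of a species' visual range does each street lamp stimulate?

Synthesizes the four lamp archetypes (LPS, HPS, LED, MH), finds each lamp's
emission region, and computes the percent-of-range-stimulated index for a
UV-sensitive insect and a dichromatic mammal.
"""

import lampvision as lv

grid = lv.default_grid()
lamps = lv.generate_lamp_fleet(grid=grid, seed=1)

insect = lv.SpeciesEntry("bee-like insect", "Insecta",
                         [lv.Pigment(350, "UVS"), lv.Pigment(440, "SWS"),
                          lv.Pigment(530, "MWS")])
mammal = lv.SpeciesEntry("rodent-like mammal", "Mammalia",
                         [lv.Pigment(430, "SWS"), lv.Pigment(545, "LWS")])

for sp in (insect, mammal):
    vr = lv.species_visual_range(sp, grid=grid)
    print(f"\n{sp.species_id}: visual range {vr.min_lambda_half:.0f}-"
          f"{vr.max_lambda_half:.0f} nm")
    for lamp in lamps:
        er = lv.emission_range(lamp)
        pct = lv.percent_range_stimulated(vr, er)
        lo, hi = er.span
        print(f"  {lamp.lamp_type:3s} emits {lo:5.0f}-{hi:5.0f} nm -> "
              f"stimulates {pct:5.1f}% of the visual range")
# Narrow LPS light falls outside most of what a UV-sensitive insect can see;
# broad MH light covers nearly everything a UV-blind mammal can see.
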