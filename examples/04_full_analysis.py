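"""Full synthetic-fleet analysis: 213 species x 4 lamps with Bayesian
group comparison.

Runs the whole pipeline at the default study conditions and prints the
posterior class x lamp means and the pairwise lamp comparisons within one
class, formatted like a pairwise-comparison table (mean difference with its
95% credibility interval; '*' marks intervals excluding zero).
"""

import lampvision as lv

result = lv.run_pipeline(lv.RunConfig(seed=1))

gm = result.group_means_percent.copy()
gm[["class", "lamp"]] = gm["level"].str.split(" x ", expand=True)
print("posterior mean % of visual range stimulated (95% CI):")
for cls, sub in gm.groupby("class"):
    cells = ", ".join(f"{r.lamp} {r['mean']:.1f} ({r.ci_low:.1f},{r.ci_high:.1f})"
                      for _, r in sub.iterrows())
    print(f"  {cls:10s} {cells}")

print("\npairwise lamp differences within Mammalia (column minus row style):")
pw = result.pairwise_within_class
print(lv.format_pairwise_table(pw[pw["within"] == "Mammalia"]).to_string())

counts = result.pairwise_within_lamp.groupby("within")["credible"].sum()
print("\ncredible class-pair differences per lamp (of 10):")
print(counts.to_string())
# Broad lamps (HPS, LED, MH) stimulate far more of every class's visual
# range than LPS, and they amplify between-class disparities — mammals,
# whose range excludes the UV, gain the most.
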