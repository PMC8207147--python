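"""Paired past/present morph-frequency change tests on a simulated valley.

Generates a two-era survey, pairs past and present sites by location
(within 50 m), and tests each morph's frequency change across the valley
with a paired t-test or Wilcoxon signed-rank test, chosen by
Shapiro-Wilk normality of the paired differences and an F-test of
variance homogeneity. Site-level changes within +/-3 percentage points
count as "no change".
"""
from cepaea import ValleyScenario, generate_survey, pair_sites, site_frequencies
from cepaea.morph_stats import valley_change_table

# present era: yellows shifted up 8 points at every altitude
scn = ValleyScenario(valley="Demo", present_shift={"yellow": 0.08, "pink": -0.08}, seed=24)
past, present = generate_survey(scn)
freq = site_frequencies(past + present)
pairs = pair_sites(freq[freq.era == "past"], freq[freq.era == "present"])
changes, directions = valley_change_table(freq, {"Demo": pairs}, "past", "present")

print(changes[["morph", "mean_past_pct", "mean_present_pct", "pct_change",
               "test_used", "p_value"]].to_string(index=False))
print()
print(directions.to_string(index=False))
print(
    "\nThe simulated +8-point yellow shift is detected (small p, most sites "
    "'increase'); morphs with no built-in change hover near their past "
    "means with non-significant p."
)
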