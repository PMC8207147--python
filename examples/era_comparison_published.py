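"""Fisher r-to-z comparison of the published Pyrenean cline coefficients.

Uses the packaged per-valley survey summaries (altitudinal correlation of
yellow/unbanded/banded morph frequencies in the 1960s vs 2017/18, and the
number of analyzable sites per valley and era) and tests, per valley and
morph, whether the past and present correlation coefficients differ.
"""
from cepaea import era_comparison_reference

print(f"{'valley':8} {'morph':9} {'r past':>7} {'r now':>7} {'z':>7} {'p(1-sided)':>11}")
for c in era_comparison_reference():
    print(
        f"{c.valley:8} {c.variable:9} {c.r_past:7.3f} {c.r_present:7.3f} "
        f"{c.z_value:7.3f} {c.p_one_sided:11.3f}"
    )
print(
    "\n|z| > 1.96 means the altitudinal cline changed between eras: the "
    "Vielha yellow/unbanded/banded clines weakened significantly, while "
    "Jueu, Riba and Tort show no significant change."
)
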