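"""Reflectance spectra -> CIE coordinates -> chromatic axis scores.

Simulates triplicate reflectance measurements for 20 yellow and 20 pink
shells, bins them to the 300-700 nm grid, averages replicates, converts
to CIE XYZ/xyz under D65 and fits the chromatic PCA. The designated
chromatic axis should cleanly separate the two morphs.
"""
import numpy as np

from cepaea import (
    ObserverModel,
    ShellRecord,
    chromatic_axis_scores,
    fit_color_pca,
    generate_spectra,
    preprocess_spectra,
    tristimulus,
)

records = [ShellRecord(f"Y{i}", "yellow", "unbanded", "pale") for i in range(20)]
records += [ShellRecord(f"P{i}", "pink", "banded", "other") for i in range(20)]
specs = generate_spectra(records, seed=11)
averaged = preprocess_spectra(specs)

obs = ObserverModel.default()
coords = [tristimulus(s, obs) for s in averaged]
labels = [r.color for r in sorted(records, key=lambda r: r.shell_id)]
model = fit_color_pca(coords, basis="xyz", labels=labels)
scores = chromatic_axis_scores(model, coords)

print("explained variance fractions:", np.round(model.explained_variance_fraction, 3))
yellow = np.array([lab == "yellow" for lab in labels])
print(f"chromatic axis: PC{model.chromatic_axis + 1}")
print(f"mean score  yellow shells: {scores[yellow].mean():+.4f}")
print(f"mean score  pink shells:   {scores[~yellow].mean():+.4f}")
print(
    "\nYellow shells score positive and pink negative on the designated "
    "axis (sign convention), so the quantitative measure recovers the "
    "human-scored morphs. Chromaticity is rank-2 (x+y+z=1), hence the "
    "third fraction is 0."
)
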