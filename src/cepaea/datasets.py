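"""Published summary data from the Pyrenean *Cepaea nemoralis* surveys.

The package ships the printed per-valley summaries of the 1960s and
2017/18 surveys of the Vielha, Jueu, Noguera Ribagorzana ("Riba") and
Noguera de Tort ("Tort") valleys: the number of analyzable sites per
valley and era, and the altitudinal correlation coefficient of the
yellow, unbanded and banded morph frequencies (Kendall coefficients
already carried to the Pearson scale). These are the inputs of the
era-comparison step when the raw per-site tables are not at hand.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .clines import ZComparison, fisher_z_compare


def load_survey_summary() -> pd.DataFrame:
    """Per-valley survey summary: era, site count, variable, correlation."""
    with resources.files("cepaea.data").joinpath("pyrenees_survey_summary.csv").open(
        "r"
    ) as fh:
        return pd.read_csv(fh)


def era_comparison_reference() -> list[ZComparison]:
    """Fisher r-to-z comparison of every published past/present cline pair.

    For each valley × variable present in both eras, compares the past
    and present altitudinal correlation coefficients using the published
    site counts as n.
    """
    df = load_survey_summary()
    out = []
    for (valley, variable), grp in df.groupby(["valley", "variable"], sort=False):
        eras = grp.set_index("era")
        if {"past", "present"} <= set(eras.index):
            out.append(
                fisher_z_compare(
                    float(eras.at["past", "correlation"]),
                    int(eras.at["past", "n_sites"]),
                    float(eras.at["present", "correlation"]),
                    int(eras.at["present", "n_sites"]),
                    valley=valley,
                    variable=variable,
                )
            )
    return out
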