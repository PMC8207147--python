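"""Altitudinal cline correlations and their comparison across eras.

Morph frequencies (or per-shell chromatic scores) are correlated with
altitude using Pearson's r when both variables pass Shapiro-Wilk
normality, and Kendall's τ-b otherwise (frequencies tie often, so the
tie-corrected variant is used). Outliers in the dependent variable are
removed first by the 1.5×IQR fence rule. A Kendall τ is mapped onto the
Pearson scale by Greiner's relation r = sin(πτ/2), exact under bivariate
normality, so that correlations obtained by either route can be compared
between eras with Fisher's r-to-z test:

    z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3))

where n is the number of sites (or shells) behind each coefficient.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import as_float_array

log = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation with a constant variable is undefined."""


def remove_outliers_iqr(values) -> tuple[np.ndarray, np.ndarray]:
    """Drop values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation. Returns (kept values, removed
    indices). Fewer than 4 values pass through unchanged with a warning.
    """
    arr = as_float_array(values)
    if len(arr) < 4:
        warnings.warn(
            f"IQR outlier removal skipped: only {len(arr)} values", stacklevel=2
        )
        return arr, np.array([], dtype=int)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    removed = np.flatnonzero((arr < lo) | (arr > hi))
    kept = np.delete(arr, removed)
    return kept, removed


def greiner(tau: float) -> float:
    """Greiner's relation: map Kendall's τ to the Pearson-r scale.

    r = sin(π·τ/2); odd, strictly increasing on [−1, 1], with
    |r| ≥ |τ| everywhere.
    """
    if not np.all(np.abs(tau) <= 1):
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    return np.sin(np.pi * np.asarray(tau, dtype=float) / 2) if np.ndim(tau) else float(
        np.sin(np.pi * tau / 2)
    )


@dataclass
class ClineResult:
    """One morph-vs-altitude correlation with its method metadata."""

    valley: str
    variable: str
    era: str
    n_units: int
    method: str  # "pearson" or "kendall"
    coefficient_r: float  # on the r scale (tau already transformed)
    p_value: float
    raw_tau: float | None = None
    outliers_removed: int = 0
    parametric: bool = False


def altitude_correlation(
    altitude,
    y,
    alpha: float = 0.05,
    valley: str = "",
    variable: str = "",
    era: str = "",
) -> ClineResult:
    """Correlate a variable with altitude, Pearson or Kendall as data allow.

    Outliers in ``y`` are removed by the IQR rule (with the matching
    altitudes). Both remaining variables are tested for normality
    (Shapiro-Wilk at ``alpha``); if both pass, Pearson's r with its
    two-sided t-based p is reported, otherwise Kendall's τ-b with its
    two-sided p, and the coefficient is carried to the r scale by
    Greiner's relation (the original τ is kept in ``raw_tau``).
    """
    x = as_float_array(altitude)
    yv = as_float_array(y)
    if len(x) != len(yv):
        raise ValueError("altitude and variable must have equal length")
    kept_y, removed = remove_outliers_iqr(yv)
    kept_x = np.delete(x, removed)
    if len(kept_y) < 4:
        raise UndefinedCorrelationError(
            f"{valley}/{variable}: fewer than 4 values after outlier removal"
        )
    if np.ptp(kept_x) == 0 or np.ptp(kept_y) == 0:
        raise UndefinedCorrelationError(
            f"{valley}/{variable}: constant variable, correlation undefined"
        )

    parametric = _is_normal(kept_y, alpha) and _is_normal(kept_x, alpha)
    if parametric:
        r, p = stats.pearsonr(kept_x, kept_y)
        return ClineResult(
            valley, variable, era, len(kept_y), "pearson", float(r), float(p),
            outliers_removed=len(removed), parametric=True,
        )
    tau, p = stats.kendalltau(kept_x, kept_y, variant="b")
    return ClineResult(
        valley, variable, era, len(kept_y), "kendall", greiner(float(tau)),
        float(p), raw_tau=float(tau), outliers_removed=len(removed),
        parametric=False,
    )


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000
        return stats.shapiro(values).pvalue > alpha


@dataclass
class ZComparison:
    """Fisher r-to-z comparison of one variable's cline across two eras."""

    valley: str
    variable: str
    r_past: float
    n_past: int
    r_present: float
    n_present: int
    z_value: float
    p_two_sided: float
    p_one_sided: float


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int,
    valley: str = "", variable: str = "",
) -> ZComparison:
    """Fisher's r-to-z test of the difference between two correlations.

    ``r1``/``n1`` are the first (e.g. past) coefficient and its number of
    independent units; likewise ``r2``/``n2``. Reports z and both the
    two-sided p = 2·Φ(−|z|) and the one-sided p = Φ(−|z|).
    """
    for r, n, which in ((r1, n1, "first"), (r2, n2, "second")):
        if abs(r) >= 1:
            raise ValueError(f"{which} correlation |r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"{which} sample needs n > 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p_one = float(stats.norm.sf(abs(z)))
    return ZComparison(
        valley=valley,
        variable=variable,
        r_past=float(r1),
        n_past=int(n1),
        r_present=float(r2),
        n_present=int(n2),
        z_value=float(z),
        p_two_sided=2 * p_one,
        p_one_sided=p_one,
    )


def compare_eras(
    freq: pd.DataFrame,
    past_era: str,
    present_era: str,
    variables: list[str],
    alpha: float = 0.05,
) -> tuple[list[ClineResult], list[ZComparison]]:
    """Altitude correlations per valley × era and their Fisher-z comparison.

    ``freq`` is a site_frequencies table covering both eras; for each
    valley and each variable (a ``f_<morph>`` column, given by morph
    name) the altitudinal correlation is computed in each era and the two
    coefficients compared. n for the comparison is the number of sites
    behind each correlation.
    """
    clines: list[ClineResult] = []
    comparisons: list[ZComparison] = []
    for valley in sorted(freq["valley"].unique()):
        sub = freq[freq["valley"] == valley]
        for variable in variables:
            col = variable if variable in sub.columns else f"f_{variable}"
            results = {}
            for era in (past_era, present_era):
                block = sub[sub["era"] == era]
                if len(block) < 4:
                    log.warning("%s/%s/%s: fewer than 4 sites", valley, variable, era)
                    continue
                try:
                    res = altitude_correlation(
                        block["altitude_m"], block[col], alpha,
                        valley=valley, variable=variable, era=era,
                    )
                except UndefinedCorrelationError as exc:
                    log.warning("skipping %s", exc)
                    continue
                results[era] = res
                clines.append(res)
            if past_era in results and present_era in results:
                a, b = results[past_era], results[present_era]
                try:
                    comparisons.append(
                        fisher_z_compare(
                            a.coefficient_r, a.n_units, b.coefficient_r, b.n_units,
                            valley=valley, variable=variable,
                        )
                    )
                except ValueError as exc:
                    log.warning("%s/%s: %s", valley, variable, exc)
    return clines, comparisons


def clines_table(clines: list[ClineResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "valley": c.valley, "variable": c.variable, "era": c.era,
                "n": c.n_units, "method": c.method,
                "correlation": round(c.coefficient_r, 3),
                "parametric": "Yes" if c.parametric else "No",
                "p_value": c.p_value,
                "raw_tau": None if c.raw_tau is None else round(c.raw_tau, 3),
                "outliers_removed": c.outliers_removed,
            }
            for c in clines
        ]
    )


def comparison_table(comparisons: list[ZComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "valley": c.valley, "variable": c.variable,
                "r_past": round(c.r_past, 3), "n_past": c.n_past,
                "r_present": round(c.r_present, 3), "n_present": c.n_present,
                "z_value": round(c.z_value, 3),
                "p_one_sided": c.p_one_sided, "p_two_sided": c.p_two_sided,
            }
            for c in comparisons
        ]
    )
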