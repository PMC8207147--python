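"""Per-site morph frequencies and paired past/present change tests.

A site enters the analysis only when at least ``min_site_n`` shells
(default 10) were collected there. Past and present sites are paired by
location — identical coordinates or a nearest neighbour within 50 m — and
per-site frequency changes are tested per valley with a paired Student's
t-test when the paired differences look normal (Shapiro-Wilk) and the
past/present variances homogeneous (F-test), otherwise with the Wilcoxon
signed-rank test. A site-level change within ±3 percentage points is
classed as "no change".
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import BANDINGS, COLORS, SiteSample, as_float_array

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Frequency columns produced by site_frequencies, in output order.
FREQ_COLUMNS = [f"f_{m}" for m in COLORS + BANDINGS] + ["f_pale_lip"]


class InsufficientDataError(ValueError):
    """Too few paired sites (or shells) for the requested test."""


def site_frequencies(
    sites: list[SiteSample], min_site_n: int = 10
) -> pd.DataFrame:
    """Morph frequencies and size summaries per analyzable site.

    Returns one row per (site_id, era) with shell count ``n``, the
    frequency of each colour and banding morph and of pale-lipped shells,
    and mean height, width and shape (H/W). Sites with fewer than
    ``min_site_n`` shells are excluded (and logged).
    """
    rows = []
    for site in sites:
        if not site.is_analyzable(min_site_n):
            log.info(
                "excluding site %s (%s): %d shells < %d",
                site.site_id, site.era, site.n, min_site_n,
            )
            continue
        n = site.n
        row = {
            "site_id": site.site_id,
            "era": site.era,
            "valley": site.valley,
            "lat": site.latitude,
            "lon": site.longitude,
            "altitude_m": site.altitude_m,
            "n": n,
        }
        for color in COLORS:
            row[f"f_{color}"] = sum(s.color == color for s in site.shells) / n
        for banding in BANDINGS:
            row[f"f_{banding}"] = sum(s.banding == banding for s in site.shells) / n
        row["f_pale_lip"] = sum(s.lip == "pale" for s in site.shells) / n
        heights = [s.height_mm for s in site.shells if s.height_mm is not None]
        widths = [s.width_mm for s in site.shells if s.width_mm is not None]
        shapes = [s.shape for s in site.shells if s.shape is not None]
        row["mean_height_mm"] = float(np.mean(heights)) if heights else np.nan
        row["mean_width_mm"] = float(np.mean(widths)) if widths else np.nan
        row["mean_shape"] = float(np.mean(shapes)) if shapes else np.nan
        row["mean_size_mm"] = (
            float(np.mean(heights) + np.mean(widths)) if heights and widths else np.nan
        )
        rows.append(row)
    if not rows:
        warnings.warn("site_frequencies: no analyzable sites", stacklevel=2)
        return pd.DataFrame(
            columns=["site_id", "era", "valley", "lat", "lon", "altitude_m", "n"]
            + FREQ_COLUMNS
            + ["mean_height_mm", "mean_width_mm", "mean_shape", "mean_size_mm"]
        )
    return pd.DataFrame(rows)


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between two lat/lon points."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def pair_sites(
    past: pd.DataFrame, present: pd.DataFrame, max_dist_m: float = 50.0
) -> list[tuple[str, str]]:
    """Match past to present sites by location (greedy nearest neighbour).

    Candidate pairs within ``max_dist_m`` (great-circle) are accepted in
    order of increasing distance, breaking exact ties by (past site_id,
    present site_id); each site is used at most once. Returns (past_id,
    present_id) pairs; unmatched sites are simply absent.
    """
    candidates = []
    for _, p in past.iterrows():
        for _, q in present.iterrows():
            d = haversine_m(p["lat"], p["lon"], q["lat"], q["lon"])
            if d <= max_dist_m:
                candidates.append((d, str(p["site_id"]), str(q["site_id"])))
    candidates.sort()
    used_past: set[str] = set()
    used_present: set[str] = set()
    pairs = []
    for _, pid, qid in candidates:
        if pid in used_past or qid in used_present:
            continue
        pairs.append((pid, qid))
        used_past.add(pid)
        used_present.add(qid)
    return pairs


@dataclass
class PairedChange:
    """Frequency change of one morph at one paired site."""

    site_id: str
    morph: str
    delta_pct: float
    direction: str


def classify_change(delta_pct: float, threshold_pct: float = 3.0) -> str:
    """Direction of a site-level frequency change in percentage points.

    Changes of at most ``threshold_pct`` in magnitude (boundary inclusive)
    count as ``"no_change"``.
    """
    if not np.isfinite(delta_pct):
        raise ValueError(f"delta must be finite, got {delta_pct}")
    if delta_pct > threshold_pct:
        return "increase"
    if delta_pct < -threshold_pct:
        return "decrease"
    return "no_change"


@dataclass
class ValleyChangeTest:
    """Valley-level paired test of one morph's frequency change."""

    valley: str
    morph: str
    mean_present_pct: float
    se_present_pct: float
    mean_past_pct: float
    se_past_pct: float
    pct_change: float
    test_used: str  # "paired_t" or "wilcoxon_signed_rank"
    p_value: float
    n_pairs: int


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0


def paired_change_test(
    past_pct,
    present_pct,
    valley: str = "",
    morph: str = "",
    alpha: float = 0.05,
) -> ValleyChangeTest:
    """Paired test of morph frequency change across a valley's sites.

    ``past_pct`` and ``present_pct`` are per-site frequencies (percent)
    at matched sites, in pair order. The paired t-test is used when the
    paired differences pass Shapiro-Wilk normality at ``alpha`` AND the
    past/present variances pass a two-sided F-test of homogeneity at
    ``alpha``; otherwise the Wilcoxon signed-rank test (zero differences
    dropped; exact null distribution for n ≤ 25, normal approximation
    with continuity correction above). The reported p is two-sided.
    """
    past = as_float_array(past_pct)
    present = as_float_array(present_pct)
    if len(past) != len(present):
        raise ValueError("past and present must be paired (equal length)")
    if len(past) < 5:
        raise InsufficientDataError(
            f"paired test needs >= 5 site pairs, got {len(past)}"
        )
    deltas = present - past

    parametric = _normal_deltas(deltas, alpha) and _homogeneous(past, present, alpha)
    if parametric:
        test_used = "paired_t"
        stat = stats.ttest_rel(present, past)
        p = float(stat.pvalue)
    else:
        test_used = "wilcoxon_signed_rank"
        nonzero = deltas[deltas != 0]
        if len(nonzero) == 0:
            p = 1.0
        else:
            method = "exact" if len(nonzero) <= 25 else "approx"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ties under the exact method
                res = stats.wilcoxon(
                    nonzero, zero_method="wilcox", correction=True, method=method
                )
            p = float(res.pvalue)

    return ValleyChangeTest(
        valley=valley,
        morph=morph,
        mean_present_pct=float(np.mean(present)),
        se_present_pct=_sem(present),
        mean_past_pct=float(np.mean(past)),
        se_past_pct=_sem(past),
        pct_change=float(np.mean(deltas)),
        test_used=test_used,
        p_value=p,
        n_pairs=len(past),
    )


def _normal_deltas(deltas: np.ndarray, alpha: float) -> bool:
    if np.ptp(deltas) == 0:  # Shapiro is undefined for constant input
        return False
    return stats.shapiro(deltas).pvalue > alpha


def _homogeneous(past: np.ndarray, present: np.ndarray, alpha: float) -> bool:
    v1, v2 = np.var(past, ddof=1), np.var(present, ddof=1)
    if v1 == 0 or v2 == 0:
        return False
    f = v1 / v2
    df1 = df2 = len(past) - 1
    p_one = stats.f.sf(f, df1, df2) if f > 1 else stats.f.cdf(f, df1, df2)
    return 2 * p_one > alpha


def valley_change_table(
    freq: pd.DataFrame,
    pairs_by_valley: dict[str, list[tuple[str, str]]],
    past_era: str,
    present_era: str,
    morphs: list[str] | None = None,
    threshold_pct: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Valley-level change tests and direction-of-change counts.

    ``freq`` is a site_frequencies table covering both eras;
    ``pairs_by_valley`` maps valley → (past_id, present_id) pairs.
    Returns (valley_changes, direction_counts), the first with one row
    per valley × morph (means, SEs, % change, test, p), the second with
    increase / no_change / decrease counts per the ±``threshold_pct``
    rule.
    """
    morphs = morphs or [c[2:] for c in FREQ_COLUMNS]
    past_idx = freq[freq["era"] == past_era].set_index("site_id")
    pres_idx = freq[freq["era"] == present_era].set_index("site_id")
    tests, counts = [], []
    for valley, pairs in pairs_by_valley.items():
        for morph in morphs:
            col = f"f_{morph}"
            past_v = np.array([past_idx.at[p, col] for p, _ in pairs]) * 100
            pres_v = np.array([pres_idx.at[q, col] for _, q in pairs]) * 100
            tally = {"increase": 0, "no_change": 0, "decrease": 0}
            for d in pres_v - past_v:
                tally[classify_change(d, threshold_pct)] += 1
            counts.append({"valley": valley, "morph": morph, **tally})
            try:
                t = paired_change_test(past_v, pres_v, valley=valley, morph=morph)
            except InsufficientDataError:
                continue
            tests.append(
                {
                    "valley": t.valley,
                    "morph": t.morph,
                    "mean_present_pct": round(t.mean_present_pct, 1),
                    "se_present_pct": round(t.se_present_pct, 1),
                    "mean_past_pct": round(t.mean_past_pct, 1),
                    "se_past_pct": round(t.se_past_pct, 1),
                    "pct_change": round(t.pct_change, 1),
                    "test_used": t.test_used,
                    "p_value": t.p_value,
                    "n_pairs": t.n_pairs,
                }
            )
    return pd.DataFrame(tests), pd.DataFrame(counts)
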