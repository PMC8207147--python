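"""Synthetic Pyrenean valley surveys and shell reflectance spectra.

The generator emulates the structure of a two-era altitudinal survey of
*Cepaea nemoralis*: sites scattered along a valley between roughly 800
and 2000 m, revisited decades later at the same locations, with at least
ten shells per retained site, morph frequencies following logistic
altitudinal clines of configurable midpoint and steepness, and (for the
colorimetry route) triplicate reflectance measurements per shell drawn
from per-morph spectral templates.

Morph probabilities at a site come from per-morph logistic propensities

    g_m(alt) = baseline_m + amplitude_m · σ(k_m · (alt − alt0_m)),

normalised across morphs so the simplex constraint always holds even
though each morph has an independent cline. The "present" era can shift
each morph's probability by a fixed amount and multiply cline slopes,
which is how stable, steepened or flattened clines are produced.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .types import BANDINGS, CANONICAL_GRID, COLORS, ReflectanceSpectrum, ShellRecord, SiteSample


@dataclass
class MorphCline:
    """Logistic altitudinal propensity of one morph."""

    baseline: float
    amplitude: float
    alt0_m: float = 1400.0
    k_per_m: float = 0.004

    def propensity(self, altitude_m, slope_multiplier: float = 1.0) -> np.ndarray:
        g = self.baseline + self.amplitude * expit(
            self.k_per_m * slope_multiplier * (np.asarray(altitude_m, dtype=float) - self.alt0_m)
        )
        return g


@dataclass
class ValleyScenario:
    """Parameters of one simulated valley survey (both eras)."""

    valley: str = "Sintera"
    n_sites: int = 40
    altitude_range_m: tuple[float, float] = (800.0, 2000.0)
    shells_per_site_mean: float = 30.0
    shells_per_site_min: int = 10
    color_clines: dict[str, MorphCline] = field(
        default_factory=lambda: {
            "yellow": MorphCline(baseline=0.30, amplitude=0.60),
            "pink": MorphCline(baseline=0.65, amplitude=-0.50),
            "brown": MorphCline(baseline=0.05, amplitude=0.0),
        }
    )
    banding_clines: dict[str, MorphCline] = field(
        default_factory=lambda: {
            "unbanded": MorphCline(baseline=0.25, amplitude=0.55),
            "midbanded": MorphCline(baseline=0.08, amplitude=0.0),
            "banded": MorphCline(baseline=0.70, amplitude=-0.50),
        }
    )
    pale_lip_cline: MorphCline = field(
        default_factory=lambda: MorphCline(baseline=0.20, amplitude=0.50)
    )
    #: additive probability change per colour morph in the present era
    present_shift: dict[str, float] = field(default_factory=dict)
    #: multiplies every cline slope in the present era (0 flattens clines)
    present_slope_multiplier: float = 1.0
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "ValleyScenario":
        cfg = dict(cfg)
        for key in ("color_clines", "banding_clines"):
            if key in cfg:
                cfg[key] = {m: MorphCline(**v) for m, v in cfg[key].items()}
        if "pale_lip_cline" in cfg:
            cfg["pale_lip_cline"] = MorphCline(**cfg["pale_lip_cline"])
        if "altitude_range_m" in cfg:
            cfg["altitude_range_m"] = tuple(cfg["altitude_range_m"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValleyScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["altitude_range_m"] = list(self.altitude_range_m)
        return d


def stable_scenario(seed: int = 0, n_sites: int = 40) -> ValleyScenario:
    """Identical clines in both eras (the null of the era comparison)."""
    return ValleyScenario(valley="Stable", n_sites=n_sites, seed=seed)


def flattened_scenario(seed: int = 0, n_sites: int = 40) -> ValleyScenario:
    """A strong past cline erased in the present era (slope × 0)."""
    return ValleyScenario(
        valley="Flattened", n_sites=n_sites, present_slope_multiplier=0.0, seed=seed
    )


def _morph_probabilities(
    clines: dict[str, MorphCline],
    altitude: float,
    shift: dict[str, float],
    slope_multiplier: float,
) -> np.ndarray:
    morphs = list(clines)
    g = np.array(
        [clines[m].propensity(altitude, slope_multiplier) for m in morphs], dtype=float
    )
    if np.any(g < 0):
        warnings.warn("negative morph propensity clipped to 0", stacklevel=2)
        g = np.clip(g, 0.0, None)
    p = g / g.sum()
    if shift:
        p = p + np.array([shift.get(m, 0.0) for m in morphs])
        if np.any(p < 0) or np.any(p > 1):
            warnings.warn(
                "frequency shift pushed a probability outside [0, 1]; renormalised",
                stacklevel=2,
            )
            p = np.clip(p, 0.0, 1.0)
        p = p / p.sum()
    return p


def generate_survey(
    scn: ValleyScenario, seed: int | None = None
) -> tuple[list[SiteSample], list[SiteSample]]:
    """Simulate the past and present surveys of one valley.

    Site locations (altitude uniform over the configured range, lat/lon
    along a valley axis) are drawn once and revisited in the present era,
    mirroring a resampling survey. Shell counts are Poisson around the
    configured mean, truncated below at the analyzable minimum; morph
    states are drawn multinomially from the altitude-dependent
    probabilities; shell height and width get a mild positive altitude
    trend. Deterministic for a given seed.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    lo, hi = scn.altitude_range_m
    altitudes = rng.uniform(lo, hi, scn.n_sites)
    # a roughly north-south valley near the central Pyrenees
    lats = 42.6 + (altitudes - lo) / (hi - lo) * 0.15 + rng.normal(0, 1e-3, scn.n_sites)
    lons = 0.75 + rng.normal(0, 5e-3, scn.n_sites)

    eras = []
    for era, shift, slope_mult in (
        ("past", {}, 1.0),
        ("present", scn.present_shift, scn.present_slope_multiplier),
    ):
        sites = []
        for i in range(scn.n_sites):
            n = max(scn.shells_per_site_min, int(rng.poisson(scn.shells_per_site_mean)))
            p_color = _morph_probabilities(
                scn.color_clines, altitudes[i], shift, slope_mult
            )
            p_band = _morph_probabilities(
                scn.banding_clines, altitudes[i], {}, slope_mult
            )
            p_pale = float(
                np.clip(scn.pale_lip_cline.propensity(altitudes[i], slope_mult), 0, 1)
            )
            colors = rng.choice(list(scn.color_clines), size=n, p=p_color)
            bandings = rng.choice(list(scn.banding_clines), size=n, p=p_band)
            pale = rng.random(n) < p_pale
            alt_frac = (altitudes[i] - lo) / (hi - lo)
            heights = rng.normal(17.0 + 2.0 * alt_frac, 1.0, n)
            widths = rng.normal(21.0 + 1.0 * alt_frac, 1.0, n)
            site_id = f"{scn.valley[:3].upper()}-{era[:4]}-{i:03d}"
            shells = [
                ShellRecord(
                    shell_id=f"{site_id}-{j:03d}",
                    color=str(colors[j]),
                    banding=str(bandings[j]),
                    lip="pale" if pale[j] else "other",
                    height_mm=float(max(heights[j], 5.0)),
                    width_mm=float(max(widths[j], 5.0)),
                )
                for j in range(n)
            ]
            sites.append(
                SiteSample(
                    site_id=site_id,
                    valley=scn.valley,
                    latitude=float(lats[i]),
                    longitude=float(lons[i]),
                    altitude_m=float(altitudes[i]),
                    era=era,
                    shells=shells,
                )
            )
        eras.append(sites)
    return eras[0], eras[1]


@dataclass
class SpectrumTemplate:
    """Parametric reflectance curve of one morph.

    The curve is a long-pass sigmoid — a short-wave shoulder rising at
    the inflection wavelength to the maximum reflectance — which is the
    qualitative shape of yellow/pink/brown shell spectra. Shell-to-shell
    variation jitters the inflection and the maximum; each of the three
    replicate measurements adds multiplicative session jitter and
    per-wavelength Gaussian noise.
    """

    morph: str
    inflection_nm: float
    steepness_per_nm: float
    max_reflectance_pct: float
    shoulder_pct: float
    noise_sd_pct: float = 1.5
    replicate_jitter_sd: float = 0.03
    shell_inflection_sd_nm: float = 4.0
    shell_scale_sd: float = 0.08

    def curve(self, wavelength_nm: np.ndarray) -> np.ndarray:
        rise = expit(self.steepness_per_nm * (wavelength_nm - self.inflection_nm))
        return self.shoulder_pct + (self.max_reflectance_pct - self.shoulder_pct) * rise


DEFAULT_TEMPLATES: dict[str, SpectrumTemplate] = {
    "yellow": SpectrumTemplate("yellow", 510.0, 0.08, 60.0, 8.0),
    "pink": SpectrumTemplate("pink", 585.0, 0.05, 55.0, 18.0),
    "brown": SpectrumTemplate("brown", 620.0, 0.03, 30.0, 6.0),
}


def generate_spectra(
    records: list[ShellRecord],
    templates: dict[str, SpectrumTemplate] | None = None,
    seed: int = 0,
) -> list[ReflectanceSpectrum]:
    """Three replicate reflectance spectra per shell, on the canonical grid."""
    templates = DEFAULT_TEMPLATES if templates is None else templates
    rng = np.random.default_rng(seed)
    grid = CANONICAL_GRID
    out = []
    for rec in records:
        if rec.color not in templates:
            raise KeyError(f"no spectral template for morph {rec.color!r}")
        t = templates[rec.color]
        shell_t = SpectrumTemplate(
            t.morph,
            t.inflection_nm + rng.normal(0, t.shell_inflection_sd_nm),
            t.steepness_per_nm,
            t.max_reflectance_pct * (1 + rng.normal(0, t.shell_scale_sd)),
            t.shoulder_pct,
        )
        base = shell_t.curve(grid)
        for rep in (1, 2, 3):
            jitter = 1 + rng.normal(0, t.replicate_jitter_sd)
            values = base * jitter + rng.normal(0, t.noise_sd_pct, len(grid))
            out.append(
                ReflectanceSpectrum(rec.shell_id, rep, grid.copy(), np.clip(values, 0, 100))
            )
    return out
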