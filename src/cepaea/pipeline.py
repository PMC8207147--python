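"""End-to-end orchestration: survey tables (and optional spectra) in,
change/cline/era-comparison tables out.

The pipeline mirrors the analysis of a two-era altitudinal survey:

1. read the site table; optionally read, bin and replicate-average
   reflectance spectra and convert them to CIE coordinates + PCA scores;
2. per-site morph frequencies (sites with < ``min_site_n`` shells drop);
3. pair past and present sites within ``max_dist_m``; valley-level paired
   change tests and ±threshold direction counts;
4. altitudinal correlations per valley × era and Fisher r-to-z era
   comparison.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .clines import clines_table, compare_eras, comparison_table
from .colorimetry import (
    ObserverModel,
    chromatic_axis_scores,
    coordinates_table,
    fit_color_pca,
    pca_report,
    tristimulus,
)
from .morph_stats import pair_sites, site_frequencies, valley_change_table
from .spectra import preprocess_spectra, read_sites, read_spectra
from .types import BANDINGS, COLORS

log = logging.getLogger(__name__)

DEFAULT_VARIABLES = list(COLORS) + list(BANDINGS) + ["pale_lip"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run depends on."""

    sites: str
    outdir: str
    spectra: str | None = None
    spectra_dialect: str = "long"
    past_era: str = "past"
    present_era: str = "present"
    min_site_n: int = 10
    max_dist_m: float = 50.0
    threshold_pct: float = 3.0
    alpha: float = 0.05
    pca_basis: str = "xyz"
    variables: list[str] = field(default_factory=lambda: list(DEFAULT_VARIABLES))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_site_n", "max_dist_m", "threshold_pct", "alpha"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.pca_basis not in ("xyz", "XYZ"):
            raise ConfigError(f"pca_basis must be 'xyz' or 'XYZ', not {self.pca_basis!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**cfg)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(cfg),
        "outputs": [],
        "notes": [],
    }

    sites = read_sites(cfg.sites)
    freq = site_frequencies(sites, cfg.min_site_n)
    _emit(freq, outdir / "site_frequencies.csv", manifest)

    if cfg.spectra:
        _run_colorimetry(cfg, sites, outdir, manifest)
    else:
        manifest["notes"].append("no spectra supplied; colorimetry stage skipped")

    past = freq[freq["era"] == cfg.past_era]
    present = freq[freq["era"] == cfg.present_era]
    pairs_by_valley = {
        valley: pair_sites(
            past[past["valley"] == valley],
            present[present["valley"] == valley],
            cfg.max_dist_m,
        )
        for valley in sorted(freq["valley"].unique())
    }
    changes, directions = valley_change_table(
        freq, pairs_by_valley, cfg.past_era, cfg.present_era,
        threshold_pct=cfg.threshold_pct,
    )
    _emit(changes, outdir / "valley_changes.csv", manifest)
    _emit(directions, outdir / "direction_counts.csv", manifest)

    clines, comparisons = compare_eras(
        freq, cfg.past_era, cfg.present_era, cfg.variables, cfg.alpha
    )
    _emit(clines_table(clines), outdir / "clines.csv", manifest)
    _emit(comparison_table(comparisons), outdir / "era_comparison.csv", manifest)
    manifest["cline_details"] = [
        {
            "valley": c.valley, "variable": c.variable, "era": c.era,
            "method": c.method, "coefficient_r": c.coefficient_r,
            "raw_tau": c.raw_tau, "n": c.n_units, "p_value": c.p_value,
            "outliers_removed": c.outliers_removed,
        }
        for c in clines
    ]

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %s", manifest_path)
    return manifest


def _run_colorimetry(cfg: RunConfig, sites, outdir: Path, manifest: dict) -> None:
    specs = read_spectra(cfg.spectra, cfg.spectra_dialect)
    averaged = preprocess_spectra(specs)
    obs = ObserverModel.default()
    coords = [tristimulus(s, obs) for s in averaged]
    labels_by_shell = {
        shell.shell_id: shell.color for site in sites for shell in site.shells
    }
    labels = [labels_by_shell.get(c.shell_id) for c in coords]
    model = fit_color_pca(
        coords, cfg.pca_basis,
        labels=labels if all(l is not None for l in labels) else None,
    )
    chromatic_axis_scores(model, coords)  # ensures designation is usable
    _emit(coordinates_table(coords), outdir / "shell_colorimetry.csv", manifest)
    (outdir / "pca_report.json").write_text(json.dumps(pca_report(model), indent=2))
    manifest["outputs"].append("pca_report.json")


def _emit(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"].append(path.name)
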