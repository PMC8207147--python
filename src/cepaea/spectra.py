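"""Reading, binning and replicate-averaging of reflectance spectra, plus
site-survey table I/O.

Spectrometers deliver reflectance on irregular pixel grids (e.g. 2048
pixels over 178-878 nm). Before colorimetry every spectrum is binned to
the canonical 300-700 nm grid at 1 nm and the three non-consecutive
replicate measurements of each shell are averaged. Binning happens before
averaging so that replicates recorded in different calibration sessions,
which need not share a raw pixel grid, can still be combined.

Two spectra CSV dialects are supported:

``long``
    columns ``shell_id,replicate,wavelength_nm,reflectance_pct`` (canonical).
``wide``
    one ``wavelength_nm`` column plus one column per measurement named
    ``<shell_id>_<replicate>`` (e.g. ``V01-003_2``).
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BANDINGS,
    CANONICAL_GRID,
    COLORS,
    LIPS,
    CoverageError,
    ReflectanceSpectrum,
    ShellRecord,
    SiteSample,
    SpectrumError,
)

log = logging.getLogger(__name__)

SITE_COLUMNS = [
    "site_id", "valley", "lat", "lon", "altitude_m", "era",
    "shell_id", "color", "banding", "lip", "height_mm", "width_mm",
]


def bin_spectrum(
    s: ReflectanceSpectrum,
    lo: int = 300,
    hi: int = 700,
    step: int = 1,
) -> ReflectanceSpectrum:
    """Bin a raw spectrum onto the regular ``lo..hi`` grid (1 nm default).

    A raw point at wavelength ``w`` belongs to the bin nearest to ``w``;
    each bin value is the mean of its raw points. Bins that receive no
    raw point are filled by linear interpolation between filled
    neighbours. Negative reflectance (instrument noise) is clipped to 0.

    Raises
    ------
    CoverageError
        if the input grid does not cover ``[lo, hi]`` (the message names
        the uncovered side).
    """
    grid = np.arange(lo, hi + step, step, dtype=float)
    w = s.wavelength_nm
    half = step / 2.0
    if w[0] > lo + half or w[-1] < hi - half:
        gaps = []
        if w[0] > lo + half:
            gaps.append(f"[{lo}, {w[0]:.1f}) nm uncovered at the short-wave end")
        if w[-1] < hi - half:
            gaps.append(f"({w[-1]:.1f}, {hi}] nm uncovered at the long-wave end")
        raise CoverageError(
            f"shell {s.shell_id!r}: spectrum spans {w[0]:.1f}-{w[-1]:.1f} nm, "
            + "; ".join(gaps)
        )

    idx = np.rint((w - lo) / step).astype(int)
    keep = (idx >= 0) & (idx < len(grid))
    sums = np.bincount(idx[keep], weights=s.reflectance_pct[keep], minlength=len(grid))
    counts = np.bincount(idx[keep], minlength=len(grid))
    filled = counts > 0
    values = np.full(len(grid), np.nan)
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        values[~filled] = np.interp(grid[~filled], grid[filled], values[filled])
    values = np.clip(values, 0.0, None)
    return ReflectanceSpectrum(s.shell_id, s.replicate, grid, values)


def average_replicates(specs: list[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean of replicate spectra of one shell.

    All inputs must share ``shell_id`` and an identical (binned) grid.
    The result carries ``replicate = 0``, meaning "averaged". Shells are
    normally measured three times; any other replicate count is accepted
    with a warning.
    """
    if not specs:
        raise SpectrumError("average_replicates: no spectra given")
    first = specs[0]
    for s in specs[1:]:
        if s.shell_id != first.shell_id:
            raise SpectrumError(
                f"replicates mix shells {first.shell_id!r} and {s.shell_id!r}"
            )
        if not np.array_equal(s.wavelength_nm, first.wavelength_nm):
            raise SpectrumError(
                f"shell {first.shell_id!r}: replicate grids differ; bin first"
            )
    if len(specs) != 3:
        warnings.warn(
            f"shell {first.shell_id!r}: averaging {len(specs)} replicates "
            "(3 expected)",
            stacklevel=2,
        )
    mean = np.mean([s.reflectance_pct for s in specs], axis=0)
    return ReflectanceSpectrum(first.shell_id, 0, first.wavelength_nm.copy(), mean)


def read_spectra(path: str | Path, dialect: str = "long") -> list[ReflectanceSpectrum]:
    """Read reflectance spectra from CSV (see module docstring for dialects)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas detail
        raise SpectrumError(f"{path}: cannot parse CSV: {exc}") from exc
    if dialect == "long":
        return _spectra_from_long(df, path)
    if dialect == "wide":
        return _spectra_from_wide(df, path)
    raise ValueError(f"unknown spectra dialect {dialect!r}")


def _require_numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectrumError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, "
            f"data row {row}"
        )
    return values.to_numpy(dtype=float)


def _spectra_from_long(df: pd.DataFrame, path: Path) -> list[ReflectanceSpectrum]:
    missing = {"shell_id", "replicate", "wavelength_nm", "reflectance_pct"} - set(
        df.columns
    )
    if missing:
        raise SpectrumError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.copy()
    df["wavelength_nm"] = _require_numeric(df, "wavelength_nm", path)
    df["reflectance_pct"] = _require_numeric(df, "reflectance_pct", path)
    out = []
    for (shell_id, replicate), grp in df.groupby(["shell_id", "replicate"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        w = grp["wavelength_nm"].to_numpy()
        if len(np.unique(w)) != len(w):
            dup = w[np.flatnonzero(np.diff(w) == 0)[0]]
            raise SpectrumError(
                f"{path}: shell {shell_id!r} replicate {replicate}: duplicate "
                f"wavelength {dup:g} nm"
            )
        out.append(
            ReflectanceSpectrum(
                str(shell_id), int(replicate), w, grp["reflectance_pct"].to_numpy()
            )
        )
    return out


def _spectra_from_wide(df: pd.DataFrame, path: Path) -> list[ReflectanceSpectrum]:
    if "wavelength_nm" not in df.columns:
        raise SpectrumError(f"{path}: wide dialect needs a 'wavelength_nm' column")
    meas_cols = [c for c in df.columns if c != "wavelength_nm"]
    if not meas_cols:
        raise SpectrumError(f"{path}: no measurement columns (reflectance absent)")
    w = _require_numeric(df, "wavelength_nm", path)
    order = np.argsort(w)
    w = w[order]
    if len(np.unique(w)) != len(w):
        raise SpectrumError(f"{path}: duplicate wavelengths in 'wavelength_nm'")
    out = []
    for col in meas_cols:
        shell_id, sep, rep = col.rpartition("_")
        if not sep or not rep.isdigit():
            raise SpectrumError(
                f"{path}: measurement column {col!r} is not '<shell_id>_<replicate>'"
            )
        out.append(
            ReflectanceSpectrum(
                shell_id, int(rep), w, _require_numeric(df, col, path)[order]
            )
        )
    return out


def write_spectra(specs: list[ReflectanceSpectrum], path: str | Path) -> None:
    """Write spectra as canonical long CSV."""
    frames = [
        pd.DataFrame(
            {
                "shell_id": s.shell_id,
                "replicate": s.replicate,
                "wavelength_nm": s.wavelength_nm,
                "reflectance_pct": s.reflectance_pct,
            }
        )
        for s in specs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def group_by_shell(specs: list[ReflectanceSpectrum]) -> dict[str, list[ReflectanceSpectrum]]:
    """Group spectra by shell_id, preserving replicate order."""
    groups: dict[str, list[ReflectanceSpectrum]] = {}
    for s in sorted(specs, key=lambda s: (s.shell_id, s.replicate)):
        groups.setdefault(s.shell_id, []).append(s)
    return groups


def preprocess_spectra(
    specs: list[ReflectanceSpectrum],
    lo: int = 300,
    hi: int = 700,
) -> list[ReflectanceSpectrum]:
    """Bin every spectrum to the canonical grid and average replicates.

    Returns one averaged spectrum per shell, sorted by shell_id.
    """
    out = []
    for shell_id, group in group_by_shell(specs).items():
        binned = [bin_spectrum(s, lo, hi) for s in group]
        out.append(average_replicates(binned))
    return out


# ---------------------------------------------------------------------------
# Site survey tables

def read_sites(path: str | Path) -> list[SiteSample]:
    """Read a site survey table (one row per shell) into SiteSamples."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SITE_COLUMNS[:6] + SITE_COLUMNS[7:10]) - set(df.columns)
    if missing:
        raise SpectrumError(f"{path}: missing column(s) {sorted(missing)}")
    sites: dict[tuple[str, str], SiteSample] = {}
    for row_i, row in enumerate(df.itertuples(index=False)):
        key = (str(row.site_id), str(row.era))
        try:
            if key not in sites:
                sites[key] = SiteSample(
                    site_id=str(row.site_id),
                    valley=str(row.valley),
                    latitude=float(row.lat),
                    longitude=float(row.lon),
                    altitude_m=float(row.altitude_m),
                    era=str(row.era),
                )
            shell_id = str(getattr(row, "shell_id", "")) or f"{row.site_id}-{row_i}"
            height = getattr(row, "height_mm", None)
            width = getattr(row, "width_mm", None)
            sites[key].shells.append(
                ShellRecord(
                    shell_id=shell_id,
                    color=str(row.color),
                    banding=str(row.banding),
                    lip=str(row.lip),
                    height_mm=None if pd.isna(height) else float(height),
                    width_mm=None if pd.isna(width) else float(width),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SpectrumError(f"{path}: data row {row_i}: {exc}") from exc
    return list(sites.values())


def write_sites(sites: list[SiteSample], path: str | Path) -> None:
    """Write SiteSamples as a one-row-per-shell CSV (the canonical dialect)."""
    rows = []
    for site in sites:
        for shell in site.shells:
            rows.append(
                {
                    "site_id": site.site_id,
                    "valley": site.valley,
                    "lat": site.latitude,
                    "lon": site.longitude,
                    "altitude_m": site.altitude_m,
                    "era": site.era,
                    "shell_id": shell.shell_id,
                    "color": shell.color,
                    "banding": shell.banding,
                    "lip": shell.lip,
                    "height_mm": shell.height_mm,
                    "width_mm": shell.width_mm,
                }
            )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)
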