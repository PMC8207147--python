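"""Core domain types shared across the package.

The objects here mirror the things a field survey of *Cepaea nemoralis*
actually produces: reflectance spectra measured on individual shells,
human-scored shell phenotypes, and dated site collections along a valley.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Shell ground-colour categories used in all qualitative scoring.
COLORS = ("yellow", "pink", "brown")
#: Banding categories: unbanded (00000), midbanded (00300), banded (the rest).
BANDINGS = ("unbanded", "midbanded", "banded")
#: Lip colour: pale (usually white) versus any other (usually dark) colour.
LIPS = ("pale", "other")

#: Canonical wavelength grid for colorimetry, nm.
GRID_LO = 300
GRID_HI = 700
CANONICAL_GRID = np.arange(GRID_LO, GRID_HI + 1, dtype=float)


class SpectrumError(ValueError):
    """Malformed or incompatible reflectance spectrum."""


class CoverageError(SpectrumError):
    """Input spectrum does not cover the requested wavelength window."""


@dataclass
class ReflectanceSpectrum:
    """One reflectance measurement of one shell.

    Reflectance is expressed as percent of a white standard. Negative
    values can occur as instrument noise on dark shells; they are kept on
    input and clipped to zero during binning, before any colorimetry.

    ``replicate`` is 1-3 for raw measurements and 0 for a replicate
    average.
    """

    shell_id: str
    replicate: int
    wavelength_nm: np.ndarray
    reflectance_pct: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.reflectance_pct.ndim != 1:
            raise SpectrumError("wavelength and reflectance must be 1-D")
        if len(self.wavelength_nm) != len(self.reflectance_pct):
            raise SpectrumError(
                f"shell {self.shell_id!r}: {len(self.wavelength_nm)} wavelengths "
                f"but {len(self.reflectance_pct)} reflectance values"
            )
        if len(self.wavelength_nm) and np.any(np.diff(self.wavelength_nm) <= 0):
            raise SpectrumError(
                f"shell {self.shell_id!r}: wavelength grid not strictly increasing"
            )
        if not np.all(np.isfinite(self.reflectance_pct)):
            raise SpectrumError(f"shell {self.shell_id!r}: non-finite reflectance")

    @property
    def on_canonical_grid(self) -> bool:
        return (
            len(self.wavelength_nm) == len(CANONICAL_GRID)
            and bool(np.array_equal(self.wavelength_nm, CANONICAL_GRID))
        )


@dataclass
class ShellRecord:
    """Human-scored phenotype of a single shell."""

    shell_id: str
    color: str
    banding: str
    lip: str
    height_mm: float | None = None
    width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown colour {self.color!r}; expected one of {COLORS}")
        if self.banding not in BANDINGS:
            raise ValueError(
                f"unknown banding {self.banding!r}; expected one of {BANDINGS}"
            )
        if self.lip not in LIPS:
            raise ValueError(f"unknown lip {self.lip!r}; expected one of {LIPS}")
        for name in ("height_mm", "width_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def shape(self) -> float | None:
        """Shell shape H/W (spire tallness); None when a measure is missing."""
        if self.height_mm is None or self.width_mm is None:
            return None
        return self.height_mm / self.width_mm


@dataclass
class SiteSample:
    """All shells collected at one georeferenced site in one era."""

    site_id: str
    valley: str
    latitude: float
    longitude: float
    altitude_m: float
    era: str
    shells: list[ShellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.altitude_m <= 4000:
            raise ValueError(
                f"site {self.site_id!r}: altitude {self.altitude_m} m outside [0, 4000]"
            )

    @property
    def n(self) -> int:
        return len(self.shells)

    def is_analyzable(self, min_site_n: int = 10) -> bool:
        """A site enters the analysis only with at least ``min_site_n`` shells."""
        return self.n >= min_site_n


def as_float_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of numbers")
    return arr
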