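"""Human trichromatic colorimetry of shell reflectance spectra.

A binned reflectance spectrum R(λ) (fraction of a white standard) viewed
under an illuminant I(λ) stimulates the three human cone classes; the CIE
1931 2° standard observer summarises those quantum catches as the
colour-matching functions x̄, ȳ, z̄. Tristimulus values are

    X = k · Σ R(λ) I(λ) x̄(λ),   Y = k · Σ R(λ) I(λ) ȳ(λ),
    Z = k · Σ R(λ) I(λ) z̄(λ),   k = 100 / Σ I(λ) ȳ(λ),

summed over the 300-700 nm grid at 1 nm, so a perfect reflector has
Y = 100 exactly. Chromaticity coordinates x = X/(X+Y+Z) etc. discard
intensity and keep hue/saturation; a PCA of the per-shell coordinates
then yields the principal chromatic axes, one of which separates the
yellow from the pink shells.

The packaged observer tables are the published CIE 1931 2° colour-matching
functions and the D65 daylight spectral power distribution, both at 5 nm
and linearly interpolated to 1 nm. The colour-matching functions are zero
below 380 nm, so the 300-380 nm band of the grid contributes nothing to
the integrals; it is retained because reflectance is recorded from 300 nm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CANONICAL_GRID, ReflectanceSpectrum, SpectrumError


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("cepaea.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def _interp_to_grid(wl: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # outside the published support the curve is 0, not extrapolated
    return np.interp(grid, wl, values, left=0.0, right=0.0)


@dataclass
class ObserverModel:
    """CIE standard observer + illuminant sampled on the canonical grid."""

    wavelength_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    illuminant: np.ndarray
    name: str = "CIE 1931 2deg / D65"

    @classmethod
    def default(cls) -> "ObserverModel":
        """CIE 1931 2° observer under D65 daylight, 300-700 nm at 1 nm."""
        grid = CANONICAL_GRID
        cmf = _load_table("cie1931_2deg_cmf_5nm.csv")
        d65 = _load_table("illuminant_d65_5nm.csv")
        wl = cmf["wavelength_nm"].to_numpy(dtype=float)
        return cls(
            wavelength_nm=grid.copy(),
            xbar=_interp_to_grid(wl, cmf["xbar"].to_numpy(dtype=float), grid),
            ybar=_interp_to_grid(wl, cmf["ybar"].to_numpy(dtype=float), grid),
            zbar=_interp_to_grid(wl, cmf["zbar"].to_numpy(dtype=float), grid),
            illuminant=_interp_to_grid(
                d65["wavelength_nm"].to_numpy(dtype=float),
                d65["power"].to_numpy(dtype=float),
                grid,
            ),
        )

    @classmethod
    def equal_energy(cls) -> "ObserverModel":
        """Same observer under the equal-energy illuminant (I ≡ 1)."""
        obs = cls.default()
        obs.illuminant = np.ones_like(obs.wavelength_nm)
        obs.name = "CIE 1931 2deg / equal-energy"
        return obs

    @property
    def normalization(self) -> float:
        """k such that a perfect reflector has Y = 100."""
        return 100.0 / float(np.sum(self.illuminant * self.ybar))


@dataclass
class ColorCoordinates:
    """Tristimulus (XYZ), chromaticity (xyz) and PCA scores of one shell."""

    shell_id: str
    X: float
    Y: float
    Z: float
    x: float
    y: float
    z: float
    chromaticity_defined: bool = True
    pc_scores: np.ndarray | None = None

    def basis_vector(self, basis: str) -> np.ndarray:
        if basis == "xyz":
            return np.array([self.x, self.y, self.z])
        if basis == "XYZ":
            return np.array([self.X, self.Y, self.Z])
        raise ValueError(f"unknown basis {basis!r}; use 'xyz' or 'XYZ'")


def tristimulus(s: ReflectanceSpectrum, obs: ObserverModel) -> ColorCoordinates:
    """CIE tristimulus and chromaticity of a binned reflectance spectrum.

    The spectrum must be on the observer's grid, in percent reflectance.
    An all-zero spectrum yields X = Y = Z = 0 with chromaticity flagged
    undefined (set to NaN).
    """
    if not np.array_equal(s.wavelength_nm, obs.wavelength_nm):
        raise SpectrumError(
            f"shell {s.shell_id!r}: spectrum grid does not match observer grid; "
            "bin to 300-700 nm at 1 nm first"
        )
    R = s.reflectance_pct / 100.0
    k = obs.normalization
    X = k * float(np.sum(R * obs.illuminant * obs.xbar))
    Y = k * float(np.sum(R * obs.illuminant * obs.ybar))
    Z = k * float(np.sum(R * obs.illuminant * obs.zbar))
    total = X + Y + Z
    if total > 0:
        return ColorCoordinates(s.shell_id, X, Y, Z, X / total, Y / total, Z / total)
    return ColorCoordinates(
        s.shell_id, X, Y, Z, np.nan, np.nan, np.nan, chromaticity_defined=False
    )


@dataclass
class PcaModel:
    """Centred (covariance) PCA of per-shell colour coordinates.

    ``components`` rows are the orthonormal loading vectors PC1..PC3;
    ``chromatic_axis`` is the index (0-based) of the axis designated as
    the yellow-pink separator.
    """

    basis: str
    mean: np.ndarray
    components: np.ndarray
    explained_variance_fraction: np.ndarray
    chromatic_axis: int = field(default=-1)

    def transform(self, coords: list[ColorCoordinates]) -> np.ndarray:
        data = np.array([c.basis_vector(self.basis) for c in coords])
        return (data - self.mean) @ self.components.T


_RANK_EPS = 1e-9


def fit_color_pca(
    coords: list[ColorCoordinates],
    basis: str = "xyz",
    labels: list[str] | None = None,
) -> PcaModel:
    """Fit a centred PCA to shell colour coordinates and score the shells.

    The PCA is covariance-based (no variance scaling: the coordinates
    share units). Scores are written back onto each ``ColorCoordinates``.

    Axis designation and sign. The axis that separates yellow from pink
    shells is identified from human-scored ``labels`` when given (largest
    standardised yellow-pink mean difference in scores); its sign is fixed
    so yellow shells score positive on it. Without labels the last axis
    with non-negligible variance is designated and every axis's
    largest-magnitude loading is made positive. Note that exact
    chromaticity satisfies x+y+z = 1, so under the ``"xyz"`` basis the
    data are rank-2 and the third axis carries zero variance.
    """
    if len(coords) < 3:
        raise ValueError(f"PCA needs at least 3 shells, got {len(coords)}")
    data = np.array([c.basis_vector(basis) for c in coords])
    if np.isnan(data).any():
        raise ValueError("undefined chromaticity among inputs; filter these shells")
    n, p = data.shape
    if n <= p:
        warnings.warn(
            f"only {n} shells for {p} dimensions; axes beyond rank have 0 variance",
            stacklevel=2,
        )
    mean = data.mean(axis=0)
    centred = data - mean
    # SVD of the centred data == eigendecomposition of the covariance
    _, svals, vt = np.linalg.svd(centred, full_matrices=True)
    var = np.zeros(p)
    var[: len(svals)] = svals**2 / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else var
    components = vt

    scores = centred @ components.T
    axis = _designate_axis(scores, frac, labels)
    for j in range(p):
        if labels is not None and j == axis:
            continue
        if components[j, np.argmax(np.abs(components[j]))] < 0:
            components[j] = -components[j]
    if labels is not None:
        yellow = np.asarray(labels) == "yellow"
        if yellow.any() and scores[yellow, axis].mean() < 0:
            components[axis] = -components[axis]

    model = PcaModel(basis, mean, components, frac, chromatic_axis=axis)
    final = model.transform(coords)
    for c, row in zip(coords, final):
        c.pc_scores = row
    return model


def _designate_axis(
    scores: np.ndarray, frac: np.ndarray, labels: list[str] | None
) -> int:
    if labels is not None:
        lab = np.asarray(labels)
        yellow, pink = lab == "yellow", lab == "pink"
        if yellow.any() and pink.any():
            sep = np.zeros(scores.shape[1])
            for j in range(scores.shape[1]):
                spread = np.sqrt(scores[yellow, j].var() + scores[pink, j].var())
                sep[j] = abs(scores[yellow, j].mean() - scores[pink, j].mean()) / (
                    spread + 1e-12
                )
            return int(np.argmax(sep))
    informative = np.flatnonzero(frac > _RANK_EPS)
    return int(informative[-1]) if len(informative) else 0


def chromatic_axis_scores(
    model: PcaModel, coords: list[ColorCoordinates]
) -> np.ndarray:
    """Scores of shells on the designated yellow-pink chromatic axis."""
    if model.chromatic_axis < 0:
        raise RuntimeError("PCA model has no designated chromatic axis; fit first")
    return model.transform(coords)[:, model.chromatic_axis]


def coordinates_table(coords: list[ColorCoordinates]) -> pd.DataFrame:
    """Per-shell colour coordinates as a tidy DataFrame."""
    rows = []
    for c in coords:
        row = {
            "shell_id": c.shell_id,
            "X": c.X, "Y": c.Y, "Z": c.Z,
            "x": c.x, "y": c.y, "z": c.z,
        }
        if c.pc_scores is not None:
            for j, s in enumerate(c.pc_scores, start=1):
                row[f"pc{j}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def pca_report(model: PcaModel) -> dict:
    """JSON-serialisable summary of a fitted PCA."""
    return {
        "basis": model.basis,
        "mean": model.mean.tolist(),
        "loadings": model.components.tolist(),
        "explained_variance_fraction": model.explained_variance_fraction.tolist(),
        "chromatic_axis": int(model.chromatic_axis) + 1,
    }
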