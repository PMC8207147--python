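import io
import warnings

import numpy as np
import pandas as pd
import pytest

from cepaea import (
    CANONICAL_GRID,
    ReflectanceSpectrum,
    average_replicates,
    bin_spectrum,
    read_sites,
    read_spectra,
    write_sites,
    write_spectra,
)
from cepaea.types import CoverageError, SpectrumError


def make_spectrum(wavelengths, values, shell_id="s1", replicate=1):
    return ReflectanceSpectrum(shell_id, replicate, np.asarray(wavelengths, float),
                               np.asarray(values, float))


class TestReadWrite:
    def test_long_roundtrip_preserves_everything(self, tmp_path):
        w = np.linspace(178.0, 878.0, 2048)
        specs = [make_spectrum(w, 50 + 10 * np.sin(w / 40), "V01-003", r)
                 for r in (1, 2, 3)]
        path = tmp_path / "spectra.csv"
        write_spectra(specs, path)
        back = read_spectra(path)
        assert len(back) == 3
        assert {s.shell_id for s in back} == {"V01-003"}
        assert sorted(s.replicate for s in back) == [1, 2, 3]
        for a, b in zip(specs, back):
            np.testing.assert_array_equal(a.wavelength_nm, b.wavelength_nm)
            np.testing.assert_array_equal(a.reflectance_pct, b.reflectance_pct)

    def test_wide_dialect(self, tmp_path):
        df = pd.DataFrame({
            "wavelength_nm": [400.0, 500.0, 600.0],
            "A_1": [10.0, 20.0, 30.0],
            "A_2": [11.0, 21.0, 31.0],
        })
        path = tmp_path / "wide.csv"
        df.to_csv(path, index=False)
        specs = read_spectra(path, dialect="wide")
        assert [(s.shell_id, s.replicate) for s in specs] == [("A", 1), ("A", 2)]

    def test_missing_reflectance_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("shell_id,replicate,wavelength_nm\na,1,400\n")
        with pytest.raises(SpectrumError, match="missing column"):
            read_spectra(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "shell_id,replicate,wavelength_nm,reflectance_pct\n"
            "a,1,400,10\na,1,410,oops\n"
        )
        with pytest.raises(SpectrumError, match="row 1"):
            read_spectra(path)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "shell_id,replicate,wavelength_nm,reflectance_pct\n"
            "a,1,400,10\na,1,400,11\n"
        )
        with pytest.raises(SpectrumError, match="duplicate"):
            read_spectra(path)


class TestBinning:
    def test_flat_spectrum_invariant_on_fine_grid(self):
        w = np.arange(290.0, 710.0, 0.37)
        out = bin_spectrum(make_spectrum(w, np.full(len(w), 50.0)))
        np.testing.assert_array_equal(out.wavelength_nm, CANONICAL_GRID)
        np.testing.assert_allclose(out.reflectance_pct, 50.0)

    def test_linear_spectrum_recovered(self):
        w = np.arange(250.0, 750.0, 0.37)
        out = bin_spectrum(make_spectrum(w, w / 10))
        assert np.max(np.abs(out.reflectance_pct - CANONICAL_GRID / 10)) < 0.5

    def test_negative_bin_clipped_to_zero(self):
        w = CANONICAL_GRID.copy()
        v = np.full(401, 10.0)
        v[100] = -0.3
        out = bin_spectrum(make_spectrum(w, v))
        assert out.reflectance_pct[100] == 0.0

    def test_identity_on_canonical_grid(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 100, 401)
        out = bin_spectrum(make_spectrum(CANONICAL_GRID, v))
        np.testing.assert_array_equal(out.reflectance_pct, v)

    def test_coverage_error_names_gap(self):
        w = np.arange(400.0, 710.0)
        with pytest.raises(CoverageError, match="short-wave"):
            bin_spectrum(make_spectrum(w, np.full(len(w), 5.0)))

    def test_empty_bins_filled_by_interpolation(self):
        w = np.array([300.0, 400.0, 700.0])  # huge gaps on a 1 nm grid
        out = bin_spectrum(make_spectrum(w, [0.0, 100.0, 100.0]))
        assert out.reflectance_pct[50] == pytest.approx(50.0)  # 350 nm midpoint


class TestAverageReplicates:
    def test_idempotent_on_identical_replicates(self):
        s = [make_spectrum(CANONICAL_GRID, np.full(401, 42.0), replicate=r)
             for r in (1, 2, 3)]
        out = average_replicates(s)
        assert out.replicate == 0
        np.testing.assert_array_equal(out.reflectance_pct, 42.0 * np.ones(401))

    def test_pointwise_mean(self):
        s = [make_spectrum(CANONICAL_GRID, np.full(401, v), replicate=r)
             for r, v in ((1, 10.0), (2, 20.0), (3, 30.0))]
        assert average_replicates(s).reflectance_pct[0] == pytest.approx(20.0)

    def test_two_replicates_warns(self):
        s = [make_spectrum(CANONICAL_GRID, np.full(401, v), replicate=r)
             for r, v in ((1, 10.0), (2, 20.0))]
        with pytest.warns(UserWarning, match="2 replicates"):
            out = average_replicates(s)
        assert out.reflectance_pct[0] == pytest.approx(15.0)

    def test_mismatched_grids_rejected(self):
        a = make_spectrum(CANONICAL_GRID, np.zeros(401))
        b = make_spectrum(CANONICAL_GRID[:-1], np.zeros(400), replicate=2)
        with pytest.raises(SpectrumError, match="grids differ"):
            average_replicates([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(SpectrumError, match="no spectra"):
            average_replicates([])

    def test_commutes_with_binning_on_common_grid(self):
        rng = np.random.default_rng(1)
        w = np.arange(295.0, 706.0, 0.5)
        raws = [make_spectrum(w, rng.uniform(5, 95, len(w)), replicate=r)
                for r in (1, 2, 3)]
        bin_then_avg = average_replicates([bin_spectrum(s) for s in raws])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            avg_then_bin = bin_spectrum(average_replicates(raws))
        assert np.max(np.abs(bin_then_avg.reflectance_pct
                             - avg_then_bin.reflectance_pct)) < 1e-9


class TestSiteTables:
    def test_roundtrip(self, tmp_path, default_survey):
        past, present, _ = default_survey
        path = tmp_path / "sites.csv"
        write_sites(past + present, path)
        back = read_sites(path)
        assert len(back) == len(past) + len(present)
        orig = {(s.site_id, s.era): s for s in past + present}
        for site in back:
            o = orig[(site.site_id, site.era)]
            assert site.n == o.n
            assert site.altitude_m == pytest.approx(o.altitude_m)
            assert [s.color for s in site.shells] == [s.color for s in o.shells]

    def test_bad_category_reports_row(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text(
            "site_id,valley,lat,lon,altitude_m,era,shell_id,color,banding,lip,height_mm,width_mm\n"
            "s1,V,42.6,0.75,1000,past,a,chartreuse,banded,pale,18,21\n"
        )
        with pytest.raises(SpectrumError, match="row 0"):
            read_sites(path)
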