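import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cepaea import (
    CANONICAL_GRID,
    ObserverModel,
    ReflectanceSpectrum,
    chromatic_axis_scores,
    fit_color_pca,
    tristimulus,
)
from cepaea.colorimetry import ColorCoordinates, PcaModel
from cepaea.types import SpectrumError


def spectrum(values, shell_id="s"):
    return ReflectanceSpectrum(shell_id, 0, CANONICAL_GRID, np.asarray(values, float))


class TestTristimulus:
    def test_perfect_reflector_hits_d65_white_point(self, observer, white_spectrum):
        c = tristimulus(white_spectrum, observer)
        assert c.Y == pytest.approx(100.0, abs=1e-12)
        # white point computed directly from the same embedded tables
        wx = np.sum(observer.illuminant * observer.xbar)
        wy = np.sum(observer.illuminant * observer.ybar)
        wz = np.sum(observer.illuminant * observer.zbar)
        assert c.x == pytest.approx(wx / (wx + wy + wz), abs=1e-12)
        assert c.y == pytest.approx(wy / (wx + wy + wz), abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1.0))
    @settings(deadline=None, max_examples=25)
    def test_chromaticity_scale_invariant(self, observer, white_spectrum, scale):
        full = tristimulus(white_spectrum, observer)
        half = tristimulus(spectrum(white_spectrum.reflectance_pct * scale), observer)
        assert half.x == pytest.approx(full.x, abs=1e-12)
        assert half.y == pytest.approx(full.y, abs=1e-12)
        assert half.Y == pytest.approx(scale * full.Y, rel=1e-12)

    def test_equal_energy_white_point(self, white_spectrum):
        c = tristimulus(white_spectrum, ObserverModel.equal_energy())
        for coord in (c.x, c.y, c.z):
            assert coord == pytest.approx(1 / 3, abs=2e-3)

    def test_linearity(self, observer):
        rng = np.random.default_rng(2)
        r1, r2 = rng.uniform(0, 50, 401), rng.uniform(0, 50, 401)
        a, b = 0.6, 1.3
        mix = tristimulus(spectrum(a * r1 + b * r2), observer)
        c1, c2 = tristimulus(spectrum(r1), observer), tristimulus(spectrum(r2), observer)
        assert mix.X == pytest.approx(a * c1.X + b * c2.X, rel=1e-12)
        assert mix.Y == pytest.approx(a * c1.Y + b * c2.Y, rel=1e-12)
        assert mix.Z == pytest.approx(a * c1.Z + b * c2.Z, rel=1e-12)

    def test_zero_spectrum_flagged_undefined(self, observer):
        c = tristimulus(spectrum(np.zeros(401)), observer)
        assert c.X == c.Y == c.Z == 0.0
        assert not c.chromaticity_defined
        assert np.isnan(c.x)

    def test_grid_mismatch_rejected(self, observer):
        s = ReflectanceSpectrum("s", 0, np.arange(400.0, 701.0), np.zeros(301))
        with pytest.raises(SpectrumError, match="grid"):
            tristimulus(s, observer)

    def test_chromaticity_sums_to_one(self, observer):
        rng = np.random.default_rng(3)
        c = tristimulus(spectrum(rng.uniform(1, 99, 401)), observer)
        assert c.x + c.y + c.z == pytest.approx(1.0, abs=1e-9)


def coords_from_points(points):
    return [
        ColorCoordinates(f"p{i}", X=p[0], Y=p[1], Z=p[2], x=p[0], y=p[1], z=p[2])
        for i, p in enumerate(points)
    ]


class TestColorPca:
    def test_planar_data_has_zero_third_fraction(self):
        rng = np.random.default_rng(4)
        ab = rng.normal(size=(50, 2))
        points = ab @ np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        model = fit_color_pca(coords_from_points(points), basis="XYZ")
        assert model.explained_variance_fraction[2] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(5)
        model = fit_color_pca(
            coords_from_points(rng.normal(size=(10000, 3))), basis="XYZ"
        )
        np.testing.assert_allclose(
            model.explained_variance_fraction, [1 / 3, 1 / 3, 1 / 3], atol=0.02
        )

    def test_two_clusters_align_first_axis_with_separation(self):
        rng = np.random.default_rng(6)
        sep = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        points = np.vstack([
            rng.normal(scale=0.05, size=(100, 3)) - 2 * sep,
            rng.normal(scale=0.05, size=(100, 3)) + 2 * sep,
        ])
        model = fit_color_pca(coords_from_points(points), basis="XYZ")
        assert abs(model.components[0] @ sep) > 0.99

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(40, 3))
        coords = coords_from_points(points)
        model = fit_color_pca(coords, basis="XYZ")
        scores = model.transform(coords)
        back = scores @ model.components + model.mean
        np.testing.assert_allclose(back, points, atol=1e-12)

    def test_matches_reference_pca(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(8)
        points = rng.normal(size=(200, 3)) * [3.0, 1.0, 0.3]
        model = fit_color_pca(coords_from_points(points), basis="XYZ")
        ref = sklearn.PCA(n_components=3).fit(points)
        np.testing.assert_allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_,
            atol=1e-10,
        )
        for ours, theirs in zip(model.components, ref.components_):
            assert abs(ours @ theirs) == pytest.approx(1.0, abs=1e-10)

    def test_chromaticity_basis_is_rank_two(self, two_morph_coords):
        coords, labels = two_morph_coords
        model = fit_color_pca(coords, basis="xyz", labels=labels)
        assert len(model.explained_variance_fraction) == 3
        assert model.explained_variance_fraction[2] == pytest.approx(0.0, abs=1e-9)

    def test_yellow_scores_positive_on_designated_axis(self, two_morph_coords):
        coords, labels = two_morph_coords
        model = fit_color_pca(coords, basis="xyz", labels=labels)
        scores = chromatic_axis_scores(model, coords)
        yellow = np.array([l == "yellow" for l in labels])
        assert scores[yellow].mean() > 0

    def test_identical_shells_score_equal(self):
        rng = np.random.default_rng(9)
        base = coords_from_points(rng.normal(size=(20, 3)))
        model = fit_color_pca(base, basis="XYZ")
        clones = coords_from_points(np.tile([[0.3, 0.4, 0.3]], (5, 1)))
        scores = chromatic_axis_scores(model, clones)
        assert np.ptp(scores) == 0.0
        single = chromatic_axis_scores(model, clones[:1])
        assert np.isfinite(single[0])

    def test_unfitted_model_raises(self):
        model = PcaModel("XYZ", np.zeros(3), np.eye(3), np.zeros(3), chromatic_axis=-1)
        with pytest.raises(RuntimeError, match="fit"):
            chromatic_axis_scores(model, coords_from_points(np.zeros((1, 3))))

    def test_too_few_shells_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_color_pca(coords_from_points(np.zeros((2, 3))))
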