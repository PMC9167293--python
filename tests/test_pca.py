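import numpy as np
import pytest

from uvpheno.io import DEFAULT_WAVELENGTHS_NM, SpectralCube
from uvpheno.pca import (
    PCBasis,
    fit_pca,
    fix_signs,
    pool_spectra,
    project_cube,
    to_optical_density,
)
from uvpheno.phantom import EndmemberSet


def brute_force_pca(spectra):
    """Independent oracle: explicit covariance matrix + symmetric eigensolver."""
    x = np.asarray(spectra, dtype=np.float64)
    n, b = x.shape
    mean = x.mean(axis=0)
    cov = np.zeros((b, b))
    for row in x:  # loop-computed covariance, no vectorised shortcut
        d = row - mean
        cov += np.outer(d, d)
    cov /= n - 1
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order].T, mean


def align_signs(loadings, reference):
    """Flip rows of ``loadings`` to match the sign of ``reference`` rows."""
    out = loadings.copy()
    for i in range(out.shape[0]):
        if np.dot(out[i], reference[i]) < 0:
            out[i] = -out[i]
    return out


class TestPoolSpectra:
    def test_counts_without_masks(self):
        rng = np.random.default_rng(0)
        cubes = [SpectralCube(rng.random((10, 10, 4))) for _ in range(2)]
        assert pool_spectra(cubes).shape == (200, 4)

    def test_mask_selects_exact_pixels(self):
        rng = np.random.default_rng(1)
        cube = SpectralCube(rng.random((10, 10, 4)))
        mask = np.zeros((10, 10), bool)
        mask.ravel()[rng.choice(100, 37, replace=False)] = True
        assert pool_spectra([cube], [mask]).shape == (37, 4)

    def test_subsample_is_exact_and_seeded(self):
        rng = np.random.default_rng(2)
        cube = SpectralCube(rng.random((40, 40, 4)))
        a = pool_spectra([cube], max_pixels=100, seed=5)
        b = pool_spectra([cube], max_pixels=100, seed=5)
        c = pool_spectra([cube], max_pixels=100, seed=6)
        assert a.shape == (100, 4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_wavelength_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        c1 = SpectralCube(rng.random((4, 4, 4)))
        c2 = SpectralCube(rng.random((4, 4, 4)), (220, 255, 280, 310))
        with pytest.raises(ValueError, match="wavelength mismatch"):
            pool_spectra([c1, c2])

    def test_no_valid_pixels_rejected(self):
        cube = SpectralCube(np.ones((4, 4, 4)), validity=np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="no valid pixels"):
            pool_spectra([cube])


class TestFitPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(4)
        v = np.array([0.5, 0.5, 0.5, 0.5])
        m = np.array([0.9, 0.6, 0.5, 0.8])
        spectra = m + rng.standard_normal(500)[:, None] * v
        basis = fit_pca(spectra)
        np.testing.assert_allclose(np.abs(basis.loadings[0]), v, atol=1e-10)
        np.testing.assert_allclose(basis.explained_variance_ratio, [1, 0, 0, 0], atol=1e-12)

    def test_three_endmember_mixtures_have_rank_three(self):
        rng = np.random.default_rng(5)
        em = EndmemberSet().matrix()  # 3 x 4
        spectra = rng.random((300, 3)) @ em
        basis = fit_pca(spectra)
        assert basis.explained_variance_ratio[:3].sum() == pytest.approx(1.0, abs=1e-10)
        basis.validate()

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 50), (2, 731), (3, 1000)])
    def test_matches_brute_force_eigendecomposition(self, seed, n):
        rng = np.random.default_rng(seed)
        spectra = rng.random((n, 4))
        basis = fit_pca(spectra)
        evals, loadings, mean = brute_force_pca(spectra)
        np.testing.assert_allclose(basis.mean_spectrum, mean, atol=1e-12)
        np.testing.assert_allclose(
            align_signs(basis.loadings, loadings), loadings, atol=1e-8
        )
        np.testing.assert_allclose(basis.eigenvalues, evals, rtol=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        spectra = rng.random((400, 4))
        b1 = fit_pca(spectra)
        b2 = fit_pca(spectra[rng.permutation(400)])
        np.testing.assert_allclose(b1.loadings, b2.loadings, atol=1e-8)
        np.testing.assert_allclose(
            b1.explained_variance_ratio, b2.explained_variance_ratio, atol=1e-10
        )

    def test_invariants_hold_after_fit(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fit_pca(rng.random((100, 4))).validate()

    def test_rank_deficient_covariance_yields_no_nan(self):
        spectra = np.tile([0.2, 0.4, 0.6, 0.8], (50, 1))  # zero variance
        basis = fit_pca(spectra)
        assert np.isfinite(basis.explained_variance_ratio).all()
        assert np.isfinite(basis.loadings).all()

    def test_optical_density_mode_recorded_and_finite(self):
        rng = np.random.default_rng(7)
        spectra = np.clip(rng.random((200, 4)), 0, None)
        spectra[0] = 0.0  # opaque pixel must not produce inf
        basis = fit_pca(spectra, mode="optical_density")
        assert basis.mode == "optical_density"
        assert np.isfinite(basis.loadings).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="more spectra"):
            fit_pca(np.ones((3, 4)))
        bad = np.ones((10, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_pca(bad)


class TestFixSigns:
    def make_basis(self, loadings):
        return PCBasis(
            loadings=np.asarray(loadings, float),
            mean_spectrum=np.zeros(4),
            explained_variance_ratio=np.array([0.7, 0.2, 0.08, 0.02]),
            wavelengths_nm=DEFAULT_WAVELENGTHS_NM,
            fit_pixel_count=100,
        )

    def test_pc1_made_unipolar_positive(self):
        basis = self.make_basis(-0.5 * np.eye(4) + 0.0)
        basis.loadings[0] = [-0.5, -0.5, -0.5, -0.5]
        fixed = fix_signs(basis)
        np.testing.assert_allclose(fixed.loadings[0], [0.5, 0.5, 0.5, 0.5])

    def test_pc3_nucleic_acid_peak_inverted(self):
        basis = self.make_basis(np.eye(4))
        basis.loadings[2] = [0.1, 0.9, 0.3, 0.3]  # +0.9 at 255 nm -> must flip
        fixed = fix_signs(basis)
        assert fixed.loadings[2, 1] == pytest.approx(-0.9)

    def test_pc2_pc4_protein_peak_positive(self):
        basis = self.make_basis(np.eye(4))
        basis.loadings[1] = [0.2, 0.3, -0.8, 0.1]
        basis.loadings[3] = [0.1, 0.2, -0.6, 0.3]
        fixed = fix_signs(basis)
        assert fixed.loadings[1, 2] > 0 and fixed.loadings[3, 2] > 0

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        basis = fit_pca(rng.random((100, 4)))
        once = fix_signs(basis)
        twice = fix_signs(once)
        np.testing.assert_array_equal(once.loadings, twice.loadings)


class TestProjection:
    @pytest.fixture()
    def basis(self):
        rng = np.random.default_rng(9)
        return fit_pca(rng.random((500, 4)))

    def test_mean_spectrum_projects_to_origin(self, basis):
        cube = SpectralCube(np.tile(basis.mean_spectrum, (4, 4, 1)))
        proj = project_cube(cube, basis, (1, 2, 3))
        np.testing.assert_allclose(proj.data, 0.0, atol=1e-12)

    def test_pure_pc2_pixel(self, basis):
        data = np.tile(basis.mean_spectrum + 2 * basis.loadings[1], (2, 2, 1))
        proj = project_cube(SpectralCube(data), basis, (1, 2, 3))
        np.testing.assert_allclose(proj.data[0, 0], [0, 2, 0], atol=1e-10)

    def test_matches_per_pixel_dot_product_oracle(self, basis):
        rng = np.random.default_rng(10)
        cube = SpectralCube(rng.random((8, 8, 4)))
        proj = project_cube(cube, basis, (2, 3, 4))
        expected = np.empty((8, 8, 3))
        for i in range(8):  # brute-force doubly nested loop
            for j in range(8):
                centered = cube.data[i, j] - basis.mean_spectrum
                for k, pc in enumerate((2, 3, 4)):
                    expected[i, j, k] = float(np.dot(centered, basis.loadings[pc - 1]))
        np.testing.assert_allclose(proj.data, expected, atol=1e-12)

    def test_invalid_pixels_propagate_as_nan(self, basis):
        rng = np.random.default_rng(11)
        validity = np.ones((6, 6), bool)
        validity[0, 0] = False
        cube = SpectralCube(rng.random((6, 6, 4)), validity=validity)
        proj = project_cube(cube, basis)
        assert np.isnan(proj.data[0, 0]).all()
        assert np.isfinite(proj.data[1:]).all()

    def test_wavelength_mismatch_rejected(self, basis):
        cube = SpectralCube(np.ones((4, 4, 4)), (220, 255, 280, 310))
        with pytest.raises(ValueError, match="do not match basis"):
            project_cube(cube, basis)

    def test_triplet_validated(self, basis):
        cube = SpectralCube(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="out of range"):
            project_cube(cube, basis, (1, 2, 5))
        with pytest.raises(ValueError, match="distinct"):
            project_cube(cube, basis, (1, 2, 2))

    def test_uncentered_option(self, basis):
        cube = SpectralCube(np.tile(basis.mean_spectrum, (2, 2, 1)))
        proj = project_cube(cube, basis, center=False)
        expected = basis.mean_spectrum @ basis.loadings[:3].T
        np.testing.assert_allclose(proj.data[0, 0], expected, atol=1e-12)


class TestSerialization:
    def test_basis_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        basis = fit_pca(rng.random((200, 4)), mode="optical_density")
        back = PCBasis.from_json(basis.to_json(tmp_path / "b.json"))
        np.testing.assert_allclose(back.loadings, basis.loadings, atol=1e-15)
        np.testing.assert_allclose(back.mean_spectrum, basis.mean_spectrum, atol=1e-15)
        assert back.mode == "optical_density"
        assert back.fit_pixel_count == 200


def test_optical_density_floor():
    od = to_optical_density(np.array([0.0, 1e-4, 1.0]))
    assert np.isfinite(od).all()
    assert od[0] == od[1] == pytest.approx(4.0)
    assert od[2] == pytest.approx(0.0)
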