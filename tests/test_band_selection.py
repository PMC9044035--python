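"""Band selection: presets, UBS, entropy, FNGBS (vs brute force), PCA."""

import numpy as np
import pytest

from hsileaf import (
    Hypercube,
    MetadataError,
    apply_selection,
    band_entropy,
    fngbs_select,
    pca_reduce,
    preset_bands,
    ubs_select,
)
from hsileaf.wavelengths import default_wavelengths

from reference_impl import bruteforce_entropy, bruteforce_fngbs


class TestPresets:
    def test_rgb_preset_on_canonical_layout(self):
        sel = preset_bands("rgb", 147)
        assert sel.indices.tolist() == [2, 19, 39]

    def test_rgb_nir_is_union_of_both_triplets(self):
        sel = preset_bands("rgb_nir", 147)
        assert sel.m == 6
        assert set(preset_bands("rgb", 147).indices) <= set(sel.indices)
        assert set(preset_bands("nir", 147).indices) <= set(sel.indices)

    def test_noncanonical_layout_without_wavelengths_rejected(self):
        with pytest.raises(MetadataError):
            preset_bands("rgb", 10)

    def test_noncanonical_layout_rederived_by_nearest_wavelength(self):
        wl = np.linspace(450, 900, 20)
        sel = preset_bands("rgb", 20, wavelengths=wl)
        expected = [int(np.argmin(np.abs(wl - t))) + 1
                    for t in (471.44, 535.06, 602.94)]
        assert sel.indices.tolist() == sorted(expected)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_bands("cmyk", 147)


class TestUBS:
    @pytest.mark.parametrize("m,expected", [
        (3, [1, 74, 147]),
        (6, [1, 30, 59, 88, 117, 147]),
        (9, [1, 19, 37, 55, 74, 92, 110, 128, 147]),
    ])
    def test_published_selections_on_147_bands(self, m, expected):
        assert ubs_select(147, m).indices.tolist() == expected

    def test_identity_when_m_equals_band_count(self):
        assert ubs_select(5, 5).indices.tolist() == [1, 2, 3, 4, 5]

    def test_m_larger_than_bands_rejected(self):
        with pytest.raises(ValueError):
            ubs_select(5, 6)

    def test_m_one_returns_middle_band(self):
        assert ubs_select(147, 1).indices.tolist() == [74]

    @pytest.mark.parametrize("b,m", [(147, 2), (147, 15), (10, 4), (200, 60)])
    def test_endpoints_included_and_strictly_increasing(self, b, m):
        idx = ubs_select(b, m).indices
        assert idx[0] == 1 and idx[-1] == b
        assert (np.diff(idx) > 0).all()


class TestBandEntropy:
    def test_constant_band_zero_bits(self):
        assert band_entropy(np.full(100, 0.7), bins=256) == 0.0

    def test_two_equal_frequencies_one_bit(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert band_entropy(x, bins=2) == pytest.approx(1.0)

    def test_matches_bruteforce_histogram_entropy(self, rng):
        sample = rng.uniform(0, 1, size=(500, 3))
        for b in range(3):
            assert band_entropy(sample, b, bins=256) == pytest.approx(
                bruteforce_entropy(sample[:, b], 256)
            )

    def test_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=400)
        h1 = band_entropy(x, bins=64)
        h2 = band_entropy(3.0 * x + 10.0, bins=64)
        assert h1 == pytest.approx(h2)


class TestFNGBS:
    def _sample(self, n_pix, n_bands, seed):
        rng = np.random.default_rng(seed)
        # correlated neighbouring bands, like a real spectrum
        base = rng.uniform(0, 1, size=(n_pix, 1))
        drift = np.cumsum(rng.normal(0, 0.15, size=(n_pix, n_bands)), axis=1)
        return np.clip(base + drift, 0, 2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n_bands,m", [(8, 2), (10, 3), (12, 3), (12, 4), (12, 6)])
    def test_matches_bruteforce_reference(self, seed, n_bands, m):
        sample = self._sample(60, n_bands, seed)
        ours = fngbs_select(sample, m, k_neighbors=3, bins=16).indices.tolist()
        ref = bruteforce_fngbs(sample, m, k_neighbors=3, bins=16)
        assert ours == ref

    def test_m_equal_band_count_selects_every_band(self):
        sample = self._sample(40, 9, 5)
        assert fngbs_select(sample, 9).indices.tolist() == list(range(1, 10))

    def test_returns_exactly_m_distinct_indices(self):
        sample = self._sample(80, 12, 7)
        for m in (2, 3, 5):
            idx = fngbs_select(sample, m).indices
            assert len(idx) == m == len(set(idx.tolist()))
            assert (np.diff(idx) > 0).all()

    def test_constructed_winner_per_group(self):
        # 12 bands, 3 coarse groups of 4.  In each group three bands are
        # a coarsely quantized copy of the group's structure (mutually
        # identical -> density 1, but low entropy), while the "star"
        # band keeps the full continuous values: near-equal density yet
        # decisively larger entropy, so rho x H picks the star.
        rng = np.random.default_rng(9)
        n = 200
        sample = np.zeros((n, 12))
        for g, star in enumerate((2, 6, 10)):
            cluster = rng.uniform(0, 1, size=n)
            quantized = np.round(cluster * 2) / 2  # three levels only
            for b in range(4 * g, 4 * g + 4):
                sample[:, b] = quantized
            sample[:, star] = cluster
        sel = fngbs_select(sample, 3, bins=16)
        assert sel.indices.tolist() == [3, 7, 11]  # 1-based

    def test_scores_expose_density_times_entropy(self):
        sample = self._sample(50, 8, 11)
        sel, scores = fngbs_select(sample, 2, return_scores=True)
        for s in scores:
            assert s.score == pytest.approx(s.density * s.entropy)
            assert s.entropy >= 0.0


class TestPCA:
    def test_exact_rank_two_data_has_full_energy(self, rng):
        basis = rng.normal(size=(2, 6))
        coef = rng.normal(size=(100, 2))
        sel = pca_reduce(coef @ basis, 2)
        assert sel.energy == pytest.approx(1.0)

    def test_full_dimension_is_orthonormal_rotation(self, rng):
        x = rng.normal(size=(200, 5))
        sel = pca_reduce(x, 5)
        assert sel.energy == pytest.approx(1.0)
        np.testing.assert_allclose(sel.transform.T @ sel.transform, np.eye(5),
                                   atol=1e-8)

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        x = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
        centred = x - x.mean(axis=0)
        evals = np.linalg.eigvalsh(centred.T @ centred / (len(x) - 1))[::-1]
        sel = pca_reduce(x, 3)
        # energy of first 3 axes equals eigenvalue mass of top 3
        assert sel.energy == pytest.approx(evals[:3].sum() / evals.sum())

    def test_m_beyond_rank_rejected(self, rng):
        basis = rng.normal(size=(2, 5))
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(50, 2)) @ basis, 4)

    def test_reconstruction_error_non_increasing_in_m(self, rng):
        x = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        errs = []
        for m in (1, 2, 3, 4, 5, 6):
            sel = pca_reduce(x, m)
            proj = (x - sel.mean) @ sel.transform
            recon = proj @ sel.transform.T + sel.mean
            errs.append(((x - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


class TestApplySelection:
    def _cube(self, bands=147):
        vals = np.random.default_rng(0).uniform(0, 1, size=(4, 4, bands))
        return Hypercube(vals.astype(np.float32), default_wavelengths(bands))

    def test_identity_selection_is_noop(self):
        cube = self._cube(10)
        out = apply_selection(cube, ubs_select(10, 10))
        np.testing.assert_array_equal(out.values, cube.values)

    def test_ubs3_slices_published_wavelengths(self):
        cube = self._cube()
        out = apply_selection(cube, ubs_select(147, 3))
        assert out.bands == 3
        np.testing.assert_allclose(
            out.wavelengths, cube.wavelengths[[0, 73, 146]]
        )

    def test_pca_projection_shape_and_axis_labels(self):
        cube = self._cube(8)
        sample = cube.values.reshape(-1, 8).astype(np.float64)
        out = apply_selection(cube, pca_reduce(sample, 6))
        assert out.bands == 6
        assert out.scale == "arbitrary"

    def test_band_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_selection(self._cube(10), ubs_select(147, 3))
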