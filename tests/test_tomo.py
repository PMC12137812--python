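import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from xfct.tomo import (MinMaxScaler, PairAugmentOps, PhantomImage, Sinogram,
                       assemble_sinogram, augment_pair, augment_pairs,
                       build_base_pairs, make_3h_phantom, make_organ_phantom,
                       projection_count_settings, radon_project,
                       random_organ_phantom, reduce_projections,
                       resize_to_input, split_pairs)


class TestPhantoms:
    def test_3h_values_and_area(self, phantom_3h):
        grid = phantom_3h.grid
        assert set(np.unique(grid)) == {0.0, 0.3, 0.5, 1.0}
        # each 6 mm hole covers ~ pi*(3 mm)^2 within rasterization tolerance
        px_area = phantom_3h.pixel_size**2
        for conc in (1.0, 0.5, 0.3):
            area = (grid == conc).sum() * px_area
            assert area == pytest.approx(np.pi * 9.0, rel=0.1)

    def test_3h_zero_concentrations(self):
        ph = make_3h_phantom((0.0, 0.0, 0.0))
        assert np.all(ph.grid == 0)

    def test_3h_max_is_max_hole(self):
        ph = make_3h_phantom((0.7, 0.2, 0.4))
        assert ph.grid.max() == pytest.approx(0.7)

    def test_3h_geometry_validation(self):
        with pytest.raises(ValueError, match="grid"):
            make_3h_phantom((1, 1, 1), grid_size=32)
        with pytest.raises(ValueError, match="outside"):
            make_3h_phantom((1, 1, 1), hole_ring_radius=14.0)

    def test_organ_two_kidneys_two_components(self):
        spec = [(-10, 0, 4, 6, 0, 4.9), (10, 0, 4, 6, 0, 4.9)]
        ph = make_organ_phantom(spec, grid_size=63)
        _, n = cc_label(ph.grid > 0)
        assert n == 2
        assert ph.grid.max() == pytest.approx(4.9)

    def test_organ_empty_spec(self):
        ph = make_organ_phantom([], grid_size=63)
        assert np.all(ph.grid == 0)

    def test_organ_tumor_max(self):
        ph = make_organ_phantom([(0, 0, 5, 5, 0, 0.4)], grid_size=63)
        assert ph.grid.max() == pytest.approx(0.4)

    def test_organ_negative_rejected(self):
        with pytest.raises(ValueError):
            make_organ_phantom([(0, 0, 5, 5, 0, -1.0)])

    def test_random_organ_reproducible(self):
        a = random_organ_phantom(seed=5)
        b = random_organ_phantom(seed=5)
        np.testing.assert_array_equal(a.grid, b.grid)


class TestRadon:
    def test_zero_image(self):
        ph = PhantomImage(np.zeros((63, 63)))
        s = radon_project(ph, 10)
        assert np.all(s.matrix == 0)

    def test_mass_conservation(self, smooth_phantom):
        s = radon_project(smooth_phantom, 30)
        mass = smooth_phantom.grid.sum()
        np.testing.assert_allclose(s.matrix.sum(axis=1), mass, rtol=0.01)

    def test_angular_spacing_12_degrees(self, sino_30):
        assert sino_30.n_angles == 30
        np.testing.assert_allclose(np.diff(sino_30.angles), 12.0)

    def test_linearity(self, phantom_3h, smooth_phantom):
        a, b = 2.0, 0.5
        combo = PhantomImage(a * phantom_3h.grid + b * smooth_phantom.grid)
        lhs = radon_project(combo, 12).matrix
        rhs = (a * radon_project(phantom_3h, 12).matrix
               + b * radon_project(smooth_phantom, 12).matrix)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-7, atol=1e-8)


class TestAssemble:
    def test_330_values(self):
        s = assemble_sinogram(np.arange(330.0))
        assert s.matrix.shape == (30, 11)
        assert s.translation_step == 3.0
        assert s.provenance == "spectra"

    def test_zero_values(self):
        s = assemble_sinogram(np.zeros(330))
        assert np.all(s.matrix == 0)

    def test_wrong_length_names_expected(self):
        with pytest.raises(ValueError, match="330"):
            assemble_sinogram(np.zeros(300))

    def test_indexing_round_trip(self):
        rng = np.random.default_rng(0)
        vals = rng.random(330)
        perm = rng.permutation(330)
        s = assemble_sinogram(vals[perm])
        recovered = s.matrix.ravel()[np.argsort(perm)]
        np.testing.assert_array_equal(recovered, vals)


class TestReduceProjections:
    def test_identity(self, sino_30):
        r = reduce_projections(sino_30, 30)
        np.testing.assert_array_equal(r.matrix, sino_30.matrix)

    def test_half_keeps_every_second(self, sino_30):
        r = reduce_projections(sino_30, 15)
        np.testing.assert_allclose(r.angles, np.arange(15) * 24.0)

    def test_index_formula(self, sino_30):
        r = reduce_projections(sino_30, 7)
        expected = np.unique(np.round(np.arange(7) * 30 / 7).astype(int))
        np.testing.assert_array_equal(r.matrix, sino_30.matrix[expected])

    def test_out_of_range(self, sino_30):
        with pytest.raises(ValueError):
            reduce_projections(sino_30, 31)

    def test_settings_20_unique(self):
        settings = projection_count_settings()
        assert len(settings) == 20
        assert settings[0] == 30 and settings[-1] == 5
        assert len(set(settings)) == 20


class TestPairAugmentation:
    def test_identity_ops(self, sino_30, phantom_3h):
        s, img = augment_pair(sino_30, phantom_3h, PairAugmentOps())
        np.testing.assert_array_equal(s.matrix, sino_30.matrix)
        np.testing.assert_array_equal(img.grid, phantom_3h.grid)

    def test_scale_linearity(self, sino_30, phantom_3h):
        s, img = augment_pair(sino_30, phantom_3h, PairAugmentOps(scale=2.5))
        np.testing.assert_allclose(s.matrix, 2.5 * sino_30.matrix)
        np.testing.assert_allclose(img.grid, 2.5 * phantom_3h.grid)

    def test_flip_matches_radon_of_flipped_image(self, sino_30, phantom_3h):
        s, img = augment_pair(sino_30, phantom_3h, PairAugmentOps(flip=True))
        ref = radon_project(img, 30)
        np.testing.assert_allclose(s.matrix, ref.matrix, atol=1e-9)

    def test_rotation_matches_radon_of_rotated_image(self, smooth_phantom):
        sino = radon_project(smooth_phantom, 30)
        s, img = augment_pair(sino, smooth_phantom, PairAugmentOps(rotate_steps=5))
        ref = radon_project(img, 30)
        # interpolated rotation: agreement within a few percent of peak
        assert np.abs(s.matrix - ref.matrix).max() < 0.05 * ref.matrix.max()

    def test_flip_requires_uniform_even_grid(self, sino_30, phantom_3h):
        reduced = reduce_projections(sino_30, 7)  # non-uniform angle subset
        with pytest.raises(ValueError, match="uniform"):
            augment_pair(reduced, phantom_3h, PairAugmentOps(flip=True))

    def test_expansion_factor(self, sino_30, phantom_3h):
        pairs = [(reduce_projections(sino_30, k), phantom_3h) for k in (30, 10, 7)]
        out = augment_pairs(pairs, factor=5, seed=0)
        assert len(out) == 15

    def test_first_draw_is_identity(self, sino_30, phantom_3h):
        out = augment_pairs([(sino_30, phantom_3h)], factor=3, seed=0)
        np.testing.assert_array_equal(out[0][0].matrix, sino_30.matrix)

    def test_deterministic(self, sino_30, phantom_3h):
        a = augment_pairs([(sino_30, phantom_3h)], factor=4, seed=3)
        b = augment_pairs([(sino_30, phantom_3h)], factor=4, seed=3)
        for (sa, _), (sb, _) in zip(a, b):
            np.testing.assert_array_equal(sa.matrix, sb.matrix)


class TestBasePairsAndSplit:
    def test_base_pair_count(self, phantom_3h):
        images = [phantom_3h] * 4
        pairs = build_base_pairs(images, settings=[30, 15, 10, 7, 5])
        assert len(pairs) == 20

    def test_split_floor_rule_small(self):
        split = split_pairs(list(range(10)), seed=0)
        assert (len(split["train"]), len(split["val"]), len(split["test"])) == (7, 2, 1)

    def test_split_partition(self):
        items = list(range(57))
        split = split_pairs(items, seed=1)
        union = sorted(split["train"] + split["val"] + split["test"])
        assert union == items

    def test_split_empty_rejected(self):
        with pytest.raises(ValueError):
            split_pairs([])

    def test_split_bad_fractions(self):
        with pytest.raises(ValueError):
            split_pairs([1, 2], fractions=(0.5, 0.2, 0.1))


class TestResizeAndScaler:
    def test_resize_identity(self, sino_30):
        padded = Sinogram(matrix=np.random.default_rng(0).random((256, 256)),
                          angles=np.linspace(0, 359, 256))
        np.testing.assert_array_equal(resize_to_input(padded), padded.matrix)

    def test_resize_constant_preserved(self):
        s = Sinogram(matrix=np.full((30, 11), 3.7), angles=np.arange(30) * 12.0)
        out = resize_to_input(s, (64, 64))
        np.testing.assert_allclose(out, 3.7)

    def test_resize_mean_preserved(self, sino_30):
        out = resize_to_input(sino_30, (64, 64))
        assert out.mean() == pytest.approx(sino_30.matrix.mean(), rel=0.02)

    def test_minmax_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, (10, 8))
        sc = MinMaxScaler().fit(x)
        z = sc.transform(x)
        assert z.min() == pytest.approx(0.0) and z.max() == pytest.approx(1.0)
        np.testing.assert_allclose(sc.inverse_transform(z), x, atol=1e-9)

    def test_minmax_degenerate_rejected(self):
        with pytest.raises(ValueError):
            MinMaxScaler().fit(np.full((4, 4), 2.0))
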