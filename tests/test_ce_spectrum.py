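import math

import numpy as np
import pytest

from neuropil._shearlet import ShearletTransform
from neuropil.ce_spectrum import (CEMap, ce_map, ce_spectrum, complexity_map,
                                  entropy_map, feature_probabilities,
                                  jsd_max, make_stripe_image, project_stack,
                                  stripe_toy)


def scalar_entropy_complexity(P):
    """Literal scalar-loop evaluation of the entropy / complexity formulas,
    independent of the vectorised implementation."""
    N = len(P)

    def S(p):
        return -sum(pi * math.log2(pi) for pi in p if pi > 0)

    H = S(P) / math.log2(N)
    Pe = [1.0 / N] * N
    M = [(a + b) / 2 for a, b in zip(P, Pe)]
    J = S(M) - 0.5 * (S(P) + S(Pe))
    sing = [1.0] + [0.0] * (N - 1)
    Ms = [(a + b) / 2 for a, b in zip(sing, Pe)]
    Jmax = S(Ms) - 0.5 * (S(sing) + S(Pe))
    return H, H * J / Jmax


def field_from_vectors(P):
    """Wrap a (N, n) probability array as a 1 x n FeatureProbabilityField."""
    from neuropil.ce_spectrum import FeatureProbabilityField
    P = np.asarray(P, float)
    return FeatureProbabilityField(P=P[:, None, :],
                                   mask=np.ones((1, P.shape[1]), bool),
                                   bands=[("s", i) for i in range(len(P))])


class TestFormulas:
    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(2, 9))
            P = rng.dirichlet(np.ones(N))
            F = field_from_vectors(P[:, None])
            H = entropy_map(F)[0, 0]
            C = complexity_map(F)[0, 0]
            Ho, Co = scalar_entropy_complexity(list(P))
            assert abs(H - Ho) < 1e-12 and abs(C - Co) < 1e-12

    def test_hand_values_n2(self):
        # H from the definition; J_max for the singular two-feature case
        F = field_from_vectors(np.array([[0.9], [0.1]]))
        assert entropy_map(F)[0, 0] == pytest.approx(0.4690, abs=5e-5)
        assert jsd_max(2) == pytest.approx(0.31128, abs=5e-6)
        # C from the same equations, frozen via the scalar oracle
        assert complexity_map(F)[0, 0] == pytest.approx(0.2211698, abs=1e-6)

    def test_extremes(self):
        singular = field_from_vectors(np.array([[1.0], [0.0], [0.0], [0.0]]))
        assert entropy_map(singular)[0, 0] == 0.0
        assert complexity_map(singular)[0, 0] == 0.0
        uniform = field_from_vectors(np.full((5, 1), 0.2))
        assert entropy_map(uniform)[0, 0] == pytest.approx(1.0)
        assert complexity_map(uniform)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_half_half(self):
        F = field_from_vectors(np.array([[0.5], [0.25], [0.125], [0.125]]))
        assert entropy_map(F)[0, 0] == pytest.approx(1.75 / 2.0)


class TestShearletBackend:
    def test_tight_frame(self):
        st = ShearletTransform((128, 128))
        assert st.frame_residual() < 1e-12

    def test_energy_partition(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        st = ShearletTransform((64, 64), n_scales=3)
        coeffs = st.transform(img)
        total = (np.abs(coeffs) ** 2).sum() \
            + (np.abs(st.lowpass_coefficients(img)) ** 2).sum()
        assert total == pytest.approx((img ** 2).sum(), rel=1e-10)

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="64x64"):
            ShearletTransform((32, 32))

    def test_too_many_scales(self):
        with pytest.raises(ValueError, match="scales"):
            ShearletTransform((64, 64), n_scales=6)


class TestFeatureProbabilities:
    def test_grating_concentrates_probability(self):
        x = np.arange(128)
        img = np.sin(2 * np.pi * x / 8)[None, :] * np.ones((128, 1))
        F = feature_probabilities(img)
        mean_p = F.P[:, F.mask].mean(axis=1)
        assert mean_p.max() * F.n_features > 5.0

    def test_noise_is_near_uniform(self):
        rng = np.random.default_rng(3)
        F = feature_probabilities(rng.normal(size=(128, 128)))
        assert np.abs(F.P[:, F.mask].sum(axis=0) - 1.0).max() < 1e-9
        assert entropy_map(F)[F.mask].mean() > 0.6

    def test_constant_image_fully_masked(self):
        F = feature_probabilities(np.ones((64, 64)))
        assert not F.mask.any()


class TestProjectStack:
    def test_zero_stack(self):
        img = project_stack(np.zeros((4, 8, 8), dtype=np.uint8))
        assert (img == 0).all()

    def test_column_sum_before_downsampling(self):
        stack = np.zeros((7, 8, 8), dtype=np.uint8)
        stack[:, 3, 5] = 1
        img = project_stack(stack, downsample=1)
        assert img[3, 5] == 7 and img.sum() == 7

    def test_checkerboard_block_mean(self):
        plane = np.indices((8, 8)).sum(axis=0) % 2
        img = project_stack(plane[None], downsample=2)
        np.testing.assert_allclose(img, 0.5)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            project_stack(np.full((2, 4, 4), 3))


class TestSpectrum:
    @staticmethod
    def _map_from(h, c):
        h = np.atleast_2d(h)
        c = np.atleast_2d(c)
        return CEMap(H=h, C=c, mask=np.ones_like(h, bool))

    def test_identical_classes_identical_excess(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0.1, 0.9, (50, 50))
        c = 0.3 * h * (1 - h)
        maps = {"a": self._map_from(h, c), "b": self._map_from(h, c)}
        spec = ce_spectrum(maps)
        np.testing.assert_allclose(spec.excess["a"], spec.excess["b"])

    def test_offset_classes_separate(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0.1, 0.9, (60, 60))
        base = 0.3 * h * (1 - h) + 0.2
        maps = {"hi": self._map_from(h, base + 0.05),
                "lo": self._map_from(h, base - 0.05)}
        spec = ce_spectrum(maps)
        sep = np.median(spec.excess["hi"]) - np.median(spec.excess["lo"])
        assert sep == pytest.approx(0.1, abs=0.01)
        assert np.median(spec.excess["hi"]) > 0 > np.median(spec.excess["lo"])

    def test_single_populated_bin_constant_curve(self):
        h = np.full((10, 10), 0.42)
        c = np.full((10, 10), 0.2)
        spec = ce_spectrum({"a": self._map_from(h, c)})
        assert np.isfinite(spec.median_raw).sum() == 1
        np.testing.assert_allclose(spec.median_curve,
                                   spec.median_curve[0])

    def test_empty_class_rejected(self):
        h = np.zeros((8, 8))
        m = CEMap(H=h, C=h, mask=np.zeros_like(h, bool))
        with pytest.raises(ValueError, match="unmasked"):
            ce_spectrum({"a": m})


class TestStripeToy:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_entropy_up_complexity_transient(self, seed):
        toy = stripe_toy(seed=seed)
        H, C = toy[:, 1], toy[:, 2]
        assert (np.diff(H) > -0.01).all()
        assert np.diff(H).sum() > 0.2  # overall strong increase
        peak = int(np.argmax(C))
        assert 0 < peak < len(C) - 1, "complexity peak must be interior"

    def test_uncorrupted_stripes_are_ordered(self):
        m = ce_map(make_stripe_image())
        toy = stripe_toy(swap_fractions=(0.0, 1.0, 8.0), seed=0)
        assert toy[0, 1] == pytest.approx(m.H[m.mask].mean(), abs=1e-9)
        assert toy[0, 1] == toy[:, 1].min()
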