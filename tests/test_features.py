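import numpy as np
import pytest

from hemolyzer.features import (
    Backbone,
    ConvLayerSpec,
    PoolSpec,
    avg_pool,
    conv2d,
    conv_out_size,
    default_backbone,
    extract_features,
    flatten_last,
    forward_maps,
    leaky_relu,
    max_pool,
)


def loop_conv2d(x, kernels, bias, stride, padding):
    """Four-nested-loop cross-correlation, the independent reference."""
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[None]
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    K, C, kh, kw = kernels.shape
    Ho = (x.shape[1] - kh) // stride + 1
    Wo = (x.shape[2] - kw) // stride + 1
    out = np.zeros((K, Ho, Wo))
    for k in range(K):
        for i in range(Ho):
            for j in range(Wo):
                acc = bias[k]
                for c in range(C):
                    for u in range(kh):
                        for v in range(kw):
                            acc += kernels[k, c, u, v] * x[c, i * stride + u, j * stride + v]
                out[k, i, j] = acc
    return out


def loop_pool(x, k, kind):
    C, H, W = x.shape
    Ho, Wo = H // k, W // k
    out = np.zeros((C, Ho, Wo))
    for c in range(C):
        for i in range(Ho):
            for j in range(Wo):
                block = x[c, i * k : (i + 1) * k, j * k : (j + 1) * k]
                out[c, i, j] = block.mean() if kind == "avg" else block.max()
    return out


class TestConvOutSize:
    @pytest.mark.parametrize(
        "args,expect", [((5, 3, 1, 0), 3), ((128, 3, 2, 1), 64), ((7, 7, 1, 0), 1)]
    )
    def test_examples(self, args, expect):
        assert conv_out_size(*args) == expect

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            conv_out_size(2, 5, 1, 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_conv2d_shape(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(6, 12))
        k, s, p = int(rng.integers(1, 4)), int(rng.integers(1, 3)), int(rng.integers(0, 2))
        x = rng.random((w, w))
        kernels = rng.random((2, 1, k, k))
        y = conv2d(x, kernels, np.zeros(2), stride=s, padding=p)
        assert y.shape[1] == conv_out_size(w, k, s, p)
        assert y.shape[2] == conv_out_size(w, k, s, p)


class TestConv2d:
    def test_identity_kernel(self):
        x = np.arange(9, dtype=float).reshape(3, 3)
        y = conv2d(x, np.ones((1, 1, 1, 1)), 0.0)
        assert np.array_equal(y[0], x)

    def test_all_ones(self):
        y = conv2d(np.ones((2, 2)), np.ones((1, 1, 2, 2)), 0.0)
        assert y.shape == (1, 1, 1) and y[0, 0, 0] == 4.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((2, 8, 8))
        kernels = rng.standard_normal((3, 2, 3, 3))
        bias = rng.standard_normal(3)
        s, p = int(rng.integers(1, 3)), int(rng.integers(0, 2))
        got = conv2d(x, kernels, bias, stride=s, padding=p)
        want = loop_conv2d(x, kernels, bias, s, p)
        assert np.allclose(got, want, atol=1e-10)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            conv2d(np.ones((2, 2)), np.ones((1, 1, 5, 5)), 0.0)


class TestLeakyRelu:
    @pytest.mark.parametrize("x,slope,expect", [(3, 0.1, 3.0), (-2, 0.1, -0.2), (0, 0.3, 0.0)])
    def test_examples(self, x, slope, expect):
        assert leaky_relu(x, slope) == pytest.approx(expect)


class TestPooling:
    def test_examples(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert max_pool(x, 2) == pytest.approx(4.0)
        assert avg_pool(x, 2) == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((3, 6, 6))
        assert np.allclose(avg_pool(x, 2), loop_pool(x, 2, "avg"), atol=1e-12)
        assert np.allclose(max_pool(x, 3), loop_pool(x, 3, "max"), atol=1e-12)

    def test_truncates_non_divisible_dims(self):
        x = np.arange(35, dtype=float).reshape(5, 7)
        assert max_pool(x, 2).shape == (2, 3)

    def test_avg_below_max_on_nonnegative_maps(self):
        x = np.random.default_rng(7).random((2, 8, 8))
        assert np.all(avg_pool(x, 2) <= max_pool(x, 2) + 1e-12)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.ones((2, 2)), 3)


class TestFlatten:
    def test_row_major_single_map(self):
        maps = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert np.array_equal(flatten_last(maps), [1, 2, 3, 4])

    def test_two_scalar_maps(self):
        assert np.array_equal(flatten_last(np.array([[[5.0]], [[7.0]]])), [5, 7])

    def test_round_trip(self):
        maps = np.random.default_rng(1).random((3, 4, 5))
        assert np.array_equal(flatten_last(maps).reshape(3, 4, 5), maps)


class TestExtractFeatures:
    def test_one_row_per_image(self, small_dataset):
        bb = default_backbone(seed=0)
        F = extract_features(small_dataset[:6], bb)
        assert F.shape[0] == 6
        assert F.shape[1] == bb.output_dim(small_dataset[0].image.shape)

    def test_deterministic_given_seed(self, small_dataset):
        F1 = extract_features(small_dataset[:4], default_backbone(seed=3))
        F2 = extract_features(small_dataset[:4], default_backbone(seed=3))
        assert np.array_equal(F1, F2)

    def test_single_layer_stage_by_stage(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        layers = (ConvLayerSpec(3, 4, activation="leaky_relu", leaky_slope=0.1), PoolSpec("max", 2))
        bb = default_backbone(seed=5, layers=layers)
        F = extract_features([img], bb)
        kernels, bias = bb.weights[0]
        manual = loop_conv2d(img.astype(float) / 255.0, kernels, bias, 1, 0)
        manual = np.where(manual >= 0, manual, 0.1 * manual)
        manual = loop_pool(manual, 2, "max")
        assert np.allclose(F[0], manual.reshape(-1), atol=1e-10)

    def test_shape_mismatch_names_offender(self):
        imgs = [np.zeros((8, 8), np.uint8), np.zeros((9, 8), np.uint8)]
        with pytest.raises(ValueError, match="image 1"):
            extract_features(imgs, default_backbone(seed=0))

    def test_layer_dims_follow_conv_arithmetic(self, small_dataset):
        bb = default_backbone(seed=1)
        maps = forward_maps(small_dataset[0].image.astype(float) / 255.0, bb)
        h, w = small_dataset[0].image.shape
        c = 1
        for spec in bb.layers:
            if isinstance(spec, ConvLayerSpec):
                h = conv_out_size(h, spec.kernel_size, spec.stride, spec.padding)
                w = conv_out_size(w, spec.kernel_size, spec.stride, spec.padding)
                c = spec.n_kernels
            else:
                h, w = h // spec.size, w // spec.size
        assert maps.shape == (c, h, w)
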