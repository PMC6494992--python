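"""Layer-shape arithmetic, window bounds, and the network architectures."""

import numpy as np
import pytest

from ecggan import (
    ConvLayerSpec,
    DiscriminatorSpec,
    GeneratorConfig,
    PoolLayerSpec,
    ShapeError,
    ValidationError,
    build_discriminator,
    build_generator,
    conv_output_length,
    conv_window_bounds,
    discriminator_forward,
    pool_output_length,
    sample_noise,
)
from ecggan.nn import Tensor, conv1d


def enumerate_conv_windows(W, F, S, P):
    """Count filter placements by explicit enumeration over start offsets."""
    padded = W + 2 * P
    return sum(1 for start in range(0, padded, S) if start + F <= padded)


def enumerate_pool_windows(W, F, S):
    return sum(1 for start in range(0, W, S) if start + F <= W)


class TestShapeFormulas:
    @pytest.mark.parametrize(
        "args,expected",
        [((3120, 120, 5, 0), 601), ((186, 36, 3, 0), 51), ((7, 7, 1, 0), 1)],
    )
    def test_conv_output_length_reference_values(self, args, expected):
        assert conv_output_length(*args) == expected

    @pytest.mark.parametrize(
        "args,expected", [((601, 46, 3), 186), ((51, 24, 3), 10), ((9, 9, 4), 1)]
    )
    def test_pool_output_length_reference_values(self, args, expected):
        assert pool_output_length(*args) == expected

    def test_formulas_match_enumeration_over_grid(self):
        """The closed forms agree with sliding-window enumeration for all
        1 <= F <= W <= 60, 1 <= S <= 6, P in {0, 1, 2}."""
        for W in range(1, 61):
            for F in range(1, W + 1):
                for S in range(1, 7):
                    for P in (0, 1, 2):
                        assert conv_output_length(W, F, S, P) == (
                            enumerate_conv_windows(W, F, S, P)
                        ), (W, F, S, P)
                    assert pool_output_length(W, F, S) == enumerate_pool_windows(
                        W, F, S
                    ), (W, F, S)

    def test_filter_longer_than_input_raises(self):
        with pytest.raises(ShapeError):
            conv_output_length(10, 12, 1, 0)
        with pytest.raises(ShapeError):
            pool_output_length(5, 6, 1)


class TestConvWindowBounds:
    @pytest.mark.parametrize(
        "i,expected", [(1, (1, 120)), (2, (6, 125)), (601, (3001, 3120))]
    )
    def test_reference_windows(self, i, expected):
        assert conv_window_bounds(i, k=5, h=120, T=3120) == expected

    def test_window_width_is_filter_length(self):
        for i in (1, 17, 300, 601):
            l, r = conv_window_bounds(i, 5, 120, 3120)
            assert r - l + 1 == 120

    def test_windows_tile_with_stride_k(self):
        """Consecutive windows start exactly k apart and, when (T - h) is a
        multiple of k, their union covers [1, T]."""
        k, h, T = 4, 12, 48  # (48 - 12) % 4 == 0
        n = (T - h) // k + 1
        starts = [conv_window_bounds(i, k, h, T)[0] for i in range(1, n + 1)]
        assert np.all(np.diff(starts) == k)
        covered = set()
        for i in range(1, n + 1):
            l, r = conv_window_bounds(i, k, h, T)
            covered.update(range(l, r + 1))
        assert covered == set(range(1, T + 1))

    def test_out_of_range_index_raises(self):
        with pytest.raises(IndexError):
            conv_window_bounds(602, 5, 120, 3120)
        with pytest.raises(IndexError):
            conv_window_bounds(0, 5, 120, 3120)


def expected_generator_parameters(d, h, n_layers, out_dim):
    """Closed-form parameter count, derived independently of the code:
    per direction LSTM: 4h(in + h) weights + 4h biases; per layer combiner:
    two h x 2h direction maps + 2h bias; head: 2h*out + out."""
    total = 0
    width_in = d
    for _ in range(n_layers):
        lstm = 4 * h * (width_in + h) + 4 * h
        combiner = 2 * (h * 2 * h) + 2 * h
        total += 2 * lstm + combiner
        width_in = 2 * h
    return total + width_in * out_dim + out_dim


class TestGenerator:
    def test_output_shape_at_generation_settings(self):
        """Noise dim 5 and length 400 produce (n, 400, 2) outputs."""
        gen = build_generator(GeneratorConfig(noise_dim=5, seq_len=400, hidden_units=8))
        out = gen(sample_noise(3, 400, 5, seed=0))
        assert out.shape == (3, 400, 2)

    @pytest.mark.parametrize("batch,T", [(1, 10), (4, 25)])
    def test_output_shape_generic(self, batch, T):
        gen = build_generator(GeneratorConfig(noise_dim=3, seq_len=T, hidden_units=6))
        assert gen(sample_noise(batch, T, 3, seed=1)).shape == (batch, T, 2)

    def test_eval_mode_forward_is_deterministic(self):
        gen = build_generator(GeneratorConfig(noise_dim=4, seq_len=20, hidden_units=5))
        gen.eval()
        noise = sample_noise(2, 20, 4, seed=3)
        np.testing.assert_array_equal(gen(noise).data, gen(noise).data)

    def test_train_mode_dropout_varies(self):
        gen = build_generator(
            GeneratorConfig(noise_dim=4, seq_len=20, hidden_units=5, dropout_p=0.5)
        )
        gen.train()
        noise = sample_noise(2, 20, 4, seed=3)
        assert not np.array_equal(gen(noise).data, gen(noise).data)

    @pytest.mark.parametrize(
        "d,h,layers", [(5, 100, 2), (3, 7, 1), (2, 4, 3)]
    )
    def test_parameter_count_matches_closed_form(self, d, h, layers):
        gen = build_generator(
            GeneratorConfig(noise_dim=d, seq_len=10, hidden_units=h, n_bilstm_layers=layers)
        )
        assert gen.n_parameters() == expected_generator_parameters(d, h, layers, 2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            build_generator(GeneratorConfig(noise_dim=0))
        with pytest.raises(ValidationError):
            build_generator(GeneratorConfig(dropout_p=1.0))

    def test_wrong_noise_width_raises(self):
        gen = build_generator(GeneratorConfig(noise_dim=4, seq_len=10, hidden_units=3))
        with pytest.raises(ShapeError):
            gen(np.zeros((1, 10, 5)))


class TestDiscriminator:
    def test_reference_cnn_layer_lengths(self):
        """Input 1x3120x1 flows through output lengths 601, 186, 51, 10,
        then a 50-feature flatten, a 25-unit FC layer and a 2-way softmax."""
        spec = DiscriminatorSpec.cnn_default()
        assert spec.layer_output_lengths() == [601, 186, 51, 10]
        assert spec.flat_features() == 50
        assert spec.fc_units == 25

    def test_shape_inconsistent_spec_raises_at_build(self):
        spec = DiscriminatorSpec(
            kind="cnn",
            input_length=30,
            layers=[
                ConvLayerSpec(n_filters=2, filter_length=10, stride=2),
                PoolLayerSpec(window=20, stride=1),  # 11 < 20: impossible
            ],
        )
        with pytest.raises(ShapeError):
            build_discriminator(spec)

    @pytest.mark.parametrize("kind", ["cnn", "mlp", "lstm", "gru"])
    def test_softmax_pair_valid_for_all_kinds(self, kind, rng):
        length = 64
        spec = (
            DiscriminatorSpec.scaled_cnn(length)
            if kind == "cnn"
            else DiscriminatorSpec(kind=kind, input_length=length, hidden_sizes=(8,))
        )
        disc = build_discriminator(spec, seed=0)
        probs = disc(rng.normal(size=(5, length))).data
        assert probs.shape == (5, 2)
        assert np.all(probs > 0) and np.all(probs < 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_forward_returns_probability_of_real_per_sequence(self, rng):
        spec = DiscriminatorSpec.scaled_cnn(64)
        disc = build_discriminator(spec, seed=1)
        batch = rng.normal(size=(7, 64))
        p = discriminator_forward(disc, batch)
        assert p.shape == (7,)
        assert np.all((p > 0) & (p < 1))
        decisions = discriminator_forward(disc, batch, decide=True)
        np.testing.assert_array_equal(decisions, (p >= 0.5).astype(int))

    def test_batch_order_equivariance(self, rng):
        spec = DiscriminatorSpec.scaled_cnn(64)
        disc = build_discriminator(spec, seed=2)
        batch = rng.normal(size=(6, 64))
        perm = rng.permutation(6)
        p = discriminator_forward(disc, batch)
        p_perm = discriminator_forward(disc, batch[perm])
        np.testing.assert_allclose(p_perm, p[perm], atol=1e-12)

    def test_wrong_length_input_raises(self, rng):
        disc = build_discriminator(DiscriminatorSpec.scaled_cnn(64))
        with pytest.raises(ShapeError):
            disc(rng.normal(size=(2, 65)))

    def test_conv_values_equal_hand_computed_dot_products(self):
        """Constant-weight, zero-bias convolution over a known 10-sample
        input equals windowed dot products computed with explicit loops."""
        x = np.arange(10, dtype=float)[None, None, :]  # (1, 1, 10)
        w = np.full((1, 1, 4), 0.5)
        b = np.zeros(1)
        stride = 2
        out = conv1d(Tensor(x), Tensor(w), Tensor(b), stride).data[0, 0]
        expected = []
        T, h, k = 10, 4, stride
        for i in range(1, (T - h) // k + 2):
            l, r = conv_window_bounds(i, k, h, T)  # 1-based inclusive
            expected.append(0.5 * x[0, 0, l - 1 : r].sum())
        np.testing.assert_allclose(out, expected)

    def test_scaled_cnn_spec_is_consistent(self):
        for length in (312, 624, 1560):
            spec = DiscriminatorSpec.scaled_cnn(length)
            lengths = spec.layer_output_lengths()
            assert all(n >= 1 for n in lengths)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            build_discriminator(DiscriminatorSpec(kind="transformer", input_length=10))
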