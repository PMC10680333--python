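"""Model construction, parameter accounting, bundles and attention maps."""

import numpy as np
import pytest

import flowrec as fr
from flowrec import architectures as arch
from flowrec.architectures import FORMAT_VERSION

from conftest import tiny_transformer_config

FULL_TOOLS = 2354  # full-scale vocabulary size


class TestParameterCounts:
    @pytest.mark.parametrize(
        "architecture,expected",
        [("transformer", 922_291), ("cnn", 5_772_723), ("dnn", 1_031_603)],
    )
    def test_full_scale_counts(self, architecture, expected):
        cfg = fr.config_for_vocabulary(architecture, FULL_TOOLS)
        assert fr.parameter_formula(cfg) == expected
        model = fr.build_model(cfg, seed=0)
        assert fr.count_trainable_parameters(model) == expected

    def test_tiny_transformer_hand_count(self):
        cfg = tiny_transformer_config()
        # vocab_in 7, d 8, N 6, 2 heads x 4, ffn (6, 8), hidden 5, out 7
        by_hand = (
            7 * 8 + 6 * 8                  # token + positional embeddings
            + 3 * (8 * 8 + 8) + (8 * 8 + 8)  # q, k, v, attention output
            + 2 * (8 + 8)                  # two layer norms
            + (8 * 6 + 6) + (6 * 8 + 8)    # feed-forward
            + (8 * 5 + 5)                  # hidden dense
            + (5 * 7 + 7)                  # sigmoid output
        )
        model = fr.build_transformer(cfg, seed=0)
        assert fr.count_trainable_parameters(model) == by_hand
        assert fr.parameter_formula(cfg) == by_hand

    def test_tiny_rnn_gru_closed_form(self):
        cfg = fr.config_for_vocabulary(
            "rnn", 5, d_model=6, gru_units=4, max_len=4, dropout_rate=0.0
        )
        # per GRU layer (reset-after): 3*(d*u + u^2 + 2u)
        by_hand = 6 * 6 + 3 * (6 * 4 + 16 + 8) + 3 * (4 * 4 + 16 + 8) + (4 * 6 + 6)
        model = fr.build_rnn(cfg, seed=0)
        assert fr.count_trainable_parameters(model) == by_hand

    def test_cnn_shape_arithmetic(self):
        cfg = fr.config_for_vocabulary("cnn", FULL_TOOLS)
        # (25,128,1) -> 16x3 valid conv -> (10,126,128) -> 2x2 pool -> (5,63,128)
        assert arch.CnnModel.flat_dim(cfg) == 5 * 63 * 128

    def test_dnn_first_dense_shape(self):
        cfg = fr.config_for_vocabulary("dnn", FULL_TOOLS)
        model = fr.build_dnn(cfg, seed=0)
        assert model.params["w1"].data.shape == (25 * 128, 128)

    @pytest.mark.parametrize("seed", range(20))
    def test_framework_count_matches_formula_for_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        architecture = arch.ARCHITECTURES[seed % 4]
        d = int(rng.integers(4, 12)) * 2
        over = dict(
            d_model=d,
            max_len=int(rng.integers(17, 30)),
            hidden_dense_dim=int(rng.integers(3, 12)),
            gru_units=int(rng.integers(3, 10)),
            conv_kernel=(int(rng.integers(2, 6)), int(rng.integers(2, 4))),
            conv_filters=int(rng.integers(2, 8)),
            n_heads=int(rng.integers(1, 4)),
            head_dim=int(rng.integers(2, 8)),
        )
        over["ffn_dims"] = (int(rng.integers(3, 10)), d)
        cfg = fr.config_for_vocabulary(architecture, int(rng.integers(5, 40)), **over)
        model = fr.build_model(cfg, seed=seed)
        assert fr.count_trainable_parameters(model) == fr.parameter_formula(cfg)

    def test_count_invariant_under_reinitialisation(self):
        cfg = tiny_transformer_config()
        a = fr.build_transformer(cfg, seed=1)
        b = fr.build_transformer(cfg, seed=2)
        assert fr.count_trainable_parameters(a) == fr.count_trainable_parameters(b)


class TestForward:
    def test_all_architectures_emit_scores_in_unit_interval(self):
        ids = np.array([[0, 0, 0, 1, 2, 3]])
        for architecture in arch.ARCHITECTURES:
            over = dict(d_model=8, max_len=6, hidden_dense_dim=5, gru_units=4,
                        conv_kernel=(3, 2), conv_filters=3, ffn_dims=(6, 8),
                        n_heads=2, head_dim=4)
            if architecture == "dnn":
                over["ffn_dims"] = (6, 7)
            cfg = fr.config_for_vocabulary(architecture, 5, **over)
            scores = fr.build_model(cfg, seed=0).predict(ids)
            assert scores.shape == (1, cfg.vocab_out)
            assert np.all((scores > 0) & (scores < 1))

    def test_all_padding_input_is_finite(self, tiny_transformer):
        scores = tiny_transformer.predict(np.zeros((1, 6), dtype=int))
        assert np.all(np.isfinite(scores))
        assert np.all((scores > 0) & (scores < 1))

    def test_forward_is_deterministic(self, tiny_transformer):
        ids = np.array([[0, 1, 2, 3, 4, 5]])
        a = tiny_transformer.predict(ids)
        b = tiny_transformer.predict(ids)
        np.testing.assert_array_equal(a, b)

    def test_positional_encoding_makes_order_matter(self, tiny_transformer):
        a = tiny_transformer.predict(np.array([[0, 0, 0, 1, 2, 3]]))
        b = tiny_transformer.predict(np.array([[0, 0, 0, 2, 1, 3]]))
        assert np.abs(a - b).max() > 1e-9

    def test_invalid_ffn_residual_dims_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            fr.config_for_vocabulary("transformer", 6, d_model=8, ffn_dims=(6, 6))


class TestBundles:
    def test_round_trip_predictions_bitwise_identical(self, tiny_transformer,
                                                      tiny_bundle_path):
        loaded = fr.load_bundle(tiny_bundle_path)
        ids = np.array([[0, 0, 1, 2, 3, 4]])
        np.testing.assert_array_equal(
            tiny_transformer.predict(ids), loaded.predict(ids)
        )
        assert loaded.format_version == FORMAT_VERSION

    def test_round_trip_preserves_parameter_count(self, tiny_transformer,
                                                  tiny_bundle_path):
        loaded = fr.load_bundle(tiny_bundle_path)
        assert fr.count_trainable_parameters(loaded.model) == \
            fr.count_trainable_parameters(tiny_transformer)

    def test_missing_file_raises_file_not_found(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fr.load_bundle(tmp_path / "nope.h5")

    def test_truncated_file_is_a_corrupt_container_error(self, tiny_bundle_path,
                                                         tmp_path):
        broken = tmp_path / "broken.h5"
        broken.write_bytes(tiny_bundle_path.read_bytes()[:100])
        with pytest.raises(fr.BundleError, match="corrupt"):
            fr.load_bundle(broken)

    def test_version_mismatch_is_a_distinct_error(self, tiny_bundle_path,
                                                  tmp_path):
        import h5py
        import shutil
        other = tmp_path / "other.h5"
        shutil.copy(tiny_bundle_path, other)
        with h5py.File(other, "r+") as f:
            f.attrs["format_version"] = "999"
        with pytest.raises(fr.BundleError, match="version"):
            fr.load_bundle(other)

    def test_vocabulary_size_mismatch_rejected_on_save(self, tiny_transformer,
                                                       tmp_path):
        wrong = fr.ToolVocabulary(index_of={"a": 1, "b": 2})
        with pytest.raises(ValueError, match="inconsistent"):
            fr.save_bundle(tiny_transformer, wrong, tmp_path / "x.h5")

    def test_round_trip_all_architectures(self, tmp_path):
        vocab = fr.ToolVocabulary(index_of={f"t{i}": i for i in range(1, 6)})
        ids = np.array([[0, 1, 2, 3, 4, 5]])
        for architecture in arch.ARCHITECTURES:
            over = dict(d_model=8, max_len=6, hidden_dense_dim=5, gru_units=4,
                        conv_kernel=(3, 2), conv_filters=3, ffn_dims=(6, 8),
                        n_heads=2, head_dim=4)
            if architecture == "dnn":
                over["ffn_dims"] = (6, 7)
            cfg = fr.config_for_vocabulary(architecture, 5, **over)
            model = fr.build_model(cfg, seed=4)
            path = tmp_path / f"{architecture}.h5"
            fr.save_bundle(model, vocab, path)
            loaded = fr.load_bundle(path)
            assert loaded.config.architecture == architecture
            np.testing.assert_array_equal(model.predict(ids), loaded.predict(ids))


class TestAttention:
    def test_rows_sum_to_one_over_unmasked_keys(self, tiny_transformer):
        ids = np.array([0, 0, 0, 1, 2, 3])
        amap = fr.attention_matrix(tiny_transformer, ids)
        sums = amap.weights.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-5)

    def test_padded_keys_carry_zero_weight(self, tiny_transformer):
        ids = np.array([0, 0, 0, 1, 2, 3])
        amap = fr.attention_matrix(tiny_transformer, ids)
        assert np.all(amap.weights[:, :, :3] == 0.0)
        assert np.all(amap.weights[:, :, 3:] > 0.0)

    def test_head_average_is_arithmetic_mean(self, tiny_transformer):
        ids = np.array([0, 1, 2, 3, 4, 5])
        amap = fr.attention_matrix(tiny_transformer, ids)
        np.testing.assert_allclose(amap.averaged, amap.weights.mean(axis=0))

    def test_labels_mark_padding_positions(self, tiny_transformer):
        vocab = fr.ToolVocabulary(index_of={f"t{i}": i for i in range(1, 7)})
        amap = fr.attention_matrix(
            tiny_transformer, np.array([0, 0, 0, 1, 2, 3]), vocab
        )
        assert amap.labels == ("PAD", "PAD", "PAD", "t1", "t2", "t3")

    def test_non_transformer_is_unsupported(self):
        cfg = fr.config_for_vocabulary("dnn", 5, d_model=8, max_len=6,
                                       ffn_dims=(6, 7))
        model = fr.build_dnn(cfg, seed=0)
        with pytest.raises(fr.UnsupportedArchitectureError):
            fr.attention_matrix(model, np.zeros(6, dtype=int))
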