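import numpy as np
import pytest

import ncbind as nb
from ncbind import nn
from ncbind.exceptions import (
    ConfigurationError,
    ShapeError,
    TrainingError,
)
from ncbind.network import VARIANTS, build_variant


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert nb.sigmoid(0.0) == 0.5

    def test_symmetry(self):
        xs = np.linspace(-30, 30, 101)
        np.testing.assert_allclose(nb.sigmoid(xs) + nb.sigmoid(-xs), 1.0,
                                   atol=1e-15)

    def test_saturation(self):
        assert nb.sigmoid(40.0) == pytest.approx(1.0, abs=1e-12)
        assert nb.sigmoid(-40.0) == pytest.approx(0.0, abs=1e-12)
        # no overflow at extremes
        assert np.isfinite(nb.sigmoid(np.array([-1e4, 1e4]))).all()


class TestConfig:
    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ConfigurationError):
            nb.ModelConfig(l_max=8, branch_kernels=(10, 8))

    def test_dropout_range_enforced(self):
        with pytest.raises(ConfigurationError):
            nb.ModelConfig(dropout_rate=1.0)

    def test_degenerate_config_still_valid(self, toy_dataset):
        config = nb.ModelConfig(
            branch_kernels=(1, 1), pool_size=1, lstm_units=1,
            embedding_dim=2, conv_filters=2, dense_units=2,
            epochs=1, validation_fraction=0.0, seed=0,
        )
        trained = nb.fit(toy_dataset, config)
        probs = trained.predict_proba(nb.encode_batch(toy_dataset.records))
        assert ((probs >= 0) & (probs <= 1)).all()


class TestArchitecture:
    def _layer_types(self, model):
        return {type(layer).__name__ for layer in model.iter_layers()}

    def test_full_accepts_batch_and_outputs_probabilities(self, tiny_config):
        model = nb.build_model(tiny_config)
        x = np.zeros((7, tiny_config.l_max, 3))
        x[:, :, 1] = 3  # INM codes
        probs = nb.sigmoid(model.logits(x))
        assert probs.shape == (7,)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_full_equals_build_variant_full(self, tiny_config):
        a = nb.build_model(tiny_config)
        b = build_variant("full", tiny_config)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    @pytest.mark.parametrize("kind", VARIANTS)
    def test_variant_structure(self, kind, tiny_config):
        types = self._layer_types(build_variant(kind, tiny_config))
        has_conv = "Conv1D" in types
        has_lstm = "BiLSTM" in types
        expected = {
            "cnn_only": (True, False),
            "bilstm_only": (False, True),
            "cnn_then_bilstm_series": (True, True),
            "cnn_parallel": (True, False),
            "bilstm_parallel": (False, True),
            "full": (True, True),
        }[kind]
        assert (has_conv, has_lstm) == expected

    def test_parallel_variants_have_two_branches(self, tiny_config):
        for kind, layer_name in [("full", "BiLSTM"), ("cnn_parallel", "Conv1D"),
                                 ("bilstm_parallel", "BiLSTM")]:
            model = build_variant(kind, tiny_config)
            count = sum(1 for l in model.iter_layers()
                        if type(l).__name__ == layer_name)
            assert count == 2, kind

    def test_unknown_variant_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant("transformer", tiny_config)

    def test_parameter_count_increases_with_filters(self):
        small = nb.build_model(nb.ModelConfig(conv_filters=8))
        large = nb.build_model(nb.ModelConfig(conv_filters=16))
        assert large.num_parameters() > small.num_parameters()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full model agree with central
        differences on every parameter tensor."""
        config = nb.ModelConfig(
            embedding_dim=4, conv_filters=3, lstm_units=3, dense_units=4,
            dropout_rate=0.0, seed=1,
        )
        model = nb.build_model(config)
        rng = np.random.default_rng(0)
        x = rng.random((4, config.l_max, 3))
        x[:, :, 1] = rng.integers(0, 21, (4, config.l_max))
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def loss():
            return nn.bce_with_logits(model.logits(x, training=True), y)[0]

        for layer in model.iter_layers():
            layer.zero_grad()
        base_loss, dlogits = nn.bce_with_logits(
            model.logits(x, training=True), y)
        model.backward(dlogits[:, None])

        eps = 1e-6
        pick = np.random.default_rng(2)
        for p, g in model.parameters():
            flat, gflat = p.ravel(), g.ravel()
            for idx in pick.choice(flat.size, size=min(3, flat.size),
                                   replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(numeric) + abs(gflat[idx]))
                assert abs(numeric - gflat[idx]) / denom < 1e-4


class TestTraining:
    def test_overfits_trivially_separable_data(self, toy_dataset):
        config = nb.ModelConfig(epochs=30, batch_size=8,
                                validation_fraction=0.0, seed=0)
        trained = nb.fit(toy_dataset, config)
        probs = trained.predict_proba(nb.encode_batch(toy_dataset.records))
        preds = nb.classify(probs)
        assert (preds == toy_dataset.labels).all()

    def test_zero_epochs_keeps_initialization(self, toy_dataset, tiny_config):
        config = nb.ModelConfig(**{**tiny_config.__dict__, "epochs": 0})
        model = nb.build_model(config)
        init_state = [a.copy() for a in model.state_arrays()]
        trained = nb.train(model, toy_dataset, config)
        for before, after in zip(init_state, trained.model.state_arrays()):
            np.testing.assert_array_equal(before, after)
        probs = trained.predict_proba(nb.encode_batch(toy_dataset.records))
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_class_dataset_rejected(self):
        pos = [nb.PeptideRecord(id=f"p{i}", sequence="ACDEFGHK")
               for i in range(6)]
        ds = nb.LabeledDataset(records=pos, labels=np.ones(6, dtype=int),
                               ratio=None)
        with pytest.raises(TrainingError):
            nb.fit(ds, nb.ModelConfig(epochs=1, validation_fraction=0.0))

    def test_same_seed_identical_training(self, toy_dataset, tiny_config):
        a = nb.fit(toy_dataset, tiny_config)
        b = nb.fit(toy_dataset, tiny_config)
        assert a.history[-1]["train_loss"] == pytest.approx(
            b.history[-1]["train_loss"], abs=1e-12)
        x = nb.encode_batch(toy_dataset.records)
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_history_records_every_epoch(self, toy_dataset, tiny_config):
        trained = nb.fit(toy_dataset, tiny_config)
        assert [h["epoch"] for h in trained.history] == list(
            range(1, tiny_config.epochs + 1))
        assert all(np.isfinite(h["train_loss"]) for h in trained.history)

    @pytest.mark.parametrize("kind", VARIANTS)
    def test_all_variants_train_one_epoch(self, kind):
        ds = nb.generate(nb.SyntheticConfig(n_pos=25, n_neg=25, seed=0))
        config = nb.ModelConfig(embedding_dim=8, conv_filters=8, lstm_units=8,
                                dense_units=8, epochs=1, batch_size=16,
                                validation_fraction=0.0, seed=0)
        trained = nb.fit(ds, config, variant=kind)
        probs = trained.predict_proba(nb.encode_batch(ds.records))
        assert probs.shape == (50,)
        assert ((probs >= 0) & (probs <= 1)).all()


class TestPrediction:
    def test_batch_equals_single_item_prediction(self, toy_dataset, tiny_config):
        trained = nb.fit(toy_dataset, tiny_config)
        x = nb.encode_batch(toy_dataset.records)
        batch = trained.predict_proba(x)
        singles = np.array([trained.predict_proba(x[i:i + 1])[0]
                            for i in range(len(x))])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_duplicate_inputs_get_identical_outputs(self, toy_dataset,
                                                    tiny_config):
        trained = nb.fit(toy_dataset, tiny_config)
        x = nb.encode_batch([toy_dataset.records[0]] * 3)
        probs = trained.predict_proba(x)
        assert probs[0] == probs[1] == probs[2]

    def test_shape_mismatch_raises(self, toy_dataset, tiny_config):
        trained = nb.fit(toy_dataset, tiny_config)
        with pytest.raises(ShapeError):
            trained.predict_proba(np.zeros((2, 9, 3)))


class TestClassify:
    @pytest.mark.parametrize("p,expected", [(0.51, 1), (0.5, 0), (0.0, 0),
                                            (1.0, 1)])
    def test_strictly_greater_than_rule(self, p, expected):
        assert nb.classify(np.array([p]))[0] == expected

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nb.classify(np.array([0.5]), threshold=1.5)


class TestCheckpoint:
    def test_save_load_round_trip(self, toy_dataset, tiny_config, tmp_path):
        trained = nb.fit(toy_dataset, tiny_config)
        nb.save_model(trained, tmp_path / "model")
        loaded = nb.load_model(tmp_path / "model")
        assert loaded.variant == "full"
        assert loaded.config == tiny_config
        x = nb.encode_batch(toy_dataset.records)
        np.testing.assert_array_equal(trained.predict_proba(x),
                                      loaded.predict_proba(x))
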