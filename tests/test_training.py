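"""Label-smoothed cross-entropy, the training loop, and YAML configuration."""

import math

import numpy as np
import pytest
import yaml

from ms2fp.errors import ConfigError, Ms2fpError
from ms2fp.fingerprints import tanimoto
from ms2fp.fixtures import FixtureSpec
from ms2fp.inference import greedy_decode
from ms2fp.model import MintModel, load_checkpoint
from ms2fp.config import load_yaml_config, write_config_echo, CONFIG_ECHO_FILENAME
from ms2fp.training import TrainConfig, smoothed_cross_entropy, train, CHECKPOINT_FILENAME

from conftest import build_dataset, small_model_config


class TestSmoothedCrossEntropy:
    @pytest.mark.parametrize("smoothing", [0.0, 0.1, 0.5])
    def test_uniform_logits_give_log_k(self, smoothing, rng):
        k = 11
        logits = np.zeros((6, k))
        targets = rng.integers(1, k, 6)
        assert smoothed_cross_entropy(logits, targets, smoothing) == pytest.approx(math.log(k))

    def test_perfect_prediction_limit(self):
        logits = np.full((3, 5), -100.0)
        targets = np.array([1, 2, 3])
        logits[np.arange(3), targets] = 100.0
        assert smoothed_cross_entropy(logits, targets, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_positions(self):
        # K=4, eps=0.3: q = [0.7 on true, 0.1 elsewhere]
        logits = np.array([[1.0, 2.0, 0.5, -1.0], [0.0, 0.0, 3.0, 1.0]])
        targets = np.array([1, 2])
        eps, k = 0.3, 4
        expected = 0.0
        for row, t in zip(logits, targets):
            log_p = row - math.log(np.exp(row).sum())
            q = np.full(k, eps / (k - 1))
            q[t] = 1 - eps
            expected += -(q * log_p).sum()
        expected /= 2
        assert smoothed_cross_entropy(logits, targets, eps) == pytest.approx(expected)

    def test_zero_smoothing_equals_plain_cross_entropy(self, rng):
        logits = rng.normal(size=(20, 7))
        targets = rng.integers(1, 7, 20)
        log_p = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        plain = -log_p[np.arange(20), targets].mean()
        assert smoothed_cross_entropy(logits, targets, 0.0) == pytest.approx(plain, abs=1e-9)

    def test_pad_positions_excluded(self):
        logits = np.zeros((4, 5))
        targets = np.array([0, 0, 3, 0])  # only one scored position
        assert smoothed_cross_entropy(logits, targets, 0.0) == pytest.approx(math.log(5))

    def test_all_pad_undefined(self):
        with pytest.raises(Ms2fpError):
            smoothed_cross_entropy(np.zeros((2, 5)), np.zeros(2, dtype=int), 0.0)


@pytest.fixture(scope="module")
def tiny_memorization():
    """10 synthetic spectra with 16-bit fingerprints: an overfit oracle."""
    spec = FixtureSpec(n_compounds=10, n_bits=16, seed=11)
    return spec, *build_dataset(spec)


class TestTrainLoop:
    def test_memorizes_ten_spectra(self, tiny_memorization, tmp_path):
        spec, vocab, dataset, truths = tiny_memorization
        model = MintModel(small_model_config(vocab, spec.n_bits), seed=2)
        cfg = TrainConfig(
            epochs=200,
            batch_size=10,
            label_smoothing=0.0,
            learning_rate=1e-3,
            seed=9,
            output_directory=str(tmp_path),
        )
        model, log = train(dataset, model, cfg, vocab=vocab)
        assert log.best_loss < 0.05
        for (tokens, _), truth in zip(dataset, truths):
            decoded = greedy_decode(model, tokens)
            assert decoded.bits == truth.bits.bits
            assert tanimoto(decoded, truth.bits) == 1.0

    def test_zero_epochs_is_identity(self, tiny_memorization):
        spec, vocab, dataset, _ = tiny_memorization
        model = MintModel(small_model_config(vocab, spec.n_bits), seed=2)
        before = model.state_dict()
        model, log = train(dataset, model, TrainConfig(epochs=0))
        assert log.epoch_losses == [] and log.best_loss is None
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_same_seed_reproduces_loss_sequence(self, tiny_memorization):
        spec, vocab, dataset, _ = tiny_memorization
        losses = []
        for _ in range(2):
            model = MintModel(small_model_config(vocab, spec.n_bits), seed=2)
            cfg = TrainConfig(epochs=5, batch_size=4, learning_rate=1e-3, seed=9)
            _, log = train(dataset, model, cfg)
            losses.append(log.epoch_losses)
        assert losses[0] == losses[1]

    def test_best_loss_is_minimum(self, tiny_memorization):
        spec, vocab, dataset, _ = tiny_memorization
        model = MintModel(small_model_config(vocab, spec.n_bits), seed=2)
        _, log = train(dataset, model, TrainConfig(epochs=8, batch_size=4, learning_rate=1e-3, seed=9))
        assert log.best_loss == min(log.epoch_losses)
        assert log.epoch_losses[log.best_epoch] == log.best_loss

    def test_checkpoint_matches_best_epoch(self, tiny_memorization, tmp_path):
        spec, vocab, dataset, _ = tiny_memorization
        model = MintModel(small_model_config(vocab, spec.n_bits), seed=2)
        cfg = TrainConfig(
            epochs=12, batch_size=4, learning_rate=1e-3, seed=9, output_directory=str(tmp_path)
        )
        model, log = train(dataset, model, cfg, vocab=vocab)
        reloaded, _, _, extra = load_checkpoint(tmp_path / CHECKPOINT_FILENAME)
        assert extra["best_epoch"] == log.best_epoch
        assert extra["best_loss"] == pytest.approx(log.best_loss)
        restored = reloaded.state_dict()
        returned = model.state_dict()
        assert all(np.array_equal(restored[k], returned[k]) for k in returned)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], None, TrainConfig())


MINIMAL_YAML = """\
task: train
fingerprint:
  kind: ecfp
"""


class TestYamlConfig:
    def test_minimal_yaml_fills_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(MINIMAL_YAML)
        config = load_yaml_config(path)
        assert config.task == "train"
        assert config.fingerprint.kind == "ecfp" and config.fingerprint.n_bits == 2048
        assert config.vocabulary.mz_low == 50.0 and config.vocabulary.interval == 0.01
        assert config.model.d_model == 512 and config.model.n_heads == 2
        assert config.model.encoder_vocab_size == 95001
        assert config.model.decoder_vocab_size == 2051
        assert config.train.adam_betas == (0.9, 0.98)

    def test_missing_fingerprint_kind(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("task: train\n")
        with pytest.raises(ConfigError, match="fingerprint.kind"):
            load_yaml_config(path)

    def test_missing_task(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("fingerprint:\n  kind: ecfp\n")
        with pytest.raises(ConfigError, match="task"):
            load_yaml_config(path)

    def test_invalid_value_names_key(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(MINIMAL_YAML + "tokenizer:\n  interval: -0.01\n")
        with pytest.raises(ConfigError, match="tokenizer"):
            load_yaml_config(path)

    def test_unknown_key_warns(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(MINIMAL_YAML + "  frobnicate: 3\n")
        with pytest.warns(UserWarning, match="frobnicate"):
            load_yaml_config(path)

    def test_echo_round_trips_to_equal_config(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            MINIMAL_YAML
            + f"train:\n  epochs: 3\n  output_directory: {tmp_path / 'out'}\n"
            + "tokenizer:\n  use_entropy: true\n"
        )
        config = load_yaml_config(path)
        echo_path = tmp_path / "out" / CONFIG_ECHO_FILENAME
        assert echo_path.exists()
        reparsed = load_yaml_config(echo_path, write_echo=False)
        assert reparsed == config

    def test_echo_is_valid_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(MINIMAL_YAML)
        config = load_yaml_config(path)
        out = tmp_path / "echo.yaml"
        write_config_echo(config, out)
        assert isinstance(yaml.safe_load(out.read_text()), dict)
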