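"""Positional encoding, transformer forward contracts, parameter counting, checkpoints."""

import math

import numpy as np
import pytest

from ms2fp.errors import CheckpointError, DimensionError
from ms2fp.fingerprints import FingerprintSpec
from ms2fp.model import (
    MintModel,
    ModelConfig,
    count_parameters,
    decode_step,
    embed_and_encode,
    load_checkpoint,
    positional_encoding,
    save_checkpoint,
)
from ms2fp.msp_io import Peak, Spectrum
from ms2fp.tokenizer import TokenVocabulary, encode_spectrum


def tiny_config(**overrides):
    defaults = dict(
        encoder_vocab_size=12,
        decoder_vocab_size=9,
        d_model=8,
        n_heads=2,
        n_encoder_layers=1,
        n_decoder_layers=1,
        d_feedforward=16,
        dropout=0.0,
        max_seq_len=16,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form sum of the layer shapes of the post-norm transformer."""
    d, dff = cfg.d_model, cfg.d_feedforward
    dense = lambda i, o: i * o + o  # noqa: E731
    attention = 4 * dense(d, d)
    feedforward = dense(d, dff) + dense(dff, d)
    norm = 2 * d
    encoder_layer = attention + feedforward + 2 * norm
    decoder_layer = 2 * attention + feedforward + 3 * norm
    return (
        cfg.encoder_vocab_size * d
        + cfg.decoder_vocab_size * d
        + cfg.n_encoder_layers * encoder_layer
        + cfg.n_decoder_layers * decoder_layer
        + dense(d, cfg.decoder_vocab_size)
    )


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding([0], [7.3], d_model=8)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_unit_arguments(self):
        pe = positional_encoding([1], [1.0], d_model=8)
        assert pe[0, 0] == pytest.approx(math.sin(1.0))
        assert pe[0, 1] == pytest.approx(math.cos(1.0 / 10000 ** (1 / 8)))

    def test_intensity_position_product_symmetry(self):
        for pos, intensity in [(2.0, 3.0), (5.0, 0.25), (7.0, 1.5)]:
            a = positional_encoding([pos], [2 * intensity], d_model=16)
            b = positional_encoding([2 * pos], [intensity], d_model=16)
            assert np.allclose(a, b)

    def test_bounded(self, rng):
        pe = positional_encoding(rng.integers(0, 100, 50), rng.random(50) * 3, 32)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)

    def test_classic_mode_matches_textbook_encoding(self):
        d = 16
        positions = np.arange(10)
        pe = positional_encoding(positions, np.ones(10), d, classic_pe=True)
        i = np.arange(d // 2)
        angles = positions[:, None] / 10000 ** (2 * i / d)
        assert np.allclose(pe[:, 0::2], np.sin(angles))
        assert np.allclose(pe[:, 1::2], np.cos(angles))

    def test_printed_formula_odd_exponent_differs_from_classic(self):
        pe = positional_encoding([3], [1.0], 8, classic_pe=False)
        classic = positional_encoding([3], [1.0], 8, classic_pe=True)
        assert np.allclose(pe[0, 0::2], classic[0, 0::2])  # sine columns identical
        assert not np.allclose(pe[0, 1::2], classic[0, 1::2])

    def test_misaligned_inputs(self):
        with pytest.raises(DimensionError):
            positional_encoding([0, 1], [1.0], 8)


class TestParameterCount:
    def test_tiny_config_hand_count(self):
        cfg = tiny_config(d_model=4, d_feedforward=8, encoder_vocab_size=10, decoder_vocab_size=10)
        # by hand: MHA 4*(4*4+4)=80; FF (4*8+8)+(8*4+4)=76; LN 8 each
        # encoder layer 80+76+16=172; decoder layer 160+76+24=260
        # embeddings 2*40=80; output projection 4*10+10=50
        assert count_parameters(MintModel(cfg, seed=0)) == 172 + 260 + 80 + 50

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(),
            dict(d_model=16, n_heads=4, d_feedforward=32),
            dict(n_encoder_layers=3, n_decoder_layers=2, encoder_vocab_size=101, decoder_vocab_size=35),
        ],
    )
    def test_matches_closed_form(self, overrides):
        cfg = tiny_config(**overrides)
        assert count_parameters(MintModel(cfg, seed=0)) == expected_parameter_count(cfg)

    def test_layer_additivity(self):
        base = count_parameters(MintModel(tiny_config(n_encoder_layers=1), seed=0))
        doubled = count_parameters(MintModel(tiny_config(n_encoder_layers=2), seed=0))
        per_layer = doubled - base
        tripled = count_parameters(MintModel(tiny_config(n_encoder_layers=3), seed=0))
        assert tripled == base + 2 * per_layer


class TestForwardContracts:
    @pytest.fixture()
    def model(self):
        return MintModel(tiny_config(dropout=0.1), seed=1)

    @pytest.fixture()
    def spectrum_tokens(self):
        vocab = TokenVocabulary(mz_low=50.0, mz_high=60.0, interval=1.0)
        s = Spectrum(
            peaks=[Peak(52.0, 1.0), Peak(55.0, 3.0)], precursor_mz=58.0
        )
        return encode_spectrum(s, vocab)

    def test_eval_mode_is_deterministic_despite_dropout(self, model, spectrum_tokens):
        first = embed_and_encode(spectrum_tokens, model)
        second = embed_and_encode(spectrum_tokens, model)
        assert np.array_equal(first, second)

    def test_memory_shape(self, model, spectrum_tokens):
        memory = embed_and_encode(spectrum_tokens, model)
        assert memory.shape == (spectrum_tokens.length, 8)

    def test_decode_step_is_a_distribution(self, model, spectrum_tokens):
        memory = embed_and_encode(spectrum_tokens, model)
        probs = decode_step(memory, [1, 4], model)
        assert probs.shape == (9,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_output_projection_gives_uniform(self, model, spectrum_tokens):
        model.out_proj.params["W"][...] = 0.0
        model.out_proj.params["b"][...] = 0.0
        memory = embed_and_encode(spectrum_tokens, model)
        probs = decode_step(memory, [1], model)
        assert np.allclose(probs, 1.0 / 9)

    def test_empty_prefix_rejected(self, model, spectrum_tokens):
        memory = embed_and_encode(spectrum_tokens, model)
        with pytest.raises(DimensionError):
            decode_step(memory, [], model)

    def test_token_out_of_vocabulary(self, model):
        with pytest.raises(IndexError):
            model.enc_embed.forward(np.array([[99]]))

    def test_causal_masking_by_perturbation(self, model, spectrum_tokens):
        memory = embed_and_encode(spectrum_tokens, model)
        enc_pad = np.zeros((1, memory.shape[0]), dtype=bool)
        prefix_a = np.array([[1, 4, 5, 6]])
        prefix_b = np.array([[1, 4, 7, 8]])  # differs only after position 1
        logits_a = model.decode(memory[None], enc_pad, prefix_a, train=False)
        logits_b = model.decode(memory[None], enc_pad, prefix_b, train=False)
        assert np.allclose(logits_a[0, :2], logits_b[0, :2])
        assert not np.allclose(logits_a[0, 2:], logits_b[0, 2:])

    def test_forward_outputs_finite(self, model, rng):
        enc_ids = rng.integers(1, 12, (3, 5))
        pe = rng.uniform(-1, 1, (3, 5, 8))
        enc_pad = np.zeros((3, 5), dtype=bool)
        dec_ids = rng.integers(1, 9, (3, 4))
        logits = model.forward(enc_ids, pe, enc_pad, dec_ids, train=False)
        assert logits.shape == (3, 4, 9)
        assert np.all(np.isfinite(logits))


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        cfg = tiny_config()
        model = MintModel(cfg, seed=4)
        vocab = TokenVocabulary(mz_low=50.0, mz_high=60.0, interval=1.0)
        fp_spec = FingerprintSpec(kind="custom", n_bits=6)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, vocab, fp_spec, metadata={"note": "test"})
        reloaded, vocab2, fp2, extra = load_checkpoint(path)
        assert vocab2 == vocab
        assert fp2 == fp_spec
        assert extra["note"] == "test"
        enc_ids = rng.integers(1, 12, (2, 4))
        pe = rng.uniform(-1, 1, (2, 4, 8))
        enc_pad = np.zeros((2, 4), dtype=bool)
        dec_ids = rng.integers(1, 9, (2, 3))
        original = model.forward(enc_ids, pe, enc_pad, dec_ids, train=False)
        restored = reloaded.forward(enc_ids, pe, enc_pad, dec_ids, train=False)
        assert np.array_equal(original, restored)

    def test_corrupted_checkpoint(self, tmp_path):
        path = tmp_path / "broken.npz"
        path.write_text("this is not a checkpoint")
        with pytest.raises(CheckpointError):
            load_checkpoint(path)


class TestConfigValidation:
    def test_d_model_head_divisibility(self):
        with pytest.raises(ValueError):
            tiny_config(d_model=10, n_heads=4)

    def test_odd_d_model_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(d_model=7, n_heads=1)
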