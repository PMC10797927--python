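"""Shared fixtures: synthetic libraries and a small memorization-trained model."""

import numpy as np
import pytest

from ms2fp.fixtures import FixtureSpec, generate_library
from ms2fp.model import ModelConfig, MintModel
from ms2fp.msp_io import parse_msp
from ms2fp.tokenizer import TokenVocabulary, encode_spectrum, encode_target
from ms2fp.training import TrainConfig, train

# study conditions of the desk-scale learnability check: 50 synthetic compounds
# with 64-bit fingerprints, fixed seed
LEARNABILITY_SPEC = FixtureSpec(n_compounds=50, n_bits=64, seed=7)


def build_dataset(spec: FixtureSpec, use_entropy: bool = True):
    """Generate a library, tokenize it, and return (vocab, dataset, truths)."""
    msp_text, truths = generate_library(spec)
    vocab = TokenVocabulary(mz_low=spec.mz_low, mz_high=spec.mz_high, interval=spec.interval)
    parsed = parse_msp(msp_text)
    assert len(parsed) == spec.n_compounds
    dataset = [
        (encode_spectrum(s, vocab, use_entropy=use_entropy), encode_target(t.bits))
        for s, t in zip(parsed.spectra, truths)
    ]
    return vocab, dataset, truths


def small_model_config(vocab: TokenVocabulary, n_bits: int) -> ModelConfig:
    return ModelConfig(
        encoder_vocab_size=vocab.vocab_size,
        decoder_vocab_size=n_bits + 3,
        d_model=64,
        n_heads=2,
        n_encoder_layers=1,
        n_decoder_layers=1,
        d_feedforward=128,
        dropout=0.0,
        max_seq_len=64,
    )


@pytest.fixture(scope="session")
def learnability_setup():
    """(vocab, dataset, truths) for the 50-compound learnability library."""
    return build_dataset(LEARNABILITY_SPEC)


@pytest.fixture(scope="session")
def memorized_model(learnability_setup, tmp_path_factory):
    """A small transformer trained to memorize the 50-compound library."""
    vocab, dataset, truths = learnability_setup
    model = MintModel(small_model_config(vocab, LEARNABILITY_SPEC.n_bits), seed=3)
    out_dir = tmp_path_factory.mktemp("memorized")
    cfg = TrainConfig(
        epochs=60,
        batch_size=10,
        label_smoothing=0.0,
        learning_rate=1e-3,
        seed=5,
        output_directory=str(out_dir),
    )
    model, log = train(dataset, model, cfg, vocab=vocab)
    return {"model": model, "log": log, "out_dir": out_dir, "vocab": vocab}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
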