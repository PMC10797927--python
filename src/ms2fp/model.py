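"""Encoder-decoder transformer with intensity-weighted positional encoding.

The encoder consumes m/z bin tokens whose sinusoidal positional encoding is
modulated by pseudo-intensity: the sinusoid argument is ``intensity * rank``
rather than the bare position, so abundant fragments are emphasized under the
hypothesis that ion abundance reflects sub-structure importance. Decoder-side
fingerprint-bit tokens receive no positional encoding (their ascending order
is a grammar, not a geometry). A linear layer and softmax over the decoder
vocabulary produce next-bit-token probabilities.

The network is built from the NumPy layers in :mod:`ms2fp.nn`; a checkpoint is
a ``.npz`` archive of all weights plus a JSON echo of the model configuration
and token vocabulary, so checkpoints are self-describing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ms2fp import nn
from ms2fp.errors import CheckpointError, DimensionError
from ms2fp.fingerprints import FingerprintSpec
from ms2fp.tokenizer import TokenVocabulary, TokenizedSpectrum


@dataclass
class ModelConfig:
    """Hyperparameters of the transformer.

    ``encoder_vocab_size`` is the number of m/z bins plus padding;
    ``decoder_vocab_size`` is the fingerprint length plus the three special
    tokens (pad, start, end).
    """

    encoder_vocab_size: int
    decoder_vocab_size: int
    d_model: int = 512
    n_heads: int = 2
    n_encoder_layers: int = 4
    n_decoder_layers: int = 4
    d_feedforward: int = 2048
    dropout: float = 0.1
    max_seq_len: int = 512
    classic_pe: bool = False
    scale_embedding: bool = True

    def __post_init__(self):
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (sin/cos column pairs)")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for name in (
            "encoder_vocab_size",
            "decoder_vocab_size",
            "d_model",
            "n_heads",
            "n_encoder_layers",
            "n_decoder_layers",
            "d_feedforward",
            "max_seq_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def positional_encoding(
    ranks,
    intensities,
    d_model: int,
    classic_pe: bool = False,
) -> np.ndarray:
    """Intensity-weighted sinusoidal positional encoding.

    Entry (p, 2i)   = sin(int_p * pos_p / 10000^(2i / d_model))
    Entry (p, 2i+1) = cos(int_p * pos_p / 10000^((2i+1) / d_model))

    With ``classic_pe`` the cosine column reuses the sine column's exponent
    (2i / d_model), recovering the classic sinusoidal encoding whenever the
    intensities are identically 1.
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if ranks.shape != intensities.shape:
        raise DimensionError("ranks and intensities must be aligned")
    arg = (intensities * ranks)[..., None]
    i = np.arange(d_model // 2, dtype=np.float64)
    div_even = np.power(10000.0, (2 * i) / d_model)
    odd_exponent = (2 * i) / d_model if classic_pe else (2 * i + 1) / d_model
    div_odd = np.power(10000.0, odd_exponent)
    pe = np.empty(ranks.shape + (d_model,), dtype=np.float64)
    pe[..., 0::2] = np.sin(arg / div_even)
    pe[..., 1::2] = np.cos(arg / div_odd)
    return pe


class MintModel(nn.Layer):
    """The full encoder-decoder network.

    Forward passes are batched: token-id arrays of shape (batch, length) with
    boolean is-pad masks. ``forward`` caches everything ``backward`` needs, so
    the usual usage is ``zero_grad(); forward(...); backward(dlogits)``.
    """

    def __init__(self, config: ModelConfig, seed: int | np.random.Generator = 0):
        super().__init__()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.config = config
        c = config
        self.enc_embed = self.add_child("enc_embed", nn.Embedding(c.encoder_vocab_size, c.d_model, rng))
        self.dec_embed = self.add_child("dec_embed", nn.Embedding(c.decoder_vocab_size, c.d_model, rng))
        self.enc_drop = self.add_child("enc_drop", nn.Dropout(c.dropout))
        self.dec_drop = self.add_child("dec_drop", nn.Dropout(c.dropout))
        self.encoder_layers = [
            self.add_child(
                f"encoder.{k}",
                nn.EncoderLayer(c.d_model, c.n_heads, c.d_feedforward, c.dropout, rng),
            )
            for k in range(c.n_encoder_layers)
        ]
        self.decoder_layers = [
            self.add_child(
                f"decoder.{k}",
                nn.DecoderLayer(c.d_model, c.n_heads, c.d_feedforward, c.dropout, rng),
            )
            for k in range(c.n_decoder_layers)
        ]
        self.out_proj = self.add_child("out_proj", nn.Dense(c.d_model, c.decoder_vocab_size, rng))
        self._emb_scale = math.sqrt(c.d_model) if c.scale_embedding else 1.0
        self._cache = None

    # ---------------------------------------------------------------- forward
    def encode(
        self,
        enc_ids: np.ndarray,
        enc_pe: np.ndarray,
        enc_pad: np.ndarray,
        rng: np.random.Generator | None = None,
        train: bool = False,
    ) -> np.ndarray:
        """Embed + positional-encode + dropout + encoder stack -> memory."""
        src_mask = nn.padding_mask(enc_pad)
        x = self.enc_embed.forward(enc_ids) * self._emb_scale + enc_pe
        x = self.enc_drop.forward(x, rng, train)
        for layer in self.encoder_layers:
            x = layer.forward(x, src_mask, rng, train)
        return x

    def decode(
        self,
        memory: np.ndarray,
        enc_pad: np.ndarray,
        dec_ids: np.ndarray,
        dec_pad: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        train: bool = False,
    ) -> np.ndarray:
        """Decoder stack with causal masking -> logits (batch, Ld, vocab)."""
        if dec_pad is None:
            dec_pad = np.zeros(dec_ids.shape, dtype=bool)
        tgt_mask = nn.causal_mask(dec_ids.shape[1]) + nn.padding_mask(dec_pad)
        mem_mask = nn.padding_mask(enc_pad)
        y = self.dec_embed.forward(dec_ids) * self._emb_scale
        y = self.dec_drop.forward(y, rng, train)
        for layer in self.decoder_layers:
            y = layer.forward(y, memory, tgt_mask, mem_mask, rng, train)
        return self.out_proj.forward(y)

    def forward(
        self,
        enc_ids: np.ndarray,
        enc_pe: np.ndarray,
        enc_pad: np.ndarray,
        dec_ids: np.ndarray,
        dec_pad: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        train: bool = False,
    ) -> np.ndarray:
        memory = self.encode(enc_ids, enc_pe, enc_pad, rng, train)
        return self.decode(memory, enc_pad, dec_ids, dec_pad, rng, train)

    # --------------------------------------------------------------- backward
    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from the output logits through the whole network."""
        g = self.out_proj.backward(dlogits)
        d_memory = 0.0
        for layer in reversed(self.decoder_layers):
            g, dm = layer.backward(g)
            d_memory = d_memory + dm
        g = self.dec_drop.backward(g)
        self.dec_embed.backward(g * self._emb_scale)
        g = d_memory
        for layer in reversed(self.encoder_layers):
            g = layer.backward(g)
        g = self.enc_drop.backward(g)
        self.enc_embed.backward(g * self._emb_scale)

    # --------------------------------------------------------------- weights
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: value.copy() for name, value, _ in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: value for name, value, _ in self.named_parameters()}
        missing = set(own) - set(state)
        if missing:
            raise CheckpointError(f"checkpoint missing parameters: {sorted(missing)[:3]}...")
        for name, value in own.items():
            value[...] = state[name]


def embed_and_encode(tokens: TokenizedSpectrum, model: MintModel) -> np.ndarray:
    """Encode a single tokenized spectrum to its memory matrix (length, d_model)."""
    enc_ids = np.asarray([tokens.token_ids])
    pe = positional_encoding(
        [tokens.ranks], [tokens.pseudo_intensities], model.config.d_model, model.config.classic_pe
    )
    enc_pad = np.zeros((1, tokens.length), dtype=bool)
    return model.encode(enc_ids, pe, enc_pad, train=False)[0]


def decode_step(memory: np.ndarray, prefix: list[int], model: MintModel) -> np.ndarray:
    """Next-token probabilities given an encoded spectrum and a decoder prefix."""
    if not prefix:
        raise DimensionError("decoder prefix must begin with the start token")
    enc_pad = np.zeros((1, memory.shape[0]), dtype=bool)
    logits = model.decode(memory[None, :, :], enc_pad, np.asarray([prefix]), train=False)
    return nn.softmax(logits[0, -1])


def count_parameters(model: MintModel) -> int:
    """Total trainable scalar parameters, embedding tables included."""
    return model.n_parameters()


def save_checkpoint(
    path: str | Path,
    model: MintModel,
    vocab: TokenVocabulary,
    fingerprint_spec: FingerprintSpec | None = None,
    metadata: dict | None = None,
) -> None:
    """Serialize weights plus the configuration needed to rebuild the model."""
    meta = {
        "model_config": asdict(model.config),
        "vocabulary": {"mz_low": vocab.mz_low, "mz_high": vocab.mz_high, "interval": vocab.interval},
        "fingerprint": asdict(fingerprint_spec) if fingerprint_spec else None,
        "extra": metadata or {},
    }
    arrays = {f"param/{name}": value for name, value, _ in model.named_parameters()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[MintModel, TokenVocabulary, FingerprintSpec | None, dict]:
    """Rebuild a model (weights and config) from a checkpoint file."""
    try:
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
    except Exception as err:  # noqa: BLE001 - any unreadable file is a checkpoint error
        raise CheckpointError(f"cannot load checkpoint {path}: {err}") from err
    config = ModelConfig(**meta["model_config"])
    model = MintModel(config, seed=0)
    state = {key[len("param/"):]: archive[key] for key in archive.files if key.startswith("param/")}
    model.load_state_dict(state)
    vocab = TokenVocabulary(**meta["vocabulary"])
    fp_spec = FingerprintSpec(**meta["fingerprint"]) if meta.get("fingerprint") else None
    return model, vocab, fp_spec, meta.get("extra", {})
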