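"""Beam-search decoding of fingerprint bit sequences from a trained model.

The decoder's targets are always strictly ascending bit tokens, so decoding
enforces ascent as a hard admissibility mask: after emitting bit token t, only
tokens greater than t (plus the end sentinel) may follow. This guarantees every
returned hypothesis is a valid fingerprint and keeps the beam from wasting
capacity on sequences the model was never trained to produce.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ms2fp import nn
from ms2fp.errors import DegenerateSpectrumError, TokenizationError
from ms2fp.fingerprints import BitSet, FingerprintSpec
from ms2fp.model import MintModel, embed_and_encode, load_checkpoint
from ms2fp.msp_io import parse_msp, coverage_filter
from ms2fp.tokenizer import (
    BIT_TOKEN_OFFSET,
    END_ID,
    START_ID,
    TokenizedSpectrum,
    encode_spectrum,
)


@dataclass
class BeamHypothesis:
    """A growing decoder prefix with its cumulative log probability."""

    tokens: list[int]
    log_prob: float
    finished: bool = False

    @property
    def last_bit_token(self) -> int:
        interior = [t for t in self.tokens[1:] if t >= BIT_TOKEN_OFFSET]
        return interior[-1] if interior else BIT_TOKEN_OFFSET - 1

    @property
    def n_bits_emitted(self) -> int:
        return sum(1 for t in self.tokens[1:] if t >= BIT_TOKEN_OFFSET)


@dataclass
class Prediction:
    """A decoded bit set with its beam score and rank among returned beams."""

    bits: BitSet
    score: float
    rank: int


def beam_search(
    model: MintModel,
    spectrum: TokenizedSpectrum,
    beam_width: int = 5,
    max_bits: int | None = None,
    length_penalty: float = 0.0,
) -> list[Prediction]:
    """Decode up to ``beam_width`` fingerprint hypotheses, best first.

    Hypotheses are compared by raw cumulative log probability (optionally
    normalized by length^penalty). Expansion stops at the end sentinel or after
    ``max_bits`` interior tokens, at which point only the end token remains
    admissible and the hypothesis is closed with a warning.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be at least 1")
    vocab_size = model.config.decoder_vocab_size
    n_bits = vocab_size - BIT_TOKEN_OFFSET
    if max_bits is None:
        max_bits = n_bits

    memory = embed_and_encode(spectrum, model)
    enc_pad = np.zeros((1, memory.shape[0]), dtype=bool)

    live = [BeamHypothesis(tokens=[START_ID], log_prob=0.0)]
    finished: list[BeamHypothesis] = []
    forced_termination = False

    def sort_key(h: BeamHypothesis) -> float:
        if length_penalty > 0:
            return h.log_prob / max(1, len(h.tokens) - 1) ** length_penalty
        return h.log_prob

    while live:
        dec_ids = np.asarray([h.tokens for h in live])
        mem_batch = np.broadcast_to(memory, (len(live),) + memory.shape)
        logits = model.decode(
            mem_batch, np.broadcast_to(enc_pad, (len(live), memory.shape[0])), dec_ids, train=False
        )
        log_probs = np.log(nn.softmax(logits[:, -1, :]) + 1e-300)

        expansions: list[BeamHypothesis] = []
        for row, hyp in zip(log_probs, live):
            open_bits = range(hyp.last_bit_token + 1, vocab_size)
            if hyp.n_bits_emitted >= max_bits:
                if len(open_bits):  # the cap, not the grammar, stops this hypothesis
                    forced_termination = True
                admissible = [END_ID]
            else:
                admissible = [END_ID] + list(open_bits)
            for token in admissible:
                expansions.append(
                    BeamHypothesis(
                        tokens=hyp.tokens + [token],
                        log_prob=hyp.log_prob + float(row[token]),
                        finished=token == END_ID,
                    )
                )
        expansions.sort(key=sort_key, reverse=True)
        beam = expansions[:beam_width]
        # completed hypotheses leave the beam and are never pruned by partials
        finished.extend(h for h in beam if h.finished)
        live = [h for h in beam if not h.finished]
        if len(finished) >= beam_width:
            # cumulative log probabilities only decrease with length, so once
            # enough hypotheses have finished above every live score the search
            # cannot improve
            worst_kept = sorted(finished, key=sort_key, reverse=True)[beam_width - 1]
            if all(sort_key(h) <= sort_key(worst_kept) for h in live):
                break

    if forced_termination:
        warnings.warn(
            f"beam search closed hypotheses after reaching max_bits={max_bits}",
            stacklevel=2,
        )

    finished.sort(key=sort_key, reverse=True)
    predictions = []
    for rank, hyp in enumerate(finished[:beam_width]):
        bits = tuple(t - BIT_TOKEN_OFFSET for t in hyp.tokens[1:-1])
        predictions.append(
            Prediction(bits=BitSet(bits=bits, n_bits=n_bits), score=hyp.log_prob, rank=rank)
        )
    return predictions


def greedy_decode(model: MintModel, spectrum: TokenizedSpectrum, max_bits: int | None = None) -> BitSet:
    """Width-1 beam search; convenience for memorization checks."""
    return beam_search(model, spectrum, beam_width=1, max_bits=max_bits)[0].bits


def predict_file(
    msp_path: str | Path,
    checkpoint_path: str | Path,
    beam_width: int = 5,
    max_bits: int | None = None,
    min_coverage_fraction: float = 0.9,
    use_entropy: bool = False,
    precursor_pseudo_intensity: float = 2.0,
    max_seq_len: int | None = 512,
    fingerprint_key: str = "fingerprint",
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Batch prediction over an .msp file with a self-describing checkpoint.

    Returns (and optionally writes as tab-separated text) one row per MSP
    block: identifier, status (``ok`` or the reason the spectrum was skipped),
    the predicted bit positions serialized as comma-separated integers, and
    the winning beam's log probability.
    """
    model, vocab, fp_spec, extra = load_checkpoint(checkpoint_path)
    if fp_spec is not None and fp_spec.n_bits + BIT_TOKEN_OFFSET != model.config.decoder_vocab_size:
        raise ValueError(
            "checkpoint fingerprint length inconsistent with decoder vocabulary"
        )
    with open(msp_path) as handle:
        parsed = parse_msp(handle, fingerprint_key=fingerprint_key)

    rows = []
    for spectrum in parsed.spectra:
        kept, _ = coverage_filter([spectrum], min_coverage_fraction, vocab.mz_low, vocab.mz_high)
        if not kept:
            rows.append((spectrum.name, "skipped: fragment coverage below threshold", "", math.nan))
            continue
        try:
            tokens = encode_spectrum(
                spectrum,
                vocab,
                use_entropy=use_entropy,
                precursor_pseudo_intensity=precursor_pseudo_intensity,
                max_seq_len=max_seq_len,
            )
        except (TokenizationError, DegenerateSpectrumError) as err:
            rows.append((spectrum.name, f"skipped: {err}", "", math.nan))
            continue
        best = beam_search(model, tokens, beam_width=beam_width, max_bits=max_bits)[0]
        rows.append((spectrum.name, "ok", best.bits.serialize(), best.score))

    table = pd.DataFrame(rows, columns=["identifier", "status", "predicted_bits", "beam_log_prob"])
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
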