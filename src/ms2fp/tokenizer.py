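"""Tokenization of spectra (encoder side) and fingerprints (decoder side).

Encoder side: fragment m/z values are mapped into constant-width bins over a
configured range; each token is paired with a pseudo-intensity (the unit-sum
normalized fragment intensity) and with its rank in the descending-intensity
order, which feeds the intensity-weighted positional encoding. The tokenized
precursor m/z is prepended at rank 0 with a pseudo-intensity of either the
spectrum's Shannon entropy or a constant (default 2, deliberately larger than
any normalized fragment intensity).

Decoder side: the set-bit positions of a fingerprint become a token sequence,
framed by start/end sentinels, submitted in ascending order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from ms2fp.errors import DecodeError, DegenerateSpectrumError, DimensionError, TokenizationError
from ms2fp.msp_io import Peak, Spectrum
from ms2fp.fingerprints import BitSet

# decoder-side sentinels
PAD_ID = 0
START_ID = 1
END_ID = 2
BIT_TOKEN_OFFSET = 3

#: sentinel returned by tokenize_mz for values outside the vocabulary range
OUT_OF_RANGE = None


@dataclass(frozen=True)
class TokenVocabulary:
    """Constant-interval m/z binning over [mz_low, mz_high].

    Token 0 is padding; tokens 1..n_mz_tokens are the bins. ``mz_high`` maps
    to the last bin (closed upper edge).
    """

    mz_low: float = 50.0
    mz_high: float = 1000.0
    interval: float = 0.01

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.mz_low >= self.mz_high:
            raise ValueError("mz_low must be smaller than mz_high")

    @property
    def n_mz_tokens(self) -> int:
        return math.ceil((self.mz_high - self.mz_low) / self.interval)

    @property
    def vocab_size(self) -> int:
        return self.n_mz_tokens + 1  # + padding

    pad_id: int = field(default=0, init=False, repr=False)
    first_mz_id: int = field(default=1, init=False, repr=False)


@dataclass
class TokenizedSpectrum:
    """Encoder input: aligned token, pseudo-intensity and rank sequences.

    Element 0 is the precursor; the remaining elements are fragments in
    descending pseudo-intensity order. Fragment pseudo-intensities sum to 1.
    """

    token_ids: list[int]
    pseudo_intensities: list[float]
    ranks: list[int]

    def __post_init__(self):
        if not (len(self.token_ids) == len(self.pseudo_intensities) == len(self.ranks)):
            raise DimensionError("token/intensity/rank sequences must be aligned")
        if len(self.token_ids) < 1:
            raise DimensionError("TokenizedSpectrum must be non-empty")

    @property
    def length(self) -> int:
        return len(self.token_ids)


@dataclass
class FingerprintTarget:
    """Decoder token sequence: [start] + ascending shifted bits + [end]."""

    token_ids: list[int]
    n_vocab: int

    @property
    def length(self) -> int:
        return len(self.token_ids)


def tokenize_mz(mz: float, vocab: TokenVocabulary):
    """Map an m/z value to its bin token, or OUT_OF_RANGE (None).

    The bin index is floor((mz - mz_low)/interval); the tiny additive guard
    keeps exact bin edges stable against float subtraction error. ``mz_high``
    itself maps to the last bin.
    """
    if mz < vocab.mz_low or mz > vocab.mz_high:
        return OUT_OF_RANGE
    idx = int(math.floor((mz - vocab.mz_low) / vocab.interval + 1e-9))
    if idx >= vocab.n_mz_tokens:  # closed upper edge
        idx = vocab.n_mz_tokens - 1
    return vocab.first_mz_id + idx


def normalize_intensities(peaks: Sequence[Peak]) -> list[float]:
    """Unit-sum normalization of peak intensities."""
    total = sum(p.intensity for p in peaks)
    if total <= 0:
        raise DegenerateSpectrumError("all peak intensities are zero")
    return [p.intensity / total for p in peaks]


def spectral_entropy(peaks: Sequence[Peak]) -> float:
    """Shannon entropy (natural log) of the unit-sum normalized intensities.

    Zero-intensity peaks contribute nothing; a single-peak spectrum has
    entropy 0 and an n-peak uniform spectrum has entropy ln n.
    """
    probs = normalize_intensities(peaks)
    return -sum(p * math.log(p) for p in probs if p > 0)


def encode_spectrum(
    spectrum: Spectrum,
    vocab: TokenVocabulary,
    use_entropy: bool = False,
    precursor_pseudo_intensity: float = 2.0,
    max_seq_len: int | None = 512,
) -> TokenizedSpectrum:
    """Tokenize a spectrum into the encoder input sequences.

    Fragments outside the vocabulary range are dropped; the survivors'
    intensities are unit-sum normalized and sorted by descending
    pseudo-intensity (ties broken by ascending m/z). The precursor token is
    prepended at rank 0 with pseudo-intensity equal to the spectral entropy of
    the original peak list when ``use_entropy`` is set, otherwise the constant
    ``precursor_pseudo_intensity``. Spectra longer than ``max_seq_len`` keep
    the precursor plus the most intense fragments, renormalized.
    """
    precursor_token = tokenize_mz(spectrum.precursor_mz, vocab)
    if precursor_token is OUT_OF_RANGE:
        raise TokenizationError(
            f"precursor m/z {spectrum.precursor_mz} outside vocabulary range "
            f"[{vocab.mz_low}, {vocab.mz_high}]"
        )

    fragments = []  # (token, raw_intensity, mz)
    for peak in spectrum.peaks:
        token = tokenize_mz(peak.mz, vocab)
        if token is not OUT_OF_RANGE:
            fragments.append((token, peak.intensity, peak.mz))
    if not fragments:
        raise DegenerateSpectrumError(
            f"spectrum {spectrum.name!r}: no fragments inside the vocabulary range"
        )

    total = sum(intensity for _, intensity, _ in fragments)
    if total <= 0:
        raise DegenerateSpectrumError(f"spectrum {spectrum.name!r}: zero intensity mass")
    normalized = [(tok, intensity / total, mz) for tok, intensity, mz in fragments]
    normalized.sort(key=lambda t: (-t[1], t[2]))

    if max_seq_len is not None and len(normalized) + 1 > max_seq_len:
        normalized = normalized[: max_seq_len - 1]
        kept_total = sum(w for _, w, _ in normalized)
        normalized = [(tok, w / kept_total, mz) for tok, w, mz in normalized]

    if use_entropy:
        precursor_pi = spectral_entropy(spectrum.peaks)
    else:
        precursor_pi = float(precursor_pseudo_intensity)

    token_ids = [precursor_token] + [tok for tok, _, _ in normalized]
    pseudo = [precursor_pi] + [w for _, w, _ in normalized]
    ranks = list(range(len(token_ids)))
    return TokenizedSpectrum(token_ids=token_ids, pseudo_intensities=pseudo, ranks=ranks)


def encode_target(bits: BitSet) -> FingerprintTarget:
    """Decoder target: start sentinel, shifted ascending bits, end sentinel."""
    token_ids = [START_ID] + [b + BIT_TOKEN_OFFSET for b in bits.bits] + [END_ID]
    return FingerprintTarget(token_ids=token_ids, n_vocab=bits.n_bits + BIT_TOKEN_OFFSET)


def decode_target(target: FingerprintTarget) -> BitSet:
    """Inverse of :func:`encode_target`; rejects malformed sequences."""
    tokens = target.token_ids
    if len(tokens) < 2 or tokens[0] != START_ID or tokens[-1] != END_ID:
        raise DecodeError("target must be framed by start and end sentinels")
    interior = tokens[1:-1]
    n_bits = target.n_vocab - BIT_TOKEN_OFFSET
    bits = []
    for tok in interior:
        if tok < BIT_TOKEN_OFFSET or tok >= target.n_vocab:
            raise DecodeError(f"unknown decoder token id {tok}")
        bits.append(tok - BIT_TOKEN_OFFSET)
    for b1, b2 in zip(bits, bits[1:]):
        if b2 <= b1:
            raise DecodeError("interior tokens must be strictly ascending")
    return BitSet(bits=tuple(bits), n_bits=n_bits)
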