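"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's optimized code paths: the Tanimoto
oracle loops bit by bit, the tokenizer oracle is bare floor arithmetic, and
the decoding oracle exhaustively scores every ascending bit sequence.
"""

import itertools
import math

import numpy as np

from ms2fp.model import MintModel, decode_step, embed_and_encode
from ms2fp.tokenizer import BIT_TOKEN_OFFSET, END_ID, START_ID, TokenizedSpectrum


def tanimoto_bit_loop(bits_a, bits_b, n_bits: int) -> float:
    """Bit-by-bit dense Tanimoto, defined as 1 when both vectors are empty."""
    inter = union = 0
    set_a, set_b = set(bits_a), set(bits_b)
    for bit in range(n_bits):
        a, b = bit in set_a, bit in set_b
        inter += a and b
        union += a or b
    return inter / union if union else 1.0


def tokenize_floor(mz: float, mz_low: float, mz_high: float, interval: float):
    """Plain floor-arithmetic binning with a closed upper edge."""
    if mz < mz_low or mz > mz_high:
        return None
    n = math.ceil((mz_high - mz_low) / interval)
    idx = min(int(math.floor((mz - mz_low) / interval)), n - 1)
    return 1 + idx


def exhaustive_best_sequence(
    model: MintModel, spectrum: TokenizedSpectrum, n_bits: int
) -> tuple[tuple[int, ...], float]:
    """Score every ascending bit sequence by chained next-token probabilities.

    Returns the globally optimal bit tuple and its cumulative log probability,
    the quantity beam search approximates.
    """
    memory = embed_and_encode(spectrum, model)
    best_bits, best_score = None, -np.inf
    for r in range(n_bits + 1):
        for combo in itertools.combinations(range(n_bits), r):
            tokens = [START_ID] + [b + BIT_TOKEN_OFFSET for b in combo] + [END_ID]
            score = 0.0
            for t in range(1, len(tokens)):
                probs = decode_step(memory, tokens[:t], model)
                score += math.log(probs[tokens[t]] + 1e-300)
            if score > best_score:
                best_bits, best_score = combo, score
    return best_bits, best_score
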