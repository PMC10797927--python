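"""Deterministic synthetic ``.msp`` libraries for offline end-to-end testing.

Each synthetic compound is a random sparse fingerprint whose active bits map
injectively to m/z bin centers: bit b produces exactly one fragment peak at
``bit_to_mz(b)``. The spectrum-to-fingerprint inverse problem is therefore
well-posed by construction, which isolates software correctness (tokenization,
training, decoding) from the hardness of real fragmentation chemistry. Real
spectra are *not* invertible like this; these libraries test the machinery,
not the science of fragmentation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from ms2fp.fingerprints import BitSet
from ms2fp.msp_io import Peak, Spectrum, write_msp

#: probability that any given fingerprint bit is active; mimics sparse ECFP density
BIT_ACTIVATION_PROBABILITY = 0.15


@dataclass
class FixtureSpec:
    """Parameters of a synthetic library.

    ``noise`` is the standard deviation of multiplicative log-normal jitter on
    peak intensities; m/z values sit exactly on bin centers so the bit-to-peak
    map stays invertible at any noise level.
    """

    n_compounds: int = 50
    n_bits: int = 64
    mz_low: float = 50.0
    mz_high: float = 150.0
    interval: float = 0.1
    noise: float = 0.05
    seed: int = 42
    ionization_mode: str = "positive"
    precursor_offset: float = 5.0

    def __post_init__(self):
        n_bins = int((self.mz_high - self.mz_low) / self.interval)
        if self.n_bits > n_bins:
            raise ValueError(
                f"n_bits={self.n_bits} exceeds the {n_bins} available m/z bins"
            )
        spacing = self._spacing()
        if spacing < self.interval:
            raise ValueError("bit-to-m/z map is not injective at this bin width")
        if self.bit_to_mz(self.n_bits - 1) + self.precursor_offset >= self.mz_high:
            raise ValueError("precursor m/z would fall outside the vocabulary range")

    def _spacing(self) -> float:
        usable = self.mz_high - self.mz_low - 4 * self.precursor_offset
        return usable / self.n_bits

    def bit_to_mz(self, bit: int) -> float:
        """Injective map from fingerprint bit to a fragment m/z (a bin center)."""
        mz = self.mz_low + self.precursor_offset + bit * self._spacing()
        # snap to the center of the containing bin so tokenization is exact
        bin_index = int((mz - self.mz_low) / self.interval)
        return self.mz_low + (bin_index + 0.5) * self.interval


@dataclass
class FixtureTruth:
    """Ground truth for one synthetic compound."""

    identifier: str
    bits: BitSet
    spectrum: Spectrum


def _draw_compound(spec: FixtureSpec, index: int, rng: np.random.Generator) -> FixtureTruth:
    active = np.flatnonzero(rng.random(spec.n_bits) < BIT_ACTIVATION_PROBABILITY)
    if active.size == 0:
        active = np.array([rng.integers(spec.n_bits)])
    bits = BitSet(bits=tuple(int(b) for b in active), n_bits=spec.n_bits)
    peaks = []
    for bit in bits.bits:
        intensity = rng.uniform(0.2, 1.0)
        if spec.noise > 0:
            intensity *= float(np.exp(rng.normal(0.0, spec.noise)))
        peaks.append(Peak(mz=spec.bit_to_mz(bit), intensity=intensity))
    precursor = max(p.mz for p in peaks) + spec.precursor_offset
    spectrum = Spectrum(
        peaks=peaks,
        precursor_mz=precursor,
        name=f"SYN_{index:04d}",
        ionization_mode=spec.ionization_mode,
    )
    return FixtureTruth(identifier=spectrum.name, bits=bits, spectrum=spectrum)


def generate_library(spec: FixtureSpec) -> tuple[str, list[FixtureTruth]]:
    """Synthesize an .msp library; byte-identical for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    truths = [_draw_compound(spec, i, rng) for i in range(spec.n_compounds)]
    sink = io.StringIO()
    write_msp((t.spectrum for t in truths), sink)
    return sink.getvalue(), truths


def generate_custom_bit_library(spec: FixtureSpec) -> tuple[str, list[FixtureTruth]]:
    """Like :func:`generate_library`, but blocks carry their fingerprint bits
    in the custom header and no structure strings."""
    text, truths = generate_library(spec)
    del text
    spectra = []
    for truth in truths:
        s = truth.spectrum
        spectra.append(
            Spectrum(
                peaks=s.peaks,
                precursor_mz=s.precursor_mz,
                name=s.name,
                custom_bits=list(truth.bits.bits),
                ionization_mode=s.ionization_mode,
            )
        )
    sink = io.StringIO()
    write_msp(spectra, sink)
    return sink.getvalue(), truths


def truth_table(truths: list[FixtureTruth]) -> str:
    """Tab-separated (identifier, bits) table for test assertions."""
    lines = [f"{t.identifier}\t{t.bits.serialize()}" for t in truths]
    return "\n".join(lines) + "\n"
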