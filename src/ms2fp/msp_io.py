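"""Reading and writing NIST-style ``.msp`` spectral libraries.

An ``.msp`` file is a sequence of blank-line-separated blocks. Each block holds
``Key: Value`` headers (matched case-insensitively), a ``Num Peaks: N`` line and
N peak lines of whitespace- or tab-separated m/z and intensity. Only spectra
accompanied by a precursor m/z are admitted; blocks without one are skipped and
counted rather than raised, since public library exports routinely mix MS1 and
MS/MS records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from ms2fp.errors import MspFormatError

#: header aliases (lowercased, ':'-stripped) accepted for the precursor m/z
DEFAULT_PRECURSOR_ALIASES = ("precursormz", "precursor_mz", "precursor m/z")

#: default header carrying pre-computed fingerprint bit locations
DEFAULT_FINGERPRINT_KEY = "fingerprint"


@dataclass(frozen=True)
class Peak:
    """A single fragment: mass-to-charge ratio (Da) and abundance."""

    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass
class Spectrum:
    """One MS/MS record: peak list, precursor m/z, structures and metadata.

    ``custom_bits``, when present, are pre-computed fingerprint bit locations
    carried inside the MSP block; they take precedence over structure strings
    when resolving training targets.
    """

    peaks: list[Peak]
    precursor_mz: float
    name: str = ""
    smiles: str | None = None
    inchi: str | None = None
    custom_bits: list[int] | None = None
    ionization_mode: str = "unknown"
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz is None or self.precursor_mz <= 0:
            raise ValueError("Spectrum requires a positive precursor m/z")
        if not self.peaks:
            raise ValueError("Spectrum requires a non-empty peak list")
        if self.custom_bits is not None:
            bits = list(self.custom_bits)
            if any(b < 0 for b in bits):
                raise ValueError("custom fingerprint bits must be non-negative")
            if any(b2 <= b1 for b1, b2 in zip(bits, bits[1:])):
                raise ValueError("custom fingerprint bits must be strictly ascending")


@dataclass
class ParseResult:
    """Outcome of parsing an .msp stream.

    Iterating a ParseResult iterates its spectra, so it can be used directly
    wherever a list of spectra is expected.
    """

    spectra: list[Spectrum]
    skipped_no_precursor: int = 0
    record_errors: list[MspFormatError] = field(default_factory=list)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]


def _blocks(lines: Iterable[str]) -> Iterator[list[str]]:
    block: list[str] = []
    for raw in lines:
        line = raw.rstrip("\n").rstrip("\r")
        if line.strip() == "":
            if block:
                yield block
                block = []
        else:
            block.append(line)
    if block:
        yield block


def _parse_block(
    block: list[str],
    block_index: int,
    precursor_aliases: Sequence[str],
    fingerprint_key: str,
) -> Spectrum | None:
    """Parse one MSP block; returns None when the precursor m/z is absent."""
    headers: dict[str, str] = {}
    extra: dict[str, str] = {}
    peaks: list[Peak] = []
    n_peaks_declared: int | None = None
    in_peaks = False

    for line in block:
        if not in_peaks:
            if ":" in line:
                key, _, value = line.partition(":")
                key_norm = key.strip().lower()
                value = value.strip()
                if key_norm == "num peaks":
                    try:
                        n_peaks_declared = int(value)
                    except ValueError:
                        raise MspFormatError(
                            f"block {block_index}: non-integer peak count {value!r}",
                            block_index,
                        )
                    in_peaks = True
                else:
                    headers[key_norm] = value
                continue
            # header section but no colon: treat as start of peaks only if it
            # parses as a peak line (some dialects omit Num Peaks)
            in_peaks = True
        fields = line.replace(";", " ").split()
        if len(fields) < 2:
            raise MspFormatError(
                f"block {block_index}: malformed peak line {line!r}", block_index
            )
        try:
            mz, intensity = float(fields[0]), float(fields[1])
        except ValueError:
            raise MspFormatError(
                f"block {block_index}: non-numeric peak line {line!r}", block_index
            )
        if intensity > 0:  # zero-intensity peaks carry no rank or normalization mass
            peaks.append(Peak(mz=mz, intensity=intensity))

    precursor_mz: float | None = None
    for alias in precursor_aliases:
        if alias in headers:
            try:
                precursor_mz = float(headers.pop(alias))
            except ValueError:
                raise MspFormatError(
                    f"block {block_index}: non-numeric precursor m/z", block_index
                )
            break
    if precursor_mz is None:
        return None

    custom_bits: list[int] | None = None
    fp_key = fingerprint_key.strip().lower()
    if fp_key in headers:
        raw_bits = headers.pop(fp_key)
        try:
            custom_bits = [int(tok) for tok in raw_bits.replace(";", ",").split(",") if tok.strip()]
        except ValueError:
            raise MspFormatError(
                f"block {block_index}: non-integer fingerprint bits {raw_bits!r}",
                block_index,
            )

    if n_peaks_declared is not None and n_peaks_declared > 0 and not peaks:
        raise MspFormatError(
            f"block {block_index}: no peaks with positive intensity", block_index
        )
    if not peaks:
        raise MspFormatError(f"block {block_index}: empty peak list", block_index)

    name = headers.pop("name", "")
    smiles = headers.pop("smiles", None)
    inchi = headers.pop("inchi", None)
    ion_raw = headers.pop("ionmode", headers.pop("ionization", "")).lower()
    if ion_raw.startswith("p") or ion_raw == "+":
        ionization_mode = "positive"
    elif ion_raw.startswith("n") or ion_raw == "-":
        ionization_mode = "negative"
    else:
        ionization_mode = "unknown"
    extra.update(headers)

    return Spectrum(
        peaks=peaks,
        precursor_mz=precursor_mz,
        name=name,
        smiles=smiles,
        inchi=inchi,
        custom_bits=custom_bits,
        ionization_mode=ionization_mode,
        extra=extra,
    )


def parse_msp(
    source: str | IO[str],
    precursor_aliases: Sequence[str] = DEFAULT_PRECURSOR_ALIASES,
    fingerprint_key: str = DEFAULT_FINGERPRINT_KEY,
) -> ParseResult:
    """Parse an .msp text stream (or string) into spectra.

    Blocks without a precursor m/z header are skipped and counted in
    ``skipped_no_precursor``. Malformed blocks (non-numeric peak lines, empty
    peak lists) are dropped and recorded in ``record_errors`` with their block
    index; well-formed blocks are unaffected.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    aliases = tuple(a.strip().lower() for a in precursor_aliases)

    result = ParseResult(spectra=[])
    for block_index, block in enumerate(_blocks(source)):
        try:
            spectrum = _parse_block(block, block_index, aliases, fingerprint_key)
        except MspFormatError as err:
            result.record_errors.append(err)
            continue
        if spectrum is None:
            result.skipped_no_precursor += 1
        else:
            result.spectra.append(spectrum)
    return result


def write_msp(
    spectra: Iterable[Spectrum],
    sink: IO[str],
    fingerprint_key: str = DEFAULT_FINGERPRINT_KEY,
) -> int:
    """Write spectra as NIST-style MSP blocks; returns the number written.

    ``parse_msp(write_msp(S))`` reproduces S up to float formatting (m/z and
    intensity are written with 6 decimal places).
    """
    count = 0
    for spectrum in spectra:
        if count:
            sink.write("\n")
        sink.write(f"Name: {spectrum.name}\n")
        sink.write(f"PrecursorMZ: {spectrum.precursor_mz:.6f}\n")
        if spectrum.smiles is not None:
            sink.write(f"SMILES: {spectrum.smiles}\n")
        if spectrum.inchi is not None:
            sink.write(f"InChI: {spectrum.inchi}\n")
        if spectrum.ionization_mode != "unknown":
            sink.write(f"Ionmode: {spectrum.ionization_mode}\n")
        for key, value in spectrum.extra.items():
            sink.write(f"{key}: {value}\n")
        if spectrum.custom_bits is not None:
            bits = ",".join(str(b) for b in spectrum.custom_bits)
            sink.write(f"{fingerprint_key.rstrip(':').capitalize()}: {bits}\n")
        sink.write(f"Num Peaks: {len(spectrum.peaks)}\n")
        for peak in spectrum.peaks:
            sink.write(f"{peak.mz:.6f} {peak.intensity:.6f}\n")
        count += 1
    return count


def coverage_filter(
    spectra: Sequence[Spectrum],
    min_fraction: float,
    mz_low: float,
    mz_high: float,
) -> tuple[list[Spectrum], int]:
    """Admission filter: keep spectra with enough fragments inside [mz_low, mz_high].

    A spectrum is kept iff the fraction of its peaks with m/z in the closed
    interval ``[mz_low, mz_high]`` is at least ``min_fraction``. Kept spectra
    retain all their peaks; out-of-range fragments are dropped later, at
    tokenization time. Returns ``(kept, dropped_count)``.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if mz_low >= mz_high:
        raise ValueError("mz_low must be smaller than mz_high")
    kept: list[Spectrum] = []
    dropped = 0
    for spectrum in spectra:
        in_range = sum(1 for p in spectrum.peaks if mz_low <= p.mz <= mz_high)
        if in_range / len(spectrum.peaks) >= min_fraction:
            kept.append(spectrum)
        else:
            dropped += 1
    return kept, dropped
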