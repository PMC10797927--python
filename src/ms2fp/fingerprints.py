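"""Binary molecular fingerprints and Tanimoto similarity.

Fingerprints are represented as sparse bit-position sets (``BitSet``) rather
than dense vectors: the decoder's token alphabet is exactly the set of bit
locations, so the sparse form is the native one throughout the pipeline.
ECFP (Morgan) and MACCS fingerprints are computed with RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from ms2fp.errors import AnnotationError, DimensionError, StructureError
from ms2fp.msp_io import Spectrum

RDLogger.DisableLog("rdApp.error")  # structure errors are raised, not logged

MACCS_N_BITS = 166


@dataclass(frozen=True)
class FingerprintSpec:
    """Which fingerprint to compute: kind, ECFP radius, and bit length.

    ``kind='custom'`` means bit locations are supplied inside MSP blocks and
    are never computed from structures. MACCS keys have a fixed length of 166.
    """

    kind: str = "ecfp"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if self.kind not in ("ecfp", "maccs", "custom"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.kind == "maccs" and self.n_bits != MACCS_N_BITS:
            raise ValueError(f"MACCS fingerprints are fixed at {MACCS_N_BITS} bits")
        if self.kind == "ecfp" and (self.radius < 0 or self.n_bits < 2):
            raise ValueError("ECFP requires radius >= 0 and n_bits >= 2")
        if self.n_bits < 1:
            raise ValueError("n_bits must be positive")


@dataclass(frozen=True)
class BitSet:
    """Strictly ascending set-bit positions of a binary fingerprint."""

    bits: tuple[int, ...]
    n_bits: int

    def __post_init__(self):
        object.__setattr__(self, "bits", tuple(self.bits))
        if self.n_bits < 1:
            raise ValueError("n_bits must be positive")
        for b1, b2 in zip(self.bits, self.bits[1:]):
            if b2 <= b1:
                raise ValueError("bits must be strictly ascending and unique")
        if self.bits and not (0 <= self.bits[0] and self.bits[-1] < self.n_bits):
            raise ValueError(f"bits must lie in [0, {self.n_bits})")

    def __len__(self) -> int:
        return len(self.bits)

    def serialize(self) -> str:
        return ",".join(str(b) for b in self.bits)

    @classmethod
    def deserialize(cls, text: str, n_bits: int) -> "BitSet":
        bits = tuple(int(tok) for tok in text.split(",") if tok.strip())
        return cls(bits=bits, n_bits=n_bits)


def _mol_from_structure(structure: str):
    mol = Chem.MolFromSmiles(structure)
    if mol is None and structure.lstrip().startswith("InChI="):
        mol = Chem.MolFromInchi(structure)
    return mol


def fingerprint_from_structure(structure: str, spec: FingerprintSpec) -> BitSet:
    """Compute the fingerprint bit positions of a SMILES or InChI string.

    MACCS keys are re-indexed to 0-based positions over 166 keys so that all
    fingerprint kinds share the same token arithmetic downstream.
    """
    if spec.kind == "custom":
        raise StructureError(
            "custom fingerprints come from MSP blocks, not from structures"
        )
    mol = _mol_from_structure(structure)
    if mol is None:
        raise StructureError(f"could not parse structure {structure!r}")
    if spec.kind == "ecfp":
        generator = rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius, fpSize=spec.n_bits
        )
        on_bits = sorted(generator.GetFingerprint(mol).GetOnBits())
    else:  # maccs: RDKit bit vector is 167 long with bit 0 unused (keys 1..166)
        on_bits = sorted(k - 1 for k in MACCSkeys.GenMACCSKeys(mol).GetOnBits() if k >= 1)
    return BitSet(bits=tuple(on_bits), n_bits=spec.n_bits)


def tanimoto(a: BitSet, b: BitSet) -> float:
    """Tanimoto coefficient |a ∩ b| / |a ∪ b|; 1.0 when both sets are empty."""
    if a.n_bits != b.n_bits:
        raise DimensionError(
            f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}"
        )
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def resolve_target_bits(spectrum: Spectrum, spec: FingerprintSpec) -> BitSet:
    """Training target for a spectrum: embedded custom bits, else computed.

    Custom bits carried in the MSP block take precedence over structure
    strings; otherwise the fingerprint is computed from SMILES, falling back
    to InChI. Raises :class:`AnnotationError` when neither route is available.
    """
    if spectrum.custom_bits is not None:
        bits = tuple(spectrum.custom_bits)
        if bits and bits[-1] >= spec.n_bits:
            raise DimensionError(
                f"custom bit {bits[-1]} out of range for {spec.n_bits}-bit fingerprint"
            )
        return BitSet(bits=bits, n_bits=spec.n_bits)
    last_error: StructureError | None = None
    for structure in (spectrum.smiles, spectrum.inchi):
        if structure:
            try:
                return fingerprint_from_structure(structure, spec)
            except StructureError as err:
                last_error = err
    if last_error is not None:
        raise last_error
    raise AnnotationError(
        f"spectrum {spectrum.name!r} has neither custom fingerprint bits "
        "nor a structure string"
    )


def bitsets_from_structures(
    structures: Sequence[str], spec: FingerprintSpec
) -> list[BitSet]:
    """Vector convenience wrapper used when building candidate libraries."""
    return [fingerprint_from_structure(s, spec) for s in structures]
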