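"""Scoring predictions and ranking candidate structure libraries.

Annotation works by Tanimoto similarity between a predicted fingerprint and
the fingerprints of a candidate library (e.g. a lipid structure database):
candidates are ranked by similarity, the top hit is compared with the true
compound, and summaries are reported per compound class. Compound identity is
compared on the first 14 characters of the InChIKey when identifiers look like
InChIKeys (the 2D-skeleton block), otherwise on the exact identifier string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ms2fp.errors import DimensionError, Ms2fpError
from ms2fp.fingerprints import BitSet, FingerprintSpec, fingerprint_from_structure, tanimoto

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def _canonical_identifier(identifier: str) -> str:
    """InChIKey14 when the identifier is an InChIKey, else the string itself."""
    if _INCHIKEY_RE.match(identifier):
        return identifier[:14]
    return identifier


@dataclass
class CandidateLibrary:
    """Candidate structures with pre-computed fingerprints, one shared length."""

    entries: list[tuple[str, str, BitSet]]
    spec: FingerprintSpec

    def __post_init__(self):
        lengths = {bits.n_bits for _, _, bits in self.entries}
        if len(lengths) > 1:
            raise DimensionError(f"candidate fingerprints have mixed lengths: {lengths}")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_structures(
        cls, records: Iterable[tuple[str, str]], spec: FingerprintSpec
    ) -> "CandidateLibrary":
        entries = [
            (identifier, structure, fingerprint_from_structure(structure, spec))
            for identifier, structure in records
        ]
        return cls(entries=entries, spec=spec)

    @classmethod
    def from_tsv(cls, path: str | Path, spec: FingerprintSpec) -> "CandidateLibrary":
        """Tab-separated (identifier, SMILES) file, no header."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["identifier", "smiles"])
        return cls.from_structures(frame.itertuples(index=False), spec)

    @classmethod
    def from_bitsets(
        cls, records: Iterable[tuple[str, BitSet]], spec: FingerprintSpec
    ) -> "CandidateLibrary":
        return cls(entries=[(ident, "", bits) for ident, bits in records], spec=spec)


@dataclass
class AnnotationResult:
    """Ranked candidates for one spectrum plus top-hit bookkeeping."""

    spectrum_id: str
    candidates: list[tuple[str, float]]  # (identifier, tanimoto), best first
    true_identifier: str | None = None
    top_hit_correct: bool = False
    top_tanimoto: float = 0.0


def rank_candidates(
    predicted: BitSet, library: CandidateLibrary, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Candidates sorted by descending Tanimoto to the prediction; ties by identifier."""
    if len(library) == 0:
        raise Ms2fpError("candidate library is empty")
    scored = [
        (identifier, tanimoto(predicted, bits)) for identifier, _, bits in library.entries
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    if top_k is not None:
        scored = scored[:top_k]
    return scored


def annotate_spectrum(
    spectrum_id: str,
    predicted: BitSet,
    library: CandidateLibrary,
    true_identifier: str | None = None,
    top_k: int | None = None,
) -> AnnotationResult:
    """Rank the library against a prediction and record top-hit correctness.

    A tie at rank 1 counts as correct only if the true candidate sorts first
    under the identifier tie-break.
    """
    ranked = rank_candidates(predicted, library, top_k)
    top_id, top_score = ranked[0]
    correct = False
    if true_identifier is not None:
        correct = _canonical_identifier(top_id) == _canonical_identifier(true_identifier)
    return AnnotationResult(
        spectrum_id=spectrum_id,
        candidates=ranked,
        true_identifier=true_identifier,
        top_hit_correct=correct,
        top_tanimoto=top_score,
    )


def top_hit_accuracy(results: Sequence[AnnotationResult]) -> float:
    """Fraction of spectra whose rank-1 candidate is the true compound."""
    if not results:
        raise Ms2fpError("accuracy undefined on an empty result set")
    return sum(1 for r in results if r.top_hit_correct) / len(results)


def tanimoto_summary(
    results: Sequence[AnnotationResult],
    grouping: Mapping[str, str],
    all_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group count / mean / sd / median of top-hit Tanimoto scores.

    ``grouping`` maps spectrum ids to group labels (e.g. lipid classes);
    ungrouped results are dropped. Groups with no members appear with NaN
    statistics. Standard deviation uses the sample (n-1) convention; a single
    score reports sd 0.
    """
    scores: dict[str, list[float]] = {}
    for result in results:
        label = grouping.get(result.spectrum_id)
        if label is None:
            continue
        scores.setdefault(label, []).append(result.top_tanimoto)
    labels = list(all_groups) if all_groups is not None else sorted(scores)
    rows = []
    for label in labels:
        values = scores.get(label, [])
        n = len(values)
        if n == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan))
        else:
            sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
            rows.append((label, n, float(np.mean(values)), sd, float(np.median(values))))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "median"])


def threshold_annotations(
    results: Sequence[AnnotationResult], min_tanimoto: float
) -> list[AnnotationResult]:
    """Keep results whose top-hit Tanimoto meets the similarity threshold (closed >=)."""
    if not 0 <= min_tanimoto <= 1:
        raise ValueError("min_tanimoto must be in [0, 1]")
    return [r for r in results if r.top_tanimoto >= min_tanimoto]
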