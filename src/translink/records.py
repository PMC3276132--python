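"""Nucleotide sequence records with masked-region bookkeeping.

Every sequence entering the toolkit is normalised to an uppercase string
over the alphabet {A, C, G, T, N}.  Cleaning operators (repeat masking,
vector screening) record the intervals they touched as 0-based half-open
``masked_spans`` so that downstream reports can explain what was removed
or replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

ALPHABET = frozenset("ACGTN")

Span = Tuple[int, int]


def normalize_spans(spans: Iterable[Span], length: int) -> List[Span]:
    """Sort, bound-check and merge overlapping/adjacent half-open intervals."""
    cleaned = []
    for start, end in spans:
        if start >= end:
            continue
        if start < 0 or end > length:
            raise ValueError(
                f"span ({start}, {end}) outside sequence of length {length}"
            )
        cleaned.append((int(start), int(end)))
    cleaned.sort()
    merged: List[Span] = []
    for start, end in cleaned:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class SequenceRecord:
    """A named nucleotide sequence.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any collection the record
        belongs to (uniqueness is enforced by the FASTA reader).
    residues:
        Uppercase string over ``{A, C, G, T, N}``.
    source_tag:
        Free-form provenance label, e.g. ``"EST"`` or ``"CDS"``.
    masked_spans:
        0-based half-open intervals that were replaced by ``N`` during
        cleaning; kept sorted and non-overlapping.
    """

    id: str
    residues: str
    source_tag: str = ""
    masked_spans: List[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues) if c not in ALPHABET
            )
            raise ValueError(
                f"sequence {self.id!r}: invalid character {self.residues[pos]!r} "
                f"at position {pos} (allowed: A,C,G,T,N)"
            )
        self.masked_spans = normalize_spans(self.masked_spans, len(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]
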