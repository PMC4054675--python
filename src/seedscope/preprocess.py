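"""Raw-read handling for PAR-CLIP libraries.

Adapter trimming, duplicate collapsing and T->C-aware comparison of aligned
reads against the reference. In PAR-CLIP, 4-thiouridine cross-linked to the
Argonaute protein reverse-transcribes as C, so a sense-strand T in the
reference aligned to a C in the read is diagnostic signal, not a sequencing
error; every other mismatch counts against the alignment.

All coordinates are 0-based half-open. Minus-strand alignments are
canonicalized to sense orientation at parse time so that "T->C" is literal
everywhere downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_nucleotides(sequence: str, what: str = "sequence") -> None:
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in {what}: {sorted(bad)!r}")


@dataclass(frozen=True)
class RawRead:
    """A sequencing read before alignment.

    ``trimmed`` records whether the 3' adapter was found and removed; reads
    where it was not found ran into the sequencer's length limit and may be
    extended to the next RNase T1 cleavage site later.
    """

    id: str
    sequence: str
    trimmed: bool = False


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence with its pre-collapse multiplicity."""

    sequence: str
    count: int


@dataclass(frozen=True)
class AlignedRead:
    """A collapsed read placed on the genome, in sense orientation.

    ``blocks`` are ascending, non-overlapping 0-based half-open genomic
    intervals (more than one block for spliced reads). ``sequence`` is the
    read's sense-strand sequence, so for minus-strand alignments it is the
    reverse complement of the genomic plus-strand text. ``conversions`` are
    read offsets (sense) where a reference T is read as C; ``mismatches``
    counts all other disagreements.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    sequence: str
    count: int = 1
    conversions: frozenset[int] = frozenset()
    mismatches: int = 0
    untrimmed: bool = False
    experiment: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        span = sum(e - s for s, e in self.blocks)
        if span != len(self.sequence):
            raise ValueError(
                f"block span {span} != sequence length {len(self.sequence)}"
            )

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def sense_positions(self) -> list[int]:
        """Genomic position of each read base, in sense (5'->3') order."""
        pos: list[int] = []
        for s, e in self.blocks:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return pos

    def conversion_positions(self) -> list[int]:
        """Genomic positions of the read's T->C conversions."""
        pos = self.sense_positions()
        return [pos[i] for i in sorted(self.conversions)]

    def five_prime(self) -> int:
        """Genomic position of the sense 5' end."""
        return self.blocks[-1][1] - 1 if self.strand == "-" else self.blocks[0][0]

    def three_prime(self) -> int:
        """Genomic position of the sense 3' end (last base)."""
        return self.blocks[0][0] if self.strand == "-" else self.blocks[-1][1] - 1


def _suffix_mismatches(suffix: str, prefix: str) -> int:
    mm = 0
    for a, b in zip(suffix, prefix):
        if a != b or a == "N" or b == "N":
            mm += 1
    return mm


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = 4,
    max_mismatch_fraction: float = 0.1,
) -> RawRead:
    """Remove a 3' adapter by aligning adapter prefixes to read suffixes.

    The longest read suffix matching an adapter prefix of length
    >= ``min_overlap`` with a mismatch fraction <= ``max_mismatch_fraction``
    is removed (ungapped comparison; N counts as mismatch). Removal is
    iterated until no admissible overlap remains, so adapter dimers are fully
    stripped and the operation is idempotent. If the whole read matches, the
    returned sequence is empty and the caller should discard the read.
    """
    _check_nucleotides(read.sequence, "read")
    _check_nucleotides(adapter, "adapter")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("min_overlap must be in [1, len(adapter)]")

    seq = read.sequence
    trimmed = read.trimmed
    changed = True
    while changed and seq:
        changed = False
        for overlap in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
            mm = _suffix_mismatches(seq[-overlap:], adapter[:overlap])
            if mm <= max_mismatch_fraction * overlap:
                seq = seq[:-overlap]
                trimmed = True
                changed = True
                break
    if seq == read.sequence and trimmed == read.trimmed:
        return read
    return replace(read, sequence=seq, trimmed=trimmed)


def collapse_reads(reads: Iterable[RawRead]) -> list[CollapsedRead]:
    """Collapse identical sequences, returning one record per distinct
    sequence in lexicographic order. Counts sum to the input size."""
    counts = Counter(r.sequence for r in reads)
    return [CollapsedRead(seq, n) for seq, n in sorted(counts.items())]


def classify_alignment(
    read_sequence: str, reference_window: str, strand: str = "+"
) -> tuple[int, frozenset[int]]:
    """Compare a read against its reference window, treating T->C specially.

    Both arguments are expected in sense orientation; passing ``strand='-'``
    reverse-complements both first as a convenience. Returns
    ``(mismatches, conversions)`` where conversions are sense offsets with
    reference T read as C, and mismatches counts every other disagreement.
    N never counts as conversion and always as mismatch.
    """
    if len(read_sequence) != len(reference_window):
        raise ValueError("read and reference window must have equal length")
    if strand == "-":
        read_sequence = reverse_complement(read_sequence)
        reference_window = reverse_complement(reference_window)
    conversions: set[int] = set()
    mismatches = 0
    for i, (r, g) in enumerate(zip(read_sequence, reference_window)):
        if r == "N" or g == "N":
            mismatches += 1
        elif r == g:
            continue
        elif g == "T" and r == "C":
            conversions.add(i)
        else:
            mismatches += 1
    return mismatches, frozenset(conversions)
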