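"""File formats: FASTQ, FASTA genomes, and BED12 alignments.

BED12 conventions used throughout:

* ``name``   — the collapsed read sequence (sense strand), with a trailing
  ``*`` marking reads whose 3' adapter was *not* found (untrimmed);
* ``score``  — the collapse count (number of raw reads with this sequence);
* ``blockCount/blockSizes/blockStarts`` — standard BED12 semantics, encoding
  spliced alignments; all coordinates 0-based half-open.

Conversions and mismatch counts are not stored in BED; they are recomputed
against the genome on load (``alignments_from_bed``), which also drops
alignments with non-T->C mismatches, mirroring how clusters are built only
from mismatch-free reads.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .preprocess import AlignedRead, RawRead, classify_alignment, reverse_complement


class GenomeSource:
    """Random access to reference sequence, from an in-memory dict or FASTA."""

    def __init__(self, sequences: Mapping[str, str] | None = None, fasta=None):
        self._seqs = sequences
        self._fasta = fasta

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "GenomeSource":
        return cls(sequences={k: v.upper() for k, v in sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSource":
        from pyfaidx import Fasta

        return cls(fasta=Fasta(str(path), sequence_always_upper=True))

    def __contains__(self, chrom: str) -> bool:
        if self._seqs is not None:
            return chrom in self._seqs
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence for [start, end), clipped to the chromosome."""
        start = max(start, 0)
        end = min(end, self.length(chrom))
        if start >= end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end])


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Minimal FASTQ reader (4-line records; qualities ignored)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            fh.readline()  # +
            fh.readline()  # qualities
            yield RawRead(id=header[1:].strip().split()[0], sequence=seq)


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed12(path: str | Path, reads: Iterable[AlignedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start, end = r.blocks[0][0], r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - start) for s, _ in r.blocks)
            name = r.sequence + ("*" if r.untrimmed else "")
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{name}\t{r.count}\t{r.strand}\t"
                f"{start}\t{end}\t0,0,0\t{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


def _parse_bed12_line(line: str) -> tuple[str, int, int, str, int, str, list[tuple[int, int]]]:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"expected 12 BED fields, got {len(f)}: {line!r}")
    chrom, start, end = f[0], int(f[1]), int(f[2])
    name, count, strand = f[3], int(f[4]), f[5]
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(f"inconsistent block fields in {line!r}")
    blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    if blocks[-1][1] != end:
        raise ValueError(f"blocks do not span chromEnd in {line!r}")
    return chrom, start, end, name, count, strand, blocks


def alignments_from_bed(
    path: str | Path,
    genome: GenomeSource,
    experiment: str | None = None,
    drop_mismatched: bool = True,
) -> list[AlignedRead]:
    """Load BED12 alignments, recomputing conversions against the genome.

    Each record's sense read sequence (the BED name field) is compared with
    the genomic reference over its blocks; alignments with non-T->C
    mismatches are dropped when ``drop_mismatched`` (the default, matching
    the mismatch-free requirement for cluster building).
    """
    out: list[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, _, _, name, count, strand, blocks = _parse_bed12_line(line)
            untrimmed = name.endswith("*")
            seq = name.rstrip("*").upper()
            ref = "".join(genome.fetch(chrom, s, e) for s, e in blocks)
            if strand == "-":
                ref = reverse_complement(ref)
            mismatches, conversions = classify_alignment(seq, ref)
            if drop_mismatched and mismatches > 0:
                continue
            out.append(
                AlignedRead(
                    chrom=chrom,
                    strand=strand,
                    blocks=tuple(blocks),
                    sequence=seq,
                    count=count,
                    conversions=conversions,
                    mismatches=mismatches,
                    untrimmed=untrimmed,
                    experiment=experiment,
                )
            )
    return out
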