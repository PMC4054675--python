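"""Synthetic PAR-CLIP data with known ground truth.

The forward model mirrors the generative assumptions of the inference:
each planted cluster carries one active seed k-mer; T->C conversions are
drawn per read at T positions with probability proportional to the true
positional cross-link propensity (concentrated directly upstream of the
seed, none within it); read boundaries fall immediately after guanines
whose offsets follow the true 5'/3' main-cleavage distributions, with a
planted G at each such offset. Background clusters have the same read-depth
distribution but uniform conversion and boundary noise, so they should not
fit the model at any position.

Every quantity is drawn from a single numpy Generator, so a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_bed12, write_fasta
from .model import ConversionModel
from .preprocess import AlignedRead, reverse_complement

_BASES = np.array(list("ACGT"))

#: default positional cross-link propensity (offsets -8..-1 upstream of the
#: seed start); the -1 position dominates so that the main cross-linking
#: site carries >= 60% of a cluster's conversions on average
DEFAULT_XLINK = ConversionModel(
    w_min=-8,
    w_max=-1,
    xlink=np.array([0.01, 0.02, 0.02, 0.04, 0.06, 0.08, 0.12, 0.65]),
)

#: default main-cleavage-site offset distributions (read-start offsets for
#: the 5' side, read 3'-end offsets for the 3' side, relative to seed start)
DEFAULT_CLEAVAGE5 = {-11: 0.2, -10: 0.5, -9: 0.3}
DEFAULT_CLEAVAGE3 = {9: 0.3, 10: 0.5, 11: 0.2}

#: five seed-site 7-mers used as the default active set (target sites of
#: widely expressed miRNA families: miR-15/16, let-7, miR-155, miR-21,
#: miR-122)
DEFAULT_ACTIVE_KMERS = {
    "TGCTGCT": 0.2,
    "CTACCTC": 0.2,
    "AGCATTA": 0.2,
    "TAAGCTA": 0.2,
    "ACACTCC": 0.2,
}


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated dataset."""

    active_kmers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVE_KMERS)
    )
    conversion_model: ConversionModel = field(default_factory=lambda: DEFAULT_XLINK)
    cleavage5: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLEAVAGE5))
    cleavage3: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLEAVAGE3))
    background_fraction: float = 0.1
    length_range: tuple[int, int] = (42, 56)
    #: A/C/G/T composition of cluster sequence; AU-rich like the 3' UTR
    #: context in which most miRNA target sites sit
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    depth_nb_size: float = 5.0  # negative-binomial dispersion of extra depth
    depth_mean_extra: float = 25.0  # depth = 5 + NB(size, mean_extra)
    conversion_rate: float = 0.9  # per-read rate at the maximal-propensity offset
    background_conv_rate: float = 0.01
    boundary_noise: float = 0.15  # per-read chance of using a secondary cleavage G
    t_minus1_prob: float = 0.7  # chance of a uridine directly upstream of the seed
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.active_kmers.values())
        if self.active_kmers and abs(total - 1.0) > 1e-9:
            self.active_kmers = {x: w / total for x, w in self.active_kmers.items()}
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass
class SimulatedDataset:
    experiments: dict[str, list[AlignedRead]]
    genome: dict[str, str]
    truth: SimTruth
    table: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome)
        for name, reads in self.experiments.items():
            write_bed12(outdir / f"{name}.bed", reads)
        self.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _draw(pmf: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(pmf)
    probs = np.array([pmf[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _collapse(reads: list[AlignedRead]) -> list[AlignedRead]:
    merged: dict[tuple, AlignedRead] = {}
    for r in reads:
        key = (r.chrom, r.strand, r.blocks, r.sequence)
        if key in merged:
            prev = merged[key]
            merged[key] = AlignedRead(
                chrom=r.chrom, strand=r.strand, blocks=r.blocks, sequence=r.sequence,
                count=prev.count + r.count, conversions=r.conversions,
                mismatches=0, untrimmed=False, experiment=r.experiment,
            )
        else:
            merged[key] = r
    return sorted(merged.values(), key=lambda r: (r.blocks, r.sequence))


def simulate_dataset(
    truth: SimTruth | None = None,
    n_clusters: int = 500,
    n_experiments: int = 1,
    chrom: str = "chrS",
    spacer: int = 40,
) -> SimulatedDataset:
    """Generate reads, a matching genome and a ground-truth table.

    Clusters are laid out along one synthetic chromosome separated by
    read-free spacers; roughly half are placed on the minus strand. Reads
    within an experiment are collapsed (identical placement and sequence),
    so collapse counts arise naturally.
    """
    truth = truth or SimTruth()
    rng = np.random.default_rng(truth.seed)
    kmers = sorted(truth.active_kmers)
    kmer_w = np.array([truth.active_kmers[x] for x in kmers])
    xl = truth.conversion_model
    xl_max = xl.xlink.max() if len(xl.xlink) else 1.0
    k = len(kmers[0]) if kmers else 7

    comp = np.asarray(truth.base_composition, dtype=float)
    comp = comp / comp.sum()

    genome_parts: list[str] = []
    offset = 0
    rows = []
    reads_per_exp: dict[str, list[AlignedRead]] = {
        f"exp{e + 1}": [] for e in range(n_experiments)
    }

    for ci in range(n_clusters):
        spacer_seq = "".join(rng.choice(_BASES, size=spacer, p=comp))
        genome_parts.append(spacer_seq)
        offset += spacer

        length = int(rng.integers(*truth.length_range))
        sense = rng.choice(_BASES, size=length, p=comp)
        strand = "+" if rng.random() < 0.5 else "-"
        is_background = bool(rng.random() < truth.background_fraction)

        j = None
        kmer = None
        o5 = o3 = None
        if not is_background and kmers:
            kmer = kmers[int(rng.choice(len(kmers), p=kmer_w))]
            j = int(rng.integers(15, length - k - 13))
            sense[j : j + k] = list(kmer)
            if rng.random() < truth.t_minus1_prob:
                # a cross-linkable uridine directly upstream of the seed is
                # frequent but not universal; making it deterministic would
                # plant a spurious (k+1)-mer motif
                sense[j - 1] = "T"
            o5 = _draw(truth.cleavage5, rng)
            o3 = _draw(truth.cleavage3, rng)
            # plant the cleaved G before the main/secondary 5' start and at
            # the main/secondary 3' end
            sense[j + o5 - 1] = "G"
            sense[j + o5 - 3] = "G"
            sense[j + o3] = "G"
            sense[j + o3 + 2] = "G"

        sense_str = "".join(sense)
        region_start = offset
        genome_parts.append(
            sense_str if strand == "+" else reverse_complement(sense_str)
        )
        offset += length

        depth_base = 5
        for exp in reads_per_exp:
            depth = depth_base + int(
                rng.negative_binomial(
                    truth.depth_nb_size,
                    truth.depth_nb_size / (truth.depth_nb_size + truth.depth_mean_extra),
                )
            )
            for _ in range(depth):
                if not is_background:
                    a = j + (o5 - 2 if rng.random() < truth.boundary_noise else o5)
                    b = j + (o3 + 2 if rng.random() < truth.boundary_noise else o3)
                else:
                    a = int(rng.integers(0, max(1, length // 4)))
                    b = int(rng.integers(3 * length // 4, length))
                conv_offsets = []
                for t in range(a, b + 1):
                    if sense[t] != "T":
                        continue
                    if is_background:
                        rate = 0.05
                    else:
                        o = t - j
                        if 0 <= o < k:
                            rate = 0.0  # the seed is protected by the miRNA duplex
                        elif xl.w_min <= o <= xl.w_max:
                            rate = truth.conversion_rate * xl.propensity(
                                np.array([o])
                            )[0] / xl_max
                        else:
                            rate = truth.background_conv_rate
                    if rng.random() < rate:
                        conv_offsets.append(t - a)
                read_seq = list(sense_str[a : b + 1])
                for off in conv_offsets:
                    read_seq[off] = "C"
                if strand == "+":
                    blocks = ((region_start + a, region_start + b + 1),)
                else:
                    blocks = (
                        (region_start + length - 1 - b, region_start + length - a),
                    )
                reads_per_exp[exp].append(
                    AlignedRead(
                        chrom=chrom,
                        strand=strand,
                        blocks=blocks,
                        sequence="".join(read_seq),
                        count=1,
                        conversions=frozenset(conv_offsets),
                        mismatches=0,
                        untrimmed=False,
                        experiment=exp,
                    )
                )
        seed_genomic = (
            None
            if j is None
            else (region_start + j if strand == "+" else region_start + length - 1 - j)
        )
        rows.append(
            {
                "cluster": f"sim_{ci}",
                "chrom": chrom,
                "strand": strand,
                "region_start": region_start,
                "region_end": region_start + length,
                "seed_index": j,
                "seed_genomic": seed_genomic,
                "kmer": kmer,
                "background": is_background,
            }
        )

    genome_parts.append("".join(rng.choice(_BASES, size=spacer, p=comp)))
    genome = {chrom: "".join(genome_parts)}
    experiments = {e: _collapse(reads) for e, reads in reads_per_exp.items()}
    return SimulatedDataset(
        experiments=experiments,
        genome=genome,
        truth=truth,
        table=pd.DataFrame(rows),
    )


def match_clusters(dataset: SimulatedDataset, clusters) -> pd.DataFrame:
    """Join detected clusters to planted ground truth.

    Returns one row per non-background truth cluster with the matched
    detected cluster id (the one containing the planted seed position, if
    any) and the seed's sense index within that cluster's coordinates.
    """
    rows = []
    for _, t in dataset.table[~dataset.table.background].iterrows():
        match_id, seed_index = None, None
        for c in clusters:
            if c.chrom != t.chrom or c.strand != t.strand:
                continue
            if not (c.blocks[0][0] <= t.seed_genomic < c.blocks[-1][1]):
                continue
            index = c.position_index()
            if t.seed_genomic in index:
                match_id, seed_index = c.id, index[t.seed_genomic]
                break
        rows.append(
            {
                "cluster": t.cluster,
                "kmer": t.kmer,
                "seed_genomic": t.seed_genomic,
                "matched_cluster": match_id,
                "seed_index": seed_index,
            }
        )
    return pd.DataFrame(rows)
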