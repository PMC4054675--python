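"""PAR-CLIP cluster detection, splitting, filtering and profiling.

Candidate miRNA target sites are strand-specific connected components of
overlapping reads, pooled over all experiments, filtered by read count and
read-species count. Each cluster carries a positional profile in sense
orientation: per-position T->C conversion counts (``conv``), read 5'-end
counts (``starts``) and read 3'-end counts (``ends``). The position with the
maximal pooled conversion count is the main cross-linking site, which also
anchors cluster quantification and the splitting of overlapping target
sites.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeSource
from .preprocess import AlignedRead, reverse_complement


@dataclass
class Cluster:
    """A candidate target site with its positional profile.

    ``blocks`` are merged genomic intervals (ascending; >1 block for spliced
    clusters); profile vectors and ``sequence`` are indexed in sense
    orientation, i.e. index 0 is the sense 5'-most position.
    """

    id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    reads: list[AlignedRead] = field(default_factory=list, repr=False)
    sequence: str | None = None
    conv: np.ndarray | None = None
    starts: np.ndarray | None = None
    ends: np.ndarray | None = None
    per_experiment_counts: dict[str, float] = field(default_factory=dict)
    main_site: int | None = None

    def __len__(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def sense_positions(self) -> list[int]:
        pos: list[int] = []
        for s, e in self.blocks:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return pos

    def position_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.sense_positions())}

    def genomic_position(self, sense_index: int) -> int:
        return self.sense_positions()[sense_index]

    def t_positions(self) -> np.ndarray:
        """Sense indices with a reference T (possible conversion sites)."""
        return np.flatnonzero(np.frombuffer(self.sequence.encode(), np.uint8) == ord("T"))

    def g_positions(self) -> np.ndarray:
        """Sense indices with a reference G (possible RNase T1 cleavage sites)."""
        return np.flatnonzero(np.frombuffer(self.sequence.encode(), np.uint8) == ord("G"))


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-experiment scale factors; the reference experiment has factor 1."""

    factors: dict[str, float]
    reference: str


def _merge_blocks(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def connected_components(reads: list[AlignedRead]) -> list[list[AlignedRead]]:
    """Group reads into strand-specific components of block-overlapping reads.

    Two spliced reads overlap iff any of their blocks intersect; components
    are computed by a sweep over block intervals per (chrom, strand).
    """
    by_locus: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        by_locus[(r.chrom, r.strand)].append(i)
    uf = _UnionFind(len(reads))
    for indices in by_locus.values():
        blocks = sorted(
            (s, e, i) for i in indices for s, e in reads[i].blocks
        )
        cur_end = -1
        cur_rep = -1
        for s, e, i in blocks:
            if s < cur_end:  # overlaps the running merged region
                uf.union(cur_rep, i)
                cur_end = max(cur_end, e)
            else:
                cur_rep, cur_end = i, e
    groups: dict[int, list[AlignedRead]] = defaultdict(list)
    for i, r in enumerate(reads):
        groups[uf.find(i)].append(r)
    out = list(groups.values())
    out.sort(key=lambda g: (g[0].chrom, g[0].strand, min(r.start for r in g)))
    return out


def _passes_filters(reads: list[AlignedRead], min_reads: int, min_species: int) -> bool:
    if not reads:
        return False
    total = sum(r.count for r in reads)
    species = len({r.sequence for r in reads})
    return total >= min_reads and species >= min_species


def _pooled_conversions(reads: list[AlignedRead]) -> Counter:
    conv: Counter = Counter()
    for r in reads:
        for p in r.conversion_positions():
            conv[p] += r.count
    return conv


def main_conversion_site(reads: list[AlignedRead]) -> int | None:
    """Genomic position of the maximal pooled conversion count.

    Ties break toward the smallest genomic coordinate; None if the reads
    carry no conversions at all.
    """
    conv = _pooled_conversions(reads)
    if not conv:
        return None
    best = max(conv.values())
    return min(p for p, c in conv.items() if c == best)


def split_cluster(
    cluster_reads: list[AlignedRead], min_reads: int = 5, min_species: int = 3
) -> list[list[AlignedRead]]:
    """Split a read component into sub-clusters of overlapping target sites.

    Iteratively: locate the main cross-linking site of the remaining reads,
    peel off all reads covering it as one sub-cluster (if it passes the
    read-count/species filters), and repeat on the remainder while the
    filters hold. Sub-clusters may overlap in coordinates but partition the
    peeled reads; components without any conversion have no main
    cross-linking site and yield nothing.
    """
    remaining = list(cluster_reads)
    out: list[list[AlignedRead]] = []
    while _passes_filters(remaining, min_reads, min_species):
        site = main_conversion_site(remaining)
        if site is None:
            break
        covering = [r for r in remaining if site in set(r.sense_positions())]
        if not _passes_filters(covering, min_reads, min_species):
            break
        out.append(covering)
        covered = set(map(id, covering))
        remaining = [r for r in remaining if id(r) not in covered]
    return out


def _junctions(read: AlignedRead) -> list[tuple[int, int]]:
    return [
        (read.blocks[i][1], read.blocks[i + 1][0]) for i in range(len(read.blocks) - 1)
    ]


def resolve_spliced_reads(
    reads_in_cluster: list[AlignedRead],
    exon_evidence: dict[tuple[int, int], int] | None = None,
) -> list[AlignedRead]:
    """Resolve inconsistent splicing evidence within one locus.

    First removes exon-intron reads: unspliced blocks that run across a
    junction boundary supported by any spliced read (a read continuing from
    an exon into the intron). Then, if mutually exclusive junctions remain
    (their introns overlap), only reads supporting the junction with the
    highest read count are kept. ``exon_evidence`` overrides the per-junction
    support counts; by default they are tallied from the reads themselves.
    """
    junctions: set[tuple[int, int]] = set()
    for r in reads_in_cluster:
        junctions.update(_junctions(r))
    if not junctions:
        return list(reads_in_cluster)

    def crosses_boundary(read: AlignedRead) -> bool:
        own = set(_junctions(read))
        for d, a in junctions - own:
            for s, e in read.blocks:
                # block extends over the donor (d) or acceptor (a) boundary
                if s < d < e or s < a < e:
                    return True
        return False

    kept = [r for r in reads_in_cluster if not crosses_boundary(r)]

    support: dict[tuple[int, int], int] = defaultdict(int)
    for r in kept:
        for j in _junctions(r):
            support[j] += r.count
    if exon_evidence:
        support.update(exon_evidence)

    # drop reads of the weaker junction wherever two junctions' introns overlap
    excluded: set[tuple[int, int]] = set()
    juncs = sorted(support, key=lambda j: (-support[j], j))
    for i, j1 in enumerate(juncs):
        if j1 in excluded:
            continue
        for j2 in juncs[i + 1 :]:
            if j2 in excluded:
                continue
            if j1[0] < j2[1] and j2[0] < j1[1]:  # intron overlap
                excluded.add(j2)
    if excluded:
        kept = [r for r in kept if not (set(_junctions(r)) & excluded)]
    return kept


def extend_reads(
    reads: list[AlignedRead], genome: GenomeSource, max_extension: int = 20
) -> list[AlignedRead]:
    """Extend untrimmed reads in the sense 3' direction past the next G.

    Reads whose adapter was not found were cut by the sequencer, not by
    RNase T1, so their 3' boundary carries no cleavage information; they are
    extended to end immediately after the next genomic G on the sense strand
    (a terminal G is assumed to belong to the observed fragment, so the scan
    starts beyond it), or by ``max_extension`` if no G is closer.
    """
    out: list[AlignedRead] = []
    for r in reads:
        if not r.untrimmed:
            out.append(r)
            continue
        if r.chrom not in genome:
            raise KeyError(f"chromosome {r.chrom!r} absent from genome")
        if r.strand == "+":
            end = r.blocks[-1][1]
            window = genome.fetch(r.chrom, end, end + max_extension)
            idx = window.find("G")
            ext = idx + 1 if idx >= 0 else len(window)
            if ext == 0:
                out.append(r)
                continue
            new_blocks = r.blocks[:-1] + ((r.blocks[-1][0], end + ext),)
            added = genome.fetch(r.chrom, end, end + ext)
            new_seq = r.sequence + added
        else:
            start = r.blocks[0][0]
            window = genome.fetch(r.chrom, max(0, start - max_extension), start)
            sense = reverse_complement(window)  # sense continuation beyond 3' end
            idx = sense.find("G")
            ext = idx + 1 if idx >= 0 else len(sense)
            if ext == 0:
                out.append(r)
                continue
            new_blocks = ((start - ext, r.blocks[0][1]),) + r.blocks[1:]
            new_seq = r.sequence + sense[:ext]
        out.append(
            AlignedRead(
                chrom=r.chrom,
                strand=r.strand,
                blocks=new_blocks,
                sequence=new_seq,
                count=r.count,
                conversions=r.conversions,
                mismatches=r.mismatches,
                untrimmed=r.untrimmed,
                experiment=r.experiment,
            )
        )
    return out


def detect_clusters(
    alignments: dict[str, list[AlignedRead]] | list[AlignedRead],
    min_reads: int = 5,
    min_species: int = 3,
    split: bool = True,
    resolve_spliced: bool = True,
) -> list[Cluster]:
    """Detect clusters jointly over all experiments.

    ``alignments`` maps experiment name to sense-canonicalized reads (reads
    with non-T->C mismatches are assumed excluded upstream); a bare list is
    treated as a single unnamed experiment. Components are found block-aware
    over the pooled reads, spliced inconsistencies resolved, overlapping
    target sites split at main cross-linking sites, and the read-count /
    species filters applied. Profiles are filled later by ``build_profile``.
    """
    if isinstance(alignments, list):
        alignments = {"exp1": alignments}
    pooled: list[AlignedRead] = []
    for exp, reads in alignments.items():
        for r in reads:
            if r.experiment != exp:
                from dataclasses import replace

                r = replace(r, experiment=exp)
            pooled.append(r)

    clusters: list[Cluster] = []
    for component in connected_components(pooled):
        if resolve_spliced:
            component = resolve_spliced_reads(component)
        if split:
            groups = split_cluster(component, min_reads, min_species)
        else:
            groups = [component] if _passes_filters(component, min_reads, min_species) else []
        for g in groups:
            blocks = _merge_blocks([b for r in g for b in r.blocks])
            clusters.append(
                Cluster(
                    id=f"cluster_{len(clusters)}",
                    chrom=g[0].chrom,
                    strand=g[0].strand,
                    blocks=blocks,
                    reads=g,
                )
            )
    return clusters


def build_profile(
    cluster: Cluster,
    genome: GenomeSource,
    norm_factors: NormalizationFactors | None = None,
) -> Cluster:
    """Fill a cluster's sequence and positional profile from its reads.

    Conversion, read-start and read-end counts are tallied per sense
    position, weighted by collapse counts. The main cross-linking site is
    the argmax of ``conv`` (ties to the sense 5'-most position; coverage
    argmax if the cluster has no conversions). Per-experiment quantification
    sums the counts of reads covering the main cross-linking site, scaled by
    the experiment's normalization factor.
    """
    seq = "".join(genome.fetch(cluster.chrom, s, e) for s, e in cluster.blocks)
    if cluster.strand == "-":
        seq = reverse_complement(seq)
    cluster.sequence = seq
    n = len(seq)
    index = cluster.position_index()
    conv = np.zeros(n, dtype=float)
    starts = np.zeros(n, dtype=float)
    ends = np.zeros(n, dtype=float)
    coverage = np.zeros(n, dtype=float)
    for r in cluster.reads:
        pos = r.sense_positions()
        starts[index[pos[0]]] += r.count
        ends[index[pos[-1]]] += r.count
        for p in pos:
            coverage[index[p]] += r.count
        for p in r.conversion_positions():
            conv[index[p]] += r.count
    cluster.conv, cluster.starts, cluster.ends = conv, starts, ends
    cluster.main_site = int(np.argmax(conv)) if conv.sum() > 0 else int(np.argmax(coverage))

    site_pos = cluster.genomic_position(cluster.main_site)
    raw: dict[str, float] = defaultdict(float)
    for r in cluster.reads:
        if site_pos in set(r.sense_positions()):
            raw[r.experiment or "exp1"] += r.count
    if norm_factors is not None:
        cluster.per_experiment_counts = {
            e: c * norm_factors.factors.get(e, 1.0) for e, c in raw.items()
        }
    else:
        cluster.per_experiment_counts = dict(raw)
    return cluster


def main_site_count_matrix(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster x experiment matrix of raw main-site read counts."""
    experiments = sorted({e for c in clusters for e in c.per_experiment_counts})
    data = {
        e: [c.per_experiment_counts.get(e, 0.0) for c in clusters] for e in experiments
    }
    return pd.DataFrame(data, index=[c.id for c in clusters])


def normalize_experiments(
    cluster_counts: pd.DataFrame, min_norm_count: float = 10.0
) -> tuple[NormalizationFactors, pd.DataFrame]:
    """Median-fold-change normalization against the deepest experiment.

    The reference is the experiment with the largest total count. Every
    other experiment e gets factor 1/median(count_e / count_ref) over
    clusters with count_ref > 0, so that post hoc the median fold change to
    the reference is one. Clusters where *every* experiment's normalized
    count falls below ``min_norm_count`` are removed; returns the factors
    and the surviving normalized count matrix.
    """
    if cluster_counts.shape[1] < 1:
        raise ValueError("need at least one experiment")
    totals = cluster_counts.sum(axis=0)
    if (totals == 0).any():
        dead = list(totals.index[totals == 0])
        raise ValueError(f"experiment(s) with zero total count: {dead}")
    reference = str(totals.idxmax())
    ref = cluster_counts[reference]
    factors: dict[str, float] = {}
    for e in cluster_counts.columns:
        if e == reference:
            factors[e] = 1.0
            continue
        ratios = cluster_counts.loc[ref > 0, e] / ref[ref > 0]
        med = float(ratios.median())
        if med <= 0:
            raise ValueError(f"median fold change to reference is 0 for {e!r}")
        factors[e] = 1.0 / med
    normalized = cluster_counts * pd.Series(factors)
    kept = normalized[(normalized >= min_norm_count).any(axis=1)]
    return NormalizationFactors(factors=factors, reference=reference), kept
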