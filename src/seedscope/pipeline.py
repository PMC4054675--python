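"""Orchestration: iterative model/kmerExplain loop, assignment and scoring.

The loop alternates between (a) estimating k-mer activities from positional
priors with kmerExplain and (b) refitting the generative conversion and
cleavage models at the current posterior-argmax seed positions, which yields
new priors. Round zero runs kmerExplain on uniform priors; the loop stops
when the model vectors change by less than ``outer_tol`` in max-norm or
after ``max_rounds``.

Each cluster then receives its most probable seed position g = argmax_j q,
the explaining k-mer at g, a cluster-level confidence Cscore = p_{i,g}
(model fit regardless of which k-mer sits there) and an assignment-level
confidence MAscore = q_{i,g} / sum_j q_{i,j} (how dominant the chosen
explanation is among the alternatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Cluster
from .kmerexplain import (
    EMResult,
    KmerActivities,
    enumerate_kmers,
    index_to_kmer,
    kmer_to_index,
    run_em,
)
from .model import (
    DEFAULT_WINDOW,
    CleavageModel,
    ConversionModel,
    PositionScores,
    estimate_pair_ratios,
    fit_cleavage_model,
    fit_conversion_model,
    score_positions,
)
from .preprocess import reverse_complement


@dataclass
class RunConfig:
    """Tunable parameters of a full run."""

    k: int = 7
    window: tuple[int, int] = DEFAULT_WINDOW
    min_reads: int = 5
    min_species: int = 3
    min_norm_count: float = 10.0
    min_pair_support: int = 10
    em_tol: float = 1e-4
    em_max_iter: int = 200
    outer_tol: float = 1e-3
    max_rounds: int = 20
    seed: int = 42
    whitelist: list[str] | None = None

    def __post_init__(self) -> None:
        if self.em_tol <= 0 or self.outer_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Assignment:
    """Final per-cluster call with confidence scores."""

    cluster_id: str
    g: int | None
    kmer: str | None
    cscore: float
    mascore: float
    mirnas: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


@dataclass
class ParmaResult:
    conversion_model: ConversionModel
    cleavage5: CleavageModel
    cleavage3: CleavageModel
    activities: KmerActivities
    posteriors: list[np.ndarray]
    scores: list[PositionScores]
    rows: list[np.ndarray]
    rounds: int
    log_likelihood: float
    config: RunConfig


def _uniform_priors(rows: list[np.ndarray]) -> list[np.ndarray]:
    return [np.full(len(r), 1.0 / len(r)) if len(r) else np.zeros(0) for r in rows]


def _whitelist_mask(whitelist: list[str] | None, k: int) -> np.ndarray | None:
    if whitelist is None:
        return None
    mask = np.zeros(4**k, dtype=bool)
    for kmer in whitelist:
        kmer = kmer.upper().replace("U", "T")
        if len(kmer) != k:
            raise ValueError(f"whitelist k-mer {kmer!r} has length != {k}")
        mask[kmer_to_index(kmer)] = True
    return mask


def _model_delta(
    prev: tuple[ConversionModel, CleavageModel, CleavageModel] | None,
    cur: tuple[ConversionModel, CleavageModel, CleavageModel],
    window: tuple[int, int],
) -> float:
    if prev is None:
        return np.inf
    grid = np.arange(window[0], window[1] + 1)
    d = np.max(np.abs(prev[0].xlink - cur[0].xlink))
    d = max(d, float(np.max(np.abs(prev[1].c(grid) - cur[1].c(grid)))))
    d = max(d, float(np.max(np.abs(prev[2].c(grid) - cur[2].c(grid)))))
    return d


def run_parma(clusters: list[Cluster], config: RunConfig | None = None) -> ParmaResult:
    """Run the full iterative estimation on profiled clusters.

    Clusters must have sequence and profile vectors filled (see
    ``clustering.build_profile``). Clusters shorter than k take no part in
    the EM and come back unassignable.
    """
    config = config or RunConfig()
    k = config.k
    rows = [enumerate_kmers(c.sequence, k) for c in clusters]
    whitelist = _whitelist_mask(config.whitelist, k)

    priors = _uniform_priors(rows)
    em = run_em(
        rows, priors, k, tol=config.em_tol, max_iter=config.em_max_iter,
        whitelist=whitelist,
    )
    scores: list[PositionScores] = []
    models: tuple[ConversionModel, CleavageModel, CleavageModel] | None = None
    rounds = 0
    for rounds in range(1, config.max_rounds + 1):
        seeds: list[int] = []
        fit_clusters: list[Cluster] = []
        for cluster, q in zip(clusters, em.posteriors):
            if len(q) == 0 or q.sum() == 0:
                continue
            fit_clusters.append(cluster)
            seeds.append(int(np.argmax(q)))
        if not fit_clusters:
            raise RuntimeError(f"round {rounds}: no assignable clusters to fit on")
        try:
            ratios = estimate_pair_ratios(
                fit_clusters, seeds, config.window, config.min_pair_support
            )
            conv_model = fit_conversion_model(ratios, config.window)
            model5 = fit_cleavage_model(fit_clusters, seeds, "5")
            model3 = fit_cleavage_model(fit_clusters, seeds, "3")
        except ValueError as exc:
            raise RuntimeError(f"round {rounds}: submodel fit failed: {exc}") from exc
        current = (conv_model, model5, model3)
        delta = _model_delta(models, current, config.window)
        models = current
        scores = [score_positions(c, conv_model, model5, model3, k) for c in clusters]
        priors = [s.p for s in scores]
        em = run_em(
            rows, priors, k, tol=config.em_tol, max_iter=config.em_max_iter,
            whitelist=whitelist,
        )
        if delta < config.outer_tol:
            break
    if models is None:  # max_rounds == 0: plain kmerExplain on uniform priors
        scores = [
            PositionScores(
                c.id, np.arange(len(r)), np.ones(len(r)), np.ones(len(r)),
                np.ones(len(r)), p.copy(),
            )
            for c, r, p in zip(clusters, rows, priors)
        ]
        return ParmaResult(
            conversion_model=None, cleavage5=None, cleavage3=None,  # type: ignore[arg-type]
            activities=em.activities, posteriors=em.posteriors, scores=scores,
            rows=rows, rounds=0, log_likelihood=em.log_likelihood[-1], config=config,
        )
    return ParmaResult(
        conversion_model=models[0],
        cleavage5=models[1],
        cleavage3=models[2],
        activities=em.activities,
        posteriors=em.posteriors,
        scores=scores,
        rows=rows,
        rounds=rounds,
        log_likelihood=em.log_likelihood[-1],
        config=config,
    )


def assign(
    q_row: np.ndarray,
    p_row: np.ndarray,
    row: np.ndarray | None = None,
    k: int = 7,
    cluster_id: str = "",
) -> Assignment:
    """Call the best seed position of one cluster with its two scores."""
    if len(q_row) == 0 or q_row.sum() == 0:
        return Assignment(cluster_id, None, None, 0.0, 0.0, flags={"unassigned"})
    g = int(np.argmax(q_row))
    flags: set[str] = set()
    if np.sum(q_row == q_row[g]) > 1:
        flags.add("tied_argmax")
    kmer = index_to_kmer(int(row[g]), k) if row is not None and row[g] >= 0 else None
    return Assignment(
        cluster_id=cluster_id,
        g=g,
        kmer=kmer,
        cscore=float(p_row[g]),
        mascore=float(q_row[g] / q_row.sum()),
        flags=flags,
    )


def integrate_experiments(
    q_rows: list[np.ndarray],
    p_rows: list[np.ndarray],
    weights: list[float],
    row: np.ndarray | None = None,
    k: int = 7,
    cluster_id: str = "",
) -> Assignment:
    """Combine per-experiment posteriors for one cluster.

    Posteriors are averaged with weights proportional to each experiment's
    normalized read count in the cluster; the seed is the argmax of the
    combined posterior, the Cscore the weighted mean of the per-experiment
    p at that position, and the MAscore the best per-experiment MAscore
    there. With a single experiment this reduces to ``assign``.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0 or not q_rows:
        return Assignment(cluster_id, None, None, 0.0, 0.0, flags={"unassigned"})
    w = w / w.sum()
    lengths = {len(q) for q in q_rows}
    if len(lengths) != 1:
        raise ValueError("experiments disagree on cluster positions")
    if lengths == {0}:
        return Assignment(cluster_id, None, None, 0.0, 0.0, flags={"unassigned"})
    q_bar = sum(wi * qi for wi, qi in zip(w, q_rows))
    if q_bar.sum() == 0:
        return Assignment(cluster_id, None, None, 0.0, 0.0, flags={"unassigned"})
    g = int(np.argmax(q_bar))
    flags: set[str] = set()
    if np.sum(q_bar == q_bar[g]) > 1:
        flags.add("tied_argmax")
    cscore = float(sum(wi * pi[g] for wi, pi in zip(w, p_rows)))
    mascore = max(
        (float(qi[g] / qi.sum()) for qi in q_rows if qi.sum() > 0), default=0.0
    )
    kmer = index_to_kmer(int(row[g]), k) if row is not None and row[g] >= 0 else None
    return Assignment(cluster_id, g, kmer, cscore, mascore, flags=flags)


def seed_sites(mature: str, k: int = 7) -> tuple[str, str]:
    """Target-site k-mers of a mature miRNA: (7mer-m8, 7mer-A1) style.

    The 7mer-m8 site is the reverse complement of miRNA bases 2..k+1; the
    7mer-A1 site is the reverse complement of bases 2..k followed by an A
    opposite base 1. For k != 7 the definitions truncate/extend accordingly.
    """
    m = mature.upper().replace("U", "T")
    if len(m) < k + 1:
        raise ValueError("mature sequence too short for seed-site definition")
    m8 = reverse_complement(m[1 : k + 1])
    a1 = reverse_complement(m[1:k]) + "A"
    return m8, a1


def annotate_mirnas(
    kmer: str, mirnas: list[tuple[str, str]], k: int = 7
) -> list[str]:
    """Names of all miRNAs whose 7mer-m8 or 7mer-A1 site equals ``kmer``.

    miRNAs sharing a seed (a seed family) are all returned.
    """
    kmer = kmer.upper().replace("U", "T")
    out = []
    for name, mature in mirnas:
        m8, a1 = seed_sites(mature, k)
        if kmer in (m8, a1):
            out.append(name)
    return out


def assignments(
    result: ParmaResult,
    clusters: list[Cluster],
    mirnas: list[tuple[str, str]] | None = None,
) -> list[Assignment]:
    """Per-cluster assignments from a finished run, with miRNA annotation."""
    out = []
    wl = result.activities.whitelist
    for cluster, q, s, row in zip(clusters, result.posteriors, result.scores, result.rows):
        a = assign(q, s.p, row, result.config.k, cluster.id)
        a.flags |= s.flags
        if a.kmer is not None and wl is not None and not wl[kmer_to_index(a.kmer)]:
            a.flags.add("background")
        if a.kmer is not None and mirnas:
            a.mirnas = annotate_mirnas(a.kmer, mirnas, result.config.k)
        out.append(a)
    return out
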