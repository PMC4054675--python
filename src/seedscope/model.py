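"""Generative model of PAR-CLIP signal around a miRNA seed site.

Three submodels score how well a cluster's data fit a seed starting at
position j (offsets are always ``position - j``; upstream is negative):

* conversion model — a positional cross-link propensity ``xlink(offset)``
  over a fixed window; the score for (cluster, j) is the cosine similarity
  between observed conversion counts at the cluster's T positions and the
  propensities at the corresponding offsets. Because cross-linking yields
  are only identified up to scale, the model is fitted from pairwise count
  ratios: a robust through-origin slope R_{k,l} per offset pair, combined
  into a propensity vector by a non-negative, sum-to-one constrained
  quadratic program.
* 5'/3' cleavage models — empirical cumulative distributions of the main
  RNase T1 cleavage site offset. Cleavage sites are not independent: RNase
  T1 cuts after G, and whether a given G is used depends on whether a closer
  G exists, so scoring distributes *cumulative* probability over the actual
  G positions of each cluster (the nearest G takes the CDF up to its offset,
  each further G takes the increment).

The per-position score p_{i,j} is the product of the three submodel scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .clustering import Cluster

DEFAULT_WINDOW = (-25, 15)


@dataclass
class ConversionModel:
    """Positional cross-link propensity over [w_min, w_max], summing to 1."""

    w_min: int
    w_max: int
    xlink: np.ndarray

    def __post_init__(self) -> None:
        self.xlink = np.asarray(self.xlink, dtype=float)
        if len(self.xlink) != self.w_max - self.w_min + 1:
            raise ValueError("xlink length does not match window")

    def propensity(self, offsets: np.ndarray) -> np.ndarray:
        """xlink at the given offsets; zero outside the window."""
        offsets = np.asarray(offsets)
        out = np.zeros(offsets.shape, dtype=float)
        inside = (offsets >= self.w_min) & (offsets <= self.w_max)
        out[inside] = self.xlink[offsets[inside] - self.w_min]
        return out


@dataclass
class CleavageModel:
    """Empirical CDF of the main cleavage-site offset on one side.

    ``c(i)`` is the probability that the main cleavage site is at offset i
    or closer to the seed site: for the 3' side closer means a smaller
    offset, for the 5' side a larger (less negative) one. Stored as the
    sorted sample of per-cluster main-site offsets.
    """

    side: str  # "5" or "3"
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("5", "3"):
            raise ValueError("side must be '5' or '3'")
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if len(self.samples) == 0:
            raise ValueError("cleavage model needs at least one cluster")

    def c(self, offsets) -> np.ndarray:
        offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
        n = len(self.samples)
        if self.side == "3":
            out = np.searchsorted(self.samples, offsets, side="right") / n
        else:
            out = (n - np.searchsorted(self.samples, offsets, side="left")) / n
        return out


@dataclass
class PairRatios:
    """Robust per-offset-pair propensity ratios R_{k,l} with their support."""

    ratios: dict[tuple[int, int], float]
    support: dict[tuple[int, int], int]


@dataclass
class PositionScores:
    """Submodel and product scores over the valid seed positions of a cluster."""

    cluster_id: str
    positions: np.ndarray
    s_xlink: np.ndarray
    s_upstream: np.ndarray
    s_downstream: np.ndarray
    p: np.ndarray
    flags: set[str] = field(default_factory=set)


def score_conversion(cluster: Cluster, j: int, model: ConversionModel) -> float:
    """Cosine similarity of observed vs expected conversions at T positions.

    Equals 1 iff the conversion counts restricted to the cluster's T
    positions are proportional to the model propensities there; 0 if either
    vector vanishes.
    """
    t = cluster.t_positions()
    if len(t) == 0:
        return 0.0
    obs = cluster.conv[t]
    exp = model.propensity(t - j)
    no, ne = np.linalg.norm(obs), np.linalg.norm(exp)
    if no == 0 or ne == 0:
        return 0.0
    return float(np.dot(obs, exp) / (no * ne))


def estimate_pair_ratios(
    clusters: list[Cluster],
    seed_positions: list[int],
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_pair_support: int = 10,
) -> PairRatios:
    """Robust through-origin slopes between conversion counts at offset pairs.

    For each ordered offset pair (k, l), k < l, collect clusters whose
    positions j+k and j+l are both T, and take the median of the per-cluster
    ratios conv(j+k)/conv(j+l) over clusters with conv(j+l) > 0 (a
    Theil-Sen-through-origin slope). Pairs with fewer than
    ``min_pair_support`` usable clusters are dropped.
    """
    w_min, w_max = window
    per_cluster: list[dict[int, float]] = []
    for cluster, j in zip(clusters, seed_positions):
        vals: dict[int, float] = {}
        t = set(cluster.t_positions().tolist())
        for o in range(w_min, w_max + 1):
            pos = j + o
            if 0 <= pos < len(cluster.sequence) and pos in t:
                vals[o] = float(cluster.conv[pos])
        per_cluster.append(vals)

    ratios: dict[tuple[int, int], float] = {}
    support: dict[tuple[int, int], int] = {}
    offsets = range(w_min, w_max + 1)
    for k in offsets:
        for l in range(k + 1, w_max + 1):
            obs = [
                vals[k] / vals[l]
                for vals in per_cluster
                if k in vals and l in vals and vals[l] > 0
            ]
            if len(obs) >= min_pair_support:
                ratios[(k, l)] = float(np.median(obs))
                support[(k, l)] = len(obs)
    if not ratios:
        raise ValueError("no offset pair has sufficient support; model unfittable")
    return PairRatios(ratios=ratios, support=support)


def _largest_connected(offsets: list[int], pairs) -> set[int]:
    index = {o: i for i, o in enumerate(offsets)}
    parent = list(range(len(offsets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, l in pairs:
        ri, rj = find(index[k]), find(index[l])
        if ri != rj:
            parent[rj] = ri
    comps: dict[int, set[int]] = {}
    for o in offsets:
        comps.setdefault(find(index[o]), set()).add(o)
    return max(comps.values(), key=len)


def fit_conversion_model(
    ratios: PairRatios,
    window: tuple[int, int] = DEFAULT_WINDOW,
    weighted: bool = False,
) -> ConversionModel:
    """Combine pairwise ratios into a propensity vector by constrained QP.

    Minimizes sum over pairs of (xlink(k) - R_{k,l} * xlink(l))^2 subject to
    xlink >= 0 and sum(xlink) = 1 (the sum constraint pins down the scale
    that ratios cannot). Solved as non-negative least squares with a heavily
    weighted sum-to-one row, then renormalized; offsets not connected to the
    largest pair-graph component get propensity 0.
    """
    w_min, w_max = window
    offsets = sorted({o for pair in ratios.ratios for o in pair})
    keep = _largest_connected(offsets, ratios.ratios.keys())
    active = sorted(keep)
    index = {o: i for i, o in enumerate(active)}
    rows = []
    for (k, l), r in ratios.ratios.items():
        if k not in keep or l not in keep:
            continue
        row = np.zeros(len(active))
        row[index[k]] = 1.0
        row[index[l]] = -r
        if weighted:
            row *= np.sqrt(ratios.support[(k, l)])
        rows.append(row)
    a = np.array(rows)
    lam = 1000.0 * (1.0 + np.abs(a).max())
    a_aug = np.vstack([a, lam * np.ones(len(active))])
    b = np.zeros(len(rows) + 1)
    b[-1] = lam
    x, _ = nnls(a_aug, b)
    total = x.sum()
    if total < 1e-9:
        raise ValueError("degenerate conversion-model QP (all-zero solution)")
    x /= total
    xlink = np.zeros(w_max - w_min + 1)
    for o, i in index.items():
        xlink[o - w_min] = x[i]
    return ConversionModel(w_min=w_min, w_max=w_max, xlink=xlink)


def main_cleavage_offset(cluster: Cluster, j: int, side: str) -> int:
    """Offset of the main cleavage site: argmax of ends (3') or starts (5'),
    ties toward the sense 5'-most position."""
    vec = cluster.ends if side == "3" else cluster.starts
    return int(np.argmax(vec)) - j


def fit_cleavage_model(
    clusters: list[Cluster], seed_positions: list[int], side: str
) -> CleavageModel:
    """Empirical CDF of the main cleavage-site offsets across clusters."""
    samples = [
        main_cleavage_offset(cluster, j, side)
        for cluster, j in zip(clusters, seed_positions)
    ]
    return CleavageModel(side=side, samples=np.array(samples, dtype=float))


def score_cleavage(cluster: Cluster, j: int, model: CleavageModel) -> float:
    """Boundary-count-weighted cleavage probability mass for seed position j.

    The cluster's G positions on the relevant side are ordered from the
    seed outward; the nearest receives the CDF mass up to its offset, each
    further G the increment. The score averages these masses weighted by the
    read-end counts at each G (3') or the read-start counts just after each
    G (5'). No G on the side yields the neutral score 1 (the locus cannot
    inform cleavage); Gs present but carrying no boundary counts yield 0.
    """
    g = cluster.g_positions()
    if model.side == "3":
        g = g[g - j >= 1]
        if len(g) == 0:
            return 1.0
        g = np.sort(g)
        offs = g - j
        cdf = model.c(offs)
        masses = np.diff(np.concatenate([[0.0], cdf]))
        weights = cluster.ends[g]
    else:
        starts_pos = g + 1
        ok = (starts_pos <= j) & (starts_pos < len(cluster.sequence))
        starts_pos = starts_pos[ok]
        if len(starts_pos) == 0:
            return 1.0
        starts_pos = np.sort(starts_pos)[::-1]  # nearest to seed first
        offs = starts_pos - j
        cdf = model.c(offs)
        masses = np.diff(np.concatenate([[0.0], cdf]))
        weights = cluster.starts[starts_pos]
    total = weights.sum()
    if total == 0:
        return 0.0
    return float(np.clip(np.dot(weights, masses) / total, 0.0, 1.0))


def score_positions(
    cluster: Cluster,
    conv_model: ConversionModel,
    model5: CleavageModel,
    model3: CleavageModel,
    k: int = 7,
) -> PositionScores:
    """Product score p_{i,j} over all valid seed positions of a cluster."""
    n = len(cluster.sequence)
    positions = np.arange(0, max(0, n - k + 1))
    flags: set[str] = set()
    if len(positions) == 0:
        empty = np.zeros(0)
        return PositionScores(cluster.id, positions, empty, empty, empty, empty, {"too_short"})
    sx = np.array([score_conversion(cluster, j, conv_model) for j in positions])
    su = np.array([score_cleavage(cluster, j, model5) for j in positions])
    sd = np.array([score_cleavage(cluster, j, model3) for j in positions])
    if len(cluster.g_positions()) == 0:
        flags.add("no_g")
    return PositionScores(
        cluster_id=cluster.id,
        positions=positions,
        s_xlink=sx,
        s_upstream=su,
        s_downstream=sd,
        p=sx * su * sd,
        flags=flags,
    )


def serialize_models(
    conv: ConversionModel, model5: CleavageModel, model3: CleavageModel
) -> dict:
    """JSON-ready representation of the fitted models."""
    return {
        "conversion": {
            "w_min": conv.w_min,
            "w_max": conv.w_max,
            "xlink": conv.xlink.tolist(),
        },
        "cleavage5": {"samples": model5.samples.tolist()},
        "cleavage3": {"samples": model3.samples.tolist()},
    }
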