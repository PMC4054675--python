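"""EM estimation of k-mer activity probabilities (kmerExplain).

Model: each cluster sequence is explained by exactly one k-mer — the one at
the (hidden) seed position. With activity probabilities alpha_x, the
probability of generating sequence S via position j is

    P(S | j) = alpha_{S^j} * prod_{c != j} (1 - alpha_{S^c})

and the data likelihood is prod_i sum_j P(S_i | j) * p_{i,j}, where p_{i,j}
are the positional prior scores from the generative PAR-CLIP model. The
E-step computes posteriors q_{i,j} proportional to p_{i,j} * P(S_i | j); the
M-step averages posterior mass per k-mer: alpha_x = (1/n) sum_{i,j} q_{i,j}
[S_i^j = x]. Because every posterior row sums to one, the activities sum to
one after each unconstrained M-step.

The single-explaining-k-mer assumption is what suppresses overrepresented
partial k-mers: a k-mer overlapping a truly active seed cannot absorb
posterior mass in clusters already explained by that seed.

A note on the monitored likelihood: the M-step above is the exact maximizer
of the expected complete-data log-likelihood for the model in which every
k-mer of the universe independently fires with probability alpha_x and a
cluster is explained iff exactly the k-mer at its seed position fired:

    P(S | j) = alpha_{S^j} / (1 - alpha_{S^j}) * prod_x (1 - alpha_x)

The global product is a per-cluster constant, so the posteriors q_{i,j} are
identical to those of the per-position product form (which is what
``sequence_likelihood`` reports for a single cluster and position). Under
the per-position form, averaging posterior mass over *all* n clusters would
not be the exact M-step and the likelihood trace could dip; under the
universe form it is exact, the trace is provably non-decreasing, and the
activities sum to one — so that form is the objective tracked by
``run_em`` and ``total_log_likelihood``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12

_ENCODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_BASES = "ACGT"


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        code = _ENCODE[ord(ch)]
        if code < 0:
            raise ValueError(f"invalid base {ch!r} in k-mer")
        idx = idx * 4 + code
    return int(idx)


def index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def enumerate_kmers(sequence: str, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers of ``sequence``, in order.

    Windows containing N (or any non-ACGT base) get the sentinel -1 and are
    excluded from activity updates. Sequences shorter than k yield an empty
    row.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = _ENCODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    out = np.empty(n, dtype=np.int64)
    for j in range(n):
        window = codes[j : j + k]
        out[j] = -1 if (window < 0).any() else int(window @ (4 ** np.arange(k - 1, -1, -1)))
    return out


@dataclass
class KmerActivities:
    """Activity probabilities alpha_x over all 4^k k-mers."""

    k: int
    alpha: np.ndarray
    whitelist: np.ndarray | None = None  # boolean mask over 4^k if restricted

    def top(self, n: int = 20) -> list[tuple[str, float]]:
        order = np.argsort(self.alpha)[::-1][:n]
        return [(index_to_kmer(int(i), self.k), float(self.alpha[i])) for i in order]

    def activity(self, kmer: str) -> float:
        return float(self.alpha[kmer_to_index(kmer)])


@dataclass
class EMResult:
    activities: KmerActivities
    posteriors: list[np.ndarray]
    log_likelihood: list[float]
    unassignable: list[int] = field(default_factory=list)
    n_iter: int = 0


def sequence_likelihood(row: np.ndarray, j: int, activities: KmerActivities) -> float:
    """P(S | j) under the single-explaining-k-mer model (log-space product)."""
    return float(np.exp(_log_likelihood_row(row, np.clip(activities.alpha, EPS, 1 - EPS))[j]))


def _log_likelihood_row(row: np.ndarray, alpha_clamped: np.ndarray) -> np.ndarray:
    """log P(S | j) for every position j of one cluster; -inf at sentinel
    positions (N-containing windows cannot be the explaining k-mer)."""
    valid = row >= 0
    log_a = np.full(len(row), -np.inf)
    log_1ma = np.zeros(len(row))
    a = alpha_clamped[row[valid]]
    log_a[valid] = np.log(a)
    log_1ma[valid] = np.log1p(-a)
    total = log_1ma.sum()
    return total - log_1ma + log_a


def _log_odds_row(row: np.ndarray, alpha_clamped: np.ndarray) -> np.ndarray:
    """log(alpha/(1-alpha)) per position; -inf at sentinel positions."""
    out = np.full(len(row), -np.inf)
    valid = row >= 0
    a = alpha_clamped[row[valid]]
    out[valid] = np.log(a) - np.log1p(-a)
    return out


def e_step(
    rows: list[np.ndarray],
    priors: list[np.ndarray],
    activities: KmerActivities,
) -> tuple[list[np.ndarray], list[int], float]:
    """Posterior position probabilities q_{i,j} and the data log-likelihood.

    q_{i,j} = p_{i,j} P(S_i|j) / sum_c p_{i,c} P(S_i|c), computed in log
    space with max-subtraction. The returned log-likelihood is the
    universe-form objective (see module docstring): per assignable cluster
    log sum_j p_{i,j} alpha_j/(1-alpha_j), plus n * sum_x log(1-alpha_x).
    Clusters whose row is entirely zero (no position with positive prior
    and likelihood) are returned in the unassignable list with a zero
    posterior row and take no part in the likelihood.
    """
    alpha_c = np.clip(activities.alpha, EPS, 1 - EPS)
    posteriors: list[np.ndarray] = []
    unassignable: list[int] = []
    loglik = 0.0
    n_assigned = 0
    for i, (row, p) in enumerate(zip(rows, priors)):
        if len(row) == 0:
            posteriors.append(np.zeros(0))
            unassignable.append(i)
            continue
        with np.errstate(divide="ignore"):
            logw = np.log(p) + _log_odds_row(row, alpha_c)
        m = logw.max()
        if not np.isfinite(m):
            posteriors.append(np.zeros(len(row)))
            unassignable.append(i)
            continue
        w = np.exp(logw - m)
        z = w.sum()
        posteriors.append(w / z)
        loglik += m + np.log(z)
        n_assigned += 1
    # global inactivity term; exactly-zero activities contribute log(1) = 0
    nz = activities.alpha > 0
    loglik += n_assigned * float(np.log1p(-np.clip(activities.alpha[nz], 0, 1 - EPS)).sum())
    return posteriors, unassignable, loglik


def m_step(
    posteriors: list[np.ndarray],
    rows: list[np.ndarray],
    k: int,
    whitelist: np.ndarray | None = None,
) -> KmerActivities:
    """alpha_x = (1/n) sum_{i,j} q_{i,j} [S_i^j = x] over assignable clusters.

    In whitelist mode, non-whitelisted k-mers are frozen at a small floor
    (1 / (10 * 4^k)) so that clusters lacking any whitelisted k-mer remain
    assignable as background; the whitelisted activities are rescaled to
    keep the total at one.
    """
    size = 4**k
    alpha = np.zeros(size)
    n = 0
    for q, row in zip(posteriors, rows):
        if len(q) == 0 or q.sum() == 0:
            continue
        valid = row >= 0
        np.add.at(alpha, row[valid], q[valid])
        n += 1
    if n == 0:
        raise ValueError("no assignable clusters in M-step")
    alpha /= n
    if whitelist is not None:
        floor = 1.0 / (10.0 * size)
        present = np.zeros(size, dtype=bool)
        for row in rows:
            present[row[row >= 0]] = True
        background = present & ~whitelist
        white_mass = alpha[whitelist].sum()
        budget = max(1.0 - floor * background.sum(), EPS)
        out = np.zeros(size)
        if white_mass > 0:
            out[whitelist] = alpha[whitelist] * (budget / white_mass)
        out[background] = floor
        return KmerActivities(k=k, alpha=out, whitelist=whitelist)
    return KmerActivities(k=k, alpha=alpha)


def uniform_activities(rows: list[np.ndarray], k: int) -> KmerActivities:
    """Uniform activities over the k-mers present in at least one cluster."""
    size = 4**k
    present = np.zeros(size, dtype=bool)
    for row in rows:
        present[row[row >= 0]] = True
    alpha = np.zeros(size)
    if present.sum() > 0:
        alpha[present] = 1.0 / present.sum()
    return KmerActivities(k=k, alpha=alpha)


def run_em(
    rows: list[np.ndarray],
    priors: list[np.ndarray],
    k: int,
    init: KmerActivities | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    whitelist: np.ndarray | None = None,
) -> EMResult:
    """Alternate E/M steps until the log-likelihood gain drops below tol.

    Priors stay fixed for the whole run. The likelihood trace must be
    non-decreasing (up to 1e-9 slack); a decrease beyond the slack raises,
    as it indicates an implementation bug rather than a data problem.
    """
    if len(rows) != len(priors):
        raise ValueError("rows and priors must align")
    activities = init if init is not None else uniform_activities(rows, k)
    if whitelist is not None and activities.whitelist is None:
        activities = KmerActivities(k=k, alpha=activities.alpha, whitelist=whitelist)
    trace: list[float] = []
    posteriors: list[np.ndarray] = []
    unassignable: list[int] = []
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        posteriors, unassignable, loglik = e_step(rows, priors, activities)
        if trace and loglik < trace[-1] - 1e-9 and whitelist is None:
            # the guarantee only holds for the unconstrained M-step; the
            # whitelist floor is a projection that may cost likelihood
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{trace[-1]} -> {loglik}"
            )
        converged = bool(trace) and loglik - trace[-1] < tol
        trace.append(loglik)
        activities = m_step(posteriors, rows, k, whitelist=whitelist)
        if converged:
            break
    # refresh posteriors so they correspond to the returned activities
    posteriors, unassignable, loglik = e_step(rows, priors, activities)
    if loglik < trace[-1] - 1e-9 and whitelist is None:
        raise RuntimeError("EM log-likelihood decreased at final refresh")
    trace.append(loglik)
    return EMResult(
        activities=activities,
        posteriors=posteriors,
        log_likelihood=trace,
        unassignable=unassignable,
        n_iter=iterations,
    )


def total_log_likelihood(
    rows: list[np.ndarray], priors: list[np.ndarray], activities: KmerActivities
) -> float:
    """log prod_i sum_j P(S_i|j) p_{i,j} at the given activities."""
    return e_step(rows, priors, activities)[2]
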