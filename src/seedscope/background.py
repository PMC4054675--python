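"""Chance seed-match statistics in random sequence.

These closed forms quantify why short seeds are ambiguous: a fixed k-mer
recurs every 4^k bases in uniform random sequence, so with many distinct
seeds under consideration, a typical cluster-sized window contains a seed
match by chance alone. Monte-Carlo counterparts are provided so the closed
forms can be cross-checked by direct simulation.
"""

from __future__ import annotations

import numpy as np

from .kmerexplain import _ENCODE


def expected_kmer_spacing(k: int) -> float:
    """Mean distance between successive occurrences of a fixed k-mer in
    uniform random sequence (renewal rate 4^-k per position)."""
    return float(4**k)


def seed_match_probability(length: int, n_seeds: int, k: int) -> float:
    """Probability that a random ``length``-mer contains at least one match
    to any of ``n_seeds`` distinct k-mer seeds.

    Positions are treated as independent (a good approximation for
    non-overlapping seed sets): 1 - (1 - n/4^k)^(length - k + 1).
    """
    per_pos = n_seeds / 4**k
    return 1.0 - (1.0 - per_pos) ** (length - k + 1)


def _random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int64)


def _window_match(codes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Boolean vector: does the window starting at each position equal target."""
    k = len(target)
    n = len(codes) - k + 1
    hit = np.ones(n, dtype=bool)
    for i, t in enumerate(target):
        hit &= codes[i : i + n] == t
    return hit


def mc_kmer_spacing(
    kmer: str, sequence_length: int, rng: np.random.Generator
) -> float:
    """Observed mean spacing of ``kmer`` in a random sequence: length divided
    by the occurrence count (overlaps allowed)."""
    target = _ENCODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
    if (target < 0).any():
        raise ValueError("k-mer must be over ACGT")
    codes = _random_codes(sequence_length, rng)
    hits = int(_window_match(codes, target).sum())
    if hits == 0:
        return float("inf")
    return sequence_length / hits


def mc_seed_match_probability(
    length: int, seeds: list[str], n_trials: int, rng: np.random.Generator
) -> float:
    """Fraction of random ``length``-mers containing >= 1 of the seeds."""
    k = len(seeds[0])
    if any(len(s) != k for s in seeds):
        raise ValueError("all seeds must share one length")
    weights = 4 ** np.arange(k - 1, -1, -1)
    seed_idx = {
        int(_ENCODE[np.frombuffer(s.encode(), dtype=np.uint8)] @ weights) for s in seeds
    }
    hits = 0
    codes = rng.integers(0, 4, size=(n_trials, length), dtype=np.int64)
    # integer-encode every window of every trial
    win = np.zeros((n_trials, length - k + 1), dtype=np.int64)
    for i in range(k):
        win = win * 4 + codes[:, i : i + length - k + 1]
    for row in win:
        if not seed_idx.isdisjoint(row.tolist()):
            hits += 1
    return hits / n_trials
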