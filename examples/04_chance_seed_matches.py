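"""Why 7-mers: chance seed-match statistics in random sequence.

A fixed 6-mer recurs every 4^6 = 4096 bases, so with tens of distinct
6-mer seeds in play, a cluster-sized window contains a seed match by
chance alone more than a fifth of the time — which is why k = 7 is the
default seed length. Both numbers are cross-checked by direct simulation.
"""

import numpy as np

from seedscope.background import (
    expected_kmer_spacing,
    mc_kmer_spacing,
    mc_seed_match_probability,
    seed_match_probability,
)

rng = np.random.default_rng(0)

print(f"expected spacing of a fixed 6-mer: {expected_kmer_spacing(6):.0f} bases")
mc = mc_kmer_spacing("ACGTAC", 2_000_000, rng)
print(f"observed mean spacing in 2 Mb of random sequence: {mc:.0f} bases")

p = seed_match_probability(30, 40, 6)
print(f"\nP(random 30-mer contains one of 40 distinct 6-mer seeds) = {p:.1%}")
seeds = []
while len(seeds) < 40:
    s = "".join(rng.choice(list("ACGT"), size=6))
    if s not in seeds:
        seeds.append(s)
mc_p = mc_seed_match_probability(30, seeds, 10_000, rng)
print(f"Monte-Carlo estimate over 10,000 random 30-mers: {mc_p:.1%}")
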