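"""Integrate replicate experiments into a single assignment per cluster.

Clusters are detected jointly over all experiments; counts are normalized
so the median fold change to the deepest experiment is one; each
experiment is analysed separately and the per-experiment posteriors are
combined with weights proportional to normalized read counts.
"""

import copy

import numpy as np

import seedscope as ss
from seedscope.pipeline import integrate_experiments

data = ss.simulate_dataset(ss.SimTruth(seed=11), n_clusters=100, n_experiments=2)
genome = ss.GenomeSource.from_dict(data.genome)
clusters = ss.detect_clusters(data.experiments)
for c in clusters:
    ss.build_profile(c, genome)

counts = ss.main_site_count_matrix(clusters)
factors, kept = ss.normalize_experiments(counts, min_norm_count=10)
print(f"reference experiment: {factors.reference}; "
      f"factors: { {e: round(f, 3) for e, f in factors.factors.items()} }")
print(f"{len(kept)} of {len(clusters)} clusters keep >= 10 normalized reads")

keep = set(kept.index)
clusters = [c for c in clusters if c.id in keep]
for c in clusters:
    ss.build_profile(c, genome, factors)

# per-experiment runs on experiment-specific profiles
results = {}
for exp in data.experiments:
    sub = []
    for c in clusters:
        cc = copy.copy(c)
        cc.reads = [r for r in c.reads if r.experiment == exp]
        if cc.reads:
            ss.build_profile(cc, genome, factors)
            sub.append(cc)
    results[exp] = (sub, ss.run_parma(sub, ss.RunConfig(min_pair_support=5)))

# integrate the two experiments for one cluster present in both
exp1, exp2 = sorted(results)
sub1, res1 = results[exp1]
sub2, res2 = results[exp2]
common = ({c.id for c in sub1} & {c.id for c in sub2})
cid = sorted(common)[0]
i1 = [c.id for c in sub1].index(cid)
i2 = [c.id for c in sub2].index(cid)
weights = [sub1[i1].per_experiment_counts.get(exp1, 0.0),
           sub2[i2].per_experiment_counts.get(exp2, 0.0)]
combined = integrate_experiments(
    [res1.posteriors[i1], res2.posteriors[i2]],
    [res1.scores[i1].p, res2.scores[i2].p],
    weights,
    row=res1.rows[i1],
)
print(f"\ncluster {cid}: combined g = {combined.g}, k-mer {combined.kmer}, "
      f"Cscore {combined.cscore:.3f}, MAscore {combined.mascore:.3f} "
      f"(weights {np.round(np.array(weights) / sum(weights), 2).tolist()})")
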