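"""Full iterative run: k-mer activities, seed assignment and confidence.

Runs the model/kmerExplain loop on simulated clusters, prints the top
activity k-mers (the five planted seed sites should dominate), and shows
one cluster's assignment: the chosen position g, its explaining k-mer, the
matching miRNA family, the Cscore (model fit at g) and the MAscore
(dominance of this explanation over alternatives).
"""

import seedscope as ss

MIRNAS = [
    ("hsa-miR-15a", "UAGCAGCACAUAAUGGUUUGUG"),
    ("hsa-miR-16", "UAGCAGCACGUAAAUAUUGGCG"),
    ("hsa-let-7a", "UGAGGUAGUAGGUUGUAUAGUU"),
    ("hsa-miR-155", "UUAAUGCUAAUCGUGAUAGGGGUU"),
    ("hsa-miR-21", "UAGCUUAUCAGACUGAUGUUGA"),
    ("hsa-miR-122", "UGGAGUGUGACAAUGGUGUUUG"),
]

data = ss.simulate_dataset(ss.SimTruth(seed=11), n_clusters=150)
genome = ss.GenomeSource.from_dict(data.genome)
clusters = ss.detect_clusters(data.experiments)
for c in clusters:
    ss.build_profile(c, genome)

result = ss.run_parma(clusters, ss.RunConfig(min_pair_support=5))
print(f"outer loop finished after {result.rounds} round(s)")
print("\ntop k-mer activities (planted: TGCTGCT CTACCTC AGCATTA TAAGCTA ACACTCC):")
for kmer, activity in result.activities.top(7):
    names = ss.annotate_mirnas(kmer, MIRNAS)
    print(f"  {kmer}  alpha = {activity:.3f}  {','.join(names) or '-'}")

calls = ss.assignments(result, clusters, MIRNAS)
annotated = [(c, a) for c, a in zip(clusters, calls) if a.mirnas]
c, a = max(annotated, key=lambda ca: ca[1].cscore)
print(f"\nbest-scoring cluster {c.id} ({c.chrom}:{c.blocks[0][0]}-{c.blocks[-1][1]}):")
print(f"  seed position g = {a.g}, k-mer {a.kmer} ({','.join(a.mirnas) or 'no miRNA'})")
print(f"  Cscore = {a.cscore:.3f} (how well conversions/cleavages fit a seed at g)")
print(f"  MAscore = {a.mascore:.3f} (posterior weight of this explanation)")
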