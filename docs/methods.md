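# Methods

## Data model and preprocessing

All coordinates are 0-based half-open. Minus-strand alignments are
canonicalized to sense orientation at parse time, so "a T→C conversion"
always means a sense-strand reference T read as C; downstream code never
branches on strand except when touching genomic coordinates.

Adapter trimming aligns adapter prefixes to read suffixes, ungapped,
removing the longest suffix with mismatch fraction ≤ `max_mismatch_fraction`
(default 0.1) over an overlap ≥ `min_overlap` (default 4). Removal is
iterated until nothing matches, which handles adapter dimers and makes the
operation idempotent. Reads whose adapter was *not* found hit the
sequencer's length limit rather than an RNase cut; they are flagged
untrimmed and later extended in the sense 3' direction to end immediately
after the next genomic G (cap `max_extension = 20` nt), because only
G-anchored boundaries carry cleavage information. A terminal G on the read
is treated as the fragment's own 3' G, so the scan starts beyond it.

When comparing a read to the reference, T→C differences are recorded as
conversions and excluded from the mismatch count; every other difference,
and any N on either side, is a mismatch. Only mismatch-free reads
participate in clustering.

## Clusters

Clusters are maximal strand-specific connected components of reads whose
blocks overlap (spliced reads connect through any block), pooled over all
experiments so that replicate/condition sets share one cluster frame.
Filters follow standard PAR-CLIP practice: total read count ≥ 5 and ≥ 3
distinct read species ("species" interpreted as distinct collapsed
sequences), and after normalization ≥ 10 normalized reads in at least one
experiment.

Splicing inconsistencies are resolved before splitting: reads running from
an exon across a junction boundary into the intron are removed first; if
mutually exclusive junctions remain (overlapping introns), only the
junction with the highest read support keeps its reads.

Overlapping target sites are separated by iterative peeling: find the main
cross-linking site (argmax of pooled conversion counts; ties to the sense
5'-most position), emit all reads covering it as one sub-cluster if the
filters pass, and repeat on the remainder. Components with no conversions
at all have no main cross-linking site and are dropped — every downstream
quantity (quantification, conversion scoring) is anchored on that site.

Per-experiment quantification sums the collapse counts of reads covering
the main cross-linking site. Normalization picks the deepest experiment as
reference and scales every other experiment by the reciprocal of its median
per-cluster fold change to the reference, so the median fold change is one
afterwards. Whether "the count of the main site" means covering reads or
starting reads, and whether normalization uses main-site or total counts,
are both underdetermined; covering reads and main-site counts were chosen
and are used consistently.

## Generative model

Offsets are always `position − j` for a candidate seed start `j`; upstream
is negative. Defaults: scoring window −25…+15, seed length k = 7.

**Conversion submodel.** `xlink(i)` is a non-negative propensity per offset
summing to one. The score

    s_xlink(L, j) = cos( (conv_L(t))_{t∈T(L)}, (xlink(t−j))_{t∈T(L)} )

is the cosine similarity restricted to the cluster's T positions; it is 1
exactly when observed counts are proportional to the expected propensities
and is invariant to sequencing depth. Because cross-linking yields are
identified only up to scale, fitting goes through pairwise ratios: for each
offset pair (k, l) the slope `R_{k,l}` is the median of per-cluster ratios
`conv(j+k)/conv(j+l)` over clusters with both offsets in `T(L)` and a
positive denominator (a Theil–Sen-style through-origin estimate; ≥ 10
supporting clusters per pair, all supported pairs used). The propensity
vector minimizes `Σ (xlink(k) − R_{k,l}·xlink(l))²` subject to
non-negativity and sum-to-one. The ratio-difference form
`(xlink(k)/xlink(l) − R)²` is not a quadratic objective; the linearized
residual is, and agrees with it at the optimum up to the weighting by
`xlink(l)²`. The program is solved as non-negative least squares with a
heavily weighted sum-to-one row (penalty weight 10³·(1+max|A|)) followed by
renormalization — for this convex, well-conditioned system the penalty
solution matches a simplex grid search to fine tolerance (tested). Offsets
not connected to the largest component of the pair graph are unfittable and
get zero propensity.

**Cleavage submodels.** For each cluster the main 3' (5') cleavage site is
the argmax of `end_L` (`start_L`); `c3(i)` is the fraction of clusters
whose main site offset is ≤ i (for 5': ≥ i), an empirical CDF that is
monotone by construction. Cut sites are not independent given the sequence:
RNase T1 cuts after G, and a G close to the seed shadows more distant ones.
Scoring therefore distributes *cumulative* probability over the cluster's
actual G positions: ordering the side's Gs from the seed outward, the
nearest G receives `c(o₁)` and each subsequent G the increment
`c(o_m) − c(o_{m−1})`; the score is the boundary-count-weighted mean of
these masses (end counts at the G for 3'; start counts at the position just
after the G for 5' — a read starting at position p was cleaved after p−1).
CDFs are estimated unconditionally from main sites and G-conditioning is
applied only at scoring time, where the formula requires it. A cluster with
no G on one side cannot inform that cleavage model; its score is set to the
neutral 1 (and flagged) rather than 0, so clusters at G-poor loci are not
annihilated. Gs present but carrying no boundary counts give 0.

The position score is the product
`p_{i,j} = s_xlink · s_upstream · s_downstream ∈ [0, 1]`.

## kmerExplain

Each cluster is generated by exactly one k-mer. With activities `α_x`,

    P(S | j) = α_{S^j} · Π_{c≠j} (1 − α_{S^c}),

the E-step computes `q_{i,j} ∝ p_{i,j} · P(S_i | j)` (log space,
max-subtraction; activities clamped to [1e-12, 1−1e-12]), and the M-step is
`α_x = (1/n) Σ_{i,j} q_{i,j}[S_i^j = x]`, so activities sum to one.

This M-step is the exact maximizer of the expected complete-data
log-likelihood for the equivalent formulation in which the inactivity
product runs over the whole k-mer universe,
`P(S|j) = α/(1−α) · Π_x (1−α_x)`: the global product is a per-cluster
constant, posteriors are identical, and the EM monotonicity guarantee holds
exactly. Under the per-position product the same update is only approximate
and the likelihood can dip on short, repeat-dense sequences. `run_em`
therefore monitors the universe-form objective, asserts non-decrease (1e-9
slack) and raises on violation as an implementation-bug signal.
`sequence_likelihood` exposes the per-position form for a single cluster.

Convergence: log-likelihood gain < 1e-4, cap 200 iterations (the stopping
rule is this package's choice). Clusters shorter than k, or with no
position of positive prior, are reported unassignable and excluded from the
M-step average. N-containing windows carry a sentinel and can never be the
explaining k-mer. In whitelist mode (an a-priori set of allowed seeds),
non-whitelisted k-mers are frozen at a floor of `1/(10·4^k)` instead of 0
so clusters without any whitelisted k-mer remain assignable and are flagged
background; the monotonicity guarantee applies only to the unconstrained
update.

k defaults to 7: with 6-mers, a fixed seed recurs every 4⁶ = 4096 bases,
so cluster-sized windows hit some seed of a realistic miRNA repertoire by
chance alone (>20% for 40 seeds in a 30-mer; see
`seedscope.background`), degrading identifiability.

## Iterative loop and assignment

Round 0 runs kmerExplain on uniform priors. Each subsequent round sets the
per-cluster seed estimate to the posterior argmax (hard assignment — chosen
over posterior-weighted fitting for robustness and speed), refits the three
submodels, recomputes `p`, and reruns kmerExplain; the loop stops when the
max-norm change of `xlink` and both CDFs (evaluated on the window grid)
drops below 1e-3, or after 20 rounds. On realistic data the empirical CDFs
move by ≥ 1/n whenever any cluster's seed flips, so small datasets often
use all rounds; the EM inside each round is cheap and the assignments
stabilize long before the cap.

Assignment: `g = argmax_j q_{i,j}` (ties to the smallest position,
flagged), `Cscore = p_{i,g}` — the model fit at g regardless of which k-mer
sits there — and `MAscore = q_{i,g}/Σ_j q_{i,j}` — how dominant the chosen
explanation is. Multi-experiment integration runs the loop per experiment,
averages posteriors with weights proportional to normalized cluster read
counts (a weighted mean rather than a raw weighted sum, keeping Cscore in
[0, 1]), takes `g` from the combined posterior, the Cscore as the weighted
mean of per-experiment `p(g)` and the MAscore as the best per-experiment
MAscore at g. miRNA annotation matches a k-mer against the reverse
complement of miRNA bases 2…k+1 (7mer-m8 style) or the reverse complement
of bases 2…k followed by A (7mer-A1 style); miRNAs sharing a seed are all
reported, as a family. For k ≠ 7 both definitions truncate/extend
consistently.

## Simulator

The forward model mirrors the inference assumptions. Per planted cluster:
sequence of length 42–56 (median near real cluster lengths) with AU-rich
composition (A/C/G/T = 0.3/0.2/0.2/0.3, like 3'-UTR context), one active
k-mer drawn by activity weight (defaults: five 7-mer seed sites of widely
expressed miRNA families, equal weights), a cross-linkable T directly
upstream of the seed with probability 0.7 (frequent but deliberately not
universal — a deterministic T would plant a spurious 8-mer motif),
main cleavage offsets drawn from the true c5/c3 distributions with a G
planted at each cut site (plus a secondary G used by 15% of reads as
boundary noise). Read depth is 5 + negative binomial (size 5, mean 25).
Per read, each T converts with probability
`0.9 · xlink(offset)/max(xlink)` inside the window, 0 inside the seed
(protected by the duplex), 0.01 elsewhere — calibrated so the main
cross-linking site carries well over 60% of a cluster's conversions on
average (observed ≈ 0.8). Background clusters (default 10%) share the
depth distribution but have uniform boundary jitter and a flat 5%
per-T conversion rate. Clusters alternate strands and are laid out along
one synthetic chromosome with 40 nt read-free spacers; everything derives
from one seeded generator, so outputs are byte-identical per seed.

What the simulator does *not* emulate: sequencing errors, PCR duplicates
beyond collapse counts, mapping ambiguity, transcript-level expression
structure, overlapping target sites on real 3' UTRs, or conservation.
Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions — not performance on real
libraries, where background structure is richer.

## Problem sizes and numerics

The recovery experiment uses 500 simulated clusters (≈ 450 planted), where
the pipeline assigns ≥ 90% of planted seeds within ±1 nt and estimator
recovery at true positions reaches Pearson r > 0.99 on `xlink` and
Kolmogorov distances < 0.1 on both CDFs; unit recovery tests use 120
clusters. Monte-Carlo checks use 10 Mb of sequence (6-mer spacing) and
2×10⁴ trials (seed-match probability). Degenerate inputs are handled
explicitly: empty clusters are unassignable rather than errors; an
experiment with zero total counts, an unfittable pair graph, or a
degenerate all-zero QP raise with diagnostics.

## Known limitations

* The cleavage CDFs are fitted from *assigned* seed positions of all
  clusters, so a background fraction contaminates their tails (visible as
  ≈ background-fraction Kolmogorov error in end-to-end fits); the
  conversion model is protected by the median-based ratio estimator, the
  CDFs are not.
* Hard (argmax) seed updates in the outer loop can lock in a
  self-consistent ±1-shifted solution when the sequence context directly
  upstream of seeds is nearly deterministic. Posterior-weighted (soft)
  model fitting was considered and deliberately not implemented: the
  median-based ratio estimator and the empirical main-site CDFs are
  defined per cluster-with-one-seed, and a soft variant would change their
  statistical meaning rather than merely smooth them.
* The splitting procedure discards conversion-free components, so purely
  structural clusters (no cross-link signal) never surface.
* No false-discovery-rate calibration is attempted: score distributions
  depend on background structure that the model does not estimate.
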