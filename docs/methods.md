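# Methods

## Data model

A knockout experiment deletes one gene and records which other genes
significantly change expression.  `signko` represents the outcome as a
directed, signed *functional network*: edge (u, v) with sign
s(u,v) ∈ {+1, −1}, the **complement** of the observed effect (+1 = the
knockout down-regulated the target, i.e. u normally activates v).  Only
genes implicated in at least one experiment appear; effect magnitudes are
not represented — calling significant effects from raw expression data is
upstream of this package.  At most one sign per ordered pair is allowed;
conflicting duplicate records are treated as an input error rather than
resolved by majority, on the assumption that the input is a high-confidence
pair list.

A *physical network* is a directed graph of PPI/PDI interactions whose
edges carry activation (+1), suppression (−1) or unassigned signs.  Its
undirected form is defined only when antiparallel edges agree; it is
*sign-consistent* (balanced) when no undirected cycle has a negative
edge-sign product.  Balance is decided by parity propagation and always
returns a verifiable certificate: a ±1 node coloring reproducing every edge
sign, or an explicit negative cycle.

## Sign-linear fitting

The objective is a Boolean assignment σ maximizing
|{(u,v) : s(u,v) = σ(u)σ(v)}| — MAX-E2-LIN2.  The solver is a greedy local
search:

* initial assignment i.i.d. uniform on ±1 from the run's seed;
* sweeps over a fresh random permutation of the genes; a flip is accepted
  only if it **strictly** increases the satisfied count (equal-score flips
  are rejected, guaranteeing termination since the count is bounded);
* termination after a full sweep with no accepted flip, i.e. a strict
  single-flip local maximum.

An SDP approximation exists for this problem, but the greedy search is
simpler, scales linearly per sweep, and its multi-restart consensus is the
quantity of interest anyway.  Each consensus run draws an independent seed
from the master seed; per queried pair, the fraction of runs voting each
way is reported and a call is made only when a fraction strictly exceeds
the decision cutoff (≥ 0.5; a 50/50 split at cutoff 0.5 is undecided).
Votes use products σ(u)σ(v), so the global negation ambiguity of each run
cancels without aligning runs.  Prediction is restricted to pairs in the
same undirected component — across components the product is unconstrained
by the data, and such pairs abstain in every run (component membership does
not vary across runs, so a pair either always votes or never does;
fractions always use the run count as denominator).

Local maxima need not be global: on an all-positive 4-cycle, assignments
splitting the cycle into two adjacent halves are strict local maxima
satisfying only half the edges, and are reached from a quarter of random
starts.  Consensus voting is the mitigation — wrong-basin runs are a
minority on the instances we generate — but single-run output should not
be treated as an optimum, and `brute_force_optimum` (≤ 20 genes, negation
symmetry halves the enumeration) is provided as an exact oracle.

## Sign-clustering

Similarity of genes u, v pools common upstream knockouts (g with edges
(g,u) and (g,v)) and common downstream targets (t with edges (u,t) and
(v,t)); a gene in both sets contributes two trials.  With k failures
(trials with unequal signs) in n trials the score is BinomCDF(k; n,
p_fail); no shared evidence scores 1.  The default
p_fail = 2q(1−q) is the probability that two independent edges whose sign
is + with probability q (the network's + frequency) disagree; it is
exposed as an override.  Disagreements are counted literally: coherent
anti-correlation (exact-opposite behavior) is *not* credited as
similarity, although the LL-2 notion of regularity would allow it — a
deliberate, simpler reading.

Clustering is bottom-up complete linkage: repeatedly merge the cluster
pair with the smallest maximum pairwise score, while that score is below
the a-priori similarity probability p₀ (default 0.05).  Because complete-
linkage merge scores are monotone, this greedy stop equals cutting the full
dendrogram at p₀ (maximal subtrees whose merge score is < p₀ and whose
parent's is ≥ p₀); genes never merged remain singletons.  Randomness enters
**only** through tie-breaking: ties in merge selection are resolved toward
clusters earlier in the run's random gene ordering.  Consensus repeats the
procedure over orderings and votes per pair; lowering p₀ always refines
the partition obtained at a higher p₀.

Prediction from a partition is a strict majority over the observed signs
from C(u) to C(v) (the held-out pair itself excluded when applicable);
empty or tied evidence, or an unclustered gene, is undecided.  The
two-group sign-linear model is the special case where the matrix of
group-to-group signs is a product τ_g τ_h; the multi-group model
additionally captures negative-feedback pathways whose within-group
effects are all up-regulation.

## Local-linearity tests

Three motif properties characterize every contradiction to sign-linearity
involving at most two knocked-out and two affected genes (verified
exhaustively on that universe in the test suite):

* **LL-1**: edges (a,t), (b,t), (a,b) present ⇒ s(a,b) = s(a,t)s(b,t);
  ordered (a,b) instances, antiparallel edges counted separately.
* **LL-2**: common targets t1, t2 of a, b ⇒ agreement on t1 iff agreement
  on t2 (equivalent or exactly opposite influence).
* **LL-3**: reciprocal edges ⇒ s(a,b) = s(b,a).

Prevalence is compared against a null that permutes edge signs uniformly
over the fixed topology, preserving the sign multiset.  Degree-preserving
rewiring is deliberately not used: the LL properties concern signs on fixed
motifs, and rewiring would change the instance set itself (instance counts
are invariant under the sign permutation).  Reports include a z-score
against the null and a two-sided add-one empirical p-value
(r+1)/(n_rand+1); zero instances or zero null variance are reported as NaN
rather than silently coerced.  For reciprocal pairs the permutation-null
LL-3 prevalence approaches q² + (1−q)² in the large-network limit, which
the benchmark checks against 1,000 permutations.

## Physical-edge annotation

Given a physical topology and knockout data, each consensus run fits a
model on the functional network and votes per physical edge (u, v):

* **two-group mode**: vote σ(u)σ(v) — activating when the endpoints share
  a group, suppressing otherwise;
* **multi-group mode**: vote the majority functional sign observed between
  the endpoint groups (both directions pooled); no or tied evidence
  abstains.  On sign-linear data with a two-group partition this coincides
  with the two-group rule.

Endpoints missing from the functional network (or in different components)
abstain, and the edge is emitted unassigned (`.`) — lack of data, not
evidence of absence.  Because votes are products, no cross-run alignment
is needed.  The constructive direction (`construct_explaining_annotation`)
signs any connected covering topology with σ(u)σ(v), yielding a balanced
annotation in which every undirected path from a to b telescopes to
σ(a)σ(b) = s(a,b); together with the balance checker this realizes both
structural round trips (balanced physical ⇒ sign-linear functional, and
sign-linear functional ⇒ explainable by any connected topology).

## Synthetic benchmarks

The generators define the study conditions; their defaults are fixed and
not tuned per experiment.

* **Physical topology**: a random spanning tree directed away from its
  root plus uniform extra directed edges (connectivity by construction; no
  attempt to match organism degree distributions — the correctness claims
  do not depend on them).  Balanced instances sign edges from a hidden ±1
  coloring (returned as a test oracle); frustrated instances additionally
  flip a stated number of non-tree undirected edges, each closing a
  negative cycle.
* **Functional-from-physical**: sampled sources, targets reached by
  bounded random simple walks, sign = walk aggregate sign (in balanced
  networks path choice is immaterial — all paths between two nodes share
  one aggregate sign); sources without reachable targets are resampled,
  and exhausting candidates is fatal rather than silently degraded.
* **Planted k groups**: round-robin assignment, signs from a k×k ±1
  matrix.  The *pathway motif* matrix (diagonal −1, off-diagonal +1)
  emulates mutual up-regulation within negative-feedback pathways and is
  provably not sign-linear once a group has three sampled members.
* **Noise**: i.i.d. sign flips at a configured rate, applied after the
  ground truth is recorded and returned separately.

What these benchmarks do **not** emulate: combinatorial regulation
(multi-input functions), expression magnitudes and dosage, realistic
degree structure, and correlated (non-i.i.d.) measurement error.  Passing
tests demonstrate correctness of the algorithms under their own model
assumptions, not performance on any real compendium.

## Evaluation harness

Cross-validation shuffles the edge list once, hides disjoint folds of a
configured size (last fold smaller), refits on the remainder and scores
hidden pairs against their **observed** signs (pre-noise planted truth,
when available, is scored separately).  Genes appearing only in hidden
edges drop out of training and their pairs abstain; accuracy with zero
predictions is NaN, never 0 or 1.  Identities maintained and tested:
coverage = accuracy × prediction rate; decided counts are non-increasing
along an ascending cutoff grid.  Noise robustness flips round(rate·m)
input signs and reports call consistency over pairs decided in both clean
and perturbed analyses.  Partition agreement uses the adjusted Rand index.

## Benchmark problem sizes

The shipped benchmarks (test suite and `scripts/acceptance.py`) use:
200 random 8–12-gene instances × 50 restarts against the exhaustive
oracle; 50 balanced 14-node physical networks for the round trips (small
enough that brute-force optimality is certified on every instance, and the
hidden coloring provides the optimum witness independently); planted
partitions with 30 genes per group for k ∈ {2,3,4} with ~2/3 of possible
targets sampled per knockout and 5% noise; 20–25 consensus runs instead of
the 100 used interactively (votes on these instances are near-unanimous,
so the consensus is insensitive to the run count).  The noise-robustness
instance carries 15% intrinsic sign noise: a perfectly satisfiable
instance is immune to moderate perturbation (its planted optimum remains
dominant and consistency sits at 100% across all rates), so a noisy
instance is required for the perturbation protocol to be informative.

## Known limitations

* The greedy search offers no approximation guarantee; quality claims rest
  on the exhaustive-oracle benchmark at small scale.
* Complete linkage is conservative: a gene with little shared evidence
  (e.g. most of its edges held out) blocks merges and falls out as a
  singleton, abstaining from predictions.
* The similarity score treats trials as independent; overlapping evidence
  sets violate this mildly.
* Multi-group annotation uses the group-majority rule only; no global
  objective over edge signs is optimized.
* Two-valued effects: magnitude and significance of expression changes are
  assumed to be resolved upstream.
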