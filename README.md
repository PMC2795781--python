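# signko — network-free inference of gene-knockout effects

`signko` analyzes large collections of single-gene knockout experiments.
Its input is a *functional network*: a directed graph in which an edge
(u, v) records that deleting gene *u* significantly changed the expression
of gene *v*, signed by the wild-type influence — `+` when the knockout
down-regulates the target (u normally activates v), `-` when it
up-regulates it.  From that network alone — no physical interaction map is
required — the package:

* **predicts hidden knockout effects** (up- or down-regulation) for unseen
  gene pairs, with two models of increasing flexibility;
* **tests local-linearity structure** (three motif properties, LL-1/2/3,
  compared against a sign-permutation null);
* **annotates physical interaction networks** (PPI/PDI) with activation or
  suppression signs, when a physical topology *is* available;
* **generates synthetic benchmarks** with planted ground truth, and
  evaluates everything by cross-validation, accuracy/coverage curves, and
  noise-robustness protocols.

## The two models

**Sign-linear model.**  A functional network is *sign-linear* if there is a
Boolean assignment σ: genes → {+1, −1} with every edge sign satisfying
s(u,v) = σ(u)·σ(v) — equivalently, the genes split into two groups with
down-regulation within groups and up-regulation between them.  Fitting
maximizes the number of satisfied edges (MAX-E2-LIN2, NP-hard); `signko`
uses a randomized greedy local search — flip any gene whose flip strictly
increases the satisfied count, until a strict local maximum — repeated from
many random starts.  A hidden effect of u on v is then predicted from the
consensus of σ(u)·σ(v) over runs.  The model is motivated by a structural
fact: if the latent physical network is *sign-consistent* (balanced — no
undirected cycle with negative sign product), every functional network it
can generate is sign-linear, and conversely any sign-linear functional
network is explained by signing any connected covering topology with
σ(u)·σ(v).  Both directions are implemented and tested.

**Sign-clustering model.**  Negative-feedback pathways violate
sign-linearity: pathway members often *up-regulate each other* upon
knockout, and a mutually up-regulating triple admits no Boolean assignment.
The multi-group model clusters genes by a binomial-CDF similarity —
each common upstream knockout or downstream target of a gene pair is a
Bernoulli trial, a "failure" is a trial where the two genes behaved
differently, and the score is P(X ≤ k | n, p_fail) with p_fail = 2q(1−q)
(q = frequency of `+` edges) — then cuts a complete-linkage hierarchy at an
a-priori similarity probability p₀ (default 0.05).  A hidden effect of u on
v is the majority sign of observed effects from u's group onto v's group.

## Worked example

Generate a synthetic benchmark whose functional network is produced by a
balanced (sign-consistent) physical network, then predict and evaluate:

```sh
signko simulate --preset signconsistent --seed 7 --outdir demo
signko predict-linear --net demo/FUNC.tsv --pairs demo/pairs.tsv \
    --runs 100 --seed 1 --out demo/preds.tsv
```

`demo/preds.tsv` (pairs taken from the generated network):

```
ko_gene target_gene call  frac_down frac_up n_runs
g001    g007        down  1.0000    0.0000  100
g001    g015        up    0.0000    1.0000  100
g001    g017        down  1.0000    0.0000  100
```

`frac_down`/`frac_up` are the fractions of the 100 local-search runs voting
for each effect; `call` is decided when a fraction strictly exceeds the
cutoff (default 0.5).  Unanimous votes are expected here: the source
network is balanced, so the instance is perfectly sign-linear.
Cross-validation hides 20 pairs per fold and refits on the rest:

```sh
signko crossval --net demo/FUNC.tsv --holdout 20 --folds 3 --runs 25 \
    --seed 2 --out demo/eval.tsv
# pooled accuracy=1.0000 coverage=1.0000
```

*Accuracy* is correct calls over calls made; *coverage* is correct calls
over all evaluated pairs (coverage = accuracy × prediction rate).  Other
subcommands: `predict-cluster` (multi-group model), `lltest`
(local-linearity reports), `annotate` (physical edge signs), `noise`
(perturbation consistency).

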