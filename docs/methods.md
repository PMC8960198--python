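# Methods

## Model

`mlsbm` implements a finite stochastic block model over $M \ge 1$
undirected simple graphs ("layers", e.g. modalities of a connectome) that
share one vertex set and one latent partition $z$ with a fixed label budget
$K$. Conditional on $z$, each layer's links are independent Bernoulli draws
with a block-specific probability $\eta^{(m)}_{\ell h}$; the
$\eta^{(m)}_{\ell h}$ are i.i.d. Beta$(\beta^+, \beta^-)$ across blocks and
layers, with one $(\beta^+, \beta^-)$ pair shared by all layers. Cluster
proportions follow a symmetric Dirichlet with total concentration $\alpha$
(so $\alpha/K$ per label). Self-links are excluded everywhere: the
likelihood runs over unordered pairs $i < j$, and readers silently drop
diagonal entries (with a logged count).

Beta–Bernoulli and Dirichlet–Categorical conjugacy let both $\eta$ and
$\pi$ be marginalized analytically. The collapsed joint factorizes over
layers and unordered cluster pairs $\ell \le h$ and depends on the data
only through the per-block link/non-link counts $N^{(m)\pm}_{\ell h}$ and
cluster sizes $n_k$ (`BlockStats`). Everything is evaluated in the natural-
log domain via `gammaln`/`betaln`/`digamma`; the gamma function is never
evaluated directly. Empty clusters are legitimate states of the finite
mixture — $\Gamma(\alpha/K + 0)/\Gamma(\alpha/K) = 1$ — and need no special
casing.

This is a plain (not degree-corrected) SBM for binary symmetric networks;
weighted, directed and nonparametric (CRP) variants are out of scope.

## Inference

One iteration of the sampler is:

1. a full collapsed Gibbs sweep: each vertex in turn is detached from the
   sufficient statistics, its conditional over all $K$ labels is computed
   from incremental count updates (cost $O(MK)$ per candidate instead of a
   full $O(E)$ rebuild), normalized with max-subtraction, and a new label
   is sampled;
2. $n$ random-walk Metropolis–Hastings proposals for each of $\beta^+$,
   $\beta^-$, $\alpha$, in that order, with Gaussian steps of variance 1 on
   the natural scale. Proposals $\le 0$ are rejected outright, which
   together with a flat improper prior on $(0, \infty)$ makes the
   acceptance ratio the collapsed-likelihood ratio alone.

Defaults mirror the reference schedule: $K = 360$, 100 iterations, 1,000
MH proposals per hyperparameter, and the **last sampled state is the point
estimate** — no convergence diagnostics are attempted, and none are claimed.
`fit_hyperparameters_fixed` runs only stage 2 with $z$ frozen, the
atlas-style baseline in which a fixed parcellation's hyperparameters adapt
to the data.

Choices the model description leaves open, fixed here once:

- **Initialization**: uniform random label per vertex; $\beta^+ = \beta^- =
  1$ (uniform Beta), $\alpha = K$ (unit per-label concentration).
- **Sweep order**: ascending vertex index by default, for reproducibility; a
  `randomize_order` flag draws a fresh permutation per sweep.
- **Hyperparameter prior**: flat improper on $(0,\infty)$. Only the proposal
  distribution is prescribed by the model description; the prior choice is
  ours and only matters through the (proper) posterior it induces.
- **Determinism**: all randomness flows through one
  `numpy.random.Generator`; a seed reproduces a fit bit-for-bit.

## Prediction

A partition learned on training layers is scored on a held-out network
through the Beta posterior of each block: with $a = N^+ + \beta^+$,
$b = N^- + \beta^-$,

- expected predictive log-likelihood (EPLL):
  $\sum_{i>j} A_{ij}\,[\psi(a)-\psi(a+b)] + (1-A_{ij})\,[\psi(b)-\psi(a+b)]$
  evaluated at the pair's block;
- link scores $\langle\eta\rangle = a/(a+b)$ ranked by a tie-aware
  (average-rank / Mann–Whitney) ROC AUC, links being the positive class.

With average ranks, a binary predictor's AUC equals
$(\text{sensitivity} + \text{specificity})/2$ of its confusion table, which
is exactly the direct network-to-network baseline (`direct_network_auc`).
Prediction of modality $m$ uses only modality-$m$ training counts;
hyperparameters are those of the training fit, since they parameterize the
$\eta$ posterior being averaged over. The alternative "log of the expected
predictive likelihood" is deliberately not implemented.

## Partition comparison and characterization

MI is computed in nats from the joint label contingency table
(zero-probability cells contribute 0) and normalized as
$2\,\mathrm{MI}(z,z')/[\mathrm{MI}(z,z)+\mathrm{MI}(z',z')]$, which is 1
iff the partitions agree up to relabeling and is invariant to the log base.
If both partitions are single-cluster the normalization is 0/0; they are
then trivially identical and NMI is defined as 1. Nonempty parcels are
binned as small (< 100 vertices), medium (100–1,000 inclusive) and big
(> 1,000); the laterality index of a parcel is
$\max(N_\text{left}, N_\text{right})/(N_\text{left}+N_\text{right})$
(0.5 = perfectly bilateral, 1 = unilateral), a parcel is bilateral iff both
hemispheres contribute at least one vertex, and the mean index is
unweighted over nonempty parcels. Empty parcels are bookkeeping artifacts
of fixed $K$ and are excluded from summaries.

## Blocked-permutation null

To test whether two modalities' parcels actually correspond, the
non-predicted layer is rewired by a permutation built from a clustering
learned on that layer: nonempty clusters are placed in uniformly random
order along the canonical traversal order, vertices within a cluster
keeping ascending traversal positions. Preimage blocks are exactly the
learned clusters, each mapped to a contiguous run, so the parcel size
distribution and traversal-order contiguity survive while vertex-level
cross-modal correspondence is destroyed. Within-cluster order is not
prescribed by the procedure's description; ascending traversal order is
used, which makes the single-cluster case exactly the identity. The null
does not respect anatomy or parcel shape; no stronger null is attempted.

## Synthetic data

The generator draws exactly from the generative process: $z$ once
(from an explicit $\pi$, or $\pi \sim$ Dirichlet$(\alpha/K)$), then each
layer's pairs independently. Planted-partition configurations use equal
proportions with a two-level density matrix (`within` on the diagonal,
`between` off it). Group-style networks are emulated by elementwise
aggregation of replicates followed by density thresholding: the
$L = \mathrm{round}(\text{density}\cdot n(n-1)/2)$ strongest off-diagonal
pairs are kept (round half away from zero; ties broken by weight
descending then lexicographic pair order, so results are deterministic).
Synthetic hemisphere metadata labels the first $\lceil n/2 \rceil$ vertices
"left". What the generator does **not** emulate: spatial contiguity of real
parcels, hemispheric asymmetries, degree heterogeneity within blocks, and
measurement artifacts of real connectomes — passing tests demonstrate
correctness of the machinery on model-generated data, not performance on
real brains.

## Problem sizes and numerical checks

The test-suite and `scripts/acceptance.py` work at desk scale, chosen so
the full suite runs in minutes on one CPU: exhaustive-enumeration checks at
$N \le 3$ (total probability sums to 1 within $10^{-10}$), conditional
checks at $N = 5$, chain-versus-enumerated-posterior checks at $N = 6$, and
planted-recovery / permutation-contrast experiments at $N = 300$, $K = 6$,
within-density 0.25, between 0.02, two layers — conditions under which a
single network already identifies the partition information-theoretically
but prediction of a fresh replicate is far from saturated. Dense adjacency
materialization is refused above 5,000 vertices; the statistics and sweeps
themselves are sparse and scale to much larger graphs.

## Known limitations

- **Single-site Gibbs mode-trapping.** With $K$ equal to the true number of
  blocks, the chain can condense two planted blocks under one label during
  the first sweeps while another label empties; single-vertex moves cannot
  split a merged cluster (nucleating one vertex into an empty label is
  exponentially unfavorable), so such states persist indefinitely even
  though they sit hundreds of nats below the truth. At the planted
  conditions above, roughly one seed in three recovers the partition
  exactly; the others end with one or two merged block pairs (NMI ≈ 0.93 /
  0.85). Split–merge moves would remove this failure mode but are
  deliberately out of scope. The directional conclusions (joint fit beats
  the permuted null; true partition beats random) are robust to it, since
  both arms of each comparison are affected equally.
- The MH proposal scale (variance 1) is fixed, not adapted; acceptance
  rates are logged at DEBUG level but not tuned.
- AUC and EPLL evaluation materialize all vertex pairs and are quadratic in
  $n$; fine to a few thousand vertices, deliberately not optimized beyond.
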