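# Methods

## Models

### Feature generation (compound → expression signature)

The generator predicts a 978-landmark-gene differential-expression
signature (unitless, z-score-like) from two feature blocks: a binary
Morgan fingerprint (default radius 2, 2048 bits) and a vector of molecular
properties selected and scaled as below. Each block passes through its own
dense hidden layer (defaults 2048→512 and 100→64, ReLU, optional batch
normalization), the two latents are concatenated, and a linear head maps
to the 978 genes. The loss is elementwise mean-squared error; weights
carry decoupled L2 decay (default 1e-5); the learning rate follows cosine
annealing with warm restarts,
`lr(t) = lr_min + (lr_max − lr_min)(1 + cos(π (t mod T)/T))/2`
per epoch (defaults 1e-3 → 1e-5, T = 50). Model selection uses k-fold
cross-validation (default 10) in which each compound is predicted exactly
once out-of-fold; the deployed model is then refit on the full reference
set. Evaluation is the per-compound Pearson r across the 978 genes,
averaged over compounds — this matches the question "how well is this
compound's signature predicted"; a per-gene aggregation can be computed
from the returned out-of-fold matrix if wanted.

### Compound featurization

SMILES are canonicalized with RDKit (idempotent; equivalent inputs map to
one form). The descriptor provider is pluggable; the built-in set is
RDKit's 2-D descriptor table (~210 descriptors), and an externally
supplied property list can pin the selection instead. Descriptors that are
undefined for a molecule are NaN, never silently zero; columns containing
any NaN across the compound set are dropped before selection. Selection
fits a multi-target random-forest regression of the expression matrix on
the properties and keeps the top k (default 100) by impurity importance,
ties broken by ascending column index. The supervision target of the
selection is a design choice: the selected features feed expression
prediction, so the forest predicts the expression matrix itself with
importances averaged over gene targets. Scaling is per-feature min-max to
[0, 1], anchored on a designated reference compound set; non-reference
values outside the reference range are clipped to [0, 1] so the model's
input domain stays closed, and constant features map to 0 with a warning.

When a compound has signatures from several experimental conditions, the
representative is the one with maximal signature strength — the count of
genes with |z| ≥ 2 (threshold configurable) — ties going to the earliest
candidate.

### DDI prediction

Input: the two drugs' 978-gene signatures and a side-effect id. A shared
dense layer (978 → H, ReLU) encodes each drug independently; H defaults to
978 so gate entries stay gene-indexed for interpretability (recovery
benchmarks use H = 256 for speed, see Problem sizes). The
co-administration gate for drug *i* in the context of drug *j* is
`g_i = σ(W_g [h_i ; h_j])` with a single shared weight `W_g` in self-first
order, stored as the two half-matrices it factors into; the gated latent
`h_i ⊗ g_i` is reduced by a second shared linear layer to width D
(default 128). Because both layers and the gate weight are shared and the
score below is symmetric in its two drug arguments, pair reversal is an
*exact* symmetry of the model, not just an empirical tendency; the
order-sensitive single-gate alternative was rejected for that reason.
`gates_open=True` forces g = 1 and recovers an ungated
translating-embedding scorer (ablation hook).

Each side effect r owns a relation vector r (width E, default 64) and
projection matrices M_rh, M_rt (E × D). The triplet score is the
two-direction translating distance

    S = ‖M_rh z_i + r − M_rt z_j‖₂ + ‖M_rh z_j + r − M_rt z_i‖₂,

nonnegative and symmetric; lower means more plausible. Training minimizes
a margin ranking loss. The default is the standard per-pair hinge,
`mean(max(0, S⁺ − S⁻ + margin))` over positives matched 1:1 with their
corrupted negatives (margin default 1.0): a per-relation aggregate variant
that sums all positive and negative scores inside one hinge is also
implemented (`aggregate_margin_loss`) but degenerates when set sizes
differ and is not the default. Classification orientation is lower
distance = positive; ranking metrics are computed on negated scores.

Drugs are identified only through their expression features — there is no
drug-id embedding table — which is what makes one-unseen and both-unseen
prediction possible. Side effects are closed-world: scoring an unknown
side-effect id is an error.

Interpretability: `gene_attention` returns the two gate vectors of a pair
(entries in (0,1), gene-indexed when H = 978) and `top_k_genes` extracts
the k highest-attended genes (default 100, ties by gene order);
`pair_latent` exports the gated pre-reduction representation h ⊗ g of one
drug in the context of a partner, which varies with the partner by
construction.

### Numerical core

Both networks run on a small reverse-mode autodiff module over float64
numpy arrays (matmul, row gather with scatter-add backward, batched
per-relation matrix-vector products, sigmoid/ReLU/tanh, row-wise L2 norms
with a zero-row-safe gradient, reductions) and Adam (β = 0.9/0.999,
ε = 1e-8) with decoupled weight decay so that a zero learning rate leaves
parameters bit-identical. Gradients are verified against central finite
differences in the test suite. All randomness flows through
`numpy.random.default_rng` seeded from the relevant config, so training is
bit-reproducible; per-drug hidden states are computed once per batch and
gathered per pair, which keeps the gate cost linear in the drug vocabulary
rather than the batch size.

## Data handling

Triplets are unordered: (a, b, r) and (b, a, r) are one record, stored in
canonical sorted order; duplicates collapse with a warning and
contradictory labels are an error. The three split regimes are:
9:1 triplet split with 1% of the remaining train set as validation
(unseen interaction); and drug-holdout splits where the test set contains
triplets with exactly one, or both, drugs held out (one-/both-unseen).
The holdout fraction is configurable (benchmarks use 0.2). Negative
sampling draws one negative per positive by keeping one end of the pair
and redrawing the partner uniformly, rejecting known positives, the kept
drug itself, and negatives already claimed by any split; when rejection
sampling exhausts its attempt budget the feasible corruptions are
enumerated exactly, and only a truly saturated neighbourhood raises an
error. Reversed-pair augmentation emits both orders for training-time
consumers; with the exactly symmetric default encoder it adds no
information, so the trainer consumes canonical orders. A frequency filter
drops side effects observed with fewer than a threshold (default 500)
distinct positive pairs, mirroring the curation of large adverse-event
datasets.

## Evaluation

AUC is the Mann–Whitney ranking probability (ties half credit); AUPR is
step-wise precision-recall integration (average precision, no trapezoid);
both are checked against brute-force oracles on small instances. Metrics
are computed within each side effect and macro-averaged unweighted;
side effects with one class in the test set are excluded with a warning.
Thresholds maximize Youden's J over midpoints of sorted unique scores
(ties → lower threshold), selected on validation scores when available and
applied to test. Pair-level external validation counts positively
predicted side effects per unordered pair and labels a pair positive when
the count strictly exceeds a cutoff (default 65, the mean number of side
effects per pair in large co-prescription data). The permutation test
draws `sample_size` pairs without replacement `n_perm` times (default
10,000) and reports p = (1 + #{null ≥ observed})/n_perm clipped to 1, so
an observation above every null draw reports the floor 1/n_perm.

## Synthetic worlds

The expression world draws fingerprint bits Bernoulli(0.1), properties
uniform [0, 1], pushes them through a planted linear (or
shallow-nonlinear) map to the gene space and adds Gaussian noise
(sd in expression units). It emulates the feature→signature relationship
and additive noise only — not the heavy tails, gene-gene correlation, or
cell-line heterogeneity of real differential-expression data — so passing
recovery tests demonstrates that the pipeline learns the mapping it
assumes, not that it matches real-assay accuracy.

The DDI world draws drug latents N(0,1) in a low dimension (default 8),
per-side-effect relation parameters, computes true two-direction scores
for every unordered pair, and labels the lowest-scoring
`positive_fraction` quantile per side effect positive, so every side
effect has the configured prevalence exactly and the planted parameters
form a perfect oracle (AUC 1 on any split at zero label noise). Label
noise, default 0, flips pair status symmetrically. Drug expressions are a
fixed linear embedding of the latents; real signatures are not
low-rank-exact, so again recovery shows internal consistency, not field
accuracy. Prevalence 0.2 was chosen as a realistic order of magnitude for
curated polypharmacy datasets after frequency filtering.

## Problem sizes and defaults of the benchmarks

Recovery benchmarks (shared by the test suite and
`scripts/acceptance.py`): the expression world uses 500 compounds,
128 fingerprint bits, 50 properties, noise sd 0.5, with a 256/128-width
model, no batch normalization, 150 epochs, 3-fold CV — chosen as the
smallest configuration that cleanly recovers the planted linear map. The
DDI world uses 60 drugs, 8 side effects, latent and embedding width 8,
prevalence 0.2; the model uses H = 256, D = 64, E = 32, 40 epochs,
batch 1024, margin 1.0. The drug-holdout fraction is 0.2 so the
both-unseen test set has enough pairs for stable macro metrics. Expected
behaviour at these sizes: out-of-fold r ≈ 0.96; macro AUC ≈ 0.93 (unseen
interaction) > ≈ 0.8 (one-unseen) > ≈ 0.7 (both-unseen); replacing the
translating-embedding scorer with a feed-forward head costs far more AUC
than opening the gates, which is expected because the planted world
contains translational structure but no gating structure.

## Known limitations

- Full-scale results on real LINCS/TWOSIDES data (hundreds of side
  effects, thousands of drugs) are out of scope; layer widths from the
  original large-scale setting are configurable placeholders.
- The built-in descriptor set is 2-D only; no conformer generation.
- The expression stage and the DDI stage are trained separately; no joint
  fine-tuning.
- The aggregate margin-loss variant is provided for completeness but is
  not recommended (see above).
- Batch normalization uses per-batch statistics during training, so
  training-mode outputs depend on batch composition (inference uses
  running statistics and is batch-independent).
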