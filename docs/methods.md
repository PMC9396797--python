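# Methods

## Problem and representation

An RNA secondary structure over a sequence x₁…x_L is a partner assignment:
position i pairs with at most one j, equivalently a binary symmetric L x L
adjacency ("pair") matrix Y with zero diagonal and row sums ≤ 1.
Pseudoknots — pairs (i,j), (k,l) with i<k<j<l — are first-class: nothing in
the package assumes nestedness.  Internally positions are 0-based; bpseq/ct
files (1-based) are converted at the parse/write boundary.  Dot-bracket
serialization assigns crossing pairs to extra bracket layers by greedy
coloring of the pair-crossing graph.

Bases are encoded A→1, U→2, G→3, C→4 with 0 as padding, to a fixed
encoding length; the data pipeline buckets sequences into lengths ≤128 and
129–512 and rejects longer ones.  T normalizes to U and lowercase to
uppercase; any other letter (including N) is rejected rather than silently
encoded, because the code table defines exactly four bases plus padding.
Datasets are shuffled by seed and split 80/10/10
(train = floor(0.8 n), remainder split evenly test/validate, odd record to
test; 37 records → 29/4/4).

## Hard pairing rules and the mask M

Four rules: canonical pairs only (A·U, G·C, wobble G·U); no self-pairing;
|i−j| ≥ 4 (fewer than four positions apart is forbidden, i.e. at least
three unpaired bases in a hairpin loop); at most one partner per base.
The first three depend only on sequence and are precomputed as a binary
mask M (symmetric, zero diagonal, zero band |i−j|<4, zero on padding).
Rule 4 is enforced by the projection layer and re-checked by
`validate_structure`, which reports each violation with rule number and
coordinates.  Reference structures from databases may contain
non-canonical pairs; the loaders preserve them in labels, and the mask
then simply forbids predicting them.

## Scorer architecture

`embed` (5 symbols → 10 channels, learned) → `global_semantic_extract`
(one bidirectional LSTM layer, both directions concatenated to d_model =
2·lstm_hidden, then n_encoder_layers pre-norm Transformer encoder blocks
with n_heads heads and feed-forward width 4·d_model) →
`pairwise_concat` (entry (i,j) is [h_i ; h_j], giving an L x L x 2·d_model
grid) → `generate_scores` (U-Net-style encoder/decoder: stem conv, depth-d
down path of avg-pool + 3x3 conv, mirrored up path of nearest-neighbour
upsample + conv with additive skip connections, 1x1 head to a single
logit channel).

No positional encoding is added to the Transformer: the recurrent stage
already orders its inputs, so each encoder input carries position
information implicitly.  Defaults: 6 encoder layers, 2 heads,
embed_dim 10.  The LSTM width, U-Net depth, and channel schedule are not
architecturally forced and are config keys; d_model = 64 is the full-run
default and 16–32 is used in tests.  Layer normalization inside the
encoder; initialization is Glorot-uniform from a single run seed, so
identical config + seed gives bit-identical models.  The encoding length
must be divisible by 2^depth; any such length is accepted by the model
(the data pipeline's buckets remain 128/512, while tests and the
acceptance study use length 32 to keep CPU runs small).

The package ships its own reverse-mode autograd (`rnapairnet.autograd`):
a dynamic tape over NumPy arrays with hand-written backward passes for
convolution (im2col), pooling, upsampling and softmax, verified against
finite differences in the test suite.  Adam is implemented with the
standard bias-corrected moments.

## Losses

Reference pairs occupy ~0.25% of matrix entries, so all losses are
imbalance-aware.  With ⟨·,·⟩ the matrix inner product and x the model's
soft decisions:

* soft precision p = ⟨x,y⟩ / (⟨x,y⟩ + ⟨x,1−y⟩ + ε) and soft recall
  r = ⟨x,y⟩ / (⟨x,y⟩ + ⟨1−x,y⟩ + ε); on binary x these equal the
  count-based metrics exactly (up to ε = 1e−8, added to every denominator;
  the 0/0 convention is 0).
* weighted logistic: mean of pw·y·(−log σ(S)) + (1−y)·(−log(1−σ(S))) on
  logits, pw = 256 by default.  The mean (not sum) reduction keeps pw's
  meaning independent of matrix size.
* negative soft F1: −2pr/(p+r+ε) ∈ [−1, 0].
* PR-AUC surrogate: thresholds sweep [0,1] in `auc_steps` (default 100)
  increments; at each threshold t the hard decision is replaced by
  relu(x−t) inside the soft TP/FP/FN masses, and the negated trapezoid sum
  −½ Σ (r_{k+1}−r_k)(p_k+p_{k+1}) is taken over the operating points in
  ascending-recall order, landing in [−1, 0].  The placement of the relu
  surrogate (inside the mass terms) is this package's reading; only the
  replacement of the discrete decision by relu is externally prescribed.

Losses are computed over the full padded matrix by default (matching the
padded-adjacency evaluation; a true-length mask is available in
evaluation for alternative reporting).

## Constraint projection layer

Objective: max_A ⟨σ(S)−b, A⟩ + ⟨y, A⟩ − η‖A‖₁ subject to A·1 ≤ 1, with
A masked by M throughout.  b (default 0.5) lives on the [0,1] scale
because scores are squashed exactly once at the layer boundary; y is the
label during fine-tuning and zero at inference — the only reading under
which the same update rules serve both phases.  With multiplier λ ≥ 0 the
unrolled iteration, per round t = 1…s:

1. gradient  G = σ(S) − b + y − (λ ∘ 𝟙[A·1 − 1 > 0])·1ᵀ  (the indicator is
   the subgradient of relu, 0 at the kink, and is treated as constant
   under differentiation);
2. primal step  A ← A + ρ_α^t · A ∘ M ∘ (G + Gᵀ), then clamped to [0,1]
   via relu(A) − relu(A−1);
3. hard-threshold denoise  A ← relu(|A| − η·ρ_α^t);
4. dual step  λ ← λ + ρ_β^t · relu(A·1 − 1)  (elementwise nondecreasing).

After s rounds: A ← ½(A∘M + (A∘M)ᵀ), then greedy discretization —
candidates above τ in descending score order, ties to the smallest (i,j),
each base keeping at most one partner — which enforces rule 4 exactly, so
every hard output satisfies all four rules by construction.

Numerical choices, each load-bearing:

* **Clamp to [0,1].**  The raw multiplicative ascent diverges for generic
  inputs: once a row overshoots the constraint the multiplier grows with
  the iterate, the penalty flips the gradient sign and |A| squares each
  round.  The clamp (differentiable, subgradient 0 outside the interval)
  confines the iterate to the range shared by the squashed scores and the
  binary target.
* **Feasible initialization.**  A₀ = σ(S)∘M with rows scaled down to sum
  ≤ 1.  Early-training scorers flood positives; starting infeasible makes
  λ overshoot in the first round and wipe out whole rows (zero is an
  absorbing state of a multiplicative update) before any within-row
  selection can happen.  The per-row scale is piecewise constant under
  differentiation.
* **Step indexing.**  The decaying rates ρ^t count cycles from t = 1.
* **Order of operations** within a round is primal step → denoise → dual
  step; the alternative orderings are not externally fixed.
* λ and the row-sum indicator are detached in the backward pass (their
  a.e. derivative); relu kinks use the standard subgradient.

Defaults b = 0.5, η = 0.01, ρ_α = ρ_β = 0.95, s = 20, τ = 0.5 are config
keys recorded in run manifests.  The layer is a fixed-depth unrolled
computation; no convergence claim is made or needed.

## Two-stage training

Pre-training fits the scorer alone (no projection layer) with the
weighted logistic loss and Adam.  Fine-tuning appends the projection
layer, switches to the negative soft-F1 loss on the layer's soft output
against the label, and either trains everything (`full`) or freezes all
parameters below the top stage (`freeze_below_top`: the generator's up
path and 1x1 head stay trainable; the projection layer has no
parameters).  The freeze strategy is a user flag — intended for target
families with little data or high similarity to the pre-training corpus —
not auto-detected.  The learning rate is multiplied by 0.5 whenever
consecutive epoch losses differ by less than 0.0004 (the externally
prescribed threshold; the factor, initial lr 1e−3, batch size 8 and epoch
counts are package defaults).  When a validation set is supplied the
best-validation-F1 parameters are restored at the end (validation F1
routinely peaks after 1–2 fine-tuning epochs and then degrades, because
the label term inside the projection lets the training loss improve
without the scores improving).  Adam hyperparameters are the standard
β = (0.9, 0.999), ε = 1e−8.  Every run emits a manifest (config, seed,
per-epoch losses, validation F1) so CPU runs reproduce exactly.

## Evaluation

Pair-level confusion counts are elementwise over the full padded L x L
matrices — consistent with corpus-level published count tables whose
totals (~69.45M elements) only arise under padded-matrix counting — with
P, R, F1 as usual and 0/0 → 0.  Aggregation is micro (pool counts, then
metrics; the default) or macro (average per-record metrics).  Reports
round to 4 decimal places for display.

## Synthetic data generator

Fixtures are built by stem sampling: helical stems (geometric length,
p = 0.5, minimum 2) are placed on unpaired stretches subject to the hard
rules; random filling rejects placements that would cross existing pairs,
so crossings occur exactly when a crossing stem pair is planted (with
probability `pseudoknot_prob`, default 0.3).  Pairing density (target
fraction of paired positions, default 0.4) is approached by repeated
placement with an attempt cap.  Sequences then assign a canonical pair
type to every paired position — A·U/G·C at 23% each orientation, G·U at
4%, wobble deliberately rarer as in natural helices — and uniform bases
elsewhere, so the rule mask always admits the full label (M ≥ Y), the
learnability precondition for every training experiment.

What the fixtures do not model: thermodynamics, co-variation, family
structure beyond the sampler's statistics, non-canonical pairs, or
modified bases.  Passing tests therefore demonstrate that the machinery —
encoders, losses, projection, transfer protocol — behaves as specified,
not that the trained toy models reach published accuracy on real corpora.

## Scaled-down study sizes

The acceptance studies use: 100 structures of length 20–120 (30%
pseudoknotted) for projection recovery; 1,000 random score matrices over
random sequences of length 10–60 for rule satisfaction; and, for the
transfer-learning direction check, a 200-record broad corpus and a
200-record target family of lengths 20–30 at encoding length 32, with a
narrow model (d_model 16, 2 encoder layers, U-Net depth 2, ~22k
parameters), 20 pre-training epochs and 5 fine-tuning epochs.  These
sizes are the package's desk-scale choices; published absolute accuracies
(trained on tens of thousands of sequences) are out of scope, and only
the direction of the transfer-learning effects is asserted: fine-tuning
with the projection layer beats the pretrained scorer alone, and the
pretrained start reaches the pretrained-baseline F1 in fewer epochs than
training from scratch (which does not reach it within the epoch budget).

## Known limitations

* The projection layer's within-row selection relies on relative score
  magnitudes under a shared row penalty; with many equal mid-range scores
  the greedy discretization, not the iteration, does most of the work.
* Upstream redundancy removal (e.g. 80% homology filtering) is assumed
  done by the data provider; the loaders take input as given.
* Training at encoding length 512 is supported by the code paths but is
  computationally heavy on CPU; the NumPy engine favors clarity and
  testability over speed.
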