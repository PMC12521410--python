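# Methods

`memsearch` implements two models of memory search in immediate free recall —
the Context Maintenance and Retrieval (CMR) model and a GRU encoder–decoder
with dot-product attention — together with the machinery to fit them to
behavioral data, to optimize recall behavior by reinforcement learning, and
to compare architectures statistically.  This note records the models, the
open design choices we resolved, the numerical conventions, and what the
synthetic-data experiments do and do not establish.

## The CMR model

Context is a unit-norm vector `c` in R^N (N = word-pool size).  Studying the
item at step i updates context by

    c_i = rho * c_{i-1} + beta * x_i,

where `x_i` is the item's pre-experimental context (its own one-hot, since
pre-experimental item-to-context associations are the identity), `beta` in
[0, 1] is the drift rate, and `rho` keeps `||c_i|| = 1`.  The literature
usually states only that rho normalizes; we use the closed form

    rho = sqrt(1 + beta^2 ((c.x)^2 - 1)) - beta (c.x)

(the unique nonnegative root; drift inputs are normalized to unit length
before mixing).  Hebbian outer products bind each item to the context that
preceded it: after the list, column f_i of `M_exp_fc` holds `c_{i-1}`, and
`M_exp_cf = M_exp_fc^T`.  Association updates happen **before** the drift at
each step — required for the stored columns to be the pre-item contexts.

At recall, the current context cues studied items through their stored
contexts (`a_i = c_{i-1} . c_j`) and a softmax with inverse temperature `k`
turns activations into recall probabilities over the L studied items only.
Recalling an item drifts context toward a `gamma_fc`-weighted mix of its
pre-experimental context and its reinstated study context.

Choices the equations leave open, resolved here:

* **Initial context.**  `c0` is the one-hot of a reserved "start" slot — the
  lowest pool index not on the current list — so all algebra stays in R^N
  and `c0` is orthogonal to the studied items' pre-experimental contexts.
* **Termination.**  The retrieval equations do not terminate.  Simulation
  stops after `max_attempts` samples (default L) or when the same item is
  sampled twice in a row; sampled repeats are recorded and filtered by the
  metrics layer.  This keeps simulated recall lengths in the empirically
  sensible range without adding a stop-probability parameter.
* **Position-space simulation.**  With identity pre-experimental
  associations and an off-list start slot, the recall dynamics live in the
  (L+1)-dimensional span of {c0, studied one-hots} and depend only on
  serial positions.  `simulate_position_recalls` runs there; the test suite
  asserts its recall distribution is identical to the R^N implementation.
  This makes fitting ~N/L times faster at zero approximation cost.
* **No primacy gradient.**  The model implements exactly the drift /
  Hebbian / softmax equations above; the classic primacy-boost learning-rate
  gradient is deliberately absent.

### Fitting

`fit_cmr` minimizes the sum of min-max-scaled RMSEs between the dataset's
SPC, PFR and lag-CRP curves and Monte-Carlo model curves (200 simulated
lists per candidate, freshly seeded per evaluation) over
(beta_enc, beta_rec, gamma_fc, k), with k searched on [0, 15].  The
optimizer is a small Gaussian-process Bayesian optimizer (Matern-5/2
surrogate from scikit-learn, expected-improvement acquisition over a random
candidate pool, first fifth of the budget random), 300 evaluations by
default.  Min-max scaling constants are taken over the evaluations seen so
far within the run; after the run all candidates are re-scored under the
final constants so the returned optimum is consistent.  Parameter recovery
on mock participants (truth beta_enc = 0.7, 200 lists) lands within the
±0.15 band used by the tests; beta_enc and beta_rec trade off against each
other, which is the dominant source of recovery error.

## The seq2seq model

A GRU encoder consumes the studied list one embedded item at a time and
stores every hidden state (`H`, L×d).  The decoder starts from `h_L`, is
prompted with a start-of-sequence token, and feeds each emitted token back
as its next input.  With attention, each decoding step computes softmax
weights over `H` from dot products with the current decoder state (Luong
scoring, no extra parameters), forms the attention context `alpha_j`, and
mixes `tanh(W_c [h_j; alpha_j])`.  The ablated model uses
`tanh(W_c' h_j)` with a mixing layer of matched per-layer shape.

**Retrieval rule.**  Output scores for studied items are dot products of the
mixed state against the stored encoder states — the direct analogue of
CMR's context-match rule — plus a learned end-of-sequence logit.  Two
modes: `in-list` (softmax over L studied items + EOS; off-list mass exactly
zero) and `full-vocab` (studied items keep their context-match scores;
off-list items are scored by learned output embeddings; EOS competes in the
same softmax).  Full-vocab is needed wherever incorrect recalls must be
expressible: supervised fitting of real recall sequences containing
intrusions, and reinforcement learning where intrusions are penalized.
Scoring studied items *only* through the context match, rather than adding
an identity channel for them, is a deliberate choice: with an additive
identity channel a reinforcement-learned policy can memorize item
identities and recall complete lists in arbitrary order, which flattens the
first-recall and lag profiles; the pure context-match rule makes ordered,
context-chained recall the policy's natural solution, consistent with how
recall probability is tied to the study-context match in the
temporal-context account.

**Ablation.**  Removing attention substitutes `tanh(W_c' h_j)` for the
mixed state.  In in-list mode the ablated model still scores studied items
against encoder states, because that softmax has no other item channel; in
full-vocab mode the ablated model loses the encoder-state route entirely
and recalls only from what its recurrent state carries forward plus the
learned output embeddings.  The second convention is the meaningful
ablation for reinforcement learning: if the ablated model kept dot-product
access to the stored encoder states, it would retain exactly the episodic
reinstatement capacity the ablation is meant to remove (empirically it then
matches the intact model), whereas without it a small-capacity model's
recall collapses — the behavioral pattern associated with losing the
ability to reinstate encoding contexts.

**Equivalence with context reinstatement.**  Probing the attention module
with stored states c_0..c_{L-1} and probe k·c_{j-1} yields exactly the
expectation of CMR's reinstated context under its recall distribution at
inverse temperature k.  `attention_equivalence_check` verifies this to
~1e-16 for random encoded states; it is the package's central structural
claim and is asserted in the acceptance tests at 1e-9.

**Embeddings.**  Random (frozen, default), learned, or pre-trained word
vectors (kept at native dimension behind a learned projection).  Start- and
end-of-sequence tokens always have learned embeddings outside the N item
slots.  Random embeddings default to 50 dimensions; the scaled training
experiments use 16 to match their smaller hidden sizes.

**Numerical core.**  The models run on a small reverse-mode automatic
differentiation engine over float64 numpy arrays (`memsearch.autodiff`),
with GRU cells, Adam, and the clipped-surrogate machinery built on top.
Gradients are verified against central differences in the test suite.
Forward passes are deterministic; all sampling flows through explicit
numpy generators, so every experiment is reproducible from its seed.

## Training

**Supervised individual fitting.**  Per-participant trials are split
90/5/5 at trial granularity (floored validation/test sizes, remainder to
training; empty splits are an error).  The decoder is teacher-forced on the
participant's literal recall sequence terminated by EOS — intrusions and
repeats included, hence full-vocab mode — with cross-entropy loss, Adam
(lr 0.001, betas 0.9/0.999), mini-batches of 32, early stopping after 5
epochs without validation improvement, best-validation weights restored.

**Reinforcement learning.**  Each episode presents a fresh random list
(sampled without replacement from the pool) and rolls out the policy in
sample mode for at most `max_steps` (default 2L) decoding steps.  Rewards:
+1 first correct recall, −1 off-list item, −0.5 repeat of an already
correctly recalled item, 0 for EOS.  PPO with clip 0.2, entropy bonus 0.01,
discount 0.99, batches of 4 episodes.  Details the task description leaves
open, resolved as standard practice: generalized advantage estimation with
lambda = 0.95 (lambda = 1 recovers plain discounted returns; verified
against a backward-recursion oracle), per-batch advantage normalization,
value-loss coefficient 0.5, Adam lr 1e-3, and 4 optimization passes over
each batch of episodes.  Checkpoints (parameters, optimizer moments,
generator state) are written every `checkpoint_interval` iterations — one
"epoch" — and a run can resume from any checkpoint bit-exactly.

**Problem sizes.**  The reference configuration (L = 16, d = 128, 50,000
iterations, 10,000 evaluation lists, 13 seeds per condition) is what
full-scale experiments would use.  The package's own test and acceptance
experiments run a scaled-down condition chosen to expose the same
qualitative phenomena at desk scale (`memsearch.experiments`): N = 50,
L = 8, d = 32, embedding dim 16, `max_steps` 12, 5,000 PPO iterations with
checkpoints every 500 for the optimal-policy and trajectory experiments
(3 seeds, 600 evaluation lists per checkpoint evaluated), and 1,000
iterations per model for the attention-ablation comparison (5 seed pairs,
500 evaluation lists).  One caveat of this scale is documented in the
limitations below: the *direction* of the optimized scan is not reliably
selected.

## Behavioral metrics

* **SPC** — per-position probability of at least one recall (repeats not
  double-counted).
* **PFR** — distribution of the first *correct* recall's study position;
  the denominator is all trials, so the curve sums to the fraction of
  trials with any correct recall (this keeps depressed-recall comparisons
  meaningful).
* **lag-CRP** — made(lag)/possible(lag) over transitions between
  consecutive correct-first recalls; repeats and intrusions are removed
  from the sequence before counting (the standard cleaning convention), and
  already-recalled items are excluded from the possible set.  Lags with
  zero opportunities are reported as missing (NaN), never imputed as 0, and
  are skipped in RMSEs.

A brute-force transition enumerator (tests) cross-checks the lag-CRP on
random synthetic recalls.  Serial positions are 1-based in every reported
curve.

## Statistics

Wilcoxon signed-rank on paired values: W = sum of ranks of positive
differences; zero differences dropped with a warning (n reduced); exact
p from the tie-free null distribution for n ≤ 25 (ties fall back to the
normal route), normal approximation without continuity correction
otherwise (a correction flag exists).  Effect size is the matched-pairs
rank-biserial r = (2W − T)/T.  `wilcoxon_p_from_statistic` recovers p from
a reported (W, n) pair alone.  Attention heat-maps are elementwise means
over per-trial weight matrices with early-stopping steps NaN-padded and
excluded from the mean, so averaged rows remain on the simplex.

## Synthetic data

The generator emulates the shape of immediate free-recall experiments:
pools of N unique tokens with unit-norm random embeddings, lists of L
items drawn without replacement, and mock participants whose recalls are
CMR simulations at known parameters (spread on a documented grid unless
supplied).  It reproduces list structure, contiguity and recency
statistics, repeats, and early termination — but not word frequency,
semantic similarity, inter-response times, or encoding-task effects.
Passing tests on synthetic data therefore establish correctness of the
machinery and internal consistency of the models, not fidelity to any
particular human population.

## Known limitations

* CMR here is the temporal-context core: no semantic pre-experimental
  associations, no inter-list context persistence, no source features, no
  primacy parameter.
* The recall-termination rule for CMR simulation is a package choice; fitted
  parameters are interpretable only relative to it.
* The PPO configuration beyond (clip, entropy, discount, batch size) is
  package-chosen standard practice; absolute reward trajectories depend on
  it.
* At the desk scale used here, several recall orders are exactly
  reward-equivalent once recall is complete, and the optimized policy's
  scan *direction* is decided by early training stochasticity: reward
  growth, near-certain initiation at serial position 1, and the attention
  advantage under ablation reproduce robustly across seeds, but roughly
  half of seeds converge to a backward or mixed scan instead of the
  forward (+1-lag-dominant) chain.  Forward dominance appears strongly in
  the seeds that do select it (CRP(+1) near 1).  Larger vocabularies and
  longer lists — where memorizing identities and bookkeeping arbitrary
  orders is much harder — plausibly act as the selector at full scale.
* beta_enc/beta_rec are only weakly separable from curve data of a single
  participant; recovery experiments bound beta_enc error, not joint
  identifiability.
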