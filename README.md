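# memsearch

Models of human memory search in immediate free recall, for computational
cognitive scientists: the **Context Maintenance and Retrieval (CMR)** model
and a **GRU sequence-to-sequence model with dot-product attention**, built on
a shared behavioral-analysis core (serial position curve, probability of
first recall, lag conditional response probability), with supervised
individual fitting, reinforcement-learning optimization of recall behavior,
attention-ablation experiments, and the paired nonparametric statistics used
to compare models.

## The models

**CMR.** A unit-norm context vector `c ∈ R^N` drifts toward each studied
item: `c_i = ρ c_{i−1} + β x_i`, with `ρ` the normalizing root and `x_i` the
item's pre-experimental context.  Hebbian outer products store each item's
pre-item context in association matrices `M_exp^FC` / `M_exp^CF`.  At
recall, item support is the context match `a_j(i) = c_{i−1}·c_j`, converted
to recall probabilities by a softmax with inverse temperature `k` over the
studied items; recalling an item drifts context toward a `γ_FC`-weighted mix
of its pre-experimental context and its reinstated study context
(`α_j = M_exp^FC f_{j−1}` — the "jump back in time").

**Seq2seq with attention.** A GRU encoder stores hidden states
`H = [h_1..h_L]`; the decoder starts from `h_L` and feeds each output back.
Attention weights `w_j^i = softmax_i(h_j·h_i)` give the attention context
`α_j = Σ_i w_j^i h_i`, mixed as `ĥ_j = tanh(W_c [h_j; α_j])`; outputs are
scored by the match `ĥ_j·h_i` against stored encoder states plus a learned
end-of-sequence logit.  The package's central structural result, checked
numerically: with stored contexts as encoder states, attention computes
exactly the expected CMR context reinstatement
`E[α_j] = Σ_i softmax_i(k c_{i−1}·c_{j−1}) c_{i−1}`.

Everything runs on numpy (a small built-in reverse-mode autodiff drives the
networks), is deterministic under explicit seeds, and needs no downloads —
synthetic generators produce word pools, study lists, and CMR-simulated
mock participants.

## Worked example

```python
import numpy as np
from memsearch import CMRParams, behavioral_curves, simulate_dataset
from memsearch.synth import make_wordpool, make_study_lists

rng = np.random.default_rng(0)
pool = make_wordpool(64, d_emb=8, rng=rng)
params = CMRParams(beta_enc=0.75, beta_rec=0.6, gamma_fc=0.6, k=6.0)
studies = make_study_lists(pool, L=16, n_lists=500, rng=rng)
curves = behavioral_curves(simulate_dataset(params, studies, pool, rng).trials)
print(f"CRP(+1) = {curves.crp_at(1):.3f}  CRP(-1) = {curves.crp_at(-1):.3f}  "
      f"CRP(+3) = {curves.crp_at(3):.3f}")
```

prints

```
CRP(+1) = 0.546  CRP(-1) = 0.214  CRP(+3) = 0.070
```

— the temporal-contiguity signature: transitions to the immediately
following study position dominate (0.546), backward transitions are weaker
(0.214), and distant lags fall off sharply (0.070), because recalling an
item reinstates the drifting context under which it was studied.

The `examples/` directory holds one short script per capability: CMR
simulation and curve measurement, parameter recovery by Bayesian
optimization, the attention ≡ context-reinstatement identity, supervised
fitting of recall sequences, PPO optimization of recall with trajectory
tracking, the attention ablation, and paired Wilcoxon model comparisons.
A thin `memsearch` CLI covers file validation, synthesis, CMR simulation
and fitting, curve computation, and Wilcoxon comparisons.

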