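"""Optimize free recall with PPO and watch the optimal strategy emerge.

The policy earns +1 per correct recall, -1 per intrusion, -0.5 per repeat,
and terminates itself with an end-of-sequence token.  As training
progresses the model shifts from recency (starting recall at the end of the
list) toward the optimal-policy signature: initiate at serial position 1 and
chain forward (+1 lag dominance).  (Runtime: several minutes on one CPU;
shrink n_iterations for a faster look.)
"""

import numpy as np

from memsearch import RLConfig, Seq2SeqConfig, evaluate_policy, trajectory_summaries
from memsearch.training import train_rl

rl = RLConfig(
    n_iterations=3000, list_length=8, vocab_size=50, max_steps=12,
    checkpoint_interval=500, seed=0,
)
config = Seq2SeqConfig(hidden_dim=32, vocab_size=50, embed_dim=16,
                       output_mode="full-vocab", seed=0)
model, trajectory = train_rl(rl, config, eval_lists_per_epoch=300,
                             keep_states=False)

print("epoch  iter   reward  init_first3  init_last3  crp(-1)")
for e in trajectory.epochs:
    if e.curves is None:
        continue
    s = trajectory_summaries(e.curves)
    rew = 0.0 if np.isnan(e.mean_reward) else e.mean_reward
    print(f"{e.epoch:5d} {e.iteration:6d} {rew:7.2f} {s.init_first3:12.2f} "
          f"{s.init_last3:11.2f} {s.crp_minus1:8.2f}")

final = evaluate_policy(model, rl, n_lists=2000, rng=np.random.default_rng(9))
c = final["curves"]
print(f"\nfinal mean episode reward: {final['mean_reward']:.2f} (ceiling {rl.list_length})")
print(f"PFR argmax position: {int(np.argmax(c.pfr)) + 1} (optimal: 1)")
print(f"CRP argmax lag: {c.crp_lags[int(np.nanargmax(c.crp))]:+d} (optimal: +1)")
print("Rising reward with PFR mass moving to position 1 and a growing +1-lag")
print("peak reproduces the optimal free-recall strategy.")
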