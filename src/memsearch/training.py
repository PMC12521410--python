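"""Supervised individual fitting and PPO optimization of free recall.

Supervised fitting teaches the decoder to reproduce a participant's literal
recall sequences (including repeats and intrusions, hence full-vocabulary
output mode) by teacher-forced cross-entropy, with a 90/5/5 list-level split,
Adam (lr 0.001, betas 0.9/0.999), mini-batches of 32 and early stopping with
patience 5 on validation loss.

Reinforcement learning poses recall as an episodic task: a fresh random list
per episode, +1 for each correct recall, -1 for each incorrect recall, -0.5
for repeating an already-correctly-recalled word, 0 for the end-of-sequence
token.  The policy is optimized with PPO (clip 0.2, entropy bonus 0.01,
discount 0.99, batches of 4 episodes), with periodic checkpoints so recall
strategy can be tracked across training epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import Dataset, RecallSequence, StudyList, Trial
from .metrics import BehavioralCurves, curves_from_position_recalls
from .nn import Adam
from .seq2seq import Seq2SeqConfig, Seq2SeqModel


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class SupervisedConfig:
    train_frac: float = 0.90
    val_frac: float = 0.05
    test_frac: float = 0.05
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    patience: int = 5
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class RLConfig:
    reward_correct: float = 1.0
    reward_incorrect: float = -1.0
    reward_repeat: float = -0.5
    entropy_coef: float = 0.01
    gamma: float = 0.99
    clip_coef: float = 0.2
    gae_lambda: float = 0.95
    learning_rate: float = 1e-3
    ppo_epochs: int = 4  # optimization passes over each batch
    value_coef: float = 0.5
    n_iterations: int = 50_000
    episodes_per_batch: int = 4
    list_length: int = 16
    vocab_size: int = 256
    max_steps: int | None = None  # default 2 * list_length
    checkpoint_interval: int = 5_000
    eval_lists: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_coef <= 0:
            raise ValueError("clip coefficient must be > 0")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("discount must lie in (0, 1]")
        for name in ("n_iterations", "episodes_per_batch", "list_length",
                     "vocab_size", "checkpoint_interval", "eval_lists"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def rollout_steps(self) -> int:
        return self.max_steps if self.max_steps is not None else 2 * self.list_length


@dataclass
class EpochRecord:
    epoch: int
    iteration: int
    mean_reward: float
    actor_loss: float
    critic_loss: float
    state: dict | None = None  # parameter snapshot
    curves: BehavioralCurves | None = None
    heatmap: np.ndarray | None = None


@dataclass
class TrainingTrajectory:
    epochs: list[EpochRecord] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    test_loss: float | None = None


# ---------------------------------------------------------------------------
# Data splitting


def split_trials(
    dataset: Dataset,
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    rng: np.random.Generator | None = None,
) -> tuple[Dataset, Dataset, Dataset]:
    """Random trial-level partition into train/validation/test.

    Validation and test sizes are floored; the remainder goes to training.
    Every split must be nonempty (no list appears in more than one split by
    construction: the partition is over trials).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if rng is None:
        rng = np.random.default_rng()
    n = len(dataset)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"{n} trials cannot fill splits {fractions}; "
            f"need at least {int(np.ceil(1 / min(fractions[1], fractions[2])))}"
        )
    order = rng.permutation(n)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: Dataset(
        trials=tuple(dataset.trials[i] for i in idx), wordpool=dataset.wordpool
    )
    return pick(idx_train), pick(idx_val), pick(idx_test)


# ---------------------------------------------------------------------------
# Supervised fitting


def _teacher_forced_loss(
    model: Seq2SeqModel, trials: Sequence[Trial]
) -> tuple[Tensor, int]:
    """Mean cross-entropy of the participant's recall sequence + EOS."""
    B = len(trials)
    L = trials[0].study.L
    lists = np.stack([np.asarray(t.study.positions) for t in trials])
    T = max(len(t.recall) for t in trials) + 1  # +1 for the EOS step
    targets = np.full((B, T), model.eos, dtype=int)
    mask = np.zeros((B, T))
    for b, t in enumerate(trials):
        seq = list(t.recall.outputs)
        targets[b, : len(seq)] = seq
        mask[b, : len(seq) + 1] = 1.0
    inputs = np.concatenate(
        [np.full((B, 1), model.sos, dtype=int), targets[:, :-1]], axis=1
    )
    outcomes = model.token_to_outcome(targets, lists)
    enc = model.encode_batch(lists)
    h = enc.final
    total = None
    for t in range(T):
        hhat, h, _ = model.decode_step(inputs[:, t], h, enc)
        logits = model.output_logits(hhat, enc, lists)
        logp = ad.log_softmax(logits, axis=1)
        step = ad.gather_rows(logp, outcomes[:, t]) * Tensor(mask[:, t])
        total = step.sum() if total is None else total + step.sum()
    n_steps = int(mask.sum())
    return -total * (1.0 / n_steps), n_steps


def _dataset_loss(model: Seq2SeqModel, trials: Sequence[Trial]) -> float:
    with ad.no_grad():
        loss, _ = _teacher_forced_loss(model, trials)
    return float(loss.data)


def train_supervised(
    model: Seq2SeqModel,
    splits: tuple[Dataset, Dataset, Dataset],
    config: SupervisedConfig,
) -> tuple[Seq2SeqModel, TrainingTrajectory]:
    """Fit the decoder to recall sequences; returns the best-validation model.

    Stops once validation loss has failed to improve for ``patience``
    consecutive epochs; the returned model carries the best-validation
    parameters and the trajectory records train/val losses plus the held-out
    test loss.
    """
    train, val, test = splits
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation splits must be nonempty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(
        model.params.trainable(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
    )
    trajectory = TrainingTrajectory()
    best_val = np.inf
    best_state = model.params.state_dict()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train.trials[i] for i in order[start : start + config.batch_size]]
            loss, _ = _teacher_forced_loss(model, batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        val_loss = _dataset_loss(model, val.trials)
        trajectory.train_losses.append(float(np.mean(epoch_losses)))
        trajectory.val_losses.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.params.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.params.load_state_dict(best_state)
    if len(test):
        trajectory.test_loss = _dataset_loss(model, test.trials)
    return model, trajectory


# ---------------------------------------------------------------------------
# Rewards


def episode_reward(
    study: StudyList, recall: RecallSequence, rl: RLConfig | None = None
) -> tuple[float, list[float]]:
    """Score a recall sequence: +1 first correct, -1 off-list, -0.5 repeat."""
    if rl is None:
        rl = RLConfig()
    on_list = set(study.positions)
    recalled: set[int] = set()
    per_step: list[float] = []
    for item in recall.outputs:
        if item not in on_list:
            per_step.append(rl.reward_incorrect)
        elif item in recalled:
            per_step.append(rl.reward_repeat)
        else:
            per_step.append(rl.reward_correct)
            recalled.add(item)
    return float(sum(per_step)), per_step


def _batch_rewards(
    lists: np.ndarray, tokens: np.ndarray, mask: np.ndarray, rl: RLConfig, eos: int
) -> np.ndarray:
    B, T = tokens.shape
    rewards = np.zeros((B, T))
    for b in range(B):
        on_list = set(int(x) for x in lists[b])
        recalled: set[int] = set()
        for t in range(T):
            if not mask[b, t]:
                break
            tok = int(tokens[b, t])
            if tok == eos:
                r = 0.0
            elif tok not in on_list:
                r = rl.reward_incorrect
            elif tok in recalled:
                r = rl.reward_repeat
            else:
                r = rl.reward_correct
                recalled.add(tok)
            rewards[b, t] = r
    return rewards


def discounted_returns(rewards: np.ndarray, gamma: float, mask: np.ndarray) -> np.ndarray:
    """Backward recursion G_t = r_t + gamma G_{t+1} within each episode."""
    B, T = rewards.shape
    out = np.zeros((B, T))
    running = np.zeros(B)
    for t in range(T - 1, -1, -1):
        running = rewards[:, t] + gamma * running
        running = running * mask[:, t]
        out[:, t] = running
    return out


def gae_advantages(
    rewards: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
    gamma: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation; lambda=1 recovers plain returns -
    values.  Returns (advantages, value targets)."""
    B, T = rewards.shape
    adv = np.zeros((B, T))
    last = np.zeros(B)
    for t in range(T - 1, -1, -1):
        next_value = values[:, t + 1] * mask[:, t + 1] if t + 1 < T else 0.0
        delta = rewards[:, t] + gamma * next_value - values[:, t]
        cont = mask[:, t + 1] if t + 1 < T else 0.0
        last = delta + gamma * lam * cont * last
        adv[:, t] = last * mask[:, t]
    targets = adv + values * mask
    return adv, targets


# ---------------------------------------------------------------------------
# Episodes and PPO


def sample_study_lists(
    rng: np.random.Generator, n_lists: int, vocab_size: int, list_length: int
) -> np.ndarray:
    """(n_lists, L) random lists without within-list replacement."""
    if list_length > vocab_size:
        raise ValueError("list length exceeds vocabulary size")
    keys = rng.random((n_lists, vocab_size))
    return np.argsort(keys, axis=1)[:, :list_length]


def run_episode(
    model: Seq2SeqModel, rl: RLConfig, rng: np.random.Generator
) -> dict:
    """One fresh-list episode: rollout record plus per-step rewards."""
    return run_episode_batch(model, rl, rng, n_episodes=1)


def run_episode_batch(
    model: Seq2SeqModel, rl: RLConfig, rng: np.random.Generator, n_episodes: int
) -> dict:
    lists = sample_study_lists(rng, n_episodes, rl.vocab_size, rl.list_length)
    record = model.rollout_batch(
        lists, rng=rng, mode="sample", max_steps=rl.rollout_steps
    )
    record["rewards"] = _batch_rewards(
        lists, record["tokens"], record["mask"], rl, model.eos
    )
    record["episode_rewards"] = record["rewards"].sum(axis=1)
    return record


def ppo_update(
    model: Seq2SeqModel,
    record: dict,
    rl: RLConfig,
    optimizer: Adam,
) -> dict:
    """One clipped-surrogate PPO update on a batch of episode records."""
    lists = record["lists"]
    tokens = record["tokens"]
    mask = record["mask"].astype(float)
    if mask.sum() == 0:
        raise ValueError("empty batch")
    old_logp = record["logp"]
    advantages, value_targets = gae_advantages(
        record["rewards"], record["values"], mask, rl.gamma, rl.gae_lambda
    )
    flat_mask = mask.astype(bool)
    adv_valid = advantages[flat_mask]
    adv_std = adv_valid.std()
    norm_adv = (advantages - adv_valid.mean()) / (adv_std + 1e-8)

    B, T = tokens.shape
    inputs = np.concatenate(
        [np.full((B, 1), model.sos, dtype=int), tokens[:, :-1]], axis=1
    )
    outcomes = model.token_to_outcome(tokens, lists)
    enc = model.encode_batch(lists)
    h = enc.final
    n_valid = mask.sum()
    actor_terms, critic_terms, entropy_terms = [], [], []
    for t in range(T):
        m = Tensor(mask[:, t])
        hhat, h, _ = model.decode_step(inputs[:, t], h, enc)
        logits = model.output_logits(hhat, enc, lists)
        logp = ad.log_softmax(logits, axis=1)
        step_logp = ad.gather_rows(logp, outcomes[:, t])
        ratio = ad.exp(step_logp - Tensor(old_logp[:, t]))
        adv_t = Tensor(norm_adv[:, t])
        unclipped = ratio * adv_t
        clipped = ad.clip(ratio, 1.0 - rl.clip_coef, 1.0 + rl.clip_coef) * adv_t
        actor_terms.append((ad.minimum(unclipped, clipped) * m).sum())
        probs = ad.exp(logp)
        entropy_terms.append(((probs * logp).sum(axis=1) * (-1.0) * m).sum())
        v = model.value(hhat)
        err = v - Tensor(value_targets[:, t])
        critic_terms.append((err * err * m).sum())
    actor = -sum(actor_terms[1:], actor_terms[0]) * (1.0 / n_valid)
    entropy = sum(entropy_terms[1:], entropy_terms[0]) * (1.0 / n_valid)
    critic = sum(critic_terms[1:], critic_terms[0]) * (1.0 / n_valid)
    loss = actor - rl.entropy_coef * entropy + rl.value_coef * critic
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite PPO loss")
    optimizer.zero_grad()
    loss.backward()
    for p in model.params.trainable():
        if p.grad is not None and not np.all(np.isfinite(p.grad)):
            raise FloatingPointError("non-finite PPO gradient")
    optimizer.step()
    return {
        "actor_loss": float(actor.data),
        "critic_loss": float(critic.data),
        "entropy": float(entropy.data),
    }


# ---------------------------------------------------------------------------
# The RL training loop


def _positions_from_tokens(
    lists: np.ndarray, tokens: np.ndarray, mask: np.ndarray, eos: int
) -> list[list[int | None]]:
    out: list[list[int | None]] = []
    for b in range(lists.shape[0]):
        pos_of = {int(item): i for i, item in enumerate(lists[b])}
        seq: list[int | None] = []
        for t in range(tokens.shape[1]):
            if not mask[b, t]:
                break
            tok = int(tokens[b, t])
            if tok == eos:
                break
            seq.append(pos_of.get(tok))
        out.append(seq)
    return out


def evaluate_policy(
    model: Seq2SeqModel,
    rl: RLConfig,
    n_lists: int | None = None,
    rng: np.random.Generator | None = None,
    batch_size: int = 256,
    record_attention: bool = False,
) -> dict:
    """Roll out the policy on fresh lists; behavioral curves + mean reward."""
    if n_lists is None:
        n_lists = rl.eval_lists
    if rng is None:
        rng = np.random.default_rng(rl.seed)
    position_recalls: list[list[int | None]] = []
    rewards: list[float] = []
    heatmaps: list[np.ndarray] = []
    done = 0
    while done < n_lists:
        n = min(batch_size, n_lists - done)
        lists = sample_study_lists(rng, n, rl.vocab_size, rl.list_length)
        rec = model.rollout_batch(
            lists,
            rng=rng,
            mode="sample",
            max_steps=rl.rollout_steps,
            record_attention=record_attention,
        )
        rew = _batch_rewards(lists, rec["tokens"], rec["mask"], rl, model.eos)
        rewards.extend(rew.sum(axis=1).tolist())
        position_recalls.extend(
            _positions_from_tokens(lists, rec["tokens"], rec["mask"], model.eos)
        )
        if record_attention and model.config.attention:
            attn = rec["attention"]  # (n, T, L)
            alive = rec["mask"]
            padded = np.full(
                (n, rl.rollout_steps, rl.list_length), np.nan
            )
            padded[:, : attn.shape[1]][alive] = attn[alive]
            heatmaps.append(padded)
        done += n
    curves = curves_from_position_recalls(position_recalls, rl.list_length)
    result = {
        "curves": curves,
        "position_recalls": position_recalls,
        "mean_reward": float(np.mean(rewards)),
        "n_lists": n_lists,
    }
    if heatmaps:
        result["heatmap_stack"] = np.concatenate(heatmaps, axis=0)
    return result


def _save_rl_state(
    path: Path,
    model: Seq2SeqModel,
    optimizer: Adam,
    rng: np.random.Generator,
    iteration: int,
    reward_log: list[float],
) -> None:
    path.mkdir(parents=True, exist_ok=True)
    model.save_checkpoint(path, provenance={"iteration": iteration})
    opt = optimizer.state_dict()
    np.savez(
        path / "optimizer.npz",
        t=np.array(opt["t"]),
        **{f"m{i}": m for i, m in enumerate(opt["m"])},
        **{f"v{i}": v for i, v in enumerate(opt["v"])},
    )
    meta = {
        "iteration": iteration,
        "rng_state": rng.bit_generator.state,
        "reward_log": reward_log,
    }
    (path / "train_state.json").write_text(json.dumps(meta))


def train_rl(
    rl: RLConfig,
    model_config: Seq2SeqConfig | None = None,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    eval_lists_per_epoch: int = 0,
    keep_states: bool = True,
) -> tuple[Seq2SeqModel, TrainingTrajectory]:
    """Run the PPO loop; checkpoint every ``checkpoint_interval`` iterations.

    Each checkpoint boundary defines one training epoch: the trajectory
    records the mean episode reward and losses over the epoch, a parameter
    snapshot (when ``keep_states``), and behavioral curves on
    ``eval_lists_per_epoch`` fresh lists when that is > 0.  With
    ``checkpoint_dir`` set, a resumable state is also written to disk;
    ``resume_from`` continues a run bit-exactly (parameters, optimizer
    moments and generator state are all restored).
    """
    if model_config is None:
        model_config = Seq2SeqConfig(
            vocab_size=rl.vocab_size, output_mode="full-vocab", seed=rl.seed
        )
    if model_config.output_mode != "full-vocab":
        raise ValueError(
            "reinforcement learning requires full-vocab output mode "
            "(incorrect recalls must be expressible)"
        )
    model = Seq2SeqModel(model_config)
    optimizer = Adam(model.params.trainable(), lr=rl.learning_rate)
    rng = np.random.default_rng(rl.seed)
    start_iter = 0
    reward_log: list[float] = []
    trajectory = TrainingTrajectory()
    if resume_from is not None:
        resume_from = Path(resume_from)
        model = Seq2SeqModel.load_checkpoint(resume_from)
        optimizer = Adam(model.params.trainable(), lr=rl.learning_rate)
        with np.load(resume_from / "optimizer.npz") as arc:
            n = len(optimizer.m)
            optimizer.load_state_dict(
                {
                    "t": int(arc["t"]),
                    "m": [arc[f"m{i}"] for i in range(n)],
                    "v": [arc[f"v{i}"] for i in range(n)],
                }
            )
        meta = json.loads((resume_from / "train_state.json").read_text())
        start_iter = int(meta["iteration"])
        reward_log = list(meta["reward_log"])
        rng.bit_generator.state = meta["rng_state"]

    epoch_rewards: list[float] = []
    epoch_actor: list[float] = []
    epoch_critic: list[float] = []

    def close_epoch(iteration: int) -> None:
        epoch_idx = int(np.ceil(iteration / rl.checkpoint_interval))
        rec = EpochRecord(
            epoch=epoch_idx,
            iteration=iteration,
            mean_reward=float(np.mean(epoch_rewards)) if epoch_rewards else np.nan,
            actor_loss=float(np.mean(epoch_actor)) if epoch_actor else np.nan,
            critic_loss=float(np.mean(epoch_critic)) if epoch_critic else np.nan,
            state=model.params.state_dict() if keep_states else None,
        )
        if eval_lists_per_epoch > 0:
            eval_rng = np.random.default_rng(
                int(rng.integers(0, 2**31 - 1))
            )
            ev = evaluate_policy(
                model, rl, n_lists=eval_lists_per_epoch, rng=eval_rng
            )
            rec.curves = ev["curves"]
        trajectory.epochs.append(rec)
        epoch_rewards.clear()
        epoch_actor.clear()
        epoch_critic.clear()
        if checkpoint_dir is not None:
            _save_rl_state(
                Path(checkpoint_dir) / f"iter{iteration:07d}",
                model, optimizer, rng, iteration, reward_log,
            )

    if start_iter == 0:
        close_epoch(0)  # epoch-0 snapshot: the policy before any update

    for iteration in range(start_iter, rl.n_iterations):
        record = run_episode_batch(model, rl, rng, rl.episodes_per_batch)
        for _ in range(rl.ppo_epochs):
            losses = ppo_update(model, record, rl, optimizer)
        mean_rew = float(record["episode_rewards"].mean())
        reward_log.append(mean_rew)
        epoch_rewards.append(mean_rew)
        epoch_actor.append(losses["actor_loss"])
        epoch_critic.append(losses["critic_loss"])
        if (iteration + 1) % rl.checkpoint_interval == 0:
            close_epoch(iteration + 1)
    if rl.n_iterations % rl.checkpoint_interval != 0:
        close_epoch(rl.n_iterations)
    trajectory.train_losses = reward_log
    return model, trajectory
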