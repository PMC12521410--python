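"""Canned experiment protocols at desk scale.

These functions bundle the configurations used by the package's own
reproduction experiments (see docs/methods.md for the problem sizes and why
they were chosen): the scaled optimal-recall PPO runs with epoch-0/1/final
evaluations, the attention-ablation comparison, CMR parameter recovery on a
mock participant, and the supervised single-trial overfit check.  Both the
test suite and scripts/acceptance.py drive these entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmr import CMRFit, CMRParams, fit_cmr
from .data import Dataset, RecallSequence, StudyList, Trial
from .metrics import BehavioralCurves, trajectory_summaries
from .seq2seq import Seq2SeqConfig, Seq2SeqModel, build_model
from .synth import SyntheticSpec, make_wordpool, simulate_mock_participants
from .training import (
    RLConfig,
    SupervisedConfig,
    evaluate_policy,
    split_trials,
    train_rl,
    train_supervised,
)

#: scaled-down RL condition (see docs/methods.md)
RL_LIST_LENGTH = 8
RL_VOCAB = 50
RL_HIDDEN = 32
RL_EMBED = 16
RL_MAX_STEPS = 12
RL_ITERATIONS = 5000
ABLATION_ITERATIONS = 1000


def rl_config(seed: int, n_iterations: int = RL_ITERATIONS,
              interval: int = 500) -> RLConfig:
    return RLConfig(
        n_iterations=n_iterations, list_length=RL_LIST_LENGTH,
        vocab_size=RL_VOCAB, checkpoint_interval=interval, seed=seed,
        max_steps=RL_MAX_STEPS,
    )


def model_config(seed: int, attention: bool = True) -> Seq2SeqConfig:
    return Seq2SeqConfig(
        hidden_dim=RL_HIDDEN, vocab_size=RL_VOCAB, embed_dim=RL_EMBED,
        attention=attention, output_mode="full-vocab", seed=seed,
    )


def evaluate_state(state: dict, cfg: Seq2SeqConfig, rl: RLConfig,
                   n_lists: int, seed: int) -> dict:
    model = Seq2SeqModel(cfg)
    model.params.load_state_dict(state)
    return evaluate_policy(
        model, rl, n_lists=n_lists, rng=np.random.default_rng(seed)
    )


def optimal_policy_experiment(
    seeds: tuple[int, ...],
    n_iterations: int = RL_ITERATIONS,
    eval_lists: int = 600,
) -> list[dict]:
    """PPO runs at the scaled condition; per-seed epoch-0/1/final evals.

    Returns one record per seed with the per-epoch reward trace and
    behavioral evaluations of the untrained (epoch-0), first-epoch, and
    final checkpoints.
    """
    runs = []
    for seed in seeds:
        rl = rl_config(seed, n_iterations=n_iterations)
        cfg = model_config(seed)
        model, traj = train_rl(rl, cfg, keep_states=True)
        rewards = [e.mean_reward for e in traj.epochs
                   if not np.isnan(e.mean_reward)]
        evals = {}
        for tag, idx in (("epoch0", 0), ("epoch1", 1), ("final", -1)):
            evals[tag] = evaluate_state(
                traj.epochs[idx].state, cfg, rl, eval_lists, seed + idx % 97
            )
        runs.append({"seed": seed, "rewards": rewards, "evals": evals})
    return runs


def seed_averaged_curves(runs: list[dict], tag: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pfr, crp, crp_lags) pooled over the seeds' evaluation trials.

    Pooling the trials before computing curves weights every transition
    opportunity equally (elementwise curve averaging would let a lag that is
    defined in only one seed's few trials dominate the average).
    """
    from .metrics import curves_from_position_recalls

    pooled: list = []
    for r in runs:
        pooled.extend(r["evals"][tag]["position_recalls"])
    curves = curves_from_position_recalls(
        pooled, runs[0]["evals"][tag]["curves"].L
    )
    return curves.pfr, curves.crp, curves.crp_lags


def ablation_experiment(
    seeds: tuple[int, ...],
    n_iterations: int = ABLATION_ITERATIONS,
    eval_lists: int = 500,
) -> list[dict]:
    """Matched attention / no-attention PPO runs per seed."""
    pairs = []
    for seed in seeds:
        pair = {}
        for attention in (True, False):
            rl = rl_config(seed, n_iterations=n_iterations,
                           interval=max(1, n_iterations // 2))
            cfg = model_config(seed, attention=attention)
            model, traj = train_rl(rl, cfg, keep_states=True)
            final = evaluate_policy(
                model, rl, n_lists=eval_lists,
                rng=np.random.default_rng(seed + 7),
            )
            pair[attention] = {"traj": traj, "final": final, "rl": rl,
                               "cfg": cfg}
        pairs.append(pair)
    return pairs


def cmr_recovery_experiment(
    seed: int,
    beta_enc: float = 0.7,
    gamma_fc: float = 0.5,
    n_lists: int = 200,
    budget: int = 300,
) -> tuple[CMRFit, CMRParams]:
    """Simulate one mock participant at known parameters and fit CMR back."""
    truth = CMRParams(beta_enc=beta_enc, beta_rec=0.5, gamma_fc=gamma_fc, k=6.0)
    spec = SyntheticSpec(
        N=32, L=16, n_lists=n_lists, n_participants=1,
        cmr_params=(truth,), seed=seed,
    )
    dataset, _ = simulate_mock_participants(spec)
    fit = fit_cmr(dataset, budget=budget,
                  rng=np.random.default_rng(seed + 1))
    return fit, truth


def supervised_overfit_experiment(seed: int) -> dict:
    """Overfit one repeated trial; report whether greedy output matches."""
    study = StudyList((3, 1, 4, 0))
    target = (1, 4, 3)
    trial = Trial(study=study, recall=RecallSequence(target))
    dataset = Dataset(
        trials=tuple(trial for _ in range(20)),
        wordpool=make_wordpool(8, 4, np.random.default_rng(seed)),
    )
    splits = split_trials(dataset, fractions=(0.8, 0.1, 0.1),
                          rng=np.random.default_rng(seed))
    cfg = Seq2SeqConfig(hidden_dim=24, vocab_size=8, embed_dim=8,
                        output_mode="full-vocab", seed=seed)
    model = build_model(cfg)
    model, traj = train_supervised(
        model, splits,
        SupervisedConfig(max_epochs=400, patience=400, seed=seed),
    )
    out = model.generate_recall(study, mode="greedy", max_steps=8)
    return {
        "matches": out.recall.outputs == target and out.terminated,
        "final_loss": traj.train_losses[-1],
        "target": target,
        "output": out.recall.outputs,
    }
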