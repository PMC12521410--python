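"""Self-contained synthetic data generators.

Everything the pipelines consume — word pools with embeddings, study lists,
and mock participants whose recalls are simulated from known CMR parameters —
can be generated here, so no external download is ever needed.  Defaults
emulate the shape of immediate free-recall experiments: lists of L = 16 words
drawn without replacement from a pool of N words, recall sequences that may
contain repeats and intrusions.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmr import CMRParams, simulate_recall
from .data import Dataset, StudyList, Trial, Wordpool


def make_wordpool(
    N: int, d_emb: int = 50, rng: np.random.Generator | None = None
) -> Wordpool:
    """N synthetic tokens ("w0001"...) with unit-norm random embeddings."""
    if N < 2:
        raise ValueError("pool needs at least 2 items")
    if rng is None:
        rng = np.random.default_rng()
    width = max(4, len(str(N)))
    tokens = tuple(f"w{i + 1:0{width}d}" for i in range(N))
    emb = rng.normal(size=(N, d_emb))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return Wordpool(items=tokens, embeddings=emb)


def make_study_lists(
    pool: Wordpool, L: int, n_lists: int, rng: np.random.Generator
) -> list[StudyList]:
    """Random lists of length L sampled without replacement from the pool."""
    if L > pool.N:
        raise ValueError(f"list length {L} exceeds pool size {pool.N}")
    lists = []
    for _ in range(n_lists):
        idx = rng.permutation(pool.N)[:L]
        lists.append(StudyList(tuple(int(i) for i in idx)))
    return lists


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a mock multi-participant free-recall experiment."""

    N: int = 64
    L: int = 16
    d_emb: int = 50
    n_lists: int = 96  # per participant (PEERS: 6 sessions x 16 lists)
    n_participants: int = 4
    cmr_params: tuple[CMRParams, ...] = ()  # one per participant; grid default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L > self.N:
            raise ValueError("L must not exceed N")
        for name in ("N", "L", "d_emb", "n_lists", "n_participants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cmr_params and len(self.cmr_params) != self.n_participants:
            raise ValueError("need one CMRParams per participant")

    def participant_params(self) -> tuple[CMRParams, ...]:
        """Ground-truth parameters: the supplied set, or a documented grid
        spreading drift rate and reinstatement weight across participants."""
        if self.cmr_params:
            return self.cmr_params
        grid = []
        for i in range(self.n_participants):
            frac = i / max(1, self.n_participants - 1)
            grid.append(
                CMRParams(
                    beta_enc=0.4 + 0.5 * frac,
                    beta_rec=0.5,
                    gamma_fc=0.3 + 0.4 * frac,
                    k=6.0,
                )
            )
        return tuple(grid)


def simulate_mock_participants(
    spec: SyntheticSpec,
) -> tuple[Dataset, list[dict]]:
    """CMR-simulated recalls for each mock participant.

    Returns the combined dataset plus a ground-truth table (one row per
    participant) for parameter-recovery scoring.
    """
    rng = np.random.default_rng(spec.seed)
    pool = make_wordpool(spec.N, spec.d_emb, rng)
    params_by_p = spec.participant_params()
    trials: list[Trial] = []
    truth: list[dict] = []
    for p, params in enumerate(params_by_p):
        pid = f"mock{p:03d}"
        studies = make_study_lists(pool, spec.L, spec.n_lists, rng)
        for s, study in enumerate(studies):
            trials.append(
                simulate_recall(
                    params, study, rng, spec.N,
                    participant_id=pid, session_id=f"s{s:03d}",
                )
            )
        row = {"participant_id": pid}
        row.update(params.to_dict())
        truth.append(row)
    return Dataset(trials=tuple(trials), wordpool=pool), truth
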