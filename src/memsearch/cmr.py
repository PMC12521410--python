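"""The Context Maintenance and Retrieval (CMR) model of free recall.

CMR maintains a unit-norm context vector ``c`` in R^N that drifts toward the
(pre-experimental) context of each studied item.  Hebbian outer products bind
each item ``f_i`` to the context ``c_{i-1}`` that prevailed just before it was
studied, in a pair of association matrices ``M_exp_fc`` (item -> context) and
``M_exp_cf = M_exp_fc.T`` (context -> item).  At recall, the current context
cues items by its similarity to their study contexts; recalling an item
reinstates a mix of its pre-experimental context and its stored study context
("jump back in time"), and a softmax with inverse-temperature ``k`` turns the
similarities into recall probabilities over the studied items.

Parameters
----------
beta_enc : drift rate at encoding, in [0, 1].
beta_rec : drift rate at recall, in [0, 1].
gamma_fc : weight of the reinstated experimental context vs. the item's
    pre-experimental context at recall, in [0, 1].
k : retrieval inverse temperature (>= 0); larger k means less noisy recall.
max_attempts : bound on retrieval attempts when simulating recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .data import Dataset, RecallSequence, StudyList, Trial, Wordpool


@dataclass(frozen=True)
class CMRParams:
    beta_enc: float = 0.7
    beta_rec: float = 0.5
    gamma_fc: float = 0.5
    k: float = 5.0
    max_attempts: int | None = None  # None -> list length L

    def __post_init__(self) -> None:
        for name in ("beta_enc", "beta_rec", "gamma_fc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.k) or self.k < 0:
            raise ValueError(f"k must be finite and >= 0, got {self.k}")

    def to_dict(self) -> dict:
        return {
            "beta_enc": self.beta_enc,
            "beta_rec": self.beta_rec,
            "gamma_fc": self.gamma_fc,
            "k": self.k,
            "max_attempts": self.max_attempts,
        }


@dataclass
class CMRState:
    """Model state after (partial) encoding of one list.

    ``encoded`` records, per study step, the item index and the pre-item
    context ``c_{i-1}`` that was bound to it.
    """

    c: np.ndarray
    M_exp_fc: np.ndarray
    study: StudyList | None = None
    encoded: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def N(self) -> int:
        return self.c.shape[0]

    @property
    def M_exp_cf(self) -> np.ndarray:
        # context-to-item associations are the transpose by construction
        return self.M_exp_fc.T

    @property
    def M_pre_fc(self) -> np.ndarray:
        return np.eye(self.N)

    def pre_item_contexts(self) -> np.ndarray:
        """(L, N) matrix whose row i is the context c_{i-1} bound to item i."""
        return np.stack([c for _, c in self.encoded])


def _rho(beta: float, dot: float) -> float:
    """Nonnegative scalar keeping ``rho*c + beta*x`` at unit norm for unit c, x."""
    return float(np.sqrt(1.0 + beta * beta * (dot * dot - 1.0)) - beta * dot)


def drift_context(c_prev: np.ndarray, x: np.ndarray, beta: float) -> np.ndarray:
    """Drift context toward input ``x``: c = rho*c_prev + beta*x_hat.

    ``x`` is normalized to unit length before mixing; rho is the unique
    nonnegative root that keeps the result at unit Euclidean norm.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    nx = float(np.linalg.norm(x))
    if nx == 0.0:
        raise ValueError("drift input x must be nonzero")
    x_hat = x / nx
    dot = float(np.dot(c_prev, x_hat))
    c = _rho(beta, dot) * c_prev + beta * x_hat
    return c


def start_context(N: int, study: StudyList) -> np.ndarray:
    """Default initial context c0: the pre-experimental context of a reserved
    start slot — the lowest pool index not on the study list — so that the
    algebra stays N-dimensional and c0 is linearly independent of the studied
    items' pre-experimental contexts."""
    on_list = set(study.positions)
    for i in range(N):
        if i not in on_list:
            c0 = np.zeros(N)
            c0[i] = 1.0
            return c0
    raise ValueError("study list exhausts the pool; no start slot available")


def encode_list(
    params: CMRParams,
    study: StudyList,
    N: int,
    c0: np.ndarray | None = None,
) -> CMRState:
    """Encode a study list: bind each item to the pre-item context, then drift.

    For each position i (1..L): the association matrices receive the outer
    product of ``c_{i-1}`` and the one-hot ``f_i`` *before* context drifts
    toward the item's pre-experimental context (its own one-hot, since the
    pre-experimental item-to-context map is the identity).
    """
    if c0 is None:
        c0 = start_context(N, study)
    c = np.asarray(c0, dtype=float)
    if abs(np.linalg.norm(c) - 1.0) > 1e-9:
        raise ValueError("initial context must be unit norm")
    M = np.zeros((N, N))
    state = CMRState(c=c, M_exp_fc=M, study=study)
    for item in study.positions:
        c_prev = state.c
        M[:, item] += c_prev  # Hebbian outer product c_{i-1} f_i^T
        state.encoded.append((item, c_prev.copy()))
        x = np.zeros(N)
        x[item] = 1.0  # pre-experimental context of the item
        state.c = drift_context(c_prev, x, params.beta_enc)
    return state


def reinstate_context(state: CMRState, prev_item: int) -> np.ndarray:
    """Retrieve the stored study context of ``prev_item``: M_exp_fc @ f.

    Equals the pre-item context c_{i-1} bit-exactly when the item was studied
    at position i.  Probing with an unstudied item is an error (its column is
    all zeros and would silently poison the recall dynamics).
    """
    if state.study is None or prev_item not in state.study.positions:
        raise ValueError(f"item {prev_item} was not encoded in the current list")
    return state.M_exp_fc[:, prev_item].copy()


def update_recall_context(
    state: CMRState, prev_item: int, params: CMRParams
) -> CMRState:
    """Drift the recall context toward the mix of the just-recalled item's
    pre-experimental context and its reinstated study context."""
    alpha = reinstate_context(state, prev_item)
    x = np.zeros(state.N)
    x[prev_item] = 1.0
    drive = (1.0 - params.gamma_fc) * x + params.gamma_fc * alpha
    new_c = drift_context(state.c, drive, params.beta_rec)
    return replace(state, c=new_c)


def recall_similarities(state: CMRState) -> np.ndarray:
    """Activation strengths a(i) = c_{i-1} . c_j for each studied position."""
    if not state.encoded:
        raise ValueError("no items encoded")
    return state.pre_item_contexts() @ state.c


def recall_probabilities(state: CMRState, params: CMRParams) -> np.ndarray:
    """Softmax (temperature k) of context-match over the L studied positions.

    Returned on the *pool*: an N-vector that is exactly 0 off-list and sums
    to 1 over the studied items.
    """
    sims = recall_similarities(state)
    z = params.k * sims
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    probs = np.zeros(state.N)
    for (item, _), p in zip(state.encoded, w):
        probs[item] = p
    return probs


def expected_reinstatement(
    state: CMRState, c_prev: np.ndarray, params: CMRParams
) -> np.ndarray:
    """Expectation of the reinstated context over the recall distribution
    defined by probe context ``c_prev``: sum_i softmax_i(k c_{i-1}.c_prev) c_{i-1}.

    This is the quantity the attention mechanism of the seq2seq model
    computes when its encoder states are the stored contexts.
    """
    C = state.pre_item_contexts()  # (L, N)
    z = params.k * (C @ c_prev)
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    return w @ C


def simulate_position_recalls(
    params: CMRParams, L: int, rng: np.random.Generator
) -> list[int]:
    """Sample a recall sequence as 0-based serial positions.

    With identity pre-experimental associations and an off-list start
    context, the recall dynamics live in the (L+1)-dimensional span of the
    start context and the studied items' one-hots, and depend only on serial
    positions — so simulation runs there, independent of pool size.

    Termination rule (the model family leaves this open): stop after
    ``max_attempts`` samples (default L) or when the same position is sampled
    twice in a row.  Sampled repeats are recorded; the metrics layer filters
    them when computing curves.
    """
    dim = L + 1  # coordinate 0 = start slot, 1..L = items by position
    c = np.zeros(dim)
    c[0] = 1.0
    C = np.empty((L, dim))  # pre-item contexts c_{i-1}
    for i in range(L):
        C[i] = c
        x = np.zeros(dim)
        x[i + 1] = 1.0
        c = drift_context(c, x, params.beta_enc)
    max_attempts = params.max_attempts if params.max_attempts is not None else L
    outputs: list[int] = []
    prev: int | None = None
    for _ in range(max_attempts):
        z = params.k * (C @ c)
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        pos = int(rng.choice(L, p=w))
        if pos == prev:
            break
        outputs.append(pos)
        drive = params.gamma_fc * C[pos]
        drive = drive.copy()
        drive[pos + 1] += 1.0 - params.gamma_fc
        c = drift_context(c, drive, params.beta_rec)
        prev = pos
    return outputs


def simulate_recall(
    params: CMRParams,
    study: StudyList,
    rng: np.random.Generator,
    N: int,
    participant_id: str = "cmr",
    session_id: str = "s0",
) -> Trial:
    """Encode a list and sample recalls until termination (seeded).

    Delegates to the position-space simulator, which is exactly equivalent to
    running :func:`encode_list` / :func:`update_recall_context` /
    :func:`recall_probabilities` in R^N (asserted in the test suite).
    """
    positions = simulate_position_recalls(params, study.L, rng)
    outputs = tuple(study.positions[p] for p in positions)
    return Trial(
        study=study,
        recall=RecallSequence(outputs),
        participant_id=participant_id,
        session_id=session_id,
    )


def simulate_dataset(
    params: CMRParams,
    studies: list[StudyList],
    wordpool: Wordpool,
    rng: np.random.Generator,
    participant_id: str = "cmr",
) -> Dataset:
    """Simulate one recall per study list under a single parameter set."""
    trials = tuple(
        simulate_recall(params, s, rng, wordpool.N, participant_id, f"s{i}")
        for i, s in enumerate(studies)
    )
    return Dataset(trials=trials, wordpool=wordpool)


# ---------------------------------------------------------------------------
# Fitting to behavioral curves


@dataclass
class CMRFit:
    params: CMRParams
    objective: float
    trace: list[float]
    n_sim_lists: int
    evaluations: list[tuple[dict, float]]


def fit_cmr(
    dataset: Dataset,
    budget: int = 300,
    rng: np.random.Generator | None = None,
    n_sim_lists: int = 200,
    k_max: float = 15.0,
    fit_beta_rec: bool = True,
) -> CMRFit:
    """Fit CMR parameters to a dataset's behavioral curves.

    Global derivative-free search (Gaussian-process Bayesian optimization)
    over (beta_enc, beta_rec, gamma_fc, k), minimizing the min-max-scaled sum
    of RMSEs between the dataset's SPC/PFR/lag-CRP curves and Monte-Carlo
    curves from ``n_sim_lists`` simulated lists per candidate.  Min-max
    scaling constants are taken over the evaluations seen so far within the
    run, so each curve type contributes comparably to the objective.
    """
    from .bo import bayes_minimize
    from .metrics import behavioral_curves, curve_rmses, curves_from_position_recalls

    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    if rng is None:
        rng = np.random.default_rng()
    target = behavioral_curves(dataset.trials)
    L = dataset.L

    def params_from(theta: np.ndarray) -> CMRParams:
        return CMRParams(
            beta_enc=float(theta[0]),
            beta_rec=float(theta[1]) if fit_beta_rec else float(theta[0]),
            gamma_fc=float(theta[2]),
            k=float(theta[3]) * k_max,
        )

    raw_history: list[np.ndarray] = []

    def objective(theta: np.ndarray) -> float:
        params = params_from(theta)
        sim_rng = np.random.default_rng(
            int(rng.integers(0, 2**31 - 1))
        )  # fresh seeded stream per evaluation
        recalls = [
            simulate_position_recalls(params, L, sim_rng)
            for _ in range(n_sim_lists)
        ]
        model_curves = curves_from_position_recalls(recalls, L)
        rmses = np.nan_to_num(curve_rmses(target, model_curves), nan=1.0)
        raw_history.append(rmses)
        # min-max scaling over the evaluations seen so far in this run, so
        # each curve type contributes comparably
        hist = np.stack(raw_history)
        lo, hi = hist.min(axis=0), hist.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return float(((rmses - lo) / span).sum())

    result = bayes_minimize(
        objective,
        bounds=[(0.0, 1.0)] * 4,
        budget=budget,
        rng=rng,
    )
    # re-score every candidate with the final scaling constants so the best
    # choice is consistent across the whole run
    hist = np.stack(raw_history)
    lo, hi = hist.min(axis=0), hist.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = ((hist - lo) / span).sum(axis=1)
    best_i = int(np.argmin(scaled))
    best_params = params_from(result.xs[best_i])
    evals = [
        ({"theta": [float(v) for v in x]}, float(y))
        for x, y in zip(result.xs, scaled)
    ]
    return CMRFit(
        params=best_params,
        objective=float(scaled[best_i]),
        trace=[float(y) for y in scaled],
        n_sim_lists=n_sim_lists,
        evaluations=evals,
    )
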