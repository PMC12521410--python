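"""Canonical free-recall behavioral curves and fit objectives.

Three curves summarize a set of trials with a common list length L:

* **SPC** (serial position curve): probability that the item studied at each
  position is recalled at least once.
* **PFR** (probability of first recall): probability that the *first correct*
  recall comes from each position; the denominator is all trials, so the
  curve sums to the fraction of trials with at least one correct recall.
* **lag-CRP** (conditional response probability): for each study-position lag,
  the number of transitions of that lag actually made divided by the number
  of times it could have been made.  Repeats and intrusions are removed from
  the sequence before transitions are counted, and lags to already-recalled
  items are excluded from the possible set (the standard convention).  Lags
  that were never possible are reported as NaN ("missing"), not 0.

Serial positions are 1-based in all reported curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import RecallSequence, Trial

#: recall-event labels
CORRECT = "correct-first"
REPEAT = "repeat"
INTRUSION = "intrusion"


def classify_recalls(trial: Trial) -> list[str]:
    """Label each recall output as correct-first, repeat, or intrusion."""
    on_list = set(trial.study.positions)
    labels: list[str] = []
    recalled: set[int] = set()
    for item in trial.recall.outputs:
        if item not in on_list:
            labels.append(INTRUSION)
        elif item in recalled:
            labels.append(REPEAT)
        else:
            labels.append(CORRECT)
            recalled.add(item)
    return labels


def recall_positions(trial: Trial) -> list[int | None]:
    """Map recall outputs to 0-based study positions; intrusions become None.

    Repeats keep their position (the label distinction is made downstream).
    """
    pos_of = {item: i for i, item in enumerate(trial.study.positions)}
    return [pos_of.get(item) for item in trial.recall.outputs]


@dataclass(frozen=True)
class BehavioralCurves:
    """SPC, PFR and lag-CRP for one set of trials (all length L)."""

    L: int
    spc: np.ndarray  # (L,)
    pfr: np.ndarray  # (L,)
    crp: np.ndarray  # (2L-2,), NaN where the lag was never possible

    @property
    def crp_lags(self) -> np.ndarray:
        """Lags -(L-1)..-1, +1..+(L-1) aligned with ``crp``."""
        L = self.L
        return np.concatenate([np.arange(-(L - 1), 0), np.arange(1, L)])

    def crp_at(self, lag: int) -> float:
        idx = np.where(self.crp_lags == lag)[0]
        if len(idx) == 0:
            raise ValueError(f"lag {lag} out of range for L={self.L}")
        return float(self.crp[idx[0]])

    def to_dict(self) -> dict:
        crp = [None if np.isnan(v) else float(v) for v in self.crp]
        return {
            "L": self.L,
            "spc": [float(v) for v in self.spc],
            "pfr": [float(v) for v in self.pfr],
            "crp_lags": [int(v) for v in self.crp_lags],
            "crp": crp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BehavioralCurves":
        crp = np.array(
            [np.nan if v is None else float(v) for v in d["crp"]]
        )
        return cls(
            L=int(d["L"]),
            spc=np.asarray(d["spc"], dtype=float),
            pfr=np.asarray(d["pfr"], dtype=float),
            crp=crp,
        )


def curves_from_position_recalls(
    position_recalls: Sequence[Sequence[int | None]], L: int
) -> BehavioralCurves:
    """Compute all three curves from 0-based position sequences.

    ``None`` entries are intrusions; repeated positions are repeats.  This is
    the single implementation behind both trial-level and simulation-level
    curve computation.
    """
    n_trials = len(position_recalls)
    if n_trials == 0:
        raise ValueError("no trials")
    spc_counts = np.zeros(L)
    pfr_counts = np.zeros(L)
    n_lags = 2 * L - 1  # index lag+(L-1); center (lag 0) unused
    made = np.zeros(n_lags)
    possible = np.zeros(n_lags)
    for seq in position_recalls:
        # clean sequence: correct-first recalls only, in order
        clean: list[int] = []
        seen: set[int] = set()
        for p in seq:
            if p is None or p in seen or not 0 <= p < L:
                continue
            clean.append(p)
            seen.add(p)
        for p in clean:
            spc_counts[p] += 1
        if clean:
            pfr_counts[clean[0]] += 1
        recalled: set[int] = set()
        for a, b in zip(clean, clean[1:]):
            recalled.add(a)
            for q in range(L):
                if q != a and q not in recalled:
                    possible[q - a + L - 1] += 1
            made[b - a + L - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        crp_full = made / possible
    crp_full[possible == 0] = np.nan
    crp = np.delete(crp_full, L - 1)  # drop lag 0
    return BehavioralCurves(
        L=L,
        spc=spc_counts / n_trials,
        pfr=pfr_counts / n_trials,
        crp=crp,
    )


def _check_fixed_L(trials: Sequence[Trial]) -> int:
    if not trials:
        raise ValueError("no trials")
    L = trials[0].study.L
    for t in trials:
        if t.study.L != L:
            raise ValueError(f"mixed list lengths: {t.study.L} != {L}")
    return L


def behavioral_curves(trials: Sequence[Trial]) -> BehavioralCurves:
    """All three curves for a set of fixed-L trials."""
    L = _check_fixed_L(trials)
    return curves_from_position_recalls([recall_positions(t) for t in trials], L)


def serial_position_curve(trials: Sequence[Trial]) -> np.ndarray:
    return behavioral_curves(trials).spc


def probability_first_recall(trials: Sequence[Trial]) -> np.ndarray:
    return behavioral_curves(trials).pfr


def lag_crp(trials: Sequence[Trial]) -> BehavioralCurves:
    """Lag-CRP (as part of the full curve bundle; see ``BehavioralCurves``)."""
    return behavioral_curves(trials)


def curve_rmses(a: BehavioralCurves, b: BehavioralCurves) -> np.ndarray:
    """RMSE per curve type (spc, pfr, crp), skipping lags missing in either."""
    if a.L != b.L:
        raise ValueError(f"list length mismatch: {a.L} != {b.L}")
    out = []
    for ca, cb in ((a.spc, b.spc), (a.pfr, b.pfr), (a.crp, b.crp)):
        mask = ~(np.isnan(ca) | np.isnan(cb))
        if mask.sum() == 0:
            out.append(np.nan)
        else:
            out.append(float(np.sqrt(np.mean((ca[mask] - cb[mask]) ** 2))))
    return np.array(out)


@dataclass(frozen=True)
class FitError:
    spc_rmse: float
    pfr_rmse: float
    crp_rmse: float
    aggregate: float


def fit_error(
    curves_a: BehavioralCurves,
    curves_b: BehavioralCurves,
    scale_lo: np.ndarray | None = None,
    scale_hi: np.ndarray | None = None,
) -> FitError:
    """Per-curve RMSEs plus an aggregate.

    When min-max scaling constants (per curve type) are supplied — as the CMR
    optimizer does, using the population of evaluations seen so far in its
    run — the aggregate is the sum of scaled RMSEs; otherwise the plain sum.
    """
    rmses = curve_rmses(curves_a, curves_b)
    if scale_lo is not None and scale_hi is not None:
        span = np.where(scale_hi > scale_lo, scale_hi - scale_lo, 1.0)
        agg = float(((rmses - scale_lo) / span).sum())
    else:
        agg = float(np.nansum(rmses))
    return FitError(
        spc_rmse=float(rmses[0]),
        pfr_rmse=float(rmses[1]),
        crp_rmse=float(rmses[2]),
        aggregate=agg,
    )


@dataclass(frozen=True)
class TrajectorySummary:
    init_last3: float
    init_first3: float
    crp_minus1: float


def trajectory_summaries(curves: BehavioralCurves) -> TrajectorySummary:
    """Scalar summaries used to track recall strategy across training:
    PFR mass on the last three / first three positions, and CRP at lag -1."""
    if curves.L < 3:
        raise ValueError("trajectory summaries need L >= 3")
    crp_m1 = curves.crp_at(-1)
    return TrajectorySummary(
        init_last3=float(curves.pfr[-3:].sum()),
        init_first3=float(curves.pfr[:3].sum()),
        crp_minus1=0.0 if np.isnan(crp_m1) else crp_m1,
    )
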