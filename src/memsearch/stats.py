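"""Inferential statistics for paired model comparisons, plus attention-map
aggregation.

The workhorse is the Wilcoxon signed-rank test on paired values (per-seed
recall probability under two architectures, or per-participant fit RMSE under
two models), reported as the W statistic (sum of ranks of positive
differences), a p-value (exact by enumeration-equivalent distribution for
small n, normal approximation without continuity correction otherwise), and
the matched-pairs rank-biserial correlation as the effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    n: int
    p: float
    method: str
    alternative: str


@dataclass(frozen=True)
class PairedComparison:
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired values must be equal-length 1-D arrays")
        if len(a) < 1:
            raise ValueError("need at least one pair")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


def signed_rank_statistic(diffs: np.ndarray) -> tuple[float, int]:
    """W = sum of ranks of positive differences (zeros already removed)."""
    ranks = sps.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), len(diffs)


def wilcoxon_signed_rank(
    pairs: PairedComparison,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    method: Literal["exact", "normal"] = "exact",
    correction: bool = False,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired values (a - b).

    Zero differences are dropped with a warning and n reduced (Wilcoxon's
    original prescription).  The exact method requires untied absolute
    differences and computes the p-value from the exact null distribution of
    W (identical to enumerating all 2^n sign assignments); the normal method
    uses z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24), by default without
    continuity correction.
    """
    diffs = pairs.differences
    if np.any(diffs == 0):
        warnings.warn(
            f"dropping {int((diffs == 0).sum())} zero differences", stacklevel=2
        )
        diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise ValueError("no nonzero differences; test is uninformative")
    W, _ = signed_rank_statistic(diffs)
    if method == "exact":
        ranks = sps.rankdata(np.abs(diffs))
        if len(np.unique(ranks)) != len(ranks):
            raise ValueError(
                "tied absolute differences: the exact distribution is "
                "unavailable, use method='normal'"
            )
        res = sps.wilcoxon(diffs, alternative=alternative, method="exact")
        p = float(res.pvalue)
    elif method == "normal":
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        d = W - mean
        if correction:
            d -= 0.5 * np.sign(d)
        z = d / sd
        if alternative == "two-sided":
            p = float(2.0 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(W=W, n=n, p=p, method=method, alternative=alternative)


def wilcoxon_p_from_statistic(
    W: float,
    n: int,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    method: Literal["exact", "normal"] = "normal",
    correction: bool = False,
) -> float:
    """p-value from a reported (W, n) pair, without the raw differences.

    Exact: the tie-free null distribution of the signed-rank sum (all 2^n
    equally likely sign assignments over ranks 1..n).  Normal: the same
    z approximation as :func:`wilcoxon_signed_rank`.
    """
    T = n * (n + 1) / 2.0
    if not 0 <= W <= T:
        raise ValueError(f"W={W} outside [0, {T}] for n={n}")
    if method == "exact":
        # counts[w] = number of sign assignments with rank-sum w
        counts = np.zeros(int(T) + 1)
        counts[0] = 1.0
        for r in range(1, n + 1):
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r] if r > 0 else counts
            counts = counts + shifted
        total = counts.sum()
        ge = counts[int(np.ceil(W)):].sum() / total
        le = counts[: int(np.floor(W)) + 1].sum() / total
        if alternative == "greater":
            return float(ge)
        if alternative == "less":
            return float(le)
        return float(min(1.0, 2 * min(ge, le)))
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    d = W - mean
    if correction:
        d -= 0.5 * np.sign(d)
    z = d / sd
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    if alternative == "greater":
        return float(sps.norm.sf(z))
    return float(sps.norm.cdf(z))


def rank_biserial(W: float, n: int) -> float:
    """Matched-pairs rank-biserial correlation from W and n.

    r = (R+ - R-) / T = (2W - T) / T with T = n(n+1)/2; +1 when every
    difference is positive, -1 when every difference is negative.
    """
    T = n * (n + 1) / 2.0
    if not 0 <= W <= T:
        raise ValueError(f"W={W} outside [0, {T}] for n={n}")
    return (2.0 * W - T) / T


@dataclass(frozen=True)
class ComparisonReport:
    W: float
    n: int
    p: float
    rank_biserial: float | None
    method: str
    alternative: str
    informative: bool


def compare_paired_models(
    results_a: Sequence[float],
    results_b: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    exact_max_n: int = 25,
) -> ComparisonReport:
    """Paired comparison of two models over matched units (seeds or
    participants): Wilcoxon signed-rank (exact for n <= ``exact_max_n``
    after zero removal, else normal approximation) plus rank-biserial."""
    pairs = PairedComparison(np.asarray(results_a), np.asarray(results_b))
    diffs = pairs.differences
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return ComparisonReport(
            W=np.nan, n=0, p=np.nan, rank_biserial=None,
            method="none", alternative=alternative, informative=False,
        )
    n = len(nz)
    method = "exact" if n <= exact_max_n else "normal"
    if method == "exact":
        ranks = sps.rankdata(np.abs(nz))
        if len(np.unique(ranks)) != len(ranks):
            method = "normal"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon_signed_rank(pairs, alternative=alternative, method=method)
    return ComparisonReport(
        W=res.W, n=res.n, p=res.p,
        rank_biserial=rank_biserial(res.W, res.n),
        method=method, alternative=alternative, informative=True,
    )


# ---------------------------------------------------------------------------
# Attention heat-maps


@dataclass
class HeatmapStack:
    """Per-trial attention matrices (decode steps x input positions).

    Trials whose recall stopped early carry NaN rows for the missing steps;
    those rows are excluded from the mean rather than imputed.
    """

    matrices: np.ndarray  # (n_trials, steps, positions), NaN-padded

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3:
            raise ValueError("heatmap stack must be (trials, steps, positions)")
        self.matrices = m

    @property
    def n_trials(self) -> int:
        return self.matrices.shape[0]


def attention_heatmap(stack: HeatmapStack) -> np.ndarray:
    """Elementwise mean over trials, ignoring missing (NaN) rows.

    Rows averaged only over simplex rows remain on the simplex.
    """
    if stack.n_trials == 0:
        raise ValueError("empty heatmap stack")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack.matrices, axis=0)
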