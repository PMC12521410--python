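"""Derivative-free global minimization by Gaussian-process Bayesian optimization.

A deliberately small sequential optimizer for noisy, expensive objectives on a
box: a Matern-5/2 GP surrogate (scikit-learn) is refit on all evaluations, and
the next candidate maximizes expected improvement over a random pool.  The
first fifth of the budget (at least 10 points) is pure random exploration.
All randomness flows from the supplied generator, so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass
class BOResult:
    best_x: np.ndarray
    best_y: float
    xs: list[np.ndarray]
    ys: list[float]


def bayes_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    budget: int = 300,
    rng: np.random.Generator | None = None,
    n_initial: int | None = None,
    candidate_pool: int = 512,
) -> BOResult:
    """Minimize ``objective`` over a box with ``budget`` total evaluations."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    d = len(bounds)
    if n_initial is None:
        n_initial = min(budget, max(10, budget // 5))

    def sample(n: int) -> np.ndarray:
        return lo + (hi - lo) * rng.random((n, d))

    xs: list[np.ndarray] = []
    ys: list[float] = []

    for x in sample(n_initial):
        xs.append(x)
        ys.append(float(objective(x)))

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-2, (1e-6, 1e1))

    while len(xs) < budget:
        X = np.stack(xs)
        y = np.array(ys)
        y_mu, y_sd = y.mean(), y.std() or 1.0
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=False,
            alpha=1e-8,
            n_restarts_optimizer=0,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit((X - lo) / (hi - lo), (y - y_mu) / y_sd)
        cand = sample(candidate_pool)
        mu, sd = gp.predict((cand - lo) / (hi - lo), return_std=True)
        best = (y.min() - y_mu) / y_sd
        sd = np.maximum(sd, 1e-12)
        imp = best - mu
        z = imp / sd
        ei = imp * norm.cdf(z) + sd * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        xs.append(x_next)
        ys.append(float(objective(x_next)))

    best_i = int(np.argmin(ys))
    return BOResult(best_x=xs[best_i], best_y=ys[best_i], xs=xs, ys=ys)
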