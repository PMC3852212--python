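"""Graph-based semi-supervised learning and multi-graph Laplacian fusion.

The classifier scores all patients at once by minimizing

    (f - y)' (f - y) + mu f' L f

over real-valued f, where y holds the known labels (+1 / -1) and zeros for
unlabeled patients, L is a graph Laplacian and mu trades label fit against
smoothness over the graph. The unique minimizer is the regularized-Laplacian
solve f = (I + mu L)^{-1} y.

Several graphs are fused by optimizing nonnegative combination coefficients
alpha over the constraint sum(alpha) <= budget for the convex objective
y' (I + sum_k alpha_k L_k)^{-1} y, solved by projected gradient descent;
prediction then uses f = (I + sum_k alpha_k L_k)^{-1} y.

The smoothness trade-off and the coefficient budget are distinct knobs
(``mu_smooth`` and ``mu_budget`` elsewhere) even though both play the role
of a total amount of regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .datasets import LabelVector
from .errors import (
    ConfigurationError,
    ConvergenceError,
    InvalidLaplacianError,
)
from .intra_graph import GraphLaplacian

__all__ = [
    "SSLSolution",
    "GraphCombination",
    "ssl_solve",
    "predict_labels",
    "combine_graphs",
    "ssl_solve_combined",
]


@dataclass(frozen=True)
class SSLSolution:
    """Real-valued scores f for every patient, plus the trade-off used."""

    scores: np.ndarray
    patient_ids: tuple[str, ...]
    mu: float


@dataclass(frozen=True)
class GraphCombination:
    """Optimized combination coefficients over K graph Laplacians."""

    alphas: np.ndarray
    budget: float
    laplacians: tuple[GraphLaplacian, ...]

    def __post_init__(self) -> None:
        alphas = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", alphas)
        if np.any(alphas < -1e-12):
            raise ConfigurationError("combination coefficients must be nonnegative")
        if alphas.sum() > self.budget * (1 + 1e-9) + 1e-12:
            raise ConfigurationError("combination coefficients exceed the budget")

    def summed_laplacian(self) -> GraphLaplacian:
        total = sum(a * lap.matrix for a, lap in zip(self.alphas, self.laplacians))
        return GraphLaplacian(total, self.laplacians[0].patient_ids)


def _spd_solve(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(a, lower=True), y)
    except LinAlgError as exc:
        raise InvalidLaplacianError(
            "I + mu L is not positive definite; the Laplacian is invalid"
        ) from exc


def ssl_solve(lap: GraphLaplacian, labels: LabelVector, mu: float = 1.0) -> SSLSolution:
    """Closed-form solve f = (I + mu L)^{-1} y via Cholesky (never an inverse)."""
    if mu <= 0:
        raise ConfigurationError(f"mu={mu} must be positive")
    if lap.patient_ids != labels.patient_ids:
        raise ConfigurationError("Laplacian and labels refer to different patients")
    if not labels.labeled_mask.any():
        raise ConfigurationError("no labeled patients to train on")
    y = labels.values.astype(float)
    n = lap.n_patients
    f = _spd_solve(np.eye(n) + mu * lap.matrix, y)
    return SSLSolution(f, lap.patient_ids, mu)


def predict_labels(solution: SSLSolution, threshold: float = 0.0) -> np.ndarray:
    """Threshold scores into hard +1/-1 labels; f == threshold maps to +1."""
    return np.where(solution.scores >= threshold, 1, -1)


def _project_capped_simplex(v: np.ndarray, budget: float) -> np.ndarray:
    """Euclidean projection onto {alpha >= 0, sum(alpha) <= budget}."""
    p = np.clip(v, 0.0, None)
    if p.sum() <= budget:
        return p
    # project onto the simplex {alpha >= 0, sum = budget}
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - budget
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def _objective_and_grad(
    alphas: np.ndarray, mats: list[np.ndarray], y: np.ndarray
) -> tuple[float, np.ndarray]:
    n = y.shape[0]
    a = np.eye(n)
    for ak, lk in zip(alphas, mats):
        a = a + ak * lk
    f = _spd_solve(a, y)
    obj = float(y @ f)
    grad = np.array([-(f @ (lk @ f)) for lk in mats])
    return obj, grad


def combine_graphs(
    laplacians: list[GraphLaplacian],
    labels: LabelVector,
    budget: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> GraphCombination:
    """Fit combination coefficients by projected gradient on the convex objective.

    Minimizes y' (I + sum_k alpha_k L_k)^{-1} y over alpha >= 0 with
    sum(alpha) <= budget. Fixed initial step with backtracking line search;
    stops when the objective decrease falls below ``tol``. When several
    optima exist (e.g. identical graphs) the returned alpha is whichever the
    projection path reaches — only the objective value is unique.
    """
    if not laplacians:
        raise ConfigurationError("need at least one Laplacian")
    if budget <= 0:
        raise ConfigurationError(f"budget={budget} must be positive")
    ids = laplacians[0].patient_ids
    if any(lap.patient_ids != ids for lap in laplacians):
        raise ConfigurationError("Laplacians refer to different patient sets")
    if labels.patient_ids != ids:
        raise ConfigurationError("labels refer to different patients")

    mats = [lap.matrix for lap in laplacians]
    y = labels.values.astype(float)
    k = len(mats)
    alphas = np.full(k, min(budget / k, budget / k))
    obj, grad = _objective_and_grad(alphas, mats, y)

    step = 1.0
    for _ in range(max_iter):
        # backtracking: shrink until the projected step decreases the objective
        improved = False
        trial_step = step
        for _ in range(50):
            candidate = _project_capped_simplex(alphas - trial_step * grad, budget)
            new_obj, new_grad = _objective_and_grad(candidate, mats, y)
            if new_obj <= obj - 1e-16:
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            # stationary within line-search resolution
            return GraphCombination(alphas, budget, tuple(laplacians))
        decrease = obj - new_obj
        alphas, obj, grad = candidate, new_obj, new_grad
        step = min(trial_step * 2.0, 1e6)
        if decrease < tol:
            return GraphCombination(alphas, budget, tuple(laplacians))

    # did not settle: report how far from stationarity we ended
    projected = _project_capped_simplex(alphas - grad, budget)
    raise ConvergenceError(
        f"projected gradient did not converge in {max_iter} iterations; "
        f"final projected-gradient norm {np.linalg.norm(alphas - projected):.3e}"
    )


def ssl_solve_combined(combination: GraphCombination, labels: LabelVector) -> SSLSolution:
    """Solve f = (I + sum_k alpha_k L_k)^{-1} y on the fused Laplacian."""
    lap = combination.summed_laplacian()
    if lap.patient_ids != labels.patient_ids:
        raise ConfigurationError("combination and labels refer to different patients")
    y = labels.values.astype(float)
    f = _spd_solve(np.eye(lap.n_patients) + lap.matrix, y)
    return SSLSolution(f, lap.patient_ids, float(np.sum(combination.alphas)))
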