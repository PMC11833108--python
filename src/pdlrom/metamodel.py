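"""Optimal-interpolation surrogate over parameter -> response samples.

Gauss-Markov (objective-analysis) estimation: given N known instances
of the mapping from a p-dimensional parameter vector to an m-vector
response (force at m fixed sample times), the response at a query point
q is estimated as

    y_hat(q) = c(q)^T (C + eps I)^(-1) Y,

with the Gaussian correlation c_ij = exp(-sum_d ((x_i,d - x_j,d)/l_d)^2)
over parameters normalised to the unit box.  With eps = 0 the estimate
interpolates the samples exactly; eps > 0 turns it into a smoother for
noisy responses.  New samples extend the linear system directly — there
is no training phase to repeat.

:func:`refine_loop` uses the surrogate to steer an expensive simulator:
fit the surrogate, locate its best parameters against objective
records, evaluate the true simulator there, append, repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize

__all__ = ["SampleSet", "interpolate", "cross_validate", "refine_loop",
           "RefineResult"]

#: default per-dimension correlation length in normalised units
DEFAULT_CORRELATION_LENGTH = 0.5

#: default observation-error variance
DEFAULT_NOISE_VAR = 1e-6


@dataclass(frozen=True)
class SampleSet:
    """Known parameter -> response instances on the unit box.

    ``points`` is (N, p) with every coordinate in [0, 1]; ``responses``
    is (N, m).  ``lengths`` holds the per-dimension Gaussian correlation
    lengths; ``noise_var`` the observation-error variance added to the
    correlation diagonal.
    """

    points: np.ndarray
    responses: np.ndarray
    lengths: np.ndarray | float = DEFAULT_CORRELATION_LENGTH
    noise_var: float = 0.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        rsp = np.atleast_2d(np.asarray(self.responses, dtype=float))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "responses", rsp)
        if pts.shape[0] < 1 or pts.shape[0] != rsp.shape[0]:
            raise ValueError("need N >= 1 matching points and responses")
        if np.any(pts < -1e-12) or np.any(pts > 1 + 1e-12):
            raise ValueError("points must lie in the unit box")
        if not np.all(np.isfinite(rsp)):
            raise ValueError("responses must be finite")
        lengths = np.broadcast_to(np.asarray(self.lengths, dtype=float),
                                  (pts.shape[1],)).copy()
        if np.any(lengths <= 0):
            raise ValueError("correlation lengths must be positive")
        object.__setattr__(self, "lengths", lengths)
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    def append(self, point: np.ndarray, response: np.ndarray) -> "SampleSet":
        """New sample set with one more (point, response) instance."""
        return replace(
            self,
            points=np.vstack([self.points, np.atleast_2d(point)]),
            responses=np.vstack([self.responses, np.atleast_2d(response)]),
        )


def _correlation(samples: SampleSet, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = (a[:, None, :] - b[None, :, :]) / samples.lengths
    return np.exp(-np.sum(diff**2, axis=-1))


def _background(samples: SampleSet) -> np.ndarray:
    """Background field: the per-component sample mean (zero for N = 1).

    Estimation operates on anomalies about this background, as usual in
    objective analysis; a single sample keeps the zero background so the
    estimate decays with correlation away from it.
    """
    if samples.n_samples > 1:
        return samples.responses.mean(axis=0)
    return np.zeros(samples.responses.shape[1])


def _solve_weights(samples: SampleSet) -> np.ndarray:
    """(C + eps I)^(-1) (Y - background), regularising if singular."""
    corr = _correlation(samples, samples.points, samples.points)
    corr[np.diag_indices_from(corr)] += samples.noise_var
    anomalies = samples.responses - _background(samples)
    try:
        factor = cho_factor(corr)
        return cho_solve(factor, anomalies)
    except LinAlgError:
        warnings.warn("singular correlation system (duplicate points with "
                      "eps = 0?); falling back to ridge regularisation",
                      stacklevel=2)
        corr[np.diag_indices_from(corr)] += 1e-10
        return np.linalg.solve(corr, anomalies)


def interpolate(samples: SampleSet, query) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the response at ``query`` (and its error variance).

    Returns ``(y_hat, var)``: the m-vector Gauss-Markov estimate and the
    pointwise error variance per response component (the kernel variance
    1 - c^T (C + eps I)^(-1) c scaled by each component's sample
    variance).  With ``noise_var = 0`` the estimate reproduces sample
    responses at sample points.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != samples.points.shape[1]:
        raise ValueError("query dimension mismatch")
    if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
        raise ValueError("query must lie in the unit box")
    weights = _solve_weights(samples)
    c = _correlation(samples, q, samples.points)          # (nq, N)
    y_hat = _background(samples) + c @ weights            # (nq, m)
    corr = _correlation(samples, samples.points, samples.points)
    corr[np.diag_indices_from(corr)] += samples.noise_var + 1e-12
    kernel_var = np.clip(1.0 - np.einsum(
        "qn,qn->q", c, np.linalg.solve(corr, c.T).T), 0.0, None)
    comp_var = samples.responses.var(axis=0) if samples.n_samples > 1 else \
        np.zeros(samples.responses.shape[1])
    var = kernel_var[:, None] * comp_var[None, :]
    if np.asarray(query).ndim == 1:
        return y_hat[0], var[0]
    return y_hat, var


def cross_validate(samples: SampleSet) -> dict[str, np.ndarray | float]:
    """Leave-one-out error summary of the surrogate.

    Returns per-response-component RMSE (``rmse``, length m) and the
    overall RMSE (``rmse_total``); useful for tuning correlation
    lengths.  Duplicated points with conflicting responses and eps = 0
    are flagged via ``inconsistent``.
    """
    if samples.n_samples < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    errors = np.zeros_like(samples.responses)
    for i in range(samples.n_samples):
        keep = np.arange(samples.n_samples) != i
        sub = replace(samples, points=samples.points[keep],
                      responses=samples.responses[keep])
        y_hat, _ = interpolate(sub, samples.points[i])
        errors[i] = samples.responses[i] - y_hat
    inconsistent = False
    if samples.noise_var == 0:
        _, idx, counts = np.unique(samples.points, axis=0,
                                   return_index=True, return_counts=True)
        for j, count in zip(idx, counts):
            if count > 1:
                same = np.all(np.isclose(samples.points,
                                         samples.points[j]), axis=1)
                if not np.allclose(samples.responses[same],
                                   samples.responses[j]):
                    inconsistent = True
    rmse = np.sqrt(np.mean(errors**2, axis=0))
    return {"rmse": rmse, "rmse_total": float(np.sqrt(np.mean(errors**2))),
            "inconsistent": inconsistent}


@dataclass
class RefineResult:
    """Outcome of a surrogate-guided refinement loop."""

    best_point: np.ndarray
    best_r2: float
    n_evaluations: int
    samples: SampleSet
    history: list[float] = field(default_factory=list)


def _pooled_r2_vec(pred: np.ndarray, objective: np.ndarray) -> float:
    ss_tot = float(np.sum((objective - objective.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum((objective - pred) ** 2)) / ss_tot


def refine_loop(simulator: Callable[[np.ndarray], np.ndarray],
                samples: SampleSet, objective: np.ndarray,
                budget: int, grid_points: int = 33,
                seed: int = 0) -> RefineResult:
    """Iteratively refine parameters against an expensive simulator.

    Each iteration fits the surrogate to all samples so far, locates the
    surrogate-optimal point (best pooled R² of the surrogate response
    against the flattened ``objective`` vector) by a dense deterministic
    grid over the unit box plus a local Nelder-Mead polish, evaluates
    the true ``simulator`` there, and appends the result.  Returns the
    best *truly evaluated* point after ``budget`` simulator calls.

    A simulator failure aborts the loop and returns the best so far.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    objective = np.asarray(objective, dtype=float).ravel()
    p = samples.points.shape[1]
    rng = np.random.default_rng(seed)

    def true_r2_of(response: np.ndarray) -> float:
        return _pooled_r2_vec(np.asarray(response).ravel(), objective)

    best_idx = int(np.argmax([true_r2_of(r) for r in samples.responses]))
    best_point = samples.points[best_idx].copy()
    best_r2 = true_r2_of(samples.responses[best_idx])
    history = []
    n_eval = 0
    for _ in range(budget):
        candidate = _surrogate_optimum(samples, objective, p, grid_points, rng)
        try:
            response = np.asarray(simulator(candidate), dtype=float).ravel()
        except Exception:
            break
        n_eval += 1
        r2 = true_r2_of(response)
        history.append(r2)
        samples = samples.append(candidate, response)
        if r2 > best_r2:
            best_r2, best_point = r2, candidate.copy()
    return RefineResult(best_point=best_point, best_r2=best_r2,
                        n_evaluations=n_eval, samples=samples,
                        history=history)


def _surrogate_optimum(samples: SampleSet, objective: np.ndarray, p: int,
                       grid_points: int, rng: np.random.Generator) -> np.ndarray:
    """Best surrogate point: dense grid (p <= 2) or LHS-style scatter,
    then a bounded local polish."""
    if p <= 2:
        axes = [np.linspace(0, 1, grid_points)] * p
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        candidates = mesh.reshape(-1, p)
    else:
        candidates = rng.random((grid_points**2, p))
    y_hat, _ = interpolate(samples, candidates)
    scores = [_pooled_r2_vec(y, objective) for y in y_hat]
    x0 = candidates[int(np.argmax(scores))]

    def neg_r2(x: np.ndarray) -> float:
        xc = np.clip(x, 0.0, 1.0)
        y, _ = interpolate(samples, xc)
        return -_pooled_r2_vec(y, objective)

    res = minimize(neg_r2, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
    x_best = np.clip(res.x, 0.0, 1.0)
    return x_best if -res.fun >= max(scores) else x0
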