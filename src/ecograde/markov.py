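"""Markov-chain projection of the grade distribution and transition fitting.

The grade-probability vector of the Monte-Carlo evaluation acts as the
initial state X_0 of a finite Markov chain; X_{r+1} = X_r P with P a
row-stochastic transition matrix.  With no multi-year panel data available,
P is estimated by constrained minimization of the summed relative
deviations between observed calibration distributions S(r) and the
propagated estimates X_0 P^r.  The states "certainly grade I" and
"certainly grade V" are treated as absorbing by default, so the unit
vectors on the extreme grades are exact fixed points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

EPSILON = 1e-6  # safeguarded denominator for zero observed probabilities
_ROW_TOL = 1e-9


class MarkovError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic n x n matrix of grade-transition probabilities."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise MarkovError(f"transition matrix must be square, got {m.shape}")
        if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
            raise MarkovError("transition probabilities must lie in [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, rtol=0.0, atol=1e-6):
            raise MarkovError(f"rows must sum to 1, got {rows}")
        m = np.clip(m, 0.0, 1.0)
        m /= m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "entries", m)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def power(self, r: int) -> np.ndarray:
        """P^r by repeated multiplication (steps are small integers)."""
        out = np.eye(self.n)
        for _ in range(r):
            out = out @ self.entries
        return out


@dataclass(frozen=True)
class CalibrationPoint:
    """Observed grade distribution after ``step`` transfer steps."""

    step: int
    observed: np.ndarray

    def __post_init__(self) -> None:
        if self.step < 1:
            raise MarkovError(f"calibration step must be >= 1, got {self.step}")
        obs = np.asarray(self.observed, dtype=float)
        if np.any(obs < 0):
            raise MarkovError("calibration probabilities must be >= 0")
        total = obs.sum()
        if abs(total - 1.0) > 1e-6:
            logger.warning(
                "calibration at step %d sums to %.6f; renormalizing", self.step, total
            )
        if total <= 0:
            raise MarkovError("calibration distribution sums to zero")
        object.__setattr__(self, "observed", obs / total)


@dataclass(frozen=True)
class StateTrajectory:
    """Grade distributions X_0 ... X_m under repeated transition."""

    states: np.ndarray  # shape (steps + 1, n)
    matrix: TransitionMatrix

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class FitDiagnostics:
    q: float
    n_restarts: int
    best_start: int
    q_per_restart: tuple[float, ...]
    iterations: int
    uniform_rows: tuple[int, ...] = ()  # rows that came out exactly uniform


def _check_distribution(x, n: int | None = None) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or (n is not None and v.size != n):
        raise MarkovError(f"bad state vector shape {v.shape}")
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
        raise MarkovError(f"state must be a probability vector, got {v}")
    return v / v.sum()


def propagate(initial, matrix: TransitionMatrix, steps: int) -> StateTrajectory:
    """Trajectory X_0, X_0 P, ..., X_0 P^steps."""
    if steps < 0:
        raise MarkovError("steps must be >= 0")
    x = _check_distribution(initial, matrix.n)
    states = np.empty((steps + 1, matrix.n))
    states[0] = x
    for r in range(steps):
        states[r + 1] = states[r] @ matrix.entries
    return StateTrajectory(states=states, matrix=matrix)


def objective_q(
    matrix: TransitionMatrix | np.ndarray,
    initial,
    calibration: list[CalibrationPoint],
    epsilon: float = EPSILON,
) -> float:
    """Summed relative deviation between calibration and propagated estimates.

    Q = sum_r sum_k |(S_k(r) - X_0 P^r)_k| / max(S_k(r), epsilon).  Exposed
    separately so fits can be re-verified independently of the solver.
    """
    m = matrix.entries if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    x = np.asarray(initial, dtype=float)
    q = 0.0
    max_step = max(c.step for c in calibration)
    powers = {0: np.eye(m.shape[0])}
    for r in range(1, max_step + 1):
        powers[r] = powers[r - 1] @ m
    for c in calibration:
        est = x @ powers[c.step]
        denom = np.maximum(c.observed, epsilon)
        q += float(np.abs((c.observed - est) / denom).sum())
    return q


def _absorbing_template(n: int) -> tuple[np.ndarray, list[int]]:
    """Matrix skeleton with absorbing endpoint rows; returns it plus free rows."""
    m = np.zeros((n, n))
    m[0, 0] = 1.0
    m[n - 1, n - 1] = 1.0
    return m, list(range(1, n - 1))


def fit_transition_matrix(
    initial,
    calibration: list[CalibrationPoint],
    absorbing_endpoints: bool = True,
    restarts: int = 16,
    max_iterations: int = 300,
    tolerance: float = 1e-10,
    epsilon: float = EPSILON,
    seed: int = 0,
) -> tuple[TransitionMatrix, float, FitDiagnostics]:
    """Estimate the transition matrix from sparse calibration distributions.

    Minimizes the summed relative deviation Q subject to row-stochasticity
    (rows sum to 1, entries >= 0) and, when ``absorbing_endpoints`` is on,
    the hard equalities pinning the first and last rows to unit vectors.

    The objective is non-smooth and, past one step, non-convex, so the
    solver is a multi-start SLSQP: the uniform-interior start plus
    ``restarts - 1`` random row-stochastic starts.  Uniqueness of P is not
    claimed; the trajectory fit (Q) is the contract.
    """
    if not calibration:
        raise MarkovError("at least one calibration point required")
    steps = [c.step for c in calibration]
    if len(set(steps)) != len(steps):
        raise MarkovError(f"duplicate calibration steps: {steps}")
    n = calibration[0].observed.size
    x0 = _check_distribution(initial, n)
    if restarts < 1:
        raise MarkovError("restarts must be >= 1")

    if absorbing_endpoints:
        template, free_rows = _absorbing_template(n)
    else:
        template, free_rows = np.zeros((n, n)), list(range(n))
    k = len(free_rows)

    def build(theta: np.ndarray) -> np.ndarray:
        m = template.copy()
        m[free_rows] = theta.reshape(k, n)
        return m

    # smooth |d| ~ sqrt(d^2 + delta) for the solver; exact Q is reported
    delta = 1e-12
    max_step = max(steps)

    def _estimates(m: np.ndarray):
        power = np.eye(n)
        by_step = {}
        for r in range(1, max_step + 1):
            power = power @ m
            by_step[r] = power
        return {c.step: x0 @ by_step[c.step] for c in calibration}

    def smoothed(theta: np.ndarray) -> float:
        est = _estimates(build(theta))
        q = 0.0
        for c in calibration:
            denom = np.maximum(c.observed, epsilon)
            d = (c.observed - est[c.step]) / denom
            q += float(np.sqrt(d * d + delta).sum())
        return q

    def squared_absolute(theta: np.ndarray) -> float:
        # well-scaled surrogate: safeguarded relative terms can span six
        # orders of magnitude and stall SLSQP near zero-valued calibration
        est = _estimates(build(theta))
        return float(
            sum(((c.observed - est[c.step]) ** 2).sum() for c in calibration)
        )

    constraints = [
        {
            "type": "eq",
            "fun": (lambda theta, i=i: theta.reshape(k, n)[i].sum() - 1.0),
        }
        for i in range(k)
    ]
    bounds = [(0.0, 1.0)] * (k * n)

    rng = np.random.default_rng(seed)
    starts = [np.full((k, n), 1.0 / n).ravel()]
    for _ in range(restarts - 1):
        starts.append(rng.dirichlet(np.ones(n), size=k).ravel())

    best = None
    q_list: list[float] = []
    total_iter = 0
    for idx, theta0 in enumerate(starts):
        pre = minimize(
            squared_absolute,
            theta0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": max_iterations, "ftol": tolerance},
        )
        total_iter += int(pre.get("nit", 0))
        res = minimize(
            smoothed,
            np.clip(pre.x, 0.0, 1.0),
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": max_iterations, "ftol": tolerance},
        )
        total_iter += int(res.get("nit", 0))
        theta = np.clip(res.x, 0.0, 1.0).reshape(k, n)
        if smoothed(np.clip(pre.x, 0.0, 1.0)) < smoothed(theta.ravel()):
            theta = np.clip(pre.x, 0.0, 1.0).reshape(k, n)
        sums = theta.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            q_list.append(np.inf)
            continue
        theta = theta / sums
        m = build(theta.ravel())
        q_exact = objective_q(m, x0, calibration, epsilon)
        q_list.append(q_exact)
        if best is None or q_exact < best[0]:
            best = (q_exact, m, idx)

    if best is None:
        raise MarkovError("all solver restarts failed")
    q_best, m_best, start_idx = best
    matrix = TransitionMatrix(entries=m_best)
    uniform_rows = tuple(
        i for i in free_rows
        if np.allclose(matrix.entries[i], 1.0 / n, atol=1e-9)
    )
    if uniform_rows:
        logger.info("fitted matrix has exactly-uniform rows: %s", uniform_rows)
    diag = FitDiagnostics(
        q=q_best,
        n_restarts=len(starts),
        best_start=start_idx,
        q_per_restart=tuple(q_list),
        iterations=total_iter,
        uniform_rows=uniform_rows,
    )
    return matrix, q_best, diag


def dynamic_evaluate(
    target,
    standard,
    calibration: list[CalibrationPoint],
    steps: int,
    n_trials: int = 1000,
    rng=None,
    normalize: bool = False,
    **fit_options,
):
    """Full pipeline: Monte-Carlo initial state, transition fit, projection.

    Returns ``(initial GradeProbabilities, TransitionMatrix, StateTrajectory,
    FitDiagnostics)``; the trajectory's X_0 equals the initial probabilities.
    """
    from .evaluator import evaluate  # local import avoids a cycle

    probs = evaluate(target, standard, n_trials=n_trials, rng=rng, normalize=normalize)
    matrix, _, diag = fit_transition_matrix(probs.p, calibration, **fit_options)
    trajectory = propagate(probs.p, matrix, steps)
    return probs, matrix, trajectory, diag


def read_calibration(source: str) -> list[CalibrationPoint]:
    """Parse calibration CSV text: ``step,p1,p2,...,pn`` per row."""
    import io

    import pandas as pd

    df = pd.read_csv(io.StringIO(source))
    if "step" not in df.columns:
        raise MarkovError("calibration file missing 'step' column")
    prob_cols = [c for c in df.columns if c != "step"]
    points = []
    for _, row in df.iterrows():
        points.append(
            CalibrationPoint(
                step=int(row["step"]),
                observed=row[prob_cols].to_numpy(dtype=float),
            )
        )
    return points
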