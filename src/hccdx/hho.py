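"""Harris Hawks Optimization (HHO), a population metaheuristic.

Hawks cooperatively converge on the best solution found so far (the
"rabbit"). A prey escape energy E = 2*E0*(1 - t/T), with E0 ~ U(-1, 1)
redrawn per hawk per iteration, schedules the transition from global
exploration (|E| >= 1) to four exploitation moves (|E| < 1): soft besiege,
hard besiege, and their "progressive rapid dive" variants, where candidate
positions built with Levy-flight steps are accepted only if they improve
the hawk's fitness. The rabbit update is greedy, so the best-so-far trace
is monotonically non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class HHOParams:
    n_hawks: int = 30
    n_iter: int = 100
    lb: float | np.ndarray = -1.0
    ub: float | np.ndarray = 1.0
    dim: int = 1
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    bound_mode: str = "clip"          # or "reflect"
    seed: int | None = None

    def __post_init__(self):
        if self.n_hawks < 2:
            raise ValueError("population size must be >= 2")
        if self.n_iter < 1:
            raise ValueError("need at least one iteration")
        if self.bound_mode not in ("clip", "reflect"):
            raise ValueError(f"unknown bound mode {self.bound_mode!r}")
        lb = np.broadcast_to(np.asarray(self.lb, float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, float), (self.dim,)).copy()
        if not (lb < ub).all():
            raise ValueError("lower bounds must be strictly below upper bounds")
        self.lb, self.ub = lb, ub
        if not (1.0 < self.levy_beta <= 2.0):
            raise ValueError("levy_beta must be in (1, 2]")


@dataclass
class HawkState:
    X: np.ndarray                 # N x D positions
    fitness: np.ndarray           # length-N objective values
    x_rabbit: np.ndarray          # best position ever evaluated
    f_rabbit: float
    t: int = 0


@dataclass
class HHOResult:
    best_x: np.ndarray
    best_f: float
    trace: np.ndarray             # per-iteration best-so-far fitness
    n_evals: int


def escaping_energy(e0: float, t: int, T: int) -> float:
    """E = 2*E0*(1 - t/T): decays linearly to zero over the run."""
    return 2.0 * e0 * (1.0 - t / T)


def levy_flight(dim: int, beta: float, rng: np.random.Generator,
                scale: float = 1.0) -> np.ndarray:
    """Heavy-tailed step by the Mantegna construction with exponent beta."""
    sigma_u = (math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
               / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
               ) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, dim)
    v = rng.normal(0.0, 1.0, dim)
    return scale * u / np.abs(v) ** (1 / beta)


def _bound(x, lb, ub, mode):
    if mode == "clip":
        return np.clip(x, lb, ub)
    span = ub - lb
    folded = np.mod(x - lb, 2 * span)
    return lb + np.where(folded > span, 2 * span - folded, folded)


def exploration_move(x, x_rand, x_rabbit, x_mean, lb, ub,
                     rng: np.random.Generator) -> np.ndarray:
    """Global search move used while |E| >= 1.

    Draws q, then either perches on a random hawk (q >= 0.5, using r1, r2)
    or relative to the rabbit, the population mean and the bounds
    (q < 0.5, using r3, r4). Scalar draws occur in the order
    q, r1, r2 (or q, r3, r4).
    """
    q = rng.random()
    if q >= 0.5:
        r1, r2 = rng.random(), rng.random()
        x_new = x_rand - r1 * np.abs(x_rand - 2.0 * r2 * x)
    else:
        r3, r4 = rng.random(), rng.random()
        x_new = (x_rabbit - x_mean) - r3 * (lb + r4 * (ub - lb))
    return x_new


def soft_besiege(x, x_rabbit, E: float, J: float) -> np.ndarray:
    """X' = dX - E*|J*X_rabbit - X| with dX = X_rabbit - X."""
    dx = x_rabbit - x
    return dx - E * np.abs(J * x_rabbit - x)


def hard_besiege(x, x_rabbit, E: float) -> np.ndarray:
    """X' = X_rabbit - E*|dX| with dX = X_rabbit - X."""
    dx = x_rabbit - x
    return x_rabbit - E * np.abs(dx)


def _dive(x, y_base, fx, objective, params, rng, count):
    """Accept Y, else Z = Y + S*LF(D), else keep the current position."""
    y = _bound(y_base, params.lb, params.ub, params.bound_mode)
    fy = objective(y)
    count[0] += 1
    _check_finite(fy, y)
    if fy < fx:
        return y, fy
    S = rng.random(params.dim)
    z = y + S * levy_flight(params.dim, params.levy_beta, rng, params.levy_scale)
    z = _bound(z, params.lb, params.ub, params.bound_mode)
    fz = objective(z)
    count[0] += 1
    _check_finite(fz, z)
    if fz < fx:
        return z, fz
    return x, fx


def soft_besiege_dives(x, x_rabbit, E, J, fx, objective, params, rng, count):
    """Soft besiege with progressive rapid dives (|E| >= 0.5, r < 0.5)."""
    y_base = x_rabbit - E * np.abs(J * x_rabbit - x)
    return _dive(x, y_base, fx, objective, params, rng, count)


def hard_besiege_dives(x, x_rabbit, x_mean, E, J, fx, objective, params, rng, count):
    """Hard besiege with progressive rapid dives (|E| < 0.5, r < 0.5)."""
    y_base = x_rabbit - E * np.abs(J * x_rabbit - x_mean)
    return _dive(x, y_base, fx, objective, params, rng, count)


def _check_finite(f, x):
    if not np.isfinite(f):
        raise ValueError(f"objective returned non-finite value {f!r} at position {x}")


def optimize(objective, params: HHOParams, rng: np.random.Generator | None = None,
             callback=None) -> HHOResult:
    """Minimize ``objective`` over the box [lb, ub]^D.

    Each iteration starts with a fitness sweep over the population; the
    rabbit keeps the best position over all sweeps so far (greedy update,
    hence a non-increasing trace), and the hawks then move. Moves are
    scored at the next iteration's sweep; the moves of the final iteration
    are never evaluated, so a single-iteration run returns the best of the
    initial random population. Dive moves additionally probe candidate
    positions mid-iteration, accepting one only if it improves on the
    hawk's own fitness. ``callback(t, state)`` is invoked after each
    iteration. Same seed, same trace: the run is deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    N, D, T = params.n_hawks, params.dim, params.n_iter
    X = rng.uniform(params.lb, params.ub, size=(N, D))
    count = [0]

    def ev(x):
        f = objective(x)
        count[0] += 1
        _check_finite(f, x)
        return f

    state = HawkState(X=X, fitness=np.empty(N), x_rabbit=X[0].copy(),
                      f_rabbit=np.inf)
    trace = np.empty(T)

    for t in range(T):
        state.t = t
        fitness = np.array([ev(X[i]) for i in range(N)])
        state.fitness = fitness
        best = int(np.argmin(fitness))
        if fitness[best] < state.f_rabbit:
            state.f_rabbit = float(fitness[best])
            state.x_rabbit = X[best].copy()
        trace[t] = state.f_rabbit
        x_mean = X.mean(axis=0)
        for i in range(N):
            e0 = 2.0 * rng.random() - 1.0
            J = 2.0 * (1.0 - rng.random())
            E = escaping_energy(e0, t, T)
            if abs(E) >= 1.0:
                k = int(rng.integers(N))
                x_new = exploration_move(X[i], X[k], state.x_rabbit, x_mean,
                                         params.lb, params.ub, rng)
            else:
                r = rng.random()
                if abs(E) >= 0.5 and r >= 0.5:
                    x_new = soft_besiege(X[i], state.x_rabbit, E, J)
                elif r >= 0.5:
                    x_new = hard_besiege(X[i], state.x_rabbit, E)
                elif abs(E) >= 0.5:
                    x_new, _ = soft_besiege_dives(
                        X[i], state.x_rabbit, E, J, fitness[i], objective,
                        params, rng, count)
                else:
                    x_new, _ = hard_besiege_dives(
                        X[i], state.x_rabbit, x_mean, E, J, fitness[i],
                        objective, params, rng, count)
            X[i] = _bound(x_new, params.lb, params.ub, params.bound_mode)
        if callback is not None:
            callback(t, state)

    return HHOResult(best_x=state.x_rabbit, best_f=state.f_rabbit,
                     trace=trace, n_evals=count[0])
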