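"""(mu + lambda) evolution strategy for ODE/DDE parameter estimation.

Fitness is the least-squares error between a model solution and a reference
time course (typically the average of several spatial-simulator runs) at a
sample set of time points.  The ES is the textbook self-adaptive flavour:
log-normal step-size mutation per coordinate, elitist (mu + lambda)
survival, reflection at the box bounds, and independent restarts with the
overall best returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model import Trajectory, resample_trajectory

__all__ = ["ESConfig", "FitProblem", "fitness_lsq", "es_optimize", "manual_then_es"]


@dataclass
class ESConfig:
    mu: int = 5
    lam: int = 35
    generations: int = 100
    runs: int = 10
    bounds: Optional[np.ndarray] = None  # shape (n_params, 2)
    sigma0: Optional[np.ndarray] = None  # initial step sizes; default span/10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mu > self.lam:
            raise ValueError("need mu <= lambda")
        if self.generations < 0 or self.runs < 1:
            raise ValueError("generations must be >= 0 and runs >= 1")


@dataclass
class FitProblem:
    """A model family fit against a reference trajectory.

    ``solve`` maps a parameter vector to a Trajectory covering
    ``sample_times`` with (at least) the reference's species.  Only species
    present in the reference enter the fitness.
    """

    solve: Callable[[np.ndarray], Trajectory]
    reference: Trajectory
    sample_times: np.ndarray
    bounds: np.ndarray  # (n_params, 2)
    species: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        lo, hi = self.reference.times[0], self.reference.times[-1]
        if self.sample_times[0] < lo - 1e-9 or self.sample_times[-1] > hi + 1e-9:
            raise ValueError("sample_times must lie inside the reference range")
        if self.species is None:
            self.species = self.reference.species

    def reference_matrix(self) -> np.ndarray:
        cached = getattr(self, "_ref_cache", None)
        if cached is None:
            ref = resample_trajectory(self.reference, self.sample_times)
            cached = np.column_stack([ref.column(s) for s in self.species])
            self._ref_cache = cached
        return cached


def fitness_lsq(params: np.ndarray, problem: FitProblem) -> float:
    """Sum of squared deviations over sample times and species.

    Out-of-bounds parameter vectors are rejected before evaluation; a model
    solve that fails scores +inf (and the search simply moves on).
    """
    params = np.asarray(params, dtype=float)
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    if np.any(params < lo - 1e-12) or np.any(params > hi + 1e-12):
        raise ValueError("parameters outside bounds")
    try:
        traj = problem.solve(params)
        model = resample_trajectory(traj, problem.sample_times)
        mat = np.column_stack([model.column(s) for s in problem.species])
    except (RuntimeError, FloatingPointError, ValueError):
        return math.inf
    ref = problem.reference_matrix()
    return float(np.sum((mat - ref) ** 2))


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _one_run(
    problem: FitProblem,
    config: ESConfig,
    rng: np.random.Generator,
    seed_individual: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float, list[float]]:
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    n = lo.size
    sigma0 = config.sigma0 if config.sigma0 is not None else (hi - lo) / 10.0
    sigma0 = np.broadcast_to(np.asarray(sigma0, dtype=float), (n,)).copy()
    tau_global = 1.0 / math.sqrt(2.0 * n)
    tau_coord = 1.0 / math.sqrt(2.0 * math.sqrt(n))

    pop_x = lo + (hi - lo) * rng.random((config.mu, n))
    if seed_individual is not None:
        pop_x[0] = np.clip(seed_individual, lo, hi)
    pop_s = np.tile(sigma0, (config.mu, 1))
    pop_f = np.array([fitness_lsq(x, problem) for x in pop_x])

    trace = [float(pop_f.min())]
    for _ in range(config.generations):
        parents = rng.integers(config.mu, size=config.lam)
        global_step = np.exp(tau_global * rng.normal(size=(config.lam, 1)))
        coord_step = np.exp(tau_coord * rng.normal(size=(config.lam, n)))
        off_s = pop_s[parents] * global_step * coord_step
        off_x = _reflect(pop_x[parents] + off_s * rng.normal(size=(config.lam, n)), lo, hi)
        off_f = np.array([fitness_lsq(x, problem) for x in off_x])
        all_x = np.vstack([pop_x, off_x])
        all_s = np.vstack([pop_s, off_s])
        all_f = np.concatenate([pop_f, off_f])
        best = np.argsort(all_f, kind="stable")[: config.mu]
        pop_x, pop_s, pop_f = all_x[best], all_s[best], all_f[best]
        trace.append(float(pop_f.min()))
    i = int(np.argmin(pop_f))
    return pop_x[i].copy(), float(pop_f[i]), trace


def es_optimize(
    problem: FitProblem,
    config: ESConfig,
    seed_individual: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float, list[list[float]]]:
    """Best parameters over ``config.runs`` independent ES restarts.

    Returns (best_params, best_fitness, per-run fitness traces).  Elitism
    makes each trace non-increasing.
    """
    seq = (config.seed if isinstance(config.seed, np.random.SeedSequence)
           else np.random.SeedSequence(config.seed))
    best_x, best_f, traces = None, math.inf, []
    for child in seq.spawn(config.runs):
        x, f, trace = _one_run(problem, config, np.random.default_rng(child),
                               seed_individual)
        traces.append(trace)
        if f < best_f:
            best_x, best_f = x, f
    return best_x, best_f, traces


def manual_then_es(
    problem: FitProblem,
    initial_guess: np.ndarray,
    config: ESConfig,
) -> tuple[np.ndarray, float, list[list[float]]]:
    """Two-phase workflow: a manual initial guess refined by the ES.

    The guess replaces one parent in every restart's initial population, so
    elitism guarantees the returned fitness is at most the guess's fitness.
    """
    guess = np.asarray(initial_guess, dtype=float)
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    if np.any(guess < lo) or np.any(guess > hi):
        raise ValueError("initial guess outside bounds")
    return es_optimize(problem, config, seed_individual=guess)
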