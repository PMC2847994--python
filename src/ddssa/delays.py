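"""Delay distributions: build, transform, sample.

The central object is the cumulative distribution of arrival times
P(t_a <= t) for a diffusion-driven event (a translocation first-passage time,
a pair-association time).  These CDFs are what carries spatial information
into the purely temporal engines: once tabulated, a delay is drawn by inverse
transform at negligible cost.

Three construction routes are provided, matching where the statistics come
from in practice:

* :func:`empirical_cdf` -- event times recorded by the particle simulator;
* :func:`solve_arrival_pde` / :func:`random_walk_1d` -- 1D advection-diffusion
  first-passage problems solved on a grid or sampled walker by walker;
* :func:`cdf_from_ssa_mean` -- a monotone mean SSA time course of a single
  reaction, reinterpreted as an arrival CDF (well-mixed channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .particles import ArrivalRecord

try:  # numba accelerates the lattice walk; the pure-python path is equivalent
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "DelayDistribution",
    "DelayWindowRule",
    "Diffusion1DProblem",
    "empirical_cdf",
    "sample_delay",
    "truncate",
    "solve_arrival_pde",
    "random_walk_1d",
    "cdf_from_ssa_mean",
]


@dataclass
class DelayDistribution:
    """Tabulated arrival-time CDF on a non-negative time grid.

    ``F`` is the CDF *conditional on arrival* (it reaches 1 at the last grid
    point).  Molecules that never perform the event within the generating
    horizon are bookkept separately in ``arrival_mass``: engines first decide
    arrival vs non-arrival as a Bernoulli(``arrival_mass``) draw, keeping the
    tabulated CDF proper.

    ``interp`` selects the sampling convention: ``"linear"`` interpolates the
    generalized inverse between grid points (the right default for smooth,
    PDE-derived CDFs), ``"step"`` returns tabulated support points exactly
    (empirical CDFs).
    """

    t_grid: np.ndarray
    F: np.ndarray
    arrival_mass: float = 1.0
    source: dict = field(default_factory=dict)
    interp: str = "linear"
    pdf: Optional[np.ndarray] = None  # dP/dt on t_grid when known (PDE route)
    step_cdf: bool = False  # evaluate F as a right-continuous step (empirical)

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t_grid.shape != self.F.shape or self.t_grid.ndim != 1:
            raise ValueError("t_grid and F must be 1D arrays of equal length")
        if self.t_grid.size == 0:
            raise ValueError("empty delay distribution")
        if np.any(self.t_grid < 0):
            raise ValueError("delay times must be non-negative")
        if np.any(np.diff(self.t_grid) < 0):
            raise ValueError("t_grid must be non-decreasing")
        if np.any(np.diff(self.F) < -1e-12):
            raise ValueError("CDF must be non-decreasing")
        if self.F[0] < -1e-12 or abs(self.F[-1] - 1.0) > 1e-9:
            raise ValueError("conditional CDF must start >= 0 and end at 1")
        if not 0 < self.arrival_mass <= 1:
            raise ValueError("arrival_mass must lie in (0, 1]")

    # -- evaluation ---------------------------------------------------------
    def cdf(self, t) -> np.ndarray:
        """Right-continuous CDF value(s) at ``t`` (conditional on arrival)."""
        t = np.asarray(t, dtype=float)
        if self.interp == "step" or self.step_cdf:
            idx = np.searchsorted(self.t_grid, t, side="right")
            F_ext = np.concatenate(([0.0], self.F))
            return F_ext[idx]
        return np.interp(t, self.t_grid, self.F, left=0.0, right=1.0)

    def quantile(self, u) -> np.ndarray:
        """Generalized inverse F^-1(u) for u in [0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.interp == "step":
            # generalized inverse inf{t : F(t) >= u}
            idx = np.searchsorted(self.F, u, side="left")
            idx = np.minimum(idx, self.F.size - 1)
            return self.t_grid[idx]
        F_ext = np.concatenate(([0.0], self.F))
        t_ext = np.concatenate(([self.t_grid[0]], self.t_grid))
        return np.interp(u, F_ext, t_ext)

    def mean(self) -> float:
        """Mean of the conditional arrival time (by quadrature on quantiles)."""
        u = (np.arange(10000) + 0.5) / 10000
        return float(np.mean(self.quantile(u)))

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    # -- constructors -------------------------------------------------------
    @classmethod
    def degenerate(cls, tau: float) -> "DelayDistribution":
        """A unit point mass at ``tau`` (the constant-delay limit)."""
        return cls(np.array([tau]), np.array([1.0]), interp="step",
                   source={"kind": "degenerate", "tau": tau})

    @classmethod
    def from_function(cls, cdf, t_grid) -> "DelayDistribution":
        t_grid = np.asarray(t_grid, dtype=float)
        F = np.asarray(cdf(t_grid), dtype=float)
        F = F / F[-1]
        return cls(t_grid, F, source={"kind": "tabulated-function"})

    # -- persistence --------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the CDF table plus a JSON sidecar of the metadata.

        %.17g formatting and round-trip parsing make the stored table
        bit-exact under a save/load cycle.
        """
        import json
        from pathlib import Path

        path = Path(path)
        pd.DataFrame({"t_s": self.t_grid, "F": self.F}).to_csv(
            path, index=False, float_format="%.17g")
        sidecar = {"arrival_mass": self.arrival_mass, "interp": self.interp,
                   "step_cdf": self.step_cdf,
                   "source": {k: v for k, v in self.source.items()
                              if isinstance(v, (str, int, float, bool))}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path, **kw) -> "DelayDistribution":
        import json
        from pathlib import Path

        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            kw.setdefault("arrival_mass", meta.get("arrival_mass", 1.0))
            kw.setdefault("interp", meta.get("interp", "linear"))
            kw.setdefault("step_cdf", meta.get("step_cdf", False))
            kw.setdefault("source", meta.get("source", {}))
        return cls(df["t_s"].to_numpy(), df["F"].to_numpy(), **kw)


@dataclass
class DelayWindowRule:
    """Time-windowed restriction of the inverse-transform uniform (M4).

    While simulation time lies in ``[t_start, t_end)``, the uniform variate
    for ``channel`` is drawn from ``[u_lo, u_hi)`` instead of [0, 1), which
    conditions the delay on the corresponding quantile range (e.g. u in
    [0, 0.5) restricts draws to delays below the median).
    """

    t_start: float
    t_end: float
    u_lo: float
    u_hi: float
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("active interval must be well ordered")
        if not 0 <= self.u_lo < self.u_hi <= 1:
            raise ValueError("u-interval must be a sub-interval of [0, 1)")

    def active(self, now: float) -> bool:
        return self.t_start <= now < self.t_end


def empirical_cdf(record: ArrivalRecord) -> DelayDistribution:
    """Empirical arrival CDF from recorded event times.

    The CDF is the right-continuous step function over the sorted event
    times, normalised by the *number of arrivals*; the fraction of initial
    molecules that arrived at all within the horizon goes to
    ``arrival_mass``.
    """
    times = record.event_times
    if times.size == 0:
        raise ValueError("cannot build a CDF from an empty arrival record")
    n = times.size
    F = np.arange(1, n + 1) / n
    # collapse duplicate times, keeping the highest step value
    t_unique, last_idx = np.unique(times[::-1], return_index=True)
    F_unique = F[::-1][last_idx]
    mass = times.size / record.n_initial if record.n_initial else 1.0
    return DelayDistribution(
        t_unique, F_unique, arrival_mass=min(mass, 1.0),
        source={"kind": "empirical", "event": record.event,
                "n_initial": record.n_initial, "horizon": record.horizon},
        interp="linear", step_cdf=True,
    )


def sample_delay(
    dist: DelayDistribution,
    rng: np.random.Generator,
    window: Optional[DelayWindowRule] = None,
    now: float = 0.0,
    size: Optional[int] = None,
):
    """Inverse-transform delay sample(s), optionally u-restricted by a window."""
    u = rng.random(size) if size is not None else rng.random()
    if window is not None and window.active(now):
        u = window.u_lo + (window.u_hi - window.u_lo) * u
    out = dist.quantile(u)
    return out if size is not None else float(out)


def truncate(dist: DelayDistribution, u_max: float) -> DelayDistribution:
    """Condition the delay law on F(t) <= u_max and renormalise.

    Restricting draws to small delays emulates the faster early dynamics of
    a process whose true delay distribution shrinks over time.
    """
    if not 0 < u_max <= 1:
        raise ValueError("u_max must lie in (0, 1]")
    if u_max == 1.0:
        return dist
    keep = dist.F <= u_max + 1e-12
    if not keep.any():
        keep[0] = True
    t = dist.t_grid[keep]
    F = dist.F[keep] / dist.F[keep][-1]
    return DelayDistribution(
        t, F, arrival_mass=dist.arrival_mass,
        source={**dist.source, "truncated_at": u_max}, interp=dist.interp,
        step_cdf=dist.step_cdf,
    )


# --------------------------------------------------------------------------
# 1D first-passage problems

@dataclass
class Diffusion1DProblem:
    """Advection-diffusion first passage on [0, L] with mixed boundaries.

    dp/dt = D d2p/dx2 - v dp/dx, p(x, 0) = delta(x - x0); each boundary is
    ``"absorbing"`` (Dirichlet p = 0, probability leaks out) or
    ``"reflecting"`` (zero flux).  At least one absorbing boundary is
    required for a translocation problem -- otherwise nothing ever arrives.
    Units are micrometres and seconds; ``D`` in um^2/s here (1D abstraction,
    not tied to the 3D cm^2/s convention).
    """

    D: float
    L: float
    x0: float
    v: float = 0.0
    bc_left: str = "absorbing"
    bc_right: str = "reflecting"
    dx: float = 0.01
    dt_pde: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.x0 <= self.L:
            raise ValueError("x0 must lie in [0, L]")
        for bc in (self.bc_left, self.bc_right):
            if bc not in ("absorbing", "reflecting"):
                raise ValueError(f"unknown boundary condition {bc!r}")


def solve_arrival_pde(problem: Diffusion1DProblem, t_end: float) -> DelayDistribution:
    """Arrival CDF P(t_a <= t) from a Crank-Nicolson finite-volume solve.

    The density is advanced on cell averages with second-order fluxes;
    absorbing boundaries are Dirichlet p = 0 at the wall face, reflecting
    boundaries are zero flux.  P(t) is accumulated from the discrete
    absorbing-face fluxes, so remaining mass + absorbed mass = 1 to round-off
    at every step.  The PDF dP/dt is returned on the same grid.
    """
    if problem.bc_left != "absorbing" and problem.bc_right != "absorbing":
        raise ValueError("translocation problems need at least one absorbing boundary")
    D, v, L, dx, dt = problem.D, problem.v, problem.L, problem.dx, problem.dt_pde
    n = int(round(L / dx))
    dx = L / n  # cell width; centres at (i + 1/2) dx
    # spatial operator A with A p = dp/dt; build as tridiagonal
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    # interior faces: diffusive flux D (p_i+1 - p_i)/dx, upwind-free central advection
    for i in range(n):
        if i > 0:
            diag[i] -= D / dx**2
            lower[i] += D / dx**2
            diag[i] += v / (2 * dx)
            lower[i] += v / (2 * dx)
        if i < n - 1:
            diag[i] -= D / dx**2
            upper[i] += D / dx**2
            diag[i] -= v / (2 * dx)
            upper[i] -= v / (2 * dx)
    # boundary faces: Dirichlet p = 0 at wall (half-cell gradient) or zero flux
    if problem.bc_left == "absorbing":
        diag[0] -= 2 * D / dx**2
    if problem.bc_right == "absorbing":
        diag[-1] -= 2 * D / dx**2

    n_steps = int(round(t_end / dt))
    # Crank-Nicolson: (I - dt/2 A) p_new = (I + dt/2 A) p_old
    ab = np.zeros((3, n))
    ab[0, 1:] = -dt / 2 * upper[:-1]
    ab[1, :] = 1.0 - dt / 2 * diag
    ab[2, :-1] = -dt / 2 * lower[1:]

    p = np.zeros(n)
    # discrete delta: unit mass split over the two cells bracketing x0 so its
    # centre of mass is exactly x0 (a single-cell delta biases every mode by
    # up to dx/2, visible in the early-time pdf)
    xi = problem.x0 / dx - 0.5
    j = int(np.clip(np.floor(xi), 0, n - 1))
    j2 = min(j + 1, n - 1)
    w = float(np.clip(xi - j, 0.0, 1.0))
    p[j] += (1.0 - w) / dx
    p[j2] += w / dx

    def absorbing_outflux(p_vec):
        # discrete-conservative flux (matches the operator's boundary term
        # exactly, so remaining + absorbed mass is conserved to round-off)
        flux = 0.0
        if problem.bc_left == "absorbing":
            flux += 2 * D / dx**2 * p_vec[0] * dx
        if problem.bc_right == "absorbing":
            flux += 2 * D / dx**2 * p_vec[-1] * dx
        return flux

    def absorbing_outflux_o2(p_vec):
        # second-order wall gradient (quadratic through the wall zero and the
        # first two cell centres); used for the reported pdf only
        flux = 0.0
        if problem.bc_left == "absorbing":
            flux += D * (9 * p_vec[0] - p_vec[1]) / (3 * dx)
        if problem.bc_right == "absorbing":
            flux += D * (9 * p_vec[-1] - p_vec[-2]) / (3 * dx)
        return flux

    t_grid = np.zeros(n_steps + 1)
    P = np.zeros(n_steps + 1)
    pdf = np.zeros(n_steps + 1)
    pdf[0] = absorbing_outflux_o2(p)
    mass0 = p.sum() * dx
    for k in range(1, n_steps + 1):
        rhs = p + dt / 2 * (
            np.concatenate(([0.0], lower[1:] * p[:-1]))
            + diag * p
            + np.concatenate((upper[:-1] * p[1:], [0.0]))
        )
        p_new = solve_banded((1, 1), ab, rhs)
        # trapezoidal absorbed mass over the step (consistent with CN)
        P[k] = P[k - 1] + dt / 2 * (absorbing_outflux(p) + absorbing_outflux(p_new))
        p = p_new
        t_grid[k] = k * dt
        pdf[k] = absorbing_outflux_o2(p)
        if p.sum() * dx > mass0 * (1 + 1e-6):
            raise RuntimeError("instability detected: probability mass grew")

    conservation_gap = abs(p.sum() * dx + P[-1] - mass0)
    F_final = P[-1]
    if F_final <= 0:
        raise RuntimeError("no probability absorbed; check D, x0 and t_end")
    F = np.minimum(P / F_final, 1.0)
    F[-1] = 1.0
    return DelayDistribution(
        t_grid, F, arrival_mass=1.0,
        source={
            "kind": "pde", "D": D, "v": v, "L": L, "x0": problem.x0,
            "dx": dx, "dt": dt, "absorbed_mass": F_final,
            "conservation_gap": conservation_gap,
        },
        interp="linear",
        pdf=pdf / F_final,
    )


# --------------------------------------------------------------------------
# 1D lattice random walk

def _walk_kernel_py(n_walkers, n_sites, m0, seed):
    """First-passage step counts of +-1 walks: absorbing at 0, reflecting at N.

    Exact block acceleration: from lattice position m the walk cannot touch
    site 0 (nor fold past the reflecting wall into 0) within
    j = min(m, 2N - m - 1) steps except exactly at the block end, so the net
    displacement over j unconstrained steps (2 Binomial(j, 1/2) - j, folded
    at the reflecting wall) has the exact path-law marginal.  Absorption can
    therefore be detected block end by block end without bias.
    """
    np.random.seed(seed)
    out = np.empty(n_walkers, dtype=np.int64)
    for w in range(n_walkers):
        m = m0
        t = 0
        while m > 0:
            j = min(m, 2 * n_sites - m - 1)
            if j <= 8:
                m += 2 * np.random.randint(0, 2) - 1
                t += 1
            else:
                k = np.random.binomial(j, 0.5)
                m += 2 * k - j
                t += j
            if m > n_sites:  # specular reflection (fold)
                m = 2 * n_sites - m
        out[w] = t
    return out


_walk_kernel = njit(cache=True)(_walk_kernel_py) if njit is not None else _walk_kernel_py


def random_walk_1d(
    n_walkers: int,
    step_size: float,
    L: float,
    x0: float,
    rng_or_seed,
    D: Optional[float] = None,
    dt: Optional[float] = None,
) -> ArrivalRecord:
    """First-passage times of +-step_size lattice walks on [0, L].

    The left wall (at 0) is absorbing, the right wall reflecting; ``x0`` is
    the start position measured from the absorbing wall.  The physical clock
    is ``dt`` seconds per step; when ``D`` (um^2/s) is given instead, the
    walk and a PDE with that D share a clock via dt = step^2 / (2 D).
    With neither, times are reported in steps.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    if not 0 < x0 < L:
        raise ValueError("x0 must lie strictly inside (0, L)")
    if dt is None:
        dt = step_size**2 / (2.0 * D) if D is not None else 1.0
    n_sites = int(round(L / step_size))
    m0 = int(round(x0 / step_size))
    m0 = min(max(m0, 1), n_sites)
    if isinstance(rng_or_seed, np.random.Generator):
        seed = int(rng_or_seed.integers(2**31 - 1))
    else:
        seed = int(rng_or_seed)
    steps = _walk_kernel(n_walkers, n_sites, m0, seed)
    times = steps.astype(np.float64) * dt
    return ArrivalRecord(
        times, n_initial=n_walkers, horizon=float(times.max()),
        event=f"walk1d(L={L},x0={x0},step={step_size},dt={dt})",
    )


# --------------------------------------------------------------------------
# CDFs from well-mixed SSA means

def cdf_from_ssa_mean(mean_traj, species, tol: float = 0.02) -> DelayDistribution:
    """Reinterpret a monotone mean time course as an arrival CDF.

    For a single well-mixed channel simulated in isolation, the mean
    depletion of the reactant (or accumulation of the product) as a fraction
    of its total change *is* the per-molecule event-time CDF.  Small
    Monte-Carlo wiggles are tolerated (up to ``tol`` of the total change,
    then enforced monotone); a flat time course is rejected.
    """
    y = mean_traj.column(species).astype(float)
    t = mean_traj.times
    total = y[-1] - y[0]
    if abs(total) < 1e-12:
        raise ValueError("constant time course carries no event signal")
    frac = (y - y[0]) / total  # 0 -> 1 whether decaying or accumulating
    if np.any(np.diff(frac) < -tol):
        raise ValueError("time course is non-monotone beyond tolerance")
    F = np.maximum.accumulate(np.clip(frac, 0.0, None))
    F = F / F[-1]
    return DelayDistribution(
        t, F, arrival_mass=1.0,
        source={"kind": "ssa-mean", "species": species.label}, interp="linear",
    )
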