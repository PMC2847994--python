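"""Off-lattice Brownian particle simulator with compartments and membranes.

A minimal single-particle-tracking engine in the ChemCell tradition: particles
diffuse by per-axis Gaussian steps truncated to a cube ("cube Brownian
motion"), membranes are semi-permeable spherical shells, and bimolecular
reactions fire probabilistically between particle pairs closer than a cutoff
radius.  Each time step runs three stages: particle motion (with membrane
handling), neighbour finding, and reactions.

Its role in the package is to *generate* the arrival-time statistics
(first-passage / association times) that become delay distributions for the
temporal engines, and to serve as the spatially resolved reference that those
engines are compared against.

Units: positions and radii in micrometres, diffusion constants in cm^2/s
(converted internally; 1 cm^2 = 1e8 um^2), times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .model import Reaction, ReactionNetwork, SpeciesRef, Trajectory

__all__ = [
    "SphericalGeometry",
    "ParticleSimConfig",
    "ArrivalRecord",
    "ParticleWorld",
    "brownian_step",
    "apply_boundaries",
    "find_pairs",
    "react_pairs",
    "init_positions",
    "run_particle_sim",
    "reaction_probability",
]

CM2_TO_UM2 = 1e8

#: Compartment labels used throughout: cytosol, nucleus, (outer) membrane.
CYTOSOL, NUCLEUS, MEMBRANE = "c", "n", "m"


@dataclass
class SphericalGeometry:
    """Concentric cell/nucleus spheres with per-(species, membrane) permeability.

    Defaults are typical human-carcinoma dimensions.  Permeability is the
    probability that a particle whose proposed move crosses a membrane
    actually translocates; an absent entry means 1.0 for the nuclear membrane
    (fully permeable) and 0.0 for the outer membrane (closed cell).
    """

    cell_radius: float = 7.81
    nucleus_radius: float = 4.29
    permeability: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")
        for value in self.permeability.values():
            if not 0 <= value <= 1:
                raise ValueError("permeabilities must lie in [0, 1]")

    def perm(self, species: SpeciesRef, membrane: str) -> float:
        key = (species, membrane)
        if key in self.permeability:
            return self.permeability[key]
        return 1.0 if membrane == "nuclear" else 0.0

    def compartment_of(self, r: float) -> str:
        return NUCLEUS if r < self.nucleus_radius else CYTOSOL


@dataclass
class ParticleSimConfig:
    """Stepping parameters for the particle engine.

    ``dt`` defaults to 1e-3 s (use 1e-4 s for high-diffusivity runs);
    ``bin_size`` is derived from the fastest diffusing species when not given
    and must be at least the reaction cutoff.  ``reaction_p`` maps a binary
    channel (by display name) to its per-step, per-pair reaction probability,
    capped at ``p_max``.
    """

    dt: float = 1e-3
    diffusion: dict = field(default_factory=dict)  # SpeciesRef -> D in cm^2/s
    cutoff_R: float = 0.05
    p_max: float = 0.5
    bin_size: Optional[float] = None
    reaction_p: dict = field(default_factory=dict)
    record_every: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        for D in self.diffusion.values():
            if D < 0:
                raise ValueError("diffusion constants must be non-negative")
        if self.bin_size is None:
            fastest = max(self.diffusion.values(), default=0.0)
            sigma = math.sqrt(2.0 * fastest * CM2_TO_UM2 * self.dt)
            self.bin_size = max(self.cutoff_R, 3.0 * sigma)
        if self.bin_size < self.cutoff_R:
            raise ValueError("bin_size must be >= cutoff_R")

    def channel_p(self, reaction: Reaction) -> float:
        p = self.reaction_p.get(reaction.display_name, self.p_max)
        return min(p, self.p_max)


@dataclass
class ArrivalRecord:
    """Event times (and optionally positions) collected from one spatial run."""

    event_times: np.ndarray
    n_initial: int
    horizon: float
    event: str = ""
    event_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.event_times = np.sort(np.asarray(self.event_times, dtype=float))
        if self.event_times.size and self.event_times[-1] > self.horizon + 1e-9:
            raise ValueError("event times exceed the recording horizon")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def arrival_fraction(self) -> float:
        return self.n_events / self.n_initial if self.n_initial else 0.0

    def to_csv(self, path) -> None:
        """Write event times as CSV with a JSON sidecar of the metadata."""
        import json
        from pathlib import Path

        path = Path(path)
        df = pd.DataFrame({"event_time_s": self.event_times})
        if self.event_positions is not None:
            for i, axis in enumerate("xyz"):
                df[axis] = self.event_positions[:, i]
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar = {"n_initial": self.n_initial, "horizon": self.horizon,
                   "event": self.event}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ArrivalRecord":
        import json
        from pathlib import Path

        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(".json").read_text())
        positions = (df[["x", "y", "z"]].to_numpy()
                     if {"x", "y", "z"} <= set(df.columns) else None)
        return cls(df["event_time_s"].to_numpy(), meta["n_initial"],
                   meta["horizon"], event=meta.get("event", ""),
                   event_positions=positions)


# --------------------------------------------------------------------------
# cube Brownian motion

@lru_cache(maxsize=None)
def _cube_sigma_ratio(c_cube: float = 3.0) -> float:
    """Ratio sigma_eff / sigma_nominal for variance-preserving cube truncation.

    Per-axis steps are Gaussian draws rejected outside the cube half-width
    ``c_cube * sigma_nominal``.  Truncation removes variance, so the raw draw
    scale is inflated until the *truncated* step variance equals the nominal
    2*D*dt.  The fixed point is solved once numerically and cached.
    """

    def truncated_var_ratio(r: float) -> float:
        a = c_cube / r
        z = 2.0 * stats.norm.cdf(a) - 1.0
        return r * r * (1.0 - 2.0 * a * stats.norm.pdf(a) / z) - 1.0

    return float(optimize.brentq(truncated_var_ratio, 1.0 + 1e-9, 2.0))


def _truncated_normal_steps(
    shape: tuple, sigma_nom: float, rng: np.random.Generator, c_cube: float = 3.0
) -> np.ndarray:
    sigma_eff = sigma_nom * _cube_sigma_ratio(c_cube)
    bound = c_cube * sigma_nom
    steps = rng.normal(0.0, sigma_eff, size=shape)
    bad = np.abs(steps) > bound
    while bad.any():
        steps[bad] = rng.normal(0.0, sigma_eff, size=int(bad.sum()))
        bad = np.abs(steps) > bound
    return steps


def brownian_step(
    positions: np.ndarray,
    D_cm2_s: float,
    dt: float,
    rng: np.random.Generator,
    c_cube: float = 3.0,
) -> np.ndarray:
    """Propose new positions after one cube-Brownian step (no boundaries).

    Each coordinate is displaced independently by a zero-mean Gaussian of
    standard deviation sqrt(2*D*dt), truncated (by rejection) to the cube of
    half-width ``c_cube * sqrt(2*D*dt)`` and rescaled so the truncated
    variance still equals 2*D*dt.
    """
    if D_cm2_s < 0:
        raise ValueError("diffusion constant must be non-negative")
    if D_cm2_s == 0:
        return positions.copy()
    sigma = math.sqrt(2.0 * D_cm2_s * CM2_TO_UM2 * dt)
    return positions + _truncated_normal_steps(positions.shape, sigma, rng, c_cube)


# --------------------------------------------------------------------------
# membranes

def _resolve_moves(
    old: np.ndarray,
    proposed: np.ndarray,
    species: SpeciesRef,
    geometry: SphericalGeometry,
    rng: np.random.Generator,
    sigma: float,
    can_cross_nuclear: bool,
    c_cube: float = 3.0,
    max_redraws: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised membrane handling for one species' proposed moves.

    Returns (positions, crossed_mask).  A proposed move that crosses the
    nuclear membrane succeeds with the species' permeability (provided a
    translocation target exists); failed or forbidden crossings are
    resampled -- the displacement is redrawn until the particle stays in its
    compartment (reject-and-resample in place of specular reflection).
    Crossed particles keep their proposed position (now in the new
    compartment); the caller re-labels their species.
    """
    home = species.compartment
    r_n, r_c = geometry.nucleus_radius, geometry.cell_radius

    def inside_home(pos):
        r = np.linalg.norm(pos, axis=-1)
        return (r < r_n) if home == NUCLEUS else (r_n <= r) & (r <= r_c)

    def crosses_nuclear(pos):
        r = np.linalg.norm(pos, axis=-1)
        return (r >= r_n) if home == NUCLEUS else (r < r_n)

    perm = geometry.perm(species, "nuclear") if can_cross_nuclear else 0.0
    attempt = crosses_nuclear(proposed)
    crossed = attempt & (rng.random(attempt.shape) < perm)
    # outer-membrane exits and failed/forbidden nuclear crossings are resampled
    need_resample = ~crossed & ~inside_home(proposed)
    positions = proposed.copy()
    pending = np.flatnonzero(need_resample)
    for _ in range(max_redraws):
        if pending.size == 0:
            break
        redrawn = old[pending] + _truncated_normal_steps(
            (pending.size, old.shape[1]), sigma, rng, c_cube
        )
        ok = inside_home(redrawn)
        positions[pending[ok]] = redrawn[ok]
        pending = pending[~ok]
    if pending.size:  # pathological geometry: give up, stay put
        positions[pending] = old[pending]
    return positions, crossed


def apply_boundaries(
    position: np.ndarray,
    proposed: np.ndarray,
    species: SpeciesRef,
    geometry: SphericalGeometry,
    rng: np.random.Generator,
    sigma: float = 0.0,
    can_cross_nuclear: bool = True,
) -> tuple[np.ndarray, str, bool]:
    """Single-particle membrane resolution (see :func:`_resolve_moves`).

    Returns the accepted position, the resulting compartment label and
    whether a membrane was crossed.  With ``sigma == 0`` a rejected move
    simply leaves the particle in place.
    """
    pos, crossed = _resolve_moves(
        position[None, :], proposed[None, :], species, geometry, rng,
        sigma, can_cross_nuclear,
    )
    new_r = float(np.linalg.norm(pos[0]))
    return pos[0], geometry.compartment_of(new_r), bool(crossed[0])


# --------------------------------------------------------------------------
# neighbour finding and reactions

def find_pairs(
    positions_a: np.ndarray,
    cutoff_R: float,
    positions_b: Optional[np.ndarray] = None,
    bin_size: Optional[float] = None,
) -> list[tuple[int, int]]:
    """All index pairs at Euclidean distance <= cutoff (inclusive).

    With one position set, returns unordered pairs (i < j) within it
    (dimerization); with two sets, returns (i in a, j in b) cross pairs.
    ``bin_size`` must be at least the cutoff when given (the spatial search
    structure guarantees the same adjacent-cell completeness either way).
    """
    if bin_size is not None and bin_size < cutoff_R:
        raise ValueError("bin_size must be >= cutoff_R")
    if positions_b is None:
        if len(positions_a) < 2:
            return []
        tree = cKDTree(positions_a)
        return sorted(tree.query_pairs(cutoff_R))
    if len(positions_a) == 0 or len(positions_b) == 0:
        return []
    tree_a, tree_b = cKDTree(positions_a), cKDTree(positions_b)
    neighbours = tree_a.query_ball_tree(tree_b, cutoff_R)
    return [(i, j) for i, js in enumerate(neighbours) for j in sorted(js)]


def react_pairs(
    pairs: Sequence[tuple[int, int]],
    p: float,
    rng: np.random.Generator,
    self_pairs: bool = False,
) -> list[tuple[int, int]]:
    """Select the reacting pairs for this step.

    Candidate pairs are visited in randomised order; each fires with
    probability ``p`` and a particle participates in at most one reaction per
    step.  Returns the accepted pairs.  ``self_pairs`` marks dimerization,
    where both indices address the same particle set.
    """
    if not pairs or p <= 0:
        return []
    order = rng.permutation(len(pairs))
    used_a: set[int] = set()
    used_b: set[int] = used_a if self_pairs else set()
    accepted = []
    u = rng.random(len(pairs))
    for k in order:
        i, j = pairs[k]
        if i in used_a or j in used_b:
            continue
        if u[k] < p:
            accepted.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return accepted


def reaction_probability(
    k: float, dt: float, cutoff_R: float, volume: float, p_max: float = 0.5
) -> float:
    """Well-mixed estimate of the per-step pair reaction probability.

    Approximate Smoluchowski-style conversion: a pair in contact (within the
    cutoff sphere of volume V_R = 4/3 pi R^3) should produce ``k * dt``
    expected reactions per step when averaged over a well-mixed compartment
    of volume ``volume``, giving p = k * volume * dt / V_R, capped at
    ``p_max``.  This is a convenience only -- diffusion limitation and
    repeated-contact correlations are ignored, so calibrate against a
    reference when quantitative agreement matters.
    """
    v_r = 4.0 / 3.0 * math.pi * cutoff_R**3
    return min(p_max, k * volume * dt / v_r)


# --------------------------------------------------------------------------
# initial placement

def init_positions(
    placement,
    geometry: SphericalGeometry,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` i.i.d. initial positions.

    ``placement`` is one of
    ``("uniform", compartment)`` -- uniform in the nucleus ball or cytosol shell;
    ``("cluster", center_distance, radius)`` -- uniform in a small sphere at
    ``center_distance`` from the cell centre (must not straddle a membrane);
    ``("membrane",)`` -- uniform on the outer membrane surface.
    """
    if n == 0:
        return np.empty((0, 3))
    kind = placement[0]
    if kind == "uniform":
        compartment = placement[1]
        if compartment == NUCLEUS:
            lo, hi = 0.0, geometry.nucleus_radius
        elif compartment == CYTOSOL:
            lo, hi = geometry.nucleus_radius, geometry.cell_radius
        else:
            raise ValueError(f"unknown compartment {compartment!r}")
        u = rng.random(n)
        radii = np.cbrt(lo**3 + (hi**3 - lo**3) * u)
        return radii[:, None] * _random_directions(n, rng)
    if kind == "cluster":
        center_distance, radius = placement[1], placement[2]
        lo, hi = center_distance - radius, center_distance + radius
        inside_cytosol = geometry.nucleus_radius <= lo and hi <= geometry.cell_radius
        inside_nucleus = lo >= 0 and hi <= geometry.nucleus_radius
        if not (inside_cytosol or inside_nucleus):
            raise ValueError("cluster overlaps a membrane")
        centre = np.array([center_distance, 0.0, 0.0])
        u = rng.random(n)
        radii = radius * np.cbrt(u)
        return centre + radii[:, None] * _random_directions(n, rng)
    if kind == "membrane":
        return geometry.cell_radius * _random_directions(n, rng)
    raise ValueError(f"unknown placement spec {placement!r}")


def _random_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# --------------------------------------------------------------------------
# the world and the main loop

@dataclass
class ParticleWorld:
    """Particle positions grouped by (compartment-tagged) species."""

    geometry: SphericalGeometry
    positions: dict  # SpeciesRef -> (n, 3) array
    surface_species: set = field(default_factory=set)  # constrained to outer membrane

    @classmethod
    def build(
        cls,
        geometry: SphericalGeometry,
        placements: Mapping[SpeciesRef, tuple],
        counts: Mapping[SpeciesRef, int],
        rng: np.random.Generator,
    ) -> "ParticleWorld":
        positions = {}
        surface = set()
        for sp, n in counts.items():
            placement = placements.get(sp, ("uniform", sp.compartment or CYTOSOL))
            positions[sp] = init_positions(placement, geometry, n, rng)
            if placement[0] == "membrane":
                surface.add(sp)
        return cls(geometry, positions, surface)

    def counts(self) -> dict:
        return {sp: len(pos) for sp, pos in self.positions.items()}


def _translocation_map(network: ReactionNetwork) -> dict:
    """Unary cross-compartment channels realised spatially by membranes."""
    out = {}
    for rxn in network.reactions:
        if len(rxn.reactants) == 1 and len(rxn.products) == 1:
            src, dst = rxn.reactants[0], rxn.products[0]
            if src.name == dst.name and src.compartment != dst.compartment:
                out[src] = (dst, rxn)
    return out


def run_particle_sim(
    world: ParticleWorld,
    network: ReactionNetwork,
    config: ParticleSimConfig,
    t_end: float,
    record: Sequence[str] = (),
    rng: Optional[np.random.Generator] = None,
) -> tuple[Trajectory, dict]:
    """Fixed-step three-stage particle loop: motion, neighbour finding, reactions.

    ``record`` lists event keys -- the display names of translocation or
    binary channels -- for which an :class:`ArrivalRecord` (event times and
    positions) is returned.  Translocations happen via membrane permeability,
    unary conversions as per-particle Bernoulli(1 - exp(-k dt)) trials, and
    binary channels via the pair search + per-pair probability.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = rng or np.random.default_rng(config.seed)
    geometry = world.geometry
    transloc = _translocation_map(network)
    n_initial = world.counts()

    unary_conversions = [
        r for r in network.reactions
        if len(r.reactants) == 1 and r.kind == "immediate"
        and r.reactants[0] not in transloc
    ]
    binary_channels = [r for r in network.reactions if len(r.reactants) == 2]

    events: dict[str, list] = {key: [] for key in record}
    event_pos: dict[str, list] = {key: [] for key in record}

    n_steps = int(round(t_end / config.dt))
    times = [0.0]
    species_order = tuple(network.species)
    count_rows = [[len(world.positions.get(sp, ())) for sp in species_order]]

    for step in range(1, n_steps + 1):
        t = step * config.dt
        # --- stage 1: motion + membranes (+ translocation) -----------------
        for sp in list(world.positions):
            pos = world.positions[sp]
            if len(pos) == 0:
                continue
            D = config.diffusion.get(sp, 0.0)
            if D == 0.0:
                continue
            if sp in world.surface_species:
                proposed = brownian_step(pos, D, config.dt, rng)
                norms = np.linalg.norm(proposed, axis=1, keepdims=True)
                world.positions[sp] = geometry.cell_radius * proposed / norms
                continue
            sigma = math.sqrt(2.0 * D * CM2_TO_UM2 * config.dt)
            proposed = pos + _truncated_normal_steps(pos.shape, sigma, rng)
            target = transloc.get(sp)
            new_pos, crossed = _resolve_moves(
                pos, proposed, sp, geometry, rng, sigma,
                can_cross_nuclear=target is not None,
            )
            if target is not None and crossed.any():
                dst, rxn = target
                moved = new_pos[crossed]
                world.positions[dst] = _vstack(world.positions.get(dst), moved)
                key = rxn.display_name
                if key in events:
                    events[key].extend([t] * len(moved))
                    event_pos[key].append(moved)
                new_pos = new_pos[~crossed]
            world.positions[sp] = new_pos

        # --- stage 1b: unary conversions -----------------------------------
        for rxn in unary_conversions:
            src = rxn.reactants[0]
            pos = world.positions.get(src)
            if pos is None or len(pos) == 0:
                continue
            fired = rng.random(len(pos)) < -math.expm1(-rxn.rate_k * config.dt)
            if not fired.any():
                continue
            reacted = pos[fired]
            world.positions[src] = pos[~fired]
            for prod in rxn.products:
                world.positions[prod] = _vstack(world.positions.get(prod), reacted)
            key = rxn.display_name
            if key in events:
                events[key].extend([t] * len(reacted))
                event_pos[key].append(reacted)

        # --- stages 2 + 3: neighbour finding and binary reactions ----------
        for rxn in binary_channels:
            a, b = rxn.reactants
            pos_a = world.positions.get(a)
            if pos_a is None or len(pos_a) == 0:
                continue
            if rxn.is_dimerization:
                pairs = find_pairs(pos_a, config.cutoff_R, bin_size=config.bin_size)
                hits = react_pairs(pairs, config.channel_p(rxn), rng, self_pairs=True)
                if not hits:
                    continue
                ia = np.array([h[0] for h in hits])
                ib = np.array([h[1] for h in hits])
                midpoints = 0.5 * (pos_a[ia] + pos_a[ib])
                keep = np.ones(len(pos_a), dtype=bool)
                keep[ia] = keep[ib] = False
                world.positions[a] = pos_a[keep]
            else:
                pos_b = world.positions.get(b)
                if pos_b is None or len(pos_b) == 0:
                    continue
                pairs = find_pairs(pos_a, config.cutoff_R, positions_b=pos_b,
                                   bin_size=config.bin_size)
                hits = react_pairs(pairs, config.channel_p(rxn), rng)
                if not hits:
                    continue
                ia = np.array([h[0] for h in hits])
                ib = np.array([h[1] for h in hits])
                midpoints = 0.5 * (pos_a[ia] + pos_b[ib])
                keep_a = np.ones(len(pos_a), dtype=bool)
                keep_a[ia] = False
                keep_b = np.ones(len(pos_b), dtype=bool)
                keep_b[ib] = False
                world.positions[a] = pos_a[keep_a]
                world.positions[b] = pos_b[keep_b]
            for prod in rxn.products:
                world.positions[prod] = _vstack(world.positions.get(prod), midpoints)
            key = rxn.display_name
            if key in events:
                events[key].extend([t] * len(midpoints))
                event_pos[key].append(midpoints)

        if step % config.record_every == 0 or step == n_steps:
            times.append(t)
            count_rows.append([len(world.positions.get(sp, ())) for sp in species_order])

    traj = Trajectory(np.array(times), species_order,
                      np.array(count_rows, dtype=float), kind="step")
    records = {}
    for key in record:
        pos = np.vstack(event_pos[key]) if event_pos[key] else None
        n0 = _record_n_initial(key, network, n_initial)
        records[key] = ArrivalRecord(
            np.array(events[key]), n0, horizon=t_end, event=key, event_positions=pos
        )
    return traj, records


def _record_n_initial(key: str, network: ReactionNetwork, n_initial: dict) -> int:
    for rxn in network.reactions:
        if rxn.display_name == key:
            if len(rxn.reactants) == 1:
                return n_initial.get(rxn.reactants[0], 0)
            a, b = rxn.reactants
            if rxn.is_dimerization:
                return n_initial.get(a, 0) // 2
            return min(n_initial.get(a, 0), n_initial.get(b, 0))
    raise KeyError(f"recorded event {key!r} is not a channel of the network")


def _vstack(existing: Optional[np.ndarray], new: np.ndarray) -> np.ndarray:
    if existing is None or len(existing) == 0:
        return new.copy()
    return np.vstack([existing, new])
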