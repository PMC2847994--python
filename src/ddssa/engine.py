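"""Delay stochastic simulation algorithm with distribution-drawn delays.

The core engine extends the direct-method SSA in the Barrio style: delayed
reactions fire like ordinary channels but trigger their state change at a
scheduled future time.  If a scheduled completion falls inside the next
waiting time, the engine ignores the drawn waiting time and continues from
the completion instead.  All delayed reactions are *consuming*: reactants are
reserved at selection time (moved from the free pool to "in transit") and the
products are released at completion, so counts can never go negative.

Engine modes
------------
``ssa``
    Plain direct method; no delayed channels allowed.
``const``
    Constant-delay DSSA: each delayed channel uses a fixed delay.
``m1``
    Distributed delays: each delayed channel draws its delay from a tabulated
    CDF; delayed channels run at a deliberately large propensity constant so
    their waiting time is negligible against the sampled delays.
``m3``
    Delay-minimum selection: applicable when *every* channel is delayed.
    Propensities are abandoned; each feasible channel draws a delay and the
    minimum wins, its reactants are consumed and the completion scheduled.
    When nothing is feasible, time jumps to the next completion.

Orthogonal switches: ``enable_M2`` lets non-delayed channels poach reactants
that are already committed to (unary) delayed channels, cancelling the
scheduled translocation; ``window_rules`` (M4) restrict the inverse-transform
uniform for a channel during chosen time windows.

Two independent random streams are used: one for the SSA core (waiting times,
channel selection) and one for delay sampling.  This "draw discipline" makes
the core path invariant to how many delay draws a mode consumes, so a
degenerate delay distribution reproduces the constant-delay path exactly
under a shared seed.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .delays import DelayDistribution, DelayWindowRule, sample_delay
from .model import Reaction, ReactionNetwork, SpeciesRef, Trajectory

__all__ = [
    "EngineConfig",
    "DSSAEngine",
    "propensity",
    "run_m1",
    "run_m3",
    "run_ssa",
    "run_ensemble",
    "apply_window_rules",
]


@dataclass
class EngineConfig:
    """Run-time options for the delay-SSA engine."""

    mode: str = "m1"  # ssa | const | m1 | m3
    t_end: float = 100.0
    enable_M2: bool = False
    window_rules: Sequence[DelayWindowRule] = ()
    k_delayed_scale: float = 1e4
    seed: Optional[int] = None
    max_events: int = 50_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("ssa", "const", "m1", "m3"):
            raise ValueError(f"unknown engine mode {self.mode!r}")
        if self.enable_M2 and self.mode == "m3":
            raise ValueError("M2 poaching is only meaningful in propensity modes")
        if self.k_delayed_scale <= 0:
            raise ValueError("k_delayed_scale must be positive")


def apply_window_rules(
    rules: Sequence[DelayWindowRule], channel: str, now: float
) -> Optional[DelayWindowRule]:
    """The active window rule for ``channel`` at time ``now`` (or None).

    Overlapping active rules for one channel are a configuration error.
    """
    active = [r for r in rules if (r.channel is None or r.channel == channel) and r.active(now)]
    if len(active) > 1:
        raise ValueError(f"overlapping window rules for channel {channel!r} at t={now}")
    return active[0] if active else None


def propensity(
    reaction: Reaction,
    free: Mapping[SpeciesRef, int],
    in_transit: Optional[Mapping[SpeciesRef, int]] = None,
    k_delayed_scale: Optional[float] = None,
) -> float:
    """Mass-action propensity of one channel.

    Unary: a = k n; binary: a = k n1 n2, or k n (n - 1) / 2 for dimerization.
    Delayed channels count only the free pool and, unless the channel carries
    an explicit (tuned) rate constant, use ``k_delayed_scale``.  When
    ``in_transit`` is given (M2), non-delayed channels count free + in-transit
    molecules, since committed reactants remain poachable.
    """
    if reaction.kind == "delayed":
        k = reaction.rate_k if reaction.rate_k is not None else k_delayed_scale
        if k is None:
            raise ValueError("delayed channel needs rate_k or k_delayed_scale")
        pool = free
    else:
        k = reaction.rate_k
        if in_transit is not None:
            pool = {s: free.get(s, 0) + in_transit.get(s, 0)
                    for s in reaction.reactants}
        else:
            pool = free
    for s in reaction.reactants:
        if pool.get(s, 0) < 0:
            raise ValueError(f"negative count for {s.label}")
    if len(reaction.reactants) == 1:
        return k * pool.get(reaction.reactants[0], 0)
    a, b = reaction.reactants
    if a == b:
        n = pool.get(a, 0)
        return k * n * (n - 1) / 2.0
    return k * pool.get(a, 0) * pool.get(b, 0)


class _Pending:
    __slots__ = ("time", "channel", "reserved", "cancelled")

    def __init__(self, time, channel, reserved):
        self.time = time
        self.channel = channel
        self.reserved = reserved
        self.cancelled = False


class DSSAEngine:
    """One stochastic realisation of a (delayed) reaction network.

    ``delay_map`` resolves string-valued ``delay_source`` references on the
    network's channels to :class:`DelayDistribution` objects (or to floats,
    interpreted as constant delays).
    """

    def __init__(
        self,
        network: ReactionNetwork,
        init_counts: Mapping[SpeciesRef, int],
        config: EngineConfig,
        delay_map: Optional[Mapping[str, object]] = None,
    ):
        self.network = network
        self.config = config
        self.delay_map = dict(delay_map or {})
        self._validate()

        self.free = {s: int(init_counts.get(s, 0)) for s in network.species}
        self.in_transit = {s: 0 for s in network.species}
        self.t = 0.0
        self._heap: list[tuple[float, int, _Pending]] = []
        self._alive: dict[SpeciesRef, list[_Pending]] = {s: [] for s in network.species}
        self._seq = itertools.count()
        self._n_pending = 0

        seq = (config.seed if isinstance(config.seed, np.random.SeedSequence)
               else np.random.SeedSequence(config.seed))
        core_seed, delay_seed = seq.spawn(2)
        self.rng_core = np.random.default_rng(core_seed)
        self.rng_delay = np.random.default_rng(delay_seed)

        self._times = [0.0]
        self._rows = [self._observable_row()]

    # -- setup ---------------------------------------------------------------
    def _validate(self) -> None:
        cfg, net = self.config, self.network
        delayed = [net.reactions[i] for i in net.delayed_channels()]
        if cfg.mode == "ssa" and delayed:
            raise ValueError("SSA mode cannot run delayed channels")
        if cfg.mode == "m3" and len(delayed) != len(net.reactions):
            raise ValueError("M3 requires every channel to be delayed")
        if cfg.enable_M2:
            for rxn in delayed:
                if len(rxn.reactants) != 1:
                    raise ValueError(
                        "M2 poaching is only supported for unary delayed channels"
                    )

    def _resolve(self, rxn: Reaction) -> object:
        src = rxn.delay_source
        if isinstance(src, str):
            try:
                src = self.delay_map[src]
            except KeyError:
                raise KeyError(
                    f"channel {rxn.display_name} references unknown delay "
                    f"distribution {rxn.delay_source!r}"
                ) from None
        return src

    def _draw_delay(self, rxn: Reaction) -> float:
        src = self._resolve(rxn)
        if isinstance(src, (list, tuple)):
            # piecewise-in-time distributions: [((t_start, t_end), dist), ...];
            # the generalisation of window rules to full distribution switching
            for (t_start, t_stop), dist in src:
                if t_start <= self.t < t_stop:
                    src = dist
                    break
            else:
                raise ValueError(
                    f"no active piecewise delay distribution for "
                    f"{rxn.display_name} at t={self.t}")
        if self.config.mode == "const":
            if isinstance(src, DelayDistribution):
                if src.t_grid.size != 1:
                    raise ValueError("const mode needs constant (degenerate) delays")
                return float(src.t_grid[0])
            return float(src)
        if not isinstance(src, DelayDistribution):
            src = DelayDistribution.degenerate(float(src))
        window = apply_window_rules(self.config.window_rules, rxn.display_name, self.t)
        if src.arrival_mass < 1.0 and self.rng_delay.random() >= src.arrival_mass:
            return math.inf  # this molecule never performs the event
        return sample_delay(src, self.rng_delay, window=window, now=self.t)

    # -- bookkeeping ---------------------------------------------------------
    def _observable_row(self) -> list[int]:
        # in-transit molecules are still physically present (diffusing towards
        # their destination), so the observable count is free + in transit
        return [self.free[s] + self.in_transit[s] for s in self.network.species]

    def _record(self) -> None:
        if self.t > self._times[-1]:
            self._times.append(self.t)
            self._rows.append(self._observable_row())
        else:
            self._rows[-1] = self._observable_row()

    def _schedule(self, rxn: Reaction, delay: float) -> None:
        for s in rxn.reactants:
            self.free[s] -= 1
            if self.free[s] < 0:
                raise AssertionError("consumed a reactant that was not free")
        # an infinite delay is a non-arrival: the molecule stalls in transit
        # forever (still observable, still poachable) but never completes
        entry = _Pending(self.t + delay, rxn, rxn.reactants)
        for s in rxn.reactants:
            self.in_transit[s] += 1
            self._alive[s].append(entry)
        heapq.heappush(self._heap, (entry.time, next(self._seq), entry))
        self._n_pending += 1

    def _next_pending_time(self) -> float:
        while self._heap and self._heap[0][2].cancelled:
            heapq.heappop(self._heap)
        return self._heap[0][0] if self._heap else math.inf

    def _complete_next(self) -> None:
        while True:
            time, _, entry = heapq.heappop(self._heap)
            if not entry.cancelled:
                break
        self.t = time
        self._n_pending -= 1
        for s in entry.reserved:
            self.in_transit[s] -= 1
            self._alive[s].remove(entry)
        for s in entry.channel.products:
            self.free[s] += 1
        self._record()

    def _poach(self, species: SpeciesRef) -> None:
        """Cancel a uniformly random pending entry reserving ``species`` (M2)."""
        entries = self._alive[species]
        entry = entries[self.rng_core.integers(len(entries))]
        entry.cancelled = True
        self._n_pending -= 1
        for s in entry.reserved:
            self.in_transit[s] -= 1
            self._alive[s].remove(entry)

    def mass(self, weights: Mapping[SpeciesRef, float]) -> float:
        """Weighted species mass including in-transit molecules."""
        return sum(
            weights.get(s, 0.0) * (self.free[s] + self.in_transit[s])
            for s in self.network.species
        )

    # -- propensity-based stepping (ssa / const / m1) -------------------------
    def _propensities(self) -> np.ndarray:
        cfg = self.config
        it = self.in_transit if cfg.enable_M2 else None
        return np.array([
            propensity(r, self.free, in_transit=it, k_delayed_scale=cfg.k_delayed_scale)
            for r in self.network.reactions
        ])

    def dssa_step(self) -> bool:
        """One event of the propensity-driven DSSA; False when quiescent."""
        cfg = self.config
        a = self._propensities()
        a0 = float(a.sum())
        t_pending = self._next_pending_time()
        if a0 <= 0.0:
            if t_pending > cfg.t_end:
                return False
            self._complete_next()
            return True
        w = self.rng_core.exponential(1.0 / a0)
        if t_pending <= self.t + w:
            # a scheduled completion pre-empts the drawn waiting time
            if t_pending > cfg.t_end:
                return False
            self._complete_next()
            return True
        if self.t + w > cfg.t_end:
            return False
        self.t += w
        u = self.rng_core.random() * a0
        j = int(np.searchsorted(np.cumsum(a), u, side="right"))
        j = min(j, len(a) - 1)
        rxn = self.network.reactions[j]
        if rxn.kind == "delayed":
            delay = self._draw_delay(rxn)
            self._schedule(rxn, delay)
        else:
            for s in rxn.reactants:
                n_free, n_transit = self.free[s], self.in_transit[s]
                if cfg.enable_M2 and n_transit > 0 and (
                    n_free == 0
                    or self.rng_core.random() < n_transit / (n_free + n_transit)
                ):
                    # the non-delayed reaction poaches an in-transit molecule:
                    # the scheduled translocation is cancelled and replaced
                    self._poach(s)
                else:
                    self.free[s] -= 1
                    if self.free[s] < 0:
                        raise AssertionError("negative free count")
            for s in rxn.products:
                self.free[s] += 1
        self._record()
        return True

    # -- delay-minimum stepping (m3) ------------------------------------------
    def _feasible_delayed(self) -> list[int]:
        out = []
        for j, rxn in enumerate(self.network.reactions):
            need: dict[SpeciesRef, int] = {}
            for s in rxn.reactants:
                need[s] = need.get(s, 0) + 1
            if all(self.free.get(s, 0) >= c for s, c in need.items()):
                out.append(j)
        return out

    def m3_round(self) -> bool:
        """One M3 selection round or pending-queue advance; False when done."""
        cfg = self.config
        feasible = self._feasible_delayed()
        if not feasible:
            t_pending = self._next_pending_time()
            if t_pending > cfg.t_end:
                return False
            self._complete_next()
            return True
        best_j, best_delay = feasible[0], math.inf
        for j in feasible:  # fresh draws every round; ties -> lowest index
            delay = self._draw_delay(self.network.reactions[j])
            if delay < best_delay:
                best_j, best_delay = j, delay
        # if every feasible channel drew a non-arrival, the lowest-index one
        # stalls its reactants (consumed, never completing)
        self._schedule(self.network.reactions[best_j], best_delay)
        return True

    # -- drivers ---------------------------------------------------------------
    def run(self) -> Trajectory:
        step = self.m3_round if self.config.mode == "m3" else self.dssa_step
        for _ in range(self.config.max_events):
            if not step():
                break
        else:  # pragma: no cover - safety valve
            raise RuntimeError("event budget exhausted before t_end")
        if self._times[-1] < self.config.t_end:
            self._times.append(self.config.t_end)
            self._rows.append(self._observable_row())
        return Trajectory(
            np.array(self._times), tuple(self.network.species),
            np.array(self._rows, dtype=float), kind="step",
        )


def _run(network, init, config, delay_map=None) -> Trajectory:
    return DSSAEngine(network, init, config, delay_map).run()


def run_m1(network, init, config: EngineConfig, delay_map=None) -> Trajectory:
    """Propensity-driven dDSSA with distribution-drawn delays (M1, +M2/M4)."""
    if config.mode not in ("m1", "const", "ssa"):
        raise ValueError("run_m1 drives the propensity-based modes")
    return _run(network, init, config, delay_map)


def run_m3(network, init, config: EngineConfig, delay_map=None) -> Trajectory:
    """Delay-minimum dDSSA (M3, +M4); every channel must be delayed."""
    if config.mode != "m3":
        config = EngineConfig(**{**config.__dict__, "mode": "m3"})
    return _run(network, init, config, delay_map)


def run_ssa(network, init, t_end, seed=None) -> Trajectory:
    """Plain direct-method SSA (no delays)."""
    return _run(network, init, EngineConfig(mode="ssa", t_end=t_end, seed=seed))


def run_ensemble(
    network,
    init,
    config: EngineConfig,
    runs: int,
    grid: np.ndarray,
    delay_map=None,
) -> tuple[Trajectory, list[Trajectory]]:
    """``runs`` independent realisations; returns (mean-on-grid, paths).

    Per-run seeds are spawned from ``config.seed`` so the ensemble is
    reproducible as a whole.
    """
    from .model import resample_trajectory

    seq = (config.seed if isinstance(config.seed, np.random.SeedSequence)
           else np.random.SeedSequence(config.seed))
    children = seq.spawn(runs)
    paths = []
    acc = np.zeros((len(grid), len(network.species)))
    for child in children:
        cfg = EngineConfig(**{**config.__dict__, "seed": child})
        traj = _run(network, init, cfg, delay_map)
        paths.append(traj)
        acc += resample_trajectory(traj, grid).values
    mean = Trajectory(np.asarray(grid, float), tuple(network.species),
                      acc / runs, kind="linear")
    return mean, paths
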