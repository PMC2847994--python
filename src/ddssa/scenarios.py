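"""Registry of the ten benchmark reaction-diffusion scenarios.

Scenarios 1-9 live in a spherical cell (cytosol shell around a nucleus) and
combine nuclear/cytosolic translocations with unary and binary reactions;
Scenario 10 is purely well-mixed (two competing unary channels driven by
delay distributions).  Each scenario carries a *delay-splitting plan*: the
ordered recipe for generating one delay distribution per delayed channel
from separate, inexpensive spatial (or SSA) runs --

``arrival``
    run the isolated translocation sub-process from the scenario's initial
    placement and record first-passage times;
``frozen_replay``
    seed the reactant at the positions recorded for an upstream event (e.g.
    nuclear-entry coordinates), let it diffuse and react with its partner,
    and record the event times;
``timecourse``
    read the event CDF off a monotone species time course of the full run;
``ssa_mean``
    infer the CDF from the mean SSA time course of the isolated well-mixed
    channel.

The resulting map {label -> DelayDistribution} plugs straight into the
delay-SSA engine via the channels' ``delay_source`` labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .delays import DelayDistribution, cdf_from_ssa_mean, empirical_cdf
from .engine import EngineConfig, run_ensemble
from .model import (Reaction, ReactionNetwork, SpeciesRef, Trajectory,
                    build_network, resample_trajectory)
from .particles import (ArrivalRecord, ParticleSimConfig, ParticleWorld,
                        SphericalGeometry, run_particle_sim)

__all__ = [
    "Scenario",
    "SplitPlanStep",
    "make_scenario",
    "run_delay_splitting",
    "total_relative_error",
    "compare_engines",
]


def _sp(label: str) -> SpeciesRef:
    name, _, comp = label.rpartition("_")
    return SpeciesRef(name, comp) if name else SpeciesRef(label)


@dataclass
class SplitPlanStep:
    """How to generate one delay distribution (tau label) for one channel."""

    label: str                    # tau1, tau2, ...
    kind: str                     # arrival | frozen_replay | timecourse | ssa_mean
    channel: str                  # display name of the channel this CDF feeds
    seed_from: Optional[str] = None   # label/channel whose event positions seed a replay
    partners: dict = field(default_factory=dict)  # extra species -> count in replay
    ssa_rate: Optional[float] = None  # ssa_mean: isolated unary rate constant
    monitor: Optional[SpeciesRef] = None  # timecourse: species to read the CDF from


@dataclass
class Scenario:
    """One benchmark configuration: network, geometry, placement, plan."""

    id: int
    network: ReactionNetwork
    init_counts: dict
    geometry: Optional[SphericalGeometry]
    placements: dict
    diffusion: dict               # SpeciesRef -> D in cm^2/s
    split_plan: list
    t_end: float = 500.0
    dt: float = 1e-3
    cutoff_R: float = 0.1
    reaction_p: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        planned = {step.channel for step in self.split_plan}
        for rxn in self.network.reactions:
            if rxn.kind == "delayed" and rxn.display_name not in planned:
                raise ValueError(
                    f"delayed channel {rxn.display_name} has no delay-splitting step"
                )
        labels = [s.label for s in self.split_plan]
        if len(set(labels)) != len(labels):
            raise ValueError("delay-splitting labels must be unique")

    def particle_config(self, seed=None, **overrides) -> ParticleSimConfig:
        kw = dict(dt=self.dt, diffusion=dict(self.diffusion),
                  cutoff_R=self.cutoff_R, reaction_p=dict(self.reaction_p),
                  seed=seed)
        kw.update(overrides)
        return ParticleSimConfig(**kw)

    def build_world(self, rng) -> ParticleWorld:
        return ParticleWorld.build(self.geometry, self.placements,
                                   self.init_counts, rng)

    def delayed_labels(self) -> dict:
        """Map channel display name -> delay_source label."""
        return {r.display_name: r.delay_source for r in self.network.reactions
                if r.kind == "delayed"}


# --------------------------------------------------------------------------
# scenario construction

_D_FAST, _D_SLOW = 1e-7, 1e-9  # cm^2/s
_CLUSTER = ("cluster", 7.0, 0.5)


def make_scenario(scenario_id: int, **overrides) -> Scenario:
    """Build scenario 1-10 with its published defaults.

    Common overrides: ``n_a``/``n_b``/``n_d`` initial counts, ``diffusion``
    (dict of SpeciesRef -> cm^2/s merged over the defaults), ``clustered``
    (bool; whether A_c starts in the 0.5 um cluster 7 um from the centre),
    ``tuned_k`` (explicit rate for the dominant association channel,
    Scenario 6), ``k1``/``k2`` (Scenario 10), ``t_end``, ``dt``,
    ``geometry``.
    """
    build = _BUILDERS.get(scenario_id)
    if build is None:
        raise ValueError(f"unknown scenario id {scenario_id!r} (valid: 1..10)")
    return build(**overrides)


def _geometry(overrides) -> SphericalGeometry:
    return overrides.pop("geometry", None) or SphericalGeometry()


def _common(overrides):
    return {k: overrides.pop(k) for k in ("t_end", "dt", "cutoff_R")
            if k in overrides}


def _merge_diffusion(default: dict, overrides) -> dict:
    extra = overrides.pop("diffusion", {})
    return {**default, **extra}


def _sc1(**ov) -> Scenario:
    a_c, a_n = _sp("A_c"), _sp("A_n")
    n_a = ov.pop("n_a", 1000)
    clustered = ov.pop("clustered", True)
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion({a_c: _D_FAST, a_n: _D_SLOW}, ov)
    transloc = Reaction((a_c,), (a_n,), kind="delayed", delay_source="tau1")
    net = build_network([a_c, a_n], [transloc])
    return Scenario(
        id=1, network=net, init_counts={a_c: n_a, a_n: 0}, geometry=geometry,
        placements={a_c: _CLUSTER if clustered else ("uniform", "c")},
        diffusion=diffusion,
        split_plan=[SplitPlanStep("tau1", "arrival", transloc.display_name)],
        description="nuclear translocation of clustered A_c",
        **common,
    )


def _sc2(**ov) -> Scenario:
    k = ov.pop("k", 0.1)
    sc = _sc1(**ov)
    b_n = _sp("B_n")
    decay = Reaction((_sp("A_n"),), (b_n,), rate_k=k)
    net = build_network([*sc.network.species, b_n], [*sc.network.reactions, decay])
    return replace(sc, id=2, network=net,
                   init_counts={**sc.init_counts, b_n: 0},
                   description="translocation followed by nuclear conversion A_n -> B_n")


def _sc3(**ov) -> Scenario:
    k = ov.pop("k", 0.1)
    sc = _sc1(**ov)
    b_c = _sp("B_c")
    decay = Reaction((_sp("A_c"),), (b_c,), rate_k=k)
    net = build_network([*sc.network.species, b_c], [*sc.network.reactions, decay])
    return replace(sc, id=3, network=net,
                   init_counts={**sc.init_counts, b_c: 0},
                   description="translocation competing with cytosolic A_c -> B_c (M2)")


def _sc4(**ov) -> Scenario:
    a_c, a_n, b_n, c_n = map(_sp, ("A_c", "A_n", "B_n", "C_n"))
    n_a = ov.pop("n_a", 1000)
    n_b = ov.pop("n_b", 1000)
    clustered = ov.pop("clustered", True)
    assoc_k = ov.pop("tuned_k", None)
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion(
        {a_c: _D_FAST, a_n: _D_FAST, b_n: 0.0, c_n: _D_SLOW}, ov)
    transloc = Reaction((a_c,), (a_n,), kind="delayed", delay_source="tau1")
    assoc = Reaction((a_n, b_n), (c_n,), rate_k=assoc_k, kind="delayed",
                     delay_source="tau2")
    net = build_network([a_c, a_n, b_n, c_n], [transloc, assoc])
    return Scenario(
        id=4, network=net,
        init_counts={a_c: n_a, a_n: 0, b_n: n_b, c_n: 0},
        geometry=geometry,
        placements={a_c: _CLUSTER if clustered else ("uniform", "c"),
                    b_n: ("uniform", "n")},
        diffusion=diffusion,
        split_plan=[
            SplitPlanStep("tau1", "arrival", transloc.display_name),
            SplitPlanStep("tau2", "frozen_replay", assoc.display_name,
                          seed_from="tau1", partners={b_n: n_b}),
        ],
        description="translocation followed by nuclear association A_n + B_n -> C_n",
        **common,
    )


def _sc5(**ov) -> Scenario:
    deterministic_profile = ov.pop("deterministic_profile", False)
    if deterministic_profile:
        # diffusion profile of the deterministic-model comparison
        ov.setdefault("diffusion", {})
        ov["diffusion"] = {**{_sp("A_c"): _D_FAST, _sp("A_n"): _D_FAST,
                              _sp("B_n"): 0.0, _sp("C_n"): _D_FAST},
                           **ov["diffusion"]}
    else:
        ov.setdefault("diffusion", {})
        ov["diffusion"] = {**{_sp("A_c"): _D_FAST, _sp("A_n"): _D_SLOW,
                              _sp("B_n"): _D_SLOW, _sp("C_n"): _D_SLOW},
                           **ov["diffusion"]}
    sc = _sc4(**ov)
    c_n, c_c = _sp("C_n"), _sp("C_c")
    out = Reaction((c_n,), (c_c,), kind="delayed", delay_source="tau3")
    net = build_network([*sc.network.species, c_c], [*sc.network.reactions, out])
    assoc_name = sc.split_plan[1].channel
    plan = [*sc.split_plan,
            SplitPlanStep("tau3", "frozen_replay", out.display_name,
                          seed_from="tau2")]
    return replace(sc, id=5, network=net,
                   init_counts={**sc.init_counts, c_c: 0}, split_plan=plan,
                   diffusion={**sc.diffusion, c_c: sc.diffusion[c_n]},
                   description="translocation, association, product export "
                               f"(assoc channel {assoc_name})")


def _sc6(**ov) -> Scenario:
    a_c, d_c, a_n, d_n, b_n, c_n, e_n = map(
        _sp, ("A_c", "D_c", "A_n", "D_n", "B_n", "C_n", "E_n"))
    n_a = ov.pop("n_a", 1000)
    n_d = ov.pop("n_d", 1000)
    n_b = ov.pop("n_b", 1000)
    clustered = ov.pop("clustered", False)
    tuned_k = ov.pop("tuned_k", None)  # 0.015 in the tuned configuration
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion(
        {s: _D_SLOW for s in (a_c, d_c, a_n, d_n, b_n)} | {c_n: 0.0, e_n: 0.0},
        ov)
    t_a = Reaction((a_c,), (a_n,), kind="delayed", delay_source="tau1")
    t_d = Reaction((d_c,), (d_n,), kind="delayed", delay_source="tau2")
    assoc_a = Reaction((a_n, b_n), (c_n,), rate_k=tuned_k, kind="delayed",
                       delay_source="tau3")
    assoc_d = Reaction((d_n, b_n), (e_n,), kind="delayed", delay_source="tau4")
    net = build_network([a_c, d_c, a_n, d_n, b_n, c_n, e_n],
                        [t_a, t_d, assoc_a, assoc_d])
    return Scenario(
        id=6, network=net,
        init_counts={a_c: n_a, d_c: n_d, b_n: n_b,
                     a_n: 0, d_n: 0, c_n: 0, e_n: 0},
        geometry=geometry,
        placements={a_c: _CLUSTER if clustered else ("uniform", "c"),
                    d_c: ("uniform", "c"), b_n: ("uniform", "n")},
        diffusion=diffusion,
        split_plan=[
            SplitPlanStep("tau1", "arrival", t_a.display_name),
            SplitPlanStep("tau2", "arrival", t_d.display_name),
            SplitPlanStep("tau3", "frozen_replay", assoc_a.display_name,
                          seed_from="tau1", partners={b_n: n_b}),
            SplitPlanStep("tau4", "frozen_replay", assoc_d.display_name,
                          seed_from="tau2", partners={b_n: n_b}),
        ],
        description="A_n and D_n competing for the common partner B_n",
        **common,
    )


def _sc7(**ov) -> Scenario:
    a_n, a_c, a2 = _sp("A_n"), _sp("A_c"), _sp("A2_c")
    n_a = ov.pop("n_a", 1000)
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion({a_n: _D_SLOW, a_c: _D_FAST, a2: _D_FAST}, ov)
    out = Reaction((a_n,), (a_c,), kind="delayed", delay_source="tau1")
    dimer = Reaction((a_c, a_c), (a2,), kind="delayed", delay_source="tau2")
    net = build_network([a_n, a_c, a2], [out, dimer])
    return Scenario(
        id=7, network=net, init_counts={a_n: n_a, a_c: 0, a2: 0},
        geometry=geometry, placements={a_n: ("uniform", "n")},
        diffusion=diffusion,
        split_plan=[
            SplitPlanStep("tau1", "arrival", out.display_name),
            SplitPlanStep("tau2", "frozen_replay", dimer.display_name,
                          seed_from="tau1"),
        ],
        description="nuclear export followed by cytosolic dimerization",
        **common,
    )


def _sc8(**ov) -> Scenario:
    a_n, a_c, b_c, c_c = map(_sp, ("A_n", "A_c", "B_c", "C_c"))
    n_a = ov.pop("n_a", 1000)
    n_b = ov.pop("n_b", 1000)
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion(
        {a_n: _D_SLOW, a_c: _D_FAST, b_c: _D_SLOW, c_c: _D_FAST}, ov)
    out = Reaction((a_n,), (a_c,), kind="delayed", delay_source="tau1")
    bind = Reaction((a_c, b_c), (c_c,), kind="delayed", delay_source="tau2")
    net = build_network([a_n, a_c, b_c, c_c], [out, bind])
    return Scenario(
        id=8, network=net,
        init_counts={a_n: n_a, a_c: 0, b_c: n_b, c_c: 0},
        geometry=geometry,
        placements={a_n: ("uniform", "n"), b_c: ("membrane",)},
        diffusion=diffusion,
        split_plan=[
            SplitPlanStep("tau1", "arrival", out.display_name),
            SplitPlanStep("tau2", "frozen_replay", bind.display_name,
                          seed_from="tau1", partners={b_c: n_b}),
        ],
        description="nuclear export followed by binding to a membrane species",
        **common,
    )


def _sc9(**ov) -> Scenario:
    a_c, a_n, b_c, c_c, c_n = map(_sp, ("A_c", "A_n", "B_c", "C_c", "C_n"))
    n_a = ov.pop("n_a", 1000)
    n_b = ov.pop("n_b", 500)
    geometry = _geometry(ov)
    common = _common(ov)
    diffusion = _merge_diffusion(
        {a_c: _D_FAST, b_c: _D_FAST, c_c: _D_FAST, a_n: _D_SLOW, c_n: _D_SLOW},
        ov)
    transloc = Reaction((a_c,), (a_n,), kind="delayed", delay_source="tau1")
    bind = Reaction((a_c, b_c), (c_c,), kind="delayed", delay_source="tau2")
    c_in = Reaction((c_c,), (c_n,), kind="delayed", delay_source="tau3")
    net = build_network([a_c, a_n, b_c, c_c, c_n], [transloc, bind, c_in])
    return Scenario(
        id=9, network=net,
        init_counts={a_c: n_a, b_c: n_b, a_n: 0, c_c: 0, c_n: 0},
        geometry=geometry,
        placements={a_c: ("uniform", "c"), b_c: ("uniform", "c")},
        diffusion=diffusion,
        split_plan=[
            SplitPlanStep("tau1", "arrival", transloc.display_name),
            SplitPlanStep("tau2", "timecourse", bind.display_name, monitor=b_c),
            SplitPlanStep("tau3", "frozen_replay", c_in.display_name,
                          seed_from=bind.display_name),
        ],
        description="translocation competing with association; product re-enters",
        **common,
    )


def _sc10(**ov) -> Scenario:
    a, b, c = _sp("A"), _sp("B"), _sp("C")
    n_a = ov.pop("n_a", 1000)
    k1 = ov.pop("k1", 1e-1)
    k2 = ov.pop("k2", 1.0)
    common = _common(ov)
    r1 = Reaction((a,), (b,), kind="delayed", delay_source="tau1")
    r2 = Reaction((a,), (c,), kind="delayed", delay_source="tau2")
    net = build_network([a, b, c], [r1, r2])
    return Scenario(
        id=10, network=net, init_counts={a: n_a, b: 0, c: 0},
        geometry=None, placements={}, diffusion={},
        split_plan=[
            SplitPlanStep("tau1", "ssa_mean", r1.display_name, ssa_rate=k1),
            SplitPlanStep("tau2", "ssa_mean", r2.display_name, ssa_rate=k2),
        ],
        description=f"competing well-mixed channels via delay minima (k1={k1}, k2={k2})",
        **common,
    )


_BUILDERS = {1: _sc1, 2: _sc2, 3: _sc3, 4: _sc4, 5: _sc5,
             6: _sc6, 7: _sc7, 8: _sc8, 9: _sc9, 10: _sc10}


# --------------------------------------------------------------------------
# delay splitting

def _isolated_translocation_network(scenario: Scenario, channel: str):
    """Sub-network containing only the named unary translocation channel."""
    for rxn in scenario.network.reactions:
        if rxn.display_name == channel:
            return build_network(list({*rxn.reactants, *rxn.products}), [rxn]), rxn
    raise KeyError(channel)


def run_delay_splitting(
    scenario: Scenario,
    seed: int = 0,
    t_split: Optional[Mapping[str, float]] = None,
    ssa_runs: int = 20,
    out_dir=None,
) -> tuple[dict, dict]:
    """Execute the scenario's delay-splitting plan.

    Returns ``(delay_map, records)``: the distributions keyed by their tau
    labels (ready to pass to the engines) and the intermediate
    :class:`ArrivalRecord`/trajectory artifacts keyed the same way.
    ``t_split`` optionally overrides the horizon per label (default: the
    scenario's ``t_end``); ``out_dir`` persists each distribution as
    ``<label>.csv`` plus a JSON metadata sidecar.
    """
    rng = np.random.default_rng(seed)
    t_split = dict(t_split or {})
    delay_map: dict[str, DelayDistribution] = {}
    records: dict[str, object] = {}

    needs_full = any(step.kind == "timecourse" for step in scenario.split_plan)
    full_traj = full_records = None
    if needs_full:
        record_keys = [s.channel for s in scenario.split_plan
                       if s.kind in ("timecourse",)]
        seed_keys = [s.seed_from for s in scenario.split_plan
                     if s.seed_from and s.seed_from not in
                     [p.label for p in scenario.split_plan]]
        cfg = scenario.particle_config(seed=int(rng.integers(2**31 - 1)))
        world = scenario.build_world(rng)
        full_traj, full_records = run_particle_sim(
            world, scenario.network, cfg,
            t_end=max(t_split.values(), default=scenario.t_end),
            record=list({*record_keys, *seed_keys}), rng=rng,
        )
        records["full_run"] = (full_traj, full_records)

    for step in scenario.split_plan:
        horizon = t_split.get(step.label, scenario.t_end)
        if step.kind == "arrival":
            net, rxn = _isolated_translocation_network(scenario, step.channel)
            src = rxn.reactants[0]
            cfg = scenario.particle_config(seed=int(rng.integers(2**31 - 1)))
            world = ParticleWorld.build(
                scenario.geometry,
                {src: scenario.placements.get(src, ("uniform", src.compartment))},
                {src: scenario.init_counts[src]}, rng)
            _, recs = run_particle_sim(world, net, cfg, t_end=horizon,
                                       record=[step.channel], rng=rng)
            rec = recs[step.channel]
        elif step.kind == "frozen_replay":
            rec = _frozen_replay(scenario, step, records, full_records,
                                 horizon, rng)
        elif step.kind == "timecourse":
            dist = cdf_from_ssa_mean(full_traj, step.monitor)
            delay_map[step.label] = dist
            records[step.label] = full_records.get(step.channel)
            continue
        elif step.kind == "ssa_mean":
            dist = _ssa_mean_distribution(scenario, step, ssa_runs, rng)
            delay_map[step.label] = dist
            records[step.label] = None
            continue
        else:
            raise ValueError(f"unknown split-plan step kind {step.kind!r}")
        if rec.n_events == 0:
            raise RuntimeError(
                f"delay-splitting step {step.label} recorded no events "
                f"(horizon {horizon} s too short?)")
        delay_map[step.label] = empirical_cdf(rec)
        records[step.label] = rec
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, dist in delay_map.items():
            dist.to_csv(out_dir / f"{label}.csv")
    return delay_map, records


def _frozen_replay(scenario, step, records, full_records, horizon, rng):
    """Replay a downstream event from recorded upstream event positions."""
    upstream = records.get(step.seed_from)
    if upstream is None and full_records is not None:
        upstream = full_records.get(step.seed_from)
    if upstream is None or upstream.event_positions is None:
        raise RuntimeError(
            f"step {step.label} needs recorded positions from {step.seed_from!r}")
    for rxn in scenario.network.reactions:
        if rxn.display_name == step.channel:
            break
    else:
        raise KeyError(step.channel)
    seeded = rxn.reactants[0]
    species = list({*rxn.reactants, *rxn.products})
    net = build_network(species, [rxn])
    counts = {seeded: len(upstream.event_positions)}
    placements = {}
    for partner, n in step.partners.items():
        counts[partner] = n
        placements[partner] = scenario.placements.get(
            partner, ("uniform", partner.compartment))
    world = ParticleWorld.build(scenario.geometry, placements, counts, rng)
    world.positions[seeded] = np.array(upstream.event_positions, dtype=float)
    if scenario.placements.get(rxn.reactants[-1], ("",))[0] == "membrane":
        world.surface_species.add(rxn.reactants[-1])
    cfg = scenario.particle_config(seed=int(rng.integers(2**31 - 1)))
    _, recs = run_particle_sim(world, net, cfg, t_end=horizon,
                               record=[step.channel], rng=rng)
    return recs[step.channel]


def _ssa_mean_distribution(scenario, step, ssa_runs, rng):
    """CDF of a well-mixed unary channel from the mean of isolated SSA runs."""
    a = _sp("A")
    x = _sp("X")
    n0 = scenario.init_counts[_sp("A")]
    k = step.ssa_rate
    net = build_network([a, x], [Reaction((a,), (x,), rate_k=k)])
    t_end = 10.0 / k  # survival ~ e^-10: the decay has essentially completed
    grid = np.linspace(0.0, t_end, 1000)
    cfg = EngineConfig(mode="ssa", t_end=t_end,
                       seed=np.random.SeedSequence(int(rng.integers(2**31 - 1))))
    mean, _ = run_ensemble(net, {a: n0, x: 0}, cfg, runs=ssa_runs, grid=grid)
    return cdf_from_ssa_mean(mean, a)


# --------------------------------------------------------------------------
# comparison metrics and orchestration

def total_relative_error(
    traj_a: Trajectory,
    traj_b: Trajectory,
    grid: np.ndarray,
    species: Optional[Sequence[SpeciesRef]] = None,
) -> np.ndarray:
    """e(t) = sum_s |A_s(t) - B_s(t)| / N_total(t) on the common grid.

    ``N_total`` is the total molecule count of the reference ``traj_a`` at
    each grid time; restricting ``species`` restricts both the numerator and
    the comparison (the denominator stays the full system size).
    """
    keys = species if species is not None else traj_a.species
    missing = [s for s in keys if s not in traj_b.species]
    if missing:
        raise ValueError(f"species missing from second trajectory: {missing}")
    a = resample_trajectory(traj_a, grid)
    b = resample_trajectory(traj_b, grid)
    diff = sum(np.abs(a.column(s) - b.column(s)) for s in keys)
    total = a.values.sum(axis=1)
    total = np.where(total > 0, total, 1.0)
    return diff / total


def compare_engines(
    scenario: Scenario,
    engines: Sequence[str],
    runs: int = 10,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    delay_map: Optional[dict] = None,
    particle_runs: int = 1,
    t_split: Optional[dict] = None,
    engine_kwargs: Optional[dict] = None,
    out_dir=None,
    plots: bool = False,
) -> dict:
    """Run the particle reference and the requested temporal engines.

    ``engines`` may contain ``"particle"``, ``"m1"``, ``"m1+m2"``, ``"m3"``,
    ``"ssa"``.  Returns a report dict with the mean trajectory per engine and
    the per-time total relative error against the reference (the particle
    mean when present, else the first engine).  Inapplicable engines are
    reported under ``"errors"`` rather than silently skipped.
    """
    if grid is None:
        grid = np.linspace(0.0, scenario.t_end, 201)
    rng = np.random.default_rng(seed)
    engine_kwargs = engine_kwargs or {}
    report: dict = {"scenario": scenario.id, "means": {}, "error": {},
                    "errors": {}, "grid": grid}
    if not engines:
        return report

    needs_delays = any(e in ("m1", "m1+m2", "m3", "const") for e in engines)
    if needs_delays and delay_map is None:
        delay_map, _ = run_delay_splitting(
            scenario, seed=int(rng.integers(2**31 - 1)), t_split=t_split)
    report["delay_map"] = delay_map

    for name in engines:
        try:
            if name == "particle":
                acc = np.zeros((grid.size, len(scenario.network.species)))
                for _ in range(particle_runs):
                    cfg = scenario.particle_config(seed=int(rng.integers(2**31 - 1)))
                    world = scenario.build_world(rng)
                    traj, _ = run_particle_sim(world, scenario.network, cfg,
                                               t_end=float(grid[-1]), rng=rng)
                    acc += resample_trajectory(traj, grid).values
                mean = Trajectory(grid, tuple(scenario.network.species),
                                  acc / particle_runs, kind="linear")
            else:
                mode = {"m1": "m1", "m1+m2": "m1", "m3": "m3",
                        "ssa": "ssa", "const": "const"}[name]
                cfg = EngineConfig(
                    mode=mode, t_end=float(grid[-1]),
                    enable_M2=(name == "m1+m2"),
                    seed=np.random.SeedSequence(int(rng.integers(2**31 - 1))),
                    **engine_kwargs)
                mean, _ = run_ensemble(scenario.network, scenario.init_counts,
                                       cfg, runs=runs, grid=grid,
                                       delay_map=delay_map)
            report["means"][name] = mean
        except (ValueError, KeyError, RuntimeError) as exc:
            report["errors"][name] = str(exc)

    ref_name = "particle" if "particle" in report["means"] else next(
        iter(report["means"]), None)
    if ref_name is not None:
        ref = report["means"][ref_name]
        for name, mean in report["means"].items():
            if name != ref_name:
                report["error"][name] = total_relative_error(ref, mean, grid)
    if out_dir is not None:
        _write_report(report, scenario, out_dir, runs, seed, plots)
    return report


def _write_report(report, scenario, out_dir, runs, seed, plots) -> None:
    """Persist a comparison report: mean/error CSVs, provenance, optional plots."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, mean in report["means"].items():
        mean.to_csv(out_dir / f"mean_{name.replace('+', '_')}.csv")
    if report["error"]:
        import pandas as pd

        err = pd.DataFrame({"time": report["grid"]})
        for name, series in report["error"].items():
            err[name] = series
        err.to_csv(out_dir / "total_relative_error.csv", index=False)
    provenance = {
        "scenario": scenario.id, "runs": runs, "seed": seed,
        "t_end": scenario.t_end, "dt": scenario.dt,
        "engines": sorted(report["means"]),
        "inapplicable": report["errors"],
        "initial_counts": {s.label: n for s, n in scenario.init_counts.items()},
        "diffusion_cm2_s": {s.label: d for s, d in scenario.diffusion.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for name, mean in report["means"].items():
            for s in mean.species:
                axes[0].plot(mean.times, mean.column(s),
                             label=f"{name}:{s.label}", alpha=0.7)
        axes[0].set_xlabel("time [s]")
        axes[0].set_ylabel("molecules")
        axes[0].legend(fontsize=6)
        for name, series in report["error"].items():
            axes[1].plot(report["grid"], series, label=name)
        axes[1].set_xlabel("time [s]")
        axes[1].set_ylabel("total relative error")
        axes[1].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "comparison.png", dpi=120)
        plt.close(fig)
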