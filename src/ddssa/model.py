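"""Shared domain types: species, reactions, networks, states and trajectories.

Compartments are encoded in the species themselves: the same biological
molecule in the cytosol and in the nucleus is two distinct :class:`SpeciesRef`
values (``A_c`` vs ``A_n``).  Translocation between compartments is then an
ordinary unary reaction channel, which is what lets purely temporal engines
absorb spatial transport into a delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRef",
    "Reaction",
    "ReactionNetwork",
    "PendingEntry",
    "SystemState",
    "Trajectory",
    "build_network",
    "resample_trajectory",
    "parse_species",
    "network_from_dict",
    "network_to_dict",
    "load_network",
]


@dataclass(frozen=True, order=True)
class SpeciesRef:
    """A chemical species tagged with the compartment it lives in.

    ``compartment`` is a short label such as ``"c"`` (cytosol), ``"n"``
    (nucleus) or ``"m"`` (membrane); the empty string means "no compartment
    structure" (well-mixed models such as Scenario 10's ``A -> B``/``A -> C``).
    """

    name: str
    compartment: str = ""

    @property
    def label(self) -> str:
        return f"{self.name}_{self.compartment}" if self.compartment else self.name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class Reaction:
    """One reaction channel, immediate or delayed.

    Delayed channels carry a ``delay_source`` (a :class:`~ddssa.delays.DelayDistribution`
    or a string key resolved by the caller) and are always *consuming*:
    reactants leave the free pool when the channel fires and the products
    appear only at the scheduled completion time.  This is what keeps counts
    non-negative when other channels compete for the same reactants while a
    delayed event is in transit.

    ``rate_k`` is the stochastic propensity constant: s^-1 for unary channels,
    molecule^-1 s^-1 for binary ones.  For delayed channels under the
    high-rate discipline (M1) the engine substitutes its own large constant
    unless ``rate_k`` is given explicitly (rate tuning, e.g. Scenario 6).
    """

    reactants: tuple[SpeciesRef, ...]
    products: tuple[SpeciesRef, ...]
    rate_k: Optional[float] = None
    kind: Literal["immediate", "delayed"] = "immediate"
    delay_source: object = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError(
                f"reaction channels are unary or binary, got {len(self.reactants)} reactants"
            )
        if self.kind == "immediate":
            if self.delay_source is not None:
                raise ValueError("immediate reactions cannot carry a delay_source")
            if self.rate_k is None:
                raise ValueError("immediate reactions need a rate constant")
        elif self.kind == "delayed":
            if self.delay_source is None:
                raise ValueError("delayed reactions need a delay_source")
        else:
            raise ValueError(f"unknown reaction kind {self.kind!r}")

    @property
    def consuming(self) -> bool:
        """All delayed reactions are consuming; immediate ones complete instantly."""
        return self.kind == "delayed"

    @property
    def is_dimerization(self) -> bool:
        return len(self.reactants) == 2 and self.reactants[0] == self.reactants[1]

    @property
    def display_name(self) -> str:
        if self.name:
            return self.name
        lhs = "+".join(s.label for s in self.reactants)
        rhs = "+".join(s.label for s in self.products) or "0"
        return f"{lhs}->{rhs}"

    def with_delay(self, delay_source) -> "Reaction":
        """Return a delayed copy of this channel bound to ``delay_source``."""
        return replace(self, kind="delayed", delay_source=delay_source)


@dataclass(frozen=True)
class ReactionNetwork:
    """A validated set of species and reaction channels.

    Channel order is declaration order and is part of the contract: engines
    iterate channels in this order, so a fixed seed gives bit-identical runs.
    """

    species: tuple[SpeciesRef, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate (name, compartment) species declaration")

    @property
    def species_index(self) -> dict[SpeciesRef, int]:
        return {s: i for i, s in enumerate(self.species)}

    def delayed_channels(self) -> list[int]:
        return [i for i, r in enumerate(self.reactions) if r.kind == "delayed"]

    def stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net change matrix."""
        idx = self.species_index
        mat = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for s in rxn.reactants:
                mat[j, idx[s]] -= 1
            for s in rxn.products:
                mat[j, idx[s]] += 1
        return mat

    def conserved_mass(self, weights: Mapping[SpeciesRef, float]) -> bool:
        """True if the weighted species sum is invariant under every channel."""
        w = np.array([weights.get(s, 0.0) for s in self.species])
        return bool(np.allclose(self.stoichiometry() @ w, 0.0))


def build_network(
    species: Sequence[SpeciesRef], reactions: Sequence[Reaction]
) -> ReactionNetwork:
    """Validate and assemble a reaction network.

    Raises ``ValueError`` for reactions that reference undeclared species,
    delayed reactions without a delay source (enforced by :class:`Reaction`)
    and channels with more than two reactants.
    """
    declared = set(species)
    for rxn in reactions:
        for s in (*rxn.reactants, *rxn.products):
            if s not in declared:
                raise ValueError(
                    f"reaction {rxn.display_name} references undeclared species {s.label}"
                )
    return ReactionNetwork(tuple(species), tuple(reactions))


@dataclass
class PendingEntry:
    """A scheduled delayed-reaction completion ("in transit" molecules)."""

    completion_time: float
    reaction: Reaction
    reserved: tuple[SpeciesRef, ...]
    cancellable: bool = True
    cancelled: bool = False


@dataclass
class SystemState:
    """Discrete molecule counts plus the queue of pending delayed completions."""

    t: float
    counts: dict[SpeciesRef, int]
    pending: list[PendingEntry] = field(default_factory=list)

    def total_mass(self, weights: Mapping[SpeciesRef, float]) -> float:
        """Weighted mass including molecules reserved inside pending entries."""
        m = sum(weights.get(s, 0.0) * n for s, n in self.counts.items())
        for entry in self.pending:
            if not entry.cancelled:
                m += sum(weights.get(s, 0.0) for s in entry.reserved)
        return m


@dataclass
class Trajectory:
    """Per-species time courses on a strictly increasing time grid.

    ``kind`` selects the interpolation semantics used by
    :func:`resample_trajectory`: ``"step"`` for event-driven stochastic paths
    (piecewise-constant, right-continuous) and ``"linear"`` for continuous
    ODE/DDE solutions.
    """

    times: np.ndarray
    species: tuple[SpeciesRef, ...]
    values: np.ndarray  # shape (n_times, n_species)
    kind: Literal["step", "linear"] = "step"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.shape != (self.times.size, len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({self.times.size}, {len(self.species)})"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    def column(self, species: SpeciesRef) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[s.label for s in self.species])
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, species: Iterable[SpeciesRef], kind="step"
    ) -> "Trajectory":
        species = tuple(species)
        values = df[[s.label for s in species]].to_numpy(dtype=float)
        return cls(df["time"].to_numpy(dtype=float), species, values, kind=kind)


def parse_species(label: str) -> SpeciesRef:
    """Parse a ``name_compartment`` label (``"A_c"``) or bare name (``"A"``)."""
    name, _, comp = label.rpartition("_")
    return SpeciesRef(name, comp) if name else SpeciesRef(label)


def network_from_dict(spec: Mapping) -> tuple[ReactionNetwork, dict]:
    """Build a network (plus initial counts) from a plain-dict definition.

    Expected keys: ``species`` (list of labels), ``reactions`` (list of
    {reactants, products, k, kind, delay_source, name}) and optionally
    ``initial_counts`` ({label: int}).  This is the in-memory form of a
    JSON/YAML scenario file.
    """
    species = [parse_species(s) for s in spec["species"]]
    reactions = []
    for r in spec.get("reactions", []):
        reactions.append(Reaction(
            reactants=tuple(parse_species(s) for s in r["reactants"]),
            products=tuple(parse_species(s) for s in r["products"]),
            rate_k=r.get("k"),
            kind=r.get("kind", "immediate"),
            delay_source=r.get("delay_source"),
            name=r.get("name"),
        ))
    network = build_network(species, reactions)
    init = {parse_species(s): int(n)
            for s, n in spec.get("initial_counts", {}).items()}
    return network, init


def network_to_dict(network: ReactionNetwork,
                    init_counts: Optional[Mapping[SpeciesRef, int]] = None) -> dict:
    """Inverse of :func:`network_from_dict` (delay sources become labels)."""
    out = {
        "species": [s.label for s in network.species],
        "reactions": [
            {
                "reactants": [s.label for s in rxn.reactants],
                "products": [s.label for s in rxn.products],
                **({"k": rxn.rate_k} if rxn.rate_k is not None else {}),
                "kind": rxn.kind,
                **({"delay_source": rxn.delay_source}
                   if isinstance(rxn.delay_source, str) else {}),
                **({"name": rxn.name} if rxn.name else {}),
            }
            for rxn in network.reactions
        ],
    }
    if init_counts:
        out["initial_counts"] = {s.label: int(n) for s, n in init_counts.items()}
    return out


def load_network(path) -> tuple[ReactionNetwork, dict]:
    """Load a network definition from a JSON or YAML file."""
    import json
    from pathlib import Path

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        spec = yaml.safe_load(text)
    else:
        spec = json.loads(text)
    return network_from_dict(spec)


def resample_trajectory(
    traj: Trajectory, grid: np.ndarray, kind: Optional[str] = None
) -> Trajectory:
    """Interpolate a trajectory onto ``grid``.

    Step trajectories use right-continuous piecewise-constant interpolation
    (the value at a query time is the value of the latest event at or before
    it); linear trajectories use linear interpolation.  ``grid`` must lie
    within the recorded time range.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid[0] < traj.times[0] - 1e-12 or grid[-1] > traj.times[-1] + 1e-12):
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside trajectory range "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    kind = kind or traj.kind
    if kind == "step":
        idx = np.searchsorted(traj.times, grid, side="right") - 1
        idx = np.clip(idx, 0, traj.times.size - 1)
        values = traj.values[idx]
    elif kind == "linear":
        values = np.column_stack(
            [np.interp(grid, traj.times, traj.values[:, j]) for j in range(traj.values.shape[1])]
        )
    else:  # pragma: no cover - guarded by signature
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return Trajectory(grid, traj.species, values, kind=kind)
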