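"""Permeation-model specifications, rate-parameter sets and conditions.

A permeation model is a directed state graph whose nodes are ion
configurations of the selectivity filter (which of the binding sites S0-S4
and the pore mouths are occupied) and whose edges are elementary hopping
reactions.  Edges come in four kinds:

``plain``
    a voltage- and concentration-independent rate constant (s^-1),
``bind_internal`` / ``bind_external``
    an ion-binding step proportional to the K+ activity on the internal or
    external side (base rate in s^-1 mM^-1),
``eyring``
    a voltage-dependent translocation over a single Eyring barrier sitting at
    electrical position ``s`` with characteristic voltage ``V_char`` (mV per
    e-fold change); the cycle-forward edge carries exp(s*V/V_char), its
    reverse exp(-(1-s)*V/V_char), sharing (s, V_char) via an ``eyring_group``.

A designated ``transport_cycle`` is the closed walk whose forward traversal
moves exactly one elementary charge outward.

Model specs round-trip to JSON; three specs ship with the package
(``five_state_roux``, ``four_state``, ``hard_knock_on``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import networkx as nx

from .activity import ActivityTable
from .constants import T_DEFAULT_C

__all__ = [
    "Edge",
    "EyringBarrier",
    "ModelSpec",
    "RateParameterSet",
    "Condition",
    "ModelSpecError",
    "load_model_spec",
    "BUILTIN_MODELS",
]

EDGE_KINDS = ("plain", "bind_internal", "bind_external", "eyring")

BUILTIN_MODELS = ("five_state_roux", "four_state", "hard_knock_on")


class ModelSpecError(ValueError):
    """Raised when a model specification is structurally invalid."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    param: str
    kind: str = "plain"
    eyring_group: str | None = None


@dataclass(frozen=True)
class EyringBarrier:
    """Electrical position s in [0, 1] and characteristic voltage V_char > 0 (mV)."""

    s: float
    v_char: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"electrical position s={self.s} outside [0, 1]")
        if self.v_char <= 0:
            raise ValueError(f"characteristic voltage must be positive, got {self.v_char}")


@dataclass
class ModelSpec:
    """A validated permeation-model topology."""

    name: str
    states: list[str]
    occupancy: dict[str, str]
    edges: list[Edge]
    transport_cycle: list[str]
    #: backward base rate eliminated when the Nernst/detailed-balance
    #: constraint is enforced (see :mod:`filtergate.nernst`).
    constraint_eliminated_rate: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        self._validate()
        self._index = {s: i for i, s in enumerate(self.states)}
        self._edge_by_pair = {(e.source, e.target): e for e in self.edges}

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelSpecError("duplicate state labels")
        state_set = set(self.states)
        pairs = set()
        for e in self.edges:
            if e.kind not in EDGE_KINDS:
                raise ModelSpecError(f"unknown edge kind {e.kind!r}")
            if e.source not in state_set or e.target not in state_set:
                raise ModelSpecError(f"edge {e.source}->{e.target} references unknown state")
            if e.source == e.target:
                raise ModelSpecError("self-loops are not allowed")
            if (e.source, e.target) in pairs:
                raise ModelSpecError(f"duplicate edge {e.source}->{e.target}")
            pairs.add((e.source, e.target))
            if (e.kind == "eyring") != (e.eyring_group is not None):
                raise ModelSpecError("eyring_group set iff kind is 'eyring'")
        for s, t in pairs:
            if (t, s) not in pairs:
                raise ModelSpecError(f"edge {s}->{t} has no reverse edge")
        # eyring groups: exactly one forward/backward pair per group
        groups: dict[str, list[Edge]] = {}
        for e in self.edges:
            if e.kind == "eyring":
                groups.setdefault(e.eyring_group, []).append(e)
        for g, members in groups.items():
            if len(members) != 2 or {(m.source, m.target) for m in members} != {
                (members[0].source, members[0].target),
                (members[0].target, members[0].source),
            }:
                raise ModelSpecError(
                    f"eyring group {g!r} must contain exactly one edge and its reverse"
                )
        graph = nx.DiGraph([(e.source, e.target) for e in self.edges])
        graph.add_nodes_from(self.states)
        if not nx.is_strongly_connected(graph):
            raise ModelSpecError("model graph must be strongly connected")
        cyc = self.transport_cycle
        if len(cyc) < 3 or cyc[0] != cyc[-1]:
            raise ModelSpecError("transport_cycle must be a closed walk (first == last)")
        for s, t in zip(cyc[:-1], cyc[1:]):
            if (s, t) not in pairs:
                raise ModelSpecError(f"transport_cycle uses missing edge {s}->{t}")

    # -- accessors ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        return self._index[label]

    def edge(self, source: str, target: str) -> Edge:
        return self._edge_by_pair[(source, target)]

    def cycle_pairs(self) -> list[tuple[str, str]]:
        """Consecutive (source, target) pairs of the forward transport cycle."""
        cyc = self.transport_cycle
        return list(zip(cyc[:-1], cyc[1:]))

    def is_cycle_forward(self, edge: Edge) -> bool:
        """True if the edge points along the forward (outward) transport cycle."""
        pairs = set(self.cycle_pairs())
        if (edge.source, edge.target) in pairs:
            return True
        if (edge.target, edge.source) in pairs:
            return False
        raise ModelSpecError(
            f"edge {edge.source}->{edge.target} is not on the transport cycle"
        )

    def eyring_groups(self) -> dict[str, tuple[Edge, Edge]]:
        """Map group name -> (forward edge, backward edge) along the cycle."""
        out: dict[str, tuple[Edge, Edge]] = {}
        for e in self.edges:
            if e.kind == "eyring" and self.is_cycle_forward(e):
                rev = self.edge(e.target, e.source)
                out[e.eyring_group] = (e, rev)
        return out

    def parameter_names(self) -> list[str]:
        return [e.param for e in self.edges]

    # -- JSON round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "occupancy": dict(self.occupancy),
            "edges": [
                {
                    "from": e.source,
                    "to": e.target,
                    "param": e.param,
                    "kind": e.kind,
                    **({"eyring_group": e.eyring_group} if e.eyring_group else {}),
                }
                for e in self.edges
            ],
            "transport_cycle": list(self.transport_cycle),
            "constraint_eliminated_rate": self.constraint_eliminated_rate,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelSpec":
        try:
            edges = [
                Edge(
                    source=str(e["from"]),
                    target=str(e["to"]),
                    param=str(e["param"]),
                    kind=str(e.get("kind", "plain")),
                    eyring_group=e.get("eyring_group"),
                )
                for e in doc["edges"]
            ]
            return cls(
                name=str(doc["name"]),
                states=[str(s) for s in doc["states"]],
                occupancy={str(k): str(v) for k, v in doc.get("occupancy", {}).items()},
                edges=edges,
                transport_cycle=[str(s) for s in doc["transport_cycle"]],
                constraint_eliminated_rate=doc.get("constraint_eliminated_rate"),
                notes=str(doc.get("notes", "")),
            )
        except KeyError as exc:
            raise ModelSpecError(f"model spec missing field {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_model_spec(name_or_path: str | Path) -> ModelSpec:
    """Load a shipped model spec by name, or any spec from a JSON path."""
    name = str(name_or_path)
    if name in BUILTIN_MODELS:
        text = resources.files("filtergate.model_specs").joinpath(f"{name}.json").read_text()
        return ModelSpec.from_dict(json.loads(text))
    path = Path(name_or_path)
    if not path.exists():
        raise ModelSpecError(
            f"unknown model {name!r}: not one of {BUILTIN_MODELS} and no such file"
        )
    return ModelSpec.from_json(path)


@dataclass
class RateParameterSet:
    """Base rate constants plus Eyring-barrier parameters.

    ``base_rates`` maps the edge parameter names of a :class:`ModelSpec` to
    positive base rates: s^-1 at 0 mV for plain/eyring edges, s^-1 mM^-1 for
    binding edges.  ``eyring`` maps eyring-group names to barriers.
    """

    base_rates: dict[str, float]
    eyring: dict[str, EyringBarrier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.base_rates.items():
            if not v > 0:
                raise ValueError(f"base rate {k}={v} must be positive")

    def require(self, model: ModelSpec) -> None:
        """Raise if any model edge lacks a parameter value."""
        missing = [p for p in model.parameter_names() if p not in self.base_rates]
        if missing:
            raise KeyError(f"missing base rates for parameters {missing}")
        for g in model.eyring_groups():
            if g not in self.eyring:
                raise KeyError(f"missing Eyring parameters for group {g!r}")

    def copy(self) -> "RateParameterSet":
        return RateParameterSet(dict(self.base_rates), dict(self.eyring))

    def to_dict(self) -> dict:
        return {
            "base_rates": dict(self.base_rates),
            "eyring": {g: {"s": b.s, "v_char": b.v_char} for g, b in self.eyring.items()},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RateParameterSet":
        return cls(
            base_rates={str(k): float(v) for k, v in doc["base_rates"].items()},
            eyring={
                str(g): EyringBarrier(float(b["s"]), float(b["v_char"]))
                for g, b in doc.get("eyring", {}).items()
            },
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RateParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Condition:
    """One experimental condition: voltage, bath concentrations, temperature.

    Activities are derived from concentrations with the configured activity
    table on construction.  Voltage is cis/internal-side relative to the
    grounded trans/external side, in mV.
    """

    V: float
    c_in: float
    c_out: float
    T: float = T_DEFAULT_C
    a_in: float = field(init=False)
    a_out: float = field(init=False)

    # class-level default so Condition stays hashable/frozen
    _table: ActivityTable | None = None

    def __post_init__(self) -> None:
        if self.c_in <= 0 or self.c_out <= 0:
            raise ValueError("concentrations must be positive")
        table = self._table if self._table is not None else _default_table()
        object.__setattr__(self, "a_in", float(table.activity(self.c_in)))
        object.__setattr__(self, "a_out", float(table.activity(self.c_out)))

    def with_voltage(self, V: float) -> "Condition":
        return replace(self, V=V)


_TABLE_SINGLETON: ActivityTable | None = None


def _default_table() -> ActivityTable:
    global _TABLE_SINGLETON
    if _TABLE_SINGLETON is None:
        _TABLE_SINGLETON = ActivityTable()
    return _TABLE_SINGLETON
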