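"""Core state variables and transition-rate equations of the SOP model.

A stimulus (an object or an arena location serving as context) is a pool of
representational elements distributed over three activity states: inactive
``I``, primary activity ``A1`` (which drives vigorous responding, i.e.
exploration) and secondary/refractory activity ``A2`` (which encodes recency
and suppresses re-activation).  Presentation moves elements I -> A1 at rate
``p1``; elements decay A1 -> A2 at ``pd1`` and A2 -> I at ``pd2`` regardless
of stimulus input.  Contexts acquire unidirectional associations to objects
with separate excitatory (``V+``) and inhibitory (``V-``) accumulators; the
net association lets an active context promote an object's elements directly
from I to A2 with probability ``p2``, the associative route to priming.

All rates are expressed per internal time unit tau, with one tau equal to one
3-second integration step by default (``ModelConfig.dt_seconds``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "NodeSpec",
    "NodeState",
    "LinkState",
    "LearningParams",
    "ModelConfig",
    "CANONICAL",
    "canonical_config",
    "effective_p1",
    "compute_p2",
    "state_derivatives",
    "learning_derivatives",
    "net_association",
]

#: Canonical parameter set used throughout: objects are more salient than
#: contexts, A2 outlasts A1 (pd2 < pd1), and excitatory learning dominates
#: inhibitory learning 10:1.
CANONICAL = {
    "p1_object": 0.75,
    "p1_context": 0.25,
    "pd1": 0.1,
    "pd2": 0.02,
    "L_plus": 0.25,
    "L_minus": 0.025,
    "dt_seconds": 3.0,
}


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class NodeSpec:
    """Parameters of one stimulus node.

    ``p1`` is the activation rate while the stimulus is scheduled on; ``pd1``
    and ``pd2`` are the stimulus-independent decay rates A1->A2 and A2->I.
    Context nodes never receive associative input (their p2 is identically 0).
    """

    id: str
    role: str  # "object" | "context"
    p1: float
    pd1: float
    pd2: float

    def __post_init__(self) -> None:
        if self.role not in ("object", "context"):
            raise ValueError(f"node {self.id}: unknown role {self.role!r}")
        _check_unit(f"node {self.id}: p1", self.p1)
        _check_unit(f"node {self.id}: pd1", self.pd1)
        _check_unit(f"node {self.id}: pd2", self.pd2)

    @property
    def is_object(self) -> bool:
        return self.role == "object"


@dataclass
class NodeState:
    """Occupancy of the three activity states; I + A1 + A2 == 1."""

    I: float = 1.0
    A1: float = 0.0
    A2: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.I, self.A1, self.A2)


@dataclass
class LinkState:
    """Directed context->object association with opponent accumulators.

    Both accumulators start at zero and are nondecreasing along any
    trajectory: links are potential associations that only grow when the
    required co-activity occurs.
    """

    source: str
    target: str
    v_plus: float = 0.0
    v_minus: float = 0.0


@dataclass(frozen=True)
class LearningParams:
    L_plus: float = CANONICAL["L_plus"]
    L_minus: float = CANONICAL["L_minus"]

    def __post_init__(self) -> None:
        if self.L_plus < 0 or self.L_minus < 0:
            raise ValueError("learning rates must be nonnegative")


@dataclass
class ModelConfig:
    """Full model specification: nodes, potential links, learning, timing."""

    nodes: list[NodeSpec]
    links: list[LinkState] = field(default_factory=list)
    learning: LearningParams = field(default_factory=LearningParams)
    dt_seconds: float = CANONICAL["dt_seconds"]
    #: unit in which the rates are expressed; "tau" means per integration step
    time_unit: str = "tau"

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        by_id = {n.id: n for n in self.nodes}
        if not self.links:
            # lazy instantiation: one potential association per
            # context->object pair
            self.links = [
                LinkState(c.id, o.id)
                for c in self.nodes
                if c.role == "context"
                for o in self.nodes
                if o.role == "object"
            ]
        for link in self.links:
            if by_id[link.source].role != "context":
                raise ValueError(f"link source {link.source} is not a context")
            if by_id[link.target].role != "object":
                raise ValueError(f"link target {link.target} is not an object")

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "role": n.role, "p1": n.p1, "pd1": n.pd1, "pd2": n.pd2}
                for n in self.nodes
            ],
            "learning": {"L_plus": self.learning.L_plus, "L_minus": self.learning.L_minus},
            "dt_seconds": self.dt_seconds,
            "time_unit": self.time_unit,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        known = {"nodes", "learning", "dt_seconds", "time_unit"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        nodes = [NodeSpec(**nd) for nd in data["nodes"]]
        learning = LearningParams(**data.get("learning", {}))
        return cls(
            nodes=nodes,
            learning=learning,
            dt_seconds=float(data.get("dt_seconds", CANONICAL["dt_seconds"])),
            time_unit=str(data.get("time_unit", "tau")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def canonical_config(
    object_ids: Iterable[str],
    context_ids: Iterable[str],
    *,
    pd1: float | None = None,
    pd2: float | None = None,
    L_plus: float | None = None,
    L_minus: float | None = None,
    p1_object: float | None = None,
    p1_context: float | None = None,
) -> ModelConfig:
    """Build a ModelConfig with the canonical parameters, optionally overridden."""
    c = CANONICAL
    pd1 = c["pd1"] if pd1 is None else pd1
    pd2 = c["pd2"] if pd2 is None else pd2
    p1o = c["p1_object"] if p1_object is None else p1_object
    p1x = c["p1_context"] if p1_context is None else p1_context
    nodes = [NodeSpec(i, "object", p1o, pd1, pd2) for i in object_ids]
    nodes += [NodeSpec(i, "context", p1x, pd1, pd2) for i in context_ids]
    learning = LearningParams(
        c["L_plus"] if L_plus is None else L_plus,
        c["L_minus"] if L_minus is None else L_minus,
    )
    return ModelConfig(nodes=nodes, learning=learning)


# -- transition-rate equations -------------------------------------------


def effective_p1(node: NodeSpec, active: bool) -> float:
    """Activation rate I->A1: the node's p1 while scheduled on, else 0."""
    return node.p1 if active else 0.0


def compute_p2(
    target: str,
    links: Iterable[LinkState],
    context_a1: Mapping[str, float],
) -> float:
    """Associative promotion probability I->A2 for one object.

    Aggregates A1_c * (V+ - V-) over every link targeting the object and
    truncates to [0, 1]: inhibitory contexts only offset concurrent
    excitatory drive, they never promote on their own.
    """
    total = 0.0
    for link in links:
        if link.target != target:
            continue
        a1 = context_a1.get(link.source, 0.0)
        total += a1 * (link.v_plus - link.v_minus)
    return min(1.0, max(0.0, total))


def state_derivatives(
    states: Mapping[str, NodeState],
    config: ModelConfig,
    active_set: set[str],
    links: Iterable[LinkState] | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Rates of change (dI, dA1, dA2) for every node; sums to zero exactly.

    Objects receive associative input p2 (promotion I->A2) in addition to the
    stimulus-driven p1; contexts use p2 = 0.
    """
    links = list(config.links if links is None else links)
    context_a1 = {
        n.id: states[n.id].A1 for n in config.nodes if n.role == "context"
    }
    out: dict[str, tuple[float, float, float]] = {}
    for node in config.nodes:
        s = states[node.id]
        p1 = effective_p1(node, node.id in active_set)
        p2 = compute_p2(node.id, links, context_a1) if node.is_object else 0.0
        dA1 = p1 * s.I - node.pd1 * s.A1
        dA2 = node.pd1 * s.A1 + p2 * s.I - node.pd2 * s.A2
        dI = -(dA1 + dA2)  # conservation holds exactly
        out[node.id] = (dI, dA1, dA2)
    return out


def learning_derivatives(
    links: Iterable[LinkState],
    states: Mapping[str, NodeState],
    learning: LearningParams,
) -> list[tuple[float, float]]:
    """(dV+, dV-) per link; both are products of nonnegative occupancies."""
    out = []
    for link in links:
        src, tgt = states[link.source], states[link.target]
        dvp = learning.L_plus * src.A1 * tgt.A1
        dvm = learning.L_minus * src.A1 * tgt.A2
        out.append((dvp, dvm))
    return out


def net_association(link: LinkState) -> float:
    """Net associative strength V = V+ - V- (may be negative)."""
    return link.v_plus - link.v_minus
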