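"""Trajectory-level simulation and the exact linear-system oracle.

``simulate`` advances a full node/link system through a schedule with
fixed-step classic Runge-Kutta and stores every grid point.
``closed_form_isolated_node`` provides the independent matrix-exponential
solution for a node with no incoming associations, used to validate the
integrator: within any constant-input segment the three-state system is
linear time-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import engine
from .model import ModelConfig, NodeSpec, NodeState
from .schedules import Schedule

__all__ = ["Trajectory", "rk4_step", "simulate", "closed_form_isolated_node",
           "build_system"]


@dataclass
class Trajectory:
    """Per-grid-point states of every node and link.

    ``states`` has shape (n_steps+1, 3, n_nodes) ordered (I, A1, A2);
    ``link_states`` shape (n_steps+1, 2, n_links) ordered (V+, V-).
    """

    node_ids: list[str]
    link_pairs: list[tuple[str, str]]
    states: np.ndarray
    link_states: np.ndarray
    dt_seconds: float

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    def node_index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def a1(self, node_id: str) -> np.ndarray:
        return self.states[:, 1, self.node_index(node_id)]

    def state_at(self, node_id: str, step: int) -> NodeState:
        i, a1, a2 = self.states[step, :, self.node_index(node_id)]
        return NodeState(i, a1, a2)

    def nodes_frame(self) -> pd.DataFrame:
        """Tidy table (step, seconds, node, I, A1, A2)."""
        rows = []
        for j, nid in enumerate(self.node_ids):
            for t in range(self.n_steps + 1):
                rows.append((t, t * self.dt_seconds, nid,
                             *self.states[t, :, j]))
        return pd.DataFrame(rows, columns=["step", "seconds", "node", "I", "A1", "A2"])

    def links_frame(self) -> pd.DataFrame:
        """Tidy table (step, source, target, v_plus, v_minus, v_net)."""
        rows = []
        for k, (s, tgt) in enumerate(self.link_pairs):
            for t in range(self.n_steps + 1):
                vp, vm = self.link_states[t, :, k]
                rows.append((t, s, tgt, vp, vm, vp - vm))
        return pd.DataFrame(rows, columns=["step", "source", "target",
                                           "v_plus", "v_minus", "v_net"])


def rk4_step(state: np.ndarray, deriv: Callable[[np.ndarray], np.ndarray],
             dt: float) -> np.ndarray:
    """One classic fourth-order Runge-Kutta step (weights 1,2,2,1)/6."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv(y))
    k2 = np.asarray(deriv(y + dt / 2 * k1))
    k3 = np.asarray(deriv(y + dt / 2 * k2))
    k4 = np.asarray(deriv(y + dt * k3))
    for name, k in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4)):
        if not np.isfinite(k).all():
            raise FloatingPointError(f"non-finite derivative in {name}")
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def build_system(schedule: Schedule, config: ModelConfig,
                 batch_masks: np.ndarray | None = None,
                 batch_size: int = 1) -> engine.System:
    """Assemble the vectorized engine representation of (schedule, config)."""
    node_ids = [n.id for n in config.nodes]
    missing = set(schedule.roles) - set(node_ids)
    if missing:
        raise ValueError(f"schedule references unknown nodes: {sorted(missing)}")
    index = {nid: i for i, nid in enumerate(node_ids)}
    if schedule.link_pairs is None:
        pairs = [(l.source, l.target) for l in config.links]
    else:
        pairs = schedule.link_pairs
    links = [(index[s], index[t]) for s, t in pairs]
    masks = schedule.masks(node_ids) if batch_masks is None else batch_masks
    return engine.System(
        node_ids=node_ids,
        is_object=[n.is_object for n in config.nodes],
        p1=[n.p1 for n in config.nodes],
        pd1=[n.pd1 for n in config.nodes],
        pd2=[n.pd2 for n in config.nodes],
        masks=masks,
        links=links,
        L_plus=config.learning.L_plus,
        L_minus=config.learning.L_minus,
        batch_size=batch_size,
    )


def simulate(schedule: Schedule, config: ModelConfig,
             substeps: int = engine.DEFAULT_SUBSTEPS) -> Trajectory:
    """Run a schedule from rest (all I = 1, all links at zero).

    Deterministic: repeated calls with identical inputs are bit-identical.
    Every schedule boundary must already lie on the step grid (Schedule
    construction guarantees this).
    """
    system = build_system(schedule, config)
    res = engine.integrate(system, substeps=substeps, record=True)
    if schedule.link_pairs is None:
        pairs = [(l.source, l.target) for l in config.links]
    else:
        pairs = list(schedule.link_pairs)
    return Trajectory(node_ids=system.node_ids, link_pairs=pairs,
                      states=res.states[:, :, :, 0],
                      link_states=res.link_states[:, :, :, 0],
                      dt_seconds=config.dt_seconds)


def _rate_matrix(p1: float, pd1: float, pd2: float) -> np.ndarray:
    # state order (I, A1, A2)
    return np.array([[-p1, 0.0, pd2],
                     [p1, -pd1, 0.0],
                     [0.0, pd1, -pd2]])


def closed_form_isolated_node(
    spec: NodeSpec,
    segments: Sequence[tuple[bool, float]],
    initial: NodeState | None = None,
) -> list[NodeState]:
    """Exact states of a link-free node at the end of each on/off segment.

    ``segments`` is a sequence of (stimulus_on, duration_in_tau) pairs.
    Within a segment the system is linear time-invariant; the solution is the
    matrix exponential of the 3x3 rate matrix chained across segments (the
    Pade-based ``scipy.linalg.expm`` handles repeated/defective eigenvalues
    without any special-casing).
    """
    y = np.array((initial or NodeState()).as_tuple(), dtype=float)
    out = []
    for on, duration in segments:
        if duration < 0:
            raise ValueError("segment duration must be >= 0")
        A = _rate_matrix(spec.p1 if on else 0.0, spec.pd1, spec.pd2)
        y = expm(A * duration) @ y
        out.append(NodeState(*y))
    return out
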