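"""Behavioral readout: peak A1 at test, contrasts, counterbalanced means.

Peak A1 of an object during its test window is the model's proxy for
exploration time.  Contrasts subtract the comparison object (familiar /
recent / in-place, "P") from the preferred object (novel / remote /
displaced, "Q").  Empirical designs are averaged over all context-order
permutations; the max-min spread across permutations is reported alongside
the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .integrate import Trajectory, build_system
from .model import ModelConfig
from .schedules import Schedule

log = logging.getLogger(__name__)

__all__ = ["TestReadout", "ContrastRecord", "peak_a1", "test_readouts",
           "contrast", "average_over_counterbalance"]


@dataclass(frozen=True)
class TestReadout:
    object: str
    peak_a1: float
    window: tuple[int, int]


@dataclass(frozen=True)
class ContrastRecord:
    name: str
    q_label: str
    p_label: str
    delta_a1: float
    ratio: float | None  # None when peak_a1(P) == 0


def peak_a1(trajectory: Trajectory, obj: str,
            window: tuple[int, int]) -> float:
    """Maximum A1 of ``obj`` over grid points in [start, end] (inclusive)."""
    start, end = window
    if end < start:
        raise ValueError(f"empty window {window}")
    if end > trajectory.n_steps:
        raise ValueError(f"window {window} exceeds trajectory extent "
                         f"({trajectory.n_steps} steps)")
    return float(trajectory.a1(obj)[start:end + 1].max())


def test_readouts(trajectory: Trajectory, schedule: Schedule) -> dict[str, TestReadout]:
    return {
        obj: TestReadout(obj, peak_a1(trajectory, obj, win), win)
        for obj, win in schedule.test_windows.items()
    }


def contrast(readouts: dict[str, TestReadout], q_label: str, p_label: str,
             name: str = "") -> ContrastRecord:
    """Delta and ratio of peak A1 between the Q and P objects."""
    try:
        q, p = readouts[q_label], readouts[p_label]
    except KeyError as exc:
        raise KeyError(f"no readout for object {exc.args[0]!r}") from None
    delta = q.peak_a1 - p.peak_a1
    ratio = (q.peak_a1 / p.peak_a1) if p.peak_a1 > 0 else None
    return ContrastRecord(name or f"{q_label}_vs_{p_label}",
                          q_label, p_label, delta, ratio)


def average_over_counterbalance(
    schedules: list[Schedule],
    config: ModelConfig,
    substeps: int = engine.DEFAULT_SUBSTEPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean peak A1 per object and mean contrast over permutation sets.

    All schedules must share the same stimuli, duration and contrast
    definitions (they are permutations of one design).  Returns
    ``(objects, contrasts)`` data frames; ``objects`` carries the arithmetic
    mean and the max-min spread of peak A1 across permutations, and
    ``contrasts`` the mean delta and mean ratio (permutations with a zero
    comparison peak are excluded from the ratio with a logged count).
    """
    if not schedules:
        raise ValueError("need at least one schedule")
    first = schedules[0]
    node_ids = [n.id for n in config.nodes]
    B = len(schedules)
    T = first.n_steps
    masks = np.zeros((len(node_ids), T, B), dtype=bool)
    for b, sch in enumerate(schedules):
        if sch.n_steps != T or set(sch.roles) != set(first.roles):
            raise ValueError("schedules are not permutations of one design")
        masks[:, :, b] = sch.masks(node_ids)

    windows = {}
    for obj in first.test_windows:
        ws = np.array([s.test_windows[obj][0] for s in schedules])
        we = np.array([s.test_windows[obj][1] for s in schedules])
        windows[obj] = (ws, we)

    system = build_system(first, config, batch_masks=masks, batch_size=B)
    res = engine.integrate(system, substeps=substeps, windows=windows)

    obj_rows = []
    roles = first.meta.get("object_roles", {})
    for obj in sorted(first.test_windows):
        peaks = res.peaks[obj]
        obj_rows.append((obj, roles.get(obj, ""), float(peaks.mean()),
                         float(peaks.max() - peaks.min()), B))
    objects = pd.DataFrame(obj_rows, columns=["object", "role", "mean_peak_a1",
                                              "spread", "n_runs"])

    con_rows = []
    for c in first.contrasts:
        pq, pp = res.peaks[c.q], res.peaks[c.p]
        delta = pq - pp
        ok = pp > 0
        n_excluded = int(B - ok.sum())
        if n_excluded:
            log.info("contrast %s: %d permutations with zero comparison peak "
                     "excluded from ratio", c.name, n_excluded)
        ratio = float((pq[ok] / pp[ok]).mean()) if ok.any() else np.nan
        con_rows.append((c.name, c.q, c.p, float(delta.mean()), ratio))
    contrasts = pd.DataFrame(con_rows, columns=["contrast", "q", "p",
                                                "delta_a1", "ratio"])
    return objects, contrasts
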