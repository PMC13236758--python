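"""Stimulus timelines for object-recognition procedures.

Builds the conceptual single-timeline presets (sample, ISI, sample, RI, test)
and the empirical presets that emulate four representative study designs:

* ``good_*``   -- arena tasks with 20-min habituation, 5-min samples/tests,
  contexts tiling each phase and each object on during the final half of its
  context window (SOR, RR, OIP and the combined RR+OIP variant).
* ``tam_*``    -- same sample structure with 3-min tests and a manipulated
  delay (RI for SOR/OIP, ISI for RR).
* ``whitt``    -- eight 30-s samples separated by a short or long ISI, each
  sample split into two 15-s context periods with the object on during the
  final 7.5 s; 15-min RI; 2-min test.
* ``sanderson``-- Y-maze variant: 10 visits of a 0.5-min START context
  followed by a 1-min arm whose location context is coextensive with it.

All boundaries are snapped to the 3-s integration grid; a snap that moves a
boundary is logged, and one that would move it by more than half a step is
rejected.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

STEPS_PER_MINUTE = 20  # dt = 3 s

__all__ = [
    "Event",
    "Contrast",
    "Schedule",
    "PresetParams",
    "conceptual_preset",
    "conceptual_union_schedule",
    "empirical_preset",
    "enumerate_counterbalance",
    "PresetFamily",
    "PRESET_NAMES",
]


def snap_steps(minutes: float, what: str = "boundary") -> int:
    """Convert minutes to grid steps, rounding to the nearest step."""
    raw = minutes * STEPS_PER_MINUTE
    snapped = math.floor(raw + 0.5)
    if abs(raw - snapped) > 0.5 + 1e-9:
        raise ValueError(f"{what} at {minutes} min cannot be snapped to the grid")
    if abs(raw - snapped) > 1e-9:
        log.info("snapped %s from %.2f to %d steps", what, raw, snapped)
    return snapped


@dataclass(frozen=True)
class Event:
    stimulus: str
    start: int  # steps
    end: int    # steps, exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"event {self.stimulus}: need 0 <= start < end, "
                             f"got [{self.start}, {self.end})")


@dataclass(frozen=True)
class Contrast:
    q: str      # novel / remote / displaced object
    p: str      # familiar / recent / in-place object
    name: str


@dataclass
class Schedule:
    """Timed on/off intervals plus test windows and contrast definitions."""

    events: list[Event]
    test_windows: dict[str, tuple[int, int]]  # grid points, inclusive
    contrasts: list[Contrast]
    roles: dict[str, str]  # node id -> "object" | "context"
    n_steps: int = 0
    #: explicit context->object pairs that may form associations; None means
    #: every context->object pair
    link_pairs: list[tuple[str, str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_steps == 0:
            self.n_steps = max(e.end for e in self.events) if self.events else 0
        self.n_steps = max(self.n_steps,
                           max((w[1] for w in self.test_windows.values()), default=0))
        for c in self.contrasts:
            for label in (c.q, c.p):
                if label not in self.test_windows:
                    raise ValueError(f"contrast {c.name}: {label} has no test window")

    @property
    def stimuli(self) -> list[str]:
        return sorted(self.roles)

    def masks(self, node_ids: list[str]) -> np.ndarray:
        """Boolean activity flags, shape (len(node_ids), n_steps)."""
        m = np.zeros((len(node_ids), self.n_steps), dtype=bool)
        index = {nid: i for i, nid in enumerate(node_ids)}
        for ev in self.events:
            m[index[ev.stimulus], ev.start:ev.end] = True
        return m

    def events_frame(self):
        import pandas as pd

        dt = 3.0
        return pd.DataFrame(
            [(e.stimulus, e.start, e.end, e.start * dt, e.end * dt) for e in self.events],
            columns=["stimulus", "start_step", "end_step", "start_s", "end_s"],
        )


@dataclass(frozen=True)
class PresetParams:
    task: str
    sample_minutes: float = 5.0
    test_minutes: float = 5.0
    isi_minutes: float = 2.0
    ri_minutes: float = 2.0
    habituation_minutes: float = 20.0
    n_samples: int = 1

    def __post_init__(self) -> None:
        for name in ("sample_minutes", "test_minutes", "isi_minutes",
                     "ri_minutes", "habituation_minutes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# conceptual presets
# ---------------------------------------------------------------------------

_CONCEPTUAL_CONDITIONS = {
    # condition -> (sample phase or None, displaced at test?)
    "novel": (None, False),
    "recent": (2, False),
    "remote": (1, False),
    "displaced": (2, True),
}

_CONCEPTUAL_TASKS = {
    "sor": ("novel", "recent"),
    "rr": ("remote", "recent"),
    "oip": ("displaced", "recent"),
}


def conceptual_union_schedule(
    isi_minutes: float = 2.0,
    ri_minutes: float = 2.0,
    tasks: tuple[str, ...] = ("sor", "rr", "oip"),
    sample_minutes: float = 5.0,
    test_minutes: float = 5.0,
) -> Schedule:
    """One timeline (sample, ISI, sample, RI, test) holding every condition
    object needed by ``tasks``.

    Each condition follows the same arrangement as the empirical renderings:
    the context window spans the whole phase and the object is on during the
    final half of it, so the animal "enters the location before encountering
    the object".  The sampled context is on during both samples (the arena
    is present throughout sampling, which is what lets the remote object
    accrue inhibitory extinction-like learning during the second sample).
    At test only each object's *current* context is on: in-place conditions
    are tested under the sampled context, the displaced condition under a
    fresh context never paired with it.  Condition groups do not share
    links, so the union timeline is exactly equivalent to simulating each
    condition alone.
    """
    for t in tasks:
        if t not in _CONCEPTUAL_TASKS:
            raise ValueError(f"unknown conceptual task {t!r}")
    conditions: list[str] = []
    for t in tasks:
        for c in _CONCEPTUAL_TASKS[t]:
            if c not in conditions:
                conditions.append(c)

    s = snap_steps(sample_minutes, "sample")
    te = snap_steps(test_minutes, "test")
    isi = snap_steps(isi_minutes, "ISI")
    ri = snap_steps(ri_minutes, "RI")
    s1 = (0, s)
    s2 = (s + isi, 2 * s + isi)
    tw = (2 * s + isi + ri, 2 * s + isi + ri + te)
    half = s - math.floor(s * 0.5 + 0.5)
    thalf = te - math.floor(te * 0.5 + 0.5)

    events: list[Event] = []
    roles: dict[str, str] = {}
    link_pairs: list[tuple[str, str]] = []
    need_main = any(not _CONCEPTUAL_CONDITIONS[c][1] for c in conditions)
    if need_main:
        roles["ctx_main"] = "context"
        events += [Event("ctx_main", *s1), Event("ctx_main", *s2), Event("ctx_main", *tw)]
    if "displaced" in conditions:
        roles["ctx_sample_only"] = "context"
        roles["ctx_test_only"] = "context"
        events += [Event("ctx_sample_only", *s1), Event("ctx_sample_only", *s2),
                   Event("ctx_test_only", *tw)]

    test_windows: dict[str, tuple[int, int]] = {}
    for cond in conditions:
        phase, displaced = _CONCEPTUAL_CONDITIONS[cond]
        roles[cond] = "object"
        sample_ctx = "ctx_sample_only" if displaced else "ctx_main"
        test_ctx = "ctx_test_only" if displaced else "ctx_main"
        if phase == 1:
            events.append(Event(cond, s1[0] + half, s1[1]))
        elif phase == 2:
            events.append(Event(cond, s2[0] + half, s2[1]))
        events.append(Event(cond, tw[0] + thalf, tw[1]))
        link_pairs.append((sample_ctx, cond))
        if test_ctx != sample_ctx:
            link_pairs.append((test_ctx, cond))
        test_windows[cond] = (tw[0] + thalf, tw[1])

    contrasts = [Contrast(*_CONCEPTUAL_TASKS[t], t) for t in tasks]
    return Schedule(events=events, test_windows=test_windows, contrasts=contrasts,
                    roles=roles, link_pairs=link_pairs,
                    meta={"preset": "conceptual", "tasks": tasks,
                          "isi_minutes": isi_minutes, "ri_minutes": ri_minutes})


def conceptual_preset(task: str, isi_minutes: float = 2.0,
                      ri_minutes: float = 2.0) -> Schedule:
    """Conceptual schedule for one task (``sor``, ``rr`` or ``oip``)."""
    if task not in _CONCEPTUAL_TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of "
                         f"{sorted(_CONCEPTUAL_TASKS)}")
    return conceptual_union_schedule(isi_minutes, ri_minutes, tasks=(task,))


# ---------------------------------------------------------------------------
# empirical presets
# ---------------------------------------------------------------------------


def _tile_phase(start: int, length: int, contexts: list[str],
                objects_by_context: dict[str, list[str]],
                events: list[Event], object_fraction: float = 0.5) -> int:
    """Partition [start, start+length) equally among ``contexts`` (in the
    order given); each object occupies the final ``object_fraction`` of its
    context window.  Returns the phase end."""
    n = len(contexts)
    if n == 0:
        raise ValueError("phase needs at least one context")
    if length % n:
        raise ValueError(f"phase of {length} steps does not divide into {n} contexts")
    w = length // n
    obj_steps = math.floor(w * object_fraction + 0.5)
    if abs(w * object_fraction - obj_steps) > 1e-9:
        log.info("object onset snapped from %.2f to %d steps within a %d-step "
                 "context window", w * object_fraction, obj_steps, w)
    for i, ctx in enumerate(contexts):
        cs, ce = start + i * w, start + (i + 1) * w
        events.append(Event(ctx, cs, ce))
        offset = w - obj_steps
        for obj in objects_by_context.get(ctx, []):
            events.append(Event(obj, cs + offset, ce))
    return start + length


class PresetFamily:
    """An empirical preset plus its counterbalancing space.

    ``build(key)`` constructs the schedule for one permutation key;
    ``keys()`` iterates the full counterbalancing space.  The canonical
    variant (identity permutations) is ``canonical()``.
    """

    def __init__(self, name, build, keys, params):
        self.name = name
        self._build = build
        self._keys = keys
        self.params = params

    def keys(self):
        return iter(self._keys())

    def build(self, key) -> Schedule:
        return self._build(key)

    def canonical(self) -> Schedule:
        return self.build(next(self.keys()))

    def count(self) -> int:
        return sum(1 for _ in self.keys())


def _good_tam_family(name: str, p: PresetParams, *, test_minutes: float,
                     delay_kind: str) -> PresetFamily:
    """Shared builder for the Good and Tam arena tasks."""
    task = p.task
    hab = snap_steps(p.habituation_minutes, "habituation")
    smp = snap_steps(p.sample_minutes, "sample")
    tst = snap_steps(test_minutes, "test")
    isi = snap_steps(p.isi_minutes, "ISI")
    ri = snap_steps(p.ri_minutes, "RI")

    if task in ("sor", "rr"):
        contexts = ["C1", "C2"]
    elif task in ("oip", "rr_oip"):
        contexts = ["C1", "C2", "C3", "C4"]
    else:
        raise ValueError(f"unknown task {task!r}")
    n_ctx = len(contexts)

    if task == "sor":
        objects = ["P", "Q"]
        sample_assignments = [{c: ["P"] for c in contexts}]
        test_assignment = {"C1": ["P"], "C2": ["Q"]}
        contrasts = [Contrast("Q", "P", "sor")]
        roles_q = {"Q": "novel", "P": "familiar"}
        phases = ["sample", "test"]
    elif task == "rr":
        objects = ["P", "Q"]
        sample_assignments = [{c: ["Q"] for c in contexts},
                              {c: ["P"] for c in contexts}]
        test_assignment = {"C1": ["P"], "C2": ["Q"]}
        contrasts = [Contrast("Q", "P", "rr")]
        roles_q = {"Q": "remote", "P": "recent"}
        phases = ["sample1", "sample2", "test"]
    elif task == "oip":
        objects = ["P", "Q", "R", "S"]
        sample_assignments = [{"C1": ["P"], "C2": ["Q"], "C3": ["R"], "C4": ["S"]}]
        # Q and S swap locations at test; P and R stay put
        test_assignment = {"C1": ["P"], "C2": ["S"], "C3": ["R"], "C4": ["Q"]}
        contrasts = [Contrast("Q", "P", "oip_qp"), Contrast("S", "R", "oip_sr")]
        roles_q = {"Q": "displaced", "S": "displaced", "P": "in-place", "R": "in-place"}
        phases = ["sample", "test"]
    else:  # rr_oip
        objects = ["P", "Q", "R", "S"]
        sample_assignments = [{"C1": ["P"], "C2": ["Q"]},
                              {"C3": ["R"], "C4": ["S"]}]
        # remote P, Q; recent R, S; Q and S displaced (swap with each other)
        test_assignment = {"C1": ["P"], "C4": ["Q"], "C3": ["R"], "C2": ["S"]}
        contrasts = [Contrast("Q", "R", "rr_oip_qr"),
                     Contrast("P", "R", "rr_oip_pr"),
                     Contrast("S", "R", "rr_oip_sr")]
        roles_q = {"Q": "remote-displaced", "P": "remote-in-place",
                   "S": "recent-displaced", "R": "recent-in-place"}
        phases = (["sample1", "sample2", "test"])

    n_sample_phases = len(sample_assignments)
    perms = list(itertools.permutations(range(n_ctx)))

    def keys():
        return itertools.product(*([perms] * (n_sample_phases + 1)))

    def build(key) -> Schedule:
        events: list[Event] = []
        t = 0
        if hab:
            # habituation presents each context sequentially, ascending fixed
            # order (not counterbalanced)
            t = _tile_phase(0, hab, contexts, {}, events)
        for i, assign in enumerate(sample_assignments):
            if i > 0:
                t += isi
            order = [contexts[j] for j in key[i]]
            t = _tile_phase(t, smp, order, assign, events)
        t += ri
        order = [contexts[j] for j in key[-1]]
        t = _tile_phase(t, tst, order, test_assignment, events)

        # test windows: each object's on-interval within the test phase
        test_windows = {}
        test_start = t - tst
        for ev in events:
            if ev.stimulus in objects and ev.start >= test_start:
                test_windows[ev.stimulus] = (ev.start, ev.end)
        roles = {c: "context" for c in contexts}
        roles.update({o: "object" for o in objects})
        return Schedule(events=events, test_windows=test_windows,
                        contrasts=contrasts, roles=roles, n_steps=t,
                        meta={"preset": name, "task": task, "key": key,
                              "object_roles": roles_q,
                              "delay_kind": delay_kind})

    return PresetFamily(name, build, keys, p)


def _whitt_family(p: PresetParams) -> PresetFamily:
    """Multi-sample SOR: 8 brief samples, short or long ISI, 15-min RI."""
    n_samples = p.n_samples or 8
    lead = snap_steps(p.habituation_minutes, "lead-in")
    half = snap_steps(0.25, "context period")       # 15 s
    isi = snap_steps(p.isi_minutes, "ISI")
    ri = snap_steps(p.ri_minutes, "RI")
    test_ctx = snap_steps(1.0, "test context")      # 1 min per context

    orders = [("C1", "C2"), ("C2", "C1")]

    def keys():
        return itertools.product(range(2), repeat=n_samples + 1)

    def build(key) -> Schedule:
        events: list[Event] = []
        t = lead
        for i in range(n_samples):
            if i > 0:
                t += isi
            t = _tile_phase(t, 2 * half, list(orders[key[i]]),
                            {"C1": ["P"], "C2": ["P"]}, events)
        t += ri
        t = _tile_phase(t, 2 * test_ctx, list(orders[key[-1]]),
                        {"C1": ["P"], "C2": ["Q"]}, events)
        test_start = t - 2 * test_ctx
        test_windows = {ev.stimulus: (ev.start, ev.end) for ev in events
                        if ev.stimulus in ("P", "Q") and ev.start >= test_start}
        roles = {"C1": "context", "C2": "context", "P": "object", "Q": "object"}
        return Schedule(events=events, test_windows=test_windows,
                        contrasts=[Contrast("Q", "P", "sor")], roles=roles,
                        n_steps=t, meta={"preset": "whitt", "key": key})

    return PresetFamily("whitt", build, keys, p)


def _sanderson_family(p: PresetParams) -> PresetFamily:
    """Y-maze SOR in which arm locations stand in for objects.

    Each sample visit is a 0.5-min START context followed by a 1-min arm
    entry; the arm's location context is exactly coextensive with the arm.
    Counterbalancing permutes only which arm is familiar vs novel at test.
    """
    n_visits = p.n_samples or 10
    start_len = snap_steps(0.5, "START")
    arm_len = snap_steps(1.0, "arm visit")
    isi = snap_steps(p.isi_minutes, "ISI")
    ri = snap_steps(p.ri_minutes, "RI")
    test_len = snap_steps(p.test_minutes, "test")

    def keys():
        return iter([("armA", "armB"), ("armB", "armA")])

    def build(key) -> Schedule:
        fam, nov = key
        events: list[Event] = []
        t = 0
        for i in range(n_visits):
            if i > 0:
                t += isi
            events.append(Event("start", t, t + start_len))
            t += start_len
            events.append(Event(fam, t, t + arm_len))
            events.append(Event(f"loc_{fam}", t, t + arm_len))
            t += arm_len
        t += ri
        events.append(Event("start", t, t + start_len))
        t += start_len
        for arm in (fam, nov):
            events.append(Event(arm, t, t + test_len))
            events.append(Event(f"loc_{arm}", t, t + test_len))
        test_windows = {fam: (t, t + test_len), nov: (t, t + test_len)}
        t += test_len
        roles = {"start": "context", "loc_armA": "context", "loc_armB": "context",
                 "armA": "object", "armB": "object"}
        return Schedule(events=events, test_windows=test_windows,
                        contrasts=[Contrast(nov, fam, "ymaze_sor")], roles=roles,
                        n_steps=t, meta={"preset": "sanderson", "key": key,
                                         "familiar": fam, "novel": nov})

    return PresetFamily("sanderson", build, keys, p)


_GOOD_DEFAULTS = dict(sample_minutes=5.0, isi_minutes=2.0, ri_minutes=2.0,
                      habituation_minutes=20.0)


def empirical_preset(name: str, **overrides) -> PresetFamily:
    """Build an empirical preset family by name.

    Names: ``good_sor``, ``good_rr``, ``good_oip``, ``good_rr_oip``,
    ``tam_sor``, ``tam_rr``, ``tam_oip``, ``whitt``, ``sanderson``.
    Tam presets accept ``ri_minutes`` (SOR/OIP) or ``isi_minutes`` (RR) as
    the manipulated delay; ``whitt`` accepts ``isi_minutes`` in {0.5, 4.0};
    ``sanderson`` accepts ``isi_minutes``/``ri_minutes`` in {1, 120}.
    """
    if name.startswith("good_"):
        task = name[len("good_"):]
        p = PresetParams(task=task, **{**_GOOD_DEFAULTS, **overrides})
        return _good_tam_family(name, p, test_minutes=5.0, delay_kind="ri")
    if name.startswith("tam_"):
        task = name[len("tam_"):]
        delay_kind = "isi" if task == "rr" else "ri"
        defaults = dict(sample_minutes=5.0, isi_minutes=2.0, ri_minutes=2.0,
                        habituation_minutes=20.0)
        if task == "rr":
            defaults["isi_minutes"] = 5.0
        else:
            defaults["ri_minutes"] = 5.0
        p = PresetParams(task=task, **{**defaults, **overrides})
        return _good_tam_family(name, p, test_minutes=3.0, delay_kind=delay_kind)
    if name == "whitt":
        defaults = dict(sample_minutes=0.5, test_minutes=2.0, isi_minutes=0.5,
                        ri_minutes=15.0, habituation_minutes=1.0, n_samples=8)
        p = PresetParams(task="sor_multisample", **{**defaults, **overrides})
        return _whitt_family(p)
    if name == "sanderson":
        defaults = dict(sample_minutes=1.0, test_minutes=2.0, isi_minutes=1.0,
                        ri_minutes=1.0, habituation_minutes=0.0, n_samples=10)
        p = PresetParams(task="ymaze", **{**defaults, **overrides})
        return _sanderson_family(p)
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = ["good_sor", "good_rr", "good_oip", "good_rr_oip",
                "tam_sor", "tam_rr", "tam_oip", "whitt", "sanderson"]


def enumerate_counterbalance(family: PresetFamily) -> list[Schedule]:
    """All context-order permutations of a preset; the count matches the
    closed-form factorial product for the design."""
    return [family.build(k) for k in family.keys()]
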