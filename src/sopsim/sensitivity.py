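"""Global and local sensitivity analyses of the recognition contrasts.

Three tiers over the conceptual task presets, all in the four-dimensional
space of the priming-relevant parameters (pd1, pd2, L+, L-), sampled
log-uniformly over [0.001, 1] with the salience values held canonical:

* **Parameter space partitioning (PSP)** -- classify each sampled point per
  task as *robust* (Q beats P by a proportional margin epsilon), *weak*
  (ordinal relation only) or *fail* (relation violated, or both peaks at or
  below a negligible-activity floor), and report region volumes, geometric
  summaries and constraint probabilities.
* **Sobol' variance decomposition** -- first-order, total-effect and
  second-order indices of the predicted contrast, from a Saltelli design on
  scrambled Sobol' sequences with study-style bootstrap CIs.
* **Local 2^4 factorial** -- contrast at the 16 corners obtained by +/-10%
  log-symmetric perturbation of the canonical point, with orthogonally coded
  effects and sum-of-squares shares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import engine
from .model import CANONICAL
from .schedules import conceptual_union_schedule

__all__ = [
    "ClassificationCriterion",
    "PARAM_NAMES",
    "LOG_BOUNDS",
    "classify_outcome",
    "conceptual_contrasts_batch",
    "PSPResult",
    "run_psp",
    "SobolResult",
    "run_sobol",
    "sobol_indices_from_design",
    "FactorialResult",
    "run_local_factorial",
]

PARAM_NAMES = ("pd1", "pd2", "L_plus", "L_minus")
#: log10 sampling bounds of the PSP/Sobol' prior
LOG_BOUNDS = (-3.0, 0.0)

TASKS = ("sor", "rr", "oip")


@dataclass(frozen=True)
class ClassificationCriterion:
    epsilon: float = 0.05
    floor: float = 0.005

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")


def classify_outcome(a1_q, a1_p, criterion: ClassificationCriterion):
    """Classify a contrast as 'robust', 'weak' or 'fail'.

    Vectorized; scalar inputs give a scalar label.  Negligible activity in
    both objects is a failure regardless of ordering, and ties count as
    failures (the ordinal relation is strict).
    """
    q = np.asarray(a1_q, dtype=float)
    p = np.asarray(a1_p, dtype=float)
    negligible = np.maximum(q, p) <= criterion.floor
    robust = (~negligible) & (q > (1.0 + criterion.epsilon) * p)
    weak = (~negligible) & (~robust) & (q > p)
    out = np.where(negligible, "fail",
                   np.where(robust, "robust", np.where(weak, "weak", "fail")))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# batched conceptual evaluation
# ---------------------------------------------------------------------------


def conceptual_contrasts_batch(
    pd1, pd2, L_plus, L_minus,
    isi_minutes: float = 2.0,
    ri_minutes: float = 2.0,
    tasks: tuple[str, ...] = TASKS,
    substeps: int = engine.DEFAULT_SUBSTEPS,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Peak A1 pairs (Q, P) per task for a batch of parameter points.

    The four parameter arrays share one shape (B,); p1 stays at the
    canonical 0.75 (objects) / 0.25 (contexts).  All requested tasks are
    evaluated on one union timeline, so shared conditions (the recent
    in-place object) are computed once.
    """
    pd1 = np.atleast_1d(np.asarray(pd1, dtype=float))
    B = pd1.shape[0]
    sch = conceptual_union_schedule(isi_minutes, ri_minutes, tasks=tuple(tasks))
    node_ids = sorted(sch.roles)
    is_object = [sch.roles[n] == "object" for n in node_ids]
    p1 = np.array([CANONICAL["p1_object"] if sch.roles[n] == "object"
                   else CANONICAL["p1_context"] for n in node_ids])
    index = {n: i for i, n in enumerate(node_ids)}
    links = [(index[s], index[t]) for s, t in sch.link_pairs]
    system = engine.System(
        node_ids=node_ids, is_object=is_object,
        p1=p1[:, None],
        pd1=np.broadcast_to(np.asarray(pd1, dtype=float), (len(node_ids), B)),
        pd2=np.broadcast_to(np.asarray(pd2, dtype=float), (len(node_ids), B)),
        masks=sch.masks(node_ids), links=links,
        L_plus=np.asarray(L_plus, dtype=float),
        L_minus=np.asarray(L_minus, dtype=float),
        batch_size=B,
    )
    res = engine.integrate(system, substeps=substeps, windows=sch.test_windows)
    out = {}
    for c in sch.contrasts:
        out[c.name] = (res.peaks[c.q], res.peaks[c.p])
    return out


def _sample_log_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = LOG_BOUNDS
    return 10.0 ** rng.uniform(lo, hi, size=(n, len(PARAM_NAMES)))


# ---------------------------------------------------------------------------
# parameter space partitioning
# ---------------------------------------------------------------------------


@dataclass
class PSPResult:
    """Volume proportions, region summaries and constraint probabilities."""

    volumes: pd.DataFrame       # outcome, task, epsilon, percent, sd
    regions: pd.DataFrame       # region, epsilon, parameter, geo_mean, gsd
    constraints: pd.DataFrame   # region, epsilon, P(pd1>pd2), P(L+>L-), joint
    n_samples: int = 0
    n_runs: int = 0
    per_run: pd.DataFrame | None = None


def run_psp(
    n_samples: int = 20_000,
    epsilons: tuple[float, ...] = (0.05, 0.10, 0.15),
    n_runs: int = 5,
    seed: int = 0,
    isi_minutes: float = 2.0,
    ri_minutes: float = 2.0,
    substeps: int = engine.DEFAULT_SUBSTEPS,
) -> PSPResult:
    """Monte-Carlo parameter space partitioning over the three tasks.

    Volumes are plain log-uniform Monte-Carlo fractions (volume in the
    log-space measure); the across-run standard deviation quantifies
    sampling noise.  Region summaries (geometric mean / geometric SD per
    parameter, constraint probabilities) are computed on the pooled points
    of the all-robust region and of the selective-failure region (SOR and RR
    robust, OIP fail).
    """
    run_rows = []
    pooled_points = []
    pooled_outcomes = {t: [] for t in TASKS}
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        theta = _sample_log_uniform(rng, n_samples)
        res = conceptual_contrasts_batch(*theta.T, isi_minutes, ri_minutes,
                                         substeps=substeps)
        pooled_points.append(theta)
        outcome_by_task = {}
        for task in TASKS:
            q, p = res[task]
            for eps in epsilons:
                lab = classify_outcome(q, p, ClassificationCriterion(eps))
                outcome_by_task[(task, eps)] = lab
                for outc in ("robust", "weak", "fail"):
                    run_rows.append((run, outc, task, eps,
                                     100.0 * np.mean(lab == outc)))
            pooled_outcomes[task].append(
                {eps: outcome_by_task[(task, eps)] for eps in epsilons})
        for eps in epsilons:
            all_robust = np.logical_and.reduce(
                [outcome_by_task[(t, eps)] == "robust" for t in TASKS])
            run_rows.append((run, "robust", "all", eps, 100.0 * all_robust.mean()))

    per_run = pd.DataFrame(run_rows, columns=["run", "outcome", "task",
                                              "epsilon", "percent"])
    volumes = (per_run.groupby(["outcome", "task", "epsilon"])["percent"]
               .agg(percent="mean", sd="std").reset_index())

    theta_all = np.vstack(pooled_points)
    lab_all = {
        (t, eps): np.concatenate([d[eps] for d in pooled_outcomes[t]])
        for t in TASKS for eps in epsilons
    }
    region_rows, constraint_rows = [], []
    for eps in epsilons:
        masks = {
            "all_robust": np.logical_and.reduce(
                [lab_all[(t, eps)] == "robust" for t in TASKS]),
            "impaired_oip": (lab_all[("sor", eps)] == "robust")
            & (lab_all[("rr", eps)] == "robust")
            & (lab_all[("oip", eps)] == "fail"),
        }
        for region, m in masks.items():
            pts = theta_all[m]
            if len(pts) == 0:
                continue
            logs = np.log(pts)
            for j, name in enumerate(PARAM_NAMES):
                region_rows.append((region, eps, name,
                                    float(np.exp(logs[:, j].mean())),
                                    float(np.exp(logs[:, j].std(ddof=1)))
                                    if len(pts) > 1 else np.nan))
            p_decay = float(np.mean(pts[:, 0] > pts[:, 1]))
            p_learn = float(np.mean(pts[:, 2] > pts[:, 3]))
            p_joint = float(np.mean((pts[:, 0] > pts[:, 1])
                                    & (pts[:, 2] > pts[:, 3])))
            constraint_rows.append((region, eps, p_decay, p_learn, p_joint, len(pts)))

    regions = pd.DataFrame(region_rows, columns=["region", "epsilon", "parameter",
                                                 "geo_mean", "gsd"])
    constraints = pd.DataFrame(constraint_rows,
                               columns=["region", "epsilon", "p_pd1_gt_pd2",
                                        "p_Lp_gt_Lm", "p_joint", "n_points"])
    return PSPResult(volumes=volumes, regions=regions, constraints=constraints,
                     n_samples=n_samples, n_runs=n_runs, per_run=per_run)


# ---------------------------------------------------------------------------
# Sobol' variance decomposition
# ---------------------------------------------------------------------------


def _saltelli_design(n_base: int, d: int, rng_seed: int) -> np.ndarray:
    """Second-order Saltelli design: rows [A; B; AB_i...; BA_i...].

    Returns an array of shape (n_base * (2d + 2), d) of points in [0, 1)^d
    built from one scrambled Sobol' sequence of dimension 2d.
    """
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=rng_seed)
    base = sampler.random(n_base)
    A, B = base[:, :d], base[:, d:]
    blocks = [A, B]
    for i in range(d):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(d):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    return np.vstack(blocks)


def sobol_indices_from_design(y: np.ndarray, n_base: int, d: int,
                              idx: np.ndarray | None = None):
    """Estimate S1, ST and closed second-order S2 from design outputs.

    ``y`` is ordered as produced by :func:`_saltelli_design`.  ``idx``
    optionally selects a bootstrap resample of the base rows.  Estimators:
    Saltelli-2010 for S1, Jansen for ST, and the closed-pair estimator
    (using the BA_i / AB_j blocks) minus the main effects for S2.
    """
    y = np.asarray(y, dtype=float)
    fA = y[:n_base]
    fB = y[n_base:2 * n_base]
    fAB = [y[(2 + i) * n_base:(3 + i) * n_base] for i in range(d)]
    fBA = [y[(2 + d + i) * n_base:(3 + d + i) * n_base] for i in range(d)]
    if idx is not None:
        fA, fB = fA[idx], fB[idx]
        fAB = [f[idx] for f in fAB]
        fBA = [f[idx] for f in fBA]
    allf = np.concatenate([fA, fB])
    V = allf.var()
    if V == 0:
        raise ZeroDivisionError("output variance is zero")
    S1 = np.array([np.mean(fB * (fAB[i] - fA)) / V for i in range(d)])
    ST = np.array([0.5 * np.mean((fA - fAB[i]) ** 2) / V for i in range(d)])
    S2 = {}
    f0sq = np.mean(fA * fB)
    for i, j in itertools.combinations(range(d), 2):
        Vij = np.mean(fBA[i] * fAB[j]) - f0sq
        S2[(i, j)] = Vij / V - S1[i] - S1[j]
    return S1, ST, S2


@dataclass
class SobolResult:
    task: str
    delay_minutes: float
    indices: pd.DataFrame       # parameter, S1, ST, ST_minus_S1 + CI half-widths
    s2: pd.DataFrame            # pair, S2, ci
    s_res: float
    s_res_ci: float
    n_base: int = 0
    n_runs: int = 0


def run_sobol(
    task: str,
    delay_minutes: float = 2.0,
    n_base: int = 1024,
    n_runs: int = 3,
    seed: int = 0,
    n_boot: int = 500,
    substeps: int = engine.DEFAULT_SUBSTEPS,
) -> SobolResult:
    """Sobol' indices of the conceptual contrast for one task and delay.

    The delay is the RI for SOR/OIP and the ISI for RR (the other interval
    stays at 2 min).  Parameters are sampled through the log10-uniform
    transform of the PSP prior; indices are averaged over ``n_runs``
    independently scrambled sequences, and the reported CI half-widths are
    the mean 95% bootstrap half-widths across runs.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if n_base & (n_base - 1):
        raise ValueError("n_base must be a power of two")
    d = len(PARAM_NAMES)
    lo, hi = LOG_BOUNDS
    isi, ri = (delay_minutes, 2.0) if task == "rr" else (2.0, delay_minutes)

    s1_runs, st_runs, s2_runs, sres_runs = [], [], [], []
    s1_ci, st_ci, s2_ci, sres_ci = [], [], [], []
    for run in range(n_runs):
        X = _saltelli_design(n_base, d, rng_seed=seed + run)
        theta = 10.0 ** (lo + (hi - lo) * X)
        res = conceptual_contrasts_batch(*theta.T, isi, ri, tasks=(task,),
                                         substeps=substeps)
        q, p = res[task]
        y = q - p
        if not np.isfinite(y).all():
            raise FloatingPointError("non-finite model output in Sobol' design")
        S1, ST, S2 = sobol_indices_from_design(y, n_base, d)
        sres = 1.0 - S1.sum() - sum(S2.values())
        s1_runs.append(S1); st_runs.append(ST); s2_runs.append(S2)
        sres_runs.append(sres)

        rng = np.random.default_rng(seed + 1000 + run)
        bs1, bst, bs2, bsres = [], [], [], []
        for _ in range(n_boot):
            idx = rng.integers(0, n_base, n_base)
            b1, bt, b2 = sobol_indices_from_design(y, n_base, d, idx=idx)
            bs1.append(b1); bst.append(bt)
            bs2.append([b2[k] for k in sorted(b2)])
            bsres.append(1.0 - b1.sum() - sum(b2.values()))
        half = lambda arr: (np.percentile(arr, 97.5, axis=0)
                            - np.percentile(arr, 2.5, axis=0)) / 2.0
        s1_ci.append(half(np.array(bs1)))
        st_ci.append(half(np.array(bst)))
        s2_ci.append(half(np.array(bs2)))
        sres_ci.append(half(np.array(bsres)))

    S1m = np.mean(s1_runs, axis=0)
    STm = np.mean(st_runs, axis=0)
    indices = pd.DataFrame({
        "parameter": PARAM_NAMES,
        "S1": S1m, "ST": STm, "ST_minus_S1": STm - S1m,
        "S1_ci": np.mean(s1_ci, axis=0), "ST_ci": np.mean(st_ci, axis=0),
    })
    pairs = sorted(itertools.combinations(range(d), 2))
    s2_mean = [np.mean([r[k] for r in s2_runs]) for k in pairs]
    s2 = pd.DataFrame({
        "pair": [f"{PARAM_NAMES[i]}x{PARAM_NAMES[j]}" for i, j in pairs],
        "S2": s2_mean,
        "S2_ci": np.mean(s2_ci, axis=0),
    })
    return SobolResult(task=task, delay_minutes=delay_minutes, indices=indices,
                       s2=s2, s_res=float(np.mean(sres_runs)),
                       s_res_ci=float(np.mean(sres_ci)),
                       n_base=n_base, n_runs=n_runs)


# ---------------------------------------------------------------------------
# local 2^4 factorial
# ---------------------------------------------------------------------------


@dataclass
class FactorialResult:
    task: str
    delay_minutes: float
    canonical_contrast: float
    corners: pd.DataFrame       # signs, contrast, ratio
    effects: pd.DataFrame       # term, order, effect, relative_effect, sst_share
    min_ratio: float = np.nan

    def reported_effects(self, min_share: float = 0.01) -> pd.DataFrame:
        return self.effects[self.effects.sst_share >= min_share].reset_index(drop=True)


def run_local_factorial(
    task: str,
    delay_minutes: float = 2.0,
    canonical: dict[str, float] | None = None,
    perturbation: float = 1.1,
    substeps: int = engine.DEFAULT_SUBSTEPS,
) -> FactorialResult:
    """Two-level full factorial around the canonical point.

    Corner c for parameter theta uses theta * perturbation^(+/-1)
    (log-symmetric).  Effects use orthogonal +/-1 coding: a term's effect is
    the mean of the corner contrasts multiplied by the product of its
    factors' signs (for a main effect, half the high-minus-low difference).
    SST shares are the squared effects normalized over all 15 non-constant
    terms; they are invariant to the half-vs-full effect convention.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be > 0")
    base = canonical or {n: CANONICAL[n] for n in PARAM_NAMES}
    theta0 = np.array([base[n] for n in PARAM_NAMES])
    isi, ri = (delay_minutes, 2.0) if task == "rr" else (2.0, delay_minutes)

    signs = np.array(list(itertools.product((-1, 1), repeat=len(PARAM_NAMES))))
    corners = theta0 * perturbation ** signs
    both = np.vstack([corners, theta0])
    res = conceptual_contrasts_batch(*both.T, isi, ri, tasks=(task,),
                                     substeps=substeps)
    q, p = res[task]
    contrasts = q[:-1] - p[:-1]
    ratios = np.where(p[:-1] > 0, q[:-1] / np.where(p[:-1] > 0, p[:-1], 1.0), np.inf)
    canonical_contrast = float(q[-1] - p[-1])

    rows = []
    for order in (1, 2, 3, 4):
        for combo in itertools.combinations(range(len(PARAM_NAMES)), order):
            coding = np.prod(signs[:, combo], axis=1)
            effect = float(np.mean(contrasts * coding))
            rows.append(("x".join(PARAM_NAMES[i] for i in combo), order, effect))
    eff = pd.DataFrame(rows, columns=["term", "order", "effect"])
    ss = eff.effect ** 2
    eff["sst_share"] = ss / ss.sum() if ss.sum() > 0 else 0.0
    if canonical_contrast == 0:
        raise ZeroDivisionError("canonical contrast is zero; relative effects undefined")
    eff["relative_effect"] = eff.effect / canonical_contrast

    corner_df = pd.DataFrame(signs, columns=PARAM_NAMES)
    corner_df["contrast"] = contrasts
    corner_df["ratio"] = ratios
    return FactorialResult(task=task, delay_minutes=delay_minutes,
                           canonical_contrast=canonical_contrast,
                           corners=corner_df, effects=eff,
                           min_ratio=float(np.min(ratios)))
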