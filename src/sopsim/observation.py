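"""Activation-to-seconds observation model.

The simulator's test output is a peak A1 in arbitrary activation units;
empirical studies report mean exploration seconds.  A single global scaling
constant k (seconds per A1 unit) links them, y_hat = k * A1_hat, estimated
by weighted least squares through the origin over all object-level records.

Weights are inverse-variance within each (study, task) cell, then equalized
in two stages so that every (study, task) cell within a study carries equal
weight and every study carries equal total weight -- no study or task
dominates just by reporting more object means.  Uncertainty in k comes from
an exact study-level bootstrap: all S^S ordered with-replacement resamples
of the S studies are enumerated and k refitted on each (weights
renormalized per resample), removing resampling noise entirely.

A synthetic multi-study generator stands in for published empirical
tables (whose values are figure-derived approximations and not distributed
here): it runs the task presets to obtain per-object peak A1 and emits
noisy exploration seconds with a known true scaling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EmpiricalRecord",
    "ObservationFit",
    "MetricsRow",
    "normalize_weights",
    "fit_k",
    "exact_study_bootstrap",
    "loso",
    "weighted_metrics",
    "contrast_table",
    "generate_synthetic_studies",
]

RECORD_COLUMNS = ["study", "task", "object", "role", "y", "se", "a1_hat"]


@dataclass(frozen=True)
class EmpiricalRecord:
    study: str
    task: str
    object: str
    role: str  # "Q" | "P"
    y: float   # observed mean exploration seconds
    se: float  # standard error of y
    a1_hat: float  # model peak A1 for this object

    def __post_init__(self) -> None:
        if self.y < 0:
            raise ValueError("y must be >= 0")
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if not 0.0 <= self.a1_hat <= 1.0:
            raise ValueError("a1_hat must lie in [0, 1]")


@dataclass
class ObservationFit:
    k: float
    weights: pd.Series
    fitted: pd.Series     # y_hat = k * a1_hat
    residuals: pd.Series  # e = y_hat - y
    ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class MetricsRow:
    scope: str
    n: int
    wBias: float
    wMAE: float
    wRMSE: float
    wR2: float | None = None
    sign_accuracy: float | None = None


def records_frame(records) -> pd.DataFrame:
    """Coerce records (DataFrame or iterable of EmpiricalRecord) to a frame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    return df


def normalize_weights(records, equal_within_cell: bool = False) -> pd.Series:
    """Two-stage equalized inverse-variance weights.

    Raw weights are 1/se^2.  Within each (study, task) cell they are rescaled
    to a common cell total; cells within a study share the study's weight
    equally, and studies share the overall weight equally (total = 1).  With
    ``equal_within_cell`` records inside a cell split its weight evenly
    regardless of their se (used for the combined-task contrast rule, where
    a procedure's component contrasts share its weight equally).
    """
    df = records_frame(records)
    if (df.se <= 0).any():
        raise ValueError("all standard errors must be > 0")
    if df.groupby(["study", "task"]).size().min() < 1:
        raise ValueError("empty (study, task) cell")
    raw = 1.0 / df.se**2 if not equal_within_cell else pd.Series(1.0, index=df.index)
    cell_tot = raw.groupby([df.study, df.task]).transform("sum")
    w = raw / cell_tot  # each cell sums to 1
    n_cells = df.groupby("study")["task"].transform("nunique")
    n_studies = df.study.nunique()
    w = w / n_cells / n_studies
    return w


def fit_k(records, weights: pd.Series | None = None) -> ObservationFit:
    """Closed-form WLS through the origin: k = sum(w a y) / sum(w a^2)."""
    df = records_frame(records)
    w = normalize_weights(df) if weights is None else pd.Series(
        np.asarray(weights, dtype=float), index=df.index)
    denom = float((w * df.a1_hat**2).sum())
    if denom <= 0:
        raise ZeroDivisionError("all model outputs are zero; k undefined")
    k = float((w * df.a1_hat * df.y).sum() / denom)
    fitted = k * df.a1_hat
    return ObservationFit(k=k, weights=w, fitted=fitted, residuals=fitted - df.y)


def exact_study_bootstrap(records, weights: pd.Series | None = None,
                          max_studies: int = 8) -> tuple[float, float]:
    """95% CI for k by enumerating all S^S ordered study resamples.

    Each resample draws S studies with replacement (order matters, so there
    are exactly S^S of them), reassembles the record table with the drawn
    studies relabeled as distinct draws, renormalizes the weights on the
    resample and refits k.  The interval is the 2.5/97.5 percentile pair of
    the enumerated distribution (linear interpolation).
    """
    df = records_frame(records)
    studies = sorted(df.study.unique())
    S = len(studies)
    if S > max_studies:
        raise ValueError(f"{S}^{S} resamples is too many to enumerate")
    # Weight normalization is study-local: every study's records carry a
    # fixed internal weight distribution summing to 1/S whatever the other
    # drawn studies are.  A resample's k is therefore a ratio of sums of
    # per-study moments u_s = sum(w a y) and v_s = sum(w a^2), which makes
    # the full S^S enumeration exact and cheap.
    w = normalize_weights(df)
    u = (w * df.a1_hat * df.y).groupby(df.study).sum()
    v = (w * df.a1_hat**2).groupby(df.study).sum()
    ks = []
    for draw in itertools.product(studies, repeat=S):
        denom = sum(v[s] for s in draw)
        if denom <= 0:
            raise ZeroDivisionError("resample with all-zero model outputs")
        ks.append(sum(u[s] for s in draw) / denom)
    lo, hi = np.percentile(ks, [2.5, 97.5])
    return float(lo), float(hi)


def loso(records) -> pd.DataFrame:
    """Leave-one-study-out: refit k without each study, report % change."""
    df = records_frame(records)
    studies = sorted(df.study.unique())
    if len(studies) < 2:
        raise ValueError("LOSO needs at least 2 studies")
    k_full = fit_k(df).k
    rows = []
    for s in studies:
        sub = df[df.study != s].reset_index(drop=True)
        k_s = fit_k(sub).k
        rows.append((s, k_s, 100.0 * (k_s - k_full) / k_full))
    return pd.DataFrame(rows, columns=["left_out", "k", "pct_change"])


def weighted_metrics(residuals, weights, y, level: str = "object") -> MetricsRow:
    """Weighted error metrics; sign accuracy only at the contrast level.

    wBias = sum(w e)/sum(w); wMAE = sum(w |e|)/sum(w);
    wRMSE = sqrt(sum(w e^2)/sum(w));
    wR2 = 1 - sum(w e^2) / sum(w (y - ybar_w)^2).
    At the contrast level ``y`` holds the observed deltas and ``e`` the
    delta residuals, so the predicted delta is e + y and sign accuracy is
    the weighted fraction with sign(e + y) == sign(y).
    """
    e = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not (len(e) == len(w) == len(yv)):
        raise ValueError("length mismatch")
    sw = w.sum()
    bias = float((w * e).sum() / sw)
    mae = float((w * np.abs(e)).sum() / sw)
    rmse = float(np.sqrt((w * e**2).sum() / sw))
    ybar = (w * yv).sum() / sw
    ss_tot = (w * (yv - ybar) ** 2).sum()
    r2 = float(1.0 - (w * e**2).sum() / ss_tot) if ss_tot > 0 else None
    sign_acc = None
    if level == "contrast":
        pred = e + yv
        sign_acc = float((w * (np.sign(pred) == np.sign(yv))).sum() / sw)
    return MetricsRow(scope=level, n=len(e), wBias=bias, wMAE=mae, wRMSE=rmse,
                      wR2=r2, sign_accuracy=sign_acc)


def contrast_table(records, k: float,
                   combined_tasks: tuple[str, ...] = ("rr_oip",)) -> pd.DataFrame:
    """Per-(study, task, pair) contrast deltas with contrast-level weights.

    Observed delta is y(Q) - y(P); predicted delta is k * (A1(Q) - A1(P)) --
    exactly linear in the object contrast.  Contrast weights follow the
    object-level scheme on the propagated variance se_Q^2 + se_P^2, except
    that a combined task's component contrasts split that task's weight
    equally.
    """
    df = records_frame(records)
    rows = []
    for (study, task), cell in df.groupby(["study", "task"]):
        qs = cell[cell.role == "Q"].reset_index()
        ps = cell[cell.role == "P"].reset_index()
        n = min(len(qs), len(ps))
        for i in range(n):
            qrow, prow = qs.iloc[i], ps.iloc[i]
            rows.append((study, task, f"{qrow.object}-{prow.object}",
                         qrow.y - prow.y, k * (qrow.a1_hat - prow.a1_hat),
                         float(np.sqrt(qrow.se**2 + prow.se**2))))
    con = pd.DataFrame(rows, columns=["study", "task", "pair", "delta_y",
                                      "delta_y_hat", "se"])
    pseudo = con.assign(object=con.pair, role="Q", y=con.delta_y, a1_hat=0.0)
    w_iv = normalize_weights(pseudo)
    w_eq = normalize_weights(pseudo, equal_within_cell=True)
    # a combined procedure's component contrasts split its weight equally;
    # cell/study totals are identical under both rules, so no renormalization
    combined = con.task.isin(combined_tasks).to_numpy()
    con["weight"] = np.where(combined, w_eq, w_iv)
    con["residual"] = con.delta_y_hat - con.delta_y
    return con


# ---------------------------------------------------------------------------
# synthetic multi-study fixture generator
# ---------------------------------------------------------------------------

_A1_CACHE: dict[tuple, dict[str, tuple[float, float]]] = {}


def _conceptual_a1(task: str, isi: float, ri: float) -> tuple[float, float]:
    from .sensitivity import conceptual_contrasts_batch

    key = (task, isi, ri)
    if key not in _A1_CACHE:
        res = conceptual_contrasts_batch([0.1], [0.02], [0.25], [0.025],
                                         isi, ri, tasks=(task,))
        q, p = res[task]
        _A1_CACHE[key] = (float(q[0]), float(p[0]))
    return _A1_CACHE[key]


def generate_synthetic_studies(
    k_true: float = 50.0,
    n_studies: int = 4,
    tasks: tuple[str, ...] = ("sor", "rr", "oip"),
    noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic multi-study record table with known scaling.

    Each study runs the conceptual presets at study-specific delays (drawn
    from {2, 5, 8} min) to obtain per-object peak A1 under the canonical
    parameters, then reports y = k_true * A1 + N(0, noise_sd^2) seconds
    (clipped at zero) with plausible heteroscedastic standard errors.
    Reproducible under ``seed``.
    """
    if k_true <= 0:
        raise ValueError("k_true must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    delays = np.array([2.0, 5.0, 8.0])
    rows = []
    for s in range(n_studies):
        study = f"study{s + 1}"
        for task in tasks:
            isi = float(rng.choice(delays))
            ri = float(rng.choice(delays))
            a1_q, a1_p = _conceptual_a1(task, isi, ri)
            for obj, role, a1 in ((f"{task}_Q", "Q", a1_q), (f"{task}_P", "P", a1_p)):
                y = max(0.0, k_true * a1 + rng.normal(0.0, noise_sd))
                se = float(rng.uniform(0.8, 2.5))
                rows.append((study, task, obj, role, y, se, a1))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
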