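"""Progression analysis over longitudinal pattern probabilities.

Subjects are assigned a dominant pattern at baseline only when its
probability strictly exceeds 0.5 (otherwise they are "unassigned" and
excluded from survival analyses). Conversion to a target pattern is the
first visit at which that pattern's probability strictly exceeds the
threshold; subjects never converting are right-censored at their last
visit. On the resulting event tables the module exposes Kaplan–Meier
curves, Aalen–Johansen cumulative incidence for competing targets,
Harrell's concordance index, repeated two-fold cross-validated Cox
proportional-hazards prediction, and fixed-horizon ROC discrimination with
the sensitivity-equals-specificity operating threshold. Survival machinery
is delegated to lifelines; everything around it (event construction,
splits, scoring rules) is defined here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# dominant-pattern assignment and event tables
# ---------------------------------------------------------------------------

def assign_dominant_pattern(probs, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from simplex rows; strictly-greater-than-threshold rule.

    Returns the argmax pattern index where its probability > threshold,
    else :data:`UNASSIGNED` (−1). Exact argmax ties resolve to the lowest
    index. A threshold at or below 1/M (where several patterns could tie
    around it) or above 1 draws a warning.
    """
    P = probs.probs if hasattr(probs, "probs") else np.asarray(probs, dtype=float)
    M = P.shape[1]
    if not (1.0 / M < threshold <= 1.0):
        warnings.warn(
            f"threshold {threshold} outside (1/{M}, 1]; assignment may be ambiguous",
            stacklevel=2,
        )
    labels = np.argmax(P, axis=1)
    top = P[np.arange(len(P)), labels]
    return np.where(top > threshold, labels, UNASSIGNED)


@dataclass
class EventTable:
    """One record per subject: event type, time, and baseline features.

    ``event`` is 0 for censored records (time = last follow-up) and a
    positive integer code otherwise; ``event_names`` maps codes to pattern
    names. ``features`` holds baseline risk features aligned by row.
    """

    subject_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    event_names: dict[int, str]
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("event times must be non-negative")
        if len(self.subject_id) != len(set(self.subject_id)):
            raise ValueError("one record per subject expected")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def observed(self) -> np.ndarray:
        return self.event != 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "time": self.time, "event": self.event}
        )
        if self.features is not None:
            df = pd.concat([df, self.features.reset_index(drop=True)], axis=1)
        return df


def build_pattern_event_table(
    prob_long: pd.DataFrame,
    source: str,
    targets: list[str],
    threshold: float = 0.5,
    baseline_threshold: float = 0.7,
) -> EventTable:
    """Pattern-conversion events from longitudinal probability trajectories.

    ``prob_long`` needs columns ``participant_id``, ``visit_time`` and one
    probability column per pattern (e.g. P1..P4). Subjects are kept when
    they have >= 2 visits and their baseline ``source`` probability exceeds
    ``baseline_threshold``. The event is the first post-baseline visit at
    which any target's probability strictly exceeds ``threshold`` (competing
    targets become distinct event types; if several cross at the same visit
    the earliest-listed target wins); non-converters are censored at the
    last visit. Times are years since baseline.
    """
    needed = {"participant_id", "visit_time", source, *targets}
    missing = needed - set(prob_long.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    ids, times, events, feats = [], [], [], []
    for pid, grp in prob_long.groupby("participant_id", sort=False):
        t = grp["visit_time"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"visit times not sorted for participant {pid!r}")
        if len(grp) < 2:
            continue
        if not grp.iloc[0][source] > baseline_threshold:
            continue
        event, etime = 0, t[-1] - t[0]
        for i in range(1, len(grp)):
            hit = [k for k, tg in enumerate(targets) if grp.iloc[i][tg] > threshold]
            if hit:
                event, etime = hit[0] + 1, t[i] - t[0]
                break
        ids.append(pid)
        times.append(etime)
        events.append(event)
        feats.append({f"baseline_{tg}": grp.iloc[0][tg] for tg in targets})

    return EventTable(
        subject_id=np.asarray(ids, dtype=object),
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        event_names={k + 1: tg for k, tg in enumerate(targets)},
        features=pd.DataFrame(feats) if feats else None,
    )


# ---------------------------------------------------------------------------
# survival estimators (delegated to lifelines)
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    time: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    fitter: KaplanMeierFitter

    def at(self, t) -> np.ndarray:
        """Step-function evaluation S(t)."""
        return self.fitter.predict(t)


def kaplan_meier(events: EventTable) -> SurvivalCurve:
    """Product-limit estimator with Greenwood-based confidence band."""
    if len(events) == 0:
        raise ValueError("empty event table")
    if not events.observed.any():
        warnings.warn("all records censored; survival is identically 1", stacklevel=2)
    kmf = KaplanMeierFitter()
    kmf.fit(events.time, events.observed)
    ci = kmf.confidence_interval_survival_function_
    return SurvivalCurve(
        time=kmf.survival_function_.index.to_numpy(),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        fitter=kmf,
    )


def logrank(events_a: EventTable, events_b: EventTable) -> float:
    """Two-group log-rank test p-value."""
    from lifelines.statistics import logrank_test

    res = logrank_test(
        events_a.time, events_b.time, events_a.observed, events_b.observed
    )
    return float(res.p_value)


def cumulative_incidence_competing(events: EventTable) -> dict[int, pd.DataFrame]:
    """Aalen–Johansen cause-specific cumulative incidence per event type.

    Cause incidences and the all-cause event-free probability sum to 1 at
    every time point.
    """
    codes = sorted(set(events.event[events.event != 0]))
    if not codes and not (~events.observed).any():
        raise ValueError("no events and no censoring; nothing to estimate")
    out: dict[int, pd.DataFrame] = {}
    for code in codes:
        ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf.fit(events.time, events.event, event_of_interest=code)
        cif = ajf.cumulative_density_
        out[code] = pd.DataFrame(
            {"time": cif.index.to_numpy(), "incidence": cif.iloc[:, 0].to_numpy()}
        )
    return out


def incidence_at(curve: pd.DataFrame, t: float) -> float:
    """Right-continuous step lookup on a cumulative-incidence frame."""
    idx = np.searchsorted(curve["time"].to_numpy(), t, side="right") - 1
    return float(curve["incidence"].iloc[idx]) if idx >= 0 else 0.0


# ---------------------------------------------------------------------------
# predictive-ability metrics
# ---------------------------------------------------------------------------

def concordance_index(risk, events: EventTable) -> float:
    """Harrell's C: fraction of comparable pairs correctly ordered by risk.

    Higher risk must pair with earlier events; risk ties count 0.5.
    Refuses when no pair is comparable (e.g. everything censored).
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(events):
        raise ValueError("risk scores not aligned with the event table")
    try:
        # lifelines scores "higher predicted value = longer survival"
        return float(_lifelines_cindex(events.time, -risk, events.observed))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs in the event table") from err


@dataclass
class CVCindexResult:
    values: np.ndarray  # one C per (repeat, fold), NaN where the fit failed

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def repeated_cv_cox_cindex(
    features: pd.DataFrame,
    events: EventTable,
    n_repeats: int = 100,
    folds: int = 2,
    rng: np.random.Generator | None = None,
) -> CVCindexResult:
    """Repeated k-fold CV of a Cox PH model, validation C-index per fold.

    Per repeat the subjects are randomly split into ``folds`` parts; a Cox
    proportional-hazards model fit on the training part scores the held-out
    part by its partial hazard (the composite risk score), and Harrell's C
    is computed on the held-out part. Returns all n_repeats·folds values.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(features) != len(events):
        raise ValueError("features not aligned with the event table")
    df = features.reset_index(drop=True).copy()
    df["time"] = events.time
    df["event"] = events.observed.astype(int)
    n = len(df)
    values = np.full(n_repeats * folds, np.nan)
    for rep in range(n_repeats):
        order = rng.permutation(n)
        parts = np.array_split(order, folds)
        for k in range(folds):
            val_idx = parts[k]
            train_idx = np.concatenate([parts[j] for j in range(folds) if j != k])
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df.iloc[train_idx], duration_col="time", event_col="event")
                risk = cph.predict_partial_hazard(df.iloc[val_idx]).to_numpy()
                sub = EventTable(
                    subject_id=np.asarray([f"s{i}" for i in val_idx], dtype=object),
                    time=events.time[val_idx],
                    event=events.event[val_idx],
                    event_names=events.event_names,
                )
                values[rep * folds + k] = concordance_index(risk, sub)
            except (ConvergenceError, ValueError) as err:
                logger.warning("CV repeat %d fold %d failed: %s", rep, k, err)
    return CVCindexResult(values=values)


def horizon_discrimination(
    baseline_score,
    events: EventTable,
    horizons,
    tol: float = 1e-9,
) -> dict[float, dict[str, float]]:
    """Fixed-horizon ROC discrimination of conversion by a baseline score.

    For each horizon X the binary outcome is "converted before or at X";
    subjects censored before X are excluded at that horizon. Reports the
    AUC and the operating threshold at which TPR + FPR = 1 (sensitivity =
    specificity), located by linear interpolation along the ROC curve.
    Horizons with no positives or no negatives are reported with NaNs.
    """
    score = np.asarray(baseline_score, dtype=float)
    if len(score) != len(events):
        raise ValueError("scores not aligned with the event table")
    out: dict[float, dict[str, float]] = {}
    for X in horizons:
        if X <= 0:
            raise ValueError("horizons must be positive")
        pos = events.observed & (events.time <= X)
        neg = events.time > X
        keep = pos | neg
        y = pos[keep].astype(int)
        s = score[keep]
        if y.sum() == 0 or y.sum() == len(y):
            out[float(X)] = {
                "auc": float("nan"),
                "threshold": float("nan"),
                "n_pos": int(y.sum()),
                "n_neg": int(len(y) - y.sum()),
            }
            continue
        auc = roc_auc_score(y, s)
        fpr, tpr, thr = roc_curve(y, s)
        f = tpr + fpr - 1.0  # monotone non-decreasing along the curve
        j = int(np.searchsorted(f, 0.0, side="left"))  # first f >= 0
        if j >= len(f):
            threshold = float(thr[-1])
        elif f[j] <= tol or j == 0 or not np.isfinite(thr[j - 1]):
            threshold = float(thr[j])
        else:
            w = -f[j - 1] / (f[j] - f[j - 1])
            threshold = float(thr[j - 1] + w * (thr[j] - thr[j - 1]))
        out[float(X)] = {
            "auc": float(auc),
            "threshold": threshold,
            "n_pos": int(y.sum()),
            "n_neg": int(len(y) - y.sum()),
        }
    return out
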