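"""Efficacy and welfare endpoints for tumor-bearing cohorts.

Tumor volume is the caliper product length × width × height (mm³);
survival is summarised with the Kaplan–Meier product-limit estimator
(median = earliest time at which S(t) ≤ 0.5); and humane-endpoint rules
(volume threshold, weight-loss rules, observed welfare flags) are evaluated
per animal from its measurement history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import InsufficientDataError, OrderingError

__all__ = [
    "tumor_volume",
    "KMCurve",
    "km_curve",
    "evaluate_termination",
    "load_survival_csv",
    "load_tumor_csv",
]

TUMOR_VOLUME_LIMIT_MM3 = 1000.0
WEIGHT_LOSS_CONSECUTIVE = 0.15  # >15 % below initial on 2 consecutive days
WEIGHT_LOSS_TOTAL = 0.20       # >=20 % below initial at any point


def tumor_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Caliper tumor volume, length × width × height (mm³)."""
    if min(length_mm, width_mm, height_mm) < 0:
        raise ValueError("dimensions must be >= 0")
    return length_mm * width_mm * height_mm


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit curve for one cohort."""

    timeline: np.ndarray           # event/censor times, ascending
    survival: np.ndarray           # S(t) immediately after each time
    median: float | None           # earliest t with S(t) <= 0.5, None if never
    n: int

    def survival_at(self, t) -> np.ndarray | float:
        """Right-continuous step evaluation of S(t); S = 1 before first time."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.timeline, t_arr, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(s) if t_arr.ndim == 0 else s


def km_curve(time_weeks, event) -> KMCurve:
    """Kaplan–Meier estimate from per-animal times and event flags.

    ``event`` is 1 when the animal met a termination criterion and 0 when it
    was censored (alive at study end).  Ties between events and censoring at
    the same time are resolved events-first (the lifelines convention).
    """
    time_weeks = np.asarray(time_weeks, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time_weeks) == 0:
        raise InsufficientDataError("need at least one survival record")
    if np.any(time_weeks <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time_weeks, event_observed=event)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor lifelines inserts; S=1 before the first time is
    # handled by survival_at
    if timeline[0] == 0.0:
        timeline, surv = timeline[1:], surv[1:]
    # earliest time with S(t) <= 0.5; tolerance guards exact-half ties against
    # floating-point product noise
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(timeline[below[0]]) if below.size else None
    return KMCurve(timeline=timeline, survival=surv, median=median, n=len(time_weeks))


def evaluate_termination(
    history: pd.DataFrame,
    welfare_flags: list[str] | None = None,
) -> dict[str, object]:
    """Evaluate humane-endpoint rules on one animal's measurement history.

    ``history`` columns: time_d, length_mm, width_mm, height_mm, weight_g,
    chronologically ordered.  Rules, in priority order:

    * tumor volume ≥ 1000 mm³                          → ``volume``
    * >15 % below initial weight on 2 consecutive
      measurement days                                 → ``weight_consecutive``
    * ≥20 % below initial weight on any day            → ``weight_total``
    * any externally observed welfare flag             → ``welfare:<flag>``
    """
    t = history["time_d"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise OrderingError("measurement history must be chronologically ordered")
    volumes = (
        history["length_mm"].to_numpy(dtype=float)
        * history["width_mm"].to_numpy(dtype=float)
        * history["height_mm"].to_numpy(dtype=float)
    )
    if np.any(volumes >= TUMOR_VOLUME_LIMIT_MM3):
        return {"terminate": True, "reason": "volume"}
    weights = history["weight_g"].to_numpy(dtype=float)
    initial = weights[0]
    loss = 1.0 - weights / initial
    over15 = loss > WEIGHT_LOSS_CONSECUTIVE + 1e-12
    if np.any(over15[:-1] & over15[1:]):
        return {"terminate": True, "reason": "weight_consecutive"}
    if np.any(loss >= WEIGHT_LOSS_TOTAL - 1e-12):
        return {"terminate": True, "reason": "weight_total"}
    if welfare_flags:
        return {"terminate": True, "reason": f"welfare:{welfare_flags[0]}"}
    return {"terminate": False, "reason": None}


def load_survival_csv(path) -> pd.DataFrame:
    """Survival CSV: animal_id, group, time_weeks, event."""
    df = pd.read_csv(path, comment="#")
    missing = {"animal_id", "group", "time_weeks", "event"} - set(df.columns)
    if missing:
        raise InsufficientDataError(f"survival CSV missing columns {sorted(missing)}")
    return df


def load_tumor_csv(path) -> pd.DataFrame:
    """Tumor CSV: animal_id, time_d, length_mm, width_mm, height_mm, weight_g."""
    df = pd.read_csv(path, comment="#")
    missing = {"animal_id", "time_d", "length_mm", "width_mm", "height_mm", "weight_g"} - set(
        df.columns
    )
    if missing:
        raise InsufficientDataError(f"tumor CSV missing columns {sorted(missing)}")
    return df
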