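"""Behavioral learning curves and item grouping.

Naming speed over the 12 training days is summarized per subject as the
mean of the word-naming and picture-naming reaction times, and fitted
with a power law RT = a * day^(-b): ``a`` is initial performance (ms) and
``b`` the dimensionless learning rate (larger = faster learning).  The
goodness-of-fit (R^2 on the original millisecond scale) gates which
subjects enter learning-rate analyses; the post-training outcome is the
mean RT over the plateau days (5-12).  Items are split into fast/slow
halves at the median of their post-training RTs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorTable",
    "LearningFit",
    "daily_mean_rt",
    "post_training_outcome",
    "fit_power_curve",
    "filter_fits",
    "median_split_items",
]


@dataclass(frozen=True)
class BehaviorTable:
    """Long-format behavioral data.

    ``data`` columns: subject, day, task, rt (ms), accuracy (proportion).
    ``item_rt`` (optional) columns: item, day, task, rt — group-level
    per-item reaction times used by the median-split analysis.
    """

    data: pd.DataFrame
    item_rt: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"subject", "day", "task", "rt", "accuracy"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"behavior table missing columns: {sorted(missing)}")
        if (self.data["rt"] <= 0).any():
            raise ValidationError("reaction times must be positive")
        acc = self.data["accuracy"]
        if ((acc < 0) | (acc > 1)).any():
            raise ValidationError("accuracy must lie in [0, 1]")
        days = sorted(self.data["day"].unique())
        if days != list(range(1, len(days) + 1)):
            raise ValidationError("days must be consecutive integers starting at 1")
        if self.item_rt is not None:
            req = {"item", "day", "task", "rt"}
            if req - set(self.item_rt.columns):
                raise ValidationError("item_rt table missing required columns")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["subject"]))

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["day"].unique()))

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["task"]))


@dataclass(frozen=True)
class LearningFit:
    """Power-law fit of one subject's learning curve."""

    a: float
    b: float
    r2: float
    converged: bool
    n_days: int
    message: str = ""


def daily_mean_rt(behavior: BehaviorTable) -> pd.DataFrame:
    """Per-subject per-day naming speed: the unweighted mean RT over the
    naming tasks.  Every (subject, day) must have all tasks present."""
    tasks = behavior.tasks
    counts = behavior.data.groupby(["subject", "day"])["task"].nunique()
    bad = counts[counts != len(tasks)]
    if len(bad):
        subject, day = bad.index[0]
        raise ValidationError(
            f"missing task data for subject {subject!r} on day {day}"
        )
    out = (
        behavior.data.groupby(["subject", "day"], sort=True)["rt"]
        .mean()
        .reset_index()
    )
    return out


def post_training_outcome(
    behavior: BehaviorTable, task: str, day_range: tuple[int, int] = (5, 12)
) -> pd.Series:
    """Per-subject outcome RT: mean over the plateau days (default 5-12)
    for one naming task."""
    lo, hi = day_range
    if task not in behavior.tasks:
        raise ValidationError(f"unknown task {task!r}")
    have = set(behavior.days)
    need = set(range(lo, hi + 1))
    if not need <= have:
        raise ValidationError(
            f"days {sorted(need - have)} required for the outcome are missing"
        )
    sub = behavior.data[
        (behavior.data["task"] == task)
        & behavior.data["day"].between(lo, hi)
    ]
    out = sub.groupby("subject", sort=False)["rt"].mean()
    return out.loc[list(behavior.subjects)]


def _power(x, a, b):
    return a * np.power(x, -b)


def fit_power_curve(days: np.ndarray, rts: np.ndarray) -> LearningFit:
    """Nonlinear least-squares fit of RT = a * day^(-b).

    Starting values come from ordinary least squares on log RT vs log day
    (deterministic); refinement runs on the original millisecond scale,
    and R^2 is computed there too.  A constant RT series yields b ~ 0 and
    an undefined R^2 (reported as NaN).
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(rts, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValidationError("days and rts must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValidationError("at least 3 days are required to fit the curve")
    if np.any(x <= 0):
        raise ValidationError("days must be positive")
    if np.any(y <= 0):
        raise ValidationError("reaction times must be positive")

    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    p0 = [float(np.exp(intercept)), float(-slope)]
    converged = True
    message = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_power, x, y, p0=p0, maxfev=20000)
        a_hat, b_hat = float(popt[0]), float(popt[1])
    except RuntimeError as err:  # no convergence within maxfev
        a_hat, b_hat = p0
        converged = False
        message = f"refinement did not converge: {err}"
        logger.warning("power-curve fit failed to converge: %s", err)

    resid = y - _power(x, a_hat, b_hat)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = float("nan")
        message = message or "constant RT series: R^2 undefined"
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LearningFit(a_hat, b_hat, r2, converged, x.size, message)


def filter_fits(
    fits: Mapping[str, LearningFit], r2_min: float = 0.7
) -> tuple[dict[str, LearningFit], dict[str, LearningFit]]:
    """Split fits into (kept, excluded) by the goodness-of-fit rule:
    excluded if R^2 < ``r2_min``, R^2 is undefined, or the fit did not
    converge."""
    if not (0 <= r2_min <= 1):
        raise ValidationError("r2_min must lie in [0, 1]")
    kept: dict[str, LearningFit] = {}
    excluded: dict[str, LearningFit] = {}
    for subject, fit in fits.items():
        ok = fit.converged and np.isfinite(fit.r2) and fit.r2 >= r2_min
        (kept if ok else excluded)[subject] = fit
    return kept, excluded


def median_split_items(item_outcomes: pd.Series) -> tuple[list, list]:
    """Split items into (fast, slow) halves at the median outcome RT.

    Items at or below the median go to the fast group.  Ties are broken
    by a stable sort on (RT, item id), so the two groups always differ in
    size by at most one.
    """
    if len(item_outcomes) < 2:
        raise ValidationError("median split requires at least 2 items")
    if item_outcomes.nunique() == 1:
        logger.warning("all item RTs are equal; splitting by stable item order")
    order = item_outcomes.reset_index()
    order.columns = ["item", "rt"]
    order = order.sort_values(["rt", "item"], kind="stable")
    n_fast = (len(order) + 1) // 2
    fast = order["item"].iloc[:n_fast].tolist()
    slow = order["item"].iloc[n_fast:].tolist()
    return fast, slow
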