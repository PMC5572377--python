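"""Rapid event-related design generation.

A single run presents every item of every condition twice, with the two
presentations of an item separated by a bounded number of intervening
trials, plus a handful of filler (catch) trials interleaved uniformly at
random.  Inter-stimulus intervals are jittered on a discrete grid with a
truncated-geometric profile calibrated so the expected ISI matches the
requested mean — the "many short, few long" shape typical of optimized
rapid event-related sequences.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleDesignError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "Trial",
    "EventSchedule",
    "generate_event_schedule",
    "schedule_summary",
    "validate_schedule",
    "isi_distribution",
]


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one passive-viewing run.

    Defaults reproduce a 3-language design: 3 conditions x 30 items x 2
    repetitions plus 9 underlined filler words (189 trials), 0.6 s
    stimulus duration, ISIs jittered on [1, 5] s with mean 2 s, the two
    presentations of an item spaced by 4-8 intervening trials, TR 2 s.
    """

    n_conditions: int = 3
    n_items_per_condition: int = 30
    n_repetitions: int = 2
    n_fillers: int = 9
    stim_duration: float = 0.6
    isi_min: float = 1.0
    isi_max: float = 5.0
    isi_mean: float = 2.0
    spacing_min: int = 4
    spacing_max: int = 8
    tr: float = 2.0
    seed: int | None = None
    condition_names: tuple[str, ...] | None = None
    isi_step: float = 0.5
    max_restarts: int = 1000

    def __post_init__(self) -> None:
        if self.n_conditions < 1 or self.n_items_per_condition < 1:
            raise ValidationError("condition and item counts must be positive")
        if self.n_fillers < 0:
            raise ValidationError("n_fillers must be >= 0")
        if self.n_repetitions != 2:
            raise ValidationError(
                "only designs with exactly 2 repetitions per item are supported"
            )
        if self.stim_duration <= 0 or self.tr <= 0:
            raise ValidationError("stim_duration and tr must be positive")
        if not (self.isi_min <= self.isi_mean <= self.isi_max):
            raise ValidationError("require isi_min <= isi_mean <= isi_max")
        if self.isi_min < self.isi_max and not (
            self.isi_min < self.isi_mean < self.isi_max
        ):
            raise ValidationError(
                "isi_mean must lie strictly inside (isi_min, isi_max) "
                "unless the interval is a single point"
            )
        if not (0 <= self.spacing_min <= self.spacing_max):
            raise ValidationError("require 0 <= spacing_min <= spacing_max")
        if self.isi_step <= 0:
            raise ValidationError("isi_step must be positive")
        if self.max_restarts < 1:
            raise ValidationError("max_restarts must be >= 1")

    @property
    def n_word_trials(self) -> int:
        return self.n_conditions * self.n_items_per_condition * self.n_repetitions

    @property
    def n_trials(self) -> int:
        return self.n_word_trials + self.n_fillers

    def conditions(self) -> tuple[str, ...]:
        if self.condition_names is not None:
            if len(self.condition_names) != self.n_conditions:
                raise ValidationError("condition_names length != n_conditions")
            return self.condition_names
        if self.n_conditions == 3:
            return ("artificial", "chinese", "english")
        return tuple(f"cond{i + 1}" for i in range(self.n_conditions))


@dataclass(frozen=True)
class Trial:
    onset: float
    condition: str
    item: str
    repetition: int
    is_filler: bool


@dataclass(frozen=True)
class EventSchedule:
    """An ordered trial list with onsets in seconds."""

    trials: tuple[Trial, ...]
    total_duration: float
    stim_duration: float = 0.6

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    @property
    def isis(self) -> np.ndarray:
        """Gaps between stimulus offset and the next stimulus onset."""
        on = self.onsets
        return np.diff(on) - self.stim_duration

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset": [t.onset for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "item": [t.item for t in self.trials],
                "repetition": [t.repetition for t in self.trials],
                "is_filler": [t.is_filler for t in self.trials],
            }
        )


def isi_distribution(spec: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Discrete jitter distribution on the ISI grid.

    Values are ``isi_min, isi_min + step, ..., isi_max`` with weights
    ``q**k``; ``q`` is solved numerically so the expectation equals
    ``isi_mean`` exactly.  ``q < 1`` (short ISIs dominate) whenever the
    target mean is below the grid midpoint.
    """
    if spec.isi_min == spec.isi_max:
        return np.array([spec.isi_min]), np.array([1.0])
    n = int(round((spec.isi_max - spec.isi_min) / spec.isi_step)) + 1
    values = spec.isi_min + spec.isi_step * np.arange(n)
    k = np.arange(n)

    def mean_minus_target(q: float) -> float:
        w = q**k
        return float(values @ w / w.sum()) - spec.isi_mean

    q = brentq(mean_minus_target, 1e-12, 1e6, xtol=1e-14, rtol=1e-14)
    probs = q**k
    probs /= probs.sum()
    return values, probs


def _attempt_order(
    rng: np.random.Generator, items: list[tuple[str, str]], spec: DesignSpec
) -> list[tuple[str, str, int, bool] | None] | None:
    """One randomized constructive pass; ``None`` on dead end.

    Fillers are pinned to uniformly random positions first; word slots are
    then filled left to right.  At each word slot any already-started item
    whose spacing window closes here is forced; otherwise the trial is
    drawn uniformly from items currently inside their window plus items
    not yet started (if a feasible second slot exists for them).
    """
    n_total = spec.n_trials
    smin, smax = spec.spacing_min, spec.spacing_max
    if spec.n_fillers:
        filler_pos = set(
            rng.choice(n_total, size=spec.n_fillers, replace=False).tolist()
        )
    else:
        filler_pos = set()
    word_slots = [p for p in range(n_total) if p not in filler_pos]

    def slot_in(lo: int, hi: int) -> int | None:
        """Largest word slot in [lo, hi], or None."""
        idx = bisect.bisect_right(word_slots, hi) - 1
        if idx >= 0 and word_slots[idx] >= lo:
            return word_slots[idx]
        return None

    unstarted = list(range(len(items)))
    rng.shuffle(unstarted)
    # item index -> (first position, target position for the second showing);
    # the target gap is drawn uniformly on [smin, smax] so realized spacing
    # spreads over the whole window instead of piling up at the deadline
    open_first: dict[int, tuple[int, int]] = {}
    seq: list[tuple[str, str, int, bool] | None] = [None] * n_total

    for p in word_slots:
        forced = []
        ripe = []  # inside the window and at/past their target position
        due = []
        for j, (p1, target) in open_first.items():
            lo, hi = p1 + smin + 1, p1 + smax + 1
            if hi < p:
                return None  # deadline already missed
            last = slot_in(lo, hi)
            if last is None:
                return None  # window contains no word slot at all
            if lo <= p <= hi:
                due.append(j)
                if p >= target:
                    ripe.append(j)
            if last == p:
                forced.append(j)
        if len(forced) > 1:
            return None
        if forced:
            choice, is_new = forced[0], False
        elif ripe:
            choice = ripe[int(rng.integers(len(ripe)))]
            is_new = False
        else:
            startable = (
                bool(unstarted)
                and slot_in(p + smin + 1, p + smax + 1) is not None
            )
            if startable:
                choice = unstarted[int(rng.integers(len(unstarted)))]
                is_new = True
            elif due:
                choice = due[int(rng.integers(len(due)))]
                is_new = False
            else:
                return None
        cond, item = items[choice]
        if is_new:
            unstarted.remove(choice)
            gap = int(rng.integers(smin, smax + 1))
            open_first[choice] = (p, p + gap + 1)
            seq[p] = (cond, item, 1, False)
        else:
            del open_first[choice]
            seq[p] = (cond, item, 2, False)

    if open_first or unstarted:
        return None
    k = 0
    for p in sorted(filler_pos):
        k += 1
        seq[p] = ("filler", f"filler{k:02d}", 1, True)
    return seq


def generate_event_schedule(spec: DesignSpec) -> EventSchedule:
    """Generate one schedule satisfying the repetition-spacing and ISI
    constraints, by randomized construction with restarts.

    Raises
    ------
    InfeasibleDesignError
        If no valid ordering is found within ``spec.max_restarts`` attempts.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = spec.conditions()
    items = [
        (c, f"{c}_{i + 1:02d}")
        for c in conditions
        for i in range(spec.n_items_per_condition)
    ]
    seq = None
    for _ in range(spec.max_restarts):
        seq = _attempt_order(rng, items, spec)
        if seq is not None:
            break
    if seq is None:
        raise InfeasibleDesignError(
            f"no schedule satisfying spacing [{spec.spacing_min}, "
            f"{spec.spacing_max}] found in {spec.max_restarts} attempts"
        )

    values, probs = isi_distribution(spec)
    n = len(seq)
    isis = rng.choice(values, size=max(n - 1, 0), p=probs)
    onset = 0.0
    trials = []
    for k, (cond, item, rep, is_filler) in enumerate(seq):
        trials.append(Trial(onset, cond, item, rep, is_filler))
        if k < n - 1:
            onset += spec.stim_duration + float(isis[k])
    total = trials[-1].onset + spec.stim_duration if trials else 0.0
    return EventSchedule(tuple(trials), total, spec.stim_duration)


def validate_schedule(schedule: EventSchedule, spec: DesignSpec) -> None:
    """Independent validator: re-derives every schedule invariant from the
    raw trial list and raises ``ValidationError`` on the first violation."""
    trials = schedule.trials
    onsets = [t.onset for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("onsets are not strictly increasing")
    eps = 1e-9
    for k, gap in enumerate(schedule.isis):
        if not (spec.isi_min - eps <= gap <= spec.isi_max + eps):
            raise ValidationError(f"ISI {gap:.3f}s after trial {k} out of bounds")
    positions: dict[str, list[int]] = {}
    for pos, t in enumerate(trials):
        if not t.is_filler:
            positions.setdefault(t.item, []).append(pos)
    expected = {
        f"{c}_{i + 1:02d}"
        for c in spec.conditions()
        for i in range(spec.n_items_per_condition)
    }
    if set(positions) != expected:
        raise ValidationError("item set does not match the design")
    for item, pos in positions.items():
        if len(pos) != spec.n_repetitions:
            raise ValidationError(
                f"item {item} shown {len(pos)} times, expected {spec.n_repetitions}"
            )
        gap = pos[1] - pos[0] - 1
        if not (spec.spacing_min <= gap <= spec.spacing_max):
            raise ValidationError(
                f"item {item} repetition spacing {gap} outside "
                f"[{spec.spacing_min}, {spec.spacing_max}]"
            )
    n_fillers = sum(t.is_filler for t in trials)
    if n_fillers != spec.n_fillers:
        raise ValidationError(f"{n_fillers} fillers, expected {spec.n_fillers}")


@dataclass(frozen=True)
class ScheduleSummary:
    n_trials: int
    n_nonfiller: int
    total_duration: float
    n_volumes: int


def schedule_summary(schedule: EventSchedule, tr: float) -> ScheduleSummary:
    """Trial counts and the number of volumes a scanner with repetition
    time ``tr`` needs to cover the run (ceiling of duration / TR)."""
    if tr <= 0:
        raise ValidationError("tr must be positive")
    n = schedule.n_trials
    n_word = sum(not t.is_filler for t in schedule.trials)
    vols = int(math.ceil(schedule.total_duration / tr)) if n else 0
    return ScheduleSummary(n, n_word, schedule.total_duration, vols)
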