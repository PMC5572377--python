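"""Synthetic datasets with planted ground truth.

No subject-level data were deposited for the study this pipeline
re-implements, so every downstream stage is exercised on simulated data
whose generating parameters are known.  The generator plants

* a per-subject cross-repetition correlation (rho) for the trained
  ("artificial language") condition, shared across the coupled ROIs, with
  independent draws for uncoupled ROIs and for the control ("Chinese")
  condition;
* a power-law reaction-time trajectory a * day^(-b) per subject, with a
  negative linear coupling between the subject's planted trained-condition
  Fisher z and the post-learning RT plateau (days >= 5) — higher pattern
  similarity, faster asymptotic naming;
* per-item similarities coupled negatively to per-item mean RT, plus
  per-subject pattern pairs for the two planted item halves, feeding the
  median-split contrast.

Pattern construction: repetition 2 = rho * standardize(rep 1) +
sqrt(1 - rho^2) * independent noise, so the expected Pearson correlation
between repetitions equals the planted rho while individual samples retain
the natural ~(1 - rho^2)/sqrt(n_voxels) dispersion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .learning import BehaviorTable
from .similarity import PatternSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_patterns",
    "simulate_behavior",
    "simulate_dataset",
    "planted_pattern_pair",
]

DEFAULT_ROIS = (
    "left_pars_opercularis",
    "left_pars_triangularis",
    "left_fusiform",
    "right_fusiform",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated study.

    Defaults emulate the study conditions: 24 subjects, 4 ROIs, 30 items
    per condition, 12 training days, plateau from day 5, coupling slope
    -150 ms per Fisher-z unit and 50 ms RT noise.  ``a_range`` and
    ``b_range`` (initial RT and learning rate) and the rho interval are
    set so the planted brain-behavior correlation magnitude at n = 24 is
    around 0.45-0.55, the scale of effect the method is designed to detect.
    """

    n_subjects: int = 24
    n_voxels: int = 100
    n_rois: int = 4
    roi_names: tuple[str, ...] | None = None
    rho_trained: tuple[float, float] = (0.05, 0.8)
    rho_control: tuple[float, float] = (0.05, 0.8)
    coupled_rois: tuple[str, ...] | None = (
        "left_pars_opercularis",
        "left_fusiform",
        "right_fusiform",
    )
    coupling_slope: float = -150.0  # ms per Fisher-z unit, on the plateau
    a_range: tuple[float, float] = (1800.0, 2200.0)
    b_range: tuple[float, float] = (0.25, 0.35)
    rt_noise_sd: float = 50.0  # ms
    n_days: int = 12
    n_items: int = 30
    plateau_day: int = 5
    tasks: tuple[str, ...] = ("word_naming", "picture_naming")
    item_coupling_slope: float = -150.0  # ms per Fisher-z unit (item level)
    item_rt_noise_sd: float = 20.0  # ms
    group_delta: float = 0.15  # rho offset between planted fast/slow halves
    include_item_groups: bool = True
    rt_floor: float = 200.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.rho_trained, self.rho_control):
            if not (-1 < lo <= hi < 1):
                raise ValidationError("rho intervals must lie inside (-1, 1)")
        if self.n_voxels < 3:
            raise ValidationError("n_voxels must be >= 3")
        if self.n_days < 2:
            raise ValidationError("n_days must be >= 2")
        if self.n_subjects < 1 or self.n_rois < 1 or self.n_items < 1:
            raise ValidationError("counts must be positive")
        if self.roi_names is not None and len(self.roi_names) != self.n_rois:
            raise ValidationError("roi_names length != n_rois")
        unknown = set(self.coupled_rois or ()) - set(self.rois())
        if unknown:
            raise ValidationError(f"coupled_rois not in roi set: {sorted(unknown)}")
        if not (1 <= self.plateau_day <= self.n_days):
            raise ValidationError("plateau_day must lie within the training days")

    def rois(self) -> tuple[str, ...]:
        if self.roi_names is not None:
            return self.roi_names
        if self.n_rois <= len(DEFAULT_ROIS):
            return DEFAULT_ROIS[: self.n_rois]
        return DEFAULT_ROIS + tuple(
            f"roi{i + 1}" for i in range(len(DEFAULT_ROIS), self.n_rois)
        )

    def conditions(self) -> tuple[str, ...]:
        base = ("trained", "control")
        if self.include_item_groups:
            return base + ("trained_fast", "trained_slow")
        return base


@dataclass(frozen=True)
class GroundTruth:
    """Everything that was planted, for recovery checks."""

    subjects: tuple[str, ...]
    rois: tuple[str, ...]
    conditions: tuple[str, ...]
    rho: np.ndarray  # (subject, roi, condition)
    z_latent: np.ndarray  # per-subject trained-condition Fisher z (the coupled one)
    a: np.ndarray
    b: np.ndarray
    coupling_slope: float
    item_rho: np.ndarray | None = None  # per-item planted similarity
    item_mean_rt: pd.DataFrame | None = None  # per item x task plateau mean
    fast_items: tuple[str, ...] | None = None  # planted fast (high-similarity) half

    def to_dict(self) -> dict:
        return {
            "subjects": list(self.subjects),
            "rois": list(self.rois),
            "conditions": list(self.conditions),
            "rho": self.rho.tolist(),
            "z_latent": self.z_latent.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "coupling_slope": self.coupling_slope,
            "item_rho": None if self.item_rho is None else self.item_rho.tolist(),
            "item_mean_rt": (
                None
                if self.item_mean_rt is None
                else self.item_mean_rt.reset_index().to_dict(orient="list")
            ),
            "fast_items": None if self.fast_items is None else list(self.fast_items),
        }


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent child RNG streams (patterns, behavior) from one root
    seed, so the two halves of a dataset can be regenerated separately."""
    children = np.random.SeedSequence(seed).spawn(2)
    return (np.random.default_rng(children[0]), np.random.default_rng(children[1]))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValidationError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def planted_pattern_pair(
    rng: np.random.Generator, rho: float, n_voxels: int
) -> np.ndarray:
    """Two repetition patterns with expected cross-repetition Pearson rho.

    At |rho| = 1 the noise weight vanishes and the correlation is exactly
    +/-1; inside the open interval the observed correlation fluctuates
    around rho with the natural sampling dispersion.
    """
    if not (-1 <= rho <= 1):
        raise ValidationError(f"planted rho must lie in [-1, 1], got {rho}")
    rep1 = rng.standard_normal(n_voxels)
    noise = _standardize(rng.standard_normal(n_voxels))
    rep2 = rho * _standardize(rep1) + np.sqrt(1.0 - rho * rho) * noise
    return np.stack([rep1, rep2])


def simulate_patterns(config: SimulationConfig) -> tuple[PatternSet, GroundTruth]:
    """Generate voxel patterns for every subject/ROI/condition plus the
    planted ground truth.

    The per-subject latent rho (trained condition) is shared across the
    coupled ROIs so a single subject-level similarity drives behavior;
    uncoupled ROIs and the control condition get independent draws from
    the same intervals and are therefore decoupled from behavior.
    """
    rng, _ = _streams(config.seed)
    subjects = tuple(f"sub{i + 1:02d}" for i in range(config.n_subjects))
    rois = config.rois()
    conditions = config.conditions()
    coupled = set(config.coupled_rois or ())

    rho_latent = rng.uniform(*config.rho_trained, size=config.n_subjects)
    a = rng.uniform(*config.a_range, size=config.n_subjects)
    b = rng.uniform(*config.b_range, size=config.n_subjects)

    n_cond = len(conditions)
    rho = np.empty((config.n_subjects, config.n_rois, n_cond))
    values = np.empty(
        (config.n_subjects, config.n_rois, n_cond, 2, config.n_voxels)
    )
    lo, hi = -0.95, 0.95
    for si in range(config.n_subjects):
        for ri, roi in enumerate(rois):
            base = (
                rho_latent[si]
                if roi in coupled
                else rng.uniform(*config.rho_trained)
            )
            for ci, cond in enumerate(conditions):
                if cond == "trained":
                    r = base
                elif cond == "control":
                    r = rng.uniform(*config.rho_control)
                elif cond == "trained_fast":
                    r = np.clip(base + config.group_delta, lo, hi)
                elif cond == "trained_slow":
                    r = np.clip(base - config.group_delta, lo, hi)
                else:  # pragma: no cover - conditions() is closed
                    raise ValidationError(f"unknown condition {cond!r}")
                rho[si, ri, ci] = r
                values[si, ri, ci] = planted_pattern_pair(rng, r, config.n_voxels)

    item_rho = rng.uniform(*config.rho_trained, size=config.n_items)
    item_names = tuple(f"item{i + 1:02d}" for i in range(config.n_items))
    order = np.argsort(-item_rho, kind="stable")  # most similar first
    fast = tuple(item_names[i] for i in order[: (config.n_items + 1) // 2])

    truth = GroundTruth(
        subjects=subjects,
        rois=rois,
        conditions=conditions,
        rho=rho,
        z_latent=np.arctanh(rho_latent),
        a=a,
        b=b,
        coupling_slope=config.coupling_slope,
        item_rho=item_rho,
        item_mean_rt=None,  # filled by simulate_behavior
        fast_items=fast,
    )
    patterns = PatternSet(values, subjects, rois, conditions)
    return patterns, truth


def simulate_behavior(config: SimulationConfig, truth: GroundTruth) -> BehaviorTable:
    """Reaction times and accuracies for every subject/day/task.

    RT(s, d) = a_s * d^(-b_s) + coupling_slope * z_s * [d >= plateau] +
    Gaussian noise, where z_s is the subject's planted trained-condition
    Fisher z.  Accuracy follows a saturating curve approaching ceiling
    (generated for completeness; not used in inference).  A group-level
    per-item RT table couples item RT negatively to the planted per-item
    similarity for the median-split analysis.
    """
    if len(truth.a) != config.n_subjects or truth.rho.shape[1] != config.n_rois:
        raise ValidationError("ground truth dimensions do not match the config")
    _, rng = _streams(config.seed)
    days = np.arange(1, config.n_days + 1)
    plateau = (days >= config.plateau_day).astype(float)

    rows = []
    clipped = 0
    for si, subject in enumerate(truth.subjects):
        base = truth.a[si] * days ** (-truth.b[si])
        base = base + config.coupling_slope * truth.z_latent[si] * plateau
        for task in config.tasks:
            noise = (
                rng.normal(0.0, config.rt_noise_sd, size=config.n_days)
                if config.rt_noise_sd > 0
                else np.zeros(config.n_days)
            )
            rt = base + noise
            n_low = int((rt < config.rt_floor).sum())
            if n_low:
                clipped += n_low
                rt = np.maximum(rt, config.rt_floor)
            acc = 1.0 - 0.55 * np.exp(-0.6 * (days - 1))
            acc = np.clip(acc + rng.normal(0.0, 0.02, size=config.n_days), 0.0, 1.0)
            for di, day in enumerate(days):
                rows.append((subject, int(day), task, float(rt[di]), float(acc[di])))
    if clipped:
        warnings.warn(
            f"{clipped} simulated RTs fell below the {config.rt_floor} ms floor "
            "and were clipped",
            stacklevel=2,
        )

    data = pd.DataFrame(rows, columns=["subject", "day", "task", "rt", "accuracy"])

    item_rows = []
    a_bar = float(truth.a.mean())
    b_bar = float(truth.b.mean())
    item_z = np.arctanh(truth.item_rho)
    item_effect = config.item_coupling_slope * (item_z - item_z.mean())
    item_names = [f"item{i + 1:02d}" for i in range(config.n_items)]
    for ii, item in enumerate(item_names):
        base = a_bar * days ** (-b_bar) + item_effect[ii] * plateau
        for task in config.tasks:
            noise = (
                rng.normal(0.0, config.item_rt_noise_sd, size=config.n_days)
                if config.item_rt_noise_sd > 0
                else np.zeros(config.n_days)
            )
            rt = np.maximum(base + noise, config.rt_floor)
            for di, day in enumerate(days):
                item_rows.append((item, int(day), task, float(rt[di])))
    item_rt = pd.DataFrame(item_rows, columns=["item", "day", "task", "rt"])
    return BehaviorTable(data=data, item_rt=item_rt)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[PatternSet, BehaviorTable, GroundTruth]:
    """Convenience wrapper: patterns + behavior + ground truth in one call."""
    patterns, truth = simulate_patterns(config)
    behavior = simulate_behavior(config, truth)
    plateau = behavior.item_rt[behavior.item_rt["day"] >= config.plateau_day]
    item_mean = plateau.groupby(["item", "task"])["rt"].mean().unstack("task")
    truth = GroundTruth(
        subjects=truth.subjects,
        rois=truth.rois,
        conditions=truth.conditions,
        rho=truth.rho,
        z_latent=truth.z_latent,
        a=truth.a,
        b=truth.b,
        coupling_slope=truth.coupling_slope,
        item_rho=truth.item_rho,
        item_mean_rt=item_mean,
        fast_items=truth.fast_items,
    )
    return patterns, behavior, truth
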