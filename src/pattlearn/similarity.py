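"""Cross-repetition multivoxel pattern similarity.

The similarity statistic is the Pearson correlation between the voxel-wise
activation patterns of the two repetitions of a condition, computed per
subject and region of interest, then variance-stabilized with Fisher's
z transform (atanh).  Patterns are condition-mean contrast estimates (one
value per voxel); voxel values are used as-is, with no within-pattern
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePatternError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PatternSet",
    "SimilarityTable",
    "pattern_similarity",
    "fisher_z",
    "inverse_fisher",
    "similarity_table",
    "percent_signal_change",
]

#: correlations at exactly +/-1 are clamped to this magnitude before atanh
FISHER_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class PatternSet:
    """Voxel activation patterns indexed (subject, roi, condition,
    repetition, voxel).

    ``values`` holds arbitrary activation units (e.g. GLM contrast
    estimates).  Exactly two repetitions and at least three voxels per
    region are required.
    """

    values: np.ndarray
    subjects: tuple[str, ...]
    rois: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 5:
            raise ValidationError(
                "values must be 5-d: (subject, roi, condition, repetition, voxel)"
            )
        if v.shape[3] != 2:
            raise ValidationError("exactly 2 repetitions are required")
        if v.shape[4] < 3:
            raise ValidationError("at least 3 voxels per ROI are required")
        if v.shape[:3] != (len(self.subjects), len(self.rois), len(self.conditions)):
            raise ValidationError("axis labels do not match the value array shape")
        if not np.all(np.isfinite(v)):
            raise ValidationError("pattern values must all be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[4]

    def get(self, subject: str, roi: str, condition: str, repetition: int) -> np.ndarray:
        s = self.subjects.index(subject)
        r = self.rois.index(roi)
        c = self.conditions.index(condition)
        if repetition not in (1, 2):
            raise ValidationError("repetition must be 1 or 2")
        return self.values[s, r, c, repetition - 1]


@dataclass(frozen=True)
class SimilarityTable:
    """One (r, z) pair per subject x ROI x condition; ``z = atanh(r)``."""

    frame: pd.DataFrame  # columns: subject, roi, condition, r, z
    subjects: tuple[str, ...]
    rois: tuple[str, ...]
    conditions: tuple[str, ...]

    def z_vector(self, roi: str, condition: str) -> np.ndarray:
        """Per-subject Fisher-z values in subject order."""
        sub = self.frame[
            (self.frame["roi"] == roi) & (self.frame["condition"] == condition)
        ].set_index("subject")
        return sub.loc[list(self.subjects), "z"].to_numpy()

    def r_vector(self, roi: str, condition: str) -> np.ndarray:
        sub = self.frame[
            (self.frame["roi"] == roi) & (self.frame["condition"] == condition)
        ].set_index("subject")
        return sub.loc[list(self.subjects), "r"].to_numpy()


def pattern_similarity(rep1: np.ndarray, rep2: np.ndarray) -> float:
    """Pearson correlation between the two repetitions of a pattern.

    Raises ``DegeneratePatternError`` on zero-variance input rather than
    silently returning 0 or NaN.
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("patterns must be 1-d voxel vectors")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("patterns must have at least 3 voxels")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("patterns must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegeneratePatternError("zero-variance pattern: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def fisher_z(r, clamp: float = FISHER_CLAMP):
    """Fisher's variance-stabilizing transform z = atanh(r).

    Correlations of magnitude 1 (legal but with infinite z) are clamped to
    ``clamp`` and a warning is logged, keeping downstream statistics finite.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValidationError("|r| must be <= 1")
    if np.any(np.abs(r_arr) >= clamp):
        logger.warning("clamping |r| >= %.7f before Fisher transform", clamp)
    clipped = np.clip(r_arr, -clamp, clamp)
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def inverse_fisher(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def similarity_table(patterns: PatternSet) -> SimilarityTable:
    """Cross-repetition similarity for every (subject, roi, condition) cell.

    Raises ``DegeneratePatternError`` naming the offending cell if any
    pattern has zero variance.
    """
    rows = []
    for si, s in enumerate(patterns.subjects):
        for ri, roi in enumerate(patterns.rois):
            for ci, cond in enumerate(patterns.conditions):
                rep1 = patterns.values[si, ri, ci, 0]
                rep2 = patterns.values[si, ri, ci, 1]
                try:
                    r = pattern_similarity(rep1, rep2)
                except DegeneratePatternError as err:
                    raise DegeneratePatternError(
                        f"degenerate pattern at (subject={s}, roi={roi}, "
                        f"condition={cond}): {err}"
                    ) from err
                rows.append((s, roi, cond, r, fisher_z(r)))
    frame = pd.DataFrame(rows, columns=["subject", "roi", "condition", "r", "z"])
    return SimilarityTable(frame, patterns.subjects, patterns.rois, patterns.conditions)


def percent_signal_change(contrast, run_mean, ppheight) -> float:
    """Percent signal change: contrast / run mean x peak height x 100.

    ``ppheight`` is the unitless peak height of the modeled hemodynamic
    response relative to baseline.
    """
    run_mean = float(run_mean)
    if run_mean == 0:
        raise ZeroDivisionError(
            "percent signal change undefined: run mean is zero"
        )
    return float(contrast) / run_mean * float(ppheight) * 100.0
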