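"""Brain-behavior inference.

Statistics relating per-subject cross-repetition pattern similarity
(Fisher z) to post-training naming speed:

* Pearson correlation with the classical t-based p-value;
* Steiger's z for comparing two dependent correlations sharing one
  variable (here: behavior correlated with the trained-condition vs the
  control-condition similarity);
* two permutation schemes — shuffling similarity across subjects
  (between) and swapping the two conditions' similarities within each
  subject (within), each with Monte-Carlo and exhaustive modes;
* leave-one-out cross-validated prediction of outcome RT from similarity
  with the relative error (predicted - observed) / observed;
* paired t-tests contrasting similarity of fast- vs slow-named items;
* an orchestrator running the full battery per ROI x task.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .learning import (
    BehaviorTable,
    daily_mean_rt,
    filter_fits,
    fit_power_curve,
    median_split_items,
    post_training_outcome,
)
from .similarity import PatternSet, similarity_table

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "LOOCVResult",
    "DependentCorrResult",
    "AnalysisReport",
    "correlate",
    "compare_dependent_correlations",
    "permutation_test_between",
    "permutation_test_within",
    "n_between_assignments",
    "n_within_assignments",
    "loocv_predict",
    "paired_t_test",
    "run_full_analysis",
]


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class PermutationResult:
    r_obs: float
    null_dist: np.ndarray
    p_one: float  # one-tailed, in the direction of the observed sign
    p_two: float
    n_perm: int
    scheme: str  # "between" | "within"
    seed: int | None
    exhaustive: bool = False

    def summary(self) -> dict:
        q = np.percentile(self.null_dist, [2.5, 5, 50, 95, 97.5])
        return {
            "r_obs": self.r_obs,
            "p_one": self.p_one,
            "p_two": self.p_two,
            "n_perm": self.n_perm,
            "scheme": self.scheme,
            "exhaustive": self.exhaustive,
            "null_q025": float(q[0]),
            "null_q05": float(q[1]),
            "null_median": float(q[2]),
            "null_q95": float(q[3]),
            "null_q975": float(q[4]),
        }


@dataclass(frozen=True)
class LOOCVResult:
    subjects: tuple[str, ...]
    predicted: np.ndarray
    rel_error: np.ndarray
    max_abs_error: float
    min_abs_error: float

    def summary(self) -> dict:
        return {
            "max_abs_error": self.max_abs_error,
            "min_abs_error": self.min_abs_error,
            "mean_abs_error": float(np.mean(np.abs(self.rel_error))),
        }


@dataclass(frozen=True)
class DependentCorrResult:
    z_stat: float
    p: float
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    tails: int


# --------------------------------------------------------------------------
# element-wise helpers


def _as_vector(x, name: str, min_n: int = 3) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a 1-d vector")
    if v.size < min_n:
        raise ValidationError(f"{name} needs at least {min_n} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} contains non-finite values")
    return v


def _check_nonconstant(v: np.ndarray, name: str) -> None:
    if np.ptp(v) == 0:
        raise DegenerateInputError(f"{name} is constant; statistic undefined")


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-tailed t-distribution p-value
    (n - 2 degrees of freedom)."""
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValidationError("x and y must have equal length")
    _check_nonconstant(xv, "x")
    _check_nonconstant(yv, "y")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, tails: int = 2
) -> DependentCorrResult:
    """Steiger's z for two dependent correlations sharing one variable.

    ``r_jk`` and ``r_jh`` are the correlations of the common variable j
    (behavior) with k and h (the two conditions' similarities); ``r_kh``
    is the correlation between k and h.  Uses Fisher-transformed
    correlations with the pooled-correlation covariance correction
    (Steiger 1980, the variant of the Lee & Preacher utility):

        z = (z_jk - z_jh) * sqrt((n - 3) / (2 - 2*cbar)),
        cbar = psi / (1 - rbar^2)^2,
        psi = r_kh (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_kh^2) / 2,

    with rbar = (r_jk + r_jh) / 2.  The p-value comes from the standard
    normal; ``sign(z) = sign(atanh(r_jk) - atanh(r_jh))``.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValidationError(f"{name} must satisfy |r| < 1, got {r}")
    if n <= 3:
        raise ValidationError("n must exceed 3")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    corr = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    min_eig = float(np.linalg.eigvalsh(corr)[0])
    if min_eig < -1e-10:
        raise ValidationError(
            f"correlation triple is not positive semidefinite "
            f"(min eigenvalue {min_eig:.3g}); the three correlations are "
            "mutually inconsistent"
        )
    rbar = 0.5 * (r_jk + r_jh)
    psi = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
    cbar = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * math.sqrt((n - 3) / (2 - 2 * cbar))
    if tails == 2:
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(abs(z)))
    return DependentCorrResult(float(z), min(p, 1.0), r_jk, r_jh, r_kh, n, tails)


# --------------------------------------------------------------------------
# permutation machinery


def n_between_assignments(n: int) -> int:
    """Size of the between-subject permutation space (n!)."""
    return math.factorial(n)


def n_within_assignments(n: int) -> int:
    """Size of the within-subject swap space (2^n)."""
    return 2**n


def _row_correlations(rows: np.ndarray, y_std: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` with a pre-standardized vector."""
    n = rows.shape[1]
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan  # constant null row: correlation undefined
    z = (rows - mu) / sd
    r = z @ y_std / n
    return np.nan_to_num(r, nan=0.0)


def _perm_pvalues(
    r_obs: float, null: np.ndarray, exhaustive: bool
) -> tuple[float, float]:
    """Add-one Monte-Carlo p-values, or exact proportions in exhaustive
    mode (where the identity assignment is part of the enumeration, so
    p >= 1/N and never 0).  One-tailed p is taken in the direction of the
    observed sign."""
    eps = 1e-12
    if r_obs >= 0:
        k_one = int(np.sum(null >= r_obs - eps))
    else:
        k_one = int(np.sum(null <= r_obs + eps))
    k_two = int(np.sum(np.abs(null) >= abs(r_obs) - eps))
    m = null.size
    if exhaustive:
        return k_one / m, k_two / m
    return (1 + k_one) / (m + 1), (1 + k_two) / (m + 1)


def permutation_test_between(
    similarity: Sequence[float],
    outcome: Sequence[float],
    n_perm: int = 5000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Between-subject permutation test: shuffle the similarity vector
    across subjects and recompute the Pearson correlation with outcome.

    In exhaustive mode (n <= 9) all n! orderings are enumerated and p is
    the exact proportion of the null as or more extreme than the observed
    correlation; otherwise ``n_perm`` Monte-Carlo draws are taken and the
    add-one rule is applied.
    """
    sim = _as_vector(similarity, "similarity", min_n=5)
    out = _as_vector(outcome, "outcome", min_n=5)
    if sim.size != out.size:
        raise ValidationError("similarity and outcome must have equal length")
    _check_nonconstant(sim, "similarity")
    _check_nonconstant(out, "outcome")
    n = sim.size
    r_obs, _ = correlate(sim, out)
    y_std = (out - out.mean()) / out.std()
    sim_std = (sim - sim.mean()) / sim.std()

    if exhaustive:
        if n > 9:
            raise ValidationError("exhaustive between-subject mode requires n <= 9")
        perms = np.array(list(itertools.permutations(range(n))))
        null = _row_correlations(sim_std[perms], y_std)
        n_used = perms.shape[0]
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        rows = rng.permuted(np.tile(sim_std, (n_perm, 1)), axis=1)
        null = _row_correlations(rows, y_std)
        n_used = n_perm
    p_one, p_two = _perm_pvalues(r_obs, null, exhaustive)
    return PermutationResult(
        r_obs, null, p_one, p_two, n_used, "between", seed, exhaustive
    )


def permutation_test_within(
    sim_trained: Sequence[float],
    sim_control: Sequence[float],
    outcome: Sequence[float],
    n_perm: int = 5000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Within-subject permutation test: independently swap (or not) the
    trained- and control-condition similarity values of each subject and
    recompute the trained-condition correlation with outcome.

    The full assignment space has 2^n elements; it is enumerated
    exhaustively when ``exhaustive=True`` (allowed up to n = 20, and the
    default for n <= 12), otherwise a fair coin per subject per iteration
    is tossed.
    """
    tr = _as_vector(sim_trained, "sim_trained", min_n=5)
    ct = _as_vector(sim_control, "sim_control", min_n=5)
    out = _as_vector(outcome, "outcome", min_n=5)
    if not (tr.size == ct.size == out.size):
        raise ValidationError("all vectors must have equal length")
    _check_nonconstant(tr, "sim_trained")
    _check_nonconstant(out, "outcome")
    n = tr.size
    if exhaustive is None:
        # small samples: the full 2^n space is cheaper than Monte Carlo
        exhaustive = n <= 12
    r_obs, _ = correlate(tr, out)
    y_std = (out - out.mean()) / out.std()

    if exhaustive:
        if n > 20:
            raise ValidationError("exhaustive within-subject mode requires n <= 20")
        codes = np.arange(2**n, dtype=np.int64)
        masks = (codes[:, None] >> np.arange(n)) & 1
        rows = np.where(masks.astype(bool), ct, tr)
        null = _row_correlations(rows, y_std)
        n_used = 2**n
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        masks = rng.random((n_perm, n)) < 0.5
        rows = np.where(masks, ct, tr)
        null = _row_correlations(rows, y_std)
        n_used = n_perm
    p_one, p_two = _perm_pvalues(r_obs, null, exhaustive)
    return PermutationResult(
        r_obs, null, p_one, p_two, n_used, "within", seed, exhaustive
    )


# --------------------------------------------------------------------------
# prediction and contrasts


def loocv_predict(
    similarity: Sequence[float],
    outcome: Sequence[float],
    subjects: Sequence[str] | None = None,
) -> LOOCVResult:
    """Leave-one-out cross-validated prediction of outcome from similarity.

    Each fold fits ordinary least squares ``outcome ~ 1 + similarity`` on
    the remaining n - 1 subjects and predicts the held-out subject.  The
    per-subject relative error is (predicted - observed) / observed.
    """
    sim = _as_vector(similarity, "similarity", min_n=4)
    out = _as_vector(outcome, "outcome", min_n=4)
    if sim.size != out.size:
        raise ValidationError("similarity and outcome must have equal length")
    if np.any(out == 0):
        raise ValidationError("observed outcome of 0 makes relative error undefined")
    n = sim.size
    if subjects is None:
        subjects = tuple(f"sub{i + 1:02d}" for i in range(n))
    subjects = tuple(subjects)
    if len(subjects) != n:
        raise ValidationError("subjects must match the vector length")

    predicted = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x, y = sim[mask], out[mask]
        if np.ptp(x) == 0:
            raise DegenerateInputError(
                f"training fold for held-out subject {subjects[i]!r} has "
                "constant similarity"
            )
        slope, intercept = np.polyfit(x, y, 1)
        predicted[i] = slope * sim[i] + intercept
    rel = (predicted - out) / out
    return LOOCVResult(
        subjects,
        predicted,
        rel,
        float(np.max(np.abs(rel))),
        float(np.min(np.abs(rel))),
    )


def paired_t_test(fast_z, slow_z) -> tuple[float, int, float]:
    """Classical paired t-test on per-subject similarity of fast- vs
    slow-named item groups; returns (t, df, two-tailed p) with df = n-1."""
    f = _as_vector(fast_z, "fast_z")
    s = _as_vector(slow_z, "slow_z")
    if f.size != s.size:
        raise ValidationError("groups must have equal length")
    d = f - s
    if np.ptp(d) == 0 and d[0] != 0:
        # constant nonzero difference: t is infinite
        raise DegenerateInputError("differences have zero variance")
    if np.ptp(d) == 0:
        return 0.0, f.size - 1, 1.0
    res = stats.ttest_rel(f, s)
    return float(res.statistic), f.size - 1, float(res.pvalue)


# --------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class AnalysisReport:
    """Machine-readable results of the full battery.

    ``cells`` holds one record per ROI x task; ``flagged_rois`` lists ROIs
    whose trained-condition association is significant (correlation and
    both permutation tests, two-tailed) in every task.
    """

    meta: dict
    cells: list
    learning_rate: list
    median_split: list
    flagged_rois: list

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "cells": self.cells,
            "learning_rate": self.learning_rate,
            "median_split": self.median_split,
            "flagged_rois": self.flagged_rois,
        }


def run_full_analysis(
    patterns: PatternSet,
    behavior: BehaviorTable,
    config=None,
) -> AnalysisReport:
    """Run the complete brain-behavior battery.

    Per ROI x task: trained- and control-condition correlations with the
    post-training outcome, the dependent-correlation comparison, both
    permutation tests, and LOOCV prediction.  Additionally: the
    learning-rate correlation restricted to subjects whose power-law fit
    clears the R^2 threshold, and (when item-group conditions and an item
    RT table are present) the median-split paired t-tests.

    ``config`` is a :class:`pattlearn.io.RunConfig`; defaults are used
    when omitted.  Deterministic given ``config.seed``.
    """
    from .io import RunConfig  # local import to avoid a cycle

    cfg = config or RunConfig()
    if not set(cfg.tasks) <= set(behavior.tasks):
        raise ValidationError(
            f"behavior table lacks tasks {set(cfg.tasks) - set(behavior.tasks)}"
        )
    for cond in (cfg.condition_trained, cfg.condition_control):
        if cond not in patterns.conditions:
            raise ValidationError(f"pattern set lacks condition {cond!r}")
    if tuple(patterns.subjects) != tuple(behavior.subjects):
        raise ValidationError("subject ids of patterns and behavior do not match")

    simtab = similarity_table(patterns)
    outcomes = {
        task: post_training_outcome(behavior, task, cfg.outcome_days)
        for task in cfg.tasks
    }

    # learning-curve fits on the across-task daily means
    daily = daily_mean_rt(behavior)
    fits = {}
    for subject, grp in daily.groupby("subject", sort=False):
        fits[subject] = fit_power_curve(
            grp["day"].to_numpy(), grp["rt"].to_numpy()
        )
    kept, excluded = filter_fits(fits, cfg.r2_min)

    # deterministic child seeds, one per (roi, task, scheme)
    root = np.random.SeedSequence(cfg.seed)
    children = iter(root.generate_state(4 * len(patterns.rois) * len(cfg.tasks)))

    cells = []
    flags: dict[str, list[bool]] = {roi: [] for roi in patterns.rois}
    for roi in patterns.rois:
        z_tr = simtab.z_vector(roi, cfg.condition_trained)
        z_ct = simtab.z_vector(roi, cfg.condition_control)
        r_kh, _ = correlate(z_tr, z_ct)
        for task in cfg.tasks:
            y = outcomes[task].to_numpy()
            r_tr, p_tr = correlate(z_tr, y)
            r_ct, p_ct = correlate(z_ct, y)
            dep = compare_dependent_correlations(
                r_tr, r_ct, r_kh, n=len(y), tails=cfg.dependent_tails
            )
            seed_b = int(next(children) % (2**31))
            seed_w = int(next(children) % (2**31))
            between = permutation_test_between(
                z_tr, y, n_perm=cfg.n_perm, seed=seed_b
            )
            within = permutation_test_within(
                z_tr, z_ct, y, n_perm=cfg.n_perm, seed=seed_w, exhaustive=False
            )
            loocv = loocv_predict(z_tr, y, patterns.subjects)
            significant = (
                p_tr < cfg.alpha
                and between.p_two < cfg.alpha
                and within.p_two < cfg.alpha
            )
            flags[roi].append(bool(significant))
            cells.append(
                {
                    "roi": roi,
                    "task": task,
                    "n": len(y),
                    "r_trained": r_tr,
                    "p_trained": p_tr,
                    "r_control": r_ct,
                    "p_control": p_ct,
                    "r_between_conditions": r_kh,
                    "dependent_z": dep.z_stat,
                    "dependent_p": dep.p,
                    "between_perm": between.summary(),
                    "within_perm": within.summary(),
                    "loocv": loocv.summary(),
                    "significant": bool(significant),
                }
            )

    learning_rate = []
    kept_ids = list(kept)
    if len(kept_ids) >= 3:
        idx = [patterns.subjects.index(s) for s in kept_ids]
        b_vec = np.array([kept[s].b for s in kept_ids])
        for roi in patterns.rois:
            z_tr = simtab.z_vector(roi, cfg.condition_trained)[idx]
            try:
                r_lr, p_lr = correlate(z_tr, b_vec)
                learning_rate.append(
                    {"roi": roi, "n": len(kept_ids), "r": r_lr, "p": p_lr}
                )
            except DegenerateInputError:
                learning_rate.append({"roi": roi, "n": len(kept_ids), "r": None, "p": None})

    median_split = []
    fast_c, slow_c = cfg.group_conditions
    has_groups = fast_c in patterns.conditions and slow_c in patterns.conditions
    if has_groups and behavior.item_rt is not None:
        lo, hi = cfg.outcome_days
        plateau = behavior.item_rt[behavior.item_rt["day"].between(lo, hi)]
        for task in cfg.tasks:
            per_item = (
                plateau[plateau["task"] == task].groupby("item")["rt"].mean()
            )
            fast_items, slow_items = median_split_items(per_item)
            for roi in patterns.rois:
                zf = simtab.z_vector(roi, fast_c)
                zs = simtab.z_vector(roi, slow_c)
                t, df, p = paired_t_test(zf, zs)
                median_split.append(
                    {
                        "task": task,
                        "roi": roi,
                        "t": t,
                        "df": df,
                        "p": p,
                        "n_fast_items": len(fast_items),
                        "n_slow_items": len(slow_items),
                    }
                )

    n_tests = len(cells)
    for cell in cells:
        cell["p_trained_bonferroni"] = min(1.0, cell["p_trained"] * n_tests)

    flagged = [roi for roi, fl in flags.items() if fl and all(fl)]
    meta = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "n_subjects": len(patterns.subjects),
        "rois": list(patterns.rois),
        "tasks": list(cfg.tasks),
        "outcome_days": list(cfg.outcome_days),
        "r2_min": cfg.r2_min,
        "n_fit_kept": len(kept),
        "n_fit_excluded": len(excluded),
        "excluded_subjects": sorted(excluded),
        "n_tests": n_tests,
        "multiple_testing": "none (Bonferroni column provided)",
    }
    return AnalysisReport(meta, cells, learning_rate, median_split, flagged)
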