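"""File formats, run configuration, and reports.

Tabular formats are long CSV/TSV (one voxel or one task-day per row),
chosen over wide layouts for streaming validation and diff-friendliness.
NIfTI extraction (contrast maps + binary ROI masks) is supported for
users with volumetric inputs; the core pipeline needs only the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .learning import BehaviorTable
from .similarity import PatternSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "read_pattern_table",
    "write_pattern_table",
    "read_behavior_table",
    "write_behavior_table",
    "extract_patterns_from_nifti",
    "write_report",
    "read_report",
    "render_report",
]

PATTERN_COLUMNS = ["subject", "roi", "condition", "repetition", "voxel", "value"]
FLOAT_FORMAT = "%.17g"  # exact float64 round trip


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; defaults are the study's stated constants:
    5000 permutations, alpha 0.05, outcome days 5-12, R^2 threshold 0.7,
    four anatomical ROIs, two naming tasks."""

    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    roi_names: tuple[str, ...] = (
        "left_pars_opercularis",
        "left_pars_triangularis",
        "left_fusiform",
        "right_fusiform",
    )
    tasks: tuple[str, ...] = ("word_naming", "picture_naming")
    condition_trained: str = "trained"
    condition_control: str = "control"
    group_conditions: tuple[str, str] = ("trained_fast", "trained_slow")
    r2_min: float = 0.7
    outcome_days: tuple[int, int] = (5, 12)
    dependent_tails: int = 1

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0 <= self.r2_min <= 1):
            raise ValidationError("r2_min must lie in [0, 1]")
        lo, hi = self.outcome_days
        if lo < 1 or hi < lo:
            raise ValidationError("outcome_days must be an increasing day range")
        if self.dependent_tails not in (1, 2):
            raise ValidationError("dependent_tails must be 1 or 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("roi_names", "tasks", "group_conditions", "outcome_days"):
            d[key] = list(d[key])
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("roi_names", "tasks", "group_conditions", "outcome_days"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the serialized configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# pattern tables


def write_pattern_table(patterns: PatternSet, path: str | Path) -> None:
    """Write a PatternSet as long CSV (one voxel value per row)."""
    s, r, c, _, v = patterns.values.shape
    idx = pd.MultiIndex.from_product(
        [patterns.subjects, patterns.rois, patterns.conditions, (1, 2), range(v)],
        names=PATTERN_COLUMNS[:5],
    )
    frame = pd.DataFrame({"value": patterns.values.ravel()}, index=idx).reset_index()
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_pattern_table(path: str | Path) -> PatternSet:
    """Read and validate a long-format pattern table.

    Requires the full crossing of subject x roi x condition x repetition
    x voxel with no duplicate keys; errors cite offending keys or rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = set(PATTERN_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    values = pd.to_numeric(frame["value"], errors="coerce")
    bad = frame.index[values.isna()]
    if len(bad):
        # +2: one for the header row, one for 0- vs 1-based indexing
        raise ParseError(
            f"{path}: non-numeric value at line {int(bad[0]) + 2}"
        )
    frame["value"] = values
    keys = PATTERN_COLUMNS[:5]
    dup = frame.duplicated(subset=keys)
    if dup.any():
        first = frame.loc[dup.idxmax(), keys].tolist()
        raise ParseError(f"{path}: duplicated key {tuple(first)}")

    subjects = tuple(pd.unique(frame["subject"]).astype(str))
    rois = tuple(pd.unique(frame["roi"]).astype(str))
    conditions = tuple(pd.unique(frame["condition"]).astype(str))
    voxels = np.sort(frame["voxel"].unique())
    expected = len(subjects) * len(rois) * len(conditions) * 2 * len(voxels)
    if len(frame) != expected or sorted(frame["repetition"].unique()) != [1, 2]:
        raise ParseError(
            f"{path}: incomplete crossing "
            f"({len(frame)} rows, expected {expected})"
        )
    cube = (
        frame.assign(subject=frame["subject"].astype(str),
                     roi=frame["roi"].astype(str),
                     condition=frame["condition"].astype(str))
        .set_index(keys)["value"]
        .sort_index()
    )
    arr = cube.to_numpy().reshape(
        len(subjects), len(rois), len(conditions), 2, len(voxels)
    )
    # sort_index ordered labels lexicographically; reorder to file order
    s_sorted = tuple(sorted(subjects))
    r_sorted = tuple(sorted(rois))
    c_sorted = tuple(sorted(conditions))
    ps = PatternSet(arr, s_sorted, r_sorted, c_sorted)
    # re-index back to first-appearance order for stable round trips
    s_ix = [s_sorted.index(s) for s in subjects]
    r_ix = [r_sorted.index(r) for r in rois]
    c_ix = [c_sorted.index(c) for c in conditions]
    return PatternSet(
        ps.values[np.ix_(s_ix, r_ix, c_ix)], subjects, rois, conditions
    )


# --------------------------------------------------------------------------
# behavior tables


def write_behavior_table(
    behavior: BehaviorTable, path: str | Path, items_path: str | Path | None = None
) -> None:
    behavior.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if items_path is not None and behavior.item_rt is not None:
        behavior.item_rt.to_csv(items_path, index=False, float_format=FLOAT_FORMAT)


def read_behavior_table(
    path: str | Path, items_path: str | Path | None = None
) -> BehaviorTable:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"subject", "day", "task", "rt", "accuracy"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    items = pd.read_csv(items_path) if items_path is not None else None
    try:
        return BehaviorTable(data=frame, item_rt=items)
    except ValidationError as err:
        raise ParseError(f"{path}: {err}") from err


# --------------------------------------------------------------------------
# NIfTI extraction


def extract_patterns_from_nifti(
    map_paths: dict[str, dict[int, str | Path]],
    mask_paths: dict[str, str | Path],
    subject: str = "sub01",
) -> PatternSet:
    """Build a single-subject PatternSet from per-condition-per-repetition
    contrast maps and binary ROI masks.

    ``map_paths`` maps condition -> {repetition (1|2) -> NIfTI path};
    ``mask_paths`` maps ROI name -> binary mask path.  All images must
    share grid dimensions.  Voxel order within a ROI is the ascending
    linear index of the mask's native array (C order), identical across
    conditions and repetitions.
    """
    import nibabel as nib

    conditions = tuple(map_paths)
    rois = tuple(mask_paths)
    masks = {}
    shape = None
    for roi, mpath in mask_paths.items():
        m = np.asanyarray(nib.load(str(mpath)).dataobj)
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask for {roi!r} is not binary")
        flat = np.flatnonzero(m.ravel(order="C"))
        if flat.size == 0:
            raise ValidationError(f"empty ROI: mask for {roi!r} selects no voxels")
        if flat.size < 3:
            raise ValidationError(f"ROI {roi!r} has fewer than 3 voxels")
        if shape is None:
            shape = m.shape
        elif m.shape != shape:
            raise ValidationError(f"mask grid mismatch for {roi!r}")
        masks[roi] = flat

    n_vox = max(len(v) for v in masks.values())
    if len({len(v) for v in masks.values()}) != 1:
        raise ValidationError(
            "ROIs select different voxel counts; a rectangular pattern array "
            "requires equal-sized masks (crop or pad the masks)"
        )
    values = np.empty((1, len(rois), len(conditions), 2, n_vox))
    for ci, cond in enumerate(conditions):
        reps = map_paths[cond]
        if set(reps) != {1, 2}:
            raise ValidationError(f"condition {cond!r} must map repetitions 1 and 2")
        for rep in (1, 2):
            img = np.asanyarray(nib.load(str(reps[rep])).dataobj)
            if img.shape != shape:
                raise ValidationError(
                    f"map grid mismatch for condition {cond!r} repetition {rep}"
                )
            flat_img = img.ravel(order="C")
            for ri, roi in enumerate(rois):
                values[0, ri, ci, rep - 1] = flat_img[masks[roi]]
    return PatternSet(values, (subject,), rois, conditions)


# --------------------------------------------------------------------------
# reports


def write_report(report, path: str | Path) -> None:
    """Serialize an AnalysisReport (or plain dict) to JSON, keys sorted,
    so identical config + seed reruns produce byte-identical files."""
    data = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    for key in ("meta", "cells", "flagged_rois"):
        if key not in data:
            raise ParseError(f"{path}: report missing section {key!r}")
    return data


def render_report(data: dict) -> str:
    """Human-readable summary of a report dictionary."""
    lines = []
    meta = data["meta"]
    lines.append(
        f"pattlearn analysis: n={meta['n_subjects']} subjects, "
        f"{meta['n_perm']} permutations, alpha={meta['alpha']}, seed={meta['seed']}"
    )
    lines.append(
        f"learning-curve exclusions (R^2 < {meta['r2_min']}): "
        f"{meta['n_fit_excluded']} of "
        f"{meta['n_fit_excluded'] + meta['n_fit_kept']} subjects"
    )
    lines.append("")
    header = (
        f"{'ROI':<24}{'task':<16}{'r_tr':>7}{'p_tr':>8}{'r_ct':>7}"
        f"{'dep_z':>7}{'p_btw':>8}{'p_wth':>8}{'maxerr':>8}  sig"
    )
    lines.append(header)
    for cell in data["cells"]:
        lines.append(
            f"{cell['roi']:<24}{cell['task']:<16}"
            f"{cell['r_trained']:>7.3f}{cell['p_trained']:>8.4f}"
            f"{cell['r_control']:>7.3f}{cell['dependent_z']:>7.2f}"
            f"{cell['between_perm']['p_two']:>8.4f}"
            f"{cell['within_perm']['p_two']:>8.4f}"
            f"{cell['loocv']['max_abs_error']:>8.3f}"
            f"  {'*' if cell['significant'] else '-'}"
        )
    if data.get("learning_rate"):
        lines.append("")
        lines.append("learning-rate correlations (kept fits):")
        for row in data["learning_rate"]:
            r = "NA" if row["r"] is None else f"{row['r']:.3f}"
            p = "NA" if row["p"] is None else f"{row['p']:.4f}"
            lines.append(f"  {row['roi']:<24} r={r} p={p} (n={row['n']})")
    if data.get("median_split"):
        lines.append("")
        lines.append("median-split paired t-tests (fast vs slow items):")
        for row in data["median_split"]:
            lines.append(
                f"  {row['roi']:<24}{row['task']:<16}"
                f"t({row['df']})={row['t']:.2f} p={row['p']:.4f}"
            )
    lines.append("")
    flagged = ", ".join(data["flagged_rois"]) or "none"
    lines.append(f"ROIs significant in all tasks: {flagged}")
    return "\n".join(lines)
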