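"""Densitometry and qPCR normalization with morphometric surface correction.

Densitometry: each band intensity is divided by the loading-control
(β-actin) band of the same sample; the reference-group (VE) mean ratio is
anchored to 100% and every sample is expressed relative to it.

qPCR: relative expression by the ΔΔCt method — ΔCt = Ct_target − Ct_reference
per sample, ΔΔCt against the reference-group mean ΔCt, fold = E^(−ΔΔCt) with
amplification efficiency E = 2 by default.

Surface correction multiplies each test-group (PP) sample value by the
morphometric factor *before* group statistics are recomputed — the
per-sample form, which commutes with averaging at the mean level and keeps
the SEM coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedExpression", "ExpressionError",
    "densitometric_normalize", "ddct_fold_change", "apply_surface_correction",
]

EXPRESSION_COLUMNS = ["sample_id", "group", "target_id",
                      "target_signal", "control_signal", "assay"]


class ExpressionError(ValueError):
    pass


@dataclass
class NormalizedExpression:
    """Per-sample normalized expression values with group statistics.

    ``per_sample`` has columns sample_id, group, value — percent of the
    reference-group mean for densitometry, fold change for qPCR.
    ``group_stats`` has columns group, n, mean, sem.  ``factor_applied`` is
    the surface-correction factor multiplied into the test group, if any.
    """

    target_id: str
    assay: str
    reference_group: str
    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    factor_applied: float | None = None
    ve_sem_mode: str = "zero"

    def value_arrays(self) -> dict[str, np.ndarray]:
        return {g: sub["value"].to_numpy()
                for g, sub in self.per_sample.groupby("group", sort=False)}


def _check_table(table: pd.DataFrame, assay: str, reference_group: str) -> pd.DataFrame:
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise ExpressionError(f"expression table missing columns: {missing}")
    if len(table) == 0:
        raise ExpressionError("expression table is empty")
    bad_assay = table.loc[table["assay"] != assay]
    if len(bad_assay):
        raise ExpressionError(
            f"expected assay {assay!r}, found {sorted(bad_assay['assay'].unique())}")
    targets = table["target_id"].unique()
    if len(targets) != 1:
        raise ExpressionError(
            f"one target per call; found {sorted(map(str, targets))} "
            "(split the table by target_id)")
    if reference_group not in set(table["group"]):
        raise ExpressionError(f"reference group {reference_group!r} absent from table")
    return table


def _group_stats(per_sample: pd.DataFrame, reference_group: str,
                 ve_sem_mode: str, anchor_mean: float | None) -> pd.DataFrame:
    rows = []
    for group, sub in per_sample.groupby("group", sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        n = vals.size
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        mean = float(np.mean(vals))
        if (group == reference_group and ve_sem_mode == "zero"
                and anchor_mean is not None):
            # reference anchored within-blot: reported as anchor ± 0
            mean, sem = anchor_mean, 0.0
        rows.append({"group": group, "n": n, "mean": mean, "sem": sem})
    return pd.DataFrame(rows)


def densitometric_normalize(table: pd.DataFrame, reference_group: str = "VE",
                            ve_sem_mode: str = "zero") -> NormalizedExpression:
    """Normalize band intensities to the loading control and anchor VE at 100%.

    ``ve_sem_mode="zero"`` reports the reference group as 100 ± 0% (the
    within-blot anchoring convention); ``"propagate"`` reports the reference
    group's own rescaled scatter around its anchored mean of exactly 100%.
    """
    if ve_sem_mode not in ("zero", "propagate"):
        raise ExpressionError(f"unknown ve_sem_mode {ve_sem_mode!r}")
    table = _check_table(table, "densitometry", reference_group)
    zero_ctrl = table.loc[table["control_signal"] <= 0]
    if len(zero_ctrl):
        bad = zero_ctrl.iloc[0]
        raise ExpressionError(
            f"non-positive loading-control signal for sample {bad['sample_id']!r}")
    neg = table.loc[table["target_signal"] < 0]
    if len(neg):
        raise ExpressionError(
            f"negative band intensity for sample {neg.iloc[0]['sample_id']!r}")

    ratio = table["target_signal"] / table["control_signal"]
    ref_mean = ratio[table["group"] == reference_group].mean()
    if ref_mean <= 0:
        raise ExpressionError("reference-group mean ratio is not positive")
    per_sample = pd.DataFrame({
        "sample_id": table["sample_id"],
        "group": table["group"],
        "value": 100.0 * ratio / ref_mean,
    }).reset_index(drop=True)
    stats = _group_stats(per_sample, reference_group, ve_sem_mode, anchor_mean=100.0)
    return NormalizedExpression(
        target_id=str(table["target_id"].iloc[0]), assay="densitometry",
        reference_group=reference_group, per_sample=per_sample,
        group_stats=stats, ve_sem_mode=ve_sem_mode)


def ddct_fold_change(table: pd.DataFrame, correction: float | None = None,
                     reference_group: str = "VE", efficiency: float = 2.0
                     ) -> NormalizedExpression:
    """Relative expression by the ΔΔCt method (fold change vs. reference group).

    ``target_signal`` holds the target-gene Ct, ``control_signal`` the
    reference-gene Ct.  An optional surface-correction ``correction`` factor
    is multiplied into the non-reference folds after the ΔΔCt transform.
    """
    if efficiency <= 1:
        raise ExpressionError("amplification efficiency must exceed 1")
    table = _check_table(table, "qpcr", reference_group)
    bad_ct = table.loc[~np.isfinite(table["target_signal"])
                       | ~np.isfinite(table["control_signal"])]
    if len(bad_ct):
        raise ExpressionError(
            f"missing/non-finite Ct for sample {bad_ct.iloc[0]['sample_id']!r}")
    out_of_range = table.loc[(table["target_signal"] <= 0) | (table["target_signal"] >= 45)
                             | (table["control_signal"] <= 0) | (table["control_signal"] >= 45)]
    if len(out_of_range):
        raise ExpressionError(
            f"Ct outside (0, 45) for sample {out_of_range.iloc[0]['sample_id']!r}")

    dct = table["target_signal"] - table["control_signal"]
    ref_dct = dct[table["group"] == reference_group].mean()
    ddct = dct - ref_dct
    fold = np.power(efficiency, -ddct)
    per_sample = pd.DataFrame({
        "sample_id": table["sample_id"],
        "group": table["group"],
        "value": fold,
    }).reset_index(drop=True)
    norm = NormalizedExpression(
        target_id=str(table["target_id"].iloc[0]), assay="qpcr",
        reference_group=reference_group, per_sample=per_sample,
        group_stats=_group_stats(per_sample, reference_group, "propagate", None),
        ve_sem_mode="propagate")
    if correction is not None:
        norm = apply_surface_correction(norm, correction)
    return norm


def apply_surface_correction(norm: NormalizedExpression, factor: float,
                             level: str = "per_sample") -> NormalizedExpression:
    """Multiply non-reference-group expression by the surface-correction factor.

    ``level="per_sample"`` (default) scales every non-reference sample value
    and recomputes group statistics; ``level="mean"`` scales only the group
    means/SEMs, leaving per-sample values untouched (for comparison with
    summary-level workflows).  The reference group is never modified.
    """
    if factor <= 0:
        raise ExpressionError("correction factor must be strictly positive")
    if level not in ("per_sample", "mean"):
        raise ExpressionError(f"unknown correction level {level!r}")
    if level == "per_sample":
        per_sample = norm.per_sample.copy()
        mask = per_sample["group"] != norm.reference_group
        per_sample.loc[mask, "value"] *= factor
        anchor = 100.0 if norm.assay == "densitometry" else None
        stats = _group_stats(per_sample, norm.reference_group,
                             norm.ve_sem_mode, anchor_mean=anchor)
        return replace(norm, per_sample=per_sample, group_stats=stats,
                       factor_applied=factor)
    stats = norm.group_stats.copy()
    mask = stats["group"] != norm.reference_group
    stats.loc[mask, ["mean", "sem"]] *= factor
    return replace(norm, group_stats=stats, factor_applied=factor)
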