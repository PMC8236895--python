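"""Segmentation metrics and cohort summaries.

Per region (WT, TC, ET, NC) we report the Dice coefficient
2|P∩R| / (|P|+|R|), the false-positive volume fraction |P\\R| / |R| and
the false-negative volume fraction |R\\P| / |R| (both normalized by the
reference volume, so FNVF <= 1). A detection with Dice < 0.5 counts as a
failure; cohort tables report the Dice mean +/- sd both over successful
cases and over all cases, alongside success counts "s/N".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_model import AucsegError, LabelVolume

__all__ = [
    "REGIONS",
    "REGION_CODES",
    "SUCCESS_DICE",
    "SegMetrics",
    "extract_region",
    "compute_metrics",
    "evaluate_case",
    "summarize_cohort",
]

REGION_CODES: dict[str, frozenset[int]] = {
    "WT": frozenset({1, 2, 4}),
    "TC": frozenset({1, 4}),
    "ET": frozenset({4}),
    "NC": frozenset({1}),
}
REGIONS = tuple(REGION_CODES)

SUCCESS_DICE = 0.5


@dataclass
class SegMetrics:
    """Overlap metrics for one predicted/reference mask pair."""

    dice: float
    fpvf: float  # NaN when the reference is empty (undefined)
    fnvf: float
    success: bool
    region: Optional[str] = None
    n_pred: int = 0
    n_ref: int = 0


def extract_region(label_volume: LabelVolume | np.ndarray, region: str) -> np.ndarray:
    """Binary mask of a derived region: WT={1,2,4}, TC={1,4}, ET={4}, NC={1}."""
    try:
        codes = REGION_CODES[region.upper()]
    except KeyError:
        raise AucsegError(f"unknown region {region!r}; choose from {REGIONS}")
    data = label_volume.data if isinstance(label_volume, LabelVolume) else np.asarray(label_volume)
    return np.isin(data, list(codes))


def compute_metrics(
    pred_mask: np.ndarray, ref_mask: np.ndarray, region: Optional[str] = None
) -> SegMetrics:
    """Dice / FPVF / FNVF between a predicted and a reference binary mask.

    Both masks empty -> Dice 1 with a warning (perfect agreement on
    absence); an empty reference with a nonempty prediction -> Dice 0 and
    FPVF/FNVF reported as NaN (undefined without a reference volume).
    """
    pred = np.asarray(pred_mask, dtype=bool)
    ref = np.asarray(ref_mask, dtype=bool)
    if pred.shape != ref.shape:
        raise AucsegError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((ref & ~pred).sum())
    n_pred, n_ref = tp + fp, tp + fn
    if n_pred == 0 and n_ref == 0:
        warnings.warn("both masks empty: Dice defined as 1", stacklevel=2)
        return SegMetrics(1.0, np.nan, np.nan, True, region, 0, 0)
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    if n_ref == 0:
        fpvf = fnvf = np.nan
    else:
        fpvf = fp / n_ref
        fnvf = fn / n_ref
    return SegMetrics(dice, fpvf, fnvf, dice >= SUCCESS_DICE, region, n_pred, n_ref)


def evaluate_case(
    pred: LabelVolume, ref: LabelVolume, regions: Iterable[str] = REGIONS
) -> list[SegMetrics]:
    """Metrics for every derived region of one predicted vs reference label map."""
    if pred.data.shape != ref.data.shape:
        raise AucsegError("prediction and reference label volumes differ in shape")
    return [
        compute_metrics(extract_region(pred, r), extract_region(ref, r), region=r)
        for r in regions
    ]


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return np.nan, np.nan
    return float(values.mean()), float(values.std())


def summarize_cohort(metrics: Iterable[SegMetrics]) -> pd.DataFrame:
    """Cohort table per region.

    Columns: mean/sd Dice over successful cases (Dice >= 0.5), success
    count "s/N", mean/sd FPVF and FNVF over cases where they are defined,
    plus mean/sd Dice over all cases and the count of cases excluded from
    the volume-fraction statistics (empty reference regions).
    """
    metrics = list(metrics)
    if not metrics:
        raise AucsegError("no metrics to summarize")
    rows = []
    regions = [r for r in REGIONS if any(m.region == r for m in metrics)]
    if not regions:  # region-less metrics: summarize as one group
        regions = [None]  # type: ignore[list-item]
    for region in regions:
        group = [m for m in metrics if m.region == region]
        dice = np.array([m.dice for m in group])
        succ = np.array([m.success for m in group])
        fpvf = np.array([m.fpvf for m in group])
        fnvf = np.array([m.fnvf for m in group])
        defined = np.isfinite(fpvf)
        mean_dice, sd_dice = _mean_sd(dice[succ])
        mean_dice_all, sd_dice_all = _mean_sd(dice)
        mean_fpvf, sd_fpvf = _mean_sd(fpvf[defined])
        mean_fnvf, sd_fnvf = _mean_sd(fnvf[np.isfinite(fnvf)])
        rows.append(
            {
                "region": region or "ALL",
                "mean_dice": mean_dice,
                "sd_dice": sd_dice,
                "success": f"{int(succ.sum())}/{len(group)}",
                "mean_fpvf": mean_fpvf,
                "sd_fpvf": sd_fpvf,
                "mean_fnvf": mean_fnvf,
                "sd_fnvf": sd_fnvf,
                "mean_dice_all": mean_dice_all,
                "sd_dice_all": sd_dice_all,
                "n_excluded": int((~defined).sum()),
            }
        )
    return pd.DataFrame(rows)
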