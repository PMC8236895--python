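"""Staged unsupervised segmentation of a high-grade glioma case.

The pipeline exploits the radiological signature of HGG on
multi-parametric MRI:

1. **Whole tumor (WT)** — edema is hyperintense on T2-FLAIR, so FLAIR
   intensities inside the brain are clustered into ``n_cluster1``
   subclasses and the brightest subclass is kept; the largest connected
   component is retained and its internal cavities filled (edema rings
   the tumor, so filling recovers core + enhancement).
2. **Enhancing tumor (ET)** — blood-brain-barrier breakdown is
   hyperintense on T1-CE, so T1-CE intensities *inside WT* are clustered
   into ``n_cluster2`` subclasses and the brightest kept (no component
   filtering: enhancing rims may be fragmented).
3. **Necrosis (NC)** — either ``cc`` mode (the necrotic cavity sits
   inside the enhancing rim, so dilate ET one step, fill its holes and
   take the filled interior) or ``t2`` mode (necrotic fluid is bright on
   T2: cluster T2 inside WT, the brightest subclass hole-filled and
   united with ET is the tumor core).

Tumor core TC = NC ∪ ET. Multiple tumors are handled one ROI at a time,
results pasted back into full-volume coordinates.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import clustering, morphology
from .io_model import (
    AucsegError,
    ConfigurationError,
    LabelVolume,
    MultiModalCase,
    RoiSpec,
    crop_to_roi,
    normalize_case,
    paste_mask,
)

__all__ = [
    "SegConfig",
    "StageMasks",
    "segment_whole_tumor",
    "segment_enhancing_tumor",
    "segment_necrosis_cc",
    "segment_tumor_core_t2",
    "run_pipeline",
    "enumerate_tuning_grid",
]

logger = logging.getLogger("aucseg")

NC_SEG_MODES = ("cc", "t2")


@dataclass
class SegConfig:
    """The pipeline hyper-parameters.

    ``n_cluster1/2/3`` are the subclass counts for the WT / ET / TC
    clustering stages (``n_cluster3`` is unused in ``cc`` mode);
    ``nc_seg_mode`` picks the necrosis strategy; ``method`` names the
    clustering backend; ``roi`` optionally restricts segmentation to one
    box/mask per tumor.
    """

    n_cluster1: int = 5
    n_cluster2: int = 3
    roi: Optional[list[RoiSpec]] = None
    nc_seg_mode: str = "cc"
    n_cluster3: int = 3
    method: str = "gmm"
    seed: int = 0
    tol: float = clustering.DEFAULT_TOL
    max_iter: int = clustering.DEFAULT_MAX_ITER
    fuzzifier: float = clustering.DEFAULT_FUZZIFIER
    var_floor: float = clustering.DEFAULT_VAR_FLOOR
    batch_size: int = clustering.DEFAULT_BATCH_SIZE

    def __post_init__(self) -> None:
        for name in ("n_cluster1", "n_cluster2", "n_cluster3"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        if self.nc_seg_mode not in NC_SEG_MODES:
            raise ConfigurationError(
                f"nc_seg_mode must be one of {NC_SEG_MODES}, got {self.nc_seg_mode!r}"
            )
        if self.method not in clustering.BACKENDS:
            raise ConfigurationError(
                f"method must be one of {clustering.BACKENDS}, got {self.method!r}"
            )


@dataclass
class StageMasks:
    """Per-stage binary masks in full-volume coordinates; et ⊆ tc ⊆ wt."""

    wt: np.ndarray
    et: np.ndarray
    tc: np.ndarray
    nc: np.ndarray


def _fit(samples: np.ndarray, k: int, config: SegConfig) -> clustering.ClusterResult:
    return clustering.fit_backend(
        config.method,
        samples,
        k,
        seed=config.seed,
        tol=config.tol,
        max_iter=config.max_iter,
        fuzzifier=config.fuzzifier,
        var_floor=config.var_floor,
        batch_size=config.batch_size,
    )


def wt_candidate_mask(case: MultiModalCase, config: SegConfig) -> np.ndarray:
    """Brightest-FLAIR-subclass mask before any morphological filtering.

    Exposed separately because the subclass count has a monotone effect
    here: more subclasses carve the hyperintense compartment finer, so
    the selected subclass shrinks (larger false negatives).
    """
    support = case.brain_mask
    if not support.any():
        raise AucsegError("empty brain mask")
    result = _fit(case.flair[support], config.n_cluster1, config)
    return clustering.highest_intensity_cluster_mask(result, support)


def segment_whole_tumor(case: MultiModalCase, config: SegConfig) -> np.ndarray:
    """WT from normalized FLAIR: brightest subclass, largest connected
    component, internal holes filled."""
    candidate = wt_candidate_mask(case, config)
    wt = morphology.largest_component(candidate)
    if not wt.any():
        warnings.warn("no tumor detected: empty whole-tumor mask", stacklevel=2)
        return wt
    wt = morphology.fill_holes(wt)
    return wt & case.brain_mask


def segment_enhancing_tumor(
    case: MultiModalCase, wt: np.ndarray, config: SegConfig
) -> np.ndarray:
    """ET from normalized T1-CE restricted to WT: brightest subclass, no
    component filtering (enhancing rims may be fragmented)."""
    if not wt.any():
        return np.zeros_like(wt)
    result = _fit(case.t1ce[wt], config.n_cluster2, config)
    return clustering.highest_intensity_cluster_mask(result, wt)


def segment_necrosis_cc(et: np.ndarray, wt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Necrosis by connected-component analysis of the enhancing rim.

    ET is dilated one step (3x3x3) to close small ring gaps, its holes
    filled; NC is the filled interior (excluding the dilated rim itself)
    inside WT, and TC = NC ∪ ET. An open rim yields empty NC — the
    documented failure mode that motivates ``t2`` mode.
    """
    et = np.asarray(et, dtype=bool)
    wt = np.asarray(wt, dtype=bool)
    dilated = morphology.dilate(et)
    filled = morphology.fill_holes(dilated)
    nc = filled & ~dilated & wt
    tc = nc | et
    return nc, tc


def segment_tumor_core_t2(
    case: MultiModalCase, wt: np.ndarray, et: np.ndarray, config: SegConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Tumor core by T2 clustering inside WT (``t2`` mode).

    Necrotic fluid is T2-hyperintense, so the brightest of ``n_cluster3``
    T2 subclasses inside WT, hole-filled and united with ET, is TC;
    NC = TC \\ ET.
    """
    if case.t2 is None:
        raise ConfigurationError("nc_seg_mode='t2' requires a T2 volume")
    if not wt.any():
        empty = np.zeros_like(wt)
        return empty, et.copy()
    result = _fit(case.t2[wt], config.n_cluster3, config)
    candidate = clustering.highest_intensity_cluster_mask(result, wt)
    tc = (morphology.fill_holes(candidate) & wt) | et
    nc = tc & ~et
    return nc, tc


def _segment_one(case: MultiModalCase, config: SegConfig) -> StageMasks:
    """Run the WT -> ET -> NC stages on one (possibly cropped) case."""
    t0 = time.perf_counter()
    wt = segment_whole_tumor(case, config)
    logger.info("WT stage: %d voxels (%.2fs)", int(wt.sum()), time.perf_counter() - t0)
    t0 = time.perf_counter()
    et = segment_enhancing_tumor(case, wt, config)
    logger.info("ET stage: %d voxels (%.2fs)", int(et.sum()), time.perf_counter() - t0)
    t0 = time.perf_counter()
    if config.nc_seg_mode == "cc":
        nc, tc = segment_necrosis_cc(et, wt)
    else:
        nc, tc = segment_tumor_core_t2(case, wt, et, config)
    logger.info(
        "NC stage (%s): %d voxels (%.2fs)",
        config.nc_seg_mode,
        int(nc.sum()),
        time.perf_counter() - t0,
    )
    return StageMasks(wt=wt, et=et, tc=tc, nc=nc)


def run_pipeline(
    case: MultiModalCase, config: SegConfig | None = None
) -> tuple[LabelVolume, StageMasks]:
    """Full pipeline: normalize, segment each ROI (or the whole volume),
    and assemble the label map (NC→1, edema→2, ET→4).

    Per-ROI failures are isolated so other tumors still segment; label
    conflicts between overlapping ROIs resolve by precedence
    ET > NC > edema.
    """
    config = config or SegConfig()
    if config.nc_seg_mode == "t2" and case.t2 is None:
        raise ConfigurationError(
            "nc_seg_mode='t2' requires a T2 volume (none loaded for this case)"
        )
    norm = normalize_case(case)
    shape = norm.shape
    wt_full = np.zeros(shape, dtype=bool)
    et_full = np.zeros(shape, dtype=bool)
    nc_full = np.zeros(shape, dtype=bool)
    rois: list[Optional[RoiSpec]] = list(config.roi) if config.roi else [None]
    for i, roi in enumerate(rois):
        try:
            if roi is None:
                sub, offset = norm, (0, 0, 0)
            else:
                sub, offset = crop_to_roi(norm, roi)
            masks = _segment_one(sub, config)
        except AucsegError as exc:
            warnings.warn(f"ROI {i} failed: {exc}", stacklevel=2)
            continue
        paste_mask(wt_full, masks.wt, offset)
        paste_mask(et_full, masks.et, offset)
        paste_mask(nc_full, masks.nc, offset)
    nc_full &= ~et_full  # ET wins where overlapping ROIs disagree
    tc_full = nc_full | et_full
    wt_full |= tc_full
    data = np.zeros(shape, dtype=np.int16)
    data[wt_full] = 2
    data[nc_full] = 1
    data[et_full] = 4
    labels = LabelVolume(data=data, affine=case.affine)
    stage = StageMasks(wt=wt_full, et=et_full, tc=tc_full, nc=nc_full)
    return labels, stage


def enumerate_tuning_grid(base: SegConfig | None = None) -> list[SegConfig]:
    """The semi-automatic tuning grid: n_cluster1 ∈ 3..10, n_cluster2 ∈
    3..5, and four necrosis options ({cc} ∪ {t2 with n_cluster3 ∈ 3..5}),
    96 configurations in tuning order (n_cluster1, n_cluster2,
    nc_seg_mode, n_cluster3)."""
    base = base or SegConfig()
    grid: list[SegConfig] = []
    for n1, n2 in itertools.product(range(3, 11), range(3, 6)):
        grid.append(replace(base, n_cluster1=n1, n_cluster2=n2, nc_seg_mode="cc"))
        for n3 in range(3, 6):
            grid.append(
                replace(
                    base, n_cluster1=n1, n_cluster2=n2, nc_seg_mode="t2", n_cluster3=n3
                )
            )
    return grid
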