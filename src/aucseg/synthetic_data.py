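"""Synthetic multi-parametric phantoms with ground-truth labels.

Phantoms emulate skull-stripped, co-registered BraTS-style cases: zero
background, an ellipsoidal brain, and one or more spherical tumors with
an edema shell, an enhancing rim and a necrotic interior. Compartment
mean intensities encode the radiological premises the pipeline exploits:

* FLAIR — edema brightest (brain 0.4, edema 0.9, rim 0.7, core 0.6);
* T1-CE — enhancing rim brightest (brain 0.4, edema 0.5, rim 0.95, core 0.2);
* T2 — necrotic core brightest inside the tumor (brain 0.4, edema 0.7,
  rim 0.5, core 0.9).

Additive i.i.d. Gaussian noise (default sd 0.02) is applied inside the
brain after compartment painting, then clipped to [0, 1.2]. A rim gap
angle opens a cone-shaped hole in the enhancing rim to create the
open-ring failure mode of connected-component necrosis segmentation; an
optional linear bias field emulates low-contrast acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io_model import AucsegError, LabelVolume, MultiModalCase

__all__ = [
    "TumorGeometry",
    "PhantomSpec",
    "CohortRanges",
    "DEFAULT_INTENSITIES",
    "generate_phantom",
    "generate_cohort",
]

#: Per-modality mean intensity of each compartment (pre-noise, raw units).
DEFAULT_INTENSITIES: dict[str, dict[str, float]] = {
    "flair": {"brain": 0.4, "edema": 0.9, "rim": 0.7, "core": 0.6},
    "t1ce": {"brain": 0.4, "edema": 0.5, "rim": 0.95, "core": 0.2},
    "t2": {"brain": 0.4, "edema": 0.7, "rim": 0.5, "core": 0.9},
}

_CLIP = (0.0, 1.2)


@dataclass(frozen=True)
class TumorGeometry:
    """Nested spherical tumor: necrotic interior inside an enhancing rim
    inside an edema shell.

    ``core_radius`` defaults to ``rim_inner_radius`` so the necrotic
    compartment exactly fills the rim interior; a smaller value leaves an
    edema-intensity annulus between core and rim. ``rim_gap_deg`` is the
    full aperture of a cone about the +x axis removed from the rim
    (0 = closed rim).
    """

    center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    edema_radius: float = 16.0
    rim_outer_radius: float = 11.0
    rim_inner_radius: float = 8.0
    core_radius: Optional[float] = None
    rim_gap_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.core_radius is None:
            object.__setattr__(self, "core_radius", self.rim_inner_radius)
        if not (
            0 < self.core_radius <= self.rim_inner_radius
            < self.rim_outer_radius < self.edema_radius
        ):
            raise AucsegError(
                "tumor radii must nest: core <= rim inner < rim outer < edema"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; deterministic given ``seed``."""

    shape: tuple[int, int, int] = (64, 64, 64)
    brain_center: Optional[tuple[float, float, float]] = None
    brain_semiaxes: tuple[float, float, float] = (27.0, 25.0, 23.0)
    tumors: tuple[TumorGeometry, ...] = (TumorGeometry(),)
    intensities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_INTENSITIES.items()}
    )
    noise_sd: float = 0.02
    bias_field_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise AucsegError("phantom shape must be 3D with extents >= 8")
        if self.noise_sd < 0:
            raise AucsegError("noise sd must be >= 0")
        if not self.tumors:
            raise AucsegError("at least one tumor geometry required")
        for i, ta in enumerate(self.tumors):
            for tb in self.tumors[i + 1 :]:
                dist = float(
                    np.linalg.norm(np.subtract(ta.center, tb.center))
                )
                if dist <= ta.edema_radius + tb.edema_radius:
                    raise AucsegError("tumor geometries overlap")


def _grids(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    center = spec.brain_center or tuple((s - 1) / 2.0 for s in spec.shape)
    zz, yy, xx = _grids(spec.shape)
    a, b, c = spec.brain_semiaxes
    return (
        ((zz - center[0]) / a) ** 2
        + ((yy - center[1]) / b) ** 2
        + ((xx - center[2]) / c) ** 2
    ) <= 1.0


def _tumor_compartments(
    tumor: TumorGeometry, shape: Sequence[int]
) -> dict[str, np.ndarray]:
    zz, yy, xx = _grids(shape)
    dz, dy, dx = (zz - tumor.center[0], yy - tumor.center[1], xx - tumor.center[2])
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    edema = r <= tumor.edema_radius
    rim = (r > tumor.rim_inner_radius) & (r <= tumor.rim_outer_radius)
    if tumor.rim_gap_deg > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            angle = np.degrees(np.arccos(np.clip(np.where(r > 0, dx / r, 1.0), -1, 1)))
        rim &= angle > tumor.rim_gap_deg / 2.0
    core = r <= tumor.core_radius
    return {"edema": edema, "rim": rim, "core": core}


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultiModalCase, LabelVolume, dict[int, int]]:
    """Build a phantom case, its ground-truth label map, and per-code
    voxel counts.

    Painting order per tumor is edema -> rim -> core, so the truth labels
    are core→1, edema shell→2, rim→4 and the nesting ET ⊆ TC ⊆ WT holds
    by construction. Raises when a tumor extends outside the brain.
    """
    brain = _brain_mask(spec)
    labels = np.zeros(spec.shape, dtype=np.int16)
    volumes = {m: np.where(brain, spec.intensities[m]["brain"], 0.0) for m in ("flair", "t1ce", "t2")}
    for tumor in spec.tumors:
        comp = _tumor_compartments(tumor, spec.shape)
        if np.any(comp["edema"] & ~brain):
            raise AucsegError("tumor extends outside the brain compartment")
        labels[comp["edema"]] = 2
        labels[comp["rim"]] = 4
        labels[comp["core"]] = 1
        for m, vol in volumes.items():
            vol[comp["edema"]] = spec.intensities[m]["edema"]
            vol[comp["rim"]] = spec.intensities[m]["rim"]
            vol[comp["core"]] = spec.intensities[m]["core"]
    if spec.bias_field_amplitude:
        z = np.arange(spec.shape[0], dtype=np.float64) / max(spec.shape[0] - 1, 1)
        gain = 1.0 + spec.bias_field_amplitude * (2.0 * z - 1.0)
        for vol in volumes.values():
            vol *= gain[:, None, None]
    rng = np.random.default_rng(spec.seed)
    n_in = int(brain.sum())
    for vol in volumes.values():
        if spec.noise_sd > 0:
            vol[brain] += rng.normal(0.0, spec.noise_sd, n_in)
        np.clip(vol, *_CLIP, out=vol)
    affine = np.eye(4)
    case = MultiModalCase(
        flair=volumes["flair"], t1ce=volumes["t1ce"], t2=volumes["t2"], affine=affine
    )
    truth = LabelVolume(data=labels, affine=affine)
    codes, counts = np.unique(labels, return_counts=True)
    bookkeeping = {int(c): int(n) for c, n in zip(codes, counts)}
    return case, truth, bookkeeping


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for per-case phantom geometry."""

    edema_radius: tuple[float, float] = (13.0, 17.0)
    rim_outer_frac: tuple[float, float] = (0.62, 0.72)  # fraction of edema radius
    rim_thickness: tuple[float, float] = (2.5, 3.5)
    center_jitter: float = 3.0
    noise_sd: tuple[float, float] = (0.02, 0.02)
    rim_gap_deg: tuple[float, float] = (0.0, 0.0)


def generate_cohort(
    n_cases: int,
    spec_ranges: CohortRanges | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[MultiModalCase, LabelVolume, dict[int, int]]]:
    """Draw ``n_cases`` phantoms with geometry sampled from the ranges.

    Each case gets a derived seed, so the cohort is reproducible and
    point (degenerate) ranges yield identical geometry with differing
    noise realizations.
    """
    if n_cases < 1:
        raise AucsegError("n_cases must be >= 1")
    ranges = spec_ranges or CohortRanges()
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n_cases)
    cohort = []
    for i in range(n_cases):
        geo = np.random.default_rng([int(case_seeds[i]), 1])
        edema_r = geo.uniform(*ranges.edema_radius)
        rim_outer = edema_r * geo.uniform(*ranges.rim_outer_frac)
        rim_inner = rim_outer - geo.uniform(*ranges.rim_thickness)
        center = tuple(
            (s - 1) / 2.0 + geo.uniform(-ranges.center_jitter, ranges.center_jitter)
            for s in base.shape
        )
        tumor = TumorGeometry(
            center=center,  # type: ignore[arg-type]
            edema_radius=edema_r,
            rim_outer_radius=rim_outer,
            rim_inner_radius=rim_inner,
            rim_gap_deg=geo.uniform(*ranges.rim_gap_deg),
        )
        spec = replace(
            base,
            tumors=(tumor,),
            noise_sd=geo.uniform(*ranges.noise_sd),
            seed=int(case_seeds[i]),
        )
        cohort.append(generate_phantom(spec))
    return cohort
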