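"""Case data model, NIfTI I/O, intensity normalization, and ROI cropping.

A *case* is one subject's set of co-registered, skull-stripped 3D MRI
volumes: T2-FLAIR and post-contrast T1 (T1-CE) are required, T2 is
optional and only needed when necrosis is segmented by T2 clustering.
All volumes share a shape and a voxel-to-world affine, and the background
outside the brain is exactly zero (BraTS-style skull-stripped convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AucsegError",
    "CoRegistrationError",
    "ConfigurationError",
    "EmptyRoiError",
    "MultiModalCase",
    "RoiSpec",
    "LabelVolume",
    "VALID_LABEL_CODES",
    "load_case",
    "load_labels",
    "save_labels",
    "normalize_volume",
    "normalize_case",
    "crop_to_roi",
    "paste_mask",
]

#: BraTS-2018 label convention: 1 = necrosis, 2 = edema, 4 = enhancing tumor.
VALID_LABEL_CODES = frozenset({0, 1, 2, 4})

_AFFINE_ATOL = 1e-4


class AucsegError(Exception):
    """Base class for all errors raised by this package."""


class CoRegistrationError(AucsegError):
    """Modalities do not share a shape/affine: not co-registered."""


class ConfigurationError(AucsegError):
    """Invalid or inconsistent segmentation configuration."""


class EmptyRoiError(AucsegError):
    """A region of interest selects no voxels."""


def _as_volume(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise AucsegError(f"{name} must be a 3D volume, got ndim={arr.ndim}")
    return arr


@dataclass
class MultiModalCase:
    """Aligned multi-parametric volumes and brain mask for one subject.

    The brain mask is the set of voxels nonzero in *every* present
    modality, matching the skull-stripped zero-background convention;
    all clustering operates on in-mask voxels only.
    """

    flair: np.ndarray
    t1ce: np.ndarray
    t2: Optional[np.ndarray] = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    brain_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.flair = _as_volume(self.flair, "flair")
        self.t1ce = _as_volume(self.t1ce, "t1ce")
        if self.t2 is not None:
            self.t2 = _as_volume(self.t2, "t2")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise AucsegError("affine must be 4x4")
        for name, vol in (("t1ce", self.t1ce), ("t2", self.t2)):
            if vol is not None and vol.shape != self.flair.shape:
                raise CoRegistrationError(
                    f"modalities not co-registered: flair shape {self.flair.shape} "
                    f"vs {name} shape {vol.shape}"
                )
        if self.brain_mask is None:
            self.brain_mask = self.compute_brain_mask()
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.flair.shape:
                raise AucsegError("brain_mask shape does not match volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flair.shape  # type: ignore[return-value]

    @property
    def modalities(self) -> dict[str, np.ndarray]:
        out = {"flair": self.flair, "t1ce": self.t1ce}
        if self.t2 is not None:
            out["t2"] = self.t2
        return out

    def compute_brain_mask(self) -> np.ndarray:
        mask = (self.flair != 0) & (self.t1ce != 0)
        if self.t2 is not None:
            mask &= self.t2 != 0
        return mask


@dataclass(frozen=True)
class RoiSpec:
    """A region of interest: a binary mask or a 0-based half-open index box.

    The box order is ``(zmin, zmax, ymin, ymax, xmin, xmax)`` following
    the volume's axis order.
    """

    mask: Optional[np.ndarray] = None
    bounds: Optional[tuple[int, int, int, int, int, int]] = None

    def __post_init__(self) -> None:
        if (self.mask is None) == (self.bounds is None):
            raise AucsegError("RoiSpec requires exactly one of mask or bounds")
        if self.mask is not None:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        else:
            b = tuple(int(v) for v in self.bounds)  # type: ignore[arg-type]
            if len(b) != 6:
                raise AucsegError("RoiSpec bounds must be 6 integers")
            object.__setattr__(self, "bounds", b)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RoiSpec":
        return cls(mask=mask)

    @classmethod
    def from_bounds(cls, zmin, zmax, ymin, ymax, xmin, xmax) -> "RoiSpec":
        return cls(bounds=(zmin, zmax, ymin, ymax, xmin, xmax))

    def bounding_box(self, shape: Sequence[int]) -> tuple[int, int, int, int, int, int]:
        """Resolve to a half-open index box, validated against ``shape``."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise AucsegError(
                    f"ROI mask shape {self.mask.shape} does not match volume shape {tuple(shape)}"
                )
            nz = np.nonzero(self.mask)
            if nz[0].size == 0:
                raise EmptyRoiError("empty ROI")
            return tuple(
                int(v)
                for axis in range(3)
                for v in (nz[axis].min(), nz[axis].max() + 1)
            )  # type: ignore[return-value]
        b = self.bounds
        assert b is not None
        for axis in range(3):
            lo, hi = b[2 * axis], b[2 * axis + 1]
            if not (0 <= lo < hi <= shape[axis]):
                if lo >= hi:
                    raise EmptyRoiError("empty ROI")
                raise AucsegError(
                    f"ROI bounds {b} out of range for shape {tuple(shape)}"
                )
        return b


@dataclass
class LabelVolume:
    """Integer tumor-compartment map using the BraTS code convention.

    Codes: 0 background, 1 necrosis (NC), 2 edema, 4 enhancing tumor (ET).
    Derived regions: WT = {1,2,4}, TC = {1,4}, ET = {4}.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise AucsegError("label volume must be 3D")
        self.data = self.data.astype(np.int16, copy=False)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        codes = set(np.unique(self.data).tolist())
        bad = codes - VALID_LABEL_CODES
        if bad:
            raise AucsegError(f"invalid label codes {sorted(bad)}; allowed {sorted(VALID_LABEL_CODES)}")

    def region_mask(self, region: str) -> np.ndarray:
        from .evaluation import extract_region

        return extract_region(self, region)


def load_case(
    flair_path: str | Path,
    t1ce_path: str | Path,
    t2_path: str | Path | None = None,
) -> MultiModalCase:
    """Load a case from NIfTI files; volumes must be co-registered.

    Raises :class:`CoRegistrationError` when shapes differ or affines
    disagree beyond a small absolute tolerance. The brain mask is
    computed; no normalization is applied here.
    """
    imgs = {"flair": nib.load(str(flair_path)), "t1ce": nib.load(str(t1ce_path))}
    if t2_path is not None:
        imgs["t2"] = nib.load(str(t2_path))
    ref = imgs["flair"]
    for name, img in imgs.items():
        if img.shape != ref.shape:
            raise CoRegistrationError(
                f"modalities not co-registered: flair shape {ref.shape} vs {name} shape {img.shape}"
            )
        if not np.allclose(img.affine, ref.affine, atol=_AFFINE_ATOL):
            raise CoRegistrationError(
                f"modalities not co-registered: affine of {name} differs from flair"
            )
    data = {name: np.asarray(img.dataobj, dtype=np.float64) for name, img in imgs.items()}
    return MultiModalCase(
        flair=data["flair"],
        t1ce=data["t1ce"],
        t2=data.get("t2"),
        affine=np.asarray(ref.affine, dtype=np.float64),
    )


def normalize_volume(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalize in-mask intensities to [0, 1]; zero elsewhere.

    A constant in-mask volume (max == min) degenerates to all-zero
    in-mask values with a warning, so batch runs survive corrupt cases.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AucsegError("normalization mask is empty")
    vals = volume[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    out = np.zeros_like(volume)
    if vmax == vmin:
        warnings.warn(
            "constant in-mask intensity: normalized volume set to zero", stacklevel=2
        )
        return out
    out[mask] = (vals - vmin) / (vmax - vmin)
    return out


def normalize_case(case: MultiModalCase) -> MultiModalCase:
    """Return a copy of the case with every modality min-max normalized
    over the brain mask."""
    mask = case.brain_mask
    return replace(
        case,
        flair=normalize_volume(case.flair, mask),
        t1ce=normalize_volume(case.t1ce, mask),
        t2=None if case.t2 is None else normalize_volume(case.t2, mask),
        brain_mask=mask,
    )


def _shift_affine(affine: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    out = affine.copy()
    out[:3, 3] += out[:3, :3] @ np.asarray(offset, dtype=np.float64)
    return out


def crop_to_roi(
    case: MultiModalCase, roi: RoiSpec
) -> tuple[MultiModalCase, tuple[int, int, int]]:
    """Crop a case to an ROI's bounding box.

    Returns the subvolume case and the ``(z, y, x)`` offset of its origin
    in full-volume coordinates, so stage results can be pasted back.
    """
    z0, z1, y0, y1, x0, x1 = roi.bounding_box(case.shape)
    sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    sub = MultiModalCase(
        flair=case.flair[sl],
        t1ce=case.t1ce[sl],
        t2=None if case.t2 is None else case.t2[sl],
        affine=_shift_affine(case.affine, (z0, y0, x0)),
        brain_mask=case.brain_mask[sl],
    )
    return sub, (z0, y0, x0)


def paste_mask(
    full: np.ndarray, sub: np.ndarray, offset: Sequence[int]
) -> np.ndarray:
    """Union a cropped binary mask into ``full`` at ``offset`` (in place)."""
    z0, y0, x0 = offset
    sl = (
        slice(z0, z0 + sub.shape[0]),
        slice(y0, y0 + sub.shape[1]),
        slice(x0, x0 + sub.shape[2]),
    )
    full[sl] |= sub
    return full


def save_labels(label_volume: LabelVolume, path: str | Path) -> None:
    """Write a label map to NIfTI with an integer dtype; affine preserved."""
    label_volume.validate()
    img = nib.Nifti1Image(label_volume.data.astype(np.int16), label_volume.affine)
    img.to_filename(str(path))


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelVolume(data=np.rint(data).astype(np.int16), affine=np.asarray(img.affine))
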