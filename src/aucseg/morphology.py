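"""3D morphological post-processing: connected components, hole filling,
and dilation.

Connectivity in 3D comes in three levels — 6 (faces), 18 (faces+edges),
26 (faces+edges+corners). Foreground analysis defaults to 26 and the
background used for hole filling defaults to 6, the standard
complementary pairing. Dilation is local-maximum substitution over a
structuring element; the kernel is truncated at volume borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_model import AucsegError

__all__ = [
    "ComponentLabeling",
    "default_kernel",
    "connectivity_structure",
    "connected_components",
    "largest_component",
    "fill_holes",
    "dilate",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary adjacency structure for a 6/18/26 connectivity level."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise AucsegError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, rank)


def default_kernel() -> np.ndarray:
    """Default structuring element: 3x3x3 all-true."""
    return np.ones((3, 3, 3), dtype=bool)


def _validate_kernel(kernel: np.ndarray) -> np.ndarray:
    kernel = np.asarray(kernel, dtype=bool)
    if kernel.ndim != 3:
        raise AucsegError("structuring element must be 3D")
    if any(s % 2 == 0 for s in kernel.shape):
        raise AucsegError("structuring element must have odd extent along each axis")
    center = tuple(s // 2 for s in kernel.shape)
    if not kernel[center]:
        raise AucsegError("structuring element center must be true")
    return kernel


@dataclass
class ComponentLabeling:
    """Connected-component labeling: ids contiguous 1..count, 0 = background."""

    labels: np.ndarray
    count: int
    sizes: np.ndarray  # voxel count of component id i at sizes[i-1]
    connectivity: int

    def component_mask(self, component_id: int) -> np.ndarray:
        if not (1 <= component_id <= self.count):
            raise AucsegError(f"component id {component_id} out of range 1..{self.count}")
        return self.labels == component_id


def connected_components(mask: np.ndarray, connectivity: int = 26) -> ComponentLabeling:
    """Label connected components of a binary mask.

    Components are numbered in raster-scan order of first encounter, so a
    lower id always has a smaller minimum linear voxel index.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = connectivity_structure(connectivity)
    labels, count = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=count + 1)[1:]
    return ComponentLabeling(
        labels=labels, count=int(count), sizes=sizes, connectivity=int(connectivity)
    )


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Restrict a mask to its largest connected component.

    Ties are broken toward the lowest component id (earliest raster-scan
    encounter). An empty mask yields an empty mask with a warning.
    """
    labeling = connected_components(mask, connectivity)
    if labeling.count == 0:
        warnings.warn("largest_component of an empty mask", stacklevel=2)
        return np.zeros(np.asarray(mask).shape, dtype=bool)
    best = int(np.argmax(labeling.sizes)) + 1  # argmax keeps the first/lowest id on ties
    return labeling.labels == best


def fill_holes(mask: np.ndarray, connectivity_background: int = 6) -> np.ndarray:
    """Fill internal cavities: background components not connected to the
    volume border become foreground; border-connected background is kept."""
    mask = np.asarray(mask, dtype=bool)
    inverse = ~mask
    labels, count = ndimage.label(
        inverse, structure=connectivity_structure(connectivity_background)
    )
    if count == 0:
        return mask.copy()
    border_ids = np.zeros(count + 1, dtype=bool)
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_ids[np.unique(labels[tuple(sl)])] = True
    border_ids[0] = True
    holes = ~border_ids[labels]
    return mask | holes


def dilate(volume: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Morphological dilation: each voxel becomes the maximum of the input
    over the kernel support centered there.

    Binary masks stay binary; grayscale volumes return float. Kernel
    positions falling outside the volume are ignored (no padding value is
    invented).
    """
    kernel = default_kernel() if kernel is None else _validate_kernel(kernel)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise AucsegError("dilation expects a 3D volume")
    if volume.dtype == bool:
        return ndimage.binary_dilation(volume, structure=kernel)
    out = ndimage.maximum_filter(
        volume.astype(np.float64), footprint=kernel, mode="constant", cval=-np.inf
    )
    return out
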