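"""Segmentation-quality scoring: Dice overlap and the fractional mean
absolute distance (fMAD) curve.

fMAD is asymmetric: it reports, for each distance d, the fraction of the
candidate segmentation's surface voxels whose nearest reference-surface voxel
lies within d millimetres, giving an indication of how much of a proposed
contour is already acceptably close to the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid_io import BinaryMask

logger = logging.getLogger("atlaslink")

__all__ = ["FMADCurve", "surface_voxels", "dsc", "fmad"]

# 6-connectivity: voxels share a face
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class FMADCurve:
    """Cumulative fraction of surface voxels within each distance (mm)."""

    distances: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.distances.shape != self.fractions.shape:
            raise ValueError("distances and fractions must align")


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking object voxels with a 6-connected background
    neighbour; sides facing out of the image count as background."""
    inside = mask.inside
    # border_value=0 treats out-of-image as background, so face voxels on the
    # image boundary are surface voxels
    eroded = ndimage.binary_erosion(
        inside, structure=_FACE_STRUCTURE, border_value=0
    )
    return inside & ~eroded


def dsc(b1: BinaryMask, b2: BinaryMask) -> float:
    """Dice similarity coefficient, 2|B1 ∩ B2| / (|B1| + |B2|).

    Symmetric; 1 for identical segmentations, 0 for disjoint ones.  Two empty
    masks compare as identical (1.0, with a warning) so that evaluation stays
    defined when a warped structure leaves the field of view.
    """
    if b1.grid != b2.grid:
        raise ValueError("masks must share a grid")
    n1 = int(b1.inside.sum())
    n2 = int(b2.inside.sum())
    if n1 == 0 and n2 == 0:
        logger.warning("DSC of two empty masks; defined as 1.0")
        return 1.0
    inter = int(np.count_nonzero(b1.inside & b2.inside))
    return 2.0 * inter / (n1 + n2)


def fmad(b1: BinaryMask, b2: BinaryMask, distances) -> FMADCurve:
    """Fraction of b1's surface voxels within each distance (mm, 3-D
    Euclidean with anisotropic spacing) of b2's nearest surface voxel."""
    if b1.grid != b2.grid:
        raise ValueError("masks must share a grid")
    s1 = surface_voxels(b1)
    if not s1.any():
        raise ValueError("candidate mask has no surface voxels")
    s2 = surface_voxels(b2)
    if not s2.any():
        raise ValueError("reference mask has no surface voxels")
    # distance (mm) from every voxel to the nearest reference surface voxel
    dist_to_s2 = ndimage.distance_transform_edt(~s2, sampling=b2.grid.spacing)
    d = dist_to_s2[s1]
    distances = np.sort(np.asarray(distances, dtype=float))
    fractions = np.array([(d <= thr).mean() for thr in distances])
    return FMADCurve(distances, fractions)
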