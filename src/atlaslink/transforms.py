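"""Spatial transformations: B-spline free-form deformations, dense
displacement fields, and their composition.

Transforms follow the pull-back (resampling) convention: a transform maps
fixed-space world coordinates to moving-space world coordinates, so a warped
image is ``R(x) = M(T(x))``.  Linking registrations through intermediate
images is function composition, ``T_{M<-I(l)<-F} = T_{M<-I} o ... o T_{I<-F}``;
composed transforms are materialized as dense displacement fields on the
fixed grid with one trilinear interpolation per link, which keeps the cost of
each additional link to a single resampling pass.

Out-of-domain behaviour: displacement fields clamp to the nearest border
voxel's vector; B-splines evaluate to zero displacement outside the support
of their control lattice.  Composed chains inevitably push some points past
the field of view and clamping keeps every evaluation finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from .grid_io import BinaryMask, ImageGrid, LabelMap, ScalarImage

__all__ = [
    "BSplineTransform",
    "DisplacementField",
    "TransformChain",
    "Transform",
    "identity_field",
    "compose",
    "compose_chain",
    "warp_image",
    "warp_mask",
    "warp_labels",
]


def _cubic_bspline_weights(t: np.ndarray) -> tuple[np.ndarray, ...]:
    """The four cubic B-spline basis values at fractional offset t in [0, 1).

    Returns weights for control points at cell offsets -1, 0, 1, 2.  They sum
    to one for every t (partition of unity), which is what makes a constant
    coefficient lattice an exact translation.
    """
    t2 = t * t
    t3 = t2 * t
    w0 = (1.0 - 3.0 * t + 3.0 * t2 - t3) / 6.0
    w1 = (4.0 - 6.0 * t2 + 3.0 * t3) / 6.0
    w2 = (1.0 + 3.0 * t + 3.0 * t2 - 3.0 * t3) / 6.0
    w3 = t3 / 6.0
    return w0, w1, w2, w3


@dataclass
class BSplineTransform:
    """Cubic B-spline free-form deformation on a regular control lattice.

    ``coefficients[i, j, k]`` is the 3-vector (mm) attached to the control
    point at world position ``control_origin + (i, j, k) * control_spacing``.
    The lattice must extend at least one control spacing beyond the domain so
    the cubic basis has full support everywhere inside it; use
    :meth:`covering` to build such a lattice.
    """

    control_origin: tuple[float, float, float]
    control_spacing: tuple[float, float, float]
    coefficients: np.ndarray  # (ncx, ncy, ncz, 3), mm
    domain: ImageGrid

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (ncx, ncy, ncz, 3)")
        self.control_origin = tuple(float(v) for v in self.control_origin)
        self.control_spacing = tuple(float(v) for v in self.control_spacing)
        if any(s <= 0 for s in self.control_spacing):
            raise ValueError("control spacing must be positive")

    @classmethod
    def covering(
        cls,
        domain: ImageGrid,
        control_spacing: Union[float, Sequence[float]],
        coefficients: np.ndarray | None = None,
    ) -> "BSplineTransform":
        """Build a lattice (zero coefficients by default) covering `domain`.

        The lattice is padded by three control points beyond the domain on
        each side: one for full 4-point basis support everywhere inside the
        domain, two more so the deformation stays smooth a couple of control
        spacings beyond it (composed chains and inverse iterations evaluate
        slightly out of domain).
        """
        if np.isscalar(control_spacing):
            control_spacing = (control_spacing,) * 3
        spacing = tuple(float(s) for s in control_spacing)
        shape = []
        origin = []
        for a in range(3):
            origin.append(domain.origin[a] - 3.0 * spacing[a])
            n_cells = int(np.floor(domain.extent[a] / spacing[a] + 1e-9))
            shape.append(n_cells + 8)
        if coefficients is None:
            coefficients = np.zeros((*shape, 3))
        elif tuple(coefficients.shape[:3]) != tuple(shape):
            raise ValueError(
                f"coefficient shape {coefficients.shape[:3]} does not match "
                f"required lattice {tuple(shape)}"
            )
        return cls(tuple(origin), spacing, coefficients, domain)

    # ------------------------------------------------------------------
    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors (mm) at world points, shape (N, 3).

        Points outside the lattice support get zero displacement.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        u = (pts - np.asarray(self.control_origin)) / np.asarray(self.control_spacing)
        cell = np.floor(u).astype(np.int64)

        nc = np.asarray(self.coefficients.shape[:3])
        # full support requires control indices cell-1 .. cell+2 in range
        supported = np.all((cell >= 1) & (cell + 2 <= nc - 1), axis=1)
        disp = np.zeros_like(pts)
        if not np.any(supported):
            return disp if points.ndim > 1 else disp[0]

        # map_coordinates with prefilter=False evaluates the cubic B-spline
        # expansion whose coefficients are the input array — exactly this FFD
        coords = u[supported].T
        for comp in range(3):
            disp[supported, comp] = ndimage.map_coordinates(
                self.coefficients[..., comp],
                coords,
                order=3,
                prefilter=False,
                mode="constant",
            )
        return disp if np.asarray(points).ndim > 1 else disp[0]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-space world points (N, 3) to moving-space world points."""
        pts = np.asarray(points, dtype=np.float64)
        return pts + self.displacement(pts)


@dataclass
class DisplacementField:
    """Dense per-voxel displacement vectors (mm) on an image grid."""

    grid: ImageGrid
    vectors: np.ndarray  # (*grid.shape, 3), mm

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"vector shape {self.vectors.shape} != {(*self.grid.shape, 3)}"
            )

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated displacement at world points (N, 3).

        Outside the grid the nearest border voxel's vector is used
        (edge clamp).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = self.grid.index_from_world(pts).T  # (3, N)
        out = np.empty((idx.shape[1], 3))
        for comp in range(3):
            out[:, comp] = ndimage.map_coordinates(
                self.vectors[..., comp], idx, order=1, mode="nearest"
            )
        return out if np.asarray(points).ndim > 1 else out[0]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts + self.displacement(pts)


Transform = Union[BSplineTransform, DisplacementField]


@dataclass
class TransformChain:
    """An ordered registration chain; ``transforms[0]`` is applied first to
    fixed-space points (the innermost map)."""

    transforms: list
    # number of intermediate images linked through
    @property
    def n_links(self) -> int:
        return len(self.transforms) - 1

    def __post_init__(self) -> None:
        self.transforms = list(self.transforms)
        if not self.transforms:
            raise ValueError("a registration chain holds at least one transform")
        if any(not hasattr(t, "evaluate") for t in self.transforms):
            raise TypeError("chain entries must be transforms")


def identity_field(grid: ImageGrid) -> DisplacementField:
    """The identity transform as a zero displacement field."""
    return DisplacementField(grid, np.zeros((*grid.shape, 3)))


def compose(
    outer: Transform, inner: Transform, output_grid: ImageGrid
) -> DisplacementField:
    """Materialize ``outer o inner`` as a displacement field on `output_grid`.

    The returned field ``d`` satisfies ``x + d(x) = outer(inner(x))`` at every
    grid point: exact evaluation for B-spline `outer`, trilinear interpolation
    when `outer` is itself a field.
    """
    pts = output_grid.voxel_centers().reshape(-1, 3)
    mapped = outer.evaluate(inner.evaluate(pts))
    vectors = (mapped - pts).reshape(*output_grid.shape, 3)
    return DisplacementField(output_grid, vectors)


def compose_chain(
    chain: TransformChain | Sequence[Transform], output_grid: ImageGrid
) -> DisplacementField:
    """Left-fold composition of a registration chain onto `output_grid`.

    A chain of length one is simply resampled onto the grid.
    """
    transforms = chain.transforms if isinstance(chain, TransformChain) else list(chain)
    if not transforms:
        raise ValueError("cannot compose an empty chain")
    result: Transform = transforms[0]
    if len(transforms) == 1:
        return compose(result, identity_field(output_grid), output_grid)
    for t in transforms[1:]:
        result = compose(t, result, output_grid)
    return result


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_ORDERS = {"linear": 1, "cubic_bspline": 3, "nn": 0}


def _mapped_indices(t: Transform, fixed_grid: ImageGrid, moving_grid: ImageGrid):
    pts = fixed_grid.voxel_centers().reshape(-1, 3)
    mapped = t.evaluate(pts)
    return moving_grid.index_from_world(mapped).T  # (3, N)


def warp_image(
    img: ScalarImage,
    t: Transform,
    fixed_grid: ImageGrid | None = None,
    interpolation: str = "linear",
) -> ScalarImage:
    """Resample a moving image through a transform onto the fixed grid.

    ``interpolation`` is ``linear`` or ``cubic_bspline`` (3rd-degree
    interpolating B-spline).  The identity transform with linear interpolation
    on the image's own grid reproduces the input exactly.
    """
    if fixed_grid is None:
        fixed_grid = img.grid
    if interpolation not in ("linear", "cubic_bspline"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    idx = _mapped_indices(t, fixed_grid, img.grid)
    values = ndimage.map_coordinates(
        img.values, idx, order=_ORDERS[interpolation], mode="nearest"
    )
    return ScalarImage(fixed_grid, values.reshape(fixed_grid.shape))


def warp_mask(
    mask: BinaryMask, t: Transform, fixed_grid: ImageGrid | None = None
) -> BinaryMask:
    """Transfer a binary mask by nearest-neighbour sampling at mapped points."""
    if fixed_grid is None:
        fixed_grid = mask.grid
    idx = _mapped_indices(t, fixed_grid, mask.grid)
    values = ndimage.map_coordinates(
        mask.inside.astype(np.uint8), idx, order=0, mode="nearest"
    )
    return BinaryMask(fixed_grid, values.reshape(fixed_grid.shape).astype(bool))


def warp_labels(
    labels: LabelMap, t: Transform, fixed_grid: ImageGrid | None = None
) -> LabelMap:
    """Transfer an entire label map by nearest-neighbour sampling.

    Equivalent to warping each structure's mask separately (labels are
    single-valued per voxel), but one resampling pass for all structures.
    """
    if fixed_grid is None:
        fixed_grid = labels.grid
    idx = _mapped_indices(t, fixed_grid, labels.grid)
    values = ndimage.map_coordinates(labels.labels, idx, order=0, mode="nearest")
    return LabelMap(
        fixed_grid,
        values.reshape(fixed_grid.shape),
        dict(labels.structure_names),
    )
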