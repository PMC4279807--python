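"""Synthetic phantom population: template, deformed atlases, noisy
pairwise registrations.

Stands in for a clinical atlas database.  A digital head-and-neck-like
phantom (paired gland ellipsoids, a mandible-like arc, a medulla-like tube,
slab-like node levels) is deformed by random smooth cubic B-spline
free-form deformations to produce N atlas subjects with consistent labels
and known ground-truth correspondences.  Imperfect pairwise registrations
are emulated by composing the exact inter-subject map with an independent
random smooth error field of controlled RMS magnitude, so that linking
registrations through intermediates accumulates error exactly as chained
imperfect registrations would.

All generators are deterministic per seed: atlas i uses the seed stream
``(seed; 0, i)`` and the (i, j) registration error uses ``(seed; 1, i, j)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grid_io import BinaryMask, ImageGrid, LabelMap, ScalarImage
from .transforms import (
    BSplineTransform,
    DisplacementField,
    Transform,
    compose,
    warp_image,
    warp_labels,
)

logger = logging.getLogger("atlaslink")

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "PopulationSpec",
    "Atlas",
    "make_template",
    "make_population",
    "make_pairwise_transform",
    "pairwise_provider",
    "random_ffd",
    "invert_transform",
    "simulate_sim_dsc",
    "default_phantom",
]


@dataclass(frozen=True)
class OrganSpec:
    """A rasterizable organ: ellipsoid, tube (z-axis cylinder) or arc
    (horseshoe-shaped torus section).

    radii (mm): ellipsoid semi-axes; tube (rx, ry, half_length); arc
    (major_radius, tube_radius).  ``angles_deg`` bounds the arc's polar angle
    in the xy-plane.
    """

    name: str
    shape: str
    center: tuple[float, float, float]
    radii: tuple[float, ...]
    intensity: float
    angles_deg: tuple[float, float] = (-150.0, -30.0)

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "tube", "arc"):
            raise ValueError(f"unknown organ shape {self.shape!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError("organ radii must be positive")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        if self.shape == "ellipsoid":
            half = np.asarray(self.radii)
        elif self.shape == "tube":
            half = np.asarray(self.radii)
        else:  # arc
            big, tube = self.radii
            half = np.array([big + tube, big + tube, tube])
        return c - half, c + half

    def rasterize(self, centers: np.ndarray) -> np.ndarray:
        """Boolean occupancy on voxel centers of shape (*grid, 3)."""
        x = centers[..., 0] - self.center[0]
        y = centers[..., 1] - self.center[1]
        z = centers[..., 2] - self.center[2]
        if self.shape == "ellipsoid":
            rx, ry, rz = self.radii
            return (x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
        if self.shape == "tube":
            rx, ry, half_len = self.radii
            return ((x / rx) ** 2 + (y / ry) ** 2 <= 1.0) & (np.abs(z) <= half_len)
        big, tube = self.radii
        radial = np.hypot(x, y)
        dist = np.sqrt((radial - big) ** 2 + z**2)
        angle = np.degrees(np.arctan2(y, x))
        lo, hi = self.angles_deg
        return (dist <= tube) & (angle >= lo) & (angle <= hi)


def default_organs() -> tuple[OrganSpec, ...]:
    """Seven structures mirroring a head-and-neck organ-at-risk set."""
    return (
        OrganSpec("parotid_r", "ellipsoid", (25.0, 68.0, 80.0), (10.0, 12.0, 14.0), 110.0),
        OrganSpec("parotid_l", "ellipsoid", (101.0, 68.0, 80.0), (10.0, 12.0, 14.0), 110.0),
        OrganSpec("submandibular_r", "ellipsoid", (43.0, 38.0, 52.0), (8.0, 8.0, 9.0), 95.0),
        OrganSpec("submandibular_l", "ellipsoid", (83.0, 38.0, 52.0), (8.0, 8.0, 9.0), 95.0),
        OrganSpec("mandible", "arc", (63.0, 72.0, 62.0), (34.0, 6.0), 240.0, (-150.0, -30.0)),
        OrganSpec("medulla", "tube", (63.0, 95.0, 70.0), (5.0, 5.0, 45.0), 70.0),
        OrganSpec("node_level_r", "ellipsoid", (33.0, 95.0, 70.0), (9.0, 13.0, 28.0), 55.0),
        OrganSpec("node_level_l", "ellipsoid", (93.0, 95.0, 70.0), (9.0, 13.0, 28.0), 55.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    grid: ImageGrid = ImageGrid((64, 64, 48), (2.0, 2.0, 3.0))
    organs: tuple[OrganSpec, ...] = field(default_factory=default_organs)
    background_intensity: float = 20.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.grid.origin)
        hi = lo + np.asarray(self.grid.extent)
        for organ in self.organs:
            blo, bhi = organ.bounds()
            if np.any(blo < lo) or np.any(bhi > hi):
                raise ValueError(f"organ {organ.name!r} extends outside the grid")


@dataclass(frozen=True)
class PopulationSpec:
    """Study-population parameters for the synthetic atlas cohort.

    Inter-subject anatomy varies by smooth random deformations of
    ``deformation_amplitude_mm`` RMS on a ``deformation_spacing_mm`` control
    lattice; emulated registrations err by independent smooth fields of
    ``registration_error_mm`` RMS on an ``error_spacing_mm`` lattice.
    """

    n_atlases: int = 6
    deformation_amplitude_mm: float = 4.0
    deformation_spacing_mm: float = 20.0
    registration_error_mm: float = 2.0
    error_spacing_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 2:
            raise ValueError("need at least two atlases")
        if self.deformation_amplitude_mm < 0 or self.registration_error_mm < 0:
            raise ValueError("amplitudes are non-negative")


@dataclass
class Atlas:
    """One synthetic subject with its ground-truth link to the template.

    ``to_template`` maps atlas coordinates to template coordinates (the
    pull-back used to create the atlas); ``from_template`` is its numerical
    inverse sampled on the template grid.
    """

    atlas_id: int
    image: ScalarImage
    labels: LabelMap
    to_template: BSplineTransform
    from_template: DisplacementField


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


def make_template(spec: PhantomSpec, seed: int = 0) -> tuple[ScalarImage, LabelMap]:
    """Rasterize the phantom: noisy intensities, noise-free labels."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    centers = spec.grid.voxel_centers()
    intensities = np.full(spec.grid.shape, spec.background_intensity)
    labels = np.zeros(spec.grid.shape, dtype=np.int32)
    names: dict[int, str] = {}
    for value, organ in enumerate(spec.organs, start=1):
        occupied = organ.rasterize(centers)
        intensities[occupied] = organ.intensity
        labels[occupied] = value
        names[value] = organ.name
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, spec.grid.shape)
    return ScalarImage(spec.grid, intensities), LabelMap(spec.grid, labels, names)


# ---------------------------------------------------------------------------
# Random smooth deformations
# ---------------------------------------------------------------------------

_MAX_COEFF_FRACTION = 0.4  # of the control spacing; keeps fields invertible


def random_ffd(
    domain: ImageGrid,
    control_spacing_mm: float,
    rms_mm: float,
    rng: np.random.Generator,
    max_tries: int = 8,
) -> BSplineTransform:
    """A random cubic B-spline deformation with the requested displacement
    RMS magnitude over the domain.

    Coefficients are iid Gaussian, rescaled so the realized field RMS matches
    ``rms_mm`` exactly.  The coefficient spread is capped at 0.4 x control
    spacing and the numerical Jacobian determinant is required to stay
    positive on a sample grid; violating draws are regenerated.
    """
    zero = BSplineTransform.covering(domain, control_spacing_mm)
    if rms_mm == 0:
        return zero
    shape = zero.coefficients.shape
    # decimated voxel centers for RMS measurement and Jacobian checking
    step = (2, 2, 2)
    sample = domain.voxel_centers()[:: step[0], :: step[1], :: step[2]]
    pts = sample.reshape(-1, 3)
    for attempt in range(max_tries):
        coeffs = rng.normal(0.0, 1.0, shape)
        t = BSplineTransform(zero.control_origin, zero.control_spacing, coeffs, domain)
        disp = t.displacement(pts)
        realized = math.sqrt(float(np.mean(np.sum(disp**2, axis=1))))
        scale = rms_mm / realized
        if float(np.std(coeffs)) * scale > _MAX_COEFF_FRACTION * control_spacing_mm:
            raise ValueError(
                f"requested RMS {rms_mm} mm is too large for a "
                f"{control_spacing_mm} mm control spacing to stay invertible"
            )
        t = BSplineTransform(
            zero.control_origin, zero.control_spacing, coeffs * scale, domain
        )
        if _jacobian_positive(t, sample, disp * scale):
            return t
        logger.warning("regenerating deformation draw %d: folded Jacobian", attempt)
    raise RuntimeError("could not draw an invertible deformation")


def _jacobian_positive(t: BSplineTransform, sample: np.ndarray, disp: np.ndarray) -> bool:
    """Check det(I + grad d) > 0 by finite differences on the sample grid."""
    d = disp.reshape(*sample.shape[:3], 3)
    spacing = sample[1, 1, 1] - sample[0, 0, 0]  # decimated physical steps
    jac = np.empty((*d.shape[:3], 3, 3))
    for comp in range(3):
        grads = np.gradient(d[..., comp], *spacing, edge_order=1)
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
    jac += np.eye(3)
    return bool(np.linalg.det(jac).min() > 0.05)


def invert_transform(
    t: Transform,
    grid: ImageGrid,
    tol_mm: float = 1e-2,
    max_iter: int = 60,
    pad_mm: float = 16.0,
) -> DisplacementField:
    """Numerically invert a deformation by fixed-point iteration.

    Solves x + d(x) = y for every grid point y via x <- y - d(x); converges
    for the moderate, invertible deformations the generators produce.  The
    forward displacement is sampled once on a grid padded by twice ``pad_mm``
    so iterates wandering past the image border still see smooth values; the
    iteration itself then costs one trilinear interpolation per sweep.  The
    returned field lives on a grid padded by ``pad_mm``, so later
    compositions that map points slightly outside the image still see an
    accurate inverse rather than an edge-clamped one.  ``pad_mm`` is kept in
    physical units (and should stay below the transform's smooth margin
    beyond the domain, two control spacings for the generated deformations).
    """

    def pad_grid(base: ImageGrid, mm: float) -> ImageGrid:
        pads = [int(np.ceil(mm / sp)) for sp in base.spacing]
        return ImageGrid(
            tuple(s + 2 * p for s, p in zip(base.shape, pads)),
            base.spacing,
            tuple(o - p * sp for o, p, sp in zip(base.origin, pads, base.spacing)),
        )

    outer = pad_grid(grid, 2.0 * pad_mm)
    sampled = DisplacementField(
        outer,
        t.displacement(outer.voxel_centers().reshape(-1, 3)).reshape(
            *outer.shape, 3
        ),
    )
    padded = pad_grid(grid, pad_mm)
    pts = padded.voxel_centers().reshape(-1, 3)
    x = pts.copy()
    for _ in range(max_iter):
        new_x = pts - sampled.displacement(x)
        step = np.abs(new_x - x).max()
        x = new_x
        if step < tol_mm:
            break
    else:
        logger.warning("inverse iteration stopped at %.2g mm residual", step)
    return DisplacementField(padded, (x - pts).reshape(*padded.shape, 3))


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def _rasterize_organs(
    organs: tuple[OrganSpec, ...], points: np.ndarray, grid: ImageGrid,
    names: dict[int, str],
) -> LabelMap:
    labels = np.zeros(points.shape[0], dtype=np.int32)
    for value, organ in enumerate(organs, start=1):
        labels[organ.rasterize(points)] = value
    return LabelMap(grid, labels.reshape(grid.shape), dict(names))


def make_population(
    template: tuple[ScalarImage, LabelMap],
    pop: PopulationSpec,
    organs: tuple[OrganSpec, ...] | None = None,
) -> list[Atlas]:
    """Deform the template into a cohort with known correspondences.

    Atlas i is the template pulled back through a random smooth deformation
    g_i (atlas coordinates -> template coordinates).  When the phantom's
    ``organs`` are given, each atlas's labels are rasterized analytically —
    the organ indicator evaluated at g_i of the voxel centers — which avoids
    a second voxelization error on top of the transfer's nearest-neighbour
    sampling; otherwise the template labels are nearest-neighbour warped.
    The numerical inverse of g_i on the template grid is retained so exact
    pairwise maps between any two atlases can be formed without
    registration.
    """
    image, labels = template
    grid = image.grid
    atlases: list[Atlas] = []
    for i in range(pop.n_atlases):
        rng = np.random.default_rng(np.random.SeedSequence(pop.seed, spawn_key=(0, i)))
        g = random_ffd(grid, pop.deformation_spacing_mm, pop.deformation_amplitude_mm, rng)
        if organs is not None:
            mapped = g.evaluate(grid.voxel_centers().reshape(-1, 3))
            atlas_labels = _rasterize_organs(
                organs, mapped, grid, labels.structure_names
            )
        else:
            atlas_labels = warp_labels(labels, g, grid)
        atlases.append(
            Atlas(
                atlas_id=i,
                image=warp_image(image, g, grid, interpolation="linear"),
                labels=atlas_labels,
                to_template=g,
                from_template=invert_transform(g, grid),
            )
        )
    return atlases


def exact_pairwise(atlases: list[Atlas], i: int, j: int) -> DisplacementField:
    """The ground-truth registration T_{j<-i}: fixed-atlas-i coordinates to
    the anatomically corresponding moving-atlas-j coordinates."""
    grid = atlases[i].labels.grid
    return compose(atlases[j].from_template, atlases[i].to_template, grid)


def make_pairwise_transform(
    atlases: list[Atlas],
    i: int,
    j: int,
    error_amplitude_mm: float,
    seed: int,
    error_spacing_mm: float = 12.0,
) -> DisplacementField:
    """An emulated imperfect registration of atlas j onto atlas i.

    The exact inter-subject map is composed with an independent random smooth
    error field of the stated RMS magnitude; the error draw is deterministic
    per (seed, i, j) and independent across pairs.
    """
    exact = exact_pairwise(atlases, i, j)
    if error_amplitude_mm == 0:
        return exact
    grid = atlases[i].labels.grid
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, i, j)))
    err = random_ffd(grid, error_spacing_mm, error_amplitude_mm, rng)
    return compose(exact, err, grid)


def pairwise_provider(
    atlases: list[Atlas],
    error_amplitude_mm: float,
    seed: int,
    error_spacing_mm: float = 12.0,
):
    """A caching ``(fixed, moving) -> Transform`` callable for the
    evaluation engine; each pair is materialized once."""
    cache: dict[tuple[int, int], DisplacementField] = {}

    def provider(i: int, j: int) -> DisplacementField:
        key = (i, j)
        if key not in cache:
            cache[key] = make_pairwise_transform(
                atlases, i, j, error_amplitude_mm, seed, error_spacing_mm
            )
        return cache[key]

    return provider


# ---------------------------------------------------------------------------
# Similarity/quality toy model
# ---------------------------------------------------------------------------


def simulate_sim_dsc(
    n: int,
    k: float,
    s: float,
    seed: int,
    intercept: float = 0.3,
    sim_range: tuple[float, float] = (0.0, 0.3),
) -> np.ndarray:
    """Draw (SIM, DSC) pairs from the linear quality-vs-similarity model
    DSC = a + k SIM + eps with eps ~ Normal(0, s^2); SIM uniform on
    ``sim_range``.  DSC values are clipped to [0, 1] (clipping logged).
    Returns an (n, 2) array of columns (SIM, DSC)."""
    if n < 2:
        raise ValueError("need at least two pairs")
    if s < 0:
        raise ValueError("residual sd is non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sims = rng.uniform(*sim_range, n)
    dscs = intercept + k * sims + rng.normal(0.0, s, n)
    clipped = int(np.count_nonzero((dscs < 0) | (dscs > 1)))
    if clipped:
        logger.warning("clipped %d simulated DSC values into [0, 1]", clipped)
        dscs = np.clip(dscs, 0.0, 1.0)
    return np.column_stack([sims, dscs])
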