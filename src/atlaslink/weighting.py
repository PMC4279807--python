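"""Similarity-driven fusion weights.

Atlases whose registered image resembles the patient image near a structure
tend to contribute better label proposals there.  The weight given to atlas i
is the probability that its (unobserved) segmentation quality exceeds that of
the most similar atlas, under a linear quality-vs-similarity model with
Gaussian residuals:

    w_i = 1/2 (1 - erf( (k/s) / sqrt(2) * (SIM_best - SIM_i) ))

where k is the slope of the DSC-on-SIM regression line and s the standard
deviation of its residuals.  The best atlas always receives 1/2 and k/s = 0
recovers equal weighting.  Rather than fixing k and s by regression, k/s can
be swept through a slope-angle parameterization

    k/s = sqrt(N) tan(theta) / sqrt(ss_DSC + ss_SIM tan^2(theta)
                                    - 2 ss_SIM,DSC tan(theta))

and calibrated by maximizing the mean fused DSC over leave-one-out cases.

Similarity itself is normalized cross correlation computed per structure over
a band region: all voxels whose signed distance to the structure is at most a
cut-off r (the structure plus an r-mm outer margin), evaluated in the fixed
image frame where all atlases are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .distance_fusion import (
    SignedDistanceMap,
    extract_segmentation,
    fuse,
    signed_distance,
)
from .grid_io import BinaryMask, ScalarImage
from .metrics import dsc

logger = logging.getLogger("atlaslink")

__all__ = [
    "SimilarityRecord",
    "WeightParams",
    "FusionCandidate",
    "CalibrationCase",
    "CalibrationResult",
    "band_region",
    "ncc",
    "probabilistic_weight",
    "k_over_s_from_theta",
    "calibrate",
    "rank_intermediates",
]

#: Default NCC band radius (mm) per structure kind: sharp-boundary structures
#: (mandible-like) score best with the structure region alone, the rest with
#: a 10 mm outer margin.
DEFAULT_BAND_MM = 10.0
SHARP_BAND_MM = 0.0


@dataclass(frozen=True)
class SimilarityRecord:
    atlas_id: str
    structure: str
    sim: float
    band_mm: float = DEFAULT_BAND_MM

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.sim <= 1.0 + 1e-12:
            raise ValueError(f"similarity {self.sim} outside [-1, 1]")


@dataclass(frozen=True)
class WeightParams:
    k_over_s: float
    theta_deg: float | None = None

    def __post_init__(self) -> None:
        if self.k_over_s < 0:
            raise ValueError("k/s is non-negative")


def band_region(structure_map: SignedDistanceMap, r: float) -> BinaryMask:
    """Voxels with signed distance <= r: the structure plus an r-mm margin.

    r = 0 yields the structure interior plus its border exactly.
    """
    if r < 0:
        raise ValueError("band radius is non-negative")
    return BinaryMask(structure_map.grid, structure_map.values <= r)


def ncc(f: ScalarImage, m: ScalarImage, region: BinaryMask) -> float:
    """Normalized cross correlation of two images over a region.

    Means and normalisation use region voxels only; invariant to positive
    affine rescaling of either image.  Undefined (raises) when either image
    is constant over the region.
    """
    if f.grid != region.grid or m.grid != region.grid:
        raise ValueError("images and region must share a grid")
    sel = region.inside
    n = int(sel.sum())
    if n < 2:
        raise ValueError("region must contain at least 2 voxels")
    fv = f.values[sel]
    mv = m.values[sel]
    fd = fv - fv.mean()
    md = mv - mv.mean()
    denom = math.sqrt(float(fd @ fd) * float(md @ md))
    if denom == 0.0:
        raise ValueError("NCC undefined: zero variance over the region")
    return float(fd @ md) / denom


def probabilistic_weight(sim_i: float, sim_best: float, k_over_s: float) -> float:
    """Fusion weight in (0, 1/2] from the similarity deficit of atlas i."""
    if k_over_s < 0:
        raise ValueError("k/s is non-negative")
    if sim_best < sim_i:
        raise ValueError("sim_best must be the maximum similarity")
    arg = k_over_s / math.sqrt(2.0) * (sim_best - sim_i)
    return 0.5 * (1.0 - float(special.erf(arg)))


def _sums_of_squares(sims, dscs) -> tuple[float, float, float, int]:
    sims = np.asarray(sims, dtype=float)
    dscs = np.asarray(dscs, dtype=float)
    if sims.shape != dscs.shape or sims.ndim != 1:
        raise ValueError("sims and dscs must be equal-length 1-D sequences")
    n = sims.size
    if n < 2:
        raise ValueError("need at least two (SIM, DSC) pairs")
    ds = sims - sims.mean()
    dd = dscs - dscs.mean()
    return float(ds @ ds), float(dd @ dd), float(ds @ dd), n


def k_over_s_from_theta(theta_deg: float, sims, dscs) -> float:
    """The k/s ratio implied by regression-line slope angle theta (degrees).

    With x = SIM and y = DSC, evaluating at the ordinary-least-squares angle
    theta = atan(ss_xy / ss_xx) returns exactly slope / residual-sd where the
    residual sd uses the 1/N (maximum-likelihood) normalisation.
    """
    if not -89.0 <= theta_deg <= 89.0:
        raise ValueError("theta must lie in [-89, 89] degrees")
    ss_sim, ss_dsc, ss_cross, n = _sums_of_squares(sims, dscs)
    tan_t = math.tan(math.radians(theta_deg))
    radicand = ss_dsc + ss_sim * tan_t**2 - 2.0 * ss_cross * tan_t
    if radicand <= 0:
        raise ValueError("degenerate (SIM, DSC) sample: non-positive radicand")
    return math.sqrt(n) * tan_t / math.sqrt(radicand)


@dataclass
class FusionCandidate:
    """One atlas's contribution to a fusion case."""

    atlas_id: str
    mask: BinaryMask
    sim: float
    _sdm: SignedDistanceMap | None = field(default=None, repr=False)

    def distance_map(self) -> SignedDistanceMap:
        if self._sdm is None:
            self._sdm = signed_distance(self.mask)
        return self._sdm


@dataclass
class CalibrationCase:
    """A leave-one-out fusion case: candidate masks + the reference."""

    reference: BinaryMask
    candidates: list[FusionCandidate]


@dataclass
class CalibrationResult:
    params: WeightParams
    theta_deg: np.ndarray
    k_over_s: np.ndarray
    mean_dsc: np.ndarray


def case_weights(sims, k_over_s: float) -> np.ndarray:
    """Probabilistic weights for one case's similarity vector."""
    sims = np.asarray(sims, dtype=float)
    best = float(sims.max())
    return np.array([probabilistic_weight(s, best, k_over_s) for s in sims])


def calibrate(
    cases: list[CalibrationCase],
    theta_grid=None,
) -> CalibrationResult:
    """Sweep the slope angle, score fused segmentations, return the optimum.

    For each theta, k/s is computed from the pooled (SIM, individual DSC)
    sample across all cases, per-case weights follow from each case's
    similarities, and the mean DSC of the fused segmentations against the
    references is recorded.  Default sweep: -89..+89 degrees in 1-degree
    steps.  Candidates with empty masks are dropped from their case with a
    warning (no distance map exists for them).
    """
    if theta_grid is None:
        theta_grid = np.arange(-89.0, 90.0, 1.0)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta grid must be nonempty")
    if not cases:
        raise ValueError("no calibration cases")

    prepared = []  # (reference, sdms, sims) per case
    pooled_sims: list[float] = []
    pooled_dscs: list[float] = []
    for case in cases:
        kept = [c for c in case.candidates if c.mask.inside.any()]
        dropped = len(case.candidates) - len(kept)
        if dropped:
            logger.warning("dropped %d empty candidate mask(s) from a case", dropped)
        if not kept:
            raise ValueError("a calibration case has no nonempty candidates")
        sdms = [c.distance_map() for c in kept]
        sims = np.array([c.sim for c in kept])
        for c in kept:
            pooled_sims.append(c.sim)
            pooled_dscs.append(dsc(c.mask, case.reference))
        prepared.append((case.reference, sdms, sims))

    k_values = np.empty_like(theta_grid)
    mean_dsc = np.empty_like(theta_grid)
    for it, theta in enumerate(theta_grid):
        k_over_s = k_over_s_from_theta(theta, pooled_sims, pooled_dscs)
        k_values[it] = k_over_s
        scores = []
        for reference, sdms, sims in prepared:
            # negative k/s (negative theta) legitimately up-weights the less
            # similar atlases during the sweep, so apply the erf form directly
            weights = 0.5 * (
                1.0
                - special.erf(k_over_s / math.sqrt(2.0) * (sims.max() - sims))
            )
            fused = extract_segmentation(fuse(sdms, weights))
            scores.append(dsc(fused, reference))
        mean_dsc[it] = float(np.mean(scores))

    # the reported operating point is restricted to k/s >= 0 (the weight
    # function's domain); the returned curve still covers the whole sweep
    valid = k_values >= 0
    masked = np.where(valid, mean_dsc, -np.inf)
    best_idx = int(np.argmax(masked))
    params = WeightParams(
        k_over_s=float(k_values[best_idx]), theta_deg=float(theta_grid[best_idx])
    )
    return CalibrationResult(params, theta_grid, k_values, mean_dsc)


def rank_intermediates(sims: list[SimilarityRecord]) -> list[str]:
    """Candidate atlas ids ordered by descending similarity.

    More similar images make better hubs for registration linking; ties break
    deterministically by atlas id.
    """
    return [
        rec.atlas_id
        for rec in sorted(sims, key=lambda r: (-r.sim, r.atlas_id))
    ]
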