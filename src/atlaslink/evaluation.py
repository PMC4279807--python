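"""Leave-one-out evaluation of direct vs linked atlas registrations.

Each atlas in turn plays the patient (fixed image); the remaining atlases are
registered to it either directly or through chains of intermediate atlases,
their structure labels transferred, and the Dice coefficient scored against
the fixed atlas's own manual labels.  For N atlases there are N(N-1) direct
registrations and N(N-1)(N-2) one-link combinations; longer chains are
randomly sampled because the combinatorics explode.  The module also scores
fused segmentations (one fusion per fixed/intermediate pair, with the
intermediate contributing its labels through its own direct registration),
aggregates median/quartile statistics, compares distributions with the
Wilcoxon rank-sum test, and fits the linear decay of median DSC against the
number of links.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance_fusion import extract_segmentation, fuse, signed_distance
from .grid_io import split_labels
from .metrics import dsc
from .transforms import TransformChain, compose_chain, warp_labels
from .weighting import case_weights

logger = logging.getLogger("atlaslink")

__all__ = [
    "LinkCase",
    "ExperimentConfig",
    "enumerate_direct",
    "enumerate_one_link",
    "count_chains",
    "sample_chains",
    "max_links",
    "run_experiment",
    "summarize",
    "rank_sum_test",
    "fit_link_trend",
]


@dataclass(frozen=True)
class LinkCase:
    """A registration route: fixed -> intermediates -> moving, all distinct."""

    fixed: int
    moving: int
    intermediates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "intermediates", tuple(self.intermediates))
        ids = (self.fixed, *self.intermediates, self.moving)
        if len(set(ids)) != len(ids):
            raise ValueError(f"case ids must be distinct, got {ids}")

    @property
    def n_links(self) -> int:
        return len(self.intermediates)

    @property
    def route(self) -> tuple[int, ...]:
        return (self.fixed, *self.intermediates, self.moving)


def enumerate_direct(n: int) -> list[LinkCase]:
    """All ordered (fixed, moving) pairs; n(n-1) direct registrations."""
    if n < 2:
        raise ValueError("need at least two atlases")
    return [
        LinkCase(i, j) for i in range(n) for j in range(n) if i != j
    ]


def enumerate_one_link(n: int) -> list[LinkCase]:
    """All (fixed, intermediate, moving) triples; n(n-1)(n-2) combinations."""
    if n < 3:
        raise ValueError("need at least three atlases for one-link chains")
    return [
        LinkCase(i, j, (k,))
        for i in range(n)
        for k in range(n)
        if k != i
        for j in range(n)
        if j not in (i, k)
    ]


def max_links(n: int) -> int:
    """Longest possible chain: all other atlases but the moving one serve as
    intermediates, i.e. n - 2 links (n - 1 composed transformations)."""
    if n < 2:
        raise ValueError("need at least two atlases")
    return n - 2


def count_chains(n: int, l: int) -> int:
    """Number of distinct chains with l intermediates among n atlases."""
    if l < 0 or l > max_links(n):
        raise ValueError(f"l must lie in [0, {max_links(n)}] for n = {n}")
    return n * (n - 1) * math.perm(n - 2, l)


def sample_chains(
    n: int, l: int, n_samples: int, seed: int
) -> list[LinkCase]:
    """Uniformly sample distinct chains with l intermediates, without
    replacement; returns all distinct chains when n_samples exhausts them.
    Deterministic per seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    total = count_chains(n, l)  # validates l
    rng = np.random.default_rng(seed)
    if n_samples >= total:
        cases = [
            LinkCase(i, j, mids)
            for i in range(n)
            for j in range(n)
            if j != i
            for mids in itertools.permutations(
                [a for a in range(n) if a not in (i, j)], l
            )
        ]
        return cases
    seen: set[tuple[int, ...]] = set()
    cases: list[LinkCase] = []
    while len(cases) < n_samples:
        route = tuple(int(v) for v in rng.permutation(n)[: l + 2])
        if route in seen:
            continue
        seen.add(route)
        cases.append(LinkCase(route[0], route[-1], route[1:-1]))
    return cases


# ---------------------------------------------------------------------------
# The experiment engine
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Controls the leave-one-out experiment.

    links: link counts l to evaluate (0 = direct).
    n_samples: chains sampled per l when full enumeration exceeds it; either
        one integer for all l or a mapping {l: n} (missing entries fall back
        to 100).
    include_fused: also score fused segmentations for every
        (fixed, intermediate) pair at one link, against fused direct results.
    k_over_s: weighting sharpness for fusion; 0 means equal weights, in which
        case per-atlas similarities are not needed.
    """

    links: tuple[int, ...] = (0, 1)
    n_samples: int | dict[int, int] = 100

    def samples_for(self, l: int) -> int:
        if isinstance(self.n_samples, dict):
            return int(self.n_samples.get(l, 100))
        return int(self.n_samples)
    seed: int = 0
    include_fused: bool = False
    k_over_s: float = 0.0
    structures: tuple[str, ...] | None = None
    # optional callable (fixed_id, moving_id, structure, warped_mask) -> SIM
    similarity_fn: object = None


def _chain_transforms(case: LinkCase, transform_provider) -> TransformChain:
    route = case.route
    transforms = []
    for a, b in zip(route[:-1], route[1:]):
        t = transform_provider(a, b)
        if t is None:
            raise KeyError(f"no transform available for pair ({a}, {b})")
        transforms.append(t)
    return TransformChain(transforms)


def run_experiment(atlases, transform_provider, config: ExperimentConfig) -> pd.DataFrame:
    """Score direct, linked and (optionally) fused label transfers.

    Parameters
    ----------
    atlases:
        Mapping id -> object with ``labels`` (LabelMap) and optionally
        ``image`` (ScalarImage); ids are 0..n-1.
    transform_provider:
        Callable ``(fixed_id, moving_id) -> Transform`` returning the
        registration that maps fixed-space points into the moving atlas.
    config:
        :class:`ExperimentConfig`.

    Returns a tidy DataFrame with one row per (case, structure) and columns
    fixed, moving, intermediates, n_links, structure, mode, dsc,
    dsc_direct, rel_change_pct.  ``mode`` is one of direct, linked,
    fused_direct, fused_linked; relative change is
    100 * (dsc - dsc_direct) / dsc_direct on matched cases.
    """
    ids = sorted(atlases)
    n = len(ids)
    rng = np.random.default_rng(config.seed)

    ref_masks = {
        i: dict(split_labels(atlases[i].labels)) for i in ids
    }
    structures = config.structures
    if structures is None:
        structures = tuple(sorted(ref_masks[ids[0]]))

    # cache of warped structure masks per (fixed, route)
    warped_cache: dict[tuple[int, tuple[int, ...]], dict] = {}

    def warped_masks(case: LinkCase) -> dict:
        key = (case.fixed, case.route)
        if key not in warped_cache:
            grid = atlases[case.fixed].labels.grid
            chain = _chain_transforms(case, transform_provider)
            composed = compose_chain(chain, grid)
            warped = warp_labels(atlases[case.moving].labels, composed, grid)
            warped_cache[key] = dict(split_labels(warped))
        return warped_cache[key]

    def score(case: LinkCase) -> dict[str, float]:
        masks = warped_masks(case)
        grid = atlases[case.fixed].labels.grid
        out = {}
        from .grid_io import BinaryMask

        empty = None
        for s in structures:
            ref = ref_masks[case.fixed][s]
            got = masks.get(s)
            if got is None:
                if empty is None:
                    empty = BinaryMask(grid, np.zeros(grid.shape, bool))
                got = empty
            out[s] = dsc(got, ref)
        return out

    rows: list[dict] = []
    direct_dsc: dict[tuple[int, int, str], float] = {}

    # direct scores are always needed as the matched baseline
    for case in enumerate_direct(n):
        for s, value in score(case).items():
            direct_dsc[(case.fixed, case.moving, s)] = value

    for l in sorted(set(config.links)):
        n_samples = config.samples_for(l)
        if l == 0:
            cases = enumerate_direct(n)
            if len(cases) > n_samples:
                pick = rng.choice(len(cases), size=n_samples, replace=False)
                cases = [cases[int(p)] for p in sorted(pick)]
        else:
            cases = sample_chains(n, l, n_samples, config.seed + l)
        for case in cases:
            scores = score(case)
            for s, value in scores.items():
                base = direct_dsc[(case.fixed, case.moving, s)]
                rel = 100.0 * (value - base) / base if base > 0 else np.nan
                rows.append(
                    dict(
                        fixed=case.fixed,
                        moving=case.moving,
                        intermediates="-".join(map(str, case.intermediates)),
                        n_links=l,
                        structure=s,
                        mode="direct" if l == 0 else "linked",
                        dsc=value,
                        dsc_direct=base,
                        rel_change_pct=0.0 if l == 0 else rel,
                    )
                )

    if config.include_fused:
        rows.extend(
            _fused_rows(
                ids, structures, ref_masks, warped_masks, config
            )
        )

    return pd.DataFrame(rows)


def _fused_rows(ids, structures, ref_masks, warped_masks, config):
    """Fused segmentations: direct fusion per fixed atlas, linked fusion per
    (fixed, intermediate) pair with the intermediate's labels transferred by
    its own direct registration."""
    rows = []
    fused_direct: dict[tuple[int, str], float] = {}

    def fuse_masks(fixed, contributions):
        # contributions: list of (atlas_id, mask); empty masks are dropped
        out = {}
        for s in structures:
            sdms, sims = [], []
            for j, masks in contributions:
                m = masks.get(s)
                if m is None or not m.inside.any():
                    logger.warning(
                        "atlas %s contributes no voxels for %s; dropped", j, s
                    )
                    continue
                sdms.append(signed_distance(m))
                sims.append(
                    config.similarity_fn(fixed, j, s, m)
                    if config.similarity_fn is not None
                    else 0.0
                )
            if not sdms:
                out[s] = 0.0
                continue
            weights = (
                case_weights(sims, config.k_over_s)
                if config.k_over_s > 0
                else np.ones(len(sdms))
            )
            fused = extract_segmentation(fuse(sdms, weights))
            out[s] = dsc(fused, ref_masks[fixed][s])
        return out

    n = len(ids)
    for i in ids:
        contributions = [
            (j, warped_masks(LinkCase(i, j))) for j in ids if j != i
        ]
        for s, value in fuse_masks(i, contributions).items():
            fused_direct[(i, s)] = value
            rows.append(
                dict(
                    fixed=i,
                    moving=-1,
                    intermediates="",
                    n_links=0,
                    structure=s,
                    mode="fused_direct",
                    dsc=value,
                    dsc_direct=value,
                    rel_change_pct=0.0,
                )
            )

    for i in ids:
        for k in ids:
            if k == i:
                continue
            contributions = [(k, warped_masks(LinkCase(i, k)))]
            contributions += [
                (j, warped_masks(LinkCase(i, j, (k,))))
                for j in ids
                if j not in (i, k)
            ]
            for s, value in fuse_masks(i, contributions).items():
                base = fused_direct[(i, s)]
                rel = 100.0 * (value - base) / base if base > 0 else np.nan
                rows.append(
                    dict(
                        fixed=i,
                        moving=-1,
                        intermediates=str(k),
                        n_links=1,
                        structure=s,
                        mode="fused_linked",
                        dsc=value,
                        dsc_direct=base,
                        rel_change_pct=rel,
                    )
                )
    return rows


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def summarize(values) -> tuple[float, float, float]:
    """Median with 25th and 75th percentiles (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    med, p25, p75 = np.percentile(values, [50.0, 25.0, 75.0])
    return float(med), float(p25), float(p75)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    )


def fit_link_trend(medians) -> tuple[float, float]:
    """Ordinary least-squares line through (l, median DSC) points.

    Returns (slope per link, intercept at l = 0); the intercept extrapolates
    the segmentation quality to zero registrations.
    """
    pts = np.asarray(medians, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (l, median) points")
    ls, meds = pts[:, 0], pts[:, 1]
    if np.unique(ls).size < 2:
        raise ValueError("need at least two distinct link counts")
    slope, intercept = np.polyfit(ls, meds, 1)
    return float(slope), float(intercept)
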