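"""3D box-counting fractal analysis of binary tissue masks.

For a binary mask and a box edge length ``eps`` (voxels), the volume is
tiled by an axis-aligned grid of eps-cubes anchored at index (0, 0, 0),
with partial boxes at the far edges included.  A box is *occupied* when it
contains at least one foreground voxel, and its *mass* is its foreground
voxel count.  Three indices summarise the scaling behaviour:

fractal dimension (FD)
    slope of the OLS fit of log N(eps) on log(1/eps) (natural logs),
    where N(eps) is the occupied-box count — the space-filling capacity
    of the pattern, between 0 (point) and 3 (solid).

lacunarity (Lambda)
    mean over scales of var[M(eps)] / mean[M(eps)]^2 over occupied boxes
    (population variance, fixed grid) — the gappiness/heterogeneity of
    the mass distribution; 0 for a mass-homogeneous tiling.

multifractal range (dFD)
    |slope_lower - slope_upper| of two OLS fits on the same log-log axes,
    over the lower and upper halves of the scale range (an odd scale
    count shares the middle point so both halves keep >= 2 points) —
    departure from a single power law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "BoxCountProfile",
    "FractalIndices",
    "default_box_sizes",
    "box_counts",
    "fractal_dimension",
    "lacunarity",
    "multifractal_range",
    "tissue_fractal_indices",
    "subject_fractal_features",
]


@dataclass
class BoxCountProfile:
    """Per-scale occupied-box statistics for one mask."""

    box_sizes: np.ndarray   # ascending eps, voxels
    counts: np.ndarray      # N(eps), occupied boxes
    mass_mean: np.ndarray   # mean foreground voxels per occupied box
    mass_var: np.ndarray    # population variance of occupied-box masses
    total_fg: int

    def __post_init__(self) -> None:
        self.box_sizes = np.asarray(self.box_sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        self.mass_mean = np.asarray(self.mass_mean, dtype=float)
        self.mass_var = np.asarray(self.mass_var, dtype=float)
        if not (np.diff(self.box_sizes) > 0).all():
            raise ValueError("box sizes must be strictly ascending")
        if self.total_fg > 0 and (self.counts <= 0).any():
            raise ValueError("occupied-box counts must be positive for a nonempty mask")

    @property
    def n_scales(self) -> int:
        return len(self.box_sizes)


@dataclass
class FractalIndices:
    fd: float
    lacunarity: float
    multifractal_range: float
    intercept: float
    r_squared: float
    n_scales: int


def default_box_sizes(mask_shape: Sequence[int]) -> np.ndarray:
    """Deterministic scale set: powers of 2 from 1 up to floor(min(shape)/4).

    At least four scales are required so that the two half-range slope fits
    each keep two points; smaller masks raise.
    """
    m = int(min(mask_shape))
    if m < 8:
        raise ValueError(f"mask too small for box counting: min dimension {m} < 8")
    limit = m // 4
    sizes = []
    e = 1
    while e <= limit:
        sizes.append(e)
        e *= 2
    if len(sizes) < 4:
        raise ValueError(
            f"mask of shape {tuple(mask_shape)} yields only {len(sizes)} box sizes "
            f"{sizes}; at least 4 scales are required"
        )
    return np.asarray(sizes, dtype=int)


def _box_masses(mask: np.ndarray, eps: int) -> np.ndarray:
    """Foreground mass of every grid box (occupied or not) at scale eps."""
    a, b, c = mask.shape
    pad = [(-n) % eps for n in (a, b, c)]
    if any(pad):
        mask = np.pad(mask, [(0, p) for p in pad])
    na, nb, nc = (s // eps for s in mask.shape)
    return (
        mask.reshape(na, eps, nb, eps, nc, eps)
        .sum(axis=(1, 3, 5), dtype=np.int64)
    )


def box_counts(mask: np.ndarray, box_sizes: Sequence[int]) -> BoxCountProfile:
    """Tile the mask at each scale and collect occupied-box statistics.

    Grid anchored at index (0,0,0), partial edge boxes included, single
    grid offset (no offset averaging).  Mean and population variance are
    taken over occupied boxes only, so N(eps) * mass_mean(eps) equals the
    total foreground count at every scale.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    mask = (mask > 0).astype(np.uint8)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty mask: fractal indices are undefined")
    sizes = np.asarray(sorted(int(e) for e in box_sizes), dtype=int)
    if (sizes < 1).any():
        raise ValueError("box sizes must be >= 1")
    counts, means, varis = [], [], []
    for eps in sizes:
        masses = _box_masses(mask, int(eps))
        occ = masses[masses > 0]
        counts.append(occ.size)
        means.append(float(occ.mean()))
        varis.append(float(occ.var()))  # population variance
    return BoxCountProfile(sizes, counts, means, varis, total)


def _ols_loglog(sizes: np.ndarray, counts: np.ndarray) -> Tuple[float, float, float]:
    """OLS of log N on log(1/eps); returns (slope, intercept, r_squared)."""
    x = -np.log(np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    ss_tot = ((y - ym) ** 2).sum()
    if ss_tot == 0.0:
        return slope, intercept, float("nan")
    ss_res = ((y - (intercept + slope * x)) ** 2).sum()
    return slope, intercept, 1.0 - ss_res / ss_tot


def fractal_dimension(profile: BoxCountProfile) -> Tuple[float, float, float]:
    """Fit FD as the log-log slope of the occupied-box counts.

    Degenerate profiles (all counts equal, e.g. a single voxel) return
    FD = 0 with r_squared flagged as NaN.
    """
    if profile.n_scales < 2:
        raise ValueError("fractal dimension needs at least 2 scales")
    return _ols_loglog(profile.box_sizes, profile.counts)


def lacunarity(profile: BoxCountProfile) -> float:
    """Scale-averaged var/mean^2 of occupied-box masses."""
    if profile.n_scales < 1:
        raise ValueError("lacunarity needs at least one scale")
    mu = profile.mass_mean
    if (mu <= 0).any():
        raise ValueError("lacunarity undefined: zero mean box mass")
    return float(np.mean(profile.mass_var / mu**2))


def multifractal_range(profile: BoxCountProfile) -> float:
    """|slope_lower - slope_upper| of half-range log-log fits."""
    k = profile.n_scales
    if k < 4:
        raise ValueError("multifractal range needs at least 4 scales")
    lo = math.ceil(k / 2)           # lower half: first ceil(k/2) scales
    hi = k // 2                     # upper half: last floor(k/2)+1 when k odd
    s_lo, _, _ = _ols_loglog(profile.box_sizes[:lo], profile.counts[:lo])
    s_hi, _, _ = _ols_loglog(profile.box_sizes[hi:], profile.counts[hi:])
    return abs(s_lo - s_hi)


def tissue_fractal_indices(mask: np.ndarray, box_sizes: Sequence[int] | None = None) -> FractalIndices:
    """FD, lacunarity and multifractal range for one tissue mask.

    Uses the default power-of-2 scale set unless an explicit list is given
    (self-similar fixtures such as a Menger sponge want powers of 3).
    """
    mask = np.asarray(mask)
    if box_sizes is None:
        if min(mask.shape) < 16:
            raise ValueError("mask min dimension must be >= 16 for automatic scales")
        box_sizes = default_box_sizes(mask.shape)
    profile = box_counts(mask, box_sizes)
    fd, intercept, r2 = fractal_dimension(profile)
    return FractalIndices(
        fd=fd,
        lacunarity=lacunarity(profile),
        multifractal_range=multifractal_range(profile),
        intercept=intercept,
        r_squared=r2,
        n_scales=profile.n_scales,
    )


def subject_fractal_features(left, right) -> Dict[str, Dict[str, float]]:
    """Per-tissue fractal indices averaged over the two legs.

    ``left``/``right`` are TissueMaskSet-like objects exposing ``tissues()``.
    Each index is the arithmetic mean of the per-leg values.  A tissue
    empty in either leg yields NaN indices for that tissue; the others are
    still produced.
    """
    out: Dict[str, Dict[str, float]] = {}
    for tissue, lmask in left.tissues().items():
        rmask = right.tissues()[tissue]
        if lmask.sum() == 0 or rmask.sum() == 0:
            out[tissue] = {k: float("nan") for k in ("fd", "lacunarity", "multifractal_range")}
            continue
        li = tissue_fractal_indices(lmask)
        ri = tissue_fractal_indices(rmask)
        out[tissue] = {
            "fd": (li.fd + ri.fd) / 2.0,
            "lacunarity": (li.lacunarity + ri.lacunarity) / 2.0,
            "multifractal_range": (li.multifractal_range + ri.multifractal_range) / 2.0,
        }
    return out
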