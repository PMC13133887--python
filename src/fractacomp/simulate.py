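"""Synthetic inputs: fractal phantoms, CT-like leg phantoms, cohort tables.

Everything here is generated, never measured; it exists so that the
analysis stages can be exercised against known ground truth.

* ``menger_sponge`` — deterministic self-similar fixture whose box-count
  dimension is exactly log 20 / log 3 at powers-of-3 scales.
* ``random_cantor_3d`` — stochastic fractal with expected dimension
  log(27 p) / log 3 (valid for p > 1/27), used for recovery statistics.
* ``leg_phantom`` — two cylindrical "legs" with a subcutaneous-fat
  annulus, a muscle core and fat marbling inside the core, plus the
  ground-truth tissue masks and anatomical compartments.  Marbling is
  produced by thresholding Gaussian-smoothed white noise, so the
  infiltration fraction and its spatial clustering scale are
  independently tunable.
* ``synth_cohort`` — subject tables with group-level (per-centre) feature
  distributions and an outcome drawn from a known logistic model.

All generators are bit-reproducible for a fixed seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocessing import CTVolume, TissueMaskSet

__all__ = [
    "PhantomSpec",
    "LegPhantom",
    "CohortGenSpec",
    "menger_sponge",
    "random_cantor_3d",
    "leg_phantom",
    "synth_cohort",
    "DEFAULT_COHORT_SPEC",
]


def menger_sponge(level: int) -> np.ndarray:
    """Menger sponge of edge 3^level; voxel count is exactly 20^level."""
    if not 1 <= level <= 5:
        raise ValueError("level must be in 1..5")
    i, j, k = np.indices((3, 3, 3))
    # a subcube is removed when it is central on >= 2 axes
    pattern = (((i == 1).astype(int) + (j == 1) + (k == 1)) < 2).astype(np.uint8)
    mask = np.ones((1, 1, 1), dtype=np.uint8)
    for _ in range(level):
        mask = np.kron(mask, pattern)
    return mask


def random_cantor_3d(p: float, levels: int, seed: int) -> np.ndarray:
    """Random Cantor dust: subdivide into 27 subcubes, keep each w.p. p.

    Retention is independent per subcube per level; the expected box-count
    dimension is log(27 p) / log 3, meaningful for p > 1/27.
    """
    if not (1 / 27 < p <= 1):
        raise ValueError("retention probability must satisfy 1/27 < p <= 1")
    rng = np.random.default_rng(seed)
    mask = np.ones((1, 1, 1), dtype=np.uint8)
    for _ in range(levels):
        mask = np.kron(mask, np.ones((3, 3, 3), dtype=np.uint8))
        keep = rng.random(mask.shape) < p
        mask &= keep
    return mask


# ---------------------------------------------------------------------------
# Leg phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and infiltration parameters for the two-leg CT phantom.

    Lengths are voxels on an isotropic grid of ``spacing_mm``.  The muscle
    core has radius ``core_radius``; the SAT annulus adds ``sat_thickness``.
    ``imat_fraction`` is the target fraction of core voxels converted to
    marbled fat; ``clustering_scale`` is the sigma (voxels) of the
    smoothing applied to the marbling noise field — larger values give
    coarser, blob-like infiltration.  The resolved-marbling regime is
    clustering_scale >= 2 voxels; below that the thresholded field
    degenerates toward voxel speckle whose box-count scaling is dominated
    by discretization rather than by the requested cluster geometry.  ``noise_sd`` is the HU noise on each
    tissue; 0 gives exact tissue HU values.
    """

    core_radius: float = 14.0
    sat_thickness: float = 6.0
    length: int = 48
    gap: int = 8
    margin: int = 4
    spacing_mm: float = 1.0
    imat_fraction: float = 0.20
    clustering_scale: float = 2.0
    noise_sd: float = 10.0
    muscle_hu: float = 50.0
    fat_hu: float = -100.0
    air_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius <= 0 or self.sat_thickness < 0 or self.length < 1:
            raise ValueError("geometrically impossible phantom spec")
        if not 0 <= self.imat_fraction < 1:
            raise ValueError("imat_fraction must be in [0, 1)")
        if self.clustering_scale < 0 or self.noise_sd < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class LegPhantom:
    """A generated phantom: CT volume, truth masks, anatomical compartments."""

    volume: CTVolume
    masks: TissueMaskSet           # ground truth on the full grid
    muscle_compartment: np.ndarray  # core = SM + IMAT
    subcut_compartment: np.ndarray  # annulus = SAT
    spec: PhantomSpec


def leg_phantom(spec: PhantomSpec = PhantomSpec()) -> LegPhantom:
    """Two cylinders on one grid with SAT ring, muscle core, IMAT marbling.

    Axis 0 is the left-right axis (the two cylinders are side by side);
    the cylinder axis runs along array axis 2.
    """
    r_out = spec.core_radius + spec.sat_thickness
    d_out = int(np.ceil(2 * r_out))
    nx = 2 * d_out + spec.gap + 2 * spec.margin
    ny = d_out + 2 * spec.margin
    nz = spec.length
    rng = np.random.default_rng(spec.seed)

    cy = ny / 2.0 - 0.5
    centers_x = (
        spec.margin + r_out - 0.5,
        spec.margin + d_out + spec.gap + r_out - 0.5,
    )
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    core2d = np.zeros((nx, ny), dtype=bool)
    ring2d = np.zeros((nx, ny), dtype=bool)
    for cx in centers_x:
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        core2d |= r2 <= spec.core_radius**2
        ring2d |= (r2 <= r_out**2) & (r2 > spec.core_radius**2)

    core = np.repeat(core2d[:, :, None], nz, axis=2)
    ring = np.repeat(ring2d[:, :, None], nz, axis=2)

    # marbling: per-leg quantile threshold of a smoothed noise field
    imat = np.zeros_like(core)
    if spec.imat_fraction > 0:
        field3d = rng.standard_normal((nx, ny, nz))
        if spec.clustering_scale > 0:
            field3d = ndimage.gaussian_filter(field3d, spec.clustering_scale, mode="wrap")
        for cx in centers_x:
            leg_core = core & (np.abs(x - cx) <= r_out)[:, :, None]
            vals = field3d[leg_core]
            cut = np.quantile(vals, 1.0 - spec.imat_fraction)
            imat |= leg_core & (field3d > cut)
    sm = core & ~imat

    hu = np.full((nx, ny, nz), spec.air_hu, dtype=float)
    hu[sm] = spec.muscle_hu
    hu[ring | imat] = spec.fat_hu
    if spec.noise_sd > 0:
        tissue = core | ring
        hu[tissue] += spec.noise_sd * rng.standard_normal(int(tissue.sum()))

    spacing = (spec.spacing_mm,) * 3
    return LegPhantom(
        volume=CTVolume(hu, spacing),
        masks=TissueMaskSet(sm=sm, sat=ring, imat=imat, spacing=spacing,
                            provenance={"generator": "leg_phantom", "seed": spec.seed}),
        muscle_compartment=core.astype(np.uint8),
        subcut_compartment=ring.astype(np.uint8),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGenSpec:
    """Generative spec for a synthetic subject table.

    ``groups`` maps a group name (study centre) to its size and to
    per-variable normal (mean, sd) parameters for continuous features and
    prevalences for binary flags.  The outcome is drawn from
    Bernoulli(logistic(intercept + sum beta_j z_j)) where z_j are the
    features standardized by their pooled generative mean/SD — never from
    the group structure directly.
    """

    groups: Tuple[Tuple[str, int], ...] = (("center1", 184), ("center2", 74))
    continuous: Tuple[Tuple[str, Tuple[Tuple[str, float, float], ...]], ...] = ()
    binary: Tuple[Tuple[str, Tuple[Tuple[str, float], ...]], ...] = ()
    coefficients: Tuple[Tuple[str, float], ...] = ()
    intercept: float = 0.0

    def coef_dict(self) -> Dict[str, float]:
        return dict(self.coefficients)


def _scenario_spec() -> CohortGenSpec:
    """Default scenario: two centres with group-level structure.

    Means/SDs are scenario parameters chosen for documentation realism
    (magnitudes typical of an elderly lower-extremity CT cohort); they
    parameterise a simulation, they are not data.  The outcome model puts
    signal on triglyceride, diabetes history and the IMAT features, with
    an intercept giving roughly balanced classes.
    """
    continuous = (
        ("age", (("center1", 62.0, 11.5), ("center2", 65.0, 11.0))),
        ("height_m", (("center1", 1.64, 0.08), ("center2", 1.68, 0.07))),
        ("weight_kg", (("center1", 63.5, 11.0), ("center2", 66.0, 13.0))),
        ("waist_cm", (("center1", 84.5, 10.5), ("center2", 86.5, 9.0))),
        ("hdl_c", (("center1", 0.99, 0.30), ("center2", 1.03, 0.31))),
        ("triglyceride", (("center1", 1.74, 1.05), ("center2", 1.47, 0.72))),
        ("total_cholesterol", (("center1", 4.03, 1.08), ("center2", 3.90, 1.05))),
        ("smi", (("center1", 2635.0, 650.0), ("center2", 3770.0, 1180.0))),
        ("sati", (("center1", 2170.0, 945.0), ("center2", 2930.0, 1600.0))),
        ("imati", (("center1", 421.0, 176.0), ("center2", 710.0, 345.0))),
        ("imr", (("center1", 0.19, 0.075), ("center2", 0.195, 0.081))),
        ("imat_fd", (("center1", 1.145, 0.058), ("center2", 1.150, 0.059))),
        ("imat_multifractal_range", (("center1", 0.20, 0.042), ("center2", 0.20, 0.055))),
        ("imat_lacunarity", (("center1", 39.5, 5.8), ("center2", 50.8, 10.2))),
    )
    binary = (
        ("diabetes", (("center1", 0.57, ), ("center2", 0.68))),
        ("hypertension", (("center1", 0.52,), ("center2", 0.53))),
        ("smoking", (("center1", 0.32,), ("center2", 0.49))),
        ("alcohol", (("center1", 0.21,), ("center2", 0.24))),
    )
    coefficients = (
        ("triglyceride", 0.75),
        ("diabetes", 1.1),
        ("imr", 0.65),
        ("imat_fd", 0.8),
        ("imat_multifractal_range", 0.9),
    )
    return CohortGenSpec(continuous=continuous, binary=binary,
                         coefficients=coefficients, intercept=-0.55)


DEFAULT_COHORT_SPEC = _scenario_spec()


def synth_cohort(spec: CohortGenSpec = DEFAULT_COHORT_SPEC, seed: int = 0) -> pd.DataFrame:
    """Draw a subject table from the generative spec.

    Continuous features are normal per group; binary flags Bernoulli per
    group; the outcome column ``mets_label`` is Bernoulli(logistic(eta))
    with eta = intercept + sum beta_j z_j, z standardized by the pooled
    generative moments.  Generator metadata (coefficients, intercept,
    seed) is stored in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for gi, (gname, n) in enumerate(spec.groups):
        cols: Dict[str, np.ndarray] = {
            "subject_id": np.array([f"{gname}_{i:04d}" for i in range(n)]),
            "center": np.full(n, gi + 1, dtype=int),
        }
        for var, params in spec.continuous:
            mean, sd = dict((g, (m, s)) for g, m, s in params)[gname]
            cols[var] = rng.normal(mean, sd, n)
        for var, params in spec.binary:
            prev = dict((p[0], p[1]) for p in params)[gname]
            cols[var] = (rng.random(n) < prev).astype(int)
        cols["sex"] = np.where(rng.random(n) < 0.55, "male", "female")
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)

    beta = spec.coef_dict()
    eta = np.full(len(df), spec.intercept, dtype=float)
    pooled: Dict[str, Tuple[float, float]] = {}
    sizes = dict(spec.groups)
    total = sum(sizes.values())
    for var, params in spec.continuous:
        pm = dict((g, (m, s)) for g, m, s in params)
        mean = sum(sizes[g] * pm[g][0] for g in sizes) / total
        var_within = sum(sizes[g] * pm[g][1] ** 2 for g in sizes) / total
        var_between = sum(sizes[g] * (pm[g][0] - mean) ** 2 for g in sizes) / total
        pooled[var] = (mean, float(np.sqrt(var_within + var_between)))
    for var, b in beta.items():
        if var in pooled:
            m, s = pooled[var]
            eta += b * (df[var].to_numpy() - m) / s
        else:
            eta += b * df[var].to_numpy().astype(float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    df["mets_label"] = (rng.random(len(df)) < prob).astype(int)
    df.attrs["generator"] = {
        "coefficients": beta,
        "intercept": spec.intercept,
        "standardization": pooled,
        "seed": seed,
    }
    return df
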