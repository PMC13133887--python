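"""Tissue volumes, height-normalised composition indices and ratios.

Volumes are voxel counts scaled by the physical voxel volume, reported in
cm^3.  Indices divide each tissue volume by height cubed (cm^3/m^3):
SMI (skeletal muscle), SATI (subcutaneous adipose), IMATI (intra/
inter-muscular adipose).  Inter-tissue ratios are IMR = IMATI/SMI,
MSR = SMI/SATI, ISR = IMATI/SATI; a ratio with a zero denominator is
reported as NaN (missing) rather than zero, so downstream screening is
not biased.  Per-subject volumes are totals over both legs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

__all__ = ["BodyCompositionIndices", "mask_volume", "body_indices"]


@dataclass
class BodyCompositionIndices:
    smi: float
    sati: float
    imati: float
    imr: float
    msr: float
    isr: float
    height_m: float
    raw_volumes: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {
            "smi": self.smi, "sati": self.sati, "imati": self.imati,
            "imr": self.imr, "msr": self.msr, "isr": self.isr,
        }


def mask_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Physical volume of a binary mask in cm^3 (count x voxel mm^3 / 1000)."""
    spacing = np.asarray(spacing, dtype=float)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def body_indices(volumes: Dict[str, float], height_m: float) -> BodyCompositionIndices:
    """Height-cubed-normalised indices and inter-tissue ratios.

    ``volumes`` maps tissue name ('sm', 'sat', 'imat') to cm^3.
    """
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    h3 = height_m**3
    smi = volumes["sm"] / h3
    sati = volumes["sat"] / h3
    imati = volumes["imat"] / h3
    if min(smi, sati, imati) < 0:
        raise ValueError("tissue volumes must be non-negative")
    out = BodyCompositionIndices(
        smi=smi, sati=sati, imati=imati,
        imr=_safe_ratio(imati, smi),
        msr=_safe_ratio(smi, sati),
        isr=_safe_ratio(imati, sati),
        height_m=height_m,
        raw_volumes=dict(volumes),
    )
    # ratio-consistency invariant of the container
    for got, num, den in ((out.imr, imati, smi), (out.msr, smi, sati), (out.isr, imati, sati)):
        if den > 0:
            assert math.isclose(got, num / den, rel_tol=1e-12)
    return out
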