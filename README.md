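# fractacomp

3D box-counting fractal analysis and volumetric body-composition modelling of
segmented CT tissue masks.

Metabolic syndrome (MetS) reshapes not just the *amount* of muscle and fat in
the lower extremities but their *spatial organization*: adipose tissue
threads through the muscle compartment as marbled intramuscular/intermuscular
fat (IMAT). Plain volumetric indices miss this patterning. `fractacomp`
quantifies it with three box-counting indices computed on binary tissue
masks (skeletal muscle SM, subcutaneous fat SAT, IMAT), combines them with
height-normalized volumetrics, and builds and evaluates logistic diagnostic
models for MetS. It is aimed at imaging researchers who already have CT
volumes plus anatomical compartment segmentations and want reproducible,
tested feature extraction and model building.

## The indices

For a binary mask tiled by axis-aligned boxes of edge ε (voxels), with N(ε)
occupied boxes and M(ε) the foreground mass of an occupied box:

* **Fractal dimension** — the OLS slope of `log N(ε) = FD · log(1/ε) + c`,
  the space-filling capacity of the pattern (0 for a point, 3 for a solid).
* **Lacunarity** — `Λ = mean_ε [ σ²(M(ε)) / μ(M(ε))² ]` over occupied boxes,
  the gappiness of the mass distribution (0 for a homogeneous tiling).
* **Multifractal range** — `ΔFD = |slope_lower − slope_upper|`, the absolute
  difference of the log–log slopes fitted to the lower and upper halves of
  the scale range; 0 for a perfect monofractal.

Volumetric indices divide tissue volume (cm³) by height cubed (m³): SMI,
SATI, IMATI, with the ratios IMR = IMATI/SMI, MSR = SMI/SATI, ISR =
IMATI/SATI. Model building follows univariate logistic screening
(p < 0.1), VIF (> 10) / Spearman |r| (> 0.8) collinearity pruning, and
multivariable logistic regression; evaluation covers ROC (AUC and a frozen
Youden operating point), calibration curves, decision-curve net benefit,
and ICC(2,1) segmentation reproducibility.

## Worked example

```python
import numpy as np
from fractacomp.fractal import box_counts, fractal_dimension, lacunarity, \
    multifractal_range, subject_fractal_features
from fractacomp.simulate import menger_sponge, PhantomSpec, leg_phantom
from fractacomp.preprocessing import gaussian_smooth, normalize_hu, \
    threshold_tissues, split_legs
from fractacomp.volumetrics import mask_volume, body_indices

# 1. analytic sanity check: a level-3 Menger sponge
prof = box_counts(menger_sponge(3), [1, 3, 9, 27])
fd, c, r2 = fractal_dimension(prof)
print(prof.counts.tolist())        # [8000, 400, 20, 1]
print(round(fd, 4))                # 2.7268  (= log 20 / log 3)
print(lacunarity(prof))            # 0.0     (self-similar: equal box masses)
print(round(multifractal_range(prof), 12))  # 0.0  (single power law)

# 2. a CT-like two-leg phantom through the full chain
ph = leg_phantom(PhantomSpec(imat_fraction=0.20, clustering_scale=3.0,
                             noise_sd=5.0, seed=42))
vol = gaussian_smooth(ph.volume, 1.0)                      # sigma in mm
vol = normalize_hu(vol, ph.muscle_compartment, 50.0)       # muscle median -> 50 HU
masks = threshold_tissues(vol, ph.muscle_compartment, ph.subcut_compartment)
vols = {t: mask_volume(m, masks.spacing) for t, m in masks.tissues().items()}
print({k: round(v, 1) for k, v in vols.items()})
# {'sm': 49.2, 'sat': 46.4, 'imat': 9.8}                   cm^3
print(round(body_indices(vols, 1.68).as_dict()["imr"], 3)) # 0.198

left, right = split_legs(masks)
feats = subject_fractal_features(left, right)              # mean of both legs
print({k: round(v, 3) for k, v in feats["imat"].items()})
# {'fd': 1.984, 'lacunarity': 0.72, 'multifractal_range': 0.541}
```

The phantom was built with a 20% infiltration fraction, and the recovered
IMAT volume is 9.8 of 59.0 cm³ of compartment — the chain reproduces the
requested marbling. The IMAT FD near 2 and the large ΔFD relative to SM/SAT
reflect the sparse, clustered geometry of marbled fat versus compact tissue.

An end-to-end simulated cohort (phantom images → features → three logistic
models → metrics) runs from the shell:

```sh
fractacomp run --seed 3 --n-subjects 40 --out-dir run_output
```

which prints per-model train/test AUCs and writes `subject_features.csv`,
`models.json` and `metrics.json` stamped with the config hash and seed.
Other subcommands (`preprocess`, `volumetrics`, `fractal`, `model`,
`evaluate`, `simulate`) expose the individual stages; `--config cfg.yaml`
accepts any `RunConfig` field (`hu_ranges`, `sigma_mm`, `reference_hu`,
`target_spacing_mm`, `screening_alpha`, `vif_max`, `r_max`,
`train_fraction`, ...).

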