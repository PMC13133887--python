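"""End-to-end orchestration: phantoms -> masks -> features -> models -> metrics.

``run_pipeline`` simulates a cohort of two-leg CT phantoms whose fat
infiltration depends on a latent metabolic status, pushes every subject
through the full imaging chain (smoothing, HU normalization, HU
thresholding, leg splitting, volumetrics, bilateral fractal features),
joins simulated clinical covariates, builds the clinical / radiological /
combined logistic models on a stratified training split, and writes
feature tables and per-set evaluation metrics.  Every output carries the
producing config hash and seed, and the whole run is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import logging
import os
import time
from typing import Dict

import numpy as np
import pandas as pd

from . import cohort as ch
from . import evaluation as ev
from .config import RunConfig
from .fractal import subject_fractal_features
from .preprocessing import gaussian_smooth, normalize_hu, split_legs, threshold_tissues
from .simulate import PhantomSpec, leg_phantom
from .volumetrics import body_indices, mask_volume

log = logging.getLogger("fractacomp")

__all__ = ["run_pipeline", "subject_features_from_phantom"]


def subject_features_from_phantom(phantom, config: RunConfig, height_m: float) -> Dict[str, float]:
    """Imaging features for one subject: preprocess, segment, measure.

    Smoothing and muscle-referenced HU normalization run before HU
    thresholding; tissue volumes are bilateral totals; fractal indices are
    averaged over the two legs.
    """
    vol = gaussian_smooth(phantom.volume, config.sigma_mm)
    vol = normalize_hu(vol, phantom.muscle_compartment, config.reference_hu)
    masks = threshold_tissues(vol, phantom.muscle_compartment,
                              phantom.subcut_compartment, config.hu_ranges)
    left, right = split_legs(masks)
    vols = {t: mask_volume(m, masks.spacing) for t, m in masks.tissues().items()}
    idx = body_indices(vols, height_m)
    feats: Dict[str, float] = {
        "sm_cm3": vols["sm"], "sat_cm3": vols["sat"], "imat_cm3": vols["imat"],
        **idx.as_dict(),
    }
    for tissue, vals in subject_fractal_features(left, right).items():
        for name, v in vals.items():
            feats[f"{tissue}_{name}"] = v
    return feats


def _simulate_subject_row(rng: np.random.Generator, config: RunConfig, sid: int) -> Dict[str, float]:
    """One subject: latent status drives infiltration and clinical draws."""
    status = int(rng.random() < 0.5)
    imat_fraction = float(np.clip(rng.normal(0.20 if status else 0.16, 0.045), 0.05, 0.4))
    clustering = float(np.clip(rng.normal(2.9 if status else 2.5, 0.5), 2.0, 4.5))
    spec = PhantomSpec(imat_fraction=imat_fraction, clustering_scale=clustering,
                       noise_sd=5.0, seed=int(rng.integers(2**31)))
    height_m = float(np.clip(rng.normal(1.64, 0.08), 1.4, 2.0))
    phantom = leg_phantom(spec)
    row = {"subject_id": f"subj_{sid:04d}", "mets_label": status, "height_m": height_m}
    row.update(subject_features_from_phantom(phantom, config, height_m))
    # clinical covariates with modest status-dependent shifts
    row["age"] = float(rng.normal(63, 11))
    row["weight_kg"] = float(rng.normal(66 if status else 61, 10))
    row["triglyceride"] = float(max(rng.normal(2.1 if status else 1.3, 0.9), 0.2))
    row["diabetes"] = int(rng.random() < (0.65 if status else 0.40))
    row["hypertension"] = int(rng.random() < (0.58 if status else 0.44))
    return row


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage in order and write artifacts to ``config.out_dir``.

    Stages: simulate -> preprocess/masks -> volumetrics -> fractal ->
    model -> evaluate.  A failure in any stage propagates with the stage
    name attached.  Returns a summary dict (also written as JSON).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    rng = np.random.default_rng(config.seed)
    stage = "simulate+features"
    t0 = time.time()
    try:
        rows = [_simulate_subject_row(rng, config, i) for i in range(config.n_subjects)]
        df = pd.DataFrame(rows)
        log.info("stage=%s n=%d elapsed=%.1fs", stage, len(df), time.time() - t0)

        stage = "model"
        train, test = ch.split_cohort(df, config.train_fraction, seed=config.seed)
        models = ch.build_three_models(
            train,
            clinical_candidates=["age", "weight_kg", "triglyceride", "diabetes", "hypertension"],
            alpha=config.screening_alpha, vif_max=config.vif_max, r_max=config.r_max,
        )

        stage = "evaluate"
        metrics: Dict[str, Dict] = {}
        for name, fit in models.items():
            p_train = ch.predict_prob(fit, train)
            thr = ev.youden_threshold(p_train, train["mets_label"])
            metrics[name] = {}
            for setname, part in (("train", train), ("test", test)):
                p = ch.predict_prob(fit, part)
                m = ev.operating_metrics(p, part["mets_label"], thr)
                m["auc"] = ev.auc(p, part["mets_label"])
                metrics[name][setname] = m
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    meta = {"config_hash": chash, "seed": config.seed, "config": config.to_dict()}
    feat_path = os.path.join(config.out_dir, "subject_features.csv")
    df.to_csv(feat_path, index=False)
    model_dump = {
        name: {
            "intercept": fit.intercept,
            "coefficients": fit.coefficients,
            "odds_ratios": fit.odds_ratios,
            "ci": {k: list(v) for k, v in fit.ci.items()},
            "p_values": fit.p_values,
            **meta,
        }
        for name, fit in models.items()
    }
    with open(os.path.join(config.out_dir, "models.json"), "w") as fh:
        json.dump(model_dump, fh, indent=2)
    with open(os.path.join(config.out_dir, "metrics.json"), "w") as fh:
        json.dump({**meta, "metrics": metrics}, fh, indent=2)
    return {"features": feat_path, "models": model_dump, "metrics": metrics, **meta}
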