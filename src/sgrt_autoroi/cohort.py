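"""Synthetic patient cohorts for tuning and evaluating the ROI algorithms.

Each synthetic patient bundles a randomized body, its coronal silhouette,
ground-truth joints, an ipsilateral breast contour, and a pseudo-clinical
ROI.  The breast contour is placed at joint-derived anatomical offsets
chosen so the cohort is self-consistent: the pseudo-clinical ROI built from
the true S-I shifts coincides (at zero noise) with both the body-based and
the breast-based ROI at the true per-category extensions, exactly as a
protocol-compliant planner would draw it.  Gaussian jitter on the four ROI
boundary positions emulates inter-planner variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .body import BodyModel, ShapeParams, sample_body, scale_to_height
from .errors import InvalidParameterError
from .imaging import sample_seed
from .roi import (BodySilhouette, BreastContour, ROIRegion, ShiftConfig,
                  build_roi, chest_width, si_bounds_from_joints)


@dataclass
class SyntheticPatient:
    body: BodyModel
    silhouette: BodySilhouette
    joints: Dict[str, np.ndarray]          # ground-truth 3D joints, mm
    breast_contour: BreastContour
    clinical_roi: ROIRegion                # pseudo-clinical reference ROI
    laterality: str
    category: str
    noise_sd_mm: float
    seed: int


def _normalize_mix(n: int, category_mix) -> Tuple[int, int]:
    """Resolve a category mix into (n_breast_eval, n_ptv) counts."""
    if category_mix is None:
        n_be = int(round(n * 30 / 39))     # cohort proportions: 30 breast-only : 9 PTV
        return n_be, n - n_be
    if isinstance(category_mix, str):
        parts = category_mix.split(":")
        if len(parts) != 2:
            raise InvalidParameterError(f"cannot parse category mix {category_mix!r}")
        category_mix = (int(parts[0]), int(parts[1]))
    n_be, n_ptv = int(category_mix[0]), int(category_mix[1])
    if n_be < 0 or n_ptv < 0 or n_be + n_ptv != n:
        raise InvalidParameterError(
            f"category mix {category_mix} does not partition n={n}")
    return n_be, n_ptv


def make_cohort(n: int, noise_sd_mm: float = 0.0, seed: int = 0,
                category_mix=None, p_left: float = 0.8,
                cfg: ShiftConfig | None = None,
                target_height_mm: float = 1617.0,
                silhouette_spacing_mm: float = 2.0,
                scale_bounds: Tuple[float, float] = (0.8, 1.2)
                ) -> List[SyntheticPatient]:
    """Generate a reproducible cohort of synthetic patients.

    ``category_mix`` is (n_breast_eval, n_ptv) (or "30:9"); default keeps the
    30:9 breast-only-to-PTV proportion.  ``noise_sd_mm`` is the standard
    deviation of independent Gaussian jitter applied to each of the four
    pseudo-clinical ROI boundary positions.
    """
    if n < 1:
        raise InvalidParameterError("cohort size must be >= 1")
    if noise_sd_mm < 0:
        raise InvalidParameterError("noise sd must be >= 0")
    cfg = cfg or ShiftConfig()
    n_be, n_ptv = _normalize_mix(n, category_mix)
    master = np.random.default_rng(seed)
    categories = np.array(["breast_eval"] * n_be + ["PTV"] * n_ptv)
    master.shuffle(categories)

    patients: List[SyntheticPatient] = []
    for i in range(n):
        s = sample_seed(seed + 104729, i)
        rng = np.random.default_rng(s)
        laterality = "left" if rng.random() < p_left else "right"
        category = str(categories[i])

        body = sample_body(ShapeParams.random(s, scale_bounds), scale_bounds)
        body = scale_to_height(body, target_height_mm)
        silhouette = BodySilhouette.from_body(body, spacing_mm=silhouette_spacing_mm)

        upper, lower = si_bounds_from_joints(body.joints, cfg)
        # breast contour placed so that the per-category extensions reproduce
        # the same protocol ROI borders the joints do
        if category == "breast_eval":
            contour = BreastContour(superior_z_mm=upper - cfg.breast_eval_sup_mm,
                                    inferior_z_mm=lower + cfg.breast_eval_inf_mm,
                                    laterality=laterality, category=category)
        else:
            contour = BreastContour(superior_z_mm=upper - cfg.ptv_sup_mm,
                                    inferior_z_mm=lower + cfg.ptv_inf_mm,
                                    laterality=laterality, category=category)

        chest = chest_width(silhouette, upper, lower)
        ideal = build_roi(upper, lower, chest, laterality, cfg)
        if noise_sd_mm > 0:
            jit = rng.normal(0.0, noise_sd_mm, size=4)
            croi = ROIRegion.from_landmarks(
                upper_z=ideal.landmarks["upper_z"] + jit[0],
                lower_z=ideal.landmarks["lower_z"] + jit[1],
                x_ipsi=ideal.landmarks["x_ipsi"] + jit[2],
                x_contra=ideal.landmarks["x_contra"] + jit[3],
                laterality=laterality, retraction_mm=cfg.retraction_mm)
        else:
            croi = ideal
        patients.append(SyntheticPatient(
            body=body, silhouette=silhouette, joints=body.joints,
            breast_contour=contour, clinical_roi=croi, laterality=laterality,
            category=category, noise_sd_mm=float(noise_sd_mm), seed=s))
    return patients
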