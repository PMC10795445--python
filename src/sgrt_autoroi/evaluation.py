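"""ROI comparison and tuning: Dice overlap, shift grid search, boundary distances.

The Dice similarity coefficient (DSC) between two regions A and B is
``2 |A ∩ B| / (|A| + |B|)`` computed on a common raster grid (default
1 mm/pixel) covering both regions.  The S-I shift tuning mirrors the way the
construction constants are calibrated against reference (clinical) ROIs: for
every candidate (upper, lower) shift pair the body-based ROI is rebuilt for
each reference case and the pair maximizing the mean DSC wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError
from .roi import (BreastContour, GridSpec, ROIRegion, ShiftConfig, build_roi,
                  chest_width, rasterize, si_bounds_from_joints)

#: Candidate shift values used for the default grid search (mm).
DEFAULT_SHIFT_CANDIDATES: Tuple[float, ...] = tuple(float(v) for v in range(0, 46, 5))


@dataclass
class DSCResult:
    dsc: float
    intersection: int
    area_a: int
    area_b: int
    grid: GridSpec | None = None


@dataclass
class TuningResult:
    """Mean-DSC surface over candidate (upper, lower) shift pairs."""

    upper_candidates: Tuple[float, ...]
    lower_candidates: Tuple[float, ...]
    mean_dsc: np.ndarray                  # (n_upper, n_lower)
    best_upper_mm: float
    best_lower_mm: float
    n_cases: int

    @property
    def best_dsc(self) -> float:
        i = self.upper_candidates.index(self.best_upper_mm)
        j = self.lower_candidates.index(self.best_lower_mm)
        return float(self.mean_dsc[i, j])


def dsc(mask_a: np.ndarray, mask_b: np.ndarray,
        grid: GridSpec | None = None, grid_b: GridSpec | None = None) -> DSCResult:
    """Dice similarity coefficient of two binary masks on the same grid.

    Two empty masks are defined as perfectly similar (DSC 1) with a warning.
    """
    if grid is not None and grid_b is not None and grid != grid_b:
        raise InvalidInputError("masks live on different raster grids")
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    area_a = int(a.sum())
    area_b = int(b.sum())
    inter = int(np.logical_and(a, b).sum())
    if area_a + area_b == 0:
        warnings.warn("DSC of two empty masks defined as 1")
        value = 1.0
    else:
        value = 2.0 * inter / (area_a + area_b)
    return DSCResult(dsc=float(value), intersection=inter,
                     area_a=area_a, area_b=area_b, grid=grid)


def dsc_regions(roi_a: ROIRegion, roi_b: ROIRegion,
                spacing_mm: float = 1.0) -> DSCResult:
    """DSC of two ROI polygons rasterized on a shared 1 mm (default) grid."""
    grid = GridSpec.around([roi_a.bounds(), roi_b.bounds()], spacing_mm=spacing_mm)
    return dsc(rasterize(roi_a, grid), rasterize(roi_b, grid), grid=grid)


def tune_shifts(cases: Sequence, upper_candidates: Iterable[float] = DEFAULT_SHIFT_CANDIDATES,
                lower_candidates: Iterable[float] = DEFAULT_SHIFT_CANDIDATES,
                cfg: ShiftConfig | None = None,
                grid_spacing_mm: float = 1.0) -> TuningResult:
    """Grid-search the S-I shifts maximizing mean DSC against reference ROIs.

    Each case must expose ``silhouette``, ``joints`` (mapping with LeftCollar,
    RightCollar, Spine2), ``clinical_roi`` (the reference ROIRegion) and
    ``laterality``.  Ties break toward the smallest (upper, lower) pair in
    lexicographic order.  Cases whose construction fails for some candidate
    are skipped with a warning.
    """
    cfg = cfg or ShiftConfig()
    uppers = tuple(float(u) for u in upper_candidates)
    lowers = tuple(float(v) for v in lower_candidates)
    if not uppers or not lowers:
        raise InvalidInputError("empty candidate set")
    if len(cases) == 0:
        raise InvalidInputError("need at least one reference case")

    sums = np.zeros((len(uppers), len(lowers)))
    used = 0
    for case in cases:
        ref = case.clinical_roi
        sil = case.silhouette
        # one grid per case, wide enough for every candidate ROI
        collar_z = 0.5 * (case.joints["LeftCollar"][-1] + case.joints["RightCollar"][-1])
        spine2_z = case.joints["Spine2"][-1]
        sil_x_max = sil.x0_mm + sil.mask.shape[1] * sil.spacing_mm
        x_min, z_min, x_max, z_max = ref.bounds()
        grid = GridSpec.around(
            [(x_min, z_min, x_max, z_max),
             (sil.x0_mm, spine2_z - max(lowers), sil_x_max, collar_z + max(uppers))],
            spacing_mm=grid_spacing_mm, margin_mm=10.0)
        try:
            ref_mask = rasterize(ref, grid)
            case_dsc = np.empty((len(uppers), len(lowers)))
            for i, u in enumerate(uppers):
                for j, v in enumerate(lowers):
                    trial = ShiftConfig(upper_shift_mm=u, lower_shift_mm=v,
                                        lr_fraction=cfg.lr_fraction,
                                        retraction_mm=cfg.retraction_mm)
                    upper, lower = si_bounds_from_joints(case.joints, trial)
                    chest = chest_width(sil, upper, lower)
                    roi = build_roi(upper, lower, chest, case.laterality, trial)
                    case_dsc[i, j] = dsc(rasterize(roi, grid), ref_mask).dsc
        except (DegenerateGeometryError, InvalidInputError) as exc:
            warnings.warn(f"case skipped during tuning: {exc}")
            continue
        sums += case_dsc
        used += 1
    if used == 0:
        raise DegenerateGeometryError("every case failed ROI construction")
    mean = sums / used

    best_i, best_j, best_val = 0, 0, -np.inf
    for i, u in enumerate(uppers):
        for j, v in enumerate(lowers):
            if mean[i, j] > best_val + 1e-12:
                best_i, best_j, best_val = i, j, mean[i, j]
    return TuningResult(upper_candidates=uppers, lower_candidates=lowers,
                        mean_dsc=mean, best_upper_mm=uppers[best_i],
                        best_lower_mm=lowers[best_j], n_cases=used)


def mean_boundary_distance(references: Sequence[ROIRegion],
                           contours: Sequence[BreastContour]
                           ) -> Dict[str, Tuple[float, float]]:
    """Mean signed S-I distance between reference-ROI and breast boundaries.

    Positive values mean the ROI boundary lies beyond the contour boundary,
    away from the breast (superiorly for the upper border, inferiorly for
    the lower border); returned per contour category as
    ``{category: (superior_mm, inferior_mm)}``.
    """
    if len(references) != len(contours):
        raise InvalidInputError("reference/contour counts differ")
    if not references:
        raise InvalidInputError("empty reference set")
    acc: Dict[str, List[Tuple[float, float]]] = {}
    for roi, contour in zip(references, contours):
        sup = roi.upper_z_mm - contour.superior_z_mm
        inf = contour.inferior_z_mm - roi.lower_z_mm
        acc.setdefault(contour.category, []).append((sup, inf))
    result: Dict[str, Tuple[float, float]] = {}
    for category in ("breast_eval", "PTV"):
        if category not in acc:
            warnings.warn(f"no cases in category {category}; omitted")
            continue
        arr = np.asarray(acc[category])
        result[category] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    return result
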