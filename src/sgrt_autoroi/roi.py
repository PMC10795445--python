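"""Four-step ROI construction in the coronal plane.

Given superior-inferior bounds (from predicted joints or from the
delineated breast), the algorithm (1) fixes the ROI's S-I borders,
(2) measures the chest width of the body silhouette at the row midway
between them, (3) spans a configurable fraction (default 3/4) of that width
from the ipsilateral silhouette edge toward the contralateral side, and
(4) curates the ipsilateral-superior corner with a straight chamfer between
points a fixed retraction distance (default 80 mm) along the two adjacent
edges, keeping the mobile arm/armpit out of the region.

All geometry lives in the patient coronal plane: x = patient-left positive,
z = superior positive, mm.  Right-sided treatments are handled by mirroring
the inputs across the mid-sagittal plane, constructing the left-sided ROI,
and mirroring back.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure

from ._raster import BACKGROUND_DEPTH, project_depth
from .errors import DegenerateGeometryError, InvalidInputError, InvalidParameterError

LATERALITIES = ("left", "right")
CATEGORIES = ("breast_eval", "PTV")


@dataclass(frozen=True)
class ShiftConfig:
    """Tunable boundary extensions of the ROI construction (all mm).

    ``upper_shift_mm``/``lower_shift_mm`` extend the joint-derived bounds
    superiorly/inferiorly; the per-category breast extensions play the same
    role for breast-contour-derived bounds (a negative superior extension
    pulls the ROI border inferior of the contour border).
    """

    upper_shift_mm: float = 10.0
    lower_shift_mm: float = 30.0
    lr_fraction: float = 0.75
    retraction_mm: float = 80.0
    breast_eval_sup_mm: float = 27.0
    breast_eval_inf_mm: float = 12.0
    ptv_sup_mm: float = -24.0
    ptv_inf_mm: float = 17.0

    def validate(self) -> None:
        if not (0.0 < self.lr_fraction <= 1.0):
            raise InvalidParameterError(f"lr_fraction {self.lr_fraction} not in (0, 1]")
        if self.retraction_mm < 0:
            raise InvalidParameterError("retraction_mm must be >= 0")
        for name in ("upper_shift_mm", "lower_shift_mm", "breast_eval_sup_mm",
                     "breast_eval_inf_mm", "ptv_sup_mm", "ptv_inf_mm"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class GridSpec:
    """Raster grid in the coronal plane; pixel (r, c) is centered at
    ``(x0 + (c + 0.5) s, z_top - (r + 0.5) s)``."""

    x0_mm: float
    z_top_mm: float
    spacing_mm: float
    n_rows: int
    n_cols: int

    @property
    def x_max_mm(self) -> float:
        return self.x0_mm + self.n_cols * self.spacing_mm

    @property
    def z_bottom_mm(self) -> float:
        return self.z_top_mm - self.n_rows * self.spacing_mm

    def centers(self) -> Tuple[np.ndarray, np.ndarray]:
        x = self.x0_mm + (np.arange(self.n_cols) + 0.5) * self.spacing_mm
        z = self.z_top_mm - (np.arange(self.n_rows) + 0.5) * self.spacing_mm
        return x, z

    @classmethod
    def around(cls, bounds_list: Iterable[Tuple[float, float, float, float]],
               spacing_mm: float = 1.0, margin_mm: float = 5.0) -> "GridSpec":
        """Smallest grid covering every (x_min, z_min, x_max, z_max) box."""
        bs = list(bounds_list)
        x_min = min(b[0] for b in bs) - margin_mm
        z_min = min(b[1] for b in bs) - margin_mm
        x_max = max(b[2] for b in bs) + margin_mm
        z_max = max(b[3] for b in bs) + margin_mm
        return cls(x0_mm=x_min, z_top_mm=z_max, spacing_mm=spacing_mm,
                   n_rows=int(np.ceil((z_max - z_min) / spacing_mm)),
                   n_cols=int(np.ceil((x_max - x_min) / spacing_mm)))


@dataclass
class BodySilhouette:
    """Binary coronal mask of the external body contour."""

    mask: np.ndarray          # (H, W) bool
    spacing_mm: float
    x0_mm: float              # outer edge of column 0 (patient-right)
    z_top_mm: float           # outer edge of row 0 (superior)

    def validate(self) -> None:
        if not self.mask.any():
            raise InvalidInputError("empty body silhouette")
        if measure.label(self.mask, connectivity=2).max() != 1:
            raise InvalidInputError("silhouette must be a single connected component")

    def row_for_z(self, z: float) -> int:
        r = int(np.floor((self.z_top_mm - z) / self.spacing_mm))
        return min(max(r, 0), self.mask.shape[0] - 1)

    def mirrored(self) -> "BodySilhouette":
        """Reflection across the mid-sagittal plane (x -> -x)."""
        return BodySilhouette(mask=self.mask[:, ::-1].copy(),
                              spacing_mm=self.spacing_mm,
                              x0_mm=-(self.x0_mm + self.mask.shape[1] * self.spacing_mm),
                              z_top_mm=self.z_top_mm)

    @classmethod
    def from_body(cls, body, spacing_mm: float = 2.0,
                  margin_mm: float = 10.0) -> "BodySilhouette":
        """Orthographic coronal projection of a body mesh (largest component)."""
        lo, hi = body.bbox()
        x0 = float(lo[0] - margin_mm)
        z_top = float(hi[2] + margin_mm)
        n_cols = int(np.ceil((hi[0] - lo[0] + 2 * margin_mm) / spacing_mm))
        n_rows = int(np.ceil((hi[2] - lo[2] + 2 * margin_mm) / spacing_mm))
        depth = project_depth(body.vertices, body.faces, x0, z_top,
                              spacing_mm, n_rows, n_cols)
        mask = depth > BACKGROUND_DEPTH / 2
        labels = measure.label(mask, connectivity=2)
        if labels.max() > 1:
            counts = np.bincount(labels.ravel())[1:]
            mask = labels == (1 + int(np.argmax(counts)))
        return cls(mask=mask, spacing_mm=spacing_mm, x0_mm=x0, z_top_mm=z_top)

    @classmethod
    def from_mask(cls, mask: np.ndarray, spacing_mm: float,
                  x0_mm: float, z_top_mm: float) -> "BodySilhouette":
        return cls(mask=np.asarray(mask, dtype=bool), spacing_mm=spacing_mm,
                   x0_mm=x0_mm, z_top_mm=z_top_mm)


@dataclass(frozen=True)
class BreastContour:
    """Superior-inferior extent of the delineated ipsilateral breast."""

    superior_z_mm: float
    inferior_z_mm: float
    laterality: str
    category: str = "breast_eval"

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise InvalidParameterError(f"laterality must be one of {LATERALITIES}")
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"category must be one of {CATEGORIES}")
        if not self.superior_z_mm > self.inferior_z_mm:
            raise InvalidInputError("breast contour superior edge must be above inferior")

    @classmethod
    def from_json(cls, path) -> "BreastContour":
        data = json.loads(Path(path).read_text())
        return cls(superior_z_mm=float(data["superior_z_mm"]),
                   inferior_z_mm=float(data["inferior_z_mm"]),
                   laterality=data["laterality"], category=data["category"])


@dataclass
class ChestWidth:
    """Lateral silhouette extent at the mid-row between the S-I bounds."""

    width_mm: float
    x_min_mm: float      # patient-right outer edge
    x_max_mm: float      # patient-left outer edge
    mid_z_mm: float

    def ipsilateral_edge(self, laterality: str) -> float:
        return self.x_max_mm if laterality == "left" else self.x_min_mm

    def mirrored(self) -> "ChestWidth":
        return ChestWidth(width_mm=self.width_mm, x_min_mm=-self.x_max_mm,
                          x_max_mm=-self.x_min_mm, mid_z_mm=self.mid_z_mm)


@dataclass
class ROIRegion:
    """The ROI as a simple polygon in patient coronal coordinates (mm)."""

    polygon: np.ndarray                  # (N, 2) of (x, z), counter-clockwise
    laterality: str
    provenance: str                      # "body" | "breast"
    landmarks: Dict[str, float] = field(default_factory=dict)

    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    def area_mm2(self) -> float:
        return float(self.shapely().area)

    def bounds(self) -> Tuple[float, float, float, float]:
        p = self.polygon
        return (float(p[:, 0].min()), float(p[:, 1].min()),
                float(p[:, 0].max()), float(p[:, 1].max()))

    @property
    def upper_z_mm(self) -> float:
        return float(self.polygon[:, 1].max())

    @property
    def lower_z_mm(self) -> float:
        return float(self.polygon[:, 1].min())

    def validate(self) -> None:
        poly = self.shapely()
        if not poly.is_valid or poly.area <= 0:
            raise DegenerateGeometryError("ROI polygon is not a simple positive-area polygon")

    def to_json(self, path=None) -> str:
        data = {"polygon_xz_mm": [[float(x), float(z)] for x, z in self.polygon],
                "laterality": self.laterality, "provenance": self.provenance,
                "landmarks": {k: float(v) for k, v in self.landmarks.items()}}
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ROIRegion":
        data = json.loads(Path(path).read_text())
        return cls(polygon=np.asarray(data["polygon_xz_mm"], dtype=float),
                   laterality=data["laterality"], provenance=data["provenance"],
                   landmarks=data.get("landmarks", {}))

    @classmethod
    def from_landmarks(cls, upper_z: float, lower_z: float, x_ipsi: float,
                       x_contra: float, laterality: str, retraction_mm: float,
                       provenance: str = "body") -> "ROIRegion":
        """Rebuild the chamfered rectangle from its four boundary landmarks."""
        return _polygon_from_landmarks(upper_z, lower_z, x_ipsi, x_contra,
                                       laterality, retraction_mm, provenance)


def si_bounds_from_joints(joints: Mapping[str, Sequence[float]],
                          cfg: ShiftConfig) -> Tuple[float, float]:
    """S-I bounds from the collar joints (mean z) and the Spine2 joint.

    Joints may be 2D (x, z) or 3D (x, y, z) points; the last coordinate is
    taken as z.
    """
    for name in ("LeftCollar", "RightCollar", "Spine2"):
        if name not in joints:
            raise InvalidInputError(f"missing joint {name}")
    collar_z = 0.5 * (joints["LeftCollar"][-1] + joints["RightCollar"][-1])
    upper = collar_z + cfg.upper_shift_mm
    lower = joints["Spine2"][-1] - cfg.lower_shift_mm
    if not upper > lower:
        raise DegenerateGeometryError(
            f"upper bound {upper} not above lower bound {lower}")
    return float(upper), float(lower)


def si_bounds_from_breast(contour: BreastContour,
                          cfg: ShiftConfig) -> Tuple[float, float]:
    """S-I bounds from the breast contour extent with per-category extensions."""
    if contour.category == "breast_eval":
        upper = contour.superior_z_mm + cfg.breast_eval_sup_mm
        lower = contour.inferior_z_mm - cfg.breast_eval_inf_mm
    else:
        upper = contour.superior_z_mm + cfg.ptv_sup_mm
        lower = contour.inferior_z_mm - cfg.ptv_inf_mm
    if not upper > lower:
        raise DegenerateGeometryError(
            f"upper bound {upper} not above lower bound {lower}")
    return float(upper), float(lower)


def chest_width(silhouette: BodySilhouette, upper_z: float,
                lower_z: float) -> ChestWidth:
    """Lateral body extent at the row midway between the S-I bounds.

    Edge positions are the outer edges of the outermost body pixels so that
    a phantom of known width measures exactly that width.
    """
    mid_z = 0.5 * (upper_z + lower_z)
    row = silhouette.row_for_z(mid_z)
    cols = np.nonzero(silhouette.mask[row])[0]
    if cols.size == 0:
        raise DegenerateGeometryError(f"silhouette empty at midline z={mid_z} mm")
    x_min = silhouette.x0_mm + cols[0] * silhouette.spacing_mm
    x_max = silhouette.x0_mm + (cols[-1] + 1) * silhouette.spacing_mm
    return ChestWidth(width_mm=float(x_max - x_min), x_min_mm=float(x_min),
                      x_max_mm=float(x_max), mid_z_mm=float(mid_z))


def _polygon_from_landmarks(upper_z, lower_z, x_ipsi, x_contra, laterality,
                            retraction_mm, provenance) -> ROIRegion:
    if laterality not in LATERALITIES:
        raise InvalidParameterError(f"laterality must be one of {LATERALITIES}")
    if laterality == "right":
        mirrored = _polygon_from_landmarks(upper_z, lower_z, -x_ipsi, -x_contra,
                                           "left", retraction_mm, provenance)
        poly = mirrored.polygon.copy()
        poly[:, 0] = -poly[:, 0]
        lm = dict(mirrored.landmarks)
        for key in ("x_ipsi", "x_contra", "chamfer_top_x", "chamfer_side_x"):
            if key in lm:
                lm[key] = -lm[key]
        return ROIRegion(polygon=poly[::-1].copy(), laterality="right",
                         provenance=provenance, landmarks=lm)

    height = upper_z - lower_z
    width = x_ipsi - x_contra
    if height <= 0 or width <= 0:
        raise DegenerateGeometryError("ROI rectangle collapsed")
    landmarks = {"upper_z": float(upper_z), "lower_z": float(lower_z),
                 "x_ipsi": float(x_ipsi), "x_contra": float(x_contra),
                 "retraction_mm": float(retraction_mm)}
    if retraction_mm >= min(height, width):
        warnings.warn("retraction exceeds ROI edge length; corner left uncurated")
        poly = np.array([[x_contra, lower_z], [x_ipsi, lower_z],
                         [x_ipsi, upper_z], [x_contra, upper_z]])
        landmarks["curated"] = 0.0
    elif retraction_mm == 0:
        poly = np.array([[x_contra, lower_z], [x_ipsi, lower_z],
                         [x_ipsi, upper_z], [x_contra, upper_z]])
        landmarks["curated"] = 0.0
    else:
        # chamfer the ipsilateral-superior corner
        p_side = (x_ipsi, upper_z - retraction_mm)     # on the ipsilateral edge
        p_top = (x_ipsi - retraction_mm, upper_z)      # on the superior edge
        poly = np.array([[x_contra, lower_z], [x_ipsi, lower_z],
                         list(p_side), list(p_top), [x_contra, upper_z]])
        landmarks.update(curated=1.0, chamfer_side_x=p_side[0],
                         chamfer_side_z=p_side[1], chamfer_top_x=p_top[0],
                         chamfer_top_z=p_top[1])
    return ROIRegion(polygon=poly, laterality="left", provenance=provenance,
                     landmarks=landmarks)


def build_roi(upper_z: float, lower_z: float, chest: ChestWidth,
              laterality: str, cfg: ShiftConfig,
              provenance: str = "body") -> ROIRegion:
    """Steps 3-4: span ``lr_fraction`` of the chest width from the
    ipsilateral silhouette edge and chamfer the ipsilateral-superior corner."""
    cfg.validate()
    if laterality not in LATERALITIES:
        raise InvalidParameterError(f"laterality must be one of {LATERALITIES}")
    span = cfg.lr_fraction * chest.width_mm
    if laterality == "left":
        x_ipsi = chest.x_max_mm
        x_contra = x_ipsi - span
    else:
        x_ipsi = chest.x_min_mm
        x_contra = x_ipsi + span
    return _polygon_from_landmarks(upper_z, lower_z, x_ipsi, x_contra,
                                   laterality, cfg.retraction_mm, provenance)


def generate_aroi_body(silhouette: BodySilhouette,
                       joints: Mapping[str, Sequence[float]] | None = None,
                       model=None, image=None, laterality: str = "left",
                       cfg: ShiftConfig | None = None) -> ROIRegion:
    """Body-contour-based ROI from joints (given, or predicted from an image)."""
    cfg = cfg or ShiftConfig()
    if joints is None:
        if model is None or image is None:
            raise InvalidInputError("provide either joints or (model, image)")
        from .joint_model import predict
        label = predict(model, image)
        joints = {k: (x, z) for k, (x, z) in label.to_mm(image).items()}
    upper, lower = si_bounds_from_joints(joints, cfg)
    chest = chest_width(silhouette, upper, lower)
    return build_roi(upper, lower, chest, laterality, cfg, provenance="body")


def generate_aroi_breast(silhouette: BodySilhouette, contour: BreastContour,
                         cfg: ShiftConfig | None = None) -> ROIRegion:
    """Breast-contour-based ROI; laterality comes from the contour."""
    cfg = cfg or ShiftConfig()
    upper, lower = si_bounds_from_breast(contour, cfg)
    chest = chest_width(silhouette, upper, lower)
    return build_roi(upper, lower, chest, contour.laterality, cfg,
                     provenance="breast")


def rasterize(roi: ROIRegion, grid: GridSpec) -> np.ndarray:
    """Binary mask: pixel True iff its center lies inside the ROI polygon."""
    x_min, z_min, x_max, z_max = roi.bounds()
    if (x_min < grid.x0_mm - 1e-9 or x_max > grid.x_max_mm + 1e-9
            or z_min < grid.z_bottom_mm - 1e-9 or z_max > grid.z_top_mm + 1e-9):
        raise InvalidInputError("polygon extends outside the raster grid")
    xs, zs = grid.centers()
    xx, zz = np.meshgrid(xs, zs)
    poly = roi.shapely()
    shapely.prepare(poly)
    return shapely.contains_xy(poly, xx.ravel(), zz.ravel()).reshape(grid.n_rows,
                                                                     grid.n_cols)


# ---------------------------------------------------------------------------
# External contour ingestion

def silhouette_from_polygon(polygon_xz_mm: Sequence[Sequence[float]],
                            spacing_mm: float = 1.0,
                            margin_mm: float = 5.0) -> BodySilhouette:
    """Rasterize a coronal body outline polygon into a silhouette mask."""
    pts = np.asarray(polygon_xz_mm, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InvalidInputError("body outline needs at least 3 points")
    grid = GridSpec.around([(pts[:, 0].min(), pts[:, 1].min(),
                             pts[:, 0].max(), pts[:, 1].max())],
                           spacing_mm=spacing_mm, margin_mm=margin_mm)
    region = ROIRegion(polygon=pts, laterality="left", provenance="body")
    return BodySilhouette(mask=rasterize(region, grid), spacing_mm=spacing_mm,
                          x0_mm=grid.x0_mm, z_top_mm=grid.z_top_mm)


def silhouette_from_json(path, spacing_mm: float = 1.0) -> BodySilhouette:
    data = json.loads(Path(path).read_text())
    return silhouette_from_polygon(data["polygon_xz_mm"], spacing_mm=spacing_mm)


def _structure_contours(ds, roi_name: str):
    """(z, Nx2 xy array) slices of a named structure in an RT Structure Set."""
    import pydicom  # noqa: F401  (ds is an already-read pydicom dataset)
    number = None
    for item in ds.StructureSetROISequence:
        if str(item.ROIName).strip().lower() == roi_name.strip().lower():
            number = item.ROINumber
            break
    if number is None:
        names = [str(i.ROIName) for i in ds.StructureSetROISequence]
        raise InvalidInputError(f"structure {roi_name!r} not found; present: {names}")
    slices = []
    for roi in ds.ROIContourSequence:
        if roi.ReferencedROINumber != number:
            continue
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            slices.append((float(pts[0, 2]), pts[:, :2]))
    if not slices:
        raise InvalidInputError(f"structure {roi_name!r} has no contour data")
    return slices


def breast_contour_from_dicom(path, roi_name: str, laterality: str,
                              category: str = "breast_eval") -> BreastContour:
    """S-I extent of a named structure in a DICOM-RT Structure Set file."""
    import pydicom
    ds = pydicom.dcmread(str(path))
    slices = _structure_contours(ds, roi_name)
    zs = [z for z, _ in slices]
    return BreastContour(superior_z_mm=max(zs), inferior_z_mm=min(zs),
                         laterality=laterality, category=category)


def silhouette_from_dicom(path, roi_name: str = "BODY",
                          spacing_mm: float = 2.0) -> BodySilhouette:
    """Coronal projection of an axially-contoured structure: each axial
    slice's lateral extent fills the corresponding silhouette row."""
    import pydicom
    ds = pydicom.dcmread(str(path))
    slices = _structure_contours(ds, roi_name)
    zs = np.array([z for z, _ in slices])
    x_lo = min(float(p[:, 0].min()) for _, p in slices)
    x_hi = max(float(p[:, 0].max()) for _, p in slices)
    margin = 2 * spacing_mm
    x0 = x_lo - margin
    z_top = zs.max() + margin
    n_cols = int(np.ceil((x_hi - x_lo + 2 * margin) / spacing_mm))
    n_rows = int(np.ceil((zs.max() - zs.min() + 2 * margin) / spacing_mm))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    half = max(np.median(np.diff(np.unique(zs))) if len(set(zs)) > 1 else spacing_mm,
               spacing_mm) / 2.0
    z_centers = z_top - (np.arange(n_rows) + 0.5) * spacing_mm
    for z, pts in slices:
        rows = np.nonzero(np.abs(z_centers - z) <= half)[0]
        c_lo = int(np.floor((pts[:, 0].min() - x0) / spacing_mm))
        c_hi = int(np.ceil((pts[:, 0].max() - x0) / spacing_mm))
        mask[np.ix_(rows, range(max(c_lo, 0), min(c_hi, n_cols)))] = True
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(counts)))
    return BodySilhouette(mask=mask, spacing_mm=spacing_mm, x0_mm=x0, z_top_mm=z_top)
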