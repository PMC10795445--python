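"""Procedural parametric human body in the arms-raised treatment pose.

A self-contained stand-in for learned statistical body models: the body is
assembled from stacked elliptical cross-sections (legs, torso, neck, arms)
plus an ellipsoidal head, posed with both arms abducted overhead as for
whole-breast treatment in supine position.  Shape variation is controlled by
four multiplicative scales (torso width/depth, shoulder width, limb length),
and a named joint skeleton is placed at fixed anatomical offsets of the
segment stack.

Frame convention: x = patient-left positive, y = anterior positive,
z = superior positive; units mm.  The soles rest at z = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import trimesh

from .errors import InvalidParameterError

#: Default allowed range for every shape scale.
DEFAULT_SCALE_BOUNDS: Tuple[float, float] = (0.8, 1.2)

#: Joints every generated body must carry.
REQUIRED_JOINTS = (
    "Head", "Nose", "LeftCollar", "RightCollar",
    "Spine1", "Spine2", "LeftShoulder", "RightShoulder",
)

_N_THETA = 20

# Template segment lengths (mm) for unit scales.
_LEG_LENGTH = 830.0
_TORSO_LENGTH = 560.0
_NECK_LENGTH = 70.0
_ARM_LENGTH = 600.0
_ARM_ABDUCTION_DEG = 20.0  # tilt from vertical, toward lateral

# Torso cross-sections as (offset above hip, half-width x, half-depth y).
_TORSO_SECTIONS = (
    (0.0, 160.0, 100.0),
    (80.0, 150.0, 95.0),
    (170.0, 140.0, 90.0),    # waist
    (270.0, 150.0, 95.0),
    (350.0, 165.0, 100.0),
    (420.0, 170.0, 105.0),   # chest (widest torso level)
    (490.0, 175.0, 100.0),
    (530.0, 180.0, 95.0),    # shoulder girdle
    (560.0, 150.0, 80.0),
)

#: Height above the hip of the widest (chest) torso section.
TEMPLATE_CHEST_OFFSET = 420.0

_LEG_SECTIONS = (
    (0.0, 40.0, 40.0),
    (100.0, 42.0, 42.0),
    (400.0, 55.0, 55.0),     # knee
    (600.0, 70.0, 70.0),
    (830.0, 82.0, 82.0),     # hip
)
_LEG_OFFSET_X = 95.0

_ARM_SECTIONS_REL = (        # (fraction of arm length, radius)
    (0.0, 34.0),
    (0.45, 30.0),
    (0.75, 27.0),
    (0.90, 30.0),            # hand
    (1.0, 20.0),
)
_SHOULDER_OFFSET_X = 170.0
_COLLAR_OFFSET = dict(x=45.0, y=40.0, dz=550.0)  # dz above hip


@dataclass(frozen=True)
class ShapeParams:
    """Multiplicative shape scales for the parametric body template."""

    torso_width_scale: float = 1.0
    torso_depth_scale: float = 1.0
    shoulder_width_scale: float = 1.0
    limb_length_scale: float = 1.0
    rng_seed: int = 0

    def scales(self) -> Tuple[float, float, float, float]:
        return (self.torso_width_scale, self.torso_depth_scale,
                self.shoulder_width_scale, self.limb_length_scale)

    def validate(self, bounds: Tuple[float, float] = DEFAULT_SCALE_BOUNDS) -> None:
        lo, hi = bounds
        for name in ("torso_width_scale", "torso_depth_scale",
                     "shoulder_width_scale", "limb_length_scale"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise InvalidParameterError(
                    f"{name}={v} outside allowed bounds [{lo}, {hi}]")

    @classmethod
    def random(cls, rng_seed: int,
               bounds: Tuple[float, float] = DEFAULT_SCALE_BOUNDS) -> "ShapeParams":
        """Draw each scale uniformly from ``bounds`` (reproducible from the seed)."""
        rng = np.random.default_rng(rng_seed)
        lo, hi = bounds
        s = rng.uniform(lo, hi, size=4)
        return cls(torso_width_scale=float(s[0]), torso_depth_scale=float(s[1]),
                   shoulder_width_scale=float(s[2]), limb_length_scale=float(s[3]),
                   rng_seed=int(rng_seed))


@dataclass
class BodyModel:
    """A posed body surface mesh with its named joint skeleton (mm)."""

    vertices: np.ndarray              # (N, 3) float64
    faces: np.ndarray                 # (M, 3) int64 triangle indices
    joints: Dict[str, np.ndarray]     # name -> (3,) point
    shape_seed: int
    height_mm: float

    def bbox(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def si_extent_mm(self) -> float:
        return float(self.vertices[:, 2].max() - self.vertices[:, 2].min())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export_obj(self, path) -> None:
        self.to_trimesh().export(str(path), file_type="obj")

    def export_skeleton_json(self, path) -> None:
        data = {name: [float(v) for v in pt] for name, pt in self.joints.items()}
        Path(path).write_text(json.dumps(data, indent=1))

    def validate(self) -> None:
        lo, hi = self.bbox()
        for name in REQUIRED_JOINTS:
            if name not in self.joints:
                raise InvalidParameterError(f"missing joint {name}")
        for name, pt in self.joints.items():
            if not (np.all(pt >= lo - 1e-9) and np.all(pt <= hi + 1e-9)):
                raise InvalidParameterError(f"joint {name} outside mesh bounding box")
        if abs(self.si_extent_mm() - self.height_mm) > 1.0:
            raise InvalidParameterError("height_mm inconsistent with vertex S-I extent")
        dz = abs(self.joints["LeftCollar"][2] - self.joints["RightCollar"][2])
        if dz > 15.0:
            raise InvalidParameterError("collar joints not anatomically level")


def _tube(sections, cx: float = 0.0, cy: float = 0.0):
    """Closed vertical tube of elliptical cross-sections with capped ends.

    ``sections`` is an ordered list of (z, half_x, half_y).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    rings = []
    for z, hx, hy in sections:
        rings.append(np.column_stack([cx + hx * ct, cy + hy * st,
                                      np.full(_N_THETA, z)]))
    verts = np.vstack(rings)
    n_rings = len(sections)
    faces = []
    for j in range(n_rings - 1):
        a = j * _N_THETA
        b = (j + 1) * _N_THETA
        for i in range(_N_THETA):
            i2 = (i + 1) % _N_THETA
            faces.append((a + i, a + i2, b + i2))
            faces.append((a + i, b + i2, b + i))
    # end caps: fans to the section centers
    bot = len(verts)
    verts = np.vstack([verts, [[cx, cy, sections[0][0]]],
                       [[cx, cy, sections[-1][0]]]])
    top = bot + 1
    last = (n_rings - 1) * _N_THETA
    for i in range(_N_THETA):
        i2 = (i + 1) % _N_THETA
        faces.append((bot, i2, i))
        faces.append((top, last + i, last + i2))
    return verts, np.asarray(faces, dtype=np.int64)


def _ellipsoid(center, half_axes, subdivisions: int = 2):
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = sphere.vertices * np.asarray(half_axes) + np.asarray(center)
    return np.asarray(verts, dtype=np.float64), np.asarray(sphere.faces, dtype=np.int64)


def _arm(root, side: int, length: float):
    """Straight arm tube abducted overhead; ``side`` is +1 (left) / -1 (right)."""
    sections = [(f * length, r, r) for f, r in _ARM_SECTIONS_REL]
    verts, faces = _tube(sections)
    phi = np.deg2rad(_ARM_ABDUCTION_DEG) * side
    rot = np.array([[np.cos(phi), 0.0, np.sin(phi)],
                    [0.0, 1.0, 0.0],
                    [-np.sin(phi), 0.0, np.cos(phi)]])
    verts = verts @ rot.T + np.asarray(root)
    return verts, faces


def _assemble(parts):
    verts_list, faces_list, offset = [], [], 0
    for v, f in parts:
        verts_list.append(v)
        faces_list.append(f + offset)
        offset += len(v)
    return np.vstack(verts_list), np.vstack(faces_list)


def _build(params: ShapeParams):
    tw, td, sw, ll = params.scales()
    z_hip = _LEG_LENGTH * ll
    z_shoulder_girdle = z_hip + 530.0
    z_neck_base = z_hip + _TORSO_LENGTH

    parts = []
    # legs
    leg_sections = [(z * ll, hx * tw, hy * td) for z, hx, hy in _LEG_SECTIONS]
    for side in (+1, -1):
        parts.append(_tube(leg_sections, cx=side * _LEG_OFFSET_X * tw))
    # torso; the two shoulder-girdle sections follow the shoulder width scale
    torso_sections = []
    for dz, hx, hy in _TORSO_SECTIONS:
        w = sw if dz >= 530.0 else tw
        torso_sections.append((z_hip + dz, hx * w, hy * td))
    parts.append(_tube(torso_sections))
    # neck
    parts.append(_tube([(z_neck_base, 45.0, 45.0),
                        (z_neck_base + _NECK_LENGTH, 42.0, 42.0)]))
    # head
    z_head_center = z_neck_base + _NECK_LENGTH + 105.0
    parts.append(_ellipsoid((0.0, 10.0, z_head_center), (75.0, 90.0, 115.0)))
    # arms
    arm_len = _ARM_LENGTH * ll
    for side in (+1, -1):
        root = (side * _SHOULDER_OFFSET_X * sw, 0.0, z_shoulder_girdle - 20.0)
        parts.append(_arm(root, side, arm_len))

    vertices, faces = _assemble(parts)

    joints = {
        "Pelvis": np.array([0.0, 0.0, z_hip + 10.0]),
        "Spine1": np.array([0.0, 0.0, z_hip + 230.0]),
        "Spine2": np.array([0.0, 0.0, z_hip + 350.0]),
        "LeftCollar": np.array([_COLLAR_OFFSET["x"] * tw, _COLLAR_OFFSET["y"] * td,
                                z_hip + _COLLAR_OFFSET["dz"]]),
        "RightCollar": np.array([-_COLLAR_OFFSET["x"] * tw, _COLLAR_OFFSET["y"] * td,
                                 z_hip + _COLLAR_OFFSET["dz"]]),
        "LeftShoulder": np.array([_SHOULDER_OFFSET_X * sw, 0.0, z_shoulder_girdle - 20.0]),
        "RightShoulder": np.array([-_SHOULDER_OFFSET_X * sw, 0.0, z_shoulder_girdle - 20.0]),
        "Head": np.array([0.0, 10.0, z_head_center]),
        "Nose": np.array([0.0, 95.0, z_head_center - 25.0]),
    }
    return vertices, faces, joints


def sample_body(params: ShapeParams,
                bounds: Tuple[float, float] = DEFAULT_SCALE_BOUNDS) -> BodyModel:
    """Build a posed body for the given shape parameters.

    The output is fully determined by ``params``; two calls with the same
    parameters return bit-identical vertices and joints.
    """
    params.validate(bounds)
    vertices, faces, joints = _build(params)
    body = BodyModel(vertices=vertices, faces=faces, joints=joints,
                     shape_seed=params.rng_seed,
                     height_mm=float(vertices[:, 2].max() - vertices[:, 2].min()))
    return body


#: Joint positions of the unmodified template (all scales 1.0).
TEMPLATE_JOINTS: Dict[str, np.ndarray] = _build(ShapeParams())[2]


def scale_to_height(body: BodyModel, target_height_mm: float) -> BodyModel:
    """Uniformly scale a body so its S-I vertex extent equals the target height.

    Isotropic scaling about the origin; joint-distance ratios are preserved.
    """
    if not np.isfinite(target_height_mm) or target_height_mm <= 0:
        raise InvalidParameterError(f"target height must be positive, got {target_height_mm}")
    s = target_height_mm / body.si_extent_mm()
    return BodyModel(vertices=body.vertices * s,
                     faces=body.faces,
                     joints={k: v * s for k, v in body.joints.items()},
                     shape_seed=body.shape_seed,
                     height_mm=float(target_height_mm))
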