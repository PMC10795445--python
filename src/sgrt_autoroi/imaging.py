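"""Coronal projection, randomized torso cropping and dataset assembly.

A body mesh is orthographically projected along the anterior-posterior axis
into a depth-shaded grayscale image (frontmost-surface depth, normalized per
image; background exactly 0).  The full-body image is then cropped to a
torso window emulating the scan range of breast patients: the upper edge is
drawn uniformly between the Nose and Head joints, the lower edge uniformly
between the Spine2 and Spine1 joints, and the window is made square about
the body midline before resampling to the configured size.

Image conventions are those of :mod:`sgrt_autoroi._raster`: row 0 superior,
column 0 patient-right, pixel (r, c) centered at
``(x0 + (c + 0.5) s, z_top - (r + 0.5) s)``.  Label coordinates are
real-valued (row, col) pixel indices in that center-index space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from ._raster import BACKGROUND_DEPTH, project_depth
from .body import BodyModel, ShapeParams, sample_body, scale_to_height
from .errors import InvalidInputError

#: Joints regressed by the model.
TARGET_JOINTS = ("LeftCollar", "RightCollar", "Spine2")

#: Joints the random crop needs.
CROP_JOINTS = ("Head", "Nose", "Spine1", "Spine2")

_BODY_FLOOR = 0.02   # minimum value assigned to body pixels after shading


@dataclass
class FullRender:
    """Uncropped coronal projection of one body."""

    pixels: np.ndarray          # (H, W) float, 0 outside the silhouette
    spacing_mm: float
    x0_mm: float                # outer edge of column 0 (patient-right)
    z_top_mm: float             # outer edge of row 0 (superior)

    def rowcol_to_xz(self, row: float, col: float) -> Tuple[float, float]:
        return (self.x0_mm + (col + 0.5) * self.spacing_mm,
                self.z_top_mm - (row + 0.5) * self.spacing_mm)

    def xz_to_rowcol(self, x: float, z: float) -> Tuple[float, float]:
        return ((self.z_top_mm - z) / self.spacing_mm - 0.5,
                (x - self.x0_mm) / self.spacing_mm - 0.5)


@dataclass
class CoronalImage:
    """Cropped square training image with physical provenance."""

    pixels: np.ndarray                       # (H, W), values in [0, 1]
    pixel_spacing_mm: Tuple[float, float]    # (row, col)
    crop_origin_mm: Tuple[float, float]      # (x0, z_top) outer edge of pixel (0, 0)
    source_seed: int

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def rowcol_to_xz(self, row: float, col: float) -> Tuple[float, float]:
        sr, sc = self.pixel_spacing_mm
        x0, z_top = self.crop_origin_mm
        return (x0 + (col + 0.5) * sc, z_top - (row + 0.5) * sr)

    def xz_to_rowcol(self, x: float, z: float) -> Tuple[float, float]:
        sr, sc = self.pixel_spacing_mm
        x0, z_top = self.crop_origin_mm
        return ((z_top - z) / sr - 0.5, (x - x0) / sc - 0.5)

    def validate(self, expected_size: int | None = None) -> None:
        h, w = self.pixels.shape
        if h != w:
            raise InvalidInputError("coronal image must be square")
        if expected_size is not None and h != expected_size:
            raise InvalidInputError(f"image size {h} != configured {expected_size}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise InvalidInputError("pixel values outside [0, 1]")


@dataclass
class JointLabel2D:
    """Real-valued (row, col) pixel coordinates of the three target joints."""

    coords: Dict[str, Tuple[float, float]]

    def to_mm(self, image: CoronalImage) -> Dict[str, Tuple[float, float]]:
        """Convert labels to (x, z) mm in the patient frame."""
        return {k: image.rowcol_to_xz(*rc) for k, rc in self.coords.items()}

    def as_array(self, order: Sequence[str] = TARGET_JOINTS) -> np.ndarray:
        return np.array([self.coords[k] for k in order], dtype=float)


@dataclass
class SyntheticDataset:
    samples: List[Tuple[CoronalImage, JointLabel2D]]
    train_indices: np.ndarray
    val_indices: np.ndarray
    ratio: float
    seed: int

    def __len__(self) -> int:
        return len(self.samples)


def project_coronal(body: BodyModel, spacing_mm: float = 3.0,
                    margin_mm: float = 12.0) -> Tuple[FullRender, Dict[str, Tuple[float, float]]]:
    """Orthographic coronal projection of a body with projected 2D joints.

    Pixel values encode the normalized anterior depth of the frontmost
    surface (larger = more anterior), rescaled per image to
    (``_BODY_FLOOR``, 1]; background is exactly 0.  Joints are projected by
    dropping the y coordinate and returned as (row, col) labels.
    """
    if body.faces is None or len(body.faces) == 0:
        raise InvalidInputError("cannot project an empty mesh")
    lo, hi = body.bbox()
    x0 = float(lo[0] - margin_mm)
    z_top = float(hi[2] + margin_mm)
    n_cols = int(np.ceil((hi[0] - lo[0] + 2 * margin_mm) / spacing_mm))
    n_rows = int(np.ceil((hi[2] - lo[2] + 2 * margin_mm) / spacing_mm))
    depth = project_depth(body.vertices, body.faces, x0, z_top, spacing_mm,
                          n_rows, n_cols)
    mask = depth > BACKGROUND_DEPTH / 2
    pixels = np.zeros_like(depth)
    if mask.any():
        d = depth[mask]
        span = d.max() - d.min()
        if span < 1e-9:
            pixels[mask] = 1.0
        else:
            pixels[mask] = _BODY_FLOOR + (1.0 - _BODY_FLOOR) * (d - d.min()) / span
    render = FullRender(pixels=pixels, spacing_mm=spacing_mm, x0_mm=x0, z_top_mm=z_top)
    joints2d = {name: render.xz_to_rowcol(pt[0], pt[2])
                for name, pt in body.joints.items()}
    return render, joints2d


def _resample(full: FullRender, x0: float, z_top: float, spacing: float,
              size: int) -> np.ndarray:
    """Sample the full render on the crop grid (bilinear inside the body,
    nearest-neighbour membership so the background stays exactly 0)."""
    rows = np.arange(size)
    cols = np.arange(size)
    zz = z_top - (rows + 0.5) * spacing
    xx = x0 + (cols + 0.5) * spacing
    rf = (full.z_top_mm - zz) / full.spacing_mm - 0.5
    cf = (xx - full.x0_mm) / full.spacing_mm - 0.5
    rgrid, cgrid = np.meshgrid(rf, cf, indexing="ij")
    coords = np.stack([rgrid, cgrid])
    vals = ndimage.map_coordinates(full.pixels, coords, order=1, mode="constant", cval=0.0)
    member = ndimage.map_coordinates(full.pixels, coords, order=0, mode="constant", cval=0.0) > 0
    return np.where(member, np.maximum(vals, _BODY_FLOOR / 2), 0.0)


def crop_torso(full: FullRender, joints2d: Dict[str, Tuple[float, float]],
               rng: np.random.Generator, size: int = 200,
               source_seed: int = 0, max_retries: int = 10
               ) -> Tuple[CoronalImage, JointLabel2D]:
    """Randomized torso crop with labels in cropped-image pixel coordinates.

    The superior edge is drawn uniformly between the Nose and Head joints and
    the inferior edge uniformly between Spine2 and Spine1; the window is made
    square by symmetric lateral extension about the body midline, then
    resampled to ``size`` x ``size``.
    """
    for name in CROP_JOINTS:
        if name not in joints2d:
            raise InvalidInputError(f"crop requires joint {name}")
    z_of = {name: full.rowcol_to_xz(*joints2d[name])[1] for name in CROP_JOINTS}
    x_of = {name: full.rowcol_to_xz(*joints2d[name])[0] for name in TARGET_JOINTS
            if name in joints2d}

    for _ in range(max_retries):
        z_up = float(rng.uniform(z_of["Nose"], z_of["Head"]))
        z_low = float(rng.uniform(z_of["Spine1"], z_of["Spine2"]))
        height = z_up - z_low
        if height <= 0:
            continue
        # body midline within the vertical band
        band = (np.arange(full.pixels.shape[0]) + 0.5) * full.spacing_mm
        band_z = full.z_top_mm - band
        rows_in = (band_z <= z_up) & (band_z >= z_low)
        body_cols = np.nonzero(full.pixels[rows_in].any(axis=0))[0]
        if body_cols.size == 0:
            continue
        x_left_edge = full.x0_mm + body_cols[0] * full.spacing_mm
        x_right_edge = full.x0_mm + (body_cols[-1] + 1) * full.spacing_mm
        x_mid = 0.5 * (x_left_edge + x_right_edge)
        x0 = x_mid - height / 2.0
        spacing = height / size
        image = CoronalImage(
            pixels=_resample(full, x0, z_up, spacing, size),
            pixel_spacing_mm=(spacing, spacing),
            crop_origin_mm=(x0, z_up),
            source_seed=source_seed,
        )
        label = JointLabel2D(coords={
            name: image.xz_to_rowcol(x_of[name],
                                     full.rowcol_to_xz(*joints2d[name])[1])
            for name in TARGET_JOINTS if name in joints2d})
        if all(0 <= r < size and 0 <= c < size for r, c in label.coords.values()):
            return image, label
    raise InvalidInputError("could not place a crop containing all target joints")


def sample_seed(global_seed: int, index: int) -> int:
    """Stable per-sample seed derivation (kept below 2**31)."""
    return (int(global_seed) * 1_000_003 + int(index) * 7919 + 17) % (2 ** 31)


def build_dataset(n: int, ratio: float = 0.85, seed: int = 0, size: int = 200,
                  target_height_mm: float = 1617.0,
                  render_spacing_mm: float = 3.0,
                  scale_bounds: Tuple[float, float] = (0.8, 1.2)
                  ) -> SyntheticDataset:
    """Generate ``n`` cropped image/label pairs and a seeded train/val split."""
    if n < 2:
        raise InvalidInputError("dataset needs at least 2 samples")
    if not (0.0 < ratio < 1.0):
        raise InvalidInputError("split ratio must be in (0, 1)")
    samples: List[Tuple[CoronalImage, JointLabel2D]] = []
    for i in range(n):
        s = sample_seed(seed, i)
        body = sample_body(ShapeParams.random(s, scale_bounds), scale_bounds)
        body = scale_to_height(body, target_height_mm)
        full, joints2d = project_coronal(body, spacing_mm=render_spacing_mm)
        rng = np.random.default_rng(s + 1)
        image, label = crop_torso(full, joints2d, rng, size=size, source_seed=s)
        samples.append((image, label))
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    return SyntheticDataset(samples=samples,
                            train_indices=np.sort(order[:n_train]),
                            val_indices=np.sort(order[n_train:]),
                            ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# On-disk format: one 16-bit PNG per image, one JSON sidecar per sample,
# and a manifest with the split.

def save_dataset(dataset: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (image, label) in enumerate(dataset.samples):
        stem = f"sample_{i:05d}"
        arr = np.clip(image.pixels, 0.0, 1.0)
        Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(out / f"{stem}.png")
        sidecar = {
            "labels": {k: [float(r), float(c)] for k, (r, c) in label.coords.items()},
            "pixel_spacing_mm": list(image.pixel_spacing_mm),
            "crop_origin_mm": list(image.crop_origin_mm),
            "source_seed": int(image.source_seed),
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar))
    manifest = {
        "n": len(dataset),
        "ratio": dataset.ratio,
        "seed": int(dataset.seed),
        "image_size": dataset.samples[0][0].size if dataset.samples else 0,
        "train": [int(i) for i in dataset.train_indices],
        "val": [int(i) for i in dataset.val_indices],
    }
    (out / "manifest.json").write_text(json.dumps(manifest))


def load_image(png_path, sidecar_path=None) -> Tuple[CoronalImage, JointLabel2D | None]:
    png_path = Path(png_path)
    if sidecar_path is None:
        sidecar_path = png_path.with_suffix(".json")
    arr = np.asarray(Image.open(png_path), dtype=np.float64) / 65535.0
    label = None
    spacing, origin, seed = (1.0, 1.0), (0.0, 0.0), 0
    if Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
        spacing = tuple(meta["pixel_spacing_mm"])
        origin = tuple(meta["crop_origin_mm"])
        seed = int(meta.get("source_seed", 0))
        label = JointLabel2D(coords={k: (float(v[0]), float(v[1]))
                                     for k, v in meta["labels"].items()})
    image = CoronalImage(pixels=arr, pixel_spacing_mm=spacing,
                         crop_origin_mm=origin, source_seed=seed)
    return image, label


def load_dataset(data_dir) -> SyntheticDataset:
    data = Path(data_dir)
    manifest = json.loads((data / "manifest.json").read_text())
    samples = []
    for i in range(manifest["n"]):
        image, label = load_image(data / f"sample_{i:05d}.png")
        if label is None:
            raise InvalidInputError(f"missing sidecar for sample {i}")
        samples.append((image, label))
    return SyntheticDataset(samples=samples,
                            train_indices=np.asarray(manifest["train"], dtype=int),
                            val_indices=np.asarray(manifest["val"], dtype=int),
                            ratio=float(manifest["ratio"]),
                            seed=int(manifest["seed"]))
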