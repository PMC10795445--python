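import numpy as np
import pytest

from sgrt_autoroi.body import ShapeParams, sample_body, scale_to_height
from sgrt_autoroi.cohort import make_cohort
from sgrt_autoroi.imaging import CoronalImage, JointLabel2D, SyntheticDataset
from sgrt_autoroi.joint_model import TrainConfig, train
from sgrt_autoroi.roi import BodySilhouette


@pytest.fixture(scope="session")
def template_body():
    return sample_body(ShapeParams())


@pytest.fixture(scope="session")
def scaled_body():
    return scale_to_height(sample_body(ShapeParams.random(42)), 1617.0)


@pytest.fixture(scope="session")
def cohort24():
    """24 noise-free synthetic patients (the tuning cohort size)."""
    return make_cohort(24, noise_sd_mm=0.0, seed=11)


@pytest.fixture(scope="session")
def cohort24_noisy():
    """Same cohort conditions with 5 mm boundary jitter."""
    return make_cohort(24, noise_sd_mm=5.0, seed=11)


def rect_silhouette(width_mm=300.0, x_center=0.0, z_lo=900.0, z_hi=1500.0,
                    spacing=1.0):
    """Rectangular body phantom of exactly known width."""
    n_cols = int(round(width_mm / spacing)) + 10
    n_rows = int(round((z_hi - z_lo) / spacing)) + 10
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    mask[5:-5, 5:-5] = True
    x0 = x_center - width_mm / 2 - 5 * spacing
    z_top = z_hi + 5 * spacing
    return BodySilhouette.from_mask(mask, spacing, x0, z_top)


def make_toy_dataset(n=800, size=64, seed=5):
    """Single rendered dot per image; labels are an affine map of its position."""
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:size, 0:size]
    samples = []
    for i in range(n):
        r, c = rng.uniform(12, size - 12, 2)
        px = np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / 18.0))
        px[px < 0.02] = 0.0
        px /= px.max()
        label = JointLabel2D(coords={"LeftCollar": (r - 4, c + 6),
                                     "RightCollar": (r - 4, c - 6),
                                     "Spine2": (r + 8, c)})
        samples.append((CoronalImage(pixels=px, pixel_spacing_mm=(1.0, 1.0),
                                     crop_origin_mm=(0.0, float(size)),
                                     source_seed=i), label))
    order = rng.permutation(n)
    n_train = int(round(0.8 * n))
    return SyntheticDataset(samples=samples,
                            train_indices=np.sort(order[:n_train]),
                            val_indices=np.sort(order[n_train:]),
                            ratio=0.8, seed=seed)


@pytest.fixture(scope="session")
def toy_dataset():
    return make_toy_dataset()


@pytest.fixture(scope="session")
def toy_model(toy_dataset):
    return train(toy_dataset, TrainConfig(epochs=200, learning_rate=3e-3,
                                          lr_decay=0.99, seed=0))


def brute_force_point_in_polygon(px, pz, poly):
    """Independent even-odd ray-casting test."""
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, zi = poly[i]
        xj, zj = poly[j]
        if (zi > pz) != (zj > pz) and px < (xj - xi) * (pz - zi) / (zj - zi) + xi:
            inside = not inside
        j = i
    return inside


def brute_force_rasterize(poly, grid):
    out = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r in range(grid.n_rows):
        z = grid.z_top_mm - (r + 0.5) * grid.spacing_mm
        for c in range(grid.n_cols):
            x = grid.x0_mm + (c + 0.5) * grid.spacing_mm
            out[r, c] = brute_force_point_in_polygon(x, z, poly)
    return out
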