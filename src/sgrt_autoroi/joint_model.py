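"""Joint-location regression from cropped coronal images, with MPJPE evaluation.

The regressor maps one grayscale torso image to six numbers: (row, col) for
the LeftCollar, RightCollar and Spine2 joints.  Labels are regressed in
normalized [0, 1] image coordinates internally and converted back to pixel
coordinates at the interface.  Training minimizes the mean squared error
with the Adam optimizer and stops at a fixed epoch budget.

The backbone is pluggable: any estimator with partial-fit-style ``fit`` on
(features, targets) and ``predict`` works.  The default backbone is a small
multilayer perceptron on anti-aliased downsampled pixels, sized to train on
a single CPU in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import joblib
import numpy as np
from skimage.transform import resize
from sklearn.neural_network import MLPRegressor

from .errors import InvalidInputError, TrainingDivergedError
from .imaging import CoronalImage, JointLabel2D, SyntheticDataset, TARGET_JOINTS

CHECKPOINT_FORMAT = "sgrt-autoroi-joint-model/1"


@dataclass
class TrainConfig:
    epochs: int = 2000
    learning_rate: float = 1e-3
    batch_size: int = 32
    hidden_layer_sizes: Tuple[int, ...] = (128, 64)
    alpha: float = 1e-4          # L2 weight penalty
    lr_decay: float = 1.0        # multiplicative per-epoch step-size decay
    feature_size: int = 32       # images are downsampled to this square size
    seed: int = 0
    log_every: int = 0           # epochs between log lines; 0 = silent


@dataclass
class JointPredictor:
    """A trained regressor plus the normalization it was fitted with."""

    backbone: object
    input_size: int
    feature_size: int
    norm_mean: np.ndarray
    norm_std: np.ndarray
    target_joints: Tuple[str, ...] = TARGET_JOINTS
    metadata: Dict = field(default_factory=dict)

    def features(self, image: CoronalImage) -> np.ndarray:
        if image.pixels.shape != (self.input_size, self.input_size):
            raise InvalidInputError(
                f"image size {image.pixels.shape} does not match model input "
                f"({self.input_size})")
        small = resize(image.pixels, (self.feature_size, self.feature_size),
                       anti_aliasing=True)
        x = small.ravel()
        return (x - self.norm_mean) / self.norm_std


@dataclass
class MPJPEReport:
    """Per-joint Euclidean error plus per-axis statistics, all in mm."""

    per_joint_mm: Dict[str, float]        # mean Euclidean error per joint
    mean_mm: float                        # mean Euclidean error over all joints
    sd_mm: float
    si_mean_mm: float                     # mean |Delta z| (superior-inferior)
    si_sd_mm: float
    lr_mean_mm: float                     # mean |Delta x| (left-right)
    lr_sd_mm: float
    n: int


def _feature_matrix(images: Sequence[CoronalImage], feature_size: int) -> np.ndarray:
    rows = [resize(im.pixels, (feature_size, feature_size), anti_aliasing=True).ravel()
            for im in images]
    return np.asarray(rows, dtype=np.float64)


def _label_matrix(labels: Sequence[JointLabel2D], size: int) -> np.ndarray:
    out = np.empty((len(labels), 2 * len(TARGET_JOINTS)))
    for i, lab in enumerate(labels):
        rc = lab.as_array(TARGET_JOINTS)
        out[i, 0::2] = (rc[:, 0] + 0.5) / size
        out[i, 1::2] = (rc[:, 1] + 0.5) / size
    return out


def train(dataset: SyntheticDataset, config: TrainConfig | None = None) -> JointPredictor:
    """Fit the joint regressor on the dataset's train split.

    Runs exactly ``config.epochs`` Adam epochs over the squared-error loss,
    recording train and validation loss per epoch; deterministic under a
    fixed seed and single-threaded execution.
    """
    config = config or TrainConfig()
    if len(dataset) == 0 or len(dataset.train_indices) == 0:
        raise InvalidInputError("empty training split")
    size = dataset.samples[0][0].size

    images = [s[0] for s in dataset.samples]
    labels = [s[1] for s in dataset.samples]
    X = _feature_matrix(images, config.feature_size)
    Y = _label_matrix(labels, size)
    tr, va = dataset.train_indices, dataset.val_indices
    # per-channel (single grayscale channel) normalization: scalar mean/std
    mean = np.full(X.shape[1], X[tr].mean())
    std = np.full(X.shape[1], X[tr].std() + 1e-8)
    Xn = (X - mean) / std

    est = MLPRegressor(hidden_layer_sizes=config.hidden_layer_sizes,
                       solver="adam", learning_rate_init=config.learning_rate,
                       batch_size=min(config.batch_size, len(tr)),
                       alpha=config.alpha, max_iter=1,
                       shuffle=True, random_state=config.seed, tol=0.0,
                       n_iter_no_change=10_000_000)
    history: List[Dict[str, float]] = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        for epoch in range(config.epochs):
            # one Adam epoch per call; optimizer moments persist across epochs
            est.partial_fit(Xn[tr], Y[tr])
            if config.lr_decay != 1.0:
                est._optimizer.learning_rate_init *= config.lr_decay
            train_loss = float(np.mean((est.predict(Xn[tr]) - Y[tr]) ** 2))
            rec = {"epoch": epoch + 1, "train_mse": train_loss}
            if len(va):
                rec["val_mse"] = float(np.mean((est.predict(Xn[va]) - Y[va]) ** 2))
            if not np.isfinite(train_loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
            history.append(rec)
            if config.log_every and (epoch + 1) % config.log_every == 0:
                import logging
                logging.getLogger(__name__).info("epoch %d: %s", epoch + 1, rec)

    return JointPredictor(backbone=est, input_size=size,
                          feature_size=config.feature_size,
                          norm_mean=mean, norm_std=std,
                          metadata={"epochs": config.epochs, "seed": config.seed,
                                    "final": history[-1], "history": history})


def predict(model: JointPredictor, image: CoronalImage) -> JointLabel2D:
    """Predicted (row, col) labels in the pixel coordinates of ``image``."""
    x = model.features(image)
    y = np.asarray(model.backbone.predict(x[None, :])[0], dtype=float)
    size = model.input_size
    coords = {}
    for j, name in enumerate(model.target_joints):
        coords[name] = (float(y[2 * j] * size - 0.5), float(y[2 * j + 1] * size - 0.5))
    return JointLabel2D(coords=coords)


def mpjpe(predictions: Sequence[JointLabel2D], ground_truth: Sequence[JointLabel2D],
          spacing) -> MPJPEReport:
    """Mean per-joint position error between matched label sets.

    ``spacing`` is a (row_mm, col_mm) pair applied to every sample, or a
    sequence of such pairs (one per sample).  Euclidean errors are reported
    per joint; superior-inferior (row) and left-right (column) absolute
    errors are also summarized separately.
    """
    if len(predictions) != len(ground_truth):
        raise InvalidInputError("prediction/ground-truth counts differ")
    if len(predictions) == 0:
        raise InvalidInputError("empty evaluation set")
    joints = tuple(ground_truth[0].coords.keys())
    sp = np.asarray(spacing, dtype=float)
    if sp.ndim == 1:
        sp = np.tile(sp, (len(predictions), 1))
    d_si, d_lr = [], []
    per_joint: Dict[str, List[float]] = {j: [] for j in joints}
    for i, (p, g) in enumerate(zip(predictions, ground_truth)):
        if set(p.coords) != set(g.coords):
            raise InvalidInputError("mismatched joint sets")
        for name in joints:
            dr = (p.coords[name][0] - g.coords[name][0]) * sp[i, 0]
            dc = (p.coords[name][1] - g.coords[name][1]) * sp[i, 1]
            per_joint[name].append(float(np.hypot(dr, dc)))
            d_si.append(abs(dr))
            d_lr.append(abs(dc))
    all_euclid = np.concatenate([np.asarray(v) for v in per_joint.values()])
    d_si = np.asarray(d_si)
    d_lr = np.asarray(d_lr)
    return MPJPEReport(
        per_joint_mm={k: float(np.mean(v)) for k, v in per_joint.items()},
        mean_mm=float(all_euclid.mean()), sd_mm=float(all_euclid.std()),
        si_mean_mm=float(d_si.mean()), si_sd_mm=float(d_si.std()),
        lr_mean_mm=float(d_lr.mean()), lr_sd_mm=float(d_lr.std()),
        n=len(predictions))


def save_checkpoint(model: JointPredictor, path) -> None:
    joblib.dump({"format": CHECKPOINT_FORMAT, "model": model}, path)


def load_checkpoint(path) -> JointPredictor:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != CHECKPOINT_FORMAT:
        raise InvalidInputError(f"not a joint-model checkpoint: {path}")
    return blob["model"]
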