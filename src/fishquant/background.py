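"""Rolling-ball background estimation and regression-based thresholding.

The background under diffraction-scale spots is estimated by grayscale
opening with a flat disk ("rolling ball", default radius 15 px) and
subtracted.  The residual-noise threshold for a given image is then
predicted by an ordinary-least-squares model tau = a*mean + b*sd + c
calibrated against F1-optimal thresholds computed on images with known
signal masks — mirroring a regression-thresholding stage trained once and
applied automatically per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import (
    DegenerateThresholdError,
    InvalidParameterError,
    RankDeficiencyError,
)

DEFAULT_BALL_RADIUS_PX = 15


def rolling_ball_background(image: np.ndarray, radius_px: int = DEFAULT_BALL_RADIUS_PX) -> np.ndarray:
    """Grayscale opening (erosion then dilation) with a flat disk.

    The image is reflect-padded by the radius before each morphological step
    so the opening is exact on the original support; the result is pointwise
    <= the image and idempotent.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("rolling-ball background requires a 2-D image")
    if radius_px < 1:
        raise InvalidParameterError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(image.shape):
        raise InvalidParameterError("radius larger than the image")
    fp = disk(radius_px)
    r = radius_px
    padded = np.pad(image, 2 * r, mode="reflect")
    eroded = ndimage.grey_erosion(padded, footprint=fp, mode="nearest")
    opened = ndimage.grey_dilation(eroded, footprint=fp, mode="nearest")
    return opened[2 * r : -2 * r, 2 * r : -2 * r]


def subtract_background(image: np.ndarray, radius_px: int = DEFAULT_BALL_RADIUS_PX) -> np.ndarray:
    """Image minus its rolling-ball background, clipped at zero."""
    image = np.asarray(image, dtype=float)
    return np.clip(image - rolling_ball_background(image, radius_px), 0.0, None)


def optimal_threshold(image: np.ndarray, truth_mask: np.ndarray) -> float:
    """Intensity threshold maximising pixelwise F1 against a known signal mask.

    Candidates are the image's unique intensity values (pixels kept when
    strictly above the threshold); ties are broken toward the smaller value.
    """
    image = np.asarray(image, dtype=float).ravel()
    mask = np.asarray(truth_mask, dtype=bool).ravel()
    if image.shape != mask.shape:
        raise InvalidParameterError("image and truth_mask shapes differ")
    n_pos = int(mask.sum())
    if n_pos == 0:
        raise DegenerateThresholdError("truth_mask marks no signal pixels")

    values = np.unique(image)
    # counts of signal / background pixels at each unique value
    sig_counts = np.bincount(
        np.searchsorted(values, image[mask]), minlength=len(values)
    )
    bg_counts = np.bincount(
        np.searchsorted(values, image[~mask]), minlength=len(values)
    )
    # pixels strictly above values[k]: totals minus cumulative up to k
    tp = n_pos - np.cumsum(sig_counts)
    fp = (image.size - n_pos) - np.cumsum(bg_counts)
    fn = n_pos - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    if f1.max() <= 0.0:
        raise DegenerateThresholdError("no threshold separates signal from background")
    return float(values[int(np.argmax(f1))])  # argmax returns the first (smallest) maximiser


@dataclass
class ThresholdModel:
    """OLS model tau = coef_mean*mean(image) + coef_sd*sd(image) + intercept."""

    coef_mean: float
    coef_sd: float
    intercept: float
    r: float = float("nan")
    n_calibration: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef_mean": self.coef_mean,
                "coef_sd": self.coef_sd,
                "intercept": self.intercept,
                "r": self.r,
                "n_calibration": self.n_calibration,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        return cls(**json.loads(text))


def fit_threshold_model(calibration: Sequence) -> ThresholdModel:
    """OLS of optimum threshold on (image mean, image sd) with intercept.

    ``calibration`` is an iterable of (mean, sd, tau_opt) triples; the Pearson
    correlation between fitted and observed optima is recorded as ``r``.
    """
    pts = np.asarray(list(calibration), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise InvalidParameterError("need >= 3 calibration points of (mean, sd, tau_opt)")
    X = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficiencyError("calibration design is collinear")
    coef, _, _, _ = np.linalg.lstsq(X, pts[:, 2], rcond=None)
    fitted = X @ coef
    obs = pts[:, 2]
    if fitted.std() == 0 or obs.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, obs)[0, 1])
    return ThresholdModel(
        coef_mean=float(coef[0]),
        coef_sd=float(coef[1]),
        intercept=float(coef[2]),
        r=r,
        n_calibration=len(pts),
    )


def estimate_threshold(model: ThresholdModel, image: np.ndarray) -> float:
    """Predicted threshold for an image from its mean and SD, floored at 0."""
    image = np.asarray(image, dtype=float)
    tau = model.coef_mean * image.mean() + model.coef_sd * image.std() + model.intercept
    return max(0.0, float(tau))


def apply_threshold(image: np.ndarray, tau: float) -> np.ndarray:
    """Zero every pixel <= tau (strict > keeps a pixel)."""
    if tau < 0:
        raise InvalidParameterError("threshold must be >= 0")
    image = np.asarray(image, dtype=float)
    return np.where(image > tau, image, 0.0)
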