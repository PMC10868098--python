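"""Self-supervised blind-spot denoising.

Each pixel is predicted from its square neighbourhood *excluding the pixel
itself* (the blind spot), so pixel-independent noise cannot be reproduced
and is suppressed while structure shared with the neighbourhood survives.
Two desk-scale predictors implement the principle: a masked-neighbourhood
median (training-free) and a linear regressor fitted by least squares on
randomly masked training pixels.  A deep network could be slotted behind the
same interface; the self-supervision contract (the predictor never sees the
centre pixel) is identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DimensionError, InvalidParameterError
from .stackio import FrameStack


def _offsets(radius: int) -> list:
    """Neighbourhood offsets within Chebyshev ``radius``, centre excluded."""
    return [
        (di, dj)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
        if (di, dj) != (0, 0)
    ]


@dataclass
class BlindSpotModel:
    """A trained (or training-free) blind-spot pixel predictor."""

    kind: str = "median"  # "median" or "linear"
    radius: int = 1
    weights: Optional[np.ndarray] = None  # per-offset coefficients (linear)
    bias: float = 0.0
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("median", "linear"):
            raise InvalidParameterError(f"unknown predictor kind: {self.kind}")
        if self.radius < 1:
            raise InvalidParameterError("neighbourhood radius must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "radius": self.radius,
                "weights": None if self.weights is None else np.asarray(self.weights).tolist(),
                "bias": self.bias,
                "training": self.training,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BlindSpotModel":
        d = json.loads(text)
        w = d.get("weights")
        return cls(
            kind=d["kind"],
            radius=d["radius"],
            weights=None if w is None else np.asarray(w, dtype=float),
            bias=d.get("bias", 0.0),
            training=d.get("training", {}),
        )


def _neighbor_stack(frame: np.ndarray, radius: int) -> np.ndarray:
    """(n_offsets, H, W) array of neighbour values, reflective borders."""
    padded = np.pad(frame, radius, mode="reflect")
    h, w = frame.shape
    return np.stack(
        [
            padded[radius + di : radius + di + h, radius + dj : radius + dj + w]
            for di, dj in _offsets(radius)
        ]
    )


def train_blindspot(
    frames,
    kind: str = "linear",
    radius: int = 1,
    mask_fraction: float = 0.05,
    seed: int = 0,
) -> BlindSpotModel:
    """Fit a blind-spot predictor on raw frames.

    For ``kind="linear"`` a fraction of pixels per frame is masked and a
    least-squares regression predicts each masked pixel from its neighbours;
    ``kind="median"`` needs no training and simply records the radius.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise InvalidParameterError("need at least one training frame")
    if not (0.0 < mask_fraction <= 0.5):
        raise InvalidParameterError("mask_fraction must lie in (0, 0.5]")
    side = 2 * radius + 1
    if any(min(f.shape) < side for f in frames):
        raise DimensionError(f"frames must be at least {side}x{side} for radius {radius}")
    if kind == "median":
        return BlindSpotModel(kind="median", radius=radius)

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for f in frames:
        neigh = _neighbor_stack(f, radius)
        n_px = f.size
        n_pick = max(1, int(round(mask_fraction * n_px)))
        flat_idx = rng.choice(n_px, size=n_pick, replace=False)
        xs.append(neigh.reshape(len(neigh), -1)[:, flat_idx].T)
        ys.append(f.ravel()[flat_idx])
    X = np.vstack(xs)
    y = np.concatenate(ys)
    design = np.column_stack([X, np.ones(len(X))])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    loss = float(np.mean(resid**2))
    return BlindSpotModel(
        kind="linear",
        radius=radius,
        weights=coef[:-1],
        bias=float(coef[-1]),
        training={
            "n_frames": len(frames),
            "n_pixels": int(len(y)),
            "mask_fraction": mask_fraction,
            "seed": seed,
            "final_loss": loss,
        },
    )


def _predict_frame(model: BlindSpotModel, frame: np.ndarray) -> np.ndarray:
    neigh = _neighbor_stack(np.asarray(frame, dtype=float), model.radius)
    if model.kind == "median":
        pred = np.median(neigh, axis=0)
    else:
        pred = np.tensordot(model.weights, neigh, axes=(0, 0)) + model.bias
    return np.clip(pred, 0.0, None)


def denoise_stack(model: BlindSpotModel, stack: FrameStack) -> FrameStack:
    """Replace every pixel of every frame by its blind-spot prediction."""
    side = 2 * model.radius + 1
    if min(stack.data.shape[1:]) < side:
        raise DimensionError("frames smaller than the model neighbourhood")
    out = np.empty(stack.data.shape, dtype=float)
    for t in range(stack.n_frames):
        out[t] = _predict_frame(model, stack.data[t])
    return FrameStack(
        data=out,
        pixel_size_nm=stack.pixel_size_nm,
        channel=stack.channel,
        exposure_ms=stack.exposure_ms,
        metadata={**stack.metadata, "denoised": model.kind},
    )


def denoise_frame(model: BlindSpotModel, frame: np.ndarray) -> np.ndarray:
    """Blind-spot prediction of a single 2-D frame."""
    return _predict_frame(model, frame)
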