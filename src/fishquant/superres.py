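"""Single-molecule localization and super-resolution rendering.

Blinking emitters are detected frame-by-frame as thresholded local maxima
and fitted with a symmetric integrated 2-D Gaussian by damped (Levenberg-
Marquardt) least squares, vectorised over all spots of a stack at once.
Localizations are rendered at ~20 nm pixels; the conventional-resolution
counterpart is a plain pixel-wise projection of the raw frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .background import ThresholdModel, rolling_ball_background, DEFAULT_BALL_RADIUS_PX
from .errors import DimensionError, InvalidParameterError
from .stackio import LOCALIZATION_COLUMNS, FrameStack, empty_localizations

_SQRT2PI = math.sqrt(2.0 * math.pi)


def widefield_projection(stack: FrameStack, mode: str = "mean") -> np.ndarray:
    """Diffraction-limited image: pixel-wise reduction of the raw frames."""
    if stack.n_frames < 1:
        raise DimensionError("empty stack")
    data = stack.data
    if mode == "mean":
        return data.mean(axis=0, dtype=np.float64)
    if mode == "sum":
        return data.sum(axis=0, dtype=np.float64)
    if mode == "max":
        return data.max(axis=0).astype(np.float64)
    raise InvalidParameterError(f"unknown projection mode: {mode}")


def detect_candidates(frame: np.ndarray, tau: float, min_separation_px: float = 2.0) -> list:
    """Integer peak pixels: 8-connected local maxima strictly above tau.

    Maxima closer than ``min_separation_px`` are merged to the brighter one.
    Returns a list of (row, col) tuples.
    """
    frame = np.asarray(frame, dtype=float)
    mf = ndimage.maximum_filter(frame, size=3, mode="nearest")
    peaks = np.argwhere((frame >= mf) & (frame > tau))
    if len(peaks) == 0:
        return []
    vals = frame[peaks[:, 0], peaks[:, 1]]
    return _suppress_close(peaks, vals, min_separation_px)


def _suppress_close(peaks: np.ndarray, vals: np.ndarray, min_sep: float) -> list:
    order = np.argsort(-vals, kind="stable")
    kept: list = []
    for k in order:
        p = peaks[k]
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in kept):
            kept.append((int(p[0]), int(p[1])))
    return kept


def _profiles(edges: np.ndarray, centers: np.ndarray, sigmas: np.ndarray):
    """Integrated-Gaussian pixel profiles and their derivatives, batched.

    Returns (E, dE_dc, dE_ds), each (M, n_pixels), for 1-D Gaussians with
    per-spot ``centers`` and ``sigmas`` integrated over unit pixels.
    """
    u = (edges[None, :] - centers[:, None]) / sigmas[:, None]
    cdf = ndtr(u)
    pdf = np.exp(-0.5 * u * u) / _SQRT2PI
    E = np.diff(cdf, axis=1)
    dE_dc = -(pdf[:, 1:] - pdf[:, :-1]) / sigmas[:, None]
    dE_ds = -(u[:, 1:] * pdf[:, 1:] - u[:, :-1] * pdf[:, :-1]) / sigmas[:, None]
    return E, dE_dc, dE_ds


def _model_and_jacobian(params: np.ndarray, w: int):
    """Model images and Jacobian for p = (flux, x, y, sigma, offset)."""
    N, x, y, s, b = params.T
    edges = np.arange(w + 1, dtype=float)
    Ex, dEx_dx, dEx_ds = _profiles(edges, x, s)
    Ey, dEy_dy, dEy_ds = _profiles(edges, y, s)
    shape2 = Ey[:, :, None] * Ex[:, None, :]
    model = N[:, None, None] * shape2 + b[:, None, None]
    M = len(params)
    J = np.empty((M, w * w, 5))
    J[:, :, 0] = shape2.reshape(M, -1)
    J[:, :, 1] = (N[:, None, None] * Ey[:, :, None] * dEx_dx[:, None, :]).reshape(M, -1)
    J[:, :, 2] = (N[:, None, None] * dEy_dy[:, :, None] * Ex[:, None, :]).reshape(M, -1)
    J[:, :, 3] = (
        N[:, None, None]
        * (dEy_ds[:, :, None] * Ex[:, None, :] + Ey[:, :, None] * dEx_ds[:, None, :])
    ).reshape(M, -1)
    J[:, :, 4] = 1.0
    return model.reshape(M, -1), J


def fit_gaussian_spots(
    windows: np.ndarray,
    expected_sigma_px: float,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Batched LM least-squares fit of symmetric integrated 2-D Gaussians.

    ``windows`` is (M, w, w).  Returns (params, converged): params (M, 5) as
    (flux, x, y, sigma, offset) in window pixel coordinates (pixel j spans
    [j, j+1)), and a boolean convergence mask.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[None]
    M, w, w2 = windows.shape
    if w != w2:
        raise DimensionError("fit windows must be square")
    data = windows.reshape(M, -1)

    # analytic initial guess: border-median offset, centroid, plug-in sigma
    border = np.concatenate(
        [windows[:, 0, :], windows[:, -1, :], windows[:, :, 0], windows[:, :, -1]], axis=1
    )
    b0 = np.median(border, axis=1)
    sub = np.clip(windows - b0[:, None, None], 0.0, None)
    tot = sub.sum(axis=(1, 2))
    tot_safe = np.where(tot > 0, tot, 1.0)
    jj = np.arange(w) + 0.5
    x0 = (sub.sum(axis=1) * jj).sum(axis=1) / tot_safe
    y0 = (sub.sum(axis=2) * jj).sum(axis=1) / tot_safe
    params = np.column_stack(
        [
            np.where(tot > 0, tot, 1.0),
            np.where(tot > 0, x0, w / 2.0),
            np.where(tot > 0, y0, w / 2.0),
            np.full(M, expected_sigma_px),
            b0,
        ]
    )

    lam = np.full(M, 1e-3)
    model, J = _model_and_jacobian(params, w)
    resid = data - model
    cost = (resid**2).sum(axis=1)
    active = np.ones(M, dtype=bool)
    converged = np.zeros(M, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        Ja = J[idx]
        ra = resid[idx]
        JTJ = np.einsum("mki,mkj->mij", Ja, Ja)
        JTr = np.einsum("mki,mk->mi", Ja, ra)
        diag = np.einsum("mii->mi", JTJ).copy()
        diag = np.where(diag > 1e-12, diag, 1e-12)
        A = JTJ + lam[idx, None, None] * diag[:, None, :] * np.eye(5)[None]
        try:
            step = np.linalg.solve(A, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(a, g, rcond=None)[0] for a, g in zip(A, JTr)])
        trial = params[idx] + step
        # keep parameters in a sane box while iterating
        trial[:, 3] = np.clip(trial[:, 3], 0.05, 2.0 * w)
        trial[:, 1] = np.clip(trial[:, 1], -1.0, w + 1.0)
        trial[:, 2] = np.clip(trial[:, 2], -1.0, w + 1.0)
        t_model, t_J = _model_and_jacobian(trial, w)
        t_resid = data[idx] - t_model
        t_cost = (t_resid**2).sum(axis=1)
        better = t_cost <= cost[idx]
        imp = np.abs(cost[idx] - t_cost) <= tol * np.maximum(cost[idx], 1e-30)
        params[idx[better]] = trial[better]
        model[idx[better]] = t_model[better]
        J[idx[better]] = t_J[better]
        resid[idx[better]] = t_resid[better]
        cost[idx[better]] = t_cost[better]
        lam[idx[better]] /= 3.0
        lam[idx[~better]] *= 4.0
        done = (better & imp) | (lam[idx] > 1e8)
        converged[idx[better & imp]] = True
        active[idx[done]] = False

    return params, converged


@dataclass
class FitConfig:
    window_px: int = 7
    expected_sigma_nm: float = 130.0
    gain: float = 1.0
    sigma_bounds: tuple = (0.5, 4.0)  # relative to expected PSF sigma
    max_iter: int = 100
    tol: float = 1e-8


def _accept(params: np.ndarray, converged: np.ndarray, cfg: FitConfig, pixel_size_nm: float):
    sigma_lo = cfg.sigma_bounds[0] * cfg.expected_sigma_nm / pixel_size_nm
    sigma_hi = cfg.sigma_bounds[1] * cfg.expected_sigma_nm / pixel_size_nm
    w = cfg.window_px
    return (
        converged
        & (params[:, 0] > 0)
        & (params[:, 3] >= sigma_lo)
        & (params[:, 3] <= sigma_hi)
        & (params[:, 1] > 0)
        & (params[:, 1] < w)
        & (params[:, 2] > 0)
        & (params[:, 2] < w)
    )


def fit_gaussian_spot(
    frame: np.ndarray,
    peak,
    window_px: int = 7,
    pixel_size_nm: float = 100.0,
    expected_sigma_nm: float = 130.0,
    gain: float = 1.0,
) -> Optional[dict]:
    """Sub-pixel fit of one spot; None if the fit is rejected.

    The returned record carries nanometre coordinates, the fitted PSF sigma,
    photons (flux / gain) and a Thompson-style uncertainty sigma/sqrt(N).
    """
    frame = np.asarray(frame, dtype=float)
    half = window_px // 2
    i, j = int(peak[0]), int(peak[1])
    if not (half <= i < frame.shape[0] - half and half <= j < frame.shape[1] - half):
        raise InvalidParameterError("fit window does not fit inside the frame")
    window = frame[i - half : i + half + 1, j - half : j + half + 1]
    cfg = FitConfig(window_px=window_px, expected_sigma_nm=expected_sigma_nm, gain=gain)
    params, converged = fit_gaussian_spots(
        window[None], expected_sigma_nm / pixel_size_nm, cfg.max_iter, cfg.tol
    )
    if not _accept(params, converged, cfg, pixel_size_nm)[0]:
        return None
    flux, x, y, s, b = params[0]
    photons = flux / gain
    return {
        "x_nm": (j - half + x) * pixel_size_nm,
        "y_nm": (i - half + y) * pixel_size_nm,
        "sigma_nm": s * pixel_size_nm,
        "photons": photons,
        "background": b,
        "uncertainty_nm": s * pixel_size_nm / math.sqrt(max(photons, 1e-12)),
    }


def _per_frame_thresholds(sub: np.ndarray, threshold) -> np.ndarray:
    """Per-frame detection thresholds from a model, scalar or robust default."""
    T = sub.shape[0]
    if isinstance(threshold, ThresholdModel):
        means = sub.mean(axis=(1, 2))
        sds = sub.std(axis=(1, 2))
        tau = threshold.coef_mean * means + threshold.coef_sd * sds + threshold.intercept
        return np.clip(tau, 0.0, None)
    if threshold is None:
        med = np.median(sub, axis=(1, 2))
        mad = np.median(np.abs(sub - med[:, None, None]), axis=(1, 2))
        return med + 5.0 * 1.4826 * np.maximum(mad, 1e-6)
    return np.full(T, float(threshold))


def localize_stack(
    stack: FrameStack,
    threshold=None,
    fit: Optional[FitConfig] = None,
    ball_radius_px: int = DEFAULT_BALL_RADIUS_PX,
    subtract_static_background: bool = True,
    min_separation_px: float = 2.0,
    frame_range: Optional[tuple] = None,
) -> pd.DataFrame:
    """Detect and fit emitters on every frame of a stack.

    The static autofluorescence background (rolling ball of the temporal
    mean) is subtracted from each frame, and pixels below the per-frame
    background threshold (a :class:`ThresholdModel`, a scalar, or a robust
    MAD rule when ``threshold`` is None) are zeroed.  Spots are detected as
    local maxima of the 3x3 box sum of the thresholded frame above a robust
    per-frame floor (an integrated-intensity criterion: single thresholded
    noise pixels do not look like a diffraction-limited spot), then fitted
    on the unthresholded subtracted frame.  Returns a localization table;
    the count of rejected fits is stored in ``table.attrs['n_rejected']``.
    """
    cfg = fit or FitConfig()
    data = stack.data.astype(np.float32)
    if frame_range is not None:
        data = data[frame_range[0] : frame_range[1]]
    if subtract_static_background:
        static = rolling_ball_background(data.mean(axis=0, dtype=np.float64), ball_radius_px)
        sub = np.clip(data - static.astype(np.float32), 0.0, None)
    else:
        sub = data
    tau = _per_frame_thresholds(sub, threshold)

    thresholded = np.where(sub > tau[:, None, None], sub, np.float32(0.0))
    boxsum = ndimage.uniform_filter(thresholded, size=(1, 3, 3), mode="nearest") * 9.0
    # detection floor from the un-thresholded box sums (stable statistics)
    raw_box = ndimage.uniform_filter(sub, size=(1, 3, 3), mode="nearest") * 9.0
    med = np.median(raw_box, axis=(1, 2))
    mad = np.median(np.abs(raw_box - med[:, None, None]), axis=(1, 2))
    floor = med + 5.0 * 1.4826 * np.maximum(mad, 1e-6)
    del raw_box

    mf = ndimage.maximum_filter(boxsum, size=(1, 3, 3), mode="nearest")
    cand_mask = (boxsum >= mf) & (boxsum > floor[:, None, None]) & (thresholded > 0)
    half = cfg.window_px // 2
    cand_mask[:, :half, :] = False
    cand_mask[:, -half:, :] = False
    cand_mask[:, :, :half] = False
    cand_mask[:, :, -half:] = False
    t_idx, i_idx, j_idx = np.nonzero(cand_mask)
    if len(t_idx) == 0:
        table = empty_localizations()
        table.attrs["n_rejected"] = 0
        return table

    # merge per-frame maxima closer than min_separation_px (brighter wins)
    keep_t, keep_i, keep_j = [], [], []
    for t in np.unique(t_idx):
        sel = t_idx == t
        peaks = np.column_stack([i_idx[sel], j_idx[sel]])
        vals = sub[t, peaks[:, 0], peaks[:, 1]]
        for pi, pj in _suppress_close(peaks, vals, min_separation_px):
            keep_t.append(t)
            keep_i.append(pi)
            keep_j.append(pj)
    t_idx = np.asarray(keep_t)
    i_idx = np.asarray(keep_i)
    j_idx = np.asarray(keep_j)

    w = cfg.window_px
    ii = np.arange(w)
    windows = sub[
        t_idx[:, None, None],
        (i_idx - half)[:, None, None] + ii[None, :, None],
        (j_idx - half)[:, None, None] + ii[None, None, :],
    ]
    params, converged = fit_gaussian_spots(
        windows, cfg.expected_sigma_nm / stack.pixel_size_nm, cfg.max_iter, cfg.tol
    )
    ok = _accept(params, converged, cfg, stack.pixel_size_nm)

    flux, x, y, s, b = params[ok].T
    photons = flux / cfg.gain
    px = stack.pixel_size_nm
    table = pd.DataFrame(
        {
            "frame": t_idx[ok],
            "x_nm": (j_idx[ok] - half + x) * px,
            "y_nm": (i_idx[ok] - half + y) * px,
            "sigma_nm": s * px,
            "photons": photons,
            "background": b,
            "uncertainty_nm": s * px / np.sqrt(np.maximum(photons, 1e-12)),
        }
    )
    table.attrs["n_rejected"] = int((~ok).sum())
    return table.reset_index(drop=True)


def render_superres(
    table: pd.DataFrame,
    render_px_nm: float = 20.0,
    mode: str = "histogram",
    extent_nm: Optional[tuple] = None,
) -> np.ndarray:
    """Render a localization table as a super-resolution image.

    ``histogram`` bins localization positions (image sum equals the row
    count exactly); ``gaussian`` splats each localization as an integrated
    Gaussian of width ``uncertainty_nm`` (sum equals the row count up to
    edge losses).  ``extent_nm`` is (width_nm, height_nm); it defaults to
    the data extent.
    """
    if render_px_nm <= 0:
        raise InvalidParameterError("render_px_nm must be positive")
    if extent_nm is None:
        if len(table) == 0:
            return np.zeros((1, 1))
        extent_nm = (float(table["x_nm"].max()) + render_px_nm,
                     float(table["y_nm"].max()) + render_px_nm)
    nx = int(math.ceil(extent_nm[0] / render_px_nm))
    ny = int(math.ceil(extent_nm[1] / render_px_nm))
    img = np.zeros((ny, nx))
    if len(table) == 0:
        return img
    xs = np.asarray(table["x_nm"], dtype=float) / render_px_nm
    ys = np.asarray(table["y_nm"], dtype=float) / render_px_nm
    if mode == "histogram":
        jj = np.clip(xs.astype(int), 0, nx - 1)
        ii = np.clip(ys.astype(int), 0, ny - 1)
        np.add.at(img, (ii, jj), 1.0)
        return img
    if mode != "gaussian":
        raise InvalidParameterError(f"unknown render mode: {mode}")
    sig = np.maximum(np.asarray(table["uncertainty_nm"], dtype=float) / render_px_nm, 1e-3)
    for x, y, s in zip(xs, ys, sig):
        pad = int(math.ceil(4 * s)) + 1
        j0, j1 = max(0, int(x) - pad), min(nx, int(x) + pad + 1)
        i0, i1 = max(0, int(y) - pad), min(ny, int(y) + pad + 1)
        if j1 <= j0 or i1 <= i0:
            continue
        ex = np.diff(ndtr((np.arange(j0, j1 + 1) - x) / s))
        ey = np.diff(ndtr((np.arange(i0, i1 + 1) - y) / s))
        img[i0:i1, j0:j1] += np.outer(ey, ex)
    return img
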