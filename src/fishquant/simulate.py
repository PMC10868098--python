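"""Synthetic blinking-emitter acquisition simulator.

Emulates a single-molecule FISH acquisition: each FISH locus carries a handful
of fluorophores that blink stochastically across thousands of 30-ms frames;
frames are the Poisson-sampled sum of the emitters' diffraction-limited PSFs
and a smooth autofluorescence background, plus Gaussian camera read noise.
The simulator returns full ground truth (nucleus masks, locus positions,
per-nucleus signal counts) so every downstream stage can be scored.

Coordinate convention: continuous positions in nanometres; pixel (i, j)
spans [j*p, (j+1)*p) x [i*p, (i+1)*p) nm with p the pixel pitch, origin at
the top-left, x rightward (columns), y downward (rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .errors import CoordinateRangeError, InvalidParameterError, PlacementError
from .stackio import FrameStack


@dataclass
class SimulationParams:
    """Study conditions for one simulated acquisition field.

    Frame counts (5000 signal / 1000 DAPI), 30-ms exposure, ~130-nm PSF sigma
    and 100-nm pixel pitch reflect the acquisition being emulated; photon
    budget, blink kinetics and background shape are engineering choices (the
    instrument's gain and kinetics are not public).
    """

    field_px: int = 96
    pixel_size_nm: float = 100.0
    n_frames_signal: int = 5000
    n_frames_dapi: int = 1000
    n_nuclei: int = 3
    nucleus_radius_px: tuple = (11.0, 14.0)
    her2_per_nucleus: int = 2
    cep17_per_nucleus: int = 2
    emitters_per_signal: int = 8
    signal_extent_nm: float = 80.0
    p_on: float = 0.005
    mean_photons: float = 1500.0
    psf_sigma_nm: float = 130.0
    background_amplitude: float = 30.0
    background_corr_len_px: float = 48.0
    background_offset: float = 100.0
    read_noise_sd: float = 3.0
    dapi_brightness: float = 150.0
    cluster_fraction: float = 0.0
    cluster_signals: int = 5
    min_signal_separation_nm: float = 600.0
    allow_nucleus_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.field_px < 32:
            raise InvalidParameterError("field_px must be >= 32")
        if self.pixel_size_nm <= 0 or self.psf_sigma_nm <= 0:
            raise InvalidParameterError("pixel_size_nm and psf_sigma_nm must be positive")
        if not (0.0 < self.p_on < 1.0):
            raise InvalidParameterError("p_on must lie in (0, 1)")
        for name in (
            "n_frames_signal",
            "n_frames_dapi",
            "n_nuclei",
            "her2_per_nucleus",
            "cep17_per_nucleus",
            "emitters_per_signal",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_frames_signal < 1 or self.n_frames_dapi < 1:
            raise InvalidParameterError("frame counts must be >= 1")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise InvalidParameterError("cluster_fraction must lie in [0, 1]")
        if self.cluster_signals <= 4:
            raise InvalidParameterError("cluster loci must carry more than four signals")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Nucleus:
    id: int
    centroid_nm: tuple
    semi_axes_px: tuple
    angle_rad: float
    mask: np.ndarray


@dataclass
class SignalTruth:
    channel: str
    nucleus_id: int
    centroid_nm: tuple
    emitters_nm: np.ndarray  # (k, 2) emitter positions
    is_cluster: bool = False


@dataclass
class GroundTruth:
    nuclei: list
    signals: list
    per_nucleus_counts: pd.DataFrame
    background_fields: dict = field(default_factory=dict)

    def emitters(self, channel: str) -> np.ndarray:
        """All emitter positions (nm) of one channel, stacked (N, 2)."""
        arrs = [s.emitters_nm for s in self.signals if s.channel == channel]
        if not arrs:
            return np.zeros((0, 2))
        return np.vstack(arrs)

    def nucleus_mask_image(self, shape) -> np.ndarray:
        """Label image of the true nuclei (0 = background)."""
        lab = np.zeros(shape, dtype=int)
        for nuc in self.nuclei:
            lab[nuc.mask] = nuc.id
        return lab

    def to_json_dict(self) -> dict:
        return {
            "nuclei": [
                {
                    "id": n.id,
                    "centroid_nm": list(n.centroid_nm),
                    "semi_axes_px": list(n.semi_axes_px),
                    "angle_rad": n.angle_rad,
                }
                for n in self.nuclei
            ],
            "signals": [
                {
                    "channel": s.channel,
                    "nucleus_id": s.nucleus_id,
                    "centroid_nm": list(s.centroid_nm),
                    "emitters_nm": np.asarray(s.emitters_nm).tolist(),
                    "is_cluster": s.is_cluster,
                }
                for s in self.signals
            ],
            "per_nucleus_counts": self.per_nucleus_counts.to_dict(orient="records"),
        }


def make_background_field(
    field_px: int,
    amplitude: float,
    corr_len_px: float,
    offset: float,
    seed=None,
) -> np.ndarray:
    """Smooth non-negative autofluorescence field.

    A white Gaussian field is smoothed to the requested correlation length,
    standardised, and pushed through the normal CDF, so each pixel's marginal
    is uniform on (0, 1): the per-pixel mean is exactly offset + amplitude/2.
    """
    if field_px <= 0:
        raise InvalidParameterError("field_px must be positive")
    if amplitude < 0 or corr_len_px < 1:
        raise InvalidParameterError("amplitude must be >= 0 and corr_len_px >= 1")
    if offset < 0:
        raise InvalidParameterError("offset must be >= 0")
    if amplitude == 0:
        return np.full((field_px, field_px), float(offset))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((field_px, field_px))
    z = ndimage.gaussian_filter(z, sigma=corr_len_px, mode="wrap")
    sd = z.std()
    if sd == 0:  # pragma: no cover - astronomically unlikely
        return np.full((field_px, field_px), offset + amplitude / 2.0)
    return offset + amplitude * ndtr(z / sd)


def simulate_blinking_trace(
    n_frames: int,
    p_on: float = 0.005,
    mean_photons: float = 1500.0,
    seed=None,
) -> np.ndarray:
    """Per-frame photon counts of one stochastically blinking emitter.

    Each frame is independently "on" with probability ``p_on``; an on-frame
    emits Poisson(``mean_photons``) photons, an off-frame emits none.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if not (0.0 < p_on < 1.0):
        raise InvalidParameterError("p_on must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    on = rng.random(n_frames) < p_on
    photons = rng.poisson(mean_photons, size=n_frames).astype(float)
    return photons * on


def _pixel_profile(n: int, center_px: float, sigma_px: float) -> np.ndarray:
    """Integral of a unit 1-D Gaussian over each of n unit pixels."""
    edges = np.arange(n + 1, dtype=float)
    cdf = ndtr((edges - center_px) / sigma_px)
    return np.diff(cdf)


def emitter_image(
    shape,
    emitters: np.ndarray,
    psf_sigma_nm: float,
    pixel_size_nm: float,
) -> np.ndarray:
    """Noiseless image of point emitters with an integrated 2-D Gaussian PSF.

    ``emitters`` is (N, 3): x_nm, y_nm, photons.  The PSF is integrated over
    pixel areas (not sampled at pixel centres), so the pixel sum of each
    emitter's contribution equals its photon count up to edge losses.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    emitters = np.atleast_2d(np.asarray(emitters, dtype=float))
    if emitters.size == 0:
        return img
    sigma_px = psf_sigma_nm / pixel_size_nm
    pad = int(math.ceil(5 * sigma_px)) + 1
    for x_nm, y_nm, photons in emitters:
        x_px = x_nm / pixel_size_nm
        y_px = y_nm / pixel_size_nm
        if not (0 <= x_px < w and 0 <= y_px < h):
            raise CoordinateRangeError(f"emitter ({x_nm}, {y_nm}) nm outside the field")
        j0 = max(0, int(x_px) - pad)
        j1 = min(w, int(x_px) + pad + 1)
        i0 = max(0, int(y_px) - pad)
        i1 = min(h, int(y_px) + pad + 1)
        px = _pixel_profile(j1 - j0, x_px - j0, sigma_px)
        py = _pixel_profile(i1 - i0, y_px - i0, sigma_px)
        img[i0:i1, j0:j1] += photons * np.outer(py, px)
    return img


def synthesize_frame(
    active_emitters: np.ndarray,
    psf_sigma_nm: float,
    pixel_size_nm: float,
    background_field: np.ndarray,
    read_noise_sd: float = 0.0,
    seed=None,
    shot_noise: bool = True,
) -> np.ndarray:
    """One camera frame: Poisson(PSF-rendered emitters + background) + read noise.

    ``active_emitters`` is (N, 3): x_nm, y_nm, expected photons this frame.
    The result is clipped at zero.  With ``shot_noise=False`` the noiseless
    expectation (plus read noise if requested) is returned.
    """
    background_field = np.asarray(background_field, dtype=float)
    clean = emitter_image(background_field.shape, active_emitters, psf_sigma_nm, pixel_size_nm)
    clean = clean + background_field
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = rng.poisson(clean).astype(float) if shot_noise else clean.copy()
    if read_noise_sd > 0:
        frame = frame + rng.normal(0.0, read_noise_sd, size=frame.shape)
    return np.clip(frame, 0.0, None)


def _ellipse_mask(shape, cx_px, cy_px, a_px, b_px, angle) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx + 0.5 - cx_px
    y = yy + 0.5 - cy_px
    c, s = math.cos(angle), math.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _place_nuclei(params: SimulationParams, rng: np.random.Generator) -> list:
    shape = (params.field_px, params.field_px)
    occupied = np.zeros(shape, dtype=bool)
    nuclei = []
    r_lo, r_hi = params.nucleus_radius_px
    for nid in range(1, params.n_nuclei + 1):
        for attempt in range(500):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            angle = rng.uniform(0, math.pi)
            margin = max(a, b) + 3
            if 2 * margin >= params.field_px:
                raise PlacementError("nucleus too large for the field")
            cx = rng.uniform(margin, params.field_px - margin)
            cy = rng.uniform(margin, params.field_px - margin)
            mask = _ellipse_mask(shape, cx, cy, a, b, angle)
            grown = ndimage.binary_dilation(mask, iterations=2)
            if params.allow_nucleus_overlap or not (grown & occupied).any():
                occupied |= grown
                nuclei.append(
                    Nucleus(
                        id=nid,
                        centroid_nm=(cx * params.pixel_size_nm, cy * params.pixel_size_nm),
                        semi_axes_px=(a, b),
                        angle_rad=angle,
                        mask=mask,
                    )
                )
                break
        else:
            raise PlacementError(
                f"could not place nucleus {nid} without overlap after 500 attempts"
            )
    return nuclei


def _sample_loci_in_nucleus(
    nucleus: Nucleus,
    n_loci: int,
    min_sep_nm: float,
    pixel_size_nm: float,
    margin_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Locus centres (nm) inside the nucleus, pairwise >= min_sep_nm apart."""
    interior = ndimage.binary_erosion(nucleus.mask, iterations=margin_px)
    if not interior.any():
        interior = nucleus.mask
    ii, jj = np.nonzero(interior)
    for _restart in range(50):  # greedy sequential placement with restarts
        chosen: list = []
        ok_all = True
        for _ in range(n_loci):
            placed = False
            for _attempt in range(500):
                k = rng.integers(len(ii))
                x = (jj[k] + rng.random()) * pixel_size_nm
                y = (ii[k] + rng.random()) * pixel_size_nm
                if all(math.hypot(x - px, y - py) >= min_sep_nm for px, py in chosen):
                    chosen.append((x, y))
                    placed = True
                    break
            if not placed:
                ok_all = False
                break
        if ok_all:
            return np.asarray(chosen, dtype=float).reshape(n_loci, 2)
    raise PlacementError("could not place loci with the requested separation")


def _uniform_disc(center, radius, n, rng) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * math.pi, n)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


def _build_signals(params: SimulationParams, nuclei: list, rng: np.random.Generator) -> list:
    n_cluster = int(round(params.cluster_fraction * len(nuclei)))
    cluster_ids = set(
        rng.choice([n.id for n in nuclei], size=n_cluster, replace=False).tolist()
        if n_cluster
        else []
    )
    signals = []
    extent_r = params.signal_extent_nm / 2.0
    for nuc in nuclei:
        has_cluster = nuc.id in cluster_ids
        n_her2 = params.her2_per_nucleus
        n_cep17 = params.cep17_per_nucleus
        n_loci = n_her2 + n_cep17 + (1 if has_cluster else 0)
        loci = _sample_loci_in_nucleus(
            nuc,
            n_loci,
            params.min_signal_separation_nm,
            params.pixel_size_nm,
            margin_px=3,
            rng=rng,
        )
        idx = 0
        for _ in range(n_her2):
            center = loci[idx]
            idx += 1
            signals.append(
                SignalTruth(
                    channel="HER2",
                    nucleus_id=nuc.id,
                    centroid_nm=tuple(center),
                    emitters_nm=_uniform_disc(center, extent_r, params.emitters_per_signal, rng),
                )
            )
        if has_cluster:
            # k > 4 signals co-located within signal_extent_nm: unresolvable as
            # separate spots at diffraction-limited resolution.
            cluster_center = loci[idx]
            idx += 1
            sub_centers = _uniform_disc(
                cluster_center, params.signal_extent_nm, params.cluster_signals, rng
            )
            for sc in sub_centers:
                signals.append(
                    SignalTruth(
                        channel="HER2",
                        nucleus_id=nuc.id,
                        centroid_nm=tuple(sc),
                        emitters_nm=_uniform_disc(sc, extent_r, params.emitters_per_signal, rng),
                        is_cluster=True,
                    )
                )
        for _ in range(n_cep17):
            center = loci[idx]
            idx += 1
            signals.append(
                SignalTruth(
                    channel="CEP17",
                    nucleus_id=nuc.id,
                    centroid_nm=tuple(center),
                    emitters_nm=_uniform_disc(center, extent_r, params.emitters_per_signal, rng),
                )
            )
    return signals


def _render_blinking_stack(
    emitters_nm: np.ndarray,
    n_frames: int,
    params: SimulationParams,
    background: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Poisson camera stack of blinking emitters over a static background."""
    h = w = params.field_px
    n_e = len(emitters_nm)
    sigma_px = params.psf_sigma_nm / params.pixel_size_nm
    pad = int(math.ceil(5 * sigma_px)) + 1
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    on = (
        rng.random((n_frames, n_e)) < params.p_on
        if n_e
        else np.zeros((n_frames, 0), dtype=bool)
    )
    for t0 in range(0, n_frames, chunk):
        t1 = min(t0 + chunk, n_frames)
        block = rng.poisson(background, size=(t1 - t0, h, w)).astype(np.float32)
        for t in range(t0, t1):
            active = np.nonzero(on[t])[0]
            for e in active:
                x_nm, y_nm = emitters_nm[e]
                x_px = x_nm / params.pixel_size_nm
                y_px = y_nm / params.pixel_size_nm
                j0 = max(0, int(x_px) - pad)
                j1 = min(w, int(x_px) + pad + 1)
                i0 = max(0, int(y_px) - pad)
                i1 = min(h, int(y_px) + pad + 1)
                px = _pixel_profile(j1 - j0, x_px - j0, sigma_px)
                py = _pixel_profile(i1 - i0, y_px - i0, sigma_px)
                lam = params.mean_photons * np.outer(py, px)
                block[t - t0, i0:i1, j0:j1] += rng.poisson(lam)
        if params.read_noise_sd > 0:
            block += rng.normal(0.0, params.read_noise_sd, size=block.shape).astype(np.float32)
        np.clip(block, 0, 65535, out=block)
        stack[t0:t1] = np.rint(block).astype(np.uint16)
    return stack


def simulate_field(params: SimulationParams):
    """Simulate one acquisition field.

    Returns (her2_stack, cep17_stack, dapi_stack, truth): 5000-frame blinking
    stacks for the two probe channels, a 1000-frame DAPI stack in which the
    nuclei are continuously fluorescent, and the full ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.field_px, params.field_px)

    backgrounds = {
        ch: make_background_field(
            params.field_px,
            params.background_amplitude,
            params.background_corr_len_px,
            params.background_offset,
            seed=rng,
        )
        for ch in ("HER2", "CEP17", "DAPI")
    }
    nuclei = _place_nuclei(params, rng)
    signals = _build_signals(params, nuclei, rng)

    counts = []
    for nuc in nuclei:
        h = sum(1 for s in signals if s.nucleus_id == nuc.id and s.channel == "HER2")
        c = sum(1 for s in signals if s.nucleus_id == nuc.id and s.channel == "CEP17")
        counts.append({"nucleus_id": nuc.id, "her2": h, "cep17": c})
    truth = GroundTruth(
        nuclei=nuclei,
        signals=signals,
        per_nucleus_counts=pd.DataFrame(counts, columns=["nucleus_id", "her2", "cep17"]),
        background_fields=backgrounds,
    )

    stacks = {}
    for ch in ("HER2", "CEP17"):
        stacks[ch] = FrameStack(
            data=_render_blinking_stack(
                truth.emitters(ch), params.n_frames_signal, params, backgrounds[ch], rng
            ),
            pixel_size_nm=params.pixel_size_nm,
            channel=ch,
        )

    sigma_px = params.psf_sigma_nm / params.pixel_size_nm
    nucleus_image = np.zeros(shape, dtype=float)
    for nuc in nuclei:
        nucleus_image[nuc.mask] = params.dapi_brightness
    dapi_clean = ndimage.gaussian_filter(nucleus_image, sigma_px) + backgrounds["DAPI"]
    dapi = np.empty((params.n_frames_dapi,) + shape, dtype=np.uint16)
    chunk = 500
    for t0 in range(0, params.n_frames_dapi, chunk):
        t1 = min(t0 + chunk, params.n_frames_dapi)
        block = rng.poisson(dapi_clean, size=(t1 - t0,) + shape).astype(np.float32)
        if params.read_noise_sd > 0:
            block += rng.normal(0.0, params.read_noise_sd, size=block.shape).astype(np.float32)
        np.clip(block, 0, 65535, out=block)
        dapi[t0:t1] = np.rint(block).astype(np.uint16)
    dapi_stack = FrameStack(data=dapi, pixel_size_nm=params.pixel_size_nm, channel="DAPI")

    return stacks["HER2"], stacks["CEP17"], dapi_stack, truth
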