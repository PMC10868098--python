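"""Per-nucleus HER2/CEP17 signal counting.

Two routes produce discrete FISH "signals": the super-resolution route
clusters sub-pixel localizations (single-linkage within ``eps_nm``), the
conventional route takes thresholded blobs of the diffraction-limited
projection.  Signal multiplicity is estimated against the median strength
of signals in the same sample; a signal estimated at more than four copies
whose spatial extent exceeds the isolation scale is flagged ambiguous
(">4"), the rule used when clustered spots cannot be told apart.  Counts
are assigned to DAPI-segmented nuclei and summarised into the nine
per-sample FISH metrics, including the HER2/CEP17 ratio computed over
nuclei with countable CEP17 signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .background import (
    DEFAULT_BALL_RADIUS_PX,
    ThresholdModel,
    apply_threshold,
    estimate_threshold,
    subtract_background,
)
from .errors import CalibrationError, InvalidParameterError
from .superres import _suppress_close

#: extent (nm) above which a ">4 copies" signal cannot be resolved into
#: individual spots: between the sub-diffraction spread of a true locus
#: cluster (~60 nm) and a diffraction-limited blob (~150+ nm).
DEFAULT_ISOLATION_EXTENT_NM = 100.0

SIGNAL_COLUMNS = ("x_nm", "y_nm", "strength", "extent_nm", "est_count", "ambiguous")


@dataclass
class NucleusMap:
    """Labelled nuclei (0 = background, k = nucleus k) with per-nucleus records."""

    labels: np.ndarray
    table: pd.DataFrame  # id, x_nm, y_nm, area_px
    pixel_size_nm: float = 100.0

    @property
    def n_nuclei(self) -> int:
        return len(self.table)

    def nucleus_at(self, x_nm: float, y_nm: float) -> int:
        i = int(y_nm / self.pixel_size_nm)
        j = int(x_nm / self.pixel_size_nm)
        h, w = self.labels.shape
        if not (0 <= i < h and 0 <= j < w):
            return 0
        return int(self.labels[i, j])


@dataclass
class SignalSet:
    """Discrete FISH signals of one channel for one sample."""

    channel: str
    table: pd.DataFrame  # SIGNAL_COLUMNS

    def __len__(self) -> int:
        return len(self.table)


def _empty_signals(channel: str) -> SignalSet:
    tbl = pd.DataFrame({c: pd.Series(dtype=float) for c in SIGNAL_COLUMNS})
    tbl["est_count"] = tbl["est_count"].astype(int)
    tbl["ambiguous"] = tbl["ambiguous"].astype(bool)
    return SignalSet(channel=channel, table=tbl)


def segment_nuclei(
    dapi_projection: np.ndarray,
    min_area_px: int = 50,
    pixel_size_nm: float = 100.0,
    smooth_sigma_px: float = 1.0,
    split_min_distance_px: int = 15,
) -> NucleusMap:
    """Segment nuclei from a DAPI projection.

    Gaussian smoothing, Otsu global threshold, hole filling, then a
    distance-transform watershed to split touching nuclei, and an area
    filter.  An all-background image yields an empty map.
    """
    img = ndimage.gaussian_filter(np.asarray(dapi_projection, dtype=float), smooth_sigma_px)
    if img.max() == img.min():
        return NucleusMap(
            labels=np.zeros(img.shape, dtype=int),
            table=pd.DataFrame(columns=["id", "x_nm", "y_nm", "area_px"]),
            pixel_size_nm=pixel_size_nm,
        )
    binary = img > threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=split_min_distance_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=int)
    for k, (i, j) in enumerate(peaks, start=1):
        markers[i, j] = k
    if markers.max() == 0:
        labels = ndimage.label(binary)[0]
    else:
        labels = watershed(-dist, markers, mask=binary)

    records = []
    out = np.zeros(img.shape, dtype=int)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        out[labels == prop.label] = next_id
        cy, cx = prop.centroid
        records.append(
            {
                "id": next_id,
                "x_nm": (cx + 0.5) * pixel_size_nm,
                "y_nm": (cy + 0.5) * pixel_size_nm,
                "area_px": int(prop.area),
            }
        )
        next_id += 1
    return NucleusMap(
        labels=out,
        table=pd.DataFrame(records, columns=["id", "x_nm", "y_nm", "area_px"]),
        pixel_size_nm=pixel_size_nm,
    )


def cluster_localizations(
    table: pd.DataFrame,
    eps_nm: float = 150.0,
    min_pts: int = 3,
    channel: str = "HER2",
) -> SignalSet:
    """Group localizations into signals by single-linkage within ``eps_nm``.

    Two localizations are linked if within ``eps_nm`` of each other; the
    connected components with at least ``min_pts`` members become signals
    (centroid = mean position, strength = number of localizations, extent =
    RMS radius about the centroid); smaller components are noise.
    """
    if eps_nm <= 0:
        raise InvalidParameterError("eps_nm must be positive")
    if len(table) == 0:
        return _empty_signals(channel)
    pts = np.column_stack([table["x_nm"], table["y_nm"]]).astype(float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(eps_nm, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)
    records = []
    for c in range(n_comp):
        members = pts[comp == c]
        if len(members) < min_pts:
            continue
        centroid = members.mean(axis=0)
        extent = float(np.sqrt(((members - centroid) ** 2).sum(axis=1).mean()))
        records.append(
            {
                "x_nm": centroid[0],
                "y_nm": centroid[1],
                "strength": float(len(members)),
                "extent_nm": extent,
                "est_count": 1,
                "ambiguous": False,
            }
        )
    if not records:
        return _empty_signals(channel)
    return SignalSet(channel=channel, table=pd.DataFrame(records, columns=SIGNAL_COLUMNS))


def estimate_cluster_count(
    strength: float,
    reference_signal_strength: float,
    extent_nm: float = 0.0,
    isolation_extent_nm: float = DEFAULT_ISOLATION_EXTENT_NM,
):
    """(estimated copies, ambiguous) for one signal.

    The copy number is the signal's strength relative to the median strength
    of isolated signals, rounded (half away from zero) and floored at one.
    An estimate above four in a signal wider than the isolation scale is
    reported as 5 with the ">4" (ambiguous) flag.
    """
    if reference_signal_strength <= 0:
        raise CalibrationError("reference signal strength must be positive")
    est = max(1, int(math.floor(strength / reference_signal_strength + 0.5)))
    if est > 4 and extent_nm > isolation_extent_nm:
        return 5, True
    return est, False


def assign_counts(
    signals: SignalSet,
    reference: Optional[float] = None,
    isolation_extent_nm: float = DEFAULT_ISOLATION_EXTENT_NM,
) -> SignalSet:
    """Fill est_count/ambiguous for every signal of a sample.

    The default reference is the median strength over the sample's signals
    (isolated single signals dominate the median in practice).
    """
    tbl = signals.table.copy()
    if len(tbl) == 0:
        return signals
    ref = float(np.median(tbl["strength"])) if reference is None else float(reference)
    est, amb = zip(
        *(
            estimate_cluster_count(s, ref, e, isolation_extent_nm)
            for s, e in zip(tbl["strength"], tbl["extent_nm"])
        )
    )
    tbl["est_count"] = list(est)
    tbl["ambiguous"] = list(amb)
    return SignalSet(channel=signals.channel, table=tbl)


def detect_spots_widefield(
    projection: np.ndarray,
    radius_px: int = DEFAULT_BALL_RADIUS_PX,
    threshold=None,
    min_separation_px: float = 2.0,
    pixel_size_nm: float = 100.0,
    channel: str = "HER2",
    isolation_extent_nm: float = DEFAULT_ISOLATION_EXTENT_NM,
) -> SignalSet:
    """Conventional-resolution signals from a diffraction-limited projection.

    Rolling-ball subtraction, thresholding (a :class:`ThresholdModel`, a
    scalar, or a robust MAD rule when None), then connected bright blobs
    containing a local maximum become signals; strength is the blob's
    integrated intensity and extent its intensity-weighted RMS radius.
    """
    sub = subtract_background(projection, radius_px)
    if isinstance(threshold, ThresholdModel):
        tau = estimate_threshold(threshold, sub)
    elif threshold is None:
        med = float(np.median(sub))
        mad = float(np.median(np.abs(sub - med)))
        tau = med + 5.0 * 1.4826 * max(mad, 1e-6)
    else:
        tau = float(threshold)
    thr = apply_threshold(sub, tau)

    mf = ndimage.maximum_filter(thr, size=3, mode="nearest")
    peaks = np.argwhere((thr >= mf) & (thr > 0))
    if len(peaks) == 0:
        return _empty_signals(channel)
    vals = thr[peaks[:, 0], peaks[:, 1]]
    kept = _suppress_close(peaks, vals, min_separation_px)

    labels, _ = ndimage.label(thr > 0, structure=np.ones((3, 3), dtype=int))
    blob_ids = sorted({labels[i, j] for i, j in kept if labels[i, j] > 0})
    records = []
    for bid in blob_ids:
        mask = labels == bid
        weights = thr[mask]
        ii, jj = np.nonzero(mask)
        total = weights.sum()
        cx = ((jj + 0.5) * weights).sum() / total
        cy = ((ii + 0.5) * weights).sum() / total
        rms_px = math.sqrt(
            (((jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2) * weights).sum() / total
        )
        records.append(
            {
                "x_nm": cx * pixel_size_nm,
                "y_nm": cy * pixel_size_nm,
                "strength": float(total),
                "extent_nm": rms_px * pixel_size_nm,
                "est_count": 1,
                "ambiguous": False,
            }
        )
    out = SignalSet(channel=channel, table=pd.DataFrame(records, columns=SIGNAL_COLUMNS))
    return assign_counts(out, isolation_extent_nm=isolation_extent_nm)


def count_per_nucleus(
    her2: SignalSet,
    cep17: SignalSet,
    nuclei: NucleusMap,
) -> pd.DataFrame:
    """Assign signals to nuclei by centroid-in-mask and tally per-nucleus counts.

    Returns one row per nucleus: H (summed HER2 copy estimates),
    her2_ambiguous, C, cep17_ambiguous, and cep17_countable (C >= 1 and no
    ambiguous CEP17 signal).  Signals outside every nucleus are dropped; the
    dropped counts are recorded in ``result.attrs['n_dropped']``.
    """
    rows = {
        int(nid): {
            "nucleus_id": int(nid),
            "H": 0,
            "her2_ambiguous": False,
            "C": 0,
            "cep17_ambiguous": False,
        }
        for nid in nuclei.table["id"]
    }
    dropped = {"HER2": 0, "CEP17": 0}
    for signal_set, count_key, amb_key in (
        (her2, "H", "her2_ambiguous"),
        (cep17, "C", "cep17_ambiguous"),
    ):
        for _, sig in signal_set.table.iterrows():
            nid = nuclei.nucleus_at(sig["x_nm"], sig["y_nm"])
            if nid == 0 or nid not in rows:
                dropped[signal_set.channel] += 1
                continue
            rows[nid][count_key] += int(sig["est_count"])
            rows[nid][amb_key] = bool(rows[nid][amb_key] or sig["ambiguous"])
    out = pd.DataFrame(
        list(rows.values()),
        columns=["nucleus_id", "H", "her2_ambiguous", "C", "cep17_ambiguous"],
    )
    out["cep17_countable"] = (out["C"] >= 1) & (~out["cep17_ambiguous"])
    out.attrs["n_dropped"] = dropped
    return out


@dataclass
class FISHResult:
    """The nine per-sample FISH quantification metrics."""

    nuclei_with_her2: int
    nuclei_ambiguous_her2: int
    her2_signals: int
    her2_per_nucleus: Optional[float]
    nuclei_with_cep17: int
    nuclei_ambiguous_cep17: int
    cep17_signals: int
    cep17_per_nucleus: Optional[float]
    ratio: Optional[float]
    ratio_undefined_reason: Optional[str] = None

    METRICS = (
        "nuclei_with_her2",
        "nuclei_ambiguous_her2",
        "her2_signals",
        "her2_per_nucleus",
        "nuclei_with_cep17",
        "nuclei_ambiguous_cep17",
        "cep17_signals",
        "cep17_per_nucleus",
        "ratio",
    )

    def to_dict(self) -> dict:
        return {m: getattr(self, m) for m in self.METRICS} | {
            "ratio_undefined_reason": self.ratio_undefined_reason
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FISHResult":
        return cls(
            **{m: d[m] for m in cls.METRICS},
            ratio_undefined_reason=d.get("ratio_undefined_reason"),
        )


def summarize_counts(counts: pd.DataFrame) -> FISHResult:
    """Summarise per-nucleus counts into the nine sample-level metrics.

    Ambiguous nuclei are tallied separately and excluded from the signal
    totals and per-nucleus means; the HER2/CEP17 ratio sums H and C over
    nuclei in which CEP17 is countable.  With no CEP17-countable nucleus the
    ratio is None with a reason recorded.
    """
    if len(counts) == 0:
        raise InvalidParameterError("need at least one nucleus")
    her2_ok = counts[~counts["her2_ambiguous"] & (counts["H"] >= 1)]
    cep_ok = counts[~counts["cep17_ambiguous"] & (counts["C"] >= 1)]
    her2_signals = int(her2_ok["H"].sum())
    cep17_signals = int(cep_ok["C"].sum())
    eligible = counts[counts["cep17_countable"]]
    if len(eligible) and eligible["C"].sum() > 0:
        ratio = float(eligible["H"].sum() / eligible["C"].sum())
        reason = None
    else:
        ratio = None
        reason = "no nucleus with countable CEP17 signals"
    return FISHResult(
        nuclei_with_her2=len(her2_ok),
        nuclei_ambiguous_her2=int(counts["her2_ambiguous"].sum()),
        her2_signals=her2_signals,
        her2_per_nucleus=float(her2_signals / len(her2_ok)) if len(her2_ok) else None,
        nuclei_with_cep17=len(cep_ok),
        nuclei_ambiguous_cep17=int(counts["cep17_ambiguous"].sum()),
        cep17_signals=cep17_signals,
        cep17_per_nucleus=float(cep17_signals / len(cep_ok)) if len(cep_ok) else None,
        ratio=ratio,
        ratio_undefined_reason=reason,
    )
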