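"""TMRE membrane-potential latency and TTC infarct quantification.

TMRE fluorescence in polarized mitochondria collapses when the membrane
potential is lost; per-cell traces from 5-min confocal frames are
normalized to their pre-ischaemic baseline and the latency is the
interpolated time of 50% fluorescence loss.  TTC-stained slices are
thresholded in 8-bit grayscale: pale (bleached, TTC-negative) pixels mark
infarct, and the left-ventricle infarct percentage is the tissue-pixel
weighted average over slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from .stats import StatResult, mann_whitney

logger = logging.getLogger("cardioraman")

TTC_DEFAULT_THRESHOLD = 113


@dataclass
class FluorescenceTrace:
    cell_id: str
    times_min: np.ndarray
    values: np.ndarray
    heart_id: str = "unknown"
    group: str = "SI"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.size != self.values.size:
            raise ValueError("times and values differ in length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")


@dataclass
class LatencyResult:
    cell_id: str
    latency_min: float | None
    censored: bool


@dataclass
class TTCSlice:
    image: np.ndarray        # 8-bit grayscale
    tissue_mask: np.ndarray  # boolean, same shape
    slice_id: str = "0"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.image.shape != self.tissue_mask.shape:
            raise ValueError("mask shape does not match image")
        if not self.tissue_mask.any():
            raise ValueError(f"slice {self.slice_id}: empty tissue mask")


@dataclass
class InfarctResult:
    per_slice: list  # (slice_id, bleached_fraction, tissue_pixels)
    weighted_percent: float


def extract_cell_traces(stack: np.ndarray, rois: dict[str, np.ndarray],
                        frame_interval_min: float = 5.0,
                        t0_min: float = 0.0, **meta) -> list[FluorescenceTrace]:
    """Mean ROI intensity per frame for each cell polygon.

    ``rois`` maps cell_id to an (n, 2) array of (x, y) vertices in 0-based
    pixel coordinates; pixels whose centers fall inside the polygon are
    averaged.  Frames are assumed evenly spaced at ``frame_interval_min``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames >= 2, rows, cols)")
    n_frames, h, w = stack.shape
    times = t0_min + frame_interval_min * np.arange(n_frames)
    traces = []
    for cid, poly in rois.items():
        poly = np.asarray(poly, dtype=float)
        if poly.shape[0] < 3:
            raise ValueError(f"ROI {cid}: polygon needs >= 3 vertices")
        if (poly[:, 0].min() < -0.5 or poly[:, 0].max() > w - 0.5
                or poly[:, 1].min() < -0.5 or poly[:, 1].max() > h - 0.5):
            raise ValueError(f"ROI {cid} extends outside the frame")
        mask = polygon2mask((h, w), poly[:, ::-1])  # (row, col) vertex order
        if not mask.any():
            raise ValueError(f"ROI {cid} covers no pixel centers")
        vals = stack[:, mask].mean(axis=1)
        traces.append(FluorescenceTrace(str(cid), times, vals, **meta))
    return traces


def normalize_trace(trace: FluorescenceTrace,
                    baseline_frames: int = 3) -> FluorescenceTrace:
    """Divide by the mean of the first ``baseline_frames`` values."""
    if trace.values.size <= baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    base = float(np.mean(trace.values[:baseline_frames]))
    if base <= 0:
        raise ValueError(f"cell {trace.cell_id}: nonpositive baseline")
    out = FluorescenceTrace(trace.cell_id, trace.times_min,
                            trace.values / base, trace.heart_id, trace.group)
    out.normalized = True
    return out


def latency_50(trace: FluorescenceTrace, threshold: float = 0.5) -> LatencyResult:
    """Time of 50% fluorescence loss, linearly interpolated between frames.

    Censored when the normalized trace never reaches the threshold.
    """
    if not trace.normalized:
        logger.warning("latency_50 on a non-normalized trace (cell %s)",
                       trace.cell_id)
    t, v = trace.times_min, trace.values
    below = v <= threshold
    if not below.any():
        return LatencyResult(trace.cell_id, None, censored=True)
    k = int(np.argmax(below))
    if k == 0:
        return LatencyResult(trace.cell_id, float(t[0]), censored=False)
    t0, t1, v0, v1 = t[k - 1], t[k], v[k - 1], v[k]
    lat = t0 + (t1 - t0) * (v0 - threshold) / (v0 - v1)
    return LatencyResult(trace.cell_id, float(lat), censored=False)


def compare_latencies(si: list[LatencyResult],
                      ipc: list[LatencyResult]) -> StatResult:
    """Mann-Whitney on uncensored latencies; censored cells are dropped."""
    a = [r.latency_min for r in si if not r.censored]
    b = [r.latency_min for r in ipc if not r.censored]
    n_cens = sum(r.censored for r in si) + sum(r.censored for r in ipc)
    if n_cens:
        logger.info("compare_latencies: %d censored cell(s) excluded", n_cens)
    if not a or not b:
        raise ValueError("need >= 1 uncensored latency per group")
    return mann_whitney(a, b)


def ttc_bleached_fraction(slc: TTCSlice,
                          threshold: int = TTC_DEFAULT_THRESHOLD,
                          bleached_is_bright: bool = True) -> float:
    """Fraction of tissue pixels at/above the 8-bit threshold (pale =
    TTC-negative = infarct).  The comparison direction flips for inverted
    imaging setups."""
    vals = slc.image[slc.tissue_mask]
    if bleached_is_bright:
        return float(np.mean(vals >= threshold))
    return float(np.mean(vals <= threshold))


def ttc_weighted_infarct(slices: list[TTCSlice],
                         threshold: int = TTC_DEFAULT_THRESHOLD,
                         bleached_is_bright: bool = True) -> InfarctResult:
    """Tissue-pixel weighted average infarct percentage over heart slices."""
    if not slices:
        raise ValueError("no slices")
    per_slice = []
    num = 0.0
    den = 0
    for s in slices:
        frac = ttc_bleached_fraction(s, threshold, bleached_is_bright)
        npix = int(s.tissue_mask.sum())
        per_slice.append((s.slice_id, frac, npix))
        num += frac * npix
        den += npix
    return InfarctResult(per_slice, 100.0 * num / den)
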