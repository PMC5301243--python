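"""Band-height quantification and ratio normalization.

Peak heights are read baseline-to-peak: the maximum intensity inside a
narrow search window around the assigned band centre, minus a local linear
baseline interpolated between the shoulder minima on either side.  Heights
are then normalized two ways, following the readouts used for ischaemic
time courses: (i) per-band height over the height of the 1450 cm^-1 CH2
lipid band, whose underlying amount is stable during early ischaemia, and
(ii) height over the integrated (background-subtracted) spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectrumRecord

logger = logging.getLogger("cardioraman")


@dataclass(frozen=True)
class BandDefinition:
    """An assigned Raman band and its measurement windows (cm^-1)."""

    name: str
    center: float
    assignment: str
    search_halfwidth: float = 8.0
    shoulder_halfwidth: float = 25.0

    def __post_init__(self) -> None:
        if self.search_halfwidth <= 0:
            raise ValueError("search_halfwidth must be > 0")
        if self.shoulder_halfwidth < self.search_halfwidth:
            raise ValueError("shoulder_halfwidth must be >= search_halfwidth")


#: The ten assigned bands of the myocardial spectrum under 532-nm excitation.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("750", 750.0, "reduced cytochrome c/b"),
    BandDefinition("1127", 1127.0, "reduced cytochrome c/b"),
    BandDefinition("1313", 1313.0, "reduced cytochrome c"),
    BandDefinition("1337", 1337.0, "reduced cytochrome b"),
    BandDefinition("1377", 1377.0, "oxy-Mb"),
    BandDefinition("1450", 1450.0, "CH2 bending, lipids"),
    BandDefinition("1556", 1556.0, "deoxy-Mb"),
    BandDefinition("1582", 1582.0, "reduced cytochromes"),
    BandDefinition("1587", 1587.0, "oxy-Mb"),
    BandDefinition("1640", 1640.0, "oxy-Mb"),
)

#: The subset whose time courses are routinely plotted/tested.
TIMECOURSE_BANDS = ("750", "1127", "1337", "1450")


@dataclass
class PeakMeasure:
    band: BandDefinition
    peak_position: float
    peak_intensity: float
    local_baseline: float

    @property
    def height(self) -> float:
        return self.peak_intensity - self.local_baseline


@dataclass
class PeakTable:
    """Per-spectrum band heights and normalized ratios."""

    heart_id: str
    group: str
    phase: str
    time_min: float
    point_id: str
    heights: dict = field(default_factory=dict)
    ratios_1450: dict = field(default_factory=dict)
    ratios_whole: dict = field(default_factory=dict)
    n_points: int = 1

    def to_rows(self) -> list[dict]:
        rows = []
        for band in self.heights:
            rows.append({
                "heart_id": self.heart_id, "group": self.group,
                "phase": self.phase, "time_min": self.time_min,
                "point_id": self.point_id, "band": band,
                "height": self.heights[band],
                "ratio_1450": self.ratios_1450.get(band, np.nan),
                "ratio_whole": self.ratios_whole.get(band, np.nan),
                "n_points": self.n_points,
            })
        return rows


def measure_peak(record: SpectrumRecord, band: BandDefinition) -> PeakMeasure:
    """Baseline-to-peak height of one band.

    Peak = maximum intensity within ``center +/- search_halfwidth``; the
    local baseline is the line through the shoulder minima (one on each
    side, searched between the search and shoulder half-widths), evaluated
    at the peak position.  Heights may be <= 0 for absent bands.
    """
    wn, y = record.wavenumbers, record.intensities
    c, s, sh = band.center, band.search_halfwidth, band.shoulder_halfwidth
    if wn[0] > c - sh or wn[-1] < c + sh:
        raise ValueError(
            f"band {band.name}: window [{c - sh}, {c + sh}] cm^-1 extends past "
            f"the spectrum range [{wn[0]}, {wn[-1]}]"
        )
    if not record.background_subtracted:
        logger.warning(
            "band %s measured on a spectrum without background subtraction",
            band.name,
        )
    core = (wn >= c - s) & (wn <= c + s)
    i_peak = np.argmax(np.where(core, y, -np.inf))
    peak_pos, peak_val = wn[i_peak], y[i_peak]

    def shoulder_min(lo, hi):
        m = (wn >= lo) & (wn <= hi)
        j = np.argmin(np.where(m, y, np.inf))
        return wn[j], y[j]

    xl, yl = shoulder_min(c - sh, c - s)
    xr, yr = shoulder_min(c + s, c + sh)
    baseline = yl + (yr - yl) * (peak_pos - xl) / (xr - xl)
    return PeakMeasure(band, float(peak_pos), float(peak_val), float(baseline))


def build_peak_table(record: SpectrumRecord,
                     bands=DEFAULT_BANDS,
                     reference_band: str = "1450",
                     whole_range: tuple[float, float] = (600.0, 1800.0),
                     whole_mode: str = "integral") -> PeakTable:
    """Measure every band and compute both normalizations.

    ``whole_mode='integral'`` divides by the trapezoidal integral of the
    spectrum over ``whole_range``; ``'sum_heights'`` divides by the sum of
    all band heights instead.
    """
    names = [b.name for b in bands]
    if reference_band not in names:
        raise ValueError(f"reference band {reference_band!r} not in band set")
    measures = {b.name: measure_peak(record, b) for b in bands}
    heights = {n: m.height for n, m in measures.items()}

    ref = heights[reference_band]
    ratios_1450 = {}
    if ref > 0:
        ratios_1450 = {n: h / ref for n, h in heights.items()}
    else:
        logger.warning(
            "reference band height <= 0 for heart=%s t=%s; ratios undefined",
            record.heart_id, record.time_min,
        )
        ratios_1450 = {n: np.nan for n in heights}

    if whole_mode == "integral":
        wn, y = record.wavenumbers, record.intensities
        m = (wn >= whole_range[0]) & (wn <= whole_range[1])
        whole = float(np.trapezoid(y[m], wn[m]))
    elif whole_mode == "sum_heights":
        whole = float(sum(heights.values()))
    else:
        raise ValueError(f"unknown whole_mode {whole_mode!r}")
    if whole > 0:
        ratios_whole = {n: h / whole for n, h in heights.items()}
    else:
        ratios_whole = {n: np.nan for n in heights}

    return PeakTable(record.heart_id, record.group, record.phase,
                     record.time_min, record.point_id,
                     heights, ratios_1450, ratios_whole)


def aggregate_points(tables: list[PeakTable]) -> PeakTable:
    """Average replicate-point tables of one (heart, phase, time).

    Heights and ratios are averaged band-wise; undefined (NaN) ratios are
    skipped, and the surviving n is recorded.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    key = (tables[0].heart_id, tables[0].phase, tables[0].time_min)
    for t in tables[1:]:
        if (t.heart_id, t.phase, t.time_min) != key:
            raise ValueError("cannot aggregate across hearts, phases or times")
    bands = list(tables[0].heights)

    def nanmean(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return (float(np.mean(vals)), len(vals)) if vals else (np.nan, 0)

    heights, r1450, rwhole = {}, {}, {}
    for b in bands:
        heights[b], _ = nanmean([t.heights[b] for t in tables])
        r1450[b], _ = nanmean([t.ratios_1450.get(b, np.nan) for t in tables])
        rwhole[b], _ = nanmean([t.ratios_whole.get(b, np.nan) for t in tables])
    out = PeakTable(tables[0].heart_id, tables[0].group, tables[0].phase,
                    tables[0].time_min, "mean", heights, r1450, rwhole,
                    n_points=len(tables))
    return out


def peak_frame(tables: list[PeakTable]) -> pd.DataFrame:
    """Long-format DataFrame over many peak tables (one row per band)."""
    rows: list[dict] = []
    for t in tables:
        rows.extend(t.to_rows())
    return pd.DataFrame(rows)
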