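"""Seeded synthetic cohorts for every pipeline stage.

The generator emulates a stopped-flow (global ischaemia) experiment on
Langendorff-perfused rat hearts in three arms — continuously perfused
controls, simple ischaemia (SI) and ischaemic preconditioning (IPC):

* point Raman spectra: Lorentzian bands whose amplitudes follow saturating
  cytochrome-reduction kinetics r(t) = r_inf * (1 - exp(-t/tau)) (slower
  tau under IPC, r = 0 for controls) and first-order myoglobin
  deoxygenation, on a smooth autofluorescence polynomial plus a broad
  Gaussian background hump that grows with ischaemia time;
* per-cell TMRE fluorescence: logistic decay with group-dependent latency;
* TTC slices: disk tissue masks with an exact bleached-pixel fraction;
* oximetry traces: piecewise-linear %O2 with state IV/III slopes.

Everything is reproducible: one master seed is split hierarchically per
heart (and per spectrum/cell/slice below that), so adding a heart never
perturbs the data of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (PAPER_ISCHAEMIA_TIMES, PAPER_PERFUSION_TIMES, SpectrumRecord,
                 write_rois, write_spectrum, write_stack)
from .imaging import FluorescenceTrace, TTCSlice
from .oxygen import OxygenTrace

REDUCED_DRIVERS = ("reduced_cyt_c", "reduced_cyt_b")


@dataclass(frozen=True)
class BandModel:
    """One synthetic Raman band: Lorentzian at ``center`` whose amplitude is
    scaled by the chemical driver's kinetic factor."""

    center: float          # cm^-1
    fwhm: float            # cm^-1
    base_amplitude: float  # counts at full driver occupancy
    driver: str            # reduced_cyt_c | reduced_cyt_b | oxy_mb | deoxy_mb | lipid | constant

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.base_amplitude < 0:
            raise ValueError("fwhm must be > 0 and base_amplitude >= 0")


DEFAULT_BAND_MODELS: tuple[BandModel, ...] = (
    BandModel(750.0, 12.0, 220.0, "reduced_cyt_c"),
    BandModel(1127.0, 12.0, 180.0, "reduced_cyt_c"),
    BandModel(1313.0, 14.0, 90.0, "reduced_cyt_c"),
    BandModel(1337.0, 14.0, 70.0, "reduced_cyt_b"),
    BandModel(1377.0, 14.0, 80.0, "oxy_mb"),
    BandModel(1450.0, 16.0, 160.0, "lipid"),
    BandModel(1556.0, 16.0, 120.0, "deoxy_mb"),
    BandModel(1582.0, 14.0, 140.0, "reduced_cyt_c"),
    BandModel(1587.0, 16.0, 400.0, "oxy_mb"),
    BandModel(1640.0, 18.0, 380.0, "oxy_mb"),
)


@dataclass
class KineticParams:
    """Redox kinetics of the ischaemic myocardium.

    tau_red_min: cytochrome-reduction time constants per group (minutes);
    controls stay fully oxidized (infinite tau).  tau_mb_min governs
    first-order myoglobin deoxygenation.  drift_per_min scales the broad
    background hump that accumulates during stopped-flow.
    """

    r_inf: float = 1.0
    tau_red_min: Mapping[str, float] = field(default_factory=lambda: {
        "control": math.inf, "SI": 18.0, "IPC": 35.0})
    tau_mb_min: float = 12.0
    drift_per_min: float = 1.5
    jitter_sd: float = 0.15  # lognormal sd of the per-heart overall scale


@dataclass
class TMREParams:
    latency_mean: Mapping[str, float] = field(default_factory=lambda: {
        "SI": 37.3, "IPC": 43.5})
    latency_sd: Mapping[str, float] = field(default_factory=lambda: {
        "SI": 4.5, "IPC": 2.2})
    cells_per_heart: int = 5
    frame_interval_min: float = 5.0
    n_frames: int = 16
    slope_min: float = 1.5   # logistic time scale of the collapse
    f0: float = 180.0        # baseline fluorescence, 8-bit units
    noise_sd: float = 2.0


@dataclass
class TTCParams:
    bleached_mean: Mapping[str, float] = field(default_factory=lambda: {
        "control": 0.039, "SI": 0.743, "IPC": 0.567})
    bleached_sd: float = 0.05
    n_slices: int = 5
    image_size: int = 96
    stained_gray: int = 60
    bleached_gray: int = 180
    noise_sd: float = 0.0


@dataclass
class OxygenParams:
    slope_stateIV: Mapping[str, float] = field(default_factory=lambda: {
        "control": 3.4737, "SI": 1.5124, "IPC": 2.4891})
    slope_stateIII: Mapping[str, float] = field(default_factory=lambda: {
        "control": 5.2539, "SI": 1.9377, "IPC": 3.3162})
    protein_ug: float = 750.0
    o2_start: float = 100.0
    t_mito_s: float = 60.0
    t_succinate_s: float = 180.0
    t_adp_s: float = 360.0
    duration_s: float = 540.0
    noise_sd: float = 0.0


@dataclass
class CohortParams:
    group_sizes: Mapping[str, int] = field(default_factory=lambda: {
        "control": 3, "SI": 8, "IPC": 9})
    perfusion_times: tuple = PAPER_PERFUSION_TIMES
    ischaemia_times: tuple = PAPER_ISCHAEMIA_TIMES
    points_per_time: int = 5


@dataclass
class SynthConfig:
    bands: tuple = DEFAULT_BAND_MODELS
    kinetics: KineticParams = field(default_factory=KineticParams)
    axis: tuple[float, float, float] = (600.0, 1800.0, 1.0)
    #: autofluorescence polynomial coefficients on the normalized [-1, 1] axis
    background_coeffs: tuple = (900.0, 150.0, -250.0, 0.0, 80.0)
    drift_center: float = 1300.0
    drift_fwhm: float = 600.0
    noise_sd: float = 3.0
    noise_scale: float = 800.0
    cohort: CohortParams = field(default_factory=CohortParams)
    tmre: TMREParams = field(default_factory=TMREParams)
    ttc: TTCParams = field(default_factory=TTCParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    seed: int = 0

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.axis
        return np.arange(lo, hi + step / 2, step)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> SynthConfig:
    """Build a SynthConfig from a YAML file of (possibly partial) overrides."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw = {}
    if "bands" in raw:
        kw["bands"] = tuple(BandModel(**b) for b in raw.pop("bands"))
    for key, cls in (("kinetics", KineticParams), ("cohort", CohortParams),
                     ("tmre", TMREParams), ("ttc", TTCParams),
                     ("oxygen", OxygenParams)):
        if key in raw:
            sub = raw.pop(key)
            if "tau_red_min" in sub:
                sub["tau_red_min"] = {k: (math.inf if v in ("inf", None) else float(v))
                                      for k, v in sub["tau_red_min"].items()}
            kw[key] = cls(**sub)
    kw.update(raw)
    return SynthConfig(**kw)


# ---------------------------------------------------------------------------
# kinetics and spectra

def redox_state(t_min: float, group: str,
                kinetics: KineticParams) -> tuple[float, float]:
    """Reduced-cytochrome fraction r and myoglobin oxygenation fraction m
    at ischaemia time t (minutes).  Controls stay at r = 0, m = 1."""
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    tau = kinetics.tau_red_min.get(group, math.inf)
    if group == "control" or math.isinf(tau):
        return 0.0, 1.0
    r = kinetics.r_inf * (1.0 - math.exp(-t_min / tau))
    m = math.exp(-t_min / kinetics.tau_mb_min)
    return r, m


def _driver_factor(driver: str, r: float, m: float) -> float:
    if driver in REDUCED_DRIVERS:
        return r
    if driver == "oxy_mb":
        return m
    if driver == "deoxy_mb":
        return 1.0 - m
    if driver in ("lipid", "constant"):
        return 1.0
    raise ValueError(f"unknown driver {driver!r}")


def lorentzian(wn: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return 1.0 / (1.0 + ((wn - center) / hw) ** 2)


def clean_signal(config: SynthConfig, r: float, m: float) -> np.ndarray:
    """Peak-only synthetic signal (no background, no noise) at redox (r, m)."""
    wn = config.wavenumbers()
    y = np.zeros_like(wn)
    for b in config.bands:
        if wn[0] > b.center - 3 * b.fwhm or wn[-1] < b.center + 3 * b.fwhm:
            raise ValueError(
                f"axis too narrow for band at {b.center} cm^-1 (need +/- 3 fwhm)"
            )
        amp = b.base_amplitude * _driver_factor(b.driver, r, m)
        if amp:
            y += amp * lorentzian(wn, b.center, b.fwhm)
    return y


def background_profile(config: SynthConfig) -> np.ndarray:
    wn = config.wavenumbers()
    x = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
    return np.polynomial.polynomial.polyval(x, np.asarray(config.background_coeffs))


def drift_profile(config: SynthConfig) -> np.ndarray:
    wn = config.wavenumbers()
    sigma = config.drift_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((wn - config.drift_center) / sigma) ** 2)


def simulate_spectrum(config: SynthConfig, heart_id: str, group: str,
                      phase: str, t_min: float, point_id: str,
                      rng: np.random.Generator,
                      heart_jitter: float = 1.0,
                      noise_sd: float | None = None) -> SpectrumRecord:
    """One synthetic point spectrum.

    Perfusion-phase spectra are fully oxidized regardless of group (the IPC
    maneuver restores the perfused redox baseline before stopped flow);
    ischaemia-phase spectra follow the group's kinetics.  The background
    drift term grows only during stopped flow.
    """
    wn = config.wavenumbers()
    if phase == "perfusion" or group == "control":
        r, m = 0.0, 1.0
    else:
        r, m = redox_state(t_min, group, config.kinetics)
    signal = clean_signal(config, r, m)
    bg = background_profile(config).copy()
    if phase == "ischaemia" and group != "control":
        bg = bg + config.kinetics.drift_per_min * t_min * drift_profile(config)
    clean = heart_jitter * (signal + bg)
    sd = config.noise_sd if noise_sd is None else noise_sd
    noise = 0.0
    if sd > 0:
        noise = rng.normal(0.0, sd * np.sqrt(1.0 + np.abs(signal) / config.noise_scale))
    return SpectrumRecord(wn, clean + noise, heart_id=heart_id, group=group,
                          phase=phase, time_min=float(t_min),
                          point_id=str(point_id))


def _heart_rng(seed: int, heart_index: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(heart_index, *key)))


def iter_cohort_hearts(config: SynthConfig):
    """Yield (heart_index, heart_id, group) over the configured cohort."""
    i = 0
    for group in ("control", "SI", "IPC"):
        n = config.cohort.group_sizes.get(group, 0)
        for k in range(n):
            yield i, f"{group}{k + 1:02d}", group
            i += 1


def simulate_cohort_records(config: SynthConfig, seed: int | None = None,
                            noise_sd: float | None = None,
                            points_per_time: int | None = None):
    """In-memory cohort: yields (SpectrumRecord, ground-truth dict).

    Control hearts get ischaemia-grid rows too — they stay perfused, but
    their spectra are collected at the same elapsed clock times so that
    per-time comparisons against control are possible.
    """
    seed = config.seed if seed is None else seed
    ppt = config.cohort.points_per_time if points_per_time is None else points_per_time
    for hi, heart_id, group in iter_cohort_hearts(config):
        jitter = float(np.exp(
            _heart_rng(seed, hi).normal(0.0, config.kinetics.jitter_sd)))
        schedule = ([("perfusion", t) for t in config.cohort.perfusion_times]
                    + [("ischaemia", t) for t in config.cohort.ischaemia_times])
        for ti, (phase, t) in enumerate(schedule):
            for p in range(ppt):
                rng = _heart_rng(seed, hi, ti, p)
                rec = simulate_spectrum(config, heart_id, group, phase, t,
                                        str(p), rng, heart_jitter=jitter,
                                        noise_sd=noise_sd)
                r, m = ((0.0, 1.0) if phase == "perfusion"
                        else redox_state(t, group, config.kinetics))
                yield rec, {"heart_id": heart_id, "group": group,
                            "phase": phase, "time_min": t, "point_id": p,
                            "r": r, "m": m, "jitter": jitter}


def simulate_cohort(config: SynthConfig, out_dir, seed: int | None = None,
                    force: bool = False):
    """Write the full spectra file tree + manifest + ground truth CSV."""
    from .io import load_manifest

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    rows, truth = [], []
    for rec, gt in simulate_cohort_records(config, seed=seed):
        rel = (f"spectra/{rec.heart_id}_{rec.phase}_t{int(rec.time_min):03d}"
               f"_p{rec.point_id}.csv")
        write_spectrum(rec, out / rel)
        rows.append({"path": rel, "heart_id": rec.heart_id, "group": rec.group,
                     "phase": rec.phase, "time_min": rec.time_min,
                     "point_id": rec.point_id})
        truth.append(gt)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth).to_csv(out / "ground_truth.csv", index=False)
    return load_manifest(out / "manifest.csv")


# ---------------------------------------------------------------------------
# TMRE

def _logistic_decay(t: np.ndarray, f0: float, latency: float,
                    slope: float) -> np.ndarray:
    z = np.clip((t - latency) / max(slope, 1e-9), -700.0, 700.0)
    return f0 / (1.0 + np.exp(z))


def simulate_tmre_traces(config: SynthConfig, group: str, n_cells: int,
                         rng: np.random.Generator):
    """Per-cell logistic TMRE decay traces with ground-truth latencies.

    Returns (traces, latencies); the true latency is the logistic midpoint,
    i.e. the exact time of 50% fluorescence loss.
    """
    p = config.tmre
    times = p.frame_interval_min * np.arange(p.n_frames)
    traces, latencies = [], []
    for c in range(n_cells):
        L = rng.normal(p.latency_mean[group], p.latency_sd[group])
        vals = _logistic_decay(times, p.f0, L, p.slope_min)
        if p.noise_sd > 0:
            vals = vals + rng.normal(0.0, p.noise_sd, size=vals.size)
        traces.append(FluorescenceTrace(f"{group}_cell{c}", times, vals,
                                        group=group))
        latencies.append(float(L))
    return traces, latencies


def simulate_tmre_stack(config: SynthConfig, group: str,
                        rng: np.random.Generator,
                        out_dir=None, heart_id: str = "heart1"):
    """Render a confocal-like 8-bit stack with rectangular cell ROIs.

    Returns (stack, rois, truth latencies); optionally writes stack.tif,
    rois.csv and ground_truth.csv.
    """
    p = config.tmre
    n_cells = p.cells_per_heart
    h, w = 96, 32 * n_cells
    times = p.frame_interval_min * np.arange(p.n_frames)
    stack = np.full((p.n_frames, h, w), 8.0)
    rois, latencies = {}, {}
    for c in range(n_cells):
        L = float(rng.normal(p.latency_mean[group], p.latency_sd[group]))
        x0, x1 = 32 * c + 6, 32 * c + 26
        y0, y1 = 24, 72
        vals = _logistic_decay(times, p.f0, L, p.slope_min)
        for f in range(p.n_frames):
            block = vals[f]
            if p.noise_sd > 0:
                block = block + rng.normal(0.0, p.noise_sd,
                                           size=(y1 - y0, x1 - x0))
            stack[f, y0:y1, x0:x1] = block
        cid = f"{heart_id}_cell{c}"
        rois[cid] = np.array([[x0, y0], [x1 - 1, y0], [x1 - 1, y1 - 1],
                              [x0, y1 - 1]], dtype=float)
        latencies[cid] = L
    stack = np.clip(np.round(stack), 0, 255).astype(np.uint8)
    if out_dir is not None:
        out = Path(out_dir)
        write_stack(stack, out / "stack.tif")
        write_rois(rois, out / "rois.csv")
        pd.DataFrame([{"cell_id": k, "latency_min": v}
                      for k, v in latencies.items()]
                     ).to_csv(out / "ground_truth.csv", index=False)
    return stack, rois, latencies


# ---------------------------------------------------------------------------
# TTC

def simulate_ttc_slices(config: SynthConfig, fractions,
                        rng: np.random.Generator) -> list[TTCSlice]:
    """One slice per requested bleached fraction; the bleached pixel count
    is exact, so noiseless recovery is exact by construction."""
    p = config.ttc
    n = p.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (0.42 * n) ** 2
    npix = int(mask.sum())
    slices = []
    for si, frac in enumerate(fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("bleached fraction must be in [0, 1]")
        img = np.full((n, n), 30.0)  # non-tissue backdrop
        img[mask] = p.stained_gray
        k = int(round(frac * npix))
        if k:
            rows, cols = np.nonzero(mask)
            img[rows[:k], cols[:k]] = p.bleached_gray  # top-of-disk region
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        slices.append(TTCSlice(img, mask, slice_id=str(si)))
    return slices


def simulate_ttc_heart(config: SynthConfig, group: str,
                       rng: np.random.Generator):
    """Five slices for one heart; per-slice fractions jitter around the
    group mean.  Returns (slices, true fractions)."""
    p = config.ttc
    fr = np.clip(rng.normal(p.bleached_mean[group], p.bleached_sd,
                            size=p.n_slices), 0.0, 1.0)
    # quantize to the exact pixel fractions actually rendered
    slices = simulate_ttc_slices(config, fr, rng)
    npix = int(slices[0].tissue_mask.sum())
    exact = [round(f * npix) / npix for f in fr]
    return slices, exact


# ---------------------------------------------------------------------------
# oximetry

def simulate_o2_trace(config: SynthConfig,
                      slopes: tuple[float, float] | None = None,
                      protein_ug: float | None = None,
                      rng: np.random.Generator | None = None,
                      group: str = "control") -> OxygenTrace:
    """Piecewise-linear %O2 trace at 1 Hz: flat until succinate, then the
    state IV slope, then the state III slope after ADP."""
    p = config.oxygen
    if slopes is None:
        slopes = (p.slope_stateIV[group], p.slope_stateIII[group])
    y4, y3 = slopes
    if y4 < 0 or y3 < 0:
        raise ValueError("slopes must be >= 0 (consumption magnitudes)")
    M = p.protein_ug if protein_ug is None else protein_ug
    t = np.arange(0.0, p.duration_s + 0.5, 1.0)
    o2 = np.full_like(t, p.o2_start)
    after_s = t > p.t_succinate_s
    o2[after_s] -= y4 / 60.0 * (np.minimum(t[after_s], p.t_adp_s) - p.t_succinate_s)
    after_a = t > p.t_adp_s
    o2[after_a] -= y3 / 60.0 * (t[after_a] - p.t_adp_s)
    if p.noise_sd > 0 and rng is not None:
        o2 = o2 + rng.normal(0.0, p.noise_sd, size=o2.size)
    o2 = np.clip(o2, 0.0, 110.0)
    events = [(p.t_mito_s, "mitochondria"), (p.t_succinate_s, "succinate"),
              (p.t_adp_s, "adp")]
    return OxygenTrace(t, o2, events, M)
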