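"""Spectrum, manifest, trace and image I/O.

Spectra travel as plain two-column delimited text (wavenumber cm^-1,
intensity counts); acquisition metadata lives in a ``.meta`` sidecar of
``key: value`` lines so that exports from any spectrometer are accepted
unmodified.  The cohort manifest is a CSV table mapping spectrum files to
(heart, group, phase, time) coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("cardioraman")

GROUPS = ("control", "SI", "IPC")
PHASES = ("perfusion", "ischaemia")

#: Sampling grids of the reference experimental design (minutes after the
#: start of the respective phase).
PAPER_PERFUSION_TIMES = (15, 45)
PAPER_ISCHAEMIA_TIMES = (10, 20, 30, 45, 60, 90, 120)

#: Recommended minimum number of samples for a spectrum; shorter records are
#: accepted but flagged.
RECOMMENDED_MIN_POINTS = 16


class SpectrumValidationError(ValueError):
    """A spectrum violates a structural invariant."""


class ManifestError(ValueError):
    """The cohort manifest is malformed or inconsistent."""


@dataclass
class SpectrumRecord:
    """A single point Raman spectrum with acquisition metadata.

    Parameters
    ----------
    wavenumbers
        Raman shift axis in cm^-1, strictly increasing.
    intensities
        Detector counts (arbitrary units), same length as the axis.
    heart_id, group, phase, time_min, point_id
        Cohort coordinates.  ``time_min`` counts minutes from the start of
        the given phase (perfusion start or stopped-flow onset).
    background_subtracted
        Provenance flag set by the preprocessing stage.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    heart_id: str = "unknown"
    group: str = "control"
    phase: str = "perfusion"
    time_min: float = 0.0
    point_id: str = "0"
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        wn, y = self.wavenumbers, self.intensities
        if wn.ndim != 1 or y.ndim != 1 or wn.size != y.size:
            raise SpectrumValidationError(
                "wavenumbers and intensities must be 1-D and of equal length"
            )
        if wn.size < 2:
            raise SpectrumValidationError("spectrum needs at least 2 samples")
        if wn.size < RECOMMENDED_MIN_POINTS:
            logger.warning(
                "spectrum heart=%s t=%s has only %d samples (< %d recommended)",
                self.heart_id, self.time_min, wn.size, RECOMMENDED_MIN_POINTS,
            )
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(y)):
            raise SpectrumValidationError("non-finite values in spectrum")
        if np.any(np.diff(wn) <= 0):
            raise SpectrumValidationError(
                "wavenumber axis must be strictly increasing (duplicates?)"
            )
        if self.group not in GROUPS:
            raise SpectrumValidationError(f"unknown group {self.group!r}")
        if self.phase not in PHASES:
            raise SpectrumValidationError(f"unknown phase {self.phase!r}")

    @property
    def on_paper_grid(self) -> bool:
        grid = PAPER_PERFUSION_TIMES if self.phase == "perfusion" else PAPER_ISCHAEMIA_TIMES
        return self.time_min in grid

    def copy_with(self, **kw) -> "SpectrumRecord":
        return replace(self, **kw)


_META_FIELDS = ("heart_id", "group", "phase", "time_min", "point_id",
                "background_subtracted")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def read_spectrum(path: str | Path) -> SpectrumRecord:
    """Read a two-column (wavenumber, intensity) text file.

    Comma-, tab- or whitespace-delimited; ``#`` comment lines are skipped.
    A ``.meta`` sidecar with ``key: value`` lines supplies metadata; when
    absent, defaults (control group, t=0) are filled in with a warning.
    Rows are sorted by wavenumber, so descending exports are accepted.
    """
    path = Path(path)
    wn, ys = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for delim in (",", "\t", None):
                parts = line.split(delim)
                if len(parts) >= 2:
                    break
            try:
                wn.append(float(parts[0]))
                ys.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                # tolerate a single non-numeric header row
                if lineno == 1 and not wn:
                    continue
                raise SpectrumValidationError(
                    f"{path}:{lineno}: cannot parse row {line!r}"
                ) from exc
    order = np.argsort(wn, kind="stable")
    wn = np.asarray(wn, dtype=float)[order]
    ys = np.asarray(ys, dtype=float)[order]

    meta: dict = {}
    side = _sidecar_path(path)
    if side.exists():
        for raw in side.read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#") or ":" not in line:
                continue
            key, _, val = line.partition(":")
            meta[key.strip()] = val.strip()
    else:
        logger.warning("no sidecar for %s; metadata defaults applied", path)

    kw = {}
    for f in _META_FIELDS:
        if f in meta:
            kw[f] = meta[f]
    if "time_min" in kw:
        kw["time_min"] = float(kw["time_min"])
    if "background_subtracted" in kw:
        kw["background_subtracted"] = kw["background_subtracted"].lower() in ("true", "1", "yes")
    return SpectrumRecord(wn, ys, **kw)


def write_spectrum(record: SpectrumRecord, path: str | Path) -> Path:
    """Write a spectrum as CSV plus a metadata sidecar; round-trip safe."""
    record.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1,intensity\n")
        for w, y in zip(record.wavenumbers, record.intensities):
            fh.write(f"{float(w)!r},{float(y)!r}\n")
    with open(_sidecar_path(path), "w") as fh:
        for f in _META_FIELDS:
            fh.write(f"{f}: {getattr(record, f)}\n")
    return path


@dataclass
class CohortManifest:
    """Table of spectrum files with cohort coordinates."""

    records: pd.DataFrame
    group_sizes: Mapping[str, int] = field(default_factory=dict)
    base_dir: Path | None = None

    REQUIRED = ("path", "heart_id", "group", "phase", "time_min", "point_id")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ManifestError(f"unknown groups in manifest: {sorted(bad_group)}")
        multi = df.groupby("heart_id")["group"].nunique()
        offenders = multi[multi > 1].index.tolist()
        if offenders:
            raise ManifestError(f"hearts assigned to multiple groups: {offenders}")
        dup = df.duplicated(subset=["heart_id", "phase", "time_min", "point_id"])
        if dup.any():
            raise ManifestError(
                f"duplicate (heart, phase, time, point) rows: {df[dup].index.tolist()}"
            )
        sizes = df.drop_duplicates("heart_id").groupby("group").size().to_dict()
        self.group_sizes = {g: int(sizes.get(g, 0)) for g in GROUPS if g in sizes}

    @property
    def paper_grid_flags(self) -> pd.Series:
        """Per-heart flag: True when the heart's time grid matches the
        reference design (15/45 min perfusion; 10...120 min ischaemia)."""
        def ok(sub: pd.DataFrame) -> bool:
            perf = sorted(sub.loc[sub.phase == "perfusion", "time_min"].unique())
            isch = sorted(sub.loc[sub.phase == "ischaemia", "time_min"].unique())
            return perf == list(PAPER_PERFUSION_TIMES) and isch == list(PAPER_ISCHAEMIA_TIMES)
        return self.records.groupby("heart_id").apply(ok, include_groups=False)

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def iter_spectra(self):
        """Yield (row, SpectrumRecord) for every manifest row."""
        for _, row in self.records.iterrows():
            yield row, read_spectrum(self.resolve(row["path"]))


def load_manifest(path: str | Path, check_files: bool = False) -> CohortManifest:
    """Load and validate a cohort manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    man = CohortManifest(df, base_dir=path.parent)
    if check_files:
        for p in df["path"]:
            if not man.resolve(p).exists():
                raise ManifestError(f"referenced spectrum missing: {p}")
    for heart, flag in man.paper_grid_flags.items():
        if not flag:
            logger.info("heart %s uses a non-reference time grid", heart)
    return man


# ---------------------------------------------------------------------------
# images, ROIs and traces

def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-frame 8-bit grayscale TIFF as (frames, rows, cols)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(arr: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.uint8))
    return path


def read_rois(path: str | Path) -> dict[str, np.ndarray]:
    """Read cell ROI polygons from CSV (columns cell_id, x, y; 0-based pixels).

    Returns a mapping cell_id -> (n_vertices, 2) array of (x, y).
    """
    df = pd.read_csv(path)
    return {
        str(cid): sub[["x", "y"]].to_numpy(dtype=float)
        for cid, sub in df.groupby("cell_id", sort=False)
    }


def write_rois(rois: Mapping[str, np.ndarray], path: str | Path) -> Path:
    rows = []
    for cid, poly in rois.items():
        for x, y in np.asarray(poly, dtype=float):
            rows.append({"cell_id": cid, "x": x, "y": y})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_oxygen_csv(trace_path: str | Path, events_path: str | Path,
                    protein_ug: float):
    """Read an oximetry trace CSV (time_s, o2_percent) and its events CSV
    (time_s, label) into an :class:`~cardioraman.oxygen.OxygenTrace`."""
    from .oxygen import OxygenTrace

    tr = pd.read_csv(trace_path)
    ev = pd.read_csv(events_path)
    events = [(float(t), str(lbl)) for t, lbl in zip(ev["time_s"], ev["label"])]
    return OxygenTrace(
        time_s=tr["time_s"].to_numpy(dtype=float),
        o2_percent=tr["o2_percent"].to_numpy(dtype=float),
        events=events,
        protein_ug=protein_ug,
    )


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
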