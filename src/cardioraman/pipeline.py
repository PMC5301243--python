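"""End-to-end conveniences: preprocess + quantify whole cohorts."""

from __future__ import annotations

import logging

import pandas as pd

from .io import CohortManifest, SpectrumRecord
from .peaks import DEFAULT_BANDS, build_peak_table, peak_frame
from .preprocess import DEFAULT_FIT_RANGE, preprocess_record

logger = logging.getLogger("cardioraman")


def quantify_records(records, bands=DEFAULT_BANDS, order: int = 7,
                     iterations: int = 100,
                     fit_range=DEFAULT_FIT_RANGE,
                     reference_band: str = "1450") -> pd.DataFrame:
    """Background-subtract and peak-quantify an iterable of spectra.

    Returns the long-format peak table (one row per spectrum point and
    band) used by the time-course statistics.
    """
    tables = []
    for rec in records:
        if isinstance(rec, tuple):  # (record, ground_truth) pairs pass through
            rec = rec[0]
        sub = preprocess_record(rec, order=order, iterations=iterations,
                                fit_range=fit_range)
        tables.append(build_peak_table(sub, bands=bands,
                                       reference_band=reference_band,
                                       whole_range=fit_range))
    return peak_frame(tables)


def quantify_manifest(manifest: CohortManifest, **kw) -> pd.DataFrame:
    """Quantify every spectrum referenced by a cohort manifest."""
    def records():
        for _, rec in manifest.iter_spectra():
            yield rec
    return quantify_records(records(), **kw)
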