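"""Wavenumber calibration and autofluorescence background removal.

Tissue Raman spectra under 532-nm excitation sit on a broad autofluorescence
continuum.  The background is estimated by iterative modified polynomial
fitting ("modpoly"): an order-7 polynomial is fitted by least squares, the
working spectrum is truncated to the pointwise minimum of data and fit, and
the cycle repeats for a fixed 100 iterations; the final polynomial is the
background.  Peaks, which rise above the continuum, are progressively
excluded by the truncation while the smooth baseline is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .io import SpectrumRecord, SpectrumValidationError

logger = logging.getLogger("cardioraman")

DEFAULT_FIT_RANGE = (600.0, 1800.0)


@dataclass
class CalibrationModel:
    """Polynomial map from detector pixel index to wavenumber (cm^-1)."""

    coefficients: np.ndarray  # ascending power order
    degree: int
    residual_rms: float
    pixel_range: tuple[float, float]

    def __call__(self, pixels) -> np.ndarray:
        return P.polyval(np.asarray(pixels, dtype=float), self.coefficients)


@dataclass
class BackgroundFit:
    """Result of the iterative modified polynomial background estimate."""

    coefficients: np.ndarray        # order+1 coefficients on the [-1, 1] axis
    wavenumbers: np.ndarray         # grid the fit was computed on
    background: np.ndarray
    residual: np.ndarray
    iterations_run: int
    history: np.ndarray | None = None  # per-iteration working spectra, optional


def fit_calibration(pixel_positions, reference_wavenumbers,
                    degree: int = 2) -> CalibrationModel:
    """Least-squares polynomial calibration from (pixel, wavenumber) pairs
    of known reference bands (e.g. ethanol).

    ``degree`` is 1 or 2; the fitted map must be strictly increasing over the
    spanned pixel range (a spectrograph disperses monotonically).
    """
    px = np.asarray(pixel_positions, dtype=float)
    wn = np.asarray(reference_wavenumbers, dtype=float)
    if degree not in (1, 2):
        raise ValueError("calibration degree must be 1 or 2")
    if px.size != wn.size or px.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} (pixel, wavenumber) pairs")
    order = np.argsort(px)
    px, wn = px[order], wn[order]
    if np.any(np.diff(px) <= 0) or np.any(np.diff(wn) <= 0):
        raise ValueError("reference wavenumbers must increase strictly with pixel")
    coeffs = P.polyfit(px, wn, degree)
    fitted = P.polyval(px, coeffs)
    rms = float(np.sqrt(np.mean((fitted - wn) ** 2)))
    dense = np.linspace(px[0], px[-1], 512)
    if np.any(np.diff(P.polyval(dense, coeffs)) <= 0):
        raise ValueError("fitted calibration is not monotone over the pixel range")
    return CalibrationModel(coeffs, degree, rms, (float(px[0]), float(px[-1])))


def apply_calibration(pixel_spectrum, model: CalibrationModel,
                      **metadata) -> SpectrumRecord:
    """Map a pixel-indexed spectrum onto the calibrated wavenumber axis."""
    y = np.asarray(pixel_spectrum, dtype=float)
    axis = model(np.arange(y.size))
    if np.any(np.diff(axis) <= 0):
        raise ValueError("calibration model non-monotone over this pixel range")
    return SpectrumRecord(axis, y, **metadata)


def _design_matrix(wavenumbers: np.ndarray, order: int):
    lo, hi = wavenumbers[0], wavenumbers[-1]
    x = 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0  # conditioning: [-1, 1]
    V = P.polyvander(x, order)
    Q, R = np.linalg.qr(V)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise np.linalg.LinAlgError(
            "singular polynomial fit despite axis normalization to [-1, 1]; "
            "check for a degenerate wavenumber grid"
        )
    return V, Q, R


def modpoly_background(record: SpectrumRecord, order: int = 7,
                       iterations: int = 100,
                       fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                       tol: float | None = None,
                       keep_history: bool = False) -> BackgroundFit:
    """Estimate the autofluorescence background by iterative modified
    polynomial fitting.

    Starting from the raw intensities, each round fits an order-``order``
    polynomial b to the working spectrum w on the normalized axis and sets
    ``w <- min(w, b)`` pointwise; after ``iterations`` rounds the final
    polynomial is the background and ``residual = input - background``.

    Parameters
    ----------
    tol
        Optional early-stop: quit when the working spectrum changes by less
        than ``tol`` in relative sup-norm.  Default None runs the fixed
        iteration count.
    keep_history
        Store the working spectrum after every iteration (for diagnostics).
    """
    wn, y = record.wavenumbers, record.intensities
    sel = (wn >= fit_range[0]) & (wn <= fit_range[1])
    wn, y = wn[sel], y[sel]
    if wn.size < 4 * (order + 1):
        raise ValueError(
            f"fit range contains {wn.size} points; need >= {4 * (order + 1)} "
            f"for an order-{order} background"
        )
    V, Q, R = _design_matrix(wn, order)
    w = y.astype(float).copy()
    scale = max(float(np.max(np.abs(w))), 1e-300)
    history = [] if keep_history else None
    n_run = 0
    for _ in range(iterations):
        coef = np.linalg.solve(R, Q.T @ w)
        b = V @ coef
        w_new = np.minimum(w, b)
        n_run += 1
        if history is not None:
            history.append(w_new.copy())
        if tol is not None and np.max(np.abs(w_new - w)) < tol * scale:
            w = w_new
            break
        w = w_new
    background = V @ np.linalg.solve(R, Q.T @ w)
    return BackgroundFit(
        coefficients=np.linalg.solve(R, Q.T @ w),
        wavenumbers=wn,
        background=background,
        residual=y - background,
        iterations_run=n_run,
        history=np.asarray(history) if history is not None else None,
    )


def subtract_background(record: SpectrumRecord, fit: BackgroundFit) -> SpectrumRecord:
    """Return the background-subtracted spectrum on the fit grid.

    The record is cropped to the fitted range; metadata is preserved and the
    ``background_subtracted`` provenance flag is set.  Subtracting twice is
    refused.
    """
    if record.background_subtracted:
        raise SpectrumValidationError(
            f"spectrum heart={record.heart_id} already background-subtracted"
        )
    wn = record.wavenumbers
    sel = (wn >= fit.wavenumbers[0]) & (wn <= fit.wavenumbers[-1])
    if not np.array_equal(wn[sel], fit.wavenumbers):
        raise ValueError("background fit grid does not match the spectrum grid")
    return record.copy_with(
        wavenumbers=fit.wavenumbers,
        intensities=record.intensities[sel] - fit.background,
        background_subtracted=True,
    )


def preprocess_record(record: SpectrumRecord, order: int = 7,
                      iterations: int = 100,
                      fit_range: tuple[float, float] = DEFAULT_FIT_RANGE) -> SpectrumRecord:
    """Convenience: modpoly fit + subtraction in one call."""
    fit = modpoly_background(record, order=order, iterations=iterations,
                             fit_range=fit_range)
    return subtract_background(record, fit)


def despike(record: SpectrumRecord, window: int = 7,
            z_threshold: float = 8.0) -> SpectrumRecord:
    """Replace single-pixel cosmic-ray spikes by the running median.

    A point is a spike when its deviation from the window median exceeds
    ``z_threshold`` robust standard deviations (MAD-based) of the deviations.
    Off by default in the pipeline; clean spectra pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    from scipy.ndimage import median_filter

    y = record.intensities
    med = median_filter(y, size=window, mode="nearest")
    dev = y - med
    mad = np.median(np.abs(dev - np.median(dev)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return record
    spikes = np.abs(dev) > z_threshold * robust_sd
    n = int(spikes.sum())
    if n:
        logger.info("despike: replaced %d point(s)", n)
        y = y.copy()
        y[spikes] = med[spikes]
        return record.copy_with(intensities=y)
    return record
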