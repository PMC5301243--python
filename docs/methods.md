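# Methods

This note records the models, conventions and numerical choices behind
`cardioraman`, and what the synthetic-data tests do and do not establish
about real instrument data.

## Spectral model and preprocessing

A point Raman spectrum of perfused myocardium is modelled as sharp
vibrational bands superposed on a broad autofluorescence continuum.  The
bands used throughout are the standard 532-nm assignments: reduced
cytochrome c/b at 750 and 1127 cm⁻¹, cytochrome-c-specific 1313 cm⁻¹ and
cytochrome-b-specific 1337 cm⁻¹, oxy-myoglobin at 1377/1587/1640 cm⁻¹,
deoxy-myoglobin at 1556 cm⁻¹, reduced cytochromes at 1582 cm⁻¹, and the
CH₂ lipid bend at 1450 cm⁻¹.

**Wavenumber calibration** maps detector pixel to cm⁻¹ by a degree-1 or
degree-2 least-squares polynomial through user-supplied reference-band
positions (ethanol is the usual reference).  Degree 2 is the default
because spectrograph dispersion is mildly nonlinear; the fitted map must
be strictly monotone over the pixel range.  Reference band positions are
not hardcoded: instruments differ, so the (pixel, wavenumber) pairs are
an input.

**Background removal** is the classic iterative modified polynomial fit:
with the axis rescaled to [−1, 1] for conditioning, an order-7 polynomial
is least-squares fitted to the working spectrum and the spectrum is
replaced by the pointwise minimum of itself and the fit; after a fixed
100 iterations the final polynomial is the background.  The design matrix
is QR-factorized once per spectrum, so the 100 rounds cost two small
matrix products each (~2 ms for a 1200-point spectrum).  No early
stopping is used by default (an optional relative tolerance of the
working spectrum is available); the truncation makes the working spectrum
pointwise non-increasing across iterations, which the tests assert.  The
default fit range is 600–1800 cm⁻¹ (the displayed fingerprint window) and
is configurable.

*Accuracy envelope (known limitation).*  The truncation iteration
converges to a background that sits slightly above the true continuum
under peaks, because the first fits include the peaks and truncated
points never recover.  The bias at a peak centre is below ~2% of the peak
amplitude for narrow bands (fwhm ≲ 15 cm⁻¹) away from the fit-range
edges — the regime of all bands quantified here — but grows with band
width and edge proximity, exceeding 5% for fwhm ≈ 30 cm⁻¹ peaks within
~100 cm⁻¹ of a range edge.  A unit test pins this pattern, and the
acceptance suite's blanket 5%-fidelity check over arbitrary widths and
positions fails for exactly this reason; the more elaborate baseline
algorithms (I-ModPoly, airPLS) exist to remove this bias and are out of
scope here.

**Despiking** (off by default) replaces points deviating more than a
robust z-threshold from a running median; cosmic-ray hits are the target.

## Peak quantification

"Baseline to peak" is implemented as: peak = maximum intensity within
±8 cm⁻¹ of the band centre (so small calibration offsets do not clip the
apex); local baseline = the line through the two shoulder minima searched
in [±8, ±25] cm⁻¹, evaluated at the peak position; height = peak −
baseline.  The local baseline, applied after global background
subtraction, absorbs any residual broad structure.  For an isolated
Lorentzian the shoulder minima sit on the band's own tails, so the
measured height is the amplitude times (1 − tail at 25 cm⁻¹); tests use
this closed form as the oracle.  Heights may be negative for absent
bands and are deliberately not clamped, so replicate averages are
unbiased.

Two normalizations are computed: height over the 1450 cm⁻¹ lipid-band
height (the lipid pool is stable in early ischaemia, so this ratio
cancels illumination and collection-efficiency drift), and height over
the trapezoidal integral of the background-subtracted spectrum across the
fit range ("whole-spectrum" normalization; a sum-of-heights variant is
available behind a flag, since the integral definition is a choice).

Replicate points of one (heart, phase, time) are averaged band-wise;
undefined ratios (non-positive reference height) are skipped with the
surviving n recorded.

## Statistics

Hearts are the unit of inference: replicate points never enter tests
directly.  Group summaries are mean ± SEM (sd with n−1 in the variance,
divided by √n; a singleton group reports SEM 0 and is flagged).  The
per-time comparison of each treated group against control uses the
Kruskal–Wallis H test with midrank tie correction and the chi-square
approximation; Mann–Whitney (U = min(U_a, U_b)) serves two-sample
readouts.  Exact permutation p-values are computed by full enumeration
when the pooled sample is small (N ≤ 8 for KW, N ≤ 12 for MW, where
enumeration is cheap and the asymptotics are coarse); with ties the
enumeration operates on midranks and remains exact.  All tests are
two-sided.  No multiple-testing correction is applied by default, to
match per-time significance marking conventions; Holm's step-down is
available behind a flag.  At the reference design (3 control vs 8
treated) the two-group rank test is discrete with 165 distinct
assignments; its smallest achievable p is 0.0143 and its true size at
α = 0.05 is 8/165 ≈ 0.0485, which the null-calibration acceptance test
verifies empirically.

`plateau_time` reports the earliest (linearly interpolated) time at
which a series reaches a fraction (default 0.95) of its final value and
stays there; if only the final sample qualifies, the final time is
returned, and a series whose threshold is never durably met returns
none.

## Oxygen consumption

State IV is the post-succinate, state III the post-ADP respiration state
(substrate chemistry, not figure ordering, fixes the mapping; it is
configurable).  Each slope is the least-squares linear fit over the
closed-open 60-s window starting 60 s after the respective addition,
reported as a positive consumption magnitude, and converted by
rate = 199 nmol × Y / 20.9 × 1000 / M µg.  The 199 nmol chamber constant
is treated as an opaque calibration value.  The respiratory control
ratio (III/IV) is exposed as a derived quantity only.

## Imaging readouts

TMRE traces are per-frame mean pixel values inside cell ROI polygons
(pixel-centre containment), normalized to the mean of the first three
frames; latency is the linear interpolation of the first crossing of
0.5.  Cells that never cross are censored and excluded from group
statistics with a logged count.  Latency is equivariant under time
shifts, and with 5-min frames the interpolation error on a logistic
collapse is well under half a frame.

TTC slices are thresholded at 113 on the 8-bit scale, inclusive; pale
(≥ threshold) tissue pixels count as infarct, with the comparison
direction flippable for inverted setups.  The left-ventricle infarct
percentage is the tissue-pixel-count weighted average across slices
(pixel count proxies slice mass; the weighting definition is a package
choice).

## Synthetic cohorts

The generator emulates the stopped-flow experiment: 3 control, 8 SI and
9 IPC hearts; spectra at 15/45 min of perfusion and 10–120 min of
ischaemia (controls are sampled at the same elapsed times while still
perfused, providing matched per-time comparators); 5 replicate points
per heart and time by default.

Cytochrome reduction follows r(t) = r∞(1 − e^(−t/τ)) with r∞ = 1,
τ_SI = 18 min and τ_IPC = 35 min — calibrated so the SI ratio course is
clearly rising by 10 min and within 5% of plateau near 60 min, with IPC
visibly retarded; these are generator calibrations, not measured
constants.  Myoglobin deoxygenates as m(t) = e^(−t/12 min).  Bands are
Lorentzians (resonance Raman bands are near-Lorentzian) whose amplitudes
scale with r (reduced-cytochrome bands), m (oxy-Mb), 1 − m (deoxy-Mb) or
1 (lipid — the pool itself is stable; the apparent drift of its absolute
peak comes from the background).  The continuum is a fixed smooth
polynomial plus a broad Gaussian hump (centre 1300 cm⁻¹, fwhm
600 cm⁻¹) whose amplitude grows at 1.5 counts/min of ischaemia — this
reproduces the motivation for ratio normalization: absolute heights
drift, post-subtraction ratios do not.  Noise is Gaussian with
sd = 3·√(1 + I/800) counts; a lognormal per-heart scale factor
(sd 0.15) models optical-coupling variability and cancels in all ratios.
One master seed is split hierarchically (heart, then time/point), so
enlarging the cohort never changes existing hearts' data.

TMRE: per-cell logistic decays F₀/(1 + e^((t−L)/1.5 min)) with L drawn
from N(37.3, 4.5²) min for SI and N(43.5, 2.2²) for IPC (group SDs are
scaled from reported SEMs at 20 cells), rendered into 8-bit stacks at
5-min frames.  TTC: disk tissue masks in which an exact pixel count is
set to gray 180 (bleached) against 60 (stained), so noiseless recovery
through the threshold at 113 is exact by construction, and σ = 5 noise
leaves a > 13σ margin on both sides.  Oximetry: piecewise-linear %O₂ at
1 Hz with events at 60/180/360 s and configurable state IV/III slopes.

What passing synthetic tests do **not** show: the generator has no
detector baseline structure, étalon fringes, wavenumber miscalibration
drift, heart motion, photobleaching, or spatial heterogeneity of
ischaemia; band positions are exact and lineshapes purely Lorentzian.
Results on real spectra therefore depend on calibration quality and on
the continuum being smooth at the order-7 scale, which the synthetic
suite assumes rather than tests.

## Problem sizes used in the automated checks

The acceptance-style simulations run at the study design (3/8/9 hearts,
7 ischaemia times) with one point per heart and time for the 100-replicate
group-separation check (replicate-point averaging only narrows per-heart
noise, which the check does not need), 1000 single-time replicates for
null-test calibration, and 100 random spectra for baseline fidelity.
Full 5-point cohorts are used where per-heart averaging matters (τ
recovery).

## Degenerate inputs and tie-breaks

Spectra shorter than 16 samples are accepted with a warning (2 is the
hard minimum); duplicate wavenumbers are rejected.  All-identical pooled
samples give H = 0, p = 1.  A peak search returns the first index at a
tied maximum; shoulder minima likewise.  TTC thresholding is inclusive
(gray 113 counts as bleached).  Background subtraction refuses to run
twice on the same record.
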