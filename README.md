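# cardioraman

Label-free assessment of myocardial ischaemia from spontaneous Raman
spectra of the perfused heart, with the companion readouts used to
benchmark it: TMRE membrane-potential latency, TTC infarct fraction, and
mitochondrial oxygen-consumption rates.

## The problem

When coronary flow stops, the mitochondrial electron-transport chain backs
up and cytochromes c and b accumulate in their reduced forms. Under 532-nm
excitation the reduced cytochromes have strong resonance Raman bands at
750, 1127, 1313 and 1337 cm⁻¹, so a point spectrum of the subepicardial
myocardium reports the redox state of the tissue — minutes after the onset
of ischaemia, well before membrane-potential loss (TMRE), loss of TTC
stainability, or any histological change. This package implements the full
analysis chain needed to turn raw two-column spectra into that readout,
for three experimental arms: continuously perfused controls, simple
stopped-flow ischaemia (SI), and ischaemic preconditioning (IPC).

## What it computes

* **Baseline removal** — the tissue autofluorescence continuum is
  estimated by iterative modified polynomial fitting: an order-7
  polynomial is least-squares fitted on a normalized axis and the working
  spectrum is truncated to `min(data, fit)`, for 100 iterations.
* **Band heights and ratios** — per band, height = maximum within
  ±8 cm⁻¹ of the assigned centre minus a local linear baseline through the
  shoulder minima (±8…±25 cm⁻¹). Heights are normalized by the
  1450 cm⁻¹ CH₂ lipid band (stable in early ischaemia) and, alternatively,
  by the integrated spectrum: I(ν)/I(1450) and I(ν)/∫I.
* **Time-course statistics** — per-heart aggregation of replicate points,
  mean ± SEM per group per time, and Kruskal–Wallis / Mann–Whitney
  comparisons against control at each time, with exact permutation
  p-values at small N (≤ 8 pooled for KW, ≤ 12 for MW).
* **TMRE latency** — per-cell fluorescence traces from confocal stacks,
  normalized to baseline; latency = interpolated time of 50% loss.
* **TTC infarct** — fraction of tissue pixels at/above the 113/255
  threshold per slice, combined as a tissue-pixel weighted average.
* **Respiration** — state IV/III slopes from oximetry traces (1-min
  window starting 1 min after succinate / ADP addition) converted by
  rate = 199 nmol × Y / 20.9 × 1000 / M (µg) to nmol O₂/min/mg protein.
* **Synthetic cohorts** — a seeded generator producing all four data
  modalities with known ground truth (saturating reduction kinetics
  r(t) = r∞(1 − e^(−t/τ)), τ_SI = 18 min, τ_IPC = 35 min), so the whole
  pipeline is testable without instrument data.

## Worked example

Simulate a cohort at the reference design (3 control / 8 SI / 9 IPC
hearts, ischaemia sampled at 10–120 min), quantify the 750 cm⁻¹ reduced
cytochrome band, and compare groups per time:

```python
from cardioraman import quantify_records, summary_table, timecourse_compare
from cardioraman.synth import SynthConfig, simulate_cohort_records

cfg = SynthConfig()
records = [rec for rec, truth in
           simulate_cohort_records(cfg, seed=42, points_per_time=1)
           if rec.phase == "ischaemia"]
peaks = quantify_records(records)          # modpoly + peak table, long format
print(summary_table(peaks, "ratio_1450", band="750").round(3))
print(timecourse_compare(peaks, "ratio_1450", band="750").round(4))
```

Output (abridged):

```
  group  time_min     metric  mean   sem  n
     SI      10.0 ratio_1450 0.628 0.009  8
     SI      60.0 ratio_1450 1.368 0.013  8
     SI     120.0 ratio_1450 1.419 0.010  8
    IPC      10.0 ratio_1450 0.377 0.009  9
    IPC     120.0 ratio_1450 1.387 0.014  9
control      10.0 ratio_1450 0.079 0.007  3
control     120.0 ratio_1450 0.080 0.020  3

 time_min    comparison           test  statistic  p_value  n_control  n_group
     10.0 SI vs control kruskal_wallis        6.0   0.0143          3        8
    120.0 SI vs control kruskal_wallis        6.0   0.0143          3        8
```

The I(750)/I(1450) ratio rises immediately after stopped flow and
saturates by ~60 min; IPC lags SI at every time (slower reduction
kinetics), and controls stay flat. SI differs from control already at
10 min (p = 0.014, the smallest value the chi-square-approximated rank
test can produce at n = 3 vs 8 with complete separation).

The same workflow is available from the shell:

```sh
cardioraman simulate --seed 42 --out cohort/
cardioraman quantify --manifest cohort/manifest.csv --out peaks.csv
cardioraman timecourse --peaks peaks.csv --out stats.csv
cardioraman report --peaks peaks.csv --out report/
```

plus `preprocess`, `tmre`, `ttc` and `oxygen` subcommands for the
individual stages.

## Layout

```
src/cardioraman/
  io.py          spectra / manifests / images / traces, validation
  preprocess.py  wavenumber calibration, modpoly background, despiking
  peaks.py       band definitions, heights, ratio normalizations
  stats.py       summaries, rank tests (exact + asymptotic), plateau time
  oxygen.py      state III/IV slopes and respiration rates
  imaging.py     TMRE latency, TTC infarct quantification
  synth.py       seeded multimodal synthetic-cohort generator
  pipeline.py    cohort-level conveniences
  cli.py         the `cardioraman` command
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations (including the accuracy envelope of the modified
polynomial baseline).
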