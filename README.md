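# cvhrisk

Risk stratification of myocardial-infarction survivors from Holter-ECG
RR-interval series.  The package automates a scoring method for
sleep-disordered breathing (SDB) based on **cyclic variation of heart
rate (CVHR)** — the alternating bradycardia/tachycardia pattern that
apnea–arousal cycles imprint on the nocturnal heart-rate tachogram —
together with the detection of **flat nocturnal tachograms**, the
classical autonomic risk-marker panel (HRV, heart rate turbulence,
deceleration capacity, severe autonomic failure), and the survival
analyses that relate all of these markers to 5-year all-cause mortality.

It is aimed at researchers in cardiac electrophysiology and
biosignal-based risk prediction who want a tested, scriptable version of
this analysis chain, plus a synthetic-cohort generator for validating
every stage without patient data.

## The method

Starting from a beat-annotated RR series (labels N/V/S/X), the nocturnal
6-h segment (00:00–06:00) is cut out, normal-to-normal (NN) intervals
are selected, and the instantaneous heart rate HR = 60000 / RR (bpm) is
plotted against time:

* **Flat tachogram** — excursions of the smoothed HR below 5 bpm *and*
  no visible respiratory sinus arrhythmia (HF-band modulation < 1 bpm).
  Flat tachograms cannot be scored for SDB and are themselves a strong
  mortality marker.
* **CVHR scoring** — an *arousal* is an HR rise ≥ 6 bpm above the local
  baseline lasting ≥ 10 s; ≥ 3 successive arousals separated by ≤ 2 min
  form a *CVHR episode*; total episode minutes ≥ 20 % of the segment
  (72 min of 6 h) ⇒ SDB present.
* **Risk panel** — SDNN, SDANN, RMSSD, HRV triangular index, spectral
  powers (TP/VLF/LF/HF), heart rate turbulence (TO %, TS ms/RR),
  deceleration capacity (PRSA), and SAF = abnormal HRT (TS ≤ 2.5,
  TO ≥ 0) ∧ abnormal DC (≤ 4.5 ms).
* **Survival stage** — Kaplan–Meier curves with log-log Greenwood 95 %
  bands, log-rank tests, Cox proportional-hazards models (Efron ties),
  a CVHR-threshold mortality scan, and Pearson correlation.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_recordings.py
python analysis/03_survival_analysis.py
```

The first script draws a 1590-patient synthetic cohort (seed 1) and
prints

```
cohort of 1590 patients (seed 1):
  flat tachogram: 91 (5.7%)
  SDB among non-flat: 617 (41.2%)
  5-y deaths: 155 (9.7%)
```

i.e. about 5 % of patients have a flat nocturnal tachogram and about
40 % of the scorable patients cross the 72-min SDB cutpoint.  The second
script regenerates 12 recordings and pushes them through the full
per-patient pipeline; scored CVHR minutes track the planted values
(e.g. 15.2 vs 15.5 min, 110.5 vs 110.2 min) with 100 % agreement on
flat and SDB status.  The third script runs the cohort statistics:

```
5-y mortality flat:     30.8% [22.4%, 41.4%] (n=91)
5-y mortality non-flat: 8.5% [7.2%, 10.0%] (n=1499)
log-rank flat vs non-flat: p = 5.00e-14
log-rank SDB present vs absent: p = 0.109
multivariable Cox model:  flat HR 2.33 [1.51, 3.59], p = 0.0001 ...
CVHR vs nocturnal respiratory rate: r = 0.004
```

A flat tachogram marks a high-mortality subgroup and stays an
independent predictor after adjustment, while SDB status itself does
not separate the survival curves — the structure the generator encodes
and the pipeline recovers.

There is also a CLI: `cvhrisk simulate`, `cvhrisk score`, `cvhrisk
cohort` (see `cvhrisk --help`).

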