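# Methods

## Scope and data model

The pipeline starts from beat-annotated RR-interval series: per beat, a
time from recording start, the RR interval ending at that beat (ms) and
a label (N sinus, V ventricular ectopic, S supraventricular ectopic, X
artifact).  Upstream QRS detection and annotation review are out of
scope; the CSV dialect (`time_s,rr_ms,label` with a
`# clock_start=HH:MM:SS` header) is the interchange format, with a
WFDB-style import left as an adapter point.  Clock arithmetic is
modular over 24 h, so recordings crossing midnight need no special
handling; window membership is judged by each beat's end time and the
nocturnal window [00:00, 06:00) is half-open so a boundary beat is
never counted twice.

The original scoring method gives no minimum analyzable time for the
nocturnal window.  We require coverage (in-window NN time / window
length) of at least 0.8; patients below it are flagged *non-analyzable*,
a category deliberately distinct from *flat*.

## Flat-tachogram rule

The published criterion is visual: no HR excursion ≥ 5 bpm and no
visible respiratory sinus arrhythmia (RSA), adjudicated by two readers.
Our operationalisation:

* **Excursion** — 99.5th minus 0.5th percentile of the smoothed HR
  channel (5-s running median).  Robust percentiles rather than raw
  min/max play the role of the consensus review: a single
  ectopy-adjacent artifact cannot defeat flatness.  The 5-s median
  suppresses beat-level noise while preserving the ≥ 10-s arousals the
  CVHR stage must see.
* **RSA** — amplitude of HF-band (0.15–0.40 Hz) HR modulation,
  estimated as √2 × SD of the band-passed (3rd-order Butterworth,
  forward-backward) 2-Hz resampled HR trace; "visible" means ≥ 1 bpm.
  Interval-domain sampling at ~1 Hz and linear resampling attenuate a
  0.25-Hz modulation by roughly a quarter, which the test fixtures
  account for by planting RSA amplitudes ≥ 2 bpm when RSA must be
  detected and 0 when it must not.

Both thresholds (5 bpm, 1 bpm) are configurable; whether the 5-bpm rule
applies to raw or smoothed HR is not specified in the source method, and
we apply it to the smoothed channel.

## CVHR scoring

Arousal: a maximal span where smoothed HR exceeds the local baseline by
≥ 6 bpm for ≥ 10 s.  The baseline — never defined by the manual method —
is a running 120-s lower quartile of smoothed HR, which tracks the
inter-arousal trough without being dragged up by the surges.  Because
the baseline is slow by construction, it is computed on a 0.5-Hz
decimated grid and linearly interpolated back to the 2-Hz analysis
grid; this is numerically indistinguishable from the direct filter and
about an order of magnitude cheaper.

Episodes chain ≥ 3 successive arousals with end-to-start gaps ≤ 120 s
(greedy left-to-right, which for this gap criterion equals exhaustive
maximal-run enumeration — property-tested against a brute-force
oracle).  The episode span runs from first-arousal onset to
last-arousal end, so bradycardic apnea phases between arousals count as
CVHR time, and total CVHR minutes are continuous (not whole scored
minutes).  All thresholds are inclusive (≥ 6 bpm, ≥ 10 s, ≤ 120 s, ≥ 3
arousals, ≥ 72 min) and exposed as configuration
(`arousal_min_delta_bpm`, `arousal_min_dur_s`, `max_gap_s`,
`min_arousals`, `sdb_fraction`).

SDB is called when CVHR minutes reach 20 % of the scored segment —
72 min for the 6-h nocturnal window.  Flat tachograms are routed to
`indeterminate_flat` before any arousal detection.

## Risk-marker panel

Time-domain HRV follows the standard task-force definitions, with the
HRV triangular index computed on a 1/128-s histogram bin.  Frequency-
domain powers come from Welch periodograms (Hann, 600-s segments, 50 %
overlap) of the 4-Hz cubic-spline-resampled NN tachogram, linearly
detrended per contiguous stretch; stretches are split at gaps > 20 s
and must be ≥ 5 min.  Band edges: VLF 0.0033–0.04, LF 0.04–0.15, HF
0.15–0.40 Hz; TP 0.0033–0.40 Hz.  Undefined metrics are NaN, never
silent zeros.  Whether the published marker panel uses the full
recording or only the nocturnal segment is unstated; we default to the
full recording with a `hrv_nocturnal_only` flag.

Heart rate turbulence uses the standard VPC filters (coupling < 80 %
and pause > 120 % of the mean of the two preceding NN intervals;
surrounding sinus intervals within 300–2000 ms; ≥ 2 NN before, ≥ 15
after).  TO is averaged per VPC; for TS the post-pause tachograms are
averaged first, then the steepest 5-interval least-squares slope is
taken.  Deceleration capacity uses PRSA with anchors defined by < 5 %
prolongation, a 20-beat window half-width and a 100-anchor minimum.
Patients without valid VPCs or enough anchors are *undefined* and are
excluded from the SAF denominator rather than defaulted — the source
analysis does not state how such patients were handled.

SAF = abnormal HRT (TS ≤ 2.5 ms/RR and TO ≥ 0 %) AND abnormal DC
(≤ 4.5 ms).

## Survival stage

Kaplan–Meier estimation, log-rank tests and Cox fits are delegated to
lifelines behind this package's result layer; the tests cross-check
them against brute-force product-limit and risk-set-enumeration
oracles.  Choices the source leaves open: Greenwood CIs on the
log(−log S) scale (keeps bands in [0, 1]); Efron tie handling (the
death times here are near-continuous).  The CVHR-threshold mortality
scan evaluates every observed CVHR value as a threshold and suppresses
subgroups below 20 patients; both are configurable.

## Synthetic data

`simulate_tachogram` builds HR(t) = base + RSA sinusoid (~0.25 Hz) +
slow drift (1 cycle/h) + planted episode waveform + Gaussian noise on a
4-Hz grid, then inverts the cumulative beat count so RR intervals match
inter-beat times exactly.  Episode cycles are trapezoidal surges
(default 8 bpm for 15 s every 45 s, 2.5-s ramps) preceded by apnea dips
of half the surge amplitude; spec validation guarantees planted
episodes satisfy the scoring rules by construction.  `flat_mode` forces
zero RSA and total drift < 5 bpm.

`simulate_cohort` draws a statistical twin of the study population:
age ~ N(59.2, 11.3) years, 20.6 % female, LVEF ~ N(55, 13.3) %, GRACE ~
N(96, 24.5), 17 % diabetes (normal approximations from the published
median/IQR summaries), nocturnal respiratory rate ~ N(18, 2.5)
breaths/min (typical post-MI nocturnal values; it feeds only the
null-correlation check).  Flat-tachogram status follows a logistic link
on age (log-OR 0.09/year, intercept solved for 4.8 % marginal
prevalence), so flat patients are older, as observed.  Non-flat CVHR
minutes come from a two-mode mixture — gamma(2.2, 16) low mode and
N(110, 25) high mode — with the mixing weight solved analytically so
38.6 % of non-flat patients exceed the 72-min cutpoint while the
low-CVHR tail stays populated.  Outcomes are exponential with
proportional hazards on the published multivariable log-hazards (HRs
1.73 flat, 1.06/year age, 0.98 female, 0.95/% LVEF, 1.004/point GRACE,
1.66 diabetes), with the baseline rate root-solved per cohort so the
marginal 5-year event fraction is 10.35 %, and administrative censoring
at 5 years.  Covariates are otherwise independent, which real cohorts
are not (LVEF, GRACE and diabetes correlate); the generator validates
estimator recovery, not epidemiology.  SAF status is drawn to reproduce
the published overlap structure (≈ 23 % of flat, ≈ 6 % of non-flat
patients) and is associational only — it carries no extra hazard beyond
its correlation with flat status.

What passing tests show: the detector recovers episodes *of the planted
waveform* under Gaussian noise; real recordings add ectopy bursts,
noise artifacts, non-stationary baselines and atypical CVHR
morphologies that the generator does not emulate, so synthetic recall ≈
1 is an upper bound, not a clinical performance estimate.

The group-mortality recovery helper (`simulate_group_survival`) draws
events as Bernoulli with uniform event times on (0, 5] and
administrative censoring at 5 years — the minimal structure needed to
test the product-limit estimate against a known event probability.

## Problem sizes and numerics

Detector-validity studies use 50 seeded 2-h recordings with 3–6 planted
episodes each (surge 8–12 bpm, noise SD 0.3–1.0 bpm); flat-classifier
studies use 200 one-hour fixtures whose drift spans both sides of the
5-bpm boundary with a construction margin (excursion ≤ 3.2 or ≥ 6.5
bpm; RSA 0 or ≥ 2 bpm), since exactly-at-threshold signals have no
well-defined truth under a finite-resolution estimator.  Recovery
studies run 200 cohorts of n = 1590 (Cox) and 200 groups of n = 77 /
1513 (Kaplan–Meier); CI-coverage checks pool 500 cohorts of n = 300.
The mean recovered hazard ratio slightly exceeds the generating value
(≈ 1.76–1.83 vs 1.73) — Jensen's inequality applied to the
approximately log-normal estimator, visible because the flat group is
small.  Root-finding (Brent) is used for the logistic intercept and
baseline hazard; Newton iteration inside lifelines handles the partial
likelihood, and non-convergence raises instead of returning estimates.

## Known limitations

* The arousal baseline (running lower quartile) is one reasonable
  formalisation of an undefined manual reference level; very long
  surges (> 30 s of every 120-s window) can lift it and shorten
  detected arousals.
* Atrial fibrillation and other non-sinus rhythms are out of scope
  (the source cohort was sinus-rhythm at admission).
* Nocturnal respiratory rate is an input covariate; its derivation from
  ECG morphology is not implemented.
* The GRACE score and LVEF are inputs, never computed.
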