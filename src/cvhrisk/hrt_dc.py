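"""Heart rate turbulence, deceleration capacity, and the SAF composite.

Heart rate turbulence (HRT) is the biphasic sinus-rhythm response after a
ventricular premature complex (VPC): a brief acceleration (quantified by
turbulence onset, TO, in %) followed by a deceleration (turbulence slope,
TS, in ms per RR interval).  Deceleration capacity (DC) averages the
magnitude of spontaneous heart-rate decelerations by phase-rectified
signal averaging (PRSA).  Severe autonomic failure (SAF) is the
conjunction of abnormal HRT (TS <= 2.5 ms/RR and TO >= 0%) and abnormal
DC (<= 4.5 ms).

Formulas and filters follow the standard definitions:

* TO = 100 * ((RR+1 + RR+2) - (RR-2 + RR-1)) / (RR-2 + RR-1), averaged
  over valid VPCs;
* TS = steepest least-squares slope of any 5 consecutive intervals in
  the VPC-averaged post-pause tachogram RR+1..RR+15;
* VPC validity: coupling interval < 80% and compensatory pause > 120% of
  the local reference interval, surrounding sinus intervals within
  300-2000 ms;
* PRSA anchors: NN intervals longer than their predecessor by less than
  5%; DC = (X(0) + X(1) - X(-1) - X(-2)) / 4 of the anchor-aligned
  average X(k).

Patients without valid VPCs (HRT) or enough anchors (DC) get NaN results
and are excluded from the SAF denominator rather than defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rr_io import BeatSeries

TS_ABNORMAL = 2.5  # ms/RR
TO_ABNORMAL = 0.0  # %
DC_ABNORMAL = 4.5  # ms
PHYSIOLOGIC_NN_MS = (300.0, 2000.0)
COUPLING_MAX_FRAC = 0.80
PAUSE_MIN_FRAC = 1.20
PRSA_PROLONGATION_LIMIT = 0.05
PRSA_HALF_WIDTH = 20  # beats of context required around an anchor
MIN_ANCHORS = 100
N_POST = 15  # post-pause intervals entering TS
N_PRE = 2  # pre-coupling intervals entering TO


@dataclass(frozen=True)
class HRTResult:
    turbulence_onset_pct: float
    turbulence_slope_ms_per_rr: float
    n_valid_vpc: int

    @property
    def defined(self) -> bool:
        return self.n_valid_vpc > 0

    @property
    def abnormal(self) -> bool | None:
        if not self.defined:
            return None
        return (
            self.turbulence_slope_ms_per_rr <= TS_ABNORMAL
            and self.turbulence_onset_pct >= TO_ABNORMAL
        )


@dataclass(frozen=True)
class DCResult:
    dc_ms: float
    n_anchors: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.dc_ms)

    @property
    def abnormal(self) -> bool | None:
        return (self.dc_ms <= DC_ABNORMAL) if self.defined else None


@dataclass(frozen=True)
class SAFStatus:
    saf: bool | None
    hrt_abnormal: bool | None
    dc_abnormal: bool | None

    @property
    def defined(self) -> bool:
        return self.saf is not None


def _sinus_context(labels: np.ndarray, i: int) -> bool:
    """VPC at index i with enough sinus context for HRT.

    Layout: ... N N [V] N(pause) RR+1 ... RR+15 ...  The two intervals
    before the coupling interval and the 15 after the pause must all be
    normal-to-normal, i.e. beats i-3..i-1 and i+1..i+16 labeled N.
    """
    lo, hi = i - (N_PRE + 1), i + N_POST + 2
    if lo < 0 or hi > len(labels):
        return False
    ctx = np.r_[labels[lo:i], labels[i + 1 : hi]]
    return bool(np.all(ctx == "N"))


def compute_hrt(series: BeatSeries) -> HRTResult:
    """Turbulence onset and slope averaged over valid VPCs.

    The reference interval is the mean of the two NN intervals preceding
    the coupling interval.  TO is averaged per VPC; for TS the post-pause
    tachograms are averaged first and the steepest 5-interval regression
    slope of the average is taken.
    """
    labels = series.labels
    rr = series.rr_ms
    lo_ms, hi_ms = PHYSIOLOGIC_NN_MS
    to_values = []
    post_tachograms = []
    for i in np.flatnonzero(labels == "V"):
        if not _sinus_context(labels, i):
            continue
        rr_m1, rr_m2 = rr[i - 1], rr[i - 2]
        coupling = rr[i]
        pause = rr[i + 1]
        post = rr[i + 2 : i + 2 + N_POST]
        context = np.r_[rr_m2, rr_m1, post]
        if np.any((context < lo_ms) | (context > hi_ms)):
            continue
        ref = 0.5 * (rr_m1 + rr_m2)
        if not (coupling < COUPLING_MAX_FRAC * ref and pause > PAUSE_MIN_FRAC * ref):
            continue
        to_values.append(100.0 * ((post[0] + post[1]) - (rr_m2 + rr_m1)) / (rr_m2 + rr_m1))
        post_tachograms.append(post)
    if not to_values:
        return HRTResult(np.nan, np.nan, 0)
    mean_post = np.mean(post_tachograms, axis=0)
    x = np.arange(5, dtype=float)
    slopes = [
        np.polyfit(x, mean_post[k : k + 5], 1)[0] for k in range(N_POST - 4)
    ]
    return HRTResult(
        turbulence_onset_pct=float(np.mean(to_values)),
        turbulence_slope_ms_per_rr=float(np.max(slopes)),
        n_valid_vpc=len(to_values),
    )


def compute_dc(
    nn: BeatSeries,
    min_anchors: int = MIN_ANCHORS,
    half_width: int = PRSA_HALF_WIDTH,
) -> DCResult:
    """Deceleration capacity by phase-rectified signal averaging.

    Anchors are NN intervals longer than their predecessor with
    prolongation below 5%; windows of ``half_width`` beats around each
    anchor are averaged into X(k) and DC = (X(0)+X(1)-X(-1)-X(-2)) / 4.
    """
    rr = nn.rr_ms
    if len(rr) < 2 * half_width + 2:
        return DCResult(np.nan, 0)
    prev = rr[:-1]
    cur = rr[1:]
    is_anchor = (cur > prev) & (cur < (1.0 + PRSA_PROLONGATION_LIMIT) * prev)
    anchor_idx = np.flatnonzero(is_anchor) + 1
    anchor_idx = anchor_idx[(anchor_idx >= half_width) & (anchor_idx < len(rr) - half_width)]
    if len(anchor_idx) < min_anchors:
        return DCResult(np.nan, int(len(anchor_idx)))
    offsets = np.arange(-half_width, half_width)
    windows = rr[anchor_idx[:, None] + offsets[None, :]]
    x = windows.mean(axis=0)  # x[half_width + k] == X(k)
    c = half_width
    dc = (x[c] + x[c + 1] - x[c - 1] - x[c - 2]) / 4.0
    return DCResult(float(dc), int(len(anchor_idx)))


def acceleration_capacity(nn: BeatSeries, min_anchors: int = MIN_ANCHORS) -> DCResult:
    """Acceleration-sided PRSA average (used only as a symmetry check)."""
    rr = nn.rr_ms
    hw = PRSA_HALF_WIDTH
    if len(rr) < 2 * hw + 2:
        return DCResult(np.nan, 0)
    prev, cur = rr[:-1], rr[1:]
    is_anchor = (cur < prev) & (cur > (1.0 - PRSA_PROLONGATION_LIMIT) * prev)
    anchor_idx = np.flatnonzero(is_anchor) + 1
    anchor_idx = anchor_idx[(anchor_idx >= hw) & (anchor_idx < len(rr) - hw)]
    if len(anchor_idx) < min_anchors:
        return DCResult(np.nan, int(len(anchor_idx)))
    windows = rr[anchor_idx[:, None] + np.arange(-hw, hw)[None, :]]
    x = windows.mean(axis=0)
    ac = (x[hw] + x[hw + 1] - x[hw - 1] - x[hw - 2]) / 4.0
    return DCResult(float(ac), int(len(anchor_idx)))


def classify_saf(hrt: HRTResult, dc: DCResult) -> SAFStatus:
    """Severe autonomic failure: abnormal HRT *and* abnormal DC.

    Undefined (None) when either component is undefined; such patients do
    not enter the SAF denominator.
    """
    ha, da = hrt.abnormal, dc.abnormal
    saf = (ha and da) if (ha is not None and da is not None) else None
    return SAFStatus(saf=saf, hrt_abnormal=ha, dc_abnormal=da)
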