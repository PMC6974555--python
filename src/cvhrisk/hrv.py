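"""Classical time- and frequency-domain heart-rate-variability metrics.

Conventions follow the standard HRV task-force definitions: SDNN is the
sample SD of all NN intervals; SDANN the sample SD of 5-min segment mean
NN; RMSSD the root-mean-square of successive NN differences; the HRV
triangular index the total NN count divided by the modal bin height of
the NN histogram at 1/128-s bin width.  Spectral powers are integrated
from a Welch periodogram of the 4-Hz cubic-resampled NN tachogram over
VLF 0.0033-0.04, LF 0.04-0.15 and HF 0.15-0.40 Hz (TP 0.0033-0.40 Hz).

Metrics that cannot be computed from the available data are reported as
NaN (an explicit undefined marker), never as a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .rr_io import BeatSeries

VLF_HZ = (0.0033, 0.04)
LF_HZ = (0.04, 0.15)
HF_HZ = (0.15, 0.40)
HRVTI_BIN_MS = 1000.0 / 128.0
PSD_FS = 4.0
MAX_GAP_S = 20.0
MIN_STRETCH_S = 300.0


@dataclass(frozen=True)
class HRVMetrics:
    sdnn_ms: float
    sdann_ms: float
    rmssd_ms: float
    hrv_ti: float
    tp_ms2: float
    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def time_domain(nn: BeatSeries) -> tuple[float, float, float, float]:
    """SDNN, SDANN, RMSSD and the HRV triangular index.

    Successive differences for RMSSD are taken only across contiguous NN
    pairs (no difference is formed across a gap left by ectopy removal).
    SDANN needs at least two complete 5-min segments, else NaN.
    """
    rr = nn.rr_ms
    if len(rr) < 2:
        return (np.nan, np.nan, np.nan, np.nan)
    sdnn = float(np.std(rr, ddof=1))

    t = nn.beat_times
    contiguous = np.isclose(np.diff(t) * 1000.0, rr[1:], rtol=0, atol=1.0)
    diffs = np.diff(rr)[contiguous]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else np.nan

    # SDANN over wall-time 5-min bins containing data
    seg = np.floor((t - t[0]) / 300.0).astype(int)
    n_full = int((t[-1] - t[0]) // 300)
    means = [rr[seg == k].mean() for k in range(n_full) if np.any(seg == k)]
    sdann = float(np.std(means, ddof=1)) if len(means) >= 2 else np.nan

    counts, _ = np.histogram(
        rr, bins=np.arange(rr.min(), rr.max() + 2 * HRVTI_BIN_MS, HRVTI_BIN_MS)
    )
    hrv_ti = float(len(rr) / counts.max())
    return (sdnn, sdann, rmssd, hrv_ti)


def _contiguous_stretches(nn: BeatSeries, max_gap_s: float) -> list[slice]:
    gaps = np.diff(nn.beat_times)
    breaks = np.flatnonzero(gaps > max_gap_s) + 1
    bounds = np.r_[0, breaks, len(nn)]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]


def frequency_domain(
    nn: BeatSeries,
    fs: float = PSD_FS,
    max_gap_s: float = MAX_GAP_S,
    min_stretch_s: float = MIN_STRETCH_S,
) -> tuple[float, float, float, float]:
    """Band powers (TP, VLF, LF, HF) in ms^2 of the NN tachogram.

    The series is split at gaps > 20 s; each stretch of at least 5 min is
    cubic-resampled to 4 Hz, mean-removed and linearly detrended, and its
    Welch PSD (Hann, 600-s segments, 50% overlap) estimated.  Stretch
    PSDs are averaged weighted by stretch length before band
    integration.  NaN if no stretch qualifies.
    """
    nan4 = (np.nan, np.nan, np.nan, np.nan)
    resampled = []
    for sl in _contiguous_stretches(nn, max_gap_s):
        t = nn.beat_times[sl]
        rr = nn.rr_ms[sl]
        if t[-1] - t[0] < min_stretch_s:
            continue
        grid = np.arange(t[0], t[-1], 1.0 / fs)
        y = interpolate.CubicSpline(t, rr)(grid)
        resampled.append(signal.detrend(y, type="linear"))
    if not resampled:
        return nan4
    # common Welch segment length so stretch PSDs share one frequency grid
    nperseg = min(int(600 * fs), min(len(y) for y in resampled))
    psds, weights = [], []
    for y in resampled:
        freqs, p = signal.welch(
            y, fs=fs, window="hann", nperseg=nperseg, detrend="constant"
        )
        psds.append(p)
        weights.append(len(y))
    psd = np.average(np.vstack(psds), axis=0, weights=weights)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*VLF_HZ)
    lf = band_power(*LF_HZ)
    hf = band_power(*HF_HZ)
    tp = band_power(VLF_HZ[0], HF_HZ[1])
    return (tp, vlf, lf, hf)


def compute_hrv(nn: BeatSeries) -> HRVMetrics:
    """Full per-patient HRV panel (time + frequency domain)."""
    sdnn, sdann, rmssd, ti = time_domain(nn)
    tp, vlf, lf, hf = frequency_domain(nn)
    return HRVMetrics(
        sdnn_ms=sdnn,
        sdann_ms=sdann,
        rmssd_ms=rmssd,
        hrv_ti=ti,
        tp_ms2=tp,
        vlf_ms2=vlf,
        lf_ms2=lf,
        hf_ms2=hf,
    )
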