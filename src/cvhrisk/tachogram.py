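"""Instantaneous heart-rate tachograms and flat-tachogram classification.

The tachogram plots instantaneous heart rate -- the inverse of the
normal-to-normal interval, ``60000 / rr_ms`` in beats/min -- against time.
A *flat* nocturnal tachogram is one with (1) no heart-rate excursions of
5 bpm or more and (2) no visible respiratory sinus arrhythmia (RSA); it
precludes scoring for cyclic variation of heart rate and by itself marks
severely impaired autonomic control.

The original flatness criterion is visual.  Here it is made operational:
the excursion is the 99.5th minus the 0.5th percentile of a 5-s
running-median-smoothed HR trace (robust to isolated artifacts, standing
in for the consensus review of two readers), and RSA is quantified as the
amplitude of high-frequency (0.15-0.40 Hz) HR modulation estimated from a
2-Hz evenly resampled trace, with "visible" meaning >= 1 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .rr_io import BeatSeries

RESAMPLE_HZ = 2.0
RSA_BAND_HZ = (0.15, 0.40)

FLAT_RULE_VERSION = "percentile-excursion/bandpass-rsa v1"


@dataclass(frozen=True)
class Tachogram:
    """Instantaneous-HR time series over the analysis window.

    ``times`` are seconds on the recording's wall clock (seconds from
    midnight for a nocturnal segment).  ``hr_smooth_bpm`` is the
    trend-filtered channel used for flatness and arousal detection;
    ``rsa_amplitude_bpm`` is the equivalent-sinusoid amplitude of
    high-frequency HR modulation.
    """

    times: np.ndarray
    hr_bpm: np.ndarray
    hr_smooth_bpm: np.ndarray
    rsa_amplitude_bpm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "hr_bpm", np.asarray(self.hr_bpm, dtype=float))
        object.__setattr__(self, "hr_smooth_bpm", np.asarray(self.hr_smooth_bpm, dtype=float))
        if len(self.times) != len(self.hr_bpm) or len(self.hr_bpm) != len(self.hr_smooth_bpm):
            raise ValueError("times, hr_bpm, hr_smooth_bpm must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.hr_bpm <= 0):
            raise ValueError("hr_bpm must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0

    def resampled(self, fs: float = RESAMPLE_HZ, smooth: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Evenly resampled HR trace (linear interpolation)."""
        t = np.arange(self.times[0], self.times[-1], 1.0 / fs)
        y = np.interp(t, self.times, self.hr_smooth_bpm if smooth else self.hr_bpm)
        return t, y


@dataclass(frozen=True)
class FlatResult:
    is_flat: bool
    max_excursion_bpm: float
    rsa_present: bool
    reviewer_rule_version: str = FLAT_RULE_VERSION


def _running_median(times: np.ndarray, values: np.ndarray, window_s: float) -> np.ndarray:
    """Running median over a time window on irregularly sampled data.

    Window shrinks at the ends.  Implemented with searchsorted bounds and
    a per-point median; beat series are a few tens of thousands of points
    at most, so the direct loop is fine.
    """
    half = window_s / 2.0
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    out = np.empty_like(values)
    for i in range(len(values)):
        out[i] = np.median(values[lo[i]:hi[i]])
    return out


def _rsa_amplitude(times: np.ndarray, hr: np.ndarray) -> float:
    """Amplitude (bpm) of HF-band HR modulation, as an equivalent sinusoid.

    Band-pass the 2-Hz resampled raw HR trace over 0.15-0.40 Hz; a pure
    sinusoid of amplitude A has standard deviation A/sqrt(2), so the
    amplitude estimate is sqrt(2) times the band-passed SD.
    """
    if times[-1] - times[0] < 60.0 or len(times) < 8:
        return 0.0
    t = np.arange(times[0], times[-1], 1.0 / RESAMPLE_HZ)
    y = np.interp(t, times, hr)
    sos = signal.butter(3, RSA_BAND_HZ, btype="bandpass", fs=RESAMPLE_HZ, output="sos")
    band = signal.sosfiltfilt(sos, y - np.mean(y))
    # trim filter edge transients (30 s each side)
    edge = int(30 * RESAMPLE_HZ)
    if len(band) > 2 * edge + 10:
        band = band[edge:-edge]
    return float(np.sqrt(2.0) * np.std(band))


def build_tachogram(nn: BeatSeries, smooth_window_s: float = 5.0) -> Tachogram:
    """Instantaneous-HR tachogram from an NN-filtered beat series.

    HR is 60000 / rr_ms at each NN interval's end beat; the time axis is
    the beat wall-clock time.  The smoothed channel (running median,
    default 5 s) and the RSA amplitude are computed alongside.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 NN intervals to build a tachogram")
    times = nn.clock_times
    if np.any(np.diff(times) <= 0):
        # nocturnal windows never cross midnight by default; fall back to
        # elapsed time if the wall clock wraps inside the segment
        times = nn.beat_times
    hr = 60000.0 / nn.rr_ms
    smooth = _running_median(times, hr, smooth_window_s)
    rsa = _rsa_amplitude(times, hr)
    return Tachogram(times=times, hr_bpm=hr, hr_smooth_bpm=smooth, rsa_amplitude_bpm=rsa)


def smooth_hr(tach: Tachogram, window_s: float = 5.0) -> Tachogram:
    """Recompute the smoothed channel with a different running-median window."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    smooth = _running_median(tach.times, tach.hr_bpm, window_s)
    return replace(tach, hr_smooth_bpm=smooth)


def classify_flat(
    tach: Tachogram,
    excursion_limit_bpm: float = 5.0,
    rsa_min_bpm: float = 1.0,
) -> FlatResult:
    """Apply the two-part flat-tachogram rule.

    Flat iff the robust excursion (99.5th - 0.5th percentile of smoothed
    HR) is below ``excursion_limit_bpm`` *and* no RSA is present
    (amplitude below ``rsa_min_bpm``).
    """
    excursion = float(
        np.percentile(tach.hr_smooth_bpm, 99.5) - np.percentile(tach.hr_smooth_bpm, 0.5)
    )
    rsa_present = tach.rsa_amplitude_bpm >= rsa_min_bpm
    return FlatResult(
        is_flat=(excursion < excursion_limit_bpm) and not rsa_present,
        max_excursion_bpm=excursion,
        rsa_present=rsa_present,
    )


def export_tachogram(tach: Tachogram, path) -> None:
    """Two-column delimited export (time_s, hr_bpm) for plotting."""
    np.savetxt(
        path,
        np.column_stack([tach.times, tach.hr_bpm]),
        fmt="%.3f",
        delimiter=",",
        header="time_s,hr_bpm",
        comments="",
    )
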