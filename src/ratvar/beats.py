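"""Beat-to-beat extraction from arterial-pressure waveforms.

A continuous pressure trace is reduced to per-beat quantities: the time of
each systolic peak, the pulse interval (PI) between successive peaks, and
the systolic (SAP), diastolic (DAP) and mean (MAP) pressure of each cardiac
cycle.  The PI series is the tachogram and the SAP series the systogram;
both feed the spectral variability analysis downstream.

Detection is tuned for conscious-rat pressure signals (heart rates of
roughly 300-450 bpm): systolic peaks are local maxima whose prominence
clears an adaptive fraction of the signal excursion, enforced with a
refractory period of 0.4 x the median pulse interval estimated in a first
pass.  The diastolic minimum of a beat is taken between its systolic peak
and the next one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger("ratvar")

#: fraction of the signal excursion a peak's prominence must exceed
PROMINENCE_FRACTION = 0.10
#: refractory period as a fraction of the median pulse interval
REFRACTORY_FRACTION = 0.4
#: peak-to-trough excursion (mmHg) below which a trace is considered flat
FLAT_EXCURSION_MMHG = 1.0


class SignalError(ValueError):
    """Raised for waveforms that cannot be analyzed (NaNs, too short)."""


class NoBeatsError(SignalError):
    """Raised when no cardiac cycles can be located in a waveform."""


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled arterial-pressure trace in mmHg."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    start_time: float = 0.0  # s

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("waveform needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class BeatSeries:
    """Per-beat series: systolic peak times with SAP/DAP (and optionally MAP).

    ``pi`` (pulse intervals, ms) is derived from the peak times, so it always
    has one element fewer than ``beat_times``.
    """

    beat_times: np.ndarray  # s, systolic peak times
    sap: np.ndarray  # mmHg, per-beat systolic maxima
    dap: np.ndarray  # mmHg, per-beat diastolic minima
    map_per_beat: np.ndarray | None = None  # mmHg, waveform time-average per beat

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sap = np.asarray(self.sap, dtype=float)
        self.dap = np.asarray(self.dap, dtype=float)
        n = self.beat_times.size
        if n == 0:
            raise ValueError("BeatSeries must contain at least one beat")
        if self.sap.size != n or self.dap.size != n:
            raise ValueError("beat_times, sap and dap must have equal length")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.sap <= self.dap):
            raise ValueError("sap must exceed dap for every beat")
        if self.map_per_beat is not None:
            self.map_per_beat = np.asarray(self.map_per_beat, dtype=float)
            if self.map_per_beat.size != n:
                raise ValueError("map_per_beat must match the beat count")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def pi(self) -> np.ndarray:
        """Pulse intervals in ms (peak-to-peak); length ``n_beats - 1``."""
        return np.diff(self.beat_times) * 1000.0


@dataclass(frozen=True)
class HemodynamicSummary:
    """Recording-level hemodynamics as reported per animal."""

    hr: float  # bpm
    sap_mean: float  # mmHg
    dap_mean: float  # mmHg
    map_mean: float  # mmHg

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("heart rate must be positive")
        if not (self.dap_mean < self.map_mean < self.sap_mean):
            raise ValueError("expected dap_mean < map_mean < sap_mean")


def detect_beats(waveform: Waveform) -> BeatSeries:
    """Locate systolic peaks and per-beat pressures in a pressure trace.

    Two passes are made: a first prominence-only pass yields a median pulse
    interval, which then sets the refractory period (0.4 x median PI) for
    the final pass.  The prominence threshold is a fixed fraction of the
    overall excursion, which makes detection invariant to constant offsets.

    Raises
    ------
    SignalError
        If the trace contains NaNs.
    NoBeatsError
        If the trace is flat or fewer than two peaks are found.
    """
    x = waveform.samples
    if np.any(np.isnan(x)):
        raise SignalError("waveform contains NaN samples")
    excursion = float(np.max(x) - np.min(x))
    if excursion < FLAT_EXCURSION_MMHG:
        raise NoBeatsError("no beats detected: flat signal")

    prominence = PROMINENCE_FRACTION * excursion
    # pad below the signal floor so peaks on the first/last sample count
    padded = np.concatenate(([x.min() - excursion], x, [x.min() - excursion]))
    peaks, _ = find_peaks(padded, prominence=prominence)
    if peaks.size < 2:
        raise NoBeatsError("no beats detected: fewer than 2 systolic peaks")

    median_pi_samples = float(np.median(np.diff(peaks)))
    refractory = max(1, int(round(REFRACTORY_FRACTION * median_pi_samples)))
    peaks, _ = find_peaks(padded, prominence=prominence, distance=refractory)
    peaks -= 1
    if peaks.size < 2:
        raise NoBeatsError("no beats detected after refractory filtering")

    n = peaks.size
    sap = x[peaks]
    dap = np.empty(n)
    map_per_beat = np.empty(n)
    bounds = np.append(peaks, x.size)
    for k in range(n):
        segment = x[bounds[k]:bounds[k + 1]]
        dap[k] = segment.min()
        map_per_beat[k] = segment.mean()

    beat_times = waveform.start_time + peaks / waveform.sampling_rate
    return BeatSeries(beat_times=beat_times, sap=sap, dap=dap,
                      map_per_beat=map_per_beat)


def summarize_hemodynamics(beats: BeatSeries) -> HemodynamicSummary:
    """Summarize a beat series into HR, SAP, DAP and MAP.

    HR is ``60000 / mean(PI)`` in bpm.  SAP and DAP are per-beat means.  MAP
    is the pulse-interval-weighted average of the per-beat waveform mean
    pressure when available; for beat series without an underlying waveform
    (e.g. read from a per-beat file) it falls back to the standard
    ``DAP + pulse pressure / 3`` estimate.
    """
    if beats.n_beats < 2:
        raise ValueError("need at least 2 beats to summarize hemodynamics")
    pi = beats.pi
    hr = 60000.0 / float(np.mean(pi))
    sap_mean = float(np.mean(beats.sap))
    dap_mean = float(np.mean(beats.dap))
    if beats.map_per_beat is not None:
        # time-average: weight each beat with known duration by its PI
        weights = pi
        map_mean = float(np.average(beats.map_per_beat[:-1], weights=weights))
    else:
        per_beat_map = beats.dap + (beats.sap - beats.dap) / 3.0
        map_mean = float(np.average(per_beat_map[:-1], weights=pi))
    return HemodynamicSummary(hr=hr, sap_mean=sap_mean, dap_mean=dap_mean,
                              map_mean=map_mean)
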