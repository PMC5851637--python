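"""Dynamics features and the class scheme for simulated traces.

Three features summarise each post-burn-in trace: the amplitude
(max - min, mV), the fundamental frequency of the cycle (Hz, from the first
prominent autocorrelation peak), and the number of prominent peaks per
cycle.  Traces then map to one of ten mutually exclusive labels:

* ``steady_state`` — amplitude below threshold (or decaying transient),
* ``delta``/``theta``/``alpha``/``beta``/``gamma`` — single-peak cycles in
  the clinical EEG bands [f_min,4), [4,8), [8,13), [13,30), [30,60] Hz,
* ``spike_wave``/``polyspike_wave`` — cycles of 2-8 Hz carrying two /
  three-or-more peaks per period, the model's operational seizure dynamics,
* ``other`` — everything else (aperiodic, >60 Hz, multi-peak out of band),
* ``divergent`` — failed integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "CLASS_LABELS",
    "SEIZURE_LABELS",
    "BAND_LABELS",
    "DynamicsFeatures",
    "amplitude",
    "fundamental_frequency",
    "peaks_per_cycle",
    "classify",
    "is_seizure",
    "extract_features",
]

CLASS_LABELS = (
    "steady_state",
    "delta",
    "theta",
    "alpha",
    "beta",
    "gamma",
    "spike_wave",
    "polyspike_wave",
    "other",
    "divergent",
)
BAND_LABELS = ("delta", "theta", "alpha", "beta", "gamma")
SEIZURE_LABELS = ("spike_wave", "polyspike_wave")

#: amplitude (mV) below which a trace counts as a steady state
EPS_AMP = 1e-2
#: last-quarter / full-window amplitude ratio below which a trace is treated
#: as a decaying transient (headed to a steady state)
DECAY_RATIO = 0.9
#: autocorrelation height a lag must exceed to count as the fundamental
ACF_THRESHOLD = 0.5
#: prominence floor for peak counting, as a fraction of the trace
#: amplitude.  Peaks are all strict local maxima; the floor only guards
#: against floating-point plateau wiggle.  The secondary peaks of slow
#: spike-wave cycles (damped ringing riding a relaxation oscillation) can
#: be orders of magnitude smaller than the wave itself, so a visually
#: motivated threshold (a few % of the amplitude) systematically
#: under-counts them.
PROMINENCE_FRAC = 1e-5


@dataclass
class DynamicsFeatures:
    """Per-trace feature record; frequency/peaks are None below threshold."""

    amplitude: float
    frequency: Optional[float]
    peaks_per_cycle: Optional[int]
    label: str


def _as_output(trace):
    """Accept a SimulatedTrace or a bare sample array."""
    if hasattr(trace, "output"):
        return np.asarray(trace.output, dtype=float)
    return np.asarray(trace, dtype=float)


def amplitude(trace) -> float:
    """Peak-to-peak amplitude: max(output) - min(output), in mV."""
    x = _as_output(trace)
    if x.size == 0:
        raise ValueError("empty trace")
    return float(np.max(x) - np.min(x))


def fundamental_frequency(trace, sample_rate: float = None) -> Optional[float]:
    """Fundamental frequency from the normalised autocorrelation (Hz).

    The period is the lag of the first local autocorrelation maximum above
    0.5 (unbiased normalisation), restricted to lags of at most half the
    window so that at least two full cycles support the estimate; the lag is
    refined by parabolic interpolation.  Returns None when no such peak
    exists (aperiodic trace).  Harmonic-rich cycles keep their true
    fundamental because harmonics correlate weakly at short lags.
    """
    x = _as_output(trace)
    fs = float(sample_rate if sample_rate is not None else trace.sample_rate)
    n = x.size
    if n < 4:
        raise ValueError("trace too short")
    x = x - x.mean()
    denom = float(np.dot(x, x)) / n
    if denom <= 0:
        raise ValueError("constant trace has no frequency")
    # full autocorrelation via FFT, unbiased lag normalisation
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: n // 2 + 1]
    lags = np.arange(acov.size)
    acf = (acov / (n - lags)) / denom

    m = acf.size
    if m < 3:
        return None
    # peaks need a little prominence: the autocorrelation of a slow cycle is
    # nearly flat at short lags and numerical ripple there must not register
    candidates, _ = find_peaks(acf, height=ACF_THRESHOLD, prominence=0.01)
    candidates = candidates[candidates >= 1]
    if candidates.size == 0:
        return None
    k = int(candidates[0])
    # parabolic refinement of the peak lag
    y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
    denom2 = y0 - 2 * y1 + y2
    shift = 0.0 if denom2 == 0 else 0.5 * (y0 - y2) / denom2
    shift = float(np.clip(shift, -0.5, 0.5))
    period = (k + shift) / fs
    return float(1.0 / period)


def peaks_per_cycle(trace, frequency: float, sample_rate: float = None) -> int:
    """Count of prominent local maxima per fundamental period.

    All strict local maxima (above a tiny numerical prominence floor) are
    counted over a whole number of periods and divided by that period count
    (rounded).  Requires at least two full periods in the window.
    """
    x = _as_output(trace)
    fs = float(sample_rate if sample_rate is not None else trace.sample_rate)
    if not (frequency and frequency > 0 and np.isfinite(frequency)):
        raise ValueError("valid frequency required")
    duration = x.size / fs
    n_periods = int(np.floor(duration * frequency))
    if n_periods < 2:
        raise ValueError("fewer than 2 full periods in window")
    n_use = int(round(n_periods / frequency * fs))
    seg = x[:n_use]
    amp = float(np.max(seg) - np.min(seg))
    peaks, _ = find_peaks(seg, prominence=PROMINENCE_FRAC * amp)
    return max(1, int(round(peaks.size / n_periods)))


def classify(
    amplitude_mv: float,
    frequency: Optional[float] = None,
    n_peaks: Optional[int] = None,
    *,
    divergent: bool = False,
    decaying: bool = False,
    eps_amp: float = EPS_AMP,
) -> str:
    """Map extracted features to a class label (total on valid features)."""
    if divergent:
        return "divergent"
    if amplitude_mv < eps_amp or decaying:
        return "steady_state"
    if frequency is None:
        return "other"
    f = float(frequency)
    if n_peaks is None or n_peaks < 1:
        return "other"
    if n_peaks == 1:
        if f < 4:
            return "delta"
        if f < 8:
            return "theta"
        if f < 13:
            return "alpha"
        if f < 30:
            return "beta"
        if f <= 60:
            return "gamma"
        return "other"
    if 2.0 <= f <= 8.0:
        return "spike_wave" if n_peaks == 2 else "polyspike_wave"
    return "other"


def is_seizure(label: str) -> bool:
    """True iff the label is spike-wave or poly-spike-wave dynamics."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown label {label!r}")
    return label in SEIZURE_LABELS


def features_of_trace(
    output,
    sample_rate: float,
    divergent: bool = False,
    eps_amp: float = EPS_AMP,
) -> DynamicsFeatures:
    """Full feature extraction + classification for one trace."""
    if divergent:
        return DynamicsFeatures(np.nan, None, None, "divergent")
    x = np.asarray(output, dtype=float)
    amp = amplitude(x)
    if amp < eps_amp:
        return DynamicsFeatures(amp, None, None, "steady_state")
    amp_last = amplitude(x[-(x.size // 4):])
    if amp_last < DECAY_RATIO * amp:
        return DynamicsFeatures(amp, None, None, "steady_state")
    freq = fundamental_frequency(x, sample_rate)
    if freq is None:
        return DynamicsFeatures(amp, None, None, "other")
    try:
        npk = peaks_per_cycle(x, freq, sample_rate)
    except ValueError:
        return DynamicsFeatures(amp, freq, None, "other")
    label = classify(amp, freq, npk, eps_amp=eps_amp)
    return DynamicsFeatures(amp, freq, npk, label)


def extract_features(
    outputs,
    sample_rate: float,
    divergent=None,
    eps_amp: float = EPS_AMP,
) -> pd.DataFrame:
    """Feature table for a batch of traces.

    ``outputs`` is (n, m); returns a DataFrame with columns amplitude_mV,
    frequency_Hz, peaks_per_cycle, label (one row per trace).
    """
    outputs = np.asarray(outputs, dtype=float)
    n = outputs.shape[0]
    if divergent is None:
        divergent = ~np.all(np.isfinite(outputs), axis=1)
    rows = []
    for i in range(n):
        f = features_of_trace(outputs[i], sample_rate, bool(divergent[i]), eps_amp)
        rows.append(
            (f.amplitude,
             np.nan if f.frequency is None else f.frequency,
             np.nan if f.peaks_per_cycle is None else f.peaks_per_cycle,
             f.label)
        )
    return pd.DataFrame(
        rows, columns=["amplitude_mV", "frequency_Hz", "peaks_per_cycle", "label"]
    )
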