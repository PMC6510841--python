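"""Morphological descriptors of simulated ERF waveforms.

Three kinds of descriptor are extracted: the long-latency deflection peaks
(P1m, N1m, P2m), the dominant Fourier frequency ``f_ERF``, and the envelope
decay constant ``tau_ERF``.  Peak polarity is defined operationally: the
largest-magnitude deflection after stimulus onset is the N1m and fixes the
"negative" polarity, the P1m is the last opposite-polarity local extremum
before it, and the P2m the first one after it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import hilbert

__all__ = ["WaveformMetrics", "detect_peaks", "dominant_frequency",
           "decay_constant", "waveform_metrics", "polarity_peak"]

#: P1m/P2m candidates must exceed this fraction of the N1m magnitude.
PEAK_AMPLITUDE_FLOOR = 0.01

#: Envelope peaks later than this (ms) invalidate the exponential fit.
ENVELOPE_PEAK_DEADLINE_MS = 500.0

#: Fitted decay constants beyond this multiple of the analysis window are
#: flagged as poor fits (effectively undamped within the window).
TAU_VALID_WINDOW_MULTIPLE = 2.0

#: The exponential fit uses envelope samples above this fraction of the
#: envelope peak.
ENVELOPE_DYNAMIC_RANGE = 0.05


@dataclass(frozen=True)
class WaveformMetrics:
    """Peak latencies/amplitudes plus spectral and decay descriptors."""

    p1m_latency_ms: float = np.nan
    p1m_amplitude: float = np.nan
    n1m_latency_ms: float = np.nan
    n1m_amplitude: float = np.nan
    p2m_latency_ms: float = np.nan
    p2m_amplitude: float = np.nan
    f_erf_hz: float = np.nan
    tau_erf_ms: float = np.nan
    tau_residual: float = np.nan
    p1m_absent: bool = True
    n1m_absent: bool = True
    p2m_absent: bool = True
    tau_valid: bool = False


def _series(erf):
    """Accept an ERFTrace or a (t_ms, y) pair."""
    if hasattr(erf, "t_ms") and hasattr(erf, "total"):
        return np.asarray(erf.t_ms, float), np.asarray(erf.total, float)
    t, y = erf
    return np.asarray(t, float), np.asarray(y, float)


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0 or np.abs(dt - dt[0]).max() > 1e-9 * max(dt[0], 1.0):
        raise ValueError("waveform metrics require a uniform time grid")
    return float(dt[0])


def _remove_baseline(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Subtract the signal's DC offset, estimated by the global median.

    The median tracks the resting baseline of an evoked transient (most
    samples sit near rest) and is zero for a symmetric oscillation.
    Subtracting the time-average instead would inject a boxcar into
    one-sided transients and corrupt both the spectrum and the envelope.
    """
    return y - np.median(y)


def _local_extrema(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local extrema (either polarity)."""
    d = np.diff(y)
    sign = np.sign(d)
    # propagate signs through plateaus
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.flatnonzero(sign[1:] * sign[:-1] < 0) + 1
    return turns


def detect_peaks(erf, onset_ms: float = 0.0) -> WaveformMetrics:
    """Locate the P1m, N1m and P2m deflections of one waveform.

    The N1m is the global extremum of largest magnitude after ``onset_ms``;
    its sign defines the negative polarity.  P1m/P2m are the neighbouring
    opposite-polarity local extrema, flagged absent when no candidate exceeds
    1% of the N1m magnitude.
    """
    t, y = _series(erf)
    _check_uniform(t)
    after = np.flatnonzero(t > onset_ms)
    if after.size == 0 or not np.any(y[after] != 0):
        return WaveformMetrics()
    idx_n1m = after[np.argmax(np.abs(y[after]))]
    n1m_amp = y[idx_n1m]
    sign_n = np.sign(n1m_amp)
    floor = PEAK_AMPLITUDE_FLOOR * abs(n1m_amp)

    extrema = _local_extrema(y)
    opposite = extrema[(-sign_n * y[extrema]) > floor]
    before = opposite[opposite < idx_n1m]
    after_n1m = opposite[opposite > idx_n1m]

    out = dict(
        n1m_latency_ms=float(t[idx_n1m]),
        n1m_amplitude=float(n1m_amp),
        n1m_absent=False,
    )
    if before.size:
        k = before[-1]
        out.update(p1m_latency_ms=float(t[k]), p1m_amplitude=float(y[k]),
                   p1m_absent=False)
    if after_n1m.size:
        k = after_n1m[0]
        out.update(p2m_latency_ms=float(t[k]), p2m_amplitude=float(y[k]),
                   p2m_absent=False)
    return WaveformMetrics(**out)


def polarity_peak(erf, polarity: int, floor_frac: float = 0.05,
                  onset_ms: float = 0.0) -> tuple[float, float]:
    """First local extremum of the given polarity exceeding a relative floor.

    Tracks one deflection across a family of waveforms by its polarity
    instead of relabelling peaks within each waveform; used for topography
    sweeps, where the feedforward-polarity deflection can grow from a minor
    ripple into the dominant lobe.  Returns ``(latency_ms, amplitude)`` or
    ``(nan, nan)`` when no such extremum exists.
    """
    t, y = _series(erf)
    _check_uniform(t)
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    floor = floor_frac * np.abs(y).max()
    if floor == 0:
        return np.nan, np.nan
    for k in _local_extrema(y):
        if t[k] > onset_ms and polarity * y[k] > floor:
            return float(t[k]), float(y[k])
    return np.nan, np.nan


def dominant_frequency(erf, window_ms: tuple[float, float] = (0.0, 600.0),
                       min_fft: int = 4096) -> float:
    """Dominant FFT frequency (Hz) of the mean-removed waveform.

    The DC offset (late-window baseline) is removed, the signal is
    zero-padded to at least ``min_fft`` samples for frequency resolution,
    and the zero-frequency bin is excluded.  For a damped sinusoid the
    reported value sits at the damped spectral peak,
    ``sqrt(f0^2 - (1/(2 pi tau))^2)``, which merges into the origin once the
    oscillation decays within a single cycle.
    """
    t, y = _series(erf)
    dt = _check_uniform(t)
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    x = _remove_baseline(t[sel], y[sel])
    nfft = max(int(min_fft), 1 << int(np.ceil(np.log2(max(x.size, 2)))))
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=dt / 1000.0)
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def decay_constant(erf, fit_end_ms: float = 600.0) -> tuple[float, float, bool]:
    """Envelope decay constant ``tau_ERF`` (ms) via Hilbert envelope + log fit.

    The analytic-signal magnitude gives the envelope; ``A exp(-t/tau)`` is
    fitted by least squares on the envelope itself (linear space, initialized
    from a log-space line fit) from the envelope peak to ``fit_end_ms``.
    Fitting in linear space keeps the estimate anchored to the dominant decay
    of the response; faint long-lived components that are orders of magnitude
    below the envelope peak do not drag the estimate.  Returns
    ``(tau_ms, normalized_rms_residual, valid)``; the fit is invalid when the
    envelope peaks after 500 ms or does not decay within the window.
    """
    t, y = _series(erf)
    _check_uniform(t)
    if not np.any(y != 0):
        return np.nan, np.nan, False
    x = _remove_baseline(t, y)
    # zero-padded analytic signal: keeps the envelope free of wrap-around
    nfft = 1 << int(np.ceil(np.log2(max(x.size * 2, 8))))
    env = np.abs(hilbert(x, N=nfft))[: x.size]
    peak = int(np.argmax(env))
    if t[peak] > ENVELOPE_PEAK_DEADLINE_MS:
        return np.nan, np.nan, False
    sel = (t >= t[peak]) & (t <= fit_end_ms)
    # restrict the fit to the envelope's informative dynamic range; below a
    # few percent of the peak a measured envelope is noise-dominated and a
    # modelled one may carry faint long-lived components
    sel &= env >= ENVELOPE_DYNAMIC_RANGE * env[peak]
    tt = t[sel]
    ee = env[sel]
    if tt.size < 4:
        return np.nan, np.nan, False
    eps = ee.max() * 1e-12 + 1e-300
    slope, intercept = np.polyfit(tt, np.log(np.maximum(ee, eps)), 1)
    if slope >= 0:
        return np.inf, np.nan, False
    cap = TAU_VALID_WINDOW_MULTIPLE * fit_end_ms
    tau0 = min(-1.0 / slope, cap)
    amp0 = float(np.exp(intercept + slope * tt[0]))

    def model(t, amp, tau):
        return amp * np.exp(-(t - tt[0]) / tau)

    try:
        (amp, tau), _ = curve_fit(model, tt, ee, p0=(max(amp0, eps), tau0),
                                  bounds=([0.0, 1e-3], [np.inf, np.inf]),
                                  maxfev=10000)
    except RuntimeError:
        return np.nan, np.nan, False
    resid = float(np.sqrt(np.mean((ee - model(tt, amp, tau)) ** 2)) / ee.max())
    if tau <= 0:
        return float(tau), resid, False
    valid = tau <= cap
    return float(tau), resid, valid


def waveform_metrics(erf, onset_ms: float = 0.0) -> WaveformMetrics:
    """All descriptors of one waveform in a single record."""
    peaks = detect_peaks(erf, onset_ms=onset_ms)
    if peaks.n1m_absent:
        return peaks
    f = dominant_frequency(erf)
    tau, resid, valid = decay_constant(erf)
    return WaveformMetrics(
        **{k: getattr(peaks, k) for k in (
            "p1m_latency_ms", "p1m_amplitude", "n1m_latency_ms", "n1m_amplitude",
            "p2m_latency_ms", "p2m_amplitude", "p1m_absent", "n1m_absent",
            "p2m_absent")},
        f_erf_hz=f, tau_erf_ms=tau, tau_residual=resid, tau_valid=valid,
    )
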