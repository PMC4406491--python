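"""EMG conditioning and amplitude-domain metrics.

Raw surface EMG is band-pass filtered (Butterworth, 10–500 Hz, zero phase),
smoothed to a root-mean-square envelope with a 50-ms centered rectangular
window, and summarized per contraction: mean and peak RMS over the analysis
window and the rate of EMG rise (RER, the least-squares slope of the RMS
envelope over the first 75 ms after activation onset).  M-wave peak-to-peak
amplitude normalizes the voluntary metrics (nEMG_mean, nEMG_peak, nRER);
a second normalization expresses each metric as a percentage of the
subject's protocol-wide maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import (
    InsufficientSamplesError,
    InvalidConfigError,
    InvalidInputError,
    NyquistViolationError,
)
from .trace import SampledTrace
from .torque_metrics import detect_torque_onset, _ols_slope

__all__ = [
    "EMGMetrics",
    "bandpass",
    "moving_rms",
    "detect_emg_onset",
    "compute_rer",
    "compute_emg_mean_peak",
    "mwave_p2p",
    "normalize_metrics",
    "contraction_emg_metrics",
]


@dataclass(frozen=True)
class EMGMetrics:
    """Amplitude-domain EMG metrics for one contraction."""

    emg_mean: float  # mV
    emg_peak: float  # mV
    rer: float       # mV·s⁻¹
    time_to_emg_peak: float  # s, relative to onset
    onset: float     # s, absolute within the trace


def bandpass(raw: SampledTrace, low: float = 10.0, high: float = 500.0,
             order: int = 2) -> SampledTrace:
    """Zero-phase Butterworth band-pass (forward-backward ``sosfiltfilt``).

    ``order`` is the design order per band edge (the conventional reading of
    'Butterworth order 2, band-pass'); zero-phase filtering preserves onset
    timing at the cost of squaring the magnitude response.
    """
    if low <= 0 or high <= low:
        raise InvalidConfigError(f"need 0 < low < high, got ({low}, {high})")
    if raw.rate <= 2.0 * high:
        raise NyquistViolationError(
            f"sampling rate {raw.rate} Hz must exceed twice the upper edge {high} Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=raw.rate, output="sos")
    return raw.with_values(sosfiltfilt(sos, raw.values))


def moving_rms(signal: SampledTrace, window: float = 0.05) -> SampledTrace:
    """Centered rectangular-window RMS envelope at the input rate.

    Edge samples use the truncated window (the mean square is taken over the
    samples actually inside the trace).
    """
    w = int(round(window * signal.rate))
    if w < 2:
        raise InvalidConfigError(
            f"RMS window of {window}s holds {w} samples; need >= 2")
    kernel = np.ones(w)
    sq = np.convolve(signal.values ** 2, kernel, mode="same")
    counts = np.convolve(np.ones(len(signal)), kernel, mode="same")
    return signal.with_values(np.sqrt(sq / counts))


def detect_emg_onset(rms: SampledTrace, baseline_window: float = 0.3,
                     k_sd: float = 3.0, min_hold: float = 0.02) -> float:
    """Activation onset on the RMS envelope; same threshold-and-hold contract
    as :func:`~neurofatigue.torque_metrics.detect_torque_onset`.

    No low-threshold backtracking here: the RMS envelope is smooth and its
    baseline SD is tiny, so a 1-SD backtrack threshold would sit inside the
    baseline fluctuations and make the detected onset erratic.  The centered
    RMS window already pulls the crossing slightly ahead of the true onset.
    """
    return detect_torque_onset(rms, baseline_window, k_sd, min_hold,
                               k_backtrack=None)


def compute_rer(rms: SampledTrace, onset: float, window: float = 0.075) -> float:
    """Rate of EMG rise: OLS slope of the RMS envelope over
    ``[onset, onset + window]`` (~154 samples at 2048 Hz)."""
    t, y = rms.window(onset, onset + window + 1e-9)
    if t.size < 3:
        raise InsufficientSamplesError(
            f"RER window [{onset}, {onset + window}] holds {t.size} samples; need >= 3")
    return _ols_slope(t, y)


def compute_emg_mean_peak(rms: SampledTrace, onset: float,
                          end: float) -> tuple[float, float, float]:
    """(mean, peak, time-of-peak relative to onset) of the RMS envelope over
    the half-open window ``[onset, end)``."""
    if end <= onset:
        raise InsufficientSamplesError(f"empty analysis window [{onset}, {end})")
    t, y = rms.window(onset, end)
    if t.size == 0:
        raise InsufficientSamplesError(f"no samples in window [{onset}, {end})")
    i = int(np.argmax(y))
    return float(y.mean()), float(y[i]), float(t[i] - onset)


def mwave_p2p(mwave: SampledTrace) -> float:
    """M-wave peak-to-peak amplitude: the voltage difference between the two
    extreme points of the evoked electromyographic response."""
    if len(mwave) < 3:
        raise InsufficientSamplesError("M-wave trace needs >= 3 samples")
    return float(mwave.values.max() - mwave.values.min())


def normalize_metrics(per_contraction, mmax_pre: float, mmax_post: float,
                      first_n: int = 8, last_n: int = 8,
                      variables: tuple[str, ...] = ("emg_mean", "emg_peak", "rer")):
    """Both EMG normalization schemes for one subject.

    ``per_contraction`` is a DataFrame ordered by contraction with columns in
    ``variables``.  Returns a dict with, per variable:

    * ``n_<var>_pre`` / ``n_<var>_post`` — average of the first ``first_n``
      (last ``last_n``) contractions divided by the pre (post) M-wave
      amplitude (dimensionless);
    * ``pct_<var>`` — per-contraction values as % of the subject's protocol
      maximum (ndarray).
    """
    if mmax_pre <= 0 or mmax_post <= 0:
        raise InvalidInputError("M-wave normalizers must be positive")
    out: dict[str, object] = {}
    for var in variables:
        col = np.asarray(per_contraction[var], dtype=float)
        if col.size < max(first_n, last_n):
            raise InsufficientSamplesError(
                f"{col.size} contractions < requested first/last block size")
        out[f"n_{var}_pre"] = float(col[:first_n].mean() / mmax_pre)
        out[f"n_{var}_post"] = float(col[-last_n:].mean() / mmax_post)
        out[f"pct_{var}"] = 100.0 * col / col.max()
    return out


def contraction_emg_metrics(raw: SampledTrace, analysis_end: float,
                            baseline_window: float = 0.3,
                            k_sd: float = 3.0, min_hold: float = 0.02,
                            rer_window: float = 0.075,
                            rms_window: float = 0.05,
                            onset: float | None = None) -> EMGMetrics:
    """Full EMG chain for one contraction: band-pass → RMS → onset → metrics.

    ``analysis_end`` bounds the mean/peak window (tied to the end of the
    torque isokinetic phase by the pipeline).
    """
    rms = moving_rms(bandpass(raw), rms_window)
    if onset is None:
        onset = detect_emg_onset(rms, baseline_window, k_sd, min_hold)
    rer = compute_rer(rms, onset, rer_window)
    emg_mean, emg_peak, t2p = compute_emg_mean_peak(rms, onset, analysis_end)
    return EMGMetrics(emg_mean=emg_mean, emg_peak=emg_peak, rer=rer,
                      time_to_emg_peak=t2p, onset=onset)
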