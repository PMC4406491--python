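"""Mechanical variables from torque and angular-velocity traces.

Per-contraction metrics of the exercise protocol: rate of torque development
(RTD, the least-squares slope of torque vs. time over the first 75 ms after
contraction onset), peak torque, mean torque over the isokinetic phase, time
to peak torque and time to the target angular velocity.  Neuromuscular-test
metrics: isometric MVC torque (maximum over the 500 ms preceding the
superimposed stimulation), voluntary activation by twitch interpolation,
evoked peak torque and evoked RTD of potentiated doublets, the 10:100 Hz
doublet ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientSamplesError,
    InvalidConfigError,
    InvalidInputError,
    InvalidResponseError,
    OnsetNotFoundError,
    TargetNotReachedError,
)
from .trace import SampledTrace

__all__ = [
    "TorqueMetrics",
    "NeuromuscularTest",
    "detect_torque_onset",
    "compute_rtd",
    "compute_tpeak_tmean",
    "time_to_target_velocity",
    "isokinetic_end",
    "compute_imvc",
    "voluntary_activation",
    "evoked_metrics",
    "superimposed_twitch",
    "db_ratio",
    "contraction_torque_metrics",
    "process_neuromuscular_test",
]


@dataclass(frozen=True)
class TorqueMetrics:
    """Per-contraction mechanical metrics (all times relative to onset)."""

    t_mean: float   # N·m
    t_peak: float   # N·m
    rtd: float      # N·m·s⁻¹
    time_to_peak: float          # s
    time_to_target_velocity: float  # s
    onset: float    # s, absolute within the trace


@dataclass(frozen=True)
class NeuromuscularTest:
    """Summary of one pre- or post-exercise testing bout."""

    imvc: float       # N·m
    va: float         # %
    e_tpeak: float    # N·m
    e_rtd: float      # N·m·s⁻¹
    db10: float       # N·m
    db_ratio: float   # a.u.
    m_max: float      # mV


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def detect_torque_onset(trace: SampledTrace, baseline_window: float = 0.3,
                        k_sd: float = 3.0, min_hold: float = 0.03,
                        k_backtrack: float | None = 1.0) -> float:
    """Earliest time the signal exceeds baseline mean + ``k_sd``·SD and stays
    above it for at least ``min_hold`` seconds.

    The baseline is the first ``baseline_window`` seconds of the trace,
    assumed pre-contraction.  With ``k_backtrack`` set (the default), the
    detector then walks back from that sustained crossing to the sample
    following the last one below baseline mean + ``k_backtrack``·SD — the
    usual double-threshold scheme, which removes most of the detection delay
    that a high threshold alone incurs on slowly rising signals.  Raises
    :class:`OnsetNotFoundError` when no sustained crossing exists.
    """
    n_base = int(round(baseline_window * trace.rate))
    if n_base < 2 or n_base >= len(trace):
        raise InsufficientSamplesError(
            f"baseline window of {baseline_window}s needs 2..{len(trace) - 1} samples")
    base = trace.values[:n_base]
    threshold = base.mean() + k_sd * base.std(ddof=1)
    hold = max(int(round(min_hold * trace.rate)), 1)
    above = trace.values > threshold
    # sustained crossing: `hold` consecutive samples above threshold
    run = 0
    start = None
    for i in range(n_base, len(trace)):
        run = run + 1 if above[i] else 0
        if run >= hold:
            start = i - hold + 1
            break
    if start is None:
        raise OnsetNotFoundError(
            f"no crossing of {threshold:.4g} sustained for {min_hold}s")
    if k_backtrack is not None:
        low = base.mean() + k_backtrack * base.std(ddof=1)
        i = start
        while i > 0 and trace.values[i - 1] > low:
            i -= 1
        # a sample exactly at the low threshold is the last baseline-level
        # sample and belongs to the onset (exact for noise-free signals)
        if i > 0 and trace.values[i - 1] == low:
            i -= 1
        start = i
    return trace.t0 + start / trace.rate


def compute_rtd(trace: SampledTrace, onset: float, window: float = 0.075) -> float:
    """Average slope of torque vs. time over ``[onset, onset + window]``.

    Realized as the ordinary-least-squares slope over all samples with
    ``onset <= t <= onset + window`` (8 samples at 100 Hz); OLS equals the
    endpoint-difference slope on exactly linear data and is robust to noise.
    """
    t, y = trace.window(onset, onset + window + 1e-9)
    if t.size < 3:
        raise InsufficientSamplesError(
            f"RTD window [{onset}, {onset + window}] holds {t.size} samples; need >= 3")
    return _ols_slope(t, y)


def compute_tpeak_tmean(trace: SampledTrace, onset: float,
                        end: float) -> tuple[float, float, float]:
    """(peak, mean, time-to-peak) of torque over the half-open window ``[onset, end)``."""
    if end <= onset:
        raise InsufficientSamplesError(f"empty analysis window [{onset}, {end})")
    t, y = trace.window(onset, end)
    if t.size == 0:
        raise InsufficientSamplesError(f"no samples in window [{onset}, {end})")
    i = int(np.argmax(y))
    return float(y[i]), float(y.mean()), float(t[i] - onset)


def time_to_target_velocity(velocity: SampledTrace, target: float = 240.0,
                            onset: float = 0.0) -> float:
    """Time from ``onset`` until the velocity first reaches ``target`` (°/s).

    Linear interpolation between the bracketing samples; raises
    :class:`TargetNotReachedError` if the target is never attained.
    """
    t, v = velocity.window(onset, velocity.t_end)
    if t.size == 0:
        raise InsufficientSamplesError("velocity trace has no samples after onset")
    idx = np.nonzero(v >= target)[0]
    if idx.size == 0:
        raise TargetNotReachedError(
            f"velocity peaks at {v.max():.4g}, below the target {target}")
    i = int(idx[0])
    if i == 0 or v[i] == target:
        return float(t[i] - onset)
    frac = (target - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac / velocity.rate - onset)


def isokinetic_end(velocity: SampledTrace, target: float, onset: float) -> float:
    """End of the isokinetic phase: first sample after the target is reached
    where velocity drops back below it."""
    t_reach = onset + time_to_target_velocity(velocity, target, onset)
    t, v = velocity.window(t_reach, velocity.t_end)
    below = np.nonzero(v < target)[0]
    if below.size == 0:
        return float(velocity.t_end)
    return float(t[below[0]])


def compute_imvc(trace: SampledTrace, stim_time: float, window: float = 0.5) -> float:
    """Maximal torque over the ``window`` seconds preceding the stimulation."""
    start = stim_time - window
    if start < trace.t0 - 1e-9:
        raise InsufficientSamplesError(
            f"IMVC window would start at {start:.3f}s, before the trace ({trace.t0}s)")
    t, y = trace.window(start, stim_time)
    if t.size == 0:
        raise InsufficientSamplesError("empty IMVC window")
    return float(y.max())


def voluntary_activation(superimposed_twitch: float,
                         potentiated_resting_twitch: float) -> float:
    """Twitch-interpolation voluntary activation:
    ``VA% = (1 - superimposed / resting) × 100``, clipped to [0, 100]."""
    if potentiated_resting_twitch <= 0:
        raise InvalidInputError("potentiated resting twitch must be positive")
    if superimposed_twitch < 0:
        warnings.warn("negative superimposed twitch clipped to 0", stacklevel=2)
        superimposed_twitch = 0.0
    va = (1.0 - superimposed_twitch / potentiated_resting_twitch) * 100.0
    if va < 0.0:
        warnings.warn("voluntary activation clipped to 0 %", stacklevel=2)
        va = 0.0
    return va


def evoked_metrics(response: SampledTrace, baseline: float = 0.0) -> tuple[float, float]:
    """(evoked peak torque, evoked RTD) of a baseline-corrected evoked response.

    The evoked RTD is the maximum of the central-difference first derivative,
    matching the 'maximal evoked rate of torque development' definition.
    """
    y = response.values - baseline
    if y.size < 3:
        raise InsufficientSamplesError("evoked response needs >= 3 samples")
    e_tpeak = float(y.max())
    if e_tpeak <= 0:
        raise InvalidResponseError("evoked response has no positive peak")
    deriv = np.gradient(y, response.dt)
    return e_tpeak, float(deriv.max())


def superimposed_twitch(trace: SampledTrace, stim_time: float,
                        search_window: float = 0.2,
                        baseline_window: float = 0.05) -> float:
    """Amplitude of the stimulation-evoked torque increment during an MVC.

    Local baseline is the mean torque over ``baseline_window`` seconds before
    the stimulation; the twitch is the maximum excess over that baseline
    within ``search_window`` seconds after it (may be negative with noise).
    """
    _, pre = trace.window(stim_time - baseline_window, stim_time)
    if pre.size == 0:
        raise InsufficientSamplesError("no samples before the stimulation")
    _, post = trace.window(stim_time, stim_time + search_window)
    if post.size == 0:
        raise InsufficientSamplesError("no samples after the stimulation")
    return float(post.max() - pre.mean())


def db_ratio(db10_peak: float, db100_peak: float) -> float:
    """Ratio of the 10 Hz to the 100 Hz doublet peak torque (low- vs
    high-frequency fatigue index)."""
    if db10_peak <= 0 or db100_peak <= 0:
        raise InvalidInputError("doublet peaks must be positive")
    return db10_peak / db100_peak


def contraction_torque_metrics(torque: SampledTrace, velocity: SampledTrace,
                               target_velocity: float = 240.0,
                               baseline_window: float = 0.3,
                               k_sd: float = 3.0, min_hold: float = 0.03,
                               rtd_window: float = 0.075,
                               onset: float | None = None) -> TorqueMetrics:
    """Full torque chain for one contraction.

    Detects the contraction onset (unless given), the isokinetic phase end
    from the velocity trace, and extracts RTD, T_peak, T_mean, time-to-peak
    and time-to-target-velocity.
    """
    if onset is None:
        onset = detect_torque_onset(torque, baseline_window, k_sd, min_hold)
    # The T_peak/T_mean window is the movement itself: movement onset (from
    # the velocity trace, whose rise does not change with fatigue) to the end
    # of the isokinetic phase.  RTD stays anchored to the torque onset.
    movement_onset = detect_torque_onset(velocity, baseline_window, k_sd, min_hold)
    end = isokinetic_end(velocity, target_velocity, movement_onset)
    t_peak, t_mean, t2p = compute_tpeak_tmean(torque, movement_onset, end)
    rtd = compute_rtd(torque, onset, rtd_window)
    t2v = time_to_target_velocity(velocity, target_velocity, movement_onset)
    return TorqueMetrics(t_mean=t_mean, t_peak=t_peak, rtd=rtd,
                         time_to_peak=t2p, time_to_target_velocity=t2v,
                         onset=onset)


def process_neuromuscular_test(imvc_traces, stim_time: float,
                               doublet100, doublet10, mwave_p2p_values,
                               ) -> NeuromuscularTest:
    """Summarize one testing bout from its raw traces.

    IMVC is the best 500-ms pre-stimulus maximum across the bout's MVCs; VA
    uses the superimposed twitch of that same contraction against the mean
    potentiated 100 Hz doublet; evoked metrics are averaged over the bout's
    doublets, as is the M-wave amplitude.
    """
    imvc_values = [compute_imvc(tr, stim_time) for tr in imvc_traces]
    best = int(np.argmax(imvc_values))
    sup = superimposed_twitch(imvc_traces[best], stim_time)
    evoked = [evoked_metrics(tr) for tr in doublet100]
    e_tpeak = float(np.mean([e[0] for e in evoked]))
    e_rtd = float(np.mean([e[1] for e in evoked]))
    db10 = float(np.mean([evoked_metrics(tr)[0] for tr in doublet10]))
    va = voluntary_activation(max(sup, 0.0), e_tpeak)
    return NeuromuscularTest(
        imvc=float(imvc_values[best]), va=va, e_tpeak=e_tpeak, e_rtd=e_rtd,
        db10=db10, db_ratio=db_ratio(db10, e_tpeak),
        m_max=float(np.mean(mwave_p2p_values)))
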