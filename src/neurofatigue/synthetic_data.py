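"""Synthetic repeated-maximal-contraction experiments with known ground truth.

This module emulates the recordings of an isokinetic knee-extension fatigue
protocol — 20 sets of 8 maximal contractions at 240 °/s, each lasting ~375 ms
(90° range of motion / 240 °·s⁻¹) — together with pre/post neuromuscular
testing (isometric MVCs with superimposed stimulation, potentiated 100 Hz and
10 Hz doublets, single twitches, M-waves), a VO2 series of 30-s averages and
pre/post blood lactate.  Every generated record carries exact programmed truth
so the extraction chain can be validated end to end.

Signal models
-------------
* **Torque** — zero baseline, then a linear rise whose slope *is* the
  programmed rate of torque development (RTD), a cubic Hermite segment up to
  the programmed peak at a fixed time-to-peak, and a smoothstep tail whose end
  level is solved *in the discrete sample domain* so the mean over the
  contraction window equals the programmed T_mean exactly.  The linear early
  phase makes the 0–75 ms least-squares slope equal the programmed RTD even
  when onset detection is a few samples late.
* **EMG** — Gaussian noise shaped by an effectively time-varying 4th-order
  Butterworth band-pass (proportional bandwidth 0.6 × center frequency,
  realized as overlapped Hann-windowed block filtering), normalized to unit
  RMS and multiplied by a deterministic envelope.  The envelope's early slope
  is the programmed rate of EMG rise (RER); the band center follows a
  programmable trajectory so spectral compression can be injected into the
  early contraction only.
* **Evoked responses** — bi-exponential ``K (e^{-t/τ_d} - e^{-t/τ_r})``
  waveforms; the rise time constant is solved so the true derivative maximum
  equals the programmed evoked RTD.

Fatigue is programmed as per-metric multiplicative decline schedules, linear
in set index from 100 % at set 1 down to a configured end fraction at the
last set (block means of the study this emulates decline roughly linearly;
no within-set functional form is published, so within-set decline defaults
to flat and is exposed as a parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .errors import InvalidConfigError
from .trace import SampledTrace

__all__ = [
    "ProtocolConfig",
    "ContractionRecord",
    "NeuromuscularTestRecording",
    "Experiment",
    "GroundTruth",
    "contraction_duration",
    "generate_contraction_torque",
    "generate_velocity",
    "generate_contraction_emg",
    "generate_evoked_response",
    "evoked_peak_time",
    "solve_rise_tau",
    "generate_mwave",
    "generate_imvc_trace",
    "generate_vo2",
    "generate_protocol",
    "write_experiment",
    "load_experiment",
]

# ---------------------------------------------------------------------------
# Protocol geometry and defaults
# ---------------------------------------------------------------------------

#: End-of-protocol fraction remaining for each declining metric, i.e. the
#: group-mean percent changes the generator is programmed to reproduce.
DEFAULT_END_FRACTIONS: dict[str, float] = {
    "rtd": 1.0 - 0.451,        # rate of torque development: -45.1 %
    "t_mean": 1.0 - 0.314,     # mean torque: -31.4 %
    "t_peak": 1.0 - 0.223,     # peak torque: -22.3 %
    "rer": 1.0 - 0.211,        # M_max-normalized rate of EMG rise: -21.1 %
    "emg_scale": 1.0 - 0.032,  # peak EMG envelope: -3.2 % (not significant)
    "spectral": 0.80,          # early-contraction spectral centroid: ~-20 %
}

#: Pre→post fraction remaining for the neuromuscular-test metrics.
DEFAULT_PREPOST_FRACTIONS: dict[str, float] = {
    "imvc": 1.0 - 0.326,       # isometric MVC torque: -32.6 %
    "e_tpeak": 1.0 - 0.243,    # evoked peak torque (100 Hz doublet): -24.3 %
    "e_rtd": 1.0 - 0.247,      # evoked rate of torque development: -24.7 %
    "db_ratio": 1.0 - 0.268,   # 10:100 Hz doublet ratio: -26.8 %
    "m_max": 1.0,              # M-wave amplitude: no change programmed
}

#: Group-mean baselines (healthy trained men, knee extensors).
DEFAULT_BASELINES: dict[str, float] = {
    "t_peak": 172.8,           # N·m
    "t_mean": 94.0,            # N·m
    "rtd": 1069.0,             # N·m·s⁻¹
    "time_to_velocity": 0.057,  # s, to reach 240 °/s
    "imvc": 320.0,             # N·m
    "e_tpeak": 120.6,          # N·m
    "e_rtd": 3463.0,           # N·m·s⁻¹
    "db_ratio": 0.89,          # a.u.
    "m_max": 6.34,             # mV peak-to-peak
    "emg_scale": 1.5,          # mV, peak of the RMS envelope
    "rer": 9.0,                # mV·s⁻¹, envelope rise slope
    "if_mean": 100.0,          # Hz, EMG spectral center
    "va_pre": 96.4,            # %, voluntary activation pre
    "va_post": 92.3,           # %, voluntary activation post
    "vo2_asymptote": 23.7,     # mL·min⁻¹·kg⁻¹
    "vo2_tau": 60.0,           # s
    "vo2_baseline": 4.5,       # mL·min⁻¹·kg⁻¹ at rest
    "lactate_pre": 1.3,        # mmol·L⁻¹
    "lactate_accumulation": 5.7,  # mmol·L⁻¹
}

#: Relative noise amplitudes per signal class.
DEFAULT_NOISE: dict[str, float] = {
    "torque": 0.05,     # SD relative to the contraction's peak torque
    "velocity": 0.01,   # SD relative to the target velocity
    "imvc": 0.01,       # SD relative to the plateau
    "evoked": 0.02,     # SD relative to the response amplitude
    "mwave": 0.02,      # SD relative to peak-to-peak amplitude
    "emg_floor": 0.01,  # white noise floor relative to the envelope scale
    "vo2": 0.03,        # SD relative to the asymptote
}

#: Inter-subject log-normal variability (SD of log factors).
DEFAULT_BETWEEN_SUBJECT_SD: dict[str, float] = {
    "strength": 0.15,   # common scale of all torque quantities
    "emg": 0.25,        # common scale of all EMG amplitudes (electrode/tissue)
    "rtd_shape": 0.03,  # RTD relative to strength
    "tmean_shape": 0.01,  # T_mean relative to strength
    "rer_shape": 0.04,  # RER relative to the EMG scale
    "spectral": 0.05,
    "db_ratio": 0.05,
    "vo2": 0.15,
}


def contraction_duration(range_of_motion_deg: float = 90.0,
                         velocity_dps: float = 240.0) -> float:
    """Duration of one isokinetic contraction from its geometry.

    90° of knee-joint excursion at a constant 240 °·s⁻¹ gives 0.375 s.
    """
    if range_of_motion_deg <= 0 or velocity_dps <= 0:
        raise InvalidConfigError("range of motion and velocity must be positive")
    return range_of_motion_deg / velocity_dps


def _linear_schedule(n_sets: int, end_fraction: float) -> np.ndarray:
    if not (0.0 < end_fraction <= 1.0):
        raise InvalidConfigError(f"decline end fraction must be in (0, 1], got {end_fraction}")
    if n_sets == 1:
        return np.array([1.0])
    return 1.0 - (1.0 - end_fraction) * np.arange(n_sets) / (n_sets - 1)


@dataclass
class ProtocolConfig:
    """Ground-truth parameters of one simulated experiment.

    ``decline_schedule`` maps metric name → fraction of the subject baseline
    remaining at each set (length ``n_sets``, non-increasing, in (0, 1]);
    ``prepost_fractions`` does the same for the pre→post neuromuscular tests.
    The same master ``seed`` always yields a bit-identical experiment.
    """

    n_subjects: int = 11
    n_sets: int = 20
    reps_per_set: int = 8
    contraction_duration: float = 0.375
    torque_rate: float = 100.0
    emg_rate: float = 2048.0
    target_velocity: float = 240.0
    set_interval: float = 30.0
    within_set_decline: float = 0.0  # extra fractional decline rep 1 → last rep
    decline_schedule: dict[str, np.ndarray] = field(default_factory=dict)
    prepost_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREPOST_FRACTIONS))
    baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD))
    noise_levels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.decline_schedule:
            self.decline_schedule = {
                k: _linear_schedule(self.n_sets, f)
                for k, f in DEFAULT_END_FRACTIONS.items()
            }
        else:
            self.decline_schedule = {
                k: np.asarray(v, dtype=float) for k, v in self.decline_schedule.items()
            }
        self.validate()

    def validate(self) -> None:
        for name, value in [("n_subjects", self.n_subjects),
                            ("n_sets", self.n_sets),
                            ("reps_per_set", self.reps_per_set)]:
            if int(value) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {value}")
        for name, value in [("torque_rate", self.torque_rate),
                            ("emg_rate", self.emg_rate),
                            ("target_velocity", self.target_velocity)]:
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        if self.contraction_duration < 0.3:
            raise InvalidConfigError(
                f"contraction_duration must be >= 0.3 s, got {self.contraction_duration}")
        if not (0.0 <= self.within_set_decline < 1.0):
            raise InvalidConfigError("within_set_decline must be in [0, 1)")
        for metric, sched in self.decline_schedule.items():
            if len(sched) != self.n_sets:
                raise InvalidConfigError(
                    f"decline_schedule[{metric}] must have n_sets={self.n_sets} entries")
            if np.any(sched <= 0) or np.any(sched > 1.0 + 1e-12):
                raise InvalidConfigError(
                    f"decline_schedule[{metric}] fractions must be in (0, 1]")
            if np.any(np.diff(sched) > 1e-12):
                raise InvalidConfigError(
                    f"decline_schedule[{metric}] must be non-increasing")
        for metric, frac in self.prepost_fractions.items():
            if not (0.0 < frac <= 1.0):
                raise InvalidConfigError(
                    f"prepost_fractions[{metric}] must be in (0, 1], got {frac}")
        for key, level in self.noise_levels.items():
            if level < 0:
                raise InvalidConfigError(f"noise_levels[{key}] must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["decline_schedule"] = {k: list(map(float, v))
                                 for k, v in self.decline_schedule.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# Record containers
# ---------------------------------------------------------------------------

@dataclass
class ContractionRecord:
    """Torque, velocity and EMG traces for one maximal knee extension."""

    subject: int
    set: int
    rep: int
    torque: SampledTrace
    velocity: SampledTrace
    emg: SampledTrace
    onset: float  # true contraction onset, s from trace start


@dataclass
class NeuromuscularTestRecording:
    """Raw traces of one pre- or post-exercise neuromuscular testing bout."""

    subject: int
    phase: str  # "pre" | "post"
    imvc_traces: list[SampledTrace]
    stim_time: float  # superimposed stimulation time within each IMVC trace
    doublet100: list[SampledTrace]
    doublet10: list[SampledTrace]
    twitches: list[SampledTrace]
    mwaves: list[SampledTrace]


@dataclass
class GroundTruth:
    """Programmed truth for every generated record (pandas DataFrames)."""

    contractions: "object"  # DataFrame: subject,set,rep,rtd,t_peak,t_mean,...
    tests: "object"         # DataFrame: subject,phase,imvc,va,e_tpeak,...
    vo2: "object"           # DataFrame: subject,asymptote,tau,baseline
    lactate: "object"       # DataFrame: subject,pre,post


@dataclass
class Experiment:
    """One complete synthetic experiment: signals, tests, VO2, lactate, truth."""

    config: ProtocolConfig
    contractions: list[ContractionRecord]
    tests: list[NeuromuscularTestRecording]
    vo2: dict[int, tuple[np.ndarray, np.ndarray]]  # subject -> (t_s, mL/min/kg)
    lactate: dict[int, tuple[float, float]]        # subject -> (pre, post)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Torque generation
# ---------------------------------------------------------------------------

_TIME_TO_PEAK = 0.16     # s, constant through fatigue (it is observed not to change)
_LINEAR_TIME = 0.115     # s, extent of the strictly linear rise
_RELEASE_TIME = 0.15     # s, torque release after the isokinetic phase
_VELOCITY_OVERSHOOT = 1.05
_VELOCITY_RELEASE = 0.02


def _smoothstep(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, 1.0)
    return v * v * (3.0 - 2.0 * v)


def _hermite(u, t0, t1, p0, m0, p1, m1):
    """Cubic Hermite interpolation on [t0, t1] with endpoint values/slopes."""
    h = t1 - t0
    s = (u - t0) / h
    return ((2 * s**3 - 3 * s**2 + 1) * p0 + (s**3 - 2 * s**2 + s) * h * m0
            + (-2 * s**3 + 3 * s**2) * p1 + (s**3 - s**2) * h * m1)


def _rise_geometry(rtd: float, tpeak: float, rate: float,
                   t1: float = _LINEAR_TIME,
                   tp: float = _TIME_TO_PEAK) -> tuple[float, float]:
    """Linear-phase length and time-to-peak compatible with (rtd, tpeak).

    The rise must stay strictly linear through the 75-ms slope window (so the
    extracted RTD equals the programmed one exactly) and the cubic knee to
    the peak must be monotone, which requires ``rtd·(tp + 2·t1) <= 3·tpeak``.
    For steep RTD relative to the peak, the linear phase shrinks (never below
    the last 100-Hz sample of the slope window) and the peak arrives earlier,
    snapped down to the sample grid so a sample lands exactly on the peak.
    """
    t1_max = 0.5 * (3.0 * tpeak / rtd - tp)
    t1_eff = min(t1, max(t1_max, 0.071))
    if rtd * t1_eff >= tpeak:
        raise InvalidConfigError(
            f"programmed RTD {rtd} reaches the peak {tpeak} inside the 75-ms slope window")
    tp_eff = min(tp, t1_eff + 3.0 * (tpeak - rtd * t1_eff) / rtd)
    tp_eff = np.floor(tp_eff * rate + 1e-9) / rate  # sample lands on the peak
    if tp_eff <= t1_eff:
        raise InvalidConfigError(
            f"no monotone rise exists for RTD {rtd} with peak {tpeak} at {rate} Hz")
    return t1_eff, tp_eff


def _torque_prepeak(u: np.ndarray, rtd: float, tpeak: float,
                    t1: float, tp: float) -> np.ndarray:
    """Noise-free torque for 0 <= u <= tp (linear ramp then Hermite knee)."""
    y1 = rtd * t1
    return np.where(u <= t1, rtd * u,
                    _hermite(np.minimum(u, tp), t1, tp, y1, rtd, tpeak, 0.0))


def _noise_free_torque(u: np.ndarray, rtd: float, tpeak: float,
                       tmean: float | None, duration: float, rate: float) -> np.ndarray:
    """Torque values at times ``u`` relative to onset (u may be negative)."""
    t1, tp = _rise_geometry(rtd, tpeak, rate)
    n_active = int(math.ceil(duration * rate - 1e-9))
    grid = np.arange(n_active) / rate  # the samples that form the T_mean window
    pre_mask = grid <= tp + 1e-12
    pre_vals = _torque_prepeak(grid[pre_mask], rtd, tpeak, t1, tp)
    tail_u = grid[~pre_mask]

    if tmean is None:
        end_level = 0.25 * tpeak
    else:
        if not (0 < tmean < tpeak):
            raise InvalidConfigError("programmed T_mean must lie in (0, T_peak)")
        g = _smoothstep((tail_u - tp) / (duration - tp))
        target_sum = tmean * n_active
        sum_pre = pre_vals.sum()
        if g.sum() > 0:
            end_level = (target_sum - sum_pre - tpeak * np.sum(1.0 - g)) / g.sum()
        else:
            end_level = 0.0
        if end_level > tpeak:
            raise InvalidConfigError("programmed T_mean unreachable: tail would exceed the peak")

    if end_level >= 0:
        def tail_fn(uu):
            return tpeak + (end_level - tpeak) * _smoothstep((uu - tp) / (duration - tp))
    else:
        # Mean target too low for a tail plateau: let torque reach zero at a
        # solved time t_z < duration and stay there (still exact in the mean).
        def _mean_for(t_z):
            vals = tpeak * (1.0 - _smoothstep((tail_u - tp) / (t_z - tp)))
            return (pre_vals.sum() + vals.sum()) / n_active

        lo, hi = tp + 1e-6, duration
        if _mean_for(lo) > tmean:
            raise InvalidConfigError("programmed T_mean unreachable: below the rise-phase mean")
        t_z = brentq(lambda z: _mean_for(z) - tmean, lo, hi, xtol=1e-12)

        def tail_fn(uu):
            return tpeak * (1.0 - _smoothstep((uu - tp) / (t_z - tp)))

        end_level = float(tail_fn(np.array([duration - 1e-12]))[0])

    out = np.zeros_like(u)
    rising = (u >= -1e-12) & (u <= tp + 1e-12)
    out[rising] = _torque_prepeak(u[rising], rtd, tpeak, t1, tp)
    tail = (u > tp + 1e-12) & (u < duration - 1e-12)
    out[tail] = tail_fn(u[tail])
    release = u >= duration - 1e-12
    out[release] = max(end_level, 0.0) * (
        1.0 - _smoothstep((u[release] - duration) / _RELEASE_TIME))
    return out


def generate_contraction_torque(rtd_true: float, tpeak_true: float,
                                duration: float, rate: float,
                                noise: float, rng: np.random.Generator | None = None,
                                *, tmean_true: float | None = None,
                                baseline_pad: float = 0.5,
                                tail_pad: float = 0.25) -> SampledTrace:
    """Generate one contraction's torque trace.

    The true onset sits exactly at ``baseline_pad`` seconds (on the sample
    grid).  Noise-free, the trace satisfies: OLS slope of the first 75 ms
    = ``rtd_true``; maximum sample = ``tpeak_true``; mean over the
    contraction window = ``tmean_true`` (when given).  ``noise`` is the SD
    of additive white noise relative to ``tpeak_true``.
    """
    if rate <= 0 or duration <= 0:
        raise InvalidConfigError("rate and duration must be positive")
    if rtd_true <= 0 or tpeak_true <= 0:
        raise InvalidConfigError("rtd_true and tpeak_true must be positive")
    if duration < 0.3:
        raise InvalidConfigError("contraction duration must be >= 0.3 s")
    n = int(round((baseline_pad + duration + tail_pad) * rate))
    i0 = int(round(baseline_pad * rate))
    u = (np.arange(n) - i0) / rate
    values = _noise_free_torque(u, rtd_true, tpeak_true, tmean_true, duration, rate)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * tpeak_true, size=n)
    return SampledTrace(values, rate, 0.0, unit="N·m")


def generate_velocity(duration: float, rate: float, target: float,
                      time_to_target: float, noise: float,
                      rng: np.random.Generator | None = None,
                      *, baseline_pad: float = 0.5,
                      tail_pad: float = 0.25) -> SampledTrace:
    """Angular-velocity trace: ramp, slight overshoot plateau, rapid release.

    The dynamometer plateau sits 5 % above the nominal target so that noise
    never drops a plateau sample below the target, and the release is steep
    enough that the first sample after the programmed duration is already
    below the target — the detected isokinetic phase end therefore equals
    onset + duration at sample resolution.
    """
    if target <= 0 or time_to_target <= 0:
        raise InvalidConfigError("target velocity and time_to_target must be positive")
    n = int(round((baseline_pad + duration + tail_pad) * rate))
    i0 = int(round(baseline_pad * rate))
    u = (np.arange(n) - i0) / rate
    plateau = _VELOCITY_OVERSHOOT * target
    t_ramp = time_to_target * plateau / target  # crosses `target` at time_to_target
    values = np.zeros(n)
    ramp = (u >= 0) & (u < t_ramp)
    values[ramp] = plateau * u[ramp] / t_ramp
    hold = (u >= t_ramp) & (u < duration - 1e-12)
    values[hold] = plateau
    rel = u >= duration - 1e-12
    values[rel] = plateau * (1.0 - _smoothstep((u[rel] - duration) / _VELOCITY_RELEASE))
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * target, size=n)
    return SampledTrace(values, rate, 0.0, unit="°/s")


# ---------------------------------------------------------------------------
# EMG generation
# ---------------------------------------------------------------------------

_EMG_LINEAR_TIME = 0.10   # s, extent of the strictly linear envelope rise
_EMG_PEAK_TIME = 0.228    # s, time of the envelope peak
_EMG_END_FRACTION = 0.75  # envelope level at the end of the contraction
_EMG_RELEASE = 0.08       # s, envelope decay after the contraction
_EMG_BLOCK = 128          # samples per filtering block at 2048 Hz (62.5 ms)


def _emg_envelope(u: np.ndarray, scale: float, duration: float,
                  rer: float | None, rise_time: float = 0.1) -> np.ndarray:
    """Deterministic RMS envelope (mV) at times ``u`` relative to onset."""
    out = np.zeros_like(u)
    if scale == 0:
        return out
    if rer is None:
        rising = (u >= 0) & (u < rise_time)
        out[rising] = scale * _smoothstep(u[rising] / rise_time)
        mid = (u >= rise_time) & (u < duration)
        out[mid] = scale
    else:
        t1, tp = _EMG_LINEAR_TIME, _EMG_PEAK_TIME
        y1 = rer * t1
        if y1 >= scale or rer > 3.0 * (scale - y1) / (tp - t1):
            raise InvalidConfigError(
                f"programmed RER {rer} incompatible with envelope scale {scale}")
        ramp = (u >= 0) & (u <= t1)
        out[ramp] = rer * u[ramp]
        knee = (u > t1) & (u <= tp)
        out[knee] = _hermite(u[knee], t1, tp, y1, rer, scale, 0.0)
        tail = (u > tp) & (u < duration)
        out[tail] = scale + (_EMG_END_FRACTION * scale - scale) * _smoothstep(
            (u[tail] - tp) / (duration - tp))
    rel = (u >= duration) & (u < duration + _EMG_RELEASE)
    level = out[np.searchsorted(u, duration) - 1] if np.any(u < duration) else 0.0
    out[rel] = level * (1.0 - _smoothstep((u[rel] - duration) / _EMG_RELEASE))
    return out


def _tv_bandpassed_noise(n: int, rate: float, center_at: Callable[[float], float],
                         rng: np.random.Generator,
                         rel_bandwidth: float = 0.6) -> np.ndarray:
    """White noise through a time-varying 4th-order Butterworth band-pass.

    Realized by overlap-adding Hann-windowed blocks, each filtered with the
    static band-pass whose center frequency is the trajectory value at the
    block center.  The Hann windows at 50 % overlap sum to one, so a constant
    trajectory reduces to ordinary static filtering up to block quantization.
    """
    white = rng.standard_normal(n)
    block, hop = _EMG_BLOCK, _EMG_BLOCK // 2
    pad = block
    padded = np.concatenate([rng.standard_normal(pad), white, rng.standard_normal(pad)])
    win = hann(block, sym=False)
    out = np.zeros(n + 2 * pad)
    nyq = rate / 2.0
    sos_cache: dict[float, np.ndarray] = {}
    for start in range(0, out.size - block + 1, hop):
        t_c = (start + block / 2 - pad) / rate
        c = float(center_at(t_c))
        if not (10.0 < c < 500.0):
            raise InvalidConfigError(
                f"spectral center {c:.1f} Hz at t={t_c:.3f}s outside the 10-500 Hz band")
        key = round(c * 2) / 2
        if key not in sos_cache:
            lo = max(key * (1 - rel_bandwidth / 2), 1.0)
            hi = min(key * (1 + rel_bandwidth / 2), 0.95 * nyq)
            sos_cache[key] = butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
        seg_lo = max(start - hop, 0)
        seg = sosfiltfilt(sos_cache[key], padded[seg_lo:start + block + hop])
        out[start:start + block] += win * seg[start - seg_lo:start - seg_lo + block]
    return out[pad:pad + n]


def generate_contraction_emg(envelope_scale: float,
                             spectral_center: Callable[[float], float] | float,
                             rate: float, duration: float,
                             rng: np.random.Generator | None = None,
                             *, rer: float | None = None,
                             rise_time: float = 0.1,
                             noise_floor: float = 0.0,
                             baseline_pad: float = 0.5,
                             tail_pad: float = 0.125) -> SampledTrace:
    """Generate one contraction's raw surface EMG trace (mV).

    ``spectral_center`` may be a constant (Hz) or a function of time relative
    to the contraction onset; it must stay inside the 10–500 Hz band-pass of
    the analysis chain.  The band-limited carrier is normalized to unit RMS
    over the contraction so the programmed envelope *is* the expected RMS.
    ``noise_floor`` is the SD of an additive white measurement-noise floor in
    mV.  The true activation onset sits at ``baseline_pad`` seconds.
    """
    if rate <= 0 or duration <= 0:
        raise InvalidConfigError("rate and duration must be positive")
    if envelope_scale < 0:
        raise InvalidConfigError("envelope_scale must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round((baseline_pad + duration + tail_pad) * rate))
    i0 = int(round(baseline_pad * rate))
    u = (np.arange(n) - i0) / rate
    env = _emg_envelope(u, envelope_scale, duration, rer, rise_time)
    if envelope_scale == 0 and noise_floor == 0:
        return SampledTrace(np.zeros(n), rate, 0.0, unit="mV")

    if callable(spectral_center):
        # the trajectory is defined in time relative to the activation onset
        center_at = lambda t: spectral_center(t - baseline_pad)  # noqa: E731
    else:
        c0 = float(spectral_center)
        center_at = lambda t: c0  # noqa: E731
    carrier = _tv_bandpassed_noise(n, rate, center_at, rng)
    # Normalize the carrier to unit RMS *locally*, at the 50-ms scale of the
    # downstream RMS analysis window.  With a time-varying proportional
    # bandwidth the filtered variance varies along the trace, and both a
    # global normalization and the raw band-limited amplitude fluctuations
    # would make the windowed RMS deviate from the programmed envelope; the
    # envelope is the generator's ground truth, so it must *be* the local
    # RMS.  (The amplitude fluctuation statistics of real EMG are therefore
    # not emulated — only its spectral content and envelope.)
    local_ms = uniform_filter1d(carrier ** 2, size=max(int(round(0.05 * rate)), 3),
                                mode="reflect")
    carrier = carrier / np.sqrt(np.maximum(local_ms, 1e-30))
    values = env * carrier
    if noise_floor > 0:
        values = values + rng.normal(0.0, noise_floor, size=n)
    return SampledTrace(values, rate, 0.0, unit="mV")


# ---------------------------------------------------------------------------
# Evoked responses, M-waves, IMVC, VO2
# ---------------------------------------------------------------------------

def evoked_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Analytic peak time of ``e^{-t/decay} - e^{-t/rise}``."""
    return math.log(decay_tau / rise_tau) / (1.0 / rise_tau - 1.0 / decay_tau)


def generate_evoked_response(amplitude: float, rise_tau: float, decay_tau: float,
                             rate: float, duration: float = 1.0,
                             noise: float = 0.0,
                             rng: np.random.Generator | None = None) -> SampledTrace:
    """Bi-exponential evoked twitch/doublet torque waveform.

    ``K (e^{-t/decay_tau} - e^{-t/rise_tau})`` with K chosen so the continuous
    maximum equals ``amplitude``; the waveform decays below 1 % of the
    amplitude by the default 1-s trace end.
    """
    if rate <= 0 or duration <= 0:
        raise InvalidConfigError("rate and duration must be positive")
    if not (decay_tau > rise_tau > 0):
        raise InvalidConfigError("need decay_tau > rise_tau > 0")
    t = np.arange(int(round(duration * rate))) / rate
    if amplitude == 0:
        values = np.zeros_like(t)
    else:
        t_star = evoked_peak_time(rise_tau, decay_tau)
        shape_max = math.exp(-t_star / decay_tau) - math.exp(-t_star / rise_tau)
        k = amplitude / shape_max
        values = k * (np.exp(-t / decay_tau) - np.exp(-t / rise_tau))
    if noise > 0 and amplitude != 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * abs(amplitude), size=t.size)
    return SampledTrace(values, rate, 0.0, unit="N·m")


def true_evoked_rtd(amplitude: float, rise_tau: float, decay_tau: float) -> float:
    """True derivative maximum of the bi-exponential response (at t = 0)."""
    t_star = evoked_peak_time(rise_tau, decay_tau)
    shape_max = math.exp(-t_star / decay_tau) - math.exp(-t_star / rise_tau)
    return amplitude / shape_max * (1.0 / rise_tau - 1.0 / decay_tau)


def solve_rise_tau(amplitude: float, ertd_target: float, decay_tau: float) -> float:
    """Rise time constant for which the true derivative maximum equals ``ertd_target``."""
    if amplitude <= 0 or ertd_target <= 0 or decay_tau <= 0:
        raise InvalidConfigError("amplitude, ertd_target and decay_tau must be positive")

    def f(tau_r: float) -> float:
        return true_evoked_rtd(amplitude, tau_r, decay_tau) - ertd_target

    lo, hi = 1e-4, decay_tau * (1 - 1e-6)
    if f(hi) > 0:
        raise InvalidConfigError("ertd_target too low for the given amplitude/decay_tau")
    if f(lo) < 0:
        raise InvalidConfigError("ertd_target too high for the given amplitude/decay_tau")
    return brentq(f, lo, hi, xtol=1e-12)


def generate_mwave(p2p: float, rate: float = 2048.0, duration: float = 0.05,
                   noise: float = 0.0,
                   rng: np.random.Generator | None = None) -> SampledTrace:
    """Biphasic compound muscle action potential with exact peak-to-peak amplitude."""
    if p2p < 0 or rate <= 0:
        raise InvalidConfigError("p2p must be >= 0 and rate positive")
    t = np.arange(int(round(duration * rate))) / rate
    shape = np.sin(2 * np.pi * 80.0 * (t - 0.015)) * np.exp(-(((t - 0.015) / 0.006) ** 2))
    span = shape.max() - shape.min()
    values = shape * (p2p / span) if p2p > 0 else np.zeros_like(shape)
    if noise > 0 and p2p > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * p2p, size=t.size)
    return SampledTrace(values, rate, 0.0, unit="mV")


def generate_imvc_trace(plateau: float, sup_twitch: float, rate: float = 100.0,
                        stim_time: float = 2.5, noise: float = 0.0,
                        rng: np.random.Generator | None = None) -> SampledTrace:
    """Isometric MVC torque trace with a superimposed doublet at ``stim_time``.

    Smoothstep rise to the plateau over 0.5–1.5 s, plateau held through the
    stimulation, release 1 s after it.  Noise SD is relative to the plateau.
    """
    if plateau <= 0:
        raise InvalidConfigError("plateau must be positive")
    if sup_twitch < 0:
        raise InvalidConfigError("superimposed twitch must be >= 0")
    total = stim_time + 2.0
    t = np.arange(int(round(total * rate))) / rate
    values = plateau * _smoothstep((t - 0.5) / 1.0)
    rel = t >= stim_time + 1.0
    values[rel] = plateau * (1.0 - _smoothstep((t[rel] - stim_time - 1.0) / 0.5))
    if sup_twitch > 0:
        tw = t >= stim_time
        tt = t[tw] - stim_time
        t_star = evoked_peak_time(0.03, 0.08)
        shape_max = math.exp(-t_star / 0.08) - math.exp(-t_star / 0.03)
        values[tw] += sup_twitch / shape_max * (np.exp(-tt / 0.08) - np.exp(-tt / 0.03))
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * plateau, size=t.size)
    return SampledTrace(values, rate, 0.0, unit="N·m")


def generate_vo2(asymptote: float, tau: float, baseline: float,
                 duration: float = 600.0, interval: float = 30.0,
                 noise: float = 0.0,
                 rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """VO2 series of ``interval``-second averages of a mono-exponential rise.

    Returns (window-end times in s, averaged VO2 in mL·min⁻¹·kg⁻¹); each point
    is the exact analytic mean of ``y0 + (A - y0)(1 - e^{-t/τ})`` over its
    averaging window, plus optional noise (SD relative to the asymptote).
    """
    if tau <= 0 or interval <= 0 or duration < interval:
        raise InvalidConfigError("need tau > 0, interval > 0, duration >= interval")
    ends = np.arange(interval, duration + 1e-9, interval)
    starts = ends - interval
    mean_exp = tau * (np.exp(-starts / tau) - np.exp(-ends / tau)) / interval
    values = baseline + (asymptote - baseline) * (1.0 - mean_exp)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise * asymptote, size=values.size)
    return ends, values


# ---------------------------------------------------------------------------
# Full-protocol generation
# ---------------------------------------------------------------------------

def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-record stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(k) for k in key]))


def _draw_subject_baselines(config: ProtocolConfig, subject: int) -> dict[str, float]:
    rng = _rng_for(config.seed, 1, subject)
    b = config.baseline_means
    sd = config.between_subject_sd
    strength = math.exp(rng.normal(0.0, sd["strength"]))
    emg = math.exp(rng.normal(0.0, sd["emg"]))
    out = {
        "t_peak": b["t_peak"] * strength,
        "t_mean": b["t_mean"] * strength * math.exp(rng.normal(0.0, sd["tmean_shape"])),
        "rtd": b["rtd"] * strength * math.exp(rng.normal(0.0, sd["rtd_shape"])),
        "time_to_velocity": b["time_to_velocity"],
        "imvc": b["imvc"] * strength,
        "e_tpeak": b["e_tpeak"] * strength,
        "e_rtd": b["e_rtd"] * strength * math.exp(rng.normal(0.0, sd["rtd_shape"])),
        "db_ratio": b["db_ratio"] * math.exp(rng.normal(0.0, sd["db_ratio"])),
        "m_max": b["m_max"] * emg,
        "emg_scale": b["emg_scale"] * emg,
        "rer": b["rer"] * emg * math.exp(rng.normal(0.0, sd["rer_shape"])),
        "if_mean": b["if_mean"] * math.exp(rng.normal(0.0, sd["spectral"])),
        "vo2_asymptote": b["vo2_asymptote"] * math.exp(rng.normal(0.0, sd["vo2"])),
        "vo2_tau": b["vo2_tau"] * math.exp(rng.normal(0.0, sd["vo2"])),
        "vo2_baseline": b["vo2_baseline"],
        "lactate_pre": max(0.4, rng.normal(b["lactate_pre"], 0.3)),
        "lactate_accumulation": max(0.5, rng.normal(b["lactate_accumulation"], 1.0)),
    }
    return out


def _spectral_trajectory(c0: float, factor: float,
                         ramp_start: float = 0.19,
                         ramp_len: float = 0.025) -> Callable[[float], float]:
    """Early-contraction spectral center: ``c0·factor`` before ``ramp_start``,
    recovering linearly to ``c0`` by ``ramp_start + ramp_len`` (the late
    contraction is spectrally unchanged by fatigue)."""
    def center(t: float) -> float:
        if t <= ramp_start:
            return c0 * factor
        if t >= ramp_start + ramp_len:
            return c0
        w = (t - ramp_start) / ramp_len
        return c0 * (factor + (1.0 - factor) * w)
    return center


def _emg_mean_truth(scale: float, rer: float, duration: float, rate: float) -> float:
    n_active = int(math.ceil(duration * rate - 1e-9))
    u = np.arange(n_active) / rate
    return float(np.mean(_emg_envelope(u, scale, duration, rer)))


def generate_protocol(config: ProtocolConfig) -> Experiment:
    """Generate a complete synthetic experiment with ground truth.

    Produces ``n_subjects × n_sets × reps_per_set`` contraction records, one
    pre and one post neuromuscular testing bout per subject (3 IMVCs, 3×100 Hz
    doublets, 3×10 Hz doublets, 3 single twitches, 3 M-waves), a VO2 series
    and a lactate pair.  Identical configs (including the seed) produce
    bit-identical experiments.
    """
    import pandas as pd

    cfg = config
    cfg.validate()
    noise = cfg.noise_levels
    dur = cfg.contraction_duration
    contractions: list[ContractionRecord] = []
    tests: list[NeuromuscularTestRecording] = []
    vo2: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    lactate: dict[int, tuple[float, float]] = {}
    c_rows, t_rows, v_rows, l_rows = [], [], [], []

    sched = cfg.decline_schedule
    n_reps = cfg.reps_per_set
    for subj in range(1, cfg.n_subjects + 1):
        base = _draw_subject_baselines(cfg, subj)
        for s in range(1, cfg.n_sets + 1):
            for r in range(1, n_reps + 1):
                within = 1.0 - cfg.within_set_decline * (r - 1) / max(n_reps - 1, 1)
                f = {k: sched[k][s - 1] * within for k in sched}
                rtd = base["rtd"] * f["rtd"]
                tpeak = base["t_peak"] * f["t_peak"]
                tmean = base["t_mean"] * f["t_mean"]
                scale = base["emg_scale"] * f["emg_scale"]
                rer = base["rer"] * f["rer"]
                rng_t = _rng_for(cfg.seed, 2, subj, s, r)
                torque = generate_contraction_torque(
                    rtd, tpeak, dur, cfg.torque_rate, noise["torque"], rng_t,
                    tmean_true=tmean)
                velocity = generate_velocity(
                    dur, cfg.torque_rate, cfg.target_velocity,
                    base["time_to_velocity"], noise["velocity"], rng_t)
                center = _spectral_trajectory(base["if_mean"], f["spectral"])
                emg = generate_contraction_emg(
                    scale, center, cfg.emg_rate, dur,
                    _rng_for(cfg.seed, 3, subj, s, r), rer=rer,
                    noise_floor=noise["emg_floor"] * base["emg_scale"])
                onset = 0.5
                contractions.append(ContractionRecord(subj, s, r, torque, velocity, emg, onset))
                c_rows.append(dict(
                    subject=subj, set=s, rep=r, onset=onset,
                    rtd=rtd, t_peak=tpeak, t_mean=tmean,
                    emg_scale=scale, rer=rer,
                    emg_mean=_emg_mean_truth(scale, rer, dur, cfg.emg_rate),
                    spectral_factor=f["spectral"],
                    time_to_velocity=base["time_to_velocity"]))

        for phase in ("pre", "post"):
            pf = cfg.prepost_fractions if phase == "post" else {k: 1.0 for k in cfg.prepost_fractions}
            imvc = base["imvc"] * pf["imvc"]
            e_tpeak = base["e_tpeak"] * pf["e_tpeak"]
            e_rtd = base["e_rtd"] * pf["e_rtd"]
            db_ratio = base["db_ratio"] * pf["db_ratio"]
            db10 = db_ratio * e_tpeak
            m_max = base["m_max"] * pf["m_max"]
            va = cfg.baseline_means["va_pre" if phase == "pre" else "va_post"]
            sup = (1.0 - va / 100.0) * e_tpeak
            # a bi-exponential with decay τ_d cannot have a derivative maximum
            # below e·amplitude/τ_d; lengthen the decay when the programmed
            # eRTD sits near that bound (slow-twitch-like subjects)
            decay_tau = max(0.1, 1.25 * math.e * e_tpeak / e_rtd)
            rise_tau = solve_rise_tau(e_tpeak, e_rtd, decay_tau)
            rng_n = _rng_for(cfg.seed, 4, subj, 0 if phase == "pre" else 1)
            stim_time = 2.5
            rec = NeuromuscularTestRecording(
                subject=subj, phase=phase,
                imvc_traces=[generate_imvc_trace(imvc, sup, cfg.torque_rate,
                                                 stim_time, noise["imvc"], rng_n)
                             for _ in range(3)],
                stim_time=stim_time,
                doublet100=[generate_evoked_response(e_tpeak, rise_tau, decay_tau,
                                                     cfg.torque_rate, 1.0,
                                                     noise["evoked"], rng_n)
                            for _ in range(3)],
                doublet10=[generate_evoked_response(db10, rise_tau * 1.1,
                                                    decay_tau * 1.2,
                                                    cfg.torque_rate, 1.0,
                                                    noise["evoked"], rng_n)
                           for _ in range(3)],
                twitches=[generate_evoked_response(0.5 * e_tpeak, rise_tau, decay_tau,
                                                   cfg.torque_rate, 1.0,
                                                   noise["evoked"], rng_n)
                          for _ in range(3)],
                mwaves=[generate_mwave(m_max, cfg.emg_rate, 0.05,
                                       noise["mwave"], rng_n) for _ in range(3)],
            )
            tests.append(rec)
            t_rows.append(dict(subject=subj, phase=phase, imvc=imvc, va=va,
                               e_tpeak=e_tpeak, e_rtd=e_rtd, db10=db10,
                               db_ratio=db_ratio, m_max=m_max, sup_twitch=sup))

        rng_v = _rng_for(cfg.seed, 5, subj)
        exercise_duration = cfg.n_sets * cfg.set_interval
        vo2[subj] = generate_vo2(base["vo2_asymptote"], base["vo2_tau"],
                                 base["vo2_baseline"], exercise_duration,
                                 30.0, noise["vo2"], rng_v)
        v_rows.append(dict(subject=subj, asymptote=base["vo2_asymptote"],
                           tau=base["vo2_tau"], baseline=base["vo2_baseline"]))
        la_pre = base["lactate_pre"]
        lactate[subj] = (la_pre, la_pre + base["lactate_accumulation"])
        l_rows.append(dict(subject=subj, pre=la_pre,
                           post=la_pre + base["lactate_accumulation"]))

    truth = GroundTruth(
        contractions=pd.DataFrame(c_rows),
        tests=pd.DataFrame(t_rows),
        vo2=pd.DataFrame(v_rows),
        lactate=pd.DataFrame(l_rows),
    )
    return Experiment(cfg, contractions, tests, vo2, lactate, truth)


# ---------------------------------------------------------------------------
# On-disk layout (UTF-8, comma-separated, '.' decimal, header row)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.8g"


def write_experiment(exp: Experiment, outdir) -> None:
    """Write an experiment to ``outdir`` in the pipeline's CSV layout."""
    import json
    import pathlib

    import pandas as pd
    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in exp.contractions:
        d = out / "signals" / f"{rec.subject:02d}"
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_s": rec.torque.times, "torque_Nm": rec.torque.values,
                      "velocity_dps": rec.velocity.values}).to_csv(
            d / f"{rec.set:02d}_{rec.rep}.csv", index=False, float_format=_FLOAT_FMT)
        pd.DataFrame({"t_s": rec.emg.times, "emg_mV": rec.emg.values}).to_csv(
            d / f"{rec.set:02d}_{rec.rep}_emg.csv", index=False, float_format=_FLOAT_FMT)
    for rec in exp.tests:
        d = out / "tests" / f"{rec.subject:02d}" / rec.phase
        d.mkdir(parents=True, exist_ok=True)
        groups = {"imvc": rec.imvc_traces, "doublet100": rec.doublet100,
                  "doublet10": rec.doublet10, "twitch": rec.twitches,
                  "mwave": rec.mwaves}
        for name, traces in groups.items():
            for i, tr in enumerate(traces, 1):
                col = "emg_mV" if name == "mwave" else "torque_Nm"
                pd.DataFrame({"t_s": tr.times, col: tr.values}).to_csv(
                    d / f"{name}_{i}.csv", index=False, float_format=_FLOAT_FMT)
        (d / "meta.json").write_text(json.dumps({"stim_time": rec.stim_time}))
    vo2_dir = out / "vo2"
    vo2_dir.mkdir(exist_ok=True)
    for subj, (t, v) in exp.vo2.items():
        pd.DataFrame({"t_s": t, "vo2_mlminkg": v}).to_csv(
            vo2_dir / f"{subj:02d}.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame([{"subject": s, "pre": p, "post": q}
                  for s, (p, q) in exp.lactate.items()]).to_csv(
        out / "lactate.csv", index=False, float_format=_FLOAT_FMT)
    truth = {
        "contractions": exp.truth.contractions.to_dict(orient="records"),
        "tests": exp.truth.tests.to_dict(orient="records"),
        "vo2": exp.truth.vo2.to_dict(orient="records"),
        "lactate": exp.truth.lactate.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(exp.config.to_dict(), sort_keys=True))


def load_experiment(datadir) -> Experiment:
    """Load an experiment previously written by :func:`write_experiment`."""
    import json
    import pathlib
    import re

    import pandas as pd
    import yaml

    root = pathlib.Path(datadir)
    if not (root / "config.yaml").exists():
        raise InvalidConfigError(f"no config.yaml found in {root}")
    cfg = ProtocolConfig.from_dict(yaml.safe_load((root / "config.yaml").read_text()))
    truth_raw = json.loads((root / "truth.json").read_text())
    truth = GroundTruth(
        contractions=pd.DataFrame(truth_raw["contractions"]),
        tests=pd.DataFrame(truth_raw["tests"]),
        vo2=pd.DataFrame(truth_raw["vo2"]),
        lactate=pd.DataFrame(truth_raw["lactate"]),
    )
    contractions = []
    sig_root = root / "signals"
    if not sig_root.exists():
        raise InvalidConfigError(f"no signals/ directory in {root}")
    pat = re.compile(r"^(\d+)_(\d+)\.csv$")
    for subj_dir in sorted(sig_root.iterdir()):
        subj = int(subj_dir.name)
        for f in sorted(subj_dir.glob("*_*.csv")):
            m = pat.match(f.name)
            if not m:
                continue
            s, r = int(m.group(1)), int(m.group(2))
            df = pd.read_csv(f)
            emg_df = pd.read_csv(subj_dir / f"{s:02d}_{r}_emg.csv")
            contractions.append(ContractionRecord(
                subject=subj, set=s, rep=r,
                torque=SampledTrace(df["torque_Nm"].to_numpy(), cfg.torque_rate,
                                    float(df["t_s"].iloc[0]), unit="N·m"),
                velocity=SampledTrace(df["velocity_dps"].to_numpy(), cfg.torque_rate,
                                      float(df["t_s"].iloc[0]), unit="°/s"),
                emg=SampledTrace(emg_df["emg_mV"].to_numpy(), cfg.emg_rate,
                                 float(emg_df["t_s"].iloc[0]), unit="mV"),
                onset=0.5))
    tests = []
    for subj_dir in sorted((root / "tests").iterdir()):
        subj = int(subj_dir.name)
        for phase in ("pre", "post"):
            d = subj_dir / phase
            meta = json.loads((d / "meta.json").read_text())

            def read(name, col, n=3):
                out = []
                for i in range(1, n + 1):
                    df = pd.read_csv(d / f"{name}_{i}.csv")
                    rate = cfg.emg_rate if col == "emg_mV" else cfg.torque_rate
                    out.append(SampledTrace(df[col].to_numpy(), rate,
                                            float(df["t_s"].iloc[0])))
                return out

            tests.append(NeuromuscularTestRecording(
                subject=subj, phase=phase,
                imvc_traces=read("imvc", "torque_Nm"),
                stim_time=meta["stim_time"],
                doublet100=read("doublet100", "torque_Nm"),
                doublet10=read("doublet10", "torque_Nm"),
                twitches=read("twitch", "torque_Nm"),
                mwaves=read("mwave", "emg_mV")))
    vo2 = {}
    for f in sorted((root / "vo2").glob("*.csv")):
        df = pd.read_csv(f)
        vo2[int(f.stem)] = (df["t_s"].to_numpy(), df["vo2_mlminkg"].to_numpy())
    lac_df = pd.read_csv(root / "lactate.csv")
    lactate = {int(row.subject): (float(row.pre), float(row.post))
               for row in lac_df.itertuples()}
    return Experiment(cfg, contractions, tests, vo2, lactate, truth)
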