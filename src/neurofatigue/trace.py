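"""Uniformly sampled physical signals.

:class:`SampledTrace` is the carrier for every signal in the pipeline:
torque and angular velocity at 100 Hz, raw EMG at 2048 Hz, evoked
responses, RMS envelopes.  Times are seconds with ``t0`` the time of the
first sample; all analysis intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled signal with a sampling rate and start time.

    Parameters
    ----------
    values : ndarray
        Sample values in the trace's physical unit (N·m, °/s, mV, ...).
    rate : float
        Sampling rate in Hz; must be positive.
    t0 : float, default 0.0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    unit: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.rate}")
        if values.ndim != 1 or values.size < 2:
            raise InvalidConfigError("trace needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise InvalidConfigError("trace values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def t_end(self) -> float:
        """Time just past the last sample (half-open end of the trace)."""
        return self.t0 + self.values.size / self.rate

    def index_at(self, t: float) -> int:
        """Index of the first sample at time >= ``t`` (clipped to the trace)."""
        i = int(np.ceil((t - self.t0) * self.rate - 1e-9))
        return min(max(i, 0), self.values.size)

    def window(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples and their times on the half-open interval ``[start, end)``."""
        i0, i1 = self.index_at(start), self.index_at(end)
        t = self.t0 + np.arange(i0, i1) / self.rate
        return t, self.values[i0:i1]

    def with_values(self, values: np.ndarray) -> "SampledTrace":
        return SampledTrace(values, self.rate, self.t0, self.unit)
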