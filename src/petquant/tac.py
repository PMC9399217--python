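"""Time-activity curves: the shared sampled-curve container.

A :class:`TimeActivityCurve` holds activity concentration (Bq/mL), SUV, or
%IA samples against time post-injection in minutes.  It is the common
currency between the simulator, the kinetic model, the SUV extractor and
the dosimetry fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import C11_LAMBDA_PER_MIN
from .errors import InvalidInputError


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity (or %IA / SUV) versus time post-injection.

    Parameters
    ----------
    times
        Sample mid-times in minutes, strictly increasing, non-negative.
    values
        Sample values (Bq/mL, SUV g/mL, or %IA depending on context).
    frame_durations_s
        Optional per-sample frame durations in seconds (used for
        duration-weighted fitting and noise models).
    decay_corrected
        True if physical radioactive decay has been removed from the
        samples (the usual scanner convention).
    """

    times: np.ndarray
    values: np.ndarray
    frame_durations_s: np.ndarray | None = None
    decay_corrected: bool = True

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        values = _as_float_array(self.values, "values")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.size == 0:
            raise InvalidInputError("times must be non-empty")
        if times.size != values.size:
            raise InvalidInputError("times and values must have equal length")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(times < 0):
            raise InvalidInputError("times must be non-negative")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must be finite")
        if self.frame_durations_s is not None:
            dur = _as_float_array(self.frame_durations_s, "frame_durations_s")
            if dur.size != times.size:
                raise InvalidInputError("frame_durations_s length mismatch")
            if np.any(dur <= 0):
                raise InvalidInputError("frame durations must be positive")
            object.__setattr__(self, "frame_durations_s", dur)

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t: Sequence[float]) -> np.ndarray:
        """Piecewise-linear interpolation; zero before the first sample,
        last value held after the last sample."""
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.values,
                         left=0.0, right=float(self.values[-1]))

    def with_decay_reapplied(self, lam: float = C11_LAMBDA_PER_MIN) -> "TimeActivityCurve":
        """Return the physically decaying curve (undo decay correction)."""
        if not self.decay_corrected:
            return self
        return replace(self, values=self.values * np.exp(-lam * self.times),
                       decay_corrected=False)

    def with_decay_corrected(self, lam: float = C11_LAMBDA_PER_MIN) -> "TimeActivityCurve":
        """Return the decay-corrected curve (remove physical decay)."""
        if self.decay_corrected:
            return self
        return replace(self, values=self.values * np.exp(lam * self.times),
                       decay_corrected=True)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times, "value": self.values})
        if self.frame_durations_s is not None:
            df["frame_duration_s"] = self.frame_durations_s
        df["decay_corrected"] = int(self.decay_corrected)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        if "time_min" not in df or "value" not in df:
            raise InvalidInputError(f"{path}: expected columns time_min,value")
        dur = df["frame_duration_s"].to_numpy() if "frame_duration_s" in df else None
        corrected = True
        if "decay_corrected" in df:
            corrected = bool(int(df["decay_corrected"].iloc[0]))
        return cls(times=df["time_min"].to_numpy(),
                   values=df["value"].to_numpy(),
                   frame_durations_s=dur,
                   decay_corrected=corrected)
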