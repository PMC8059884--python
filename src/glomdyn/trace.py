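"""Core containers: uniformly sampled traces, inhalation events, stimulus protocols.

Time convention: seconds, t = 0 at recording start; stimulus times share the
same clock; intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Trace",
    "InhalationEvents",
    "OdorEvent",
    "StimulusProtocol",
    "GlomdynError",
    "InvalidSpecError",
    "DegenerateBaselineError",
    "InsufficientDataError",
    "as_events",
]


class GlomdynError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidSpecError(GlomdynError):
    """A simulation or analysis specification violates its invariants."""


class DegenerateBaselineError(GlomdynError):
    """A baseline window has non-positive mean or zero variance."""


class InsufficientDataError(GlomdynError):
    """Not enough samples or events to compute the requested quantity."""


VALID_UNITS = ("raw_F", "dFF", "zscore", "flow")


@dataclass
class Trace:
    """A uniformly sampled fluorescence (or airflow) time series.

    Parameters
    ----------
    values : ndarray
        One sample per time point; finite.
    rate_hz : float
        Sampling rate in Hz, strictly positive.
    t0_s : float
        Time of the first sample in seconds.
    units : str
        One of ``raw_F``, ``dFF``, ``zscore``, ``flow``.  The tag prevents
        double normalization (ΔF/F is never applied to a ΔF/F trace).
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = "raw_F"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise InvalidSpecError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.values.ndim != 1:
            raise InvalidSpecError("Trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("Trace values must be finite")
        if self.units not in VALID_UNITS:
            raise InvalidSpecError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.values.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def index_at(self, t_s: float) -> int:
        """Nearest-sample index for an absolute time, clipped to valid range."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.values.size - 1)

    def slice_s(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open interval [start_s, end_s)."""
        i0 = int(np.ceil((start_s - self.t0_s) * self.rate_hz - 1e-9))
        i1 = int(np.ceil((end_s - self.t0_s) * self.rate_hz - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        return self.values[i0:i1]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)


@dataclass
class InhalationEvents:
    """Inhalation timing derived from a respiration trace.

    ``peak_s`` is the trough of the flow signal (inhalation is a negative
    deflection); ``onset_s`` is the time of maximal (most negative) slope in
    the exhalation-to-inhalation transition preceding each trough.
    """

    onset_s: np.ndarray
    peak_s: np.ndarray
    source: str = "flow"  # flow | thermistor | artificial

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.peak_s = np.asarray(self.peak_s, dtype=float)
        if self.onset_s.shape != self.peak_s.shape:
            raise InvalidSpecError("onset_s and peak_s must have equal length")
        if self.onset_s.size:
            if np.any(np.diff(self.peak_s) <= 0) or np.any(np.diff(self.onset_s) <= 0):
                raise InvalidSpecError("event times must be strictly increasing")
            if np.any(self.onset_s > self.peak_s + 1e-12):
                raise InvalidSpecError("each onset must precede its trough")

    def __len__(self) -> int:
        return self.onset_s.size

    def times(self, reference: str) -> np.ndarray:
        if reference == "onset":
            return self.onset_s
        if reference == "peak":
            return self.peak_s
        raise InvalidSpecError(f"reference must be 'onset' or 'peak', got {reference!r}")

    def during(self, start_s: float, end_s: float, reference: str = "onset") -> "InhalationEvents":
        """Events whose reference time falls in [start_s, end_s)."""
        t = self.times(reference)
        keep = (t >= start_s) & (t < end_s)
        return InhalationEvents(self.onset_s[keep], self.peak_s[keep], self.source)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"onset_s": self.onset_s, "peak_s": self.peak_s}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "flow") -> "InhalationEvents":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["onset_s"].to_numpy(), df["peak_s"].to_numpy(), source)


@dataclass(frozen=True)
class OdorEvent:
    """One odorant presentation."""

    odor: str
    onset_s: float
    offset_s: float
    concentration_rel: float = 1.0

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class StimulusProtocol:
    """Sequence of odorant presentations for one recording."""

    events: list[OdorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.offset_s <= ev.onset_s:
                raise InvalidSpecError(f"odor event {ev.odor!r} has non-positive duration")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def for_odor(self, odor: str) -> OdorEvent:
        for ev in self.events:
            if ev.odor == odor:
                return ev
        raise KeyError(f"no event for odor {odor!r}")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"odor": ev.odor, "onset_s": ev.onset_s, "offset_s": ev.offset_s,
             "concentration_rel": ev.concentration_rel}
            for ev in self.events
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        payload = json.loads(Path(path).read_text())
        return cls([OdorEvent(**item) for item in payload])


def as_events(times_s: Sequence[float], source: str = "artificial") -> InhalationEvents:
    """Build events where onset and trough coincide (e.g., idealized pulses)."""
    t = np.asarray(times_s, dtype=float)
    return InhalationEvents(t, t, source)
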