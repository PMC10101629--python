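"""Shared survival-data containers.

Time is measured in months throughout the statistical layer; conversion to
model cycles happens only in :mod:`hccea.cohort`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PseudoIPD", "DigitizedCurve", "RiskTable", "KMCurve"]


@dataclass
class PseudoIPD:
    """Individual-patient survival records: one (time, event) pair per subject.

    ``event`` is 1 for an observed event and 0 for right censoring.
    ``approximate`` marks data reconstructed without a numbers-at-risk table.
    """

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""
    approximate: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("pseudo-IPD needs at least one record")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have the same length")
        if np.any(self.times <= 0):
            raise ValueError("all survival times must be strictly positive")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm_label: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), arm_label=arm_label)


@dataclass
class DigitizedCurve:
    """Digitized Kaplan-Meier coordinates: (time, survival) pairs read off a
    published figure (or emulated by :func:`hccea.synthetic.digitize`)."""

    times: np.ndarray
    survival: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("digitized curve needs at least one coordinate")
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("digitized curve increases somewhere; survival must be nonincreasing")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm_label: str = "") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(), arm_label=arm_label)


@dataclass
class RiskTable:
    """Numbers at risk at the start of reporting intervals, as printed under a
    published KM figure."""

    starts: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.starts.ndim != 1 or self.starts.size == 0:
            raise ValueError("risk table needs at least one interval")
        if self.starts.shape != self.n_risk.shape:
            raise ValueError("starts and n_risk must have the same length")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("interval starts must be strictly increasing")
        if np.any(self.n_risk < 0):
            raise ValueError("numbers at risk must be nonnegative")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("numbers at risk must be nonincreasing")

    @property
    def n_intervals(self) -> int:
        return int(self.starts.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"interval_start": self.starts, "n_risk": self.n_risk})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, total_events: int | None = None) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["interval_start"].to_numpy(), df["n_risk"].to_numpy(),
                   total_events=total_events)


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function.

    ``times``/``survival`` hold the step grid (including t=0, S=1);
    ``obs_times`` keeps the underlying observation times so numbers at risk
    can be queried at arbitrary interval starts.
    """

    times: np.ndarray
    survival: np.ndarray
    obs_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    arm_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("KM curve must start at (t=0, S=1)")
        if np.any(np.diff(self.times) < 0) or np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM curve must be a nonincreasing step function")
        if self.obs_times is not None:
            self.obs_times = np.sort(np.asarray(self.obs_times, dtype=float))

    @property
    def max_time(self) -> float:
        if self.obs_times is not None and self.obs_times.size:
            return float(self.obs_times[-1])
        return float(self.times[-1])

    def evaluate(self, t):
        """S(t) with right-continuous step convention; constant after the
        last observed time."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("evaluation times must be nonnegative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = self.survival[np.clip(idx, 0, self.survival.size - 1)]
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def n_at_risk(self, starts):
        """Number of subjects still under observation at each start time
        (subjects with observation time >= start)."""
        if self.obs_times is None:
            raise ValueError("KM curve carries no observation times")
        starts = np.atleast_1d(np.asarray(starts, dtype=float))
        return (self.obs_times.size
                - np.searchsorted(self.obs_times, starts, side="left")).astype(int)

    def risk_table(self, starts) -> RiskTable:
        starts = np.atleast_1d(np.asarray(starts, dtype=float))
        return RiskTable(starts, self.n_at_risk(starts))
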