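"""Three-state partitioned-survival cohort engine.

State occupancies are read directly off the PFS and OS curves
(PFS occupancy = S_pfs, PD = S_os - S_pfs clamped at 0, Death = 1 - S_os),
which is the curve-difference construction the model is built on; a
per-cycle transition-matrix exporter is provided for inspection but the
trace is authoritative.

Cycle time stamps are cycle starts, t_k = k * cycle_days; state membership
and discounting are evaluated at cycle start and cycle 0 is undiscounted.
Half-cycle correction (off by default) halves the first and last cycle's
contributions in any accumulation that uses :func:`cycle_weights`.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import survival_at

log = logging.getLogger(__name__)

__all__ = ["ModelSettings", "CohortTrace", "n_cycles", "build_trace",
           "discount_factor", "cycle_weights", "transition_matrices"]

DAYS_PER_MONTH_FACTOR = 12.0  # months = days / (days_per_year / 12)


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings (defaults: 21-day cycles, 10-year horizon, 5%
    annual discounting, WTP $37,654.50/QALY)."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.05
    days_per_year: float = 365.25
    half_cycle_correction: bool = False
    wtp: float = 37654.50

    def __post_init__(self):
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be > 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ValueError("discount rate must be in [0, 1)")

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / self.days_per_year

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / (self.days_per_year / DAYS_PER_MONTH_FACTOR)


def n_cycles(settings: ModelSettings) -> int:
    """ceil(horizon / cycle length); 174 at the default settings.

    A 1e-3 cycle tolerance absorbs rounded horizon inputs (e.g. a horizon
    printed as 0.0575 years is one 21-day cycle, not two).
    """
    x = settings.horizon_years * settings.days_per_year / settings.cycle_days
    return int(math.ceil(x - 1e-3))


@dataclass
class CohortTrace:
    """Per-cycle occupancy of the PFS / PD / Death states.

    Arrays are indexed by cycle (cycle starts); ``clamped_mass`` is the total
    PD occupancy clamped to zero where noise made S_os < S_pfs.
    """

    t_months: np.ndarray
    occ_pfs: np.ndarray
    occ_pd: np.ndarray
    occ_dead: np.ndarray
    strategy: str = ""
    clamped_mass: float = 0.0

    def __post_init__(self):
        sums = self.occ_pfs + self.occ_pd + self.occ_dead
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("trace rows must sum to 1")
        if abs(self.occ_pfs[0] - 1.0) > 1e-9:
            raise ValueError("trace must start with the whole cohort in PFS")

    @property
    def n_rows(self) -> int:
        return int(self.t_months.size)

    def to_frame(self, settings: ModelSettings | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "cycle": np.arange(self.n_rows),
            "t_months": self.t_months,
            "pfs": self.occ_pfs,
            "pd": self.occ_pd,
            "dead": self.occ_dead,
        })
        if settings is not None:
            df["discount_factor"] = discount_factor(df["cycle"].to_numpy(),
                                                    settings)
        return df


def build_trace(s_pfs, s_os, settings: ModelSettings,
                strategy: str = "") -> CohortTrace:
    """Partitioned-survival trace over the model horizon.

    ``s_pfs`` / ``s_os`` are survival curves (fit objects or callables) in
    months.  PD occupancy is clamped at 0 where S_os < S_pfs; the clamped
    mass is logged and recorded.
    """
    nc = n_cycles(settings)
    k = np.arange(nc)
    t_months = k * settings.cycle_months
    spfs = np.asarray(survival_at(s_pfs, t_months), dtype=float)
    sos = np.asarray(survival_at(s_os, t_months), dtype=float)
    if abs(spfs[0] - 1.0) > 1e-9 or abs(sos[0] - 1.0) > 1e-9:
        raise ValueError("survival curves must start at S(0) = 1")
    raw_pd = sos - spfs
    clamped = float(np.sum(np.clip(-raw_pd, 0.0, None)))
    occ_pd = np.clip(raw_pd, 0.0, None)
    occ_dead = 1.0 - np.maximum(sos, spfs)
    occ_pfs = 1.0 - occ_pd - occ_dead
    if clamped > 0:
        log.warning("PD occupancy clamped at 0 in trace for %r "
                    "(total clamped mass %.3g)", strategy, clamped)
    return CohortTrace(t_months=t_months, occ_pfs=occ_pfs, occ_pd=occ_pd,
                       occ_dead=occ_dead, strategy=strategy,
                       clamped_mass=clamped)


def discount_factor(cycle_index, settings: ModelSettings):
    """(1 + r)^(-t_years) with t_years = cycle * cycle_days / days_per_year."""
    k = np.asarray(cycle_index, dtype=float)
    t_years = k * settings.cycle_days / settings.days_per_year
    out = (1.0 + settings.discount_rate_annual) ** (-t_years)
    return float(out) if out.ndim == 0 else out


def cycle_weights(settings: ModelSettings, n_rows: int) -> np.ndarray:
    """Accumulation weights per cycle: all ones, or first/last halved under
    half-cycle correction."""
    w = np.ones(n_rows)
    if settings.half_cycle_correction and n_rows > 1:
        w[0] = 0.5
        w[-1] = 0.5
    return w


def transition_matrices(trace: CohortTrace) -> pd.DataFrame:
    """Per-cycle transition probabilities implied by the trace (inspection
    only; the occupancy trace is authoritative).

    The PFS->PD / PFS->Death split is not identified by the two curves alone;
    deaths are attributed proportionally to current PFS and PD occupancy.
    """
    rows = []
    for k in range(trace.n_rows - 1):
        pfs0, pd0 = trace.occ_pfs[k], trace.occ_pd[k]
        dead_new = trace.occ_dead[k + 1] - trace.occ_dead[k]
        alive0 = pfs0 + pd0
        p_die = dead_new / alive0 if alive0 > 0 else 0.0
        p_pfs_stay = trace.occ_pfs[k + 1] / pfs0 if pfs0 > 0 else 0.0
        p_pfs_die = min(p_die, 1.0 - p_pfs_stay)
        p_pfs_pd = max(1.0 - p_pfs_stay - p_pfs_die, 0.0)
        rows.append({"cycle": k, "pfs_to_pfs": p_pfs_stay,
                     "pfs_to_pd": p_pfs_pd, "pfs_to_dead": p_pfs_die,
                     "pd_to_dead": min(p_die, 1.0)})
    return pd.DataFrame(rows)
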