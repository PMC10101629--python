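"""Costs, QALYs, incremental cost-effectiveness, dominance and the frontier.

Costing conventions:

* a cycle is 21 days by default; daily dosing is costed as dose x 21,
  every-3-weeks administrations as 1 per cycle, every-2-weeks as 1.5 per
  cycle (continuous-rate approximation rather than calendar simulation);
* baseline body weight 60 kg for per-kg dosing;
* grade >=3 adverse-event costs and utility decrements are applied once at
  model entry, expectation-weighted by incidence;
* second-line therapy (camrelizumab + apatinib by default) accrues for PD
  occupancy, optionally scaled by a treated fraction or cut off after a
  configurable number of model cycles;
* per-mg linear pricing (no vial wastage).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelSettings, cycle_weights, discount_factor

log = logging.getLogger(__name__)

__all__ = ["DoseRule", "Schedule", "DrugComponent", "AdverseEvent",
           "StrategySpec", "UtilitySet", "SecondLineSpec", "CEResult",
           "cycle_drug_cost", "accumulate", "incremental_vs_reference",
           "frontier", "net_monetary_benefit"]


@dataclass(frozen=True)
class DoseRule:
    """Dose per administration: fixed mg, mg per kg, or a body-weight
    threshold rule (mg_below under the threshold, mg_at_or_above otherwise)."""

    kind: str  # fixed | per_kg | weight_threshold
    mg: float = 0.0
    mg_per_kg: float = 0.0
    threshold_kg: float = 60.0
    mg_below: float = 0.0
    mg_at_or_above: float = 0.0

    def dose_mg(self, body_weight_kg: float) -> float:
        if self.kind == "fixed":
            return self.mg
        if self.kind == "per_kg":
            return self.mg_per_kg * body_weight_kg
        if self.kind == "weight_threshold":
            return (self.mg_at_or_above if body_weight_kg >= self.threshold_kg
                    else self.mg_below)
        raise ValueError(f"unknown dose rule {self.kind!r}")


@dataclass(frozen=True)
class Schedule:
    """Administration schedule: per-day (times_per_day), per-cycle, or
    every-k-weeks."""

    kind: str  # per_day | per_cycle | every_k_weeks
    times_per_day: int = 1
    weeks: float = 3.0

    def administrations_per_cycle(self, cycle_days: float) -> float:
        if self.kind == "per_day":
            return self.times_per_day * cycle_days
        if self.kind == "per_cycle":
            return 1.0
        if self.kind == "every_k_weeks":
            return cycle_days / (7.0 * self.weeks)
        raise ValueError(f"unknown schedule {self.kind!r}")


@dataclass(frozen=True)
class DrugComponent:
    drug: str
    dose: DoseRule
    schedule: Schedule
    unit_price: float  # USD per mg or per administration
    price_basis: str = "per_mg"  # per_mg | per_admin

    def cycle_cost(self, cycle_days: float, body_weight_kg: float) -> float:
        if self.unit_price < 0:
            raise ValueError("unit price must be >= 0")
        admins = self.schedule.administrations_per_cycle(cycle_days)
        if self.price_basis == "per_admin":
            return self.unit_price * admins
        if self.price_basis == "per_mg":
            return self.unit_price * self.dose.dose_mg(body_weight_kg) * admins
        raise ValueError(f"unknown price basis {self.price_basis!r}")


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self):
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("AE incidence must be in [0, 1]")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError("AE cost and disutility must be >= 0")


@dataclass(frozen=True)
class StrategySpec:
    """One first-line treatment arm: regimen, effect sizes vs the reference,
    adverse-event profile and per-cycle testing cost."""

    name: str
    regimen: tuple
    hr_pfs: float = 1.0
    hr_os: float = 1.0
    ae_events: tuple = ()
    testing_cost_per_cycle: float = 0.0
    group: str = ""

    def __post_init__(self):
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("hazard ratios must be > 0")
        if self.testing_cost_per_cycle < 0:
            raise ValueError("testing cost must be >= 0")

    @property
    def ae_cost(self) -> float:
        return sum(a.incidence * a.cost for a in self.ae_events)

    @property
    def ae_disutility(self) -> float:
        return sum(a.incidence * a.disutility for a in self.ae_events)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (defaults: PFS 0.760, PD 0.680)."""

    u_pfs: float = 0.760
    u_pd: float = 0.680

    def __post_init__(self):
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError("utilities must be in [0, 1]")
        if self.u_pfs < self.u_pd:
            log.warning("u_pfs (%.3f) < u_pd (%.3f): progression would "
                        "improve quality of life", self.u_pfs, self.u_pd)


@dataclass(frozen=True)
class SecondLineSpec:
    """Second-line regimen applied during PD occupancy (default
    camrelizumab 200 mg q2w + apatinib 250 mg daily)."""

    components: tuple
    treated_fraction: float = 1.0
    max_cycles: int | None = None  # cut second-line cost after this model cycle

    def __post_init__(self):
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise ValueError("treated_fraction must be in [0, 1]")

    def cycle_cost(self, cycle_days: float, body_weight_kg: float) -> float:
        return self.treated_fraction * sum(
            c.cycle_cost(cycle_days, body_weight_kg) for c in self.components)


@dataclass
class CEResult:
    """Discounted totals for one strategy, plus incremental quantities once
    a comparison has been made."""

    strategy: str
    total_cost: float
    ly: float
    qaly: float
    incr_cost: float | None = None
    incr_qaly: float | None = None
    icer: float | None = None
    dominance: str = "none"

    def __post_init__(self):
        if self.total_cost < 0:
            raise ValueError("total cost must be >= 0")


def cycle_drug_cost(strategy: StrategySpec, settings: ModelSettings,
                    body_weight_kg: float = 60.0) -> float:
    """First-line drug cost per cycle per person in PFS (USD)."""
    return sum(c.cycle_cost(settings.cycle_days, body_weight_kg)
               for c in strategy.regimen)


def accumulate(trace: CohortTrace, strategy: StrategySpec,
               second_line: SecondLineSpec, utilities: UtilitySet,
               settings: ModelSettings, body_weight_kg: float = 60.0,
               testing_in_pd: bool = True) -> CEResult:
    """Discounted total cost, life-years and QALYs for one strategy.

    Per cycle: PFS occupancy accrues first-line drug + testing cost and
    u_pfs; PD occupancy accrues second-line drug (+ testing when enabled)
    and u_pd.  AE cost and disutility are one-off at cycle 0.
    """
    n = trace.n_rows
    k = np.arange(n)
    disc = discount_factor(k, settings)
    w = cycle_weights(settings, n)
    cyc_years = settings.cycle_years

    c_first = cycle_drug_cost(strategy, settings, body_weight_kg)
    c_second = second_line.cycle_cost(settings.cycle_days, body_weight_kg)
    c_test = strategy.testing_cost_per_cycle
    second_active = np.ones(n)
    if second_line.max_cycles is not None:
        second_active[k >= second_line.max_cycles] = 0.0

    cost_k = (trace.occ_pfs * (c_first + c_test)
              + trace.occ_pd * (c_second * second_active
                                + (c_test if testing_in_pd else 0.0)))
    total_cost = float(np.sum(w * disc * cost_k)) + strategy.ae_cost

    alive = trace.occ_pfs + trace.occ_pd
    ly = float(np.sum(w * disc * alive) * cyc_years)
    qaly = float(np.sum(w * disc * (trace.occ_pfs * utilities.u_pfs
                                    + trace.occ_pd * utilities.u_pd))
                 * cyc_years) - strategy.ae_disutility
    return CEResult(strategy=strategy.name, total_cost=total_cost,
                    ly=ly, qaly=qaly)


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """NMB = WTP x QALY - cost."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * result.qaly - result.total_cost


def incremental_vs_reference(results: list[CEResult],
                             reference: str) -> pd.DataFrame:
    """Incremental cost, incremental QALYs and ICER of every strategy
    against a common reference.

    Columns mirror the standard base-case table: strategy, cost, incrC,
    QALY, incrE, comparator, ICER, note (costs and ICERs rounded to whole
    dollars, QALYs to 2 decimals).  Negative incremental QALYs with positive
    incremental cost are flagged "dominated by reference" instead of a bare
    negative ICER; cheaper-and-better strategies are flagged "dominant".
    """
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    by_name = {r.strategy: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not in results")
    ref = by_name[reference]

    rows = []
    for r in results:
        if r.strategy == reference:
            rows.append({"strategy": r.strategy,
                         "cost": round(r.total_cost),
                         "incrC": np.nan, "QALY": round(r.qaly, 2),
                         "incrE": np.nan, "comparator": "", "ICER": np.nan,
                         "note": "reference"})
            continue
        dc = r.total_cost - ref.total_cost
        de = r.qaly - ref.qaly
        icer = None
        note = ""
        if de > 0 and dc <= 0:
            note = "dominant"
        elif de <= 0 and dc >= 0:
            note = "dominated by reference"
        elif de == 0:
            note = "equal effectiveness"
        else:
            icer = dc / de
        r.incr_cost, r.incr_qaly, r.icer = dc, de, icer
        rows.append({"strategy": r.strategy, "cost": round(r.total_cost),
                     "incrC": round(dc), "QALY": round(r.qaly, 2),
                     "incrE": round(de, 2), "comparator": reference,
                     "ICER": np.nan if icer is None else round(icer),
                     "note": note})
    return pd.DataFrame(rows)


def frontier(results: list[CEResult]) -> pd.DataFrame:
    """Cost-effectiveness frontier with dominance labels.

    Strategies are ordered by cost; strictly dominated entries (another
    strategy costs no more and yields no fewer QALYs, one strictly) are
    removed first, then extended dominance is removed iteratively wherever
    sequential ICERs are strictly non-monotone.  Frontier members carry the
    pairwise ICER versus the next-cheaper frontier member.
    """
    if len(results) < 2:
        raise ValueError("frontier needs at least two strategies")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    order = sorted(results, key=lambda r: (r.total_cost, -r.qaly))
    labels = {r.strategy: "none" for r in results}

    # strict dominance
    for r in results:
        for other in results:
            if other is r:
                continue
            if (other.total_cost <= r.total_cost and other.qaly >= r.qaly
                    and (other.total_cost < r.total_cost
                         or other.qaly > r.qaly)):
                labels[r.strategy] = "dominated"
                break

    # extended dominance: remove interior strategies whose sequential ICERs
    # are strictly decreasing at the next step
    active = [r for r in order if labels[r.strategy] == "none"]
    # exact cost+QALY duplicates: keep the first, drop the rest
    j = 0
    while j < len(active) - 1:
        if active[j + 1].qaly <= active[j].qaly:
            labels[active[j + 1].strategy] = "dominated"
            active.pop(j + 1)
        else:
            j += 1
    changed = True
    while changed and len(active) > 2:
        changed = False
        icers = [(active[j + 1].total_cost - active[j].total_cost)
                 / (active[j + 1].qaly - active[j].qaly)
                 for j in range(len(active) - 1)]
        for j in range(len(icers) - 1):
            if icers[j] > icers[j + 1] + 1e-12:
                labels[active[j + 1].strategy] = "extended-dominated"
                active.pop(j + 1)
                changed = True
                break

    rows = []
    prev = None
    for r in order:
        lab = labels[r.strategy]
        icer = None
        if lab == "none":
            if prev is not None:
                icer = ((r.total_cost - prev.total_cost)
                        / (r.qaly - prev.qaly))
            prev = r
        r.dominance = lab
        rows.append({"strategy": r.strategy, "cost": round(r.total_cost),
                     "QALY": round(r.qaly, 2),
                     "ICER": np.nan if icer is None else round(icer),
                     "dominance": lab})
    return pd.DataFrame(rows)
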