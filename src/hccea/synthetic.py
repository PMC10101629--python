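"""Synthetic study generator.

Emulates the inputs the analysis consumes: trial arms drawn from known
parametric survival (the reference arm mirrors a sorafenib pivotal-trial
population), Kaplan-Meier curves, figure digitization on a time grid with
optional probability-scale jitter, and the strategy/cost/utility/HR
configuration tables with +/-20% uncertainty ranges.

Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from . import survival as sv
from .data import DigitizedCurve, KMCurve, PseudoIPD

__all__ = ["TrialArmSpec", "GroundTruth", "simulate_arm", "km_curve",
           "digitize", "make_model_inputs"]


@dataclass(frozen=True)
class TrialArmSpec:
    """One simulated trial arm: a survival family with known parameters,
    a sample size, and an administrative follow-up cutoff (months)."""

    name: str
    dist_family: str
    dist_params: dict
    n_patients: int
    max_followup: float = math.inf
    seed: int = 0
    dropout_rate: float = 0.0  # optional uniform-dropout fraction, default off

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.max_followup > 0:
            raise ValueError("max_followup must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        # validates family name and parameter domain, raising a named message
        sv.log_sf(self.dist_family, self.dist_params, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """The generating truth carried alongside a simulated arm, for oracles."""

    arm_spec: TrialArmSpec
    true_median: float
    grid_times: np.ndarray
    grid_survival: np.ndarray


def ground_truth(spec: TrialArmSpec, grid=None) -> GroundTruth:
    if grid is None:
        grid = np.linspace(0.0, min(spec.max_followup, 60.0), 25)
    grid = np.asarray(grid, dtype=float)
    return GroundTruth(
        arm_spec=spec,
        true_median=sv.true_median(spec.dist_family, spec.dist_params),
        grid_times=grid,
        grid_survival=sv.sf(spec.dist_family, spec.dist_params, grid),
    )


def simulate_arm(spec: TrialArmSpec) -> PseudoIPD:
    """Draw one arm; event times beyond ``max_followup`` are administratively
    censored at the cutoff.  Optional uniform dropout censors a random
    fraction of subjects at a Uniform(0, max_followup) time."""
    rng = np.random.default_rng(spec.seed)
    t_event = sv.sample_times(spec.dist_family, spec.dist_params,
                              spec.n_patients, rng)
    t_cens = np.full(spec.n_patients, spec.max_followup)
    if spec.dropout_rate > 0.0:
        cutoff = spec.max_followup if math.isfinite(spec.max_followup) \
            else float(np.quantile(t_event, 0.99))
        drops = rng.uniform(size=spec.n_patients) < spec.dropout_rate
        t_drop = rng.uniform(0.0, cutoff, size=spec.n_patients)
        t_cens = np.where(drops, np.minimum(t_cens, t_drop), t_cens)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    # guard against zero times from dropout draws at exactly 0
    times = np.maximum(times, 1e-9)
    return PseudoIPD(times=times, events=events, arm_label=spec.name)


def km_curve(ipd: PseudoIPD) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate as a right-continuous step
    curve, with the observation times retained for risk-table queries."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    surv = kmf.survival_function_
    return KMCurve(times=surv.index.to_numpy(dtype=float),
                   survival=surv.iloc[:, 0].to_numpy(dtype=float),
                   obs_times=ipd.times,
                   arm_label=ipd.arm_label)


def digitize(curve: KMCurve, grid, jitter_sd: float = 0.0,
             seed: int | None = None) -> DigitizedCurve:
    """Read a step curve off at grid times, mimicking manual figure
    digitization: optional Gaussian probability-scale jitter, clipped to
    [0, 1] and forced nonincreasing by isotonic (running-minimum) clipping.

    ``jitter_sd = 0`` reproduces the curve exactly on the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be strictly increasing")
    if grid[0] < 0 or grid[-1] > curve.max_time + 1e-9:
        raise ValueError("grid must lie within the curve's observed support")
    vals = np.asarray(curve.evaluate(grid), dtype=float)
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, jitter_sd, size=vals.size)
    vals = np.clip(vals, 0.0, 1.0)
    vals = np.minimum.accumulate(vals)
    return DigitizedCurve(times=grid, survival=vals, arm_label=curve.arm_label)


# ---------------------------------------------------------------------------
# Model-input tables (strategies, prices, utilities, HRs)
# ---------------------------------------------------------------------------

def _rng20(base: float) -> dict:
    """base value with the +/-20% deterministic sensitivity range."""
    return {"base": base, "low": 0.8 * base, "high": 1.2 * base}


def _component(drug, dose, schedule, price, basis="per_mg"):
    return {"drug": drug, "dose": dose, "schedule": schedule,
            "unit_price": _rng20(price), "price_basis": basis}


_DAILY = lambda times=1: {"kind": "per_day", "times_per_day": times}
_Q3W = {"kind": "every_k_weeks", "weeks": 3}
_Q2W = {"kind": "every_k_weeks", "weeks": 2}
_FIXED = lambda mg: {"kind": "fixed", "mg": mg}
_PERKG = lambda mg: {"kind": "per_kg", "mg_per_kg": mg}


def make_model_inputs(seed: int = 0) -> dict:
    """Full analysis configuration as a JSON-able dict.

    Nine first-line strategies (reference: sorafenib) with dosing rules,
    synthetic 2022-USD unit prices, hazard ratios versus the reference for
    PFS and OS, grade>=3 adverse-event profiles, a camrelizumab+apatinib
    second line, utilities (PFS 0.760, PD 0.680), and synthetic reference
    trial arms (log-logistic PFS/OS with medians 5.5 and 10.7 months).
    Every uncertain parameter carries a +/-20% low/high range.
    """
    strategies = [
        {"name": "sorafenib", "group": "tki",
         "components": [_component("sorafenib", _FIXED(400), _DAILY(2), 0.05)],
         "hr_pfs": _rng20(1.0), "hr_os": _rng20(1.0),
         "ae": (0.45, 1800.0, 0.05)},
        {"name": "sunitinib", "group": "tki",
         "components": [_component("sunitinib", _FIXED(12.5), _DAILY(1), 0.9)],
         "hr_pfs": _rng20(0.58), "hr_os": _rng20(0.52),
         "ae": (0.50, 2200.0, 0.06)},
        {"name": "donafenib", "group": "tki",
         "components": [_component("donafenib", _FIXED(200), _DAILY(2), 0.30)],
         "hr_pfs": _rng20(0.80), "hr_os": _rng20(0.71),
         "ae": (0.38, 1500.0, 0.04)},
        {"name": "lenvatinib", "group": "tki",
         "components": [_component("lenvatinib", _FIXED(8), _DAILY(1), 1.2)],
         "hr_pfs": _rng20(0.52), "hr_os": _rng20(0.50),
         "ae": (0.57, 2400.0, 0.06)},
        {"name": "sorafenib_plus_erlotinib", "group": "tki",
         "components": [_component("sorafenib", _FIXED(400), _DAILY(2), 0.05),
                        _component("erlotinib", _FIXED(150), _DAILY(1), 0.35)],
         "hr_pfs": _rng20(0.55), "hr_os": _rng20(0.51),
         "ae": (0.55, 2100.0, 0.06)},
        {"name": "linifanib", "group": "tki",
         "components": [_component("linifanib", _FIXED(17.5), _DAILY(1), 3.0)],
         "hr_pfs": _rng20(0.54), "hr_os": _rng20(0.50),
         "ae": (0.60, 2600.0, 0.07)},
        {"name": "brivanib", "group": "tki",
         "components": [_component("brivanib", _FIXED(800), _DAILY(1), 0.12)],
         "hr_pfs": _rng20(0.56), "hr_os": _rng20(0.51),
         "ae": (0.52, 2000.0, 0.06)},
        {"name": "sintilimab_plus_ibi305", "group": "ici",
         "components": [_component("sintilimab", _FIXED(200), _Q3W, 0.86),
                        _component("bevacizumab_biosimilar", _PERKG(15), _Q3W, 0.23)],
         "hr_pfs": _rng20(0.46), "hr_os": _rng20(0.47),
         "ae": (0.34, 2800.0, 0.05)},
        {"name": "atezolizumab_plus_bevacizumab", "group": "ici",
         "components": [_component("atezolizumab", _FIXED(1200), _Q3W, 2.8),
                        _component("bevacizumab", _PERKG(15), _Q3W, 0.6)],
         "hr_pfs": _rng20(0.47), "hr_os": _rng20(0.48),
         "ae": (0.36, 3000.0, 0.05)},
    ]
    for s in strategies:
        inc, cost, disu = s.pop("ae")
        s["ae_events"] = [{
            "name": "grade3plus_pooled",
            "incidence": _rng20(inc),
            "cost": _rng20(cost),
            "disutility": _rng20(disu),
        }]
        s["testing_cost_per_cycle"] = _rng20(120.0)

    config = {
        "settings": {
            "cycle_days": 21.0,
            "horizon_years": 10.0,
            "discount_rate_annual": 0.05,
            "days_per_year": 365.25,
            "half_cycle_correction": False,
            "wtp": 37654.50,
        },
        "body_weight_kg": 60.0,
        "reference": "sorafenib",
        "utilities": {"u_pfs": _rng20(0.760), "u_pd": _rng20(0.680)},
        "second_line": {
            "components": [
                _component("camrelizumab", _FIXED(200), _Q2W, 1.45),
                _component("apatinib", _FIXED(250), _DAILY(1), 0.06),
            ],
            "treated_fraction": 1.0,
            "max_cycles": None,
        },
        "testing_in_pd": True,
        "strategies": strategies,
        "curve_sources": {
            "pfs": {"synthetic": {
                "name": "sorafenib_pfs", "dist_family": "loglogistic",
                "dist_params": {"scale": 5.5, "shape": 1.4},
                "n_patients": 299, "max_followup": 30.0}},
            "os": {"synthetic": {
                "name": "sorafenib_os", "dist_family": "loglogistic",
                "dist_params": {"scale": 10.7, "shape": 1.6},
                "n_patients": 299, "max_followup": 40.0}},
            "digitize": {"grid_step_months": 0.5, "jitter_sd": 0.005,
                         "risk_interval_months": 6.0},
        },
        "psa": {"n_iter": 10000},
        "wtp_grid": [float(w) for w in range(0, 80001, 5000)],
        "seed": int(seed),
    }
    return config
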