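"""Configuration, pipeline orchestration and report generation.

``run_base_case`` executes the full chain — simulate/load digitized curves,
reconstruct pseudo-IPD, fit the five parametric families per endpoint,
select by AIC, apply per-strategy hazard ratios, build cohort traces,
accumulate discounted costs/QALYs, and produce the incremental table and
the efficiency frontier.  ``run_uncertainty`` adds one-way (tornado) and
probabilistic sensitivity analyses with CEACs.

All randomness flows from a single root seed split per stage, so whole-
pipeline output is reproducible bit-for-bit.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reconstruct as rc
from . import synthetic as syn
from . import uncertainty as unc
from .cohort import ModelSettings, build_trace, n_cycles
from .data import DigitizedCurve, PseudoIPD, RiskTable
from .econ import (AdverseEvent, CEResult, DoseRule, DrugComponent, Schedule,
                   SecondLineSpec, StrategySpec, UtilitySet, accumulate,
                   frontier, incremental_vs_reference)
from .survival import apply_hr, fit_all, fits_to_frame, select_by_aic
from .uncertainty import ParamSpec

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_base_case", "run_uncertainty",
           "example_config", "evaluate_strategies"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _base(x):
    """Uncertain parameters are stored as {'base': b, 'low': l, 'high': h};
    plain numbers are accepted as degenerate."""
    return float(x["base"]) if isinstance(x, dict) else float(x)


def _component_from_dict(d: dict, price_override: float | None = None) -> DrugComponent:
    dose = DoseRule(**d["dose"])
    sched = Schedule(**d["schedule"])
    price = price_override if price_override is not None \
        else _base(d["unit_price"])
    return DrugComponent(drug=d["drug"], dose=dose, schedule=sched,
                         unit_price=price,
                         price_basis=d.get("price_basis", "per_mg"))


@dataclass
class AnalysisConfig:
    """Parsed analysis configuration plus the raw dict it came from."""

    settings: ModelSettings
    strategies: list[StrategySpec]
    reference: str
    second_line: SecondLineSpec
    utilities: UtilitySet
    body_weight_kg: float
    testing_in_pd: bool
    curve_sources: dict
    psa_params: list[ParamSpec]
    psa_n_iter: int
    wtp_grid: list[float]
    seed: int
    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        settings = ModelSettings(**d["settings"])
        strategies = [_strategy_from_dict(s) for s in d["strategies"]]
        names = [s.name for s in strategies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strategy names in config")
        reference = d["reference"]
        if reference not in names:
            raise ValueError(f"reference strategy {reference!r} not defined")
        second = SecondLineSpec(
            components=tuple(_component_from_dict(c)
                             for c in d["second_line"]["components"]),
            treated_fraction=d["second_line"].get("treated_fraction", 1.0),
            max_cycles=d["second_line"].get("max_cycles"))
        utilities = UtilitySet(u_pfs=_base(d["utilities"]["u_pfs"]),
                               u_pd=_base(d["utilities"]["u_pd"]))
        cs = d.get("curve_sources", {})
        for ep in ("pfs", "os"):
            if ep not in cs:
                raise ValueError(f"curve_sources must define endpoint {ep!r}")
        return cls(settings=settings, strategies=strategies,
                   reference=reference, second_line=second,
                   utilities=utilities,
                   body_weight_kg=float(d.get("body_weight_kg", 60.0)),
                   testing_in_pd=bool(d.get("testing_in_pd", True)),
                   curve_sources=cs,
                   psa_params=_param_specs_from_dict(d),
                   psa_n_iter=int(d.get("psa", {}).get("n_iter", 10000)),
                   wtp_grid=[float(w) for w in
                             d.get("wtp_grid", [settings.wtp])],
                   seed=int(d.get("seed", 0)),
                   raw=d)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.raw, fh, indent=2)


def _strategy_from_dict(s: dict, overrides: dict | None = None) -> StrategySpec:
    o = overrides or {}
    name = s["name"]
    comps = tuple(
        _component_from_dict(c, o.get(f"price.{name}.{c['drug']}"))
        for c in s["components"])
    aes = tuple(
        AdverseEvent(
            name=a["name"],
            incidence=o.get(f"ae_incidence.{name}.{a['name']}",
                            _base(a["incidence"])),
            cost=o.get(f"ae_cost.{name}.{a['name']}", _base(a["cost"])),
            disutility=o.get(f"ae_disutility.{name}.{a['name']}",
                             _base(a["disutility"])))
        for a in s.get("ae_events", ()))
    return StrategySpec(
        name=name, regimen=comps,
        hr_pfs=o.get(f"hr_pfs.{name}", _base(s.get("hr_pfs", 1.0))),
        hr_os=o.get(f"hr_os.{name}", _base(s.get("hr_os", 1.0))),
        ae_events=aes,
        testing_cost_per_cycle=o.get(f"testing_cost.{name}",
                                     _base(s.get("testing_cost_per_cycle", 0.0))),
        group=s.get("group", ""))


def _param_specs_from_dict(d: dict) -> list[ParamSpec]:
    """Every {base, low, high} entry in the config becomes a named ParamSpec
    with the PSA family implied by its role: beta for probabilities and
    utilities, gamma for costs, lognormal for hazard ratios."""
    specs: list[ParamSpec] = []

    def add(name, entry, family, role):
        if not isinstance(entry, dict):
            return
        specs.append(ParamSpec(name=name, base=float(entry["base"]),
                               low=float(entry["low"]),
                               high=float(entry["high"]),
                               psa_family=family, role=role))

    add("utility.pfs", d["utilities"]["u_pfs"], "beta", "probability/utility")
    add("utility.pd", d["utilities"]["u_pd"], "beta", "probability/utility")
    for s in d["strategies"]:
        name = s["name"]
        is_ref = name == d["reference"]
        for c in s["components"]:
            add(f"price.{name}.{c['drug']}", c["unit_price"], "gamma", "cost")
        if not is_ref:  # the reference defines the curves; HR vs itself is 1
            add(f"hr_pfs.{name}", s.get("hr_pfs"), "lognormal", "hazard-ratio")
            add(f"hr_os.{name}", s.get("hr_os"), "lognormal", "hazard-ratio")
        for a in s.get("ae_events", ()):
            add(f"ae_incidence.{name}.{a['name']}", a["incidence"], "beta",
                "probability/utility")
            add(f"ae_cost.{name}.{a['name']}", a["cost"], "gamma", "cost")
            add(f"ae_disutility.{name}.{a['name']}", a["disutility"], "beta",
                "probability/utility")
        add(f"testing_cost.{name}", s.get("testing_cost_per_cycle"),
            "gamma", "cost")
    for c in d["second_line"]["components"]:
        add(f"price.second_line.{c['drug']}", c["unit_price"], "gamma", "cost")
    return specs


def example_config(seed: int = 0) -> AnalysisConfig:
    """The shipped nine-strategy synthetic example."""
    return AnalysisConfig.from_dict(syn.make_model_inputs(seed))


# ---------------------------------------------------------------------------
# Reference-curve acquisition and fitting
# ---------------------------------------------------------------------------

def _stage_seeds(root_seed: int) -> dict:
    state = np.random.SeedSequence(root_seed).generate_state(6)
    names = ("sim_pfs", "sim_os", "dig_pfs", "dig_os", "psa", "spare")
    return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


def load_reference_ipd(config: AnalysisConfig) -> dict[str, PseudoIPD]:
    """Pseudo-IPD per endpoint, either reconstructed from digitized CSV
    inputs or generated through the full synthetic path (simulate -> KM ->
    digitize -> risk table -> reconstruct)."""
    seeds = _stage_seeds(config.seed)
    out: dict[str, PseudoIPD] = {}
    dig_cfg = config.curve_sources.get("digitize", {})
    for ep in ("pfs", "os"):
        src = config.curve_sources[ep]
        if "synthetic" in src:
            spec = syn.TrialArmSpec(seed=seeds[f"sim_{ep}"],
                                    **src["synthetic"])
            truth = syn.simulate_arm(spec)
            km = syn.km_curve(truth)
            step = float(dig_cfg.get("grid_step_months", 0.5))
            grid = np.arange(0.0, km.max_time + 1e-9, step)
            dig = syn.digitize(km, grid,
                               jitter_sd=float(dig_cfg.get("jitter_sd", 0.0)),
                               seed=seeds[f"dig_{ep}"])
            r_step = float(dig_cfg.get("risk_interval_months", 6.0))
            risk = km.risk_table(np.arange(0.0, km.max_time, r_step))
            out[ep] = rc.reconstruct_ipd(dig, risk, arm_label=f"reference_{ep}")
        elif "curve_csv" in src:
            dig = DigitizedCurve.from_csv(src["curve_csv"],
                                          arm_label=f"reference_{ep}")
            if "risk_csv" in src:
                risk = RiskTable.from_csv(src["risk_csv"],
                                          total_events=src.get("total_events"))
                out[ep] = rc.reconstruct_ipd(dig, risk)
            else:
                out[ep] = rc.reconstruct_without_risk_table(
                    dig, int(src["n_total"]))
        elif "ipd_csv" in src:
            out[ep] = PseudoIPD.from_csv(src["ipd_csv"],
                                         arm_label=f"reference_{ep}")
        else:
            raise ValueError(f"curve source for {ep!r} must provide "
                             "'synthetic', 'curve_csv' or 'ipd_csv'")
    return out


def fit_endpoint(ipd: PseudoIPD, endpoint: str = ""):
    """Fit all five families, select by AIC; warns when the winner is not
    log-logistic (the family the reference analysis selected)."""
    fits = fit_all(ipd)
    sel = select_by_aic(fits)
    if sel.family != "loglogistic":
        log.warning("AIC selected %s for endpoint %s (log-logistic was the "
                    "reference choice); re-check the fit table",
                    sel.family, endpoint)
    return fits, sel


# ---------------------------------------------------------------------------
# Model evaluation under parameter overrides
# ---------------------------------------------------------------------------

def evaluate_strategies(config: AnalysisConfig, fit_pfs, fit_os,
                        overrides: dict | None = None,
                        collect_traces: bool = False):
    """Evaluate every strategy: HR-adjusted curves -> trace -> discounted
    cost/LY/QALY.  ``overrides`` pins named parameters (see the param-spec
    naming in the config layer); everything else stays at base value.

    Returns a DataFrame (strategy, cost, ly, qaly), plus {strategy: trace}
    when ``collect_traces`` is set.
    """
    o = dict(overrides or {})
    unknown = [k for k in o if not _known_param(config, k)]
    if unknown:
        raise ValueError(f"unknown parameter name(s): {unknown}")
    settings = config.settings
    utilities = UtilitySet(
        u_pfs=o.get("utility.pfs", config.utilities.u_pfs),
        u_pd=o.get("utility.pd", config.utilities.u_pd))
    second = SecondLineSpec(
        components=tuple(
            _component_from_dict(c, o.get(f"price.second_line.{c['drug']}"))
            for c in config.raw["second_line"]["components"]),
        treated_fraction=config.second_line.treated_fraction,
        max_cycles=config.second_line.max_cycles)
    rows = []
    traces = {}
    for s_raw in config.raw["strategies"]:
        strat = _strategy_from_dict(s_raw, o)
        s_pfs = apply_hr(fit_pfs, strat.hr_pfs, "PFS", strat.name)
        s_os = apply_hr(fit_os, strat.hr_os, "OS", strat.name)
        trace = build_trace(s_pfs, s_os, settings, strategy=strat.name)
        res = accumulate(trace, strat, second, utilities, settings,
                         body_weight_kg=config.body_weight_kg,
                         testing_in_pd=config.testing_in_pd)
        rows.append({"strategy": strat.name, "cost": res.total_cost,
                     "ly": res.ly, "qaly": res.qaly})
        if collect_traces:
            traces[strat.name] = trace
    df = pd.DataFrame(rows)
    return (df, traces) if collect_traces else df


def _known_param(config: AnalysisConfig, name: str) -> bool:
    if name in ("utility.pfs", "utility.pd"):
        return True
    return name in {p.name for p in config.psa_params} \
        or any(name == f"hr_{ep}.{config.reference}" for ep in ("pfs", "os"))


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

@dataclass
class BaseCaseResult:
    config: AnalysisConfig
    ipd: dict
    fits: dict
    selected: dict
    ce_results: list[CEResult]
    base_table: pd.DataFrame
    frontier_all: pd.DataFrame
    frontiers_by_group: dict
    traces: dict


def run_base_case(config: AnalysisConfig, outdir=None) -> BaseCaseResult:
    """Execute reconstruct -> fit -> adjust -> trace -> accumulate ->
    incremental table + frontier; optionally write CSV reports and a run
    log to ``outdir``."""
    try:
        ipd = load_reference_ipd(config)
    except Exception as exc:
        raise RuntimeError(f"curve-acquisition stage failed: {exc}") from exc
    fits, selected = {}, {}
    for ep, data in ipd.items():
        try:
            fits[ep], selected[ep] = fit_endpoint(data, ep)
        except Exception as exc:
            raise RuntimeError(f"fitting stage ({ep}) failed: {exc}") from exc
    df, traces = evaluate_strategies(config, selected["pfs"], selected["os"],
                                     collect_traces=True)
    ce_results = [CEResult(strategy=r.strategy, total_cost=r.cost, ly=r.ly,
                           qaly=r.qaly)
                  for r in df.itertuples()]
    base_table = incremental_vs_reference(ce_results, config.reference)
    frontier_all = frontier(ce_results)
    groups = {s.name: s.group for s in config.strategies}
    frontiers_by_group = {}
    for g in sorted({v for v in groups.values() if v}):
        members = [r for r in ce_results if groups[r.strategy] == g]
        if len(members) >= 2:
            frontiers_by_group[g] = frontier(members)
    result = BaseCaseResult(config=config, ipd=ipd, fits=fits,
                            selected=selected, ce_results=ce_results,
                            base_table=base_table, frontier_all=frontier_all,
                            frontiers_by_group=frontiers_by_group,
                            traces=traces)
    if outdir is not None:
        _write_base_case(result, outdir)
    return result


@dataclass
class UncertaintyResult:
    tornado: pd.DataFrame
    psa: unc.PSARun
    ceac: unc.CEAC


def run_uncertainty(config: AnalysisConfig, base: BaseCaseResult | None = None,
                    outdir=None, n_iter: int | None = None,
                    tornado_comparisons: list[tuple[str, str]] | None = None
                    ) -> UncertaintyResult:
    """Tornado (every strategy vs the reference by default), PSA, CEAC."""
    if base is None:
        base = run_base_case(config)
    model = lambda ov: evaluate_strategies(  # noqa: E731
        config, base.selected["pfs"], base.selected["os"], ov)
    if tornado_comparisons is None:
        tornado_comparisons = [(s.name, config.reference)
                               for s in config.strategies
                               if s.name != config.reference]
    tornado_frames = []
    if config.psa_params:
        for pair in tornado_comparisons:
            tf = unc.tornado(config.psa_params, model, pair)
            tf.insert(0, "comparison", f"{pair[0]} vs {pair[1]}")
            tornado_frames.append(tf)
    tornado_df = pd.concat(tornado_frames, ignore_index=True) \
        if tornado_frames else pd.DataFrame()
    seeds = _stage_seeds(config.seed)
    run = unc.run_psa(model, config.psa_params,
                      n_iter if n_iter is not None else config.psa_n_iter,
                      seed=seeds["psa"])
    curves = unc.ceac(run, config.wtp_grid)
    result = UncertaintyResult(tornado=tornado_df, psa=run, ceac=curves)
    if outdir is not None:
        _write_uncertainty(result, outdir)
    return result


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _write_base_case(res: BaseCaseResult, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    res.base_table.to_csv(os.path.join(outdir, "base_case.csv"), index=False)
    fr = res.frontier_all.copy()
    fr.insert(0, "group", "all")
    parts = [fr]
    for g, f in res.frontiers_by_group.items():
        f = f.copy()
        f.insert(0, "group", g)
        parts.append(f)
    pd.concat(parts, ignore_index=True).to_csv(
        os.path.join(outdir, "frontier.csv"), index=False)
    for ep in res.fits:
        fits_to_frame(res.fits[ep], res.selected[ep]).to_csv(
            os.path.join(outdir, f"fits_{ep}.csv"), index=False)
    trace_frames = []
    for name, tr in res.traces.items():
        df = tr.to_frame(res.config.settings)
        df.insert(0, "strategy", name)
        trace_frames.append(df)
    pd.concat(trace_frames, ignore_index=True).to_csv(
        os.path.join(outdir, "traces.csv"), index=False)
    with open(os.path.join(outdir, "run_log.txt"), "w") as fh:
        fh.write(_run_log_text(res))


def _run_log_text(res: BaseCaseResult) -> str:
    lines = [f"root seed: {res.config.seed}",
             f"stage seeds: {_stage_seeds(res.config.seed)}",
             f"cycles: {n_cycles(res.config.settings)}"]
    for ep in res.fits:
        lines.append(f"[{ep}] selected family: {res.selected[ep].family} "
                     f"(AIC {res.selected[ep].aic:.2f})")
        for f in res.fits[ep]:
            lines.append(f"  {f.family}: loglik {f.loglik:.3f} "
                         f"AIC {f.aic:.2f} params {f.params}")
    for name, tr in res.traces.items():
        if tr.clamped_mass > 0:
            lines.append(f"clamped PD mass for {name}: {tr.clamped_mass:.4g}")
    lines.append("assumption-divergence notes: half-cycle correction "
                 f"{'on' if res.config.settings.half_cycle_correction else 'off'}; "
                 "lenvatinib costed per config dose rule; second-line cost "
                 f"cap: {res.config.second_line.max_cycles}; q2w dosing "
                 "costed as 1.5 administrations per 21-day cycle; testing "
                 f"costs in PD: {res.config.testing_in_pd}")
    return "\n".join(lines) + "\n"


def _write_uncertainty(res: UncertaintyResult, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    res.tornado.to_csv(os.path.join(outdir, "tornado.csv"), index=False)
    res.psa.to_frame().to_csv(os.path.join(outdir, "psa_scatter.csv"),
                              index=False)
    res.ceac.to_frame().to_csv(os.path.join(outdir, "ceac.csv"), index=False)
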