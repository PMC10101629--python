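"""One-way deterministic sensitivity analysis, probabilistic sensitivity
analysis, and cost-effectiveness acceptability curves.

Distribution assignment follows standard practice for health-economic PSA:
beta for probabilities/utilities, gamma for costs, lognormal for hazard
ratios.  An uncertainty interval (low, high) is converted to a standard
error via the normal approximation sd = (high - low) / (2 * 1.96), and
moments are matched; a lognormal HR uses log-mean ln(base) and log-sd
(ln high - ln low) / (2 * 1.96).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParamSpec", "PSARun", "CEAC", "one_way", "tornado",
           "draw_params", "run_psa", "ceac"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model parameter: base value, deterministic range, and
    the PSA distribution family implied by its role."""

    name: str
    base: float
    low: float
    high: float
    psa_family: str = "fixed"  # beta | gamma | lognormal | fixed
    role: str = "other"  # probability/utility | cost | hazard-ratio | other

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high "
                f"({self.low}, {self.base}, {self.high})")
        if self.psa_family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ValueError(f"{self.name}: unknown PSA family "
                             f"{self.psa_family!r}")
        if self.psa_family == "beta" and not (0.0 <= self.low
                                              and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta support requires the range "
                             "to lie in [0, 1]")
        if self.psa_family == "lognormal" and self.low <= 0:
            raise ValueError(f"{self.name}: lognormal requires low > 0")


def _draw_one(spec: ParamSpec, rng: np.random.Generator, size=None):
    sd = (spec.high - spec.low) / (2.0 * _Z95)
    if spec.psa_family == "fixed" or sd == 0.0:
        return spec.base if size is None else np.full(size, spec.base)
    if spec.psa_family == "beta":
        m, v = spec.base, sd * sd
        if m <= 0.0 or m >= 1.0 or m * (1.0 - m) <= v:
            raise ValueError(
                f"{spec.name}: beta moment matching infeasible "
                f"(mean {m}, variance {v})")
        nu = m * (1.0 - m) / v - 1.0
        return rng.beta(m * nu, (1.0 - m) * nu, size=size)
    if spec.psa_family == "gamma":
        m, v = spec.base, sd * sd
        if m <= 0:
            raise ValueError(f"{spec.name}: gamma needs a positive mean")
        return rng.gamma(m * m / v, v / m, size=size)
    # lognormal
    sdlog = (np.log(spec.high) - np.log(spec.low)) / (2.0 * _Z95)
    return rng.lognormal(np.log(spec.base), sdlog, size=size)


def draw_params(specs: list[ParamSpec], seed) -> dict:
    """One PSA parameter set, deterministic per seed.  ``seed`` may be an
    integer or a ``numpy.random.Generator``."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return {s.name: float(np.asarray(_draw_one(s, rng))) for s in specs}


def one_way(param: ParamSpec, model, pair: tuple[str, str]):
    """Deterministic one-way sweep of one parameter.

    ``model(overrides)`` must return a DataFrame with columns
    strategy/cost/qaly; ``pair`` is (comparator, reference).  Returns
    (icer_low, icer_high) for the pair with the parameter pinned at its low
    then high value, everything else at base.
    """
    out = []
    for value in (param.low, param.high):
        res = model({param.name: value})
        out.append(_pair_icer(res, pair, param.name))
    return tuple(out)


def _pair_icer(res: pd.DataFrame, pair: tuple[str, str], pname: str) -> float:
    res = res.set_index("strategy")
    for s in pair:
        if s not in res.index:
            raise ValueError(f"strategy {s!r} missing from model output "
                             f"(parameter {pname!r})")
    a, b = res.loc[pair[0]], res.loc[pair[1]]
    de = a["qaly"] - b["qaly"]
    if de == 0:
        return np.inf
    return float((a["cost"] - b["cost"]) / de)


def tornado(params: list[ParamSpec], model, pair: tuple[str, str]) -> pd.DataFrame:
    """One-way results for every parameter, ranked by ICER swing
    |icer_high - icer_low| descending."""
    if not params:
        raise ValueError("tornado needs at least one parameter")
    rows = []
    for p in params:
        lo, hi = one_way(p, model, pair)
        rows.append({"parameter": p.name, "low_icer": lo, "high_icer": hi,
                     "width": abs(hi - lo)})
    df = pd.DataFrame(rows).sort_values("width", ascending=False,
                                        kind="stable")
    return df.reset_index(drop=True)


@dataclass
class PSARun:
    """Retained per-iteration PSA output: (cost, qaly) per strategy."""

    strategies: list[str]
    costs: np.ndarray  # (n_iter, n_strategies)
    qalys: np.ndarray
    n_iter: int
    seed: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_iter):
            for j, s in enumerate(self.strategies):
                rows.append({"iteration": i, "strategy": s,
                             "cost": self.costs[i, j],
                             "qaly": self.qalys[i, j]})
        return pd.DataFrame(rows)


def run_psa(model, specs: list[ParamSpec], n_iter: int, seed: int,
            max_failure_fraction: float = 0.01) -> PSARun:
    """Monte-Carlo PSA: ``n_iter`` full model evaluations under parameter
    draws; aborts if more than ``max_failure_fraction`` of iterations fail
    model preconditions."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorized draws, one column per iteration, consumed row-wise
    draws = {s.name: np.atleast_1d(_draw_one(s, rng, size=n_iter))
             for s in specs}
    strategies = None
    costs = qalys = None
    n_failed = 0
    for i in range(n_iter):
        params = {k: float(v[i]) for k, v in draws.items()}
        try:
            res = model(params)
        except (ValueError, FloatingPointError) as exc:
            n_failed += 1
            if n_failed > max(1, max_failure_fraction * n_iter):
                raise RuntimeError(
                    f"PSA aborted: {n_failed} failed iterations "
                    f"(last error: {exc})") from exc
            continue
        if strategies is None:
            strategies = list(res["strategy"])
            costs = np.full((n_iter, len(strategies)), np.nan)
            qalys = np.full((n_iter, len(strategies)), np.nan)
        costs[i] = res["cost"].to_numpy()
        qalys[i] = res["qaly"].to_numpy()
    if strategies is None:
        raise RuntimeError("every PSA iteration failed")
    ok = ~np.isnan(costs[:, 0])
    return PSARun(strategies=strategies, costs=costs[ok], qalys=qalys[ok],
                  n_iter=int(ok.sum()), seed=seed, n_failed=n_failed)


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curves: probability each strategy
    has the highest net monetary benefit, by WTP."""

    wtp_grid: np.ndarray
    strategies: list[str]
    prob_ce: np.ndarray  # (n_wtp, n_strategies)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.wtp_grid):
            for j, s in enumerate(self.strategies):
                rows.append({"wtp": w, "strategy": s,
                             "probability": self.prob_ce[i, j]})
        return pd.DataFrame(rows)


def ceac(run: PSARun, wtp_grid) -> CEAC:
    """At each WTP, each strategy's probability of being cost-effective is
    the fraction of iterations in which it attains the strictly highest NMB;
    exact ties split equally."""
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if run.n_iter == 0:
        raise ValueError("empty PSA run")
    probs = np.zeros((wtp_grid.size, len(run.strategies)))
    for i, w in enumerate(wtp_grid):
        nmb = w * run.qalys - run.costs  # (iter, strat)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEAC(wtp_grid=wtp_grid, strategies=list(run.strategies),
                prob_ce=probs)
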