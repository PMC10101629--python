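# Methods

This note records the model, the numerical conventions, and the design
choices behind `hccea`, in the order the pipeline runs.

## Pseudo-IPD reconstruction (Guyot algorithm)

Inputs are digitized KM coordinates (t_k, S_k) — strictly increasing
times, nonincreasing survival in [0, 1] — and a numbers-at-risk table
(interval start, n at risk). Within each risk interval the algorithm
guesses a censoring count, spreads the censor times uniformly (each at the
fraction midpoint of its slot), allocates events at each coordinate so the
re-estimated product-limit curve tracks the digitized survival ratios
(fractional counts are rounded half-to-even with the residual carried
forward, so interval totals are conserved), and iterates on the censoring
count until the implied number at risk at the next interval start matches
the published figure. The reconstructed cohort always has exactly the
first published number at risk; survivors past the last coordinate are
administratively censored there.

Conventions that needed fixing and why:

* **Interval ownership.** A risk interval owns the coordinates in
  (start_i, start_{i+1}], half-open on the left. A drop observed exactly
  at a boundary coordinate represents events just before the boundary,
  which the published number at risk at that boundary already excludes;
  attributing it to the later interval forces the reconciliation step to
  invent spurious censorings.
* **Event timing.** Events whose drop is first seen at coordinate k are
  timed immediately before t_k (offset 0.1 % of the cell width). With
  zero digitization jitter and a grid denser than the event times, the
  re-estimated KM then reproduces the digitized values at the coordinates
  exactly *and* per-interval event counts match the generating sample
  exactly; timing events exactly at t_k or at t_{k-1} each break one of
  the two properties.
* **Inconsistency detection.** The reconstruction raises an error, naming
  the interval, when the curve's drops already remove more subjects than
  the risk table allows with zero censoring — by more than
  max(3, 10 % of current n). The slack absorbs the 1–4 subject
  perturbations that ordinary digitization jitter induces at small n;
  a genuine curve/risk-table contradiction exceeds it immediately.
* **Reported total events**, when supplied, are reconciled by a
  final-interval adjustment (end-censorings converted to events or vice
  versa) rather than a global rescale, so earlier intervals keep their
  risk-table-reconciled counts.
* Without a risk table, `reconstruct_without_risk_table` assumes no
  censoring before the last coordinate (cumulative events track
  n·(1 − S_k)) and flags its output `approximate`.

## Parametric survival models

Five families with parameterizations fixed package-wide (the chief
cross-package reproducibility hazard is silent parameterization drift):

| family | S(t) | parameters |
|---|---|---|
| exponential | exp(−λt) | rate λ > 0 |
| Weibull | exp(−(t/α)^β) | scale α, shape β > 0 |
| log-logistic | 1 / (1 + (t/α)^β) | scale α, shape β > 0 |
| log-normal | 1 − Φ((ln t − μ)/σ) | μ ∈ ℝ, σ > 0 |
| Gompertz | exp(−(λ/γ)(e^{γt} − 1)) | rate λ, shape γ > 0 |

The censored log-likelihood is Σ_events ln h(t_i) + Σ_all ln S(t_i).
Optimization runs on log-transformed parameters (μ untransformed) with
Nelder–Mead from three moment-based starts plus a polishing restart at the
incumbent optimum (tolerances 1e−12); this reproduces the exponential
closed form d/Σt to better than 1e−6 relative and matches lifelines'
log-logistic fitter to 1e−3 on shared data. Zero-event samples are
rejected: shape parameters are not identified and even the exponential
MLE is degenerate there. Model choice is by minimum AIC = 2k − 2 ln L;
exact ties go to the fewer-parameter model, residual ties to the fixed
family order above. Selection is re-run on every dataset; a log warning is
emitted when the winner is not log-logistic, the family the reference
analysis of this indication selected. Times are months everywhere in the
statistical layer. Comparator strategies use proportional hazards,
S_adj = S_base^HR, applied separately per endpoint (PFS and OS each carry
their own HR, since published network-meta-analysis tables report both).

## Cohort engine

A partitioned-survival three-state model: at each cycle-start time t_k
(k · 21 days, converted to months with 365.25/12 days per month),
occupancy is read directly off the curves — PFS = S_PFS, PD =
max(S_OS − S_PFS, 0), death = 1 − S_OS. The model is "Markov" only in the
bookkeeping sense; no transition matrix is inverted (an implied-matrix
exporter exists for inspection, with deaths attributed proportionally to
the alive states, but the trace is authoritative). When noise or extreme
HR combinations make S_OS < S_PFS, PD is clamped at 0, death absorbs the
difference so rows still sum to 1, and the clamped mass is logged.

The horizon is ceil(10 y × 365.25 d / 21 d) = 174 cycles (a 1e−3 cycle
tolerance in the ceiling absorbs horizon values printed with few digits).
Discounting is (1.05)^(−t_years) evaluated at cycle starts, cycle 0
undiscounted. Half-cycle correction (halving the first and last cycle's
contributions) ships as a flag, default off, because the original
analysis does not state its cycle-timing convention; switching it on
moves totals by less than one cycle's occupancy.

## Costs and QALYs

Per cycle, PFS occupancy accrues the first-line regimen cost plus testing
cost; PD occupancy accrues the second-line regimen (camrelizumab 200 mg
q2w + apatinib 250 mg daily by default) plus testing (testing in PD is a
flag, default on). Dosing rules: fixed mg, per-kg mg (60 kg baseline
weight), or weight-threshold; schedules per-day, per-cycle, or
every-k-weeks with q2w costed as 21/14 = 1.5 administrations per 21-day
cycle (continuous-rate approximation, not calendar simulation). Pricing is
linear per mg (or per administration) with no vial-wastage model. Grade ≥3
adverse events enter once at model entry, expectation-weighted:
Σ incidence·cost added to cost, Σ incidence·disutility subtracted from
QALYs — the source treats them as one-off utility decrements without
duration data. Second-line cost accrues for the entire PD occupancy by
default; a treated-fraction scale and a model-cycle cutoff are exposed in
config because one-way analysis shows second-line price among the most
influential parameters. Lenvatinib is costed at 8 mg/day in the shipped
tables (the below-60-kg dose, consistent with the 60 kg baseline and the
source's own base case); the 12 mg weight-threshold rule is available.

QALYs weight occupancy by u_PFS = 0.760 and u_PD = 0.680; both QALYs and
life-years are discounted. Reported tables round costs and ICERs to whole
dollars and QALYs to two decimals. Incremental comparisons against the
reference flag sign anomalies ("dominant", "dominated by reference")
instead of reporting a bare negative ICER. The frontier routine sorts by
cost, removes strict dominance (≤ cost and ≥ QALY, one strict), then
iteratively removes extended dominance wherever sequential ICERs are
*strictly* decreasing — exactly collinear strategies are retained — and
reports each frontier member's ICER versus the next-cheaper member.

## Sensitivity analysis

Deterministic: every uncertain parameter carries a (low, high) range —
±20 % of base in the shipped tables — and one-way analysis re-evaluates
the full model with the parameter pinned at each end, everything else at
base; the tornado ranks parameters by |ICER_high − ICER_low|.

Probabilistic: distributions follow parameter role — beta for
probabilities and utilities, gamma for costs, lognormal for hazard ratios.
An interval becomes a standard error via the normal approximation
sd = (high − low)/(2 · 1.96); beta and gamma parameters are moment-matched
to (base, sd), the lognormal takes log-mean ln(base) and log-sd
(ln high − ln low)/(2 · 1.96). The source never states its
interval-to-distribution rule; this is the conventional choice. Baseline
curve-parameter uncertainty is *not* drawn — only HRs, costs and
utilities, matching the distribution list the analysis names. The CEAC is
multi-way: at each WTP, a strategy's probability is the fraction of
iterations in which it attains the strictly highest NMB, with exact ties
split equally (ties occur only under degenerate distributions, where equal
splitting is unbiased). A run aborts if more than 1 % of iterations fail
model preconditions. The reference strategy's HR is identically 1 and is
never a PSA parameter.

All randomness flows from one root seed, split per stage
(arm simulation per endpoint, digitization per endpoint, PSA) via
`numpy.random.SeedSequence`; pipeline outputs are bit-identical across
runs with the same seed.

## Synthetic study conditions

The generator emulates the study's input structure, not its unpublished
supplementary values:

* **Reference trial arms**: log-logistic PFS (median 5.5 months,
  shape 1.4) and OS (median 10.7 months, shape 1.6), n = 299 per endpoint
  with administrative censoring at 30/40 months — medians and sample size
  mirror the pivotal sorafenib trial population; shapes are chosen to give
  realistic heavy-tailed aHCC survival. Uniform dropout is available but
  off by default, as the source describes none.
* **Digitization**: a 0.5-month grid with Gaussian probability-scale
  jitter of sd 0.005 (about half a percentage point, a plausible manual
  digitization error), clipped to [0, 1] and made monotone by
  running-minimum isotonic clipping; risk tables every 6 months, as
  printed under typical oncology KM figures.
* **Strategy tables**: dosing exactly as licensed for the nine regimens;
  unit prices are synthetic 2022-USD values on the Chinese-market scale
  (domestic agents far cheaper than imported ones); HRs versus sorafenib
  are plausible network-meta-analysis magnitudes (0.46–0.80, ICIs
  strongest); pooled grade ≥3 AE profiles per strategy; testing cost
  $120/cycle; utilities 0.760/0.680; every parameter at ±20 %.

Because prices and HRs are synthetic, the shipped example's absolute
totals are not, and are not meant to be, the published base-case totals —
those depend on supplementary values the source does not print. What the
passing tests do establish: the arithmetic pipeline reproduces the
published incremental and dominance results exactly when fed the published
totals; the reconstruction, fitting, cohort and PSA layers each reproduce
their closed-form, generator-truth, or brute-force oracles. What they do
not establish: fidelity of the synthetic prices/HRs to the unpublished
supplementary tables, PFS/OS digitizations of real figures being mutually
consistent (the generator enforces PFS ≤ OS in distribution; real
digitizations may cross, which the PD clamp handles), or any real-world
calibration of AE profiles.

## Problem sizes used in checks

Reconstruction fidelity runs at n = 200 with 5 risk intervals;
exponential-MLE and recovery oracles at n = 500–5,000; the AIC selection
study uses 50 replicates at n = 1,000; the shipped example's PSA runs the
full 10,000 iterations. These sizes give the oracles sub-percent Monte
Carlo noise while keeping the whole suite a few minutes on one CPU.

## Known limitations

* No spline/Royston–Parmar or cure models; no joint PFS–OS modeling.
* Cohort-level second-line cutoff is approximate (a model-cycle cutoff,
  not time-since-progression, which a cohort trace cannot identify).
* No EVPI, no budget impact, no currency/CPI conversion engine (prices
  enter already in USD), no subgroup analysis.
* The PFS→PD vs PFS→death split in the exported transition matrices is an
  identifiability convention, not an estimate.
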