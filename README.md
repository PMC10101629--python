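# hccea

Cost-effectiveness analysis of first-line systemic therapies for
unresectable advanced hepatocellular carcinoma (aHCC), from the perspective
of a payer choosing among nine regimens — sorafenib (the reference),
sunitinib, donafenib, lenvatinib, sorafenib + erlotinib, linifanib,
brivanib, sintilimab + IBI305, and atezolizumab + bevacizumab — with
camrelizumab + apatinib as the common second line.

The package is aimed at health economists and methodologists who want the
whole published-evidence pipeline as tested, reusable code:

1. **Curve reconstruction** — digitized Kaplan–Meier coordinates
   (time, survival) plus numbers-at-risk tables are converted to pseudo
   individual-patient data (IPD) with the Guyot iterative algorithm.
2. **Parametric fitting** — exponential, Weibull, log-logistic, log-normal
   and Gompertz models are fitted to the pseudo-IPD by maximum likelihood
   and the family with minimum AIC = 2k − 2 ln L is selected per endpoint.
3. **Comparator arms** — each non-reference strategy's curves come from the
   reference fit under proportional hazards,
   S_adj(t) = S_ref(t)^HR, with per-endpoint hazard ratios (e.g. from a
   network meta-analysis) supplied as configuration.
4. **Cohort model** — a three-state partitioned-survival model
   (progression-free survival PFS, progressed disease PD, death) over a
   10-year horizon in 21-day cycles: occupancy(PFS) = S_PFS(t),
   occupancy(PD) = S_OS(t) − S_PFS(t), occupancy(death) = 1 − S_OS(t),
   discounted at 5 %/year.
5. **Health economics** — per-cycle drug/testing costs from dosing rules
   (60 kg baseline weight), utilities 0.760 (PFS) and 0.680 (PD), one-off
   expected adverse-event costs and disutilities; incremental
   cost-effectiveness ratios ICER = ΔC/ΔE against the reference, strict and
   extended dominance, and the efficiency frontier.
6. **Uncertainty** — one-way sensitivity analysis over ±20 % parameter
   ranges (tornado ranking), and probabilistic sensitivity analysis
   (beta/gamma/lognormal distributions for utilities/costs/HRs, 10,000
   Monte-Carlo iterations) summarized as cost-effectiveness acceptability
   curves: P(strategy has the highest net monetary benefit
   NMB = WTP·QALY − cost) on a willingness-to-pay grid. The shipped WTP
   threshold is $37,654.50/QALY.

Published trial inputs are not redistributed; a first-class synthetic-data
module generates trial arms from known survival families, emulates figure
digitization (grid sampling, probability-scale jitter, isotonic clipping)
and emits a complete nine-strategy strategy/cost/utility/HR configuration,
so the entire pipeline runs and is testable offline.

## Worked example

```python
from hccea import example_config, run_base_case

cfg = example_config(seed=1)          # shipped 9-strategy synthetic study
base = run_base_case(cfg, outdir="results")
print(base.base_table[["strategy", "cost", "incrC", "QALY", "incrE", "ICER"]])
```

prints (seed 1):

```
                        strategy    cost     incrC  QALY  incrE      ICER
0                      sorafenib   22996       NaN  0.98    NaN       NaN
1                      sunitinib   25629    2633.0  1.87   0.89    2968.0
2                      donafenib   64820   41824.0  1.40   0.42  100713.0
3                     lenvatinib   24195    1199.0  1.94   0.96    1248.0
4       sorafenib_plus_erlotinib   77649   54653.0  1.91   0.92   59244.0
5                      linifanib   53259   30263.0  1.93   0.95   31947.0
6                       brivanib   79005   56009.0  1.90   0.92   60781.0
7         sintilimab_plus_ibi305   30040    7045.0  2.08   1.10    6421.0
8  atezolizumab_plus_bevacizumab  157564  134569.0  2.04   1.06  127080.0
```

Each row is one first-line strategy: `cost` is the discounted 10-year total
cost in USD, `QALY` the discounted quality-adjusted life-years, `incrC` /
`incrE` the increments versus the reference (sorafenib), and `ICER` the
incremental cost per QALY gained. `base.frontier_all` labels dominated and
extendedly dominated strategies; with these synthetic prices and hazard
ratios, lenvatinib and sintilimab + IBI305 form the frontier with
sorafenib, and the remaining six strategies are dominated.
`run_uncertainty(cfg, base=base, outdir="results")` adds the tornado,
PSA scatter and CEAC tables.

The same pipeline runs from a shell:

```sh
hccea report --outdir results --seed 1          # shipped example
hccea reconstruct --curve curve.csv --risk risk.csv --out ipd.csv
hccea fit --ipd ipd.csv --out fits.csv
```

To analyse real digitized curves, point `curve_sources` in the JSON config
at `curve,survival` and `interval_start,n_risk` CSV files and set each
strategy's prices and hazard ratios.

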