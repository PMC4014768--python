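# bmdbatch

Standardized, batch-mode **benchmark-dose (BMD) modeling** for summary
dose–response data.

Health assessments of environmental chemicals need a point of departure
(POD): the dose from which low-dose extrapolation starts. Traditional PODs
(NOAELs, LOAELs) are limited to the tested doses and ignore the shape of the
dose–response curve. BMD modeling instead fits parametric models to the data
and reports the dose producing a prespecified benchmark response (BMR),
together with its one-sided lower confidence limit (BMDL). Done one chemical
at a time, BMD modeling is slow and inconsistent: analysts differ in BMRs,
model suites, fit criteria, and selection rules. `bmdbatch` runs the whole
workflow with prespecified, automated rules — so hundreds of datasets can be
processed identically, transparently, and reproducibly.

It is written for toxicologists, risk assessors, and statisticians working
with the group-level summary tables that animal studies actually report:
doses, group sizes, and either affected counts (dichotomous endpoints) or
group means and SDs (continuous endpoints).

## The statistics

For each dataset the appropriate candidate suite is fitted by maximum
likelihood:

* **dichotomous** (binomial): Gamma, Dichotomous Hill, Logistic, LogLogistic,
  Probit, LogProbit, Weibull, Multistage of degree *g* − 1
  (e.g. Multistage: *p(d)* = γ + (1 − γ)(1 − e^(−Σ βᵢ dⁱ)), βᵢ ≥ 0);
* **continuous** (normal): Exponential 2–5, Hill, Power, Polynomial of degree
  *g* − 1, Linear — each under constant variance σ² and modeled variance
  σᵢ² = α·|μ(dᵢ)|^ρ;
* **dichotomous-cancer**: multistage-cancer at every degree 1 … *g* − 1.

The BMD solves `(p(BMD) − p(0))/(1 − p(0)) = 0.10` (10% extra risk) for
dichotomous data, or `|μ(BMD) − μ(0)| = 1 × σ̂₀` (one model-estimated control
SD) for continuous data. The BMDL is the profile-likelihood one-sided 95%
lower bound: the smallest D < BMD at which the constrained re-maximized
log-likelihood stays within χ²₁(0.90)/2 = 1.35277 of the maximum.

Each fit is classified **Unusable / Questionable / Viable** by automated
rules (goodness-of-fit p < 0.05, poorly modeled variance, BMDL above the
highest dose, BMD/BMDL > 20; low-dose extrapolation beyond 3× and
BMD/BMDL > 5 are non-fatal warnings). Among Viable fits the lowest-AIC model
is selected when the BMDLs span no more than 3-fold, otherwise the
lowest-BMDL model; AIC ties are averaged. Datasets with no Viable fit are
re-run with the highest dose dropped, while at least three dose groups
remain. Per chemical, the lowest BMD (preferring warning-free selections)
and the lowest BMDL are reported, and candidate reference values are derived
by dividing a BMDL by the product of uncertainty factors.

## Worked example

```python
import bmdbatch as bb

ds = bb.DoseResponseDataset(
    "example", "dichotomous",
    doses=[0, 5, 15, 50, 150], n=[50] * 5,
    incidence=[2, 5, 12, 25, 41],
)
rec = bb.run_dataset(ds)
sel = rec.selected
print(rec.outcome, sel.model_names, sel.selection_rule)
print(f"BMD10 = {sel.bmd:.3f}, BMDL10 = {sel.bmdl:.3f}")
```

prints

```
modeled ['LogLogistic'] lowest_aic
BMD10 = 7.991, BMDL10 = 4.328
```

All eight dichotomous models were fitted; the four best by AIC were

```
LogLogistic      aic= 227.15 gof=0.866 bmd=7.99 bmdl=4.33 Viable
Weibull          aic= 227.59 gof=0.688 bmd=8.70 bmdl=6.98 Viable
Gamma            aic= 227.59 gof=0.688 bmd=8.70 bmdl=6.98 Viable
DichotomousHill  aic= 229.15 gof=0.592 bmd=7.99 bmdl=4.32 Viable
```

The Viable BMDLs span less than 3-fold, so the lowest-AIC model
(LogLogistic) is selected: a 10% extra-risk dose of 8.0 with 95% lower bound
4.3 (no warnings — the BMD sits just above the lowest tested dose of 5 and
the BMD/BMDL ratio is 1.8). A candidate reference value with the standard
uncertainty-factor stack (UF_A = UF_H = UF_S = 10, UF_D = 3) is
`bb.candidate_reference_value(sel.bmdl, 10, 10, 10, 3).crv` → `0.00144`.

The statsmodels-style object API exposes single fits directly:

```python
from bmdbatch import DoseResponseModel
from bmdbatch.models import Multistage

res = DoseResponseModel(ds, Multistage(degree=4)).fit()
print(res.summary())        # estimates, AIC, GOF, scaled residuals
res.bmd(), res.bmdl()       # 10% extra-risk BMD and its 95% lower bound
res.plot()                  # fitted curve over the observed proportions
```

A thin CLI wraps the same library for shell use:

```bash
bmdbatch fit   --input data.csv --dtype dichotomous --out out/
bmdbatch batch --input data.csv --config rules.yaml --out out/
bmdbatch simulate --design design.yaml --reps 100 --seed 1 --out sims/
bmdbatch report --sessions out/ --pods pods.csv --out report/
```

Input CSVs are long-format (one row per dose group) with columns
`dataset_id, chemical_id, endpoint, dtype, dose, n, incidence, mean, sd`;
outputs are JSON session records (every fit, class, warning, retry, and the
selection rationale) plus per-dataset and per-chemical summary CSVs.

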