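# tiapbms — population-based model selection for time-integrated activities

Internal dosimetry for molecular radiotherapy (e.g. ¹⁷⁷Lu-PSMA radioligand
therapy) needs the **time-integrated activity** (TIA) of each organ: the
integral of its activity–time curve, which multiplied by a dose factor gives
the absorbed dose. Clinical time–activity data are sparse — often three
scintigraphy points per patient — and the computed TIA depends strongly on
the fit function chosen. `tiapbms` implements a population-based answer for
physicists and pharmacometricians: fit a whole family of sum-of-exponential
(SOE) curves to *all* patients at once with a non-linear mixed-effects
(NLME) model, let the data rank the functions, and average over the
plausible ones.

## The method

Eleven candidate functions f2a … f6b parameterise mono-, bi- and
tri-exponential kinetics, each term decaying with rate λⱼ + λ_phys
(biological plus physical decay, λ_phys = ln 2 / 6.6443 d for ¹⁷⁷Lu), e.g.

    f3a(t) = A₁ e^−(λ₁+λ_phys)t + A₂ e^−λ_phys·t

with A_j ≥ 0, λ_j ≥ 0 and fractions α ∈ [0, 1]. Individual parameters
follow a log-normal population model P_i = TVP·exp(η_i), η_i ~ N(0, ω²),
with multiplicative residual error on the observations
(ln y = ln f + ε, ε ~ N(0, σ_res²)). Each candidate is fitted by
maximising a Laplace-approximated marginal likelihood; goodness of fit is
gated on convergence and on the coefficient of variation of the fixed
effects, CV = √(exp(se²) − 1) < 0.5. Gate-passing candidates are scored
with the small-sample corrected Akaike criterion and its weights

    AICc = −2 ln P + 2K + 2K(K+1)/(N−K−1),
    w_i  = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2),

and the model-averaged TIA per patient is TIA_MA = Σ_i w_i · TIA_i, with
every TIA in closed form (termwise Σ A(1−e^−μT)/μ, horizon 100 000 min).
A leave-one-patient-out jackknife measures selection stability. Two
baselines are included for comparison: IBMS (per-patient weighted least
squares, constant-CV weights with fractional SD 0.15) and SP-PBMS (a joint
population fit with one parameter shared across patients), with TIA
standard deviations propagated by Saltelli-style frequency-based sampling
through log-normal parameter marginals (ω = 1028, 8193 evaluations).
Methods are compared by the relative deviation of their TIAs from the
model-averaged reference, RD = (TIA_j − TIA_MA)/TIA_MA, summarised as
RMSE = √(SD² + mean²) over patients.

## Worked example

Since no patient data ship with the package, the built-in generator
emulates the study design — 13 patients, scans near 1.1 h, 20.7 h and
163.8 h post injection (one patient with one extra point, three with two),
46 observations in total:

```python
from tiapbms import generate_cohort, ModelSelection

sim = generate_cohort(seed=42)          # f3a truth, omega=0.3, sigma_res=0.15
sel = ModelSelection(functions=("f2a", "f3a", "f3c", "f4a"), n_starts=2)
sel.fit(sim.cohort)
print(sel.table_[["K", "AICc", "weight", "cv_max", "passed_gate"]].round(3))
print("best:", sel.best_function_)
print(sel.model_average_tia().round(1).head(3))
```

prints

```
          K    AICc  weight  cv_max  passed_gate
function
f2a       5  -2.070   0.008   0.049         True
f3a       7 -10.131   0.471   0.149         True
f3c       7 -10.335   0.521   0.158         True
f4a       9  -4.367   0.000   3.018        False
best: f3c
P01    133.4
P02    219.9
P03    169.5
```

K counts fixed effects + random-effect variances + the residual parameter
(3+3+1 = 7 for f3a). f4a converges but fails the CV < 0.5 gate, so its
weight is exactly 0; the bi-exponential parameterisations carry almost all
the weight, and the model-averaged TIAs are in minutes per unit injected
activity (133.4 min ≈ 2.2 h for patient P01). On this particular seed the
equivalent reparameterisation f3c edges out the generating f3a — across
many cohorts f3a wins most often (see the selection-recovery experiment).

The same workflow is available from the shell:

```bash
tia-pbms simulate --out cohort.csv --seed 42
tia-pbms select cohort.csv --functions f2a,f3a,f3c,f4a
tia-pbms ibms cohort.csv --tia-sd
tia-pbms run --config config.yaml
```

## Layout

| module | contents |
| --- | --- |
| `tiapbms.functions` | the 11 SOE functions, constraints, closed-form TIA |
| `tiapbms.nlme` | Laplace NLME engine (`NLMECurveModel`) |
| `tiapbms.selection` | AICc, Akaike weights, gate, averaging, jackknife |
| `tiapbms.baselines` | IBMS and SP-PBMS weighted least squares |
| `tiapbms.uncertainty` | frequency-based sampling, log-normal moments |
| `tiapbms.metrics` | RD / RMSE report tables |
| `tiapbms.simulate` | study-design synthetic cohorts with known truth |
| `tiapbms.experiments` | seed-driven recovery experiments |
| `tiapbms.io`, `tiapbms.cli` | cohort I/O, run configs, `tia-pbms` CLI |

See `docs/methods.md` for the modelling details, numerical choices and
limitations.
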