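# nbpvf — NBPVF-Weibull lifetime modeling

Failure-time data from engineering and biomedical reliability studies
often show *mixed-state* failure rates — bathtub, unimodal, or
decreasing-increasing-decreasing hazards — that the two-parameter Weibull
cannot capture. The **NBPVF-Weibull** ("new beta power very flexible
Weibull") is a three-parameter lifetime distribution built for exactly
this situation, and this package implements it end to end: the
distribution itself, maximum-likelihood fitting with an analytic score,
information-criterion comparison against four rival Weibull-family
models, a Monte-Carlo harness for estimator bias/MSE evaluation, and
goodness-of-fit diagnostics.

## The model

Start from the very flexible Weibull (VF-Weibull) base, with shape
`α > 0` and rate `σ > 0`:

    G(w; α, σ) = 1 − exp(−e^z),   z = σw − w^(−α),   w > 0.

Apply the beta power transformation (BPT), which maps any CDF `G` to

    F = (β^G − (1 − G)) / β,      β > 0,

injecting one extra shape parameter. The composition is the
NBPVF-Weibull CDF

    F(w; α, σ, β) = [β^(1 − exp(−e^z)) − exp(−e^z)] / β,

which reduces to the VF-Weibull at `β = 1` (the implementation is exact
and continuous there, so optimizers may cross `β = 1` freely). Its
hazard `h = f / S` takes increasing, decreasing, unimodal, bathtub, and
modified-unimodal shapes depending on `(α, σ, β)`.

Parameters are estimated by maximizing the complete-sample
log-likelihood

    ℓ(α, σ, β) = Σ log(σ + α wᵢ^(−α−1)) + Σ zᵢ − Σ e^{zᵢ}
                 − n log β + Σ log[1 + (log β) β^(1 − exp(−e^{zᵢ}))],

and competing families (Weibull, flexible Weibull, and their
exponentiated versions) are ranked by AIC, CAIC, BIC, and HQIC.

## Worked example

Draw a synthetic failure-time sample, fit it, and rank the candidate
families:

```sh
nbpvf synth --alpha 0.6 --sigma 1.3 --beta 0.9 -n 200 --seed 1234 --output sample.txt
nbpvf fit --input sample.txt --family nbpvf
nbpvf compare --input sample.txt --families nbpvf,weibull,f_weibull,e_weibull,ef_weibull
```

The `fit` command prints the ML solution as JSON:

```json
{
  "converged": true,
  "family": "nbpvf",
  "loglik": -95.30013466539758,
  "n": 200,
  "n_evals": 1792,
  "params": {
    "alpha": 0.5708306370397812,
    "beta": 0.999999977231519,
    "sigma": 1.263072552818258
  },
  "seed": 0,
  "start": [0.5, 1.0, 1.0],
  "version": "0.1.0"
}
```

— the fitted `(α̂, σ̂) ≈ (0.571, 1.263)` sits close to the generating
`(0.6, 1.3)`, while `β̂` lands at 1 even though the data came from
`β = 0.9`: the likelihood's slope in `β` vanishes identically at
`β = 1`, so `β = 1` is a stationary point for *every* sample and the
transformation parameter is the hard one to pin down (the Monte-Carlo
study quantifies this). `compare` prints the four-criterion ranking;
smallest AIC fits best, with complexity penalized:

```
     Model       AIC      CAIC       BIC      HQIC
vf_weibull 194.60027 194.66118 201.19690 197.26983
     nbpvf 196.60027 196.72272 206.49522 200.60461
ef_weibull 198.13955 198.26200 208.03451 202.14389
 e_weibull 204.41445 204.53690 214.30940 208.41879
   weibull 207.11934 207.18026 213.71598 209.78890
 f_weibull 218.22282 218.28373 224.81946 220.89238
```

(here the two-parameter `β = 1` submodel wins on parsimony, as it
should: the full model spends one AIC point on a parameter the base
family already explains).

Python API equivalents live in `nbpvf.distributions` (densities,
quantiles, sampling), `nbpvf.estimation` (`fit_mle`, `score`,
`profile_loglik`), `nbpvf.model_selection` (`compare`),
`nbpvf.simulation` (`run_study`), and `nbpvf.diagnostics`
(`describe`, `ecdf`, `kaplan_meier`, `qq_points`).

Two classical engineering data sets ship as plain-text fixtures
(transcribed from their primary sources and verified against published
summary statistics): 23 secondary-reactor-pump failure times and 50
electronic-machine failure times. Load them with
`nbpvf.load_bundled_dataset("reactor_pumps")`.

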