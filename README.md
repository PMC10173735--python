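# ctldyn

Quantitative modelling of cytotoxic T lymphocyte (CTL) activity inside
melanoma, for systems immunologists who want to weigh *cytolytic*
against *cytostatic* tumor control and ask which immune checkpoints
drive CTL exhaustion.

The core is a cell-cycle-resolved tumor-immune ODE system.  Tumor cells
cycle between G1 (`G`) and S-G2-M (`S`); volume is `V = S + G`:

```
dS/dt =  k_gs·G·(1 + k_i·I/V)⁻¹ − k_sg·S − α·k_e·E·S/V
dG/dt = −k_gs·G·(1 + k_i·I/V)⁻¹ + 2·k_sg·S − α·k_e·E·G/V
dE/dt =  s₀·V + α·s_e·E − d_E·E                 (CTLs, from day 0)
dI/dt =  α·E − d_i·I                            (IFN-γ)
dX/dt =  E·(1 + k_A·I/V) − d_X·X                (X ∈ {P, P_L, L, H})
```

CTLs kill tumor cells (`k_e`) and secrete IFN-γ, which arrests the
G1→S transition (`k_i`) and induces the checkpoints PDCD1/PD-1 (`P`),
CD274/PD-L1 (`P_L`), LAG3 (`L`) and HAVCR2/TIM-3 (`H`).  The per-CTL
checkpoint load sets the exhaustion level
`R = k_l·L/E + k_t·H/E + k_p·(P/E)(P_L/V)`, and the activity
`α = (1 + k_ex·R)⁻¹` throttles killing, expansion and IFN-γ secretion.

Around this model the package provides:

- **calibration** of the basal cycle rates from untreated growth data
  (`k_sg = g(1+r)/r`, `k_gs = g(1+2r)`), interval growth-rate
  transforms, and the CTL-count vs cycle-ratio Pearson statistic;
- **inference**: a joint Gaussian log likelihood over eight
  observables (CTL counts, interval growth rates, S-G2-M:G1 ratios,
  IFN-γ and checkpoint expression), an exhaustive (k_e, k_i) grid
  search for the input-forced two-state model, multistart bounded
  maximum likelihood over checkpoint model variants, and AIC ranking;
- **identifiability**: adaptive Metropolis parallel hierarchical
  posterior sampling, 1–99% credible intervals with
  undetermined-bound flagging, likelihood sweeps, posterior-predictive
  ensembles;
- a **synthetic study generator** reproducing the experimental layout
  (5/5 untreated and 5/5/2 treated mice, cryosection imaging on days
  1–14, pooled microarray samples on days 1–7 with above-background
  flags and 75th-percentile normalization), so the whole pipeline is
  testable without any downloads.

## Worked example

Generate a noise-free synthetic study from a HAVCR2-dominant ground
truth, fit two model variants, and rank them:

```python
from ctldyn import (TumorImmuneParams, NoiseModel, generate_full_dataset,
                    multistart_fit, compare_variants, basal_growth_rate)

truth = TumorImmuneParams(s0=0.001, se=2.0, dE=0.5, di=2.0, kgs=1.64,
                          ksg=0.66, ki=4.0, ke=2.0, kt=1.0, dl=0.5,
                          dt=0.1, dp=2.0, dpl=2.0)
print("basal growth rate:", round(basal_growth_rate(1.64, 0.66), 3), "per day")

data = generate_full_dataset(truth, seed=3, noise=NoiseModel.none())
fits = [multistart_fit(data.observations, v, n_starts=25, seed=7)
        for v in ("havcr2_only", "none")]
print(compare_variants(fits).to_string(index=False))
best = fits[0].params
print(f"recovered: se={best.se:.3f} dE={best.dE:.3f} di={best.di:.3f} "
      f"ki={best.ki:.3f} kt={best.kt:.3f}")
```

Output:

```
basal growth rate: 0.401 per day
    variant  n_free_params          logL       AIC     dAIC
havcr2_only             11 -1.219071e-15 22.000000 0.000000
       none             10 -1.989482e+00 23.978964 1.978964
recovered: se=2.000 dE=0.500 di=2.000 ki=4.000 kt=1.000
```

The calibrated cycle rates (1.64, 0.66 per day) grow the tumor at
0.40/day.  On data generated with HAVCR2 as the sole exhaustion driver,
the HAVCR2-only variant reaches a perfect fit (logL ≈ 0) and wins the
AIC comparison, and every generating parameter is recovered exactly.
The exhaustion-free variant cannot represent the IFN-γ shutdown and
pays for it in likelihood.

## Command line

The same stages are scriptable over a shared run directory:

```
ctldyn run  --config config.yaml --seed 7 --out runs/demo     # all stages
ctldyn synth      --config config.yaml --out runs/demo
ctldyn calibrate  --out runs/demo
ctldyn gridsearch --out runs/demo --kmax 20 --step 0.1
ctldyn fit        --out runs/demo --variant all --starts 200
ctldyn compare    --out runs/demo
ctldyn mcmc       --out runs/demo
```

`run` executes synth → calibrate → gridsearch → fit → compare → mcmc →
report and writes a manifest with per-stage seeds and output hashes;
rerunning the same config and seed reproduces the hashes bit for bit.

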