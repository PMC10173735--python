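# Methods

## The model

`ctldyn` models the interaction between a growing melanoma and
adoptively transferred cytotoxic T lymphocytes (CTLs) with a
cell-cycle-resolved ODE system.  Tumor cells occupy two compartments —
G1 (`G`) and the pooled S-G2-M phases (`S`), both in mm³-equivalents
under a constant-cell-density assumption, so tumor volume is
`V = S + G`:

    dS/dt =  kgs·G·(1 + ki·I/V)⁻¹ − ksg·S − α·ke·E·S/V
    dG/dt = −kgs·G·(1 + ki·I/V)⁻¹ + 2·ksg·S − α·ke·E·G/V

Every division returns two G1 daughters, hence the factor 2.  Without
immune terms the system grows exponentially at the dominant eigenvalue
of `[[−ksg, kgs], [2ksg, −kgs]]`, with a steady-state S:G ratio
`r = kgs/(g + ksg)`; inverting these relations
(`ksg = g(1+r)/r`, `kgs = g(1+2r)`) calibrates the two cycle rates from
the untreated growth rate and the imaging-derived cycle ratio, which is
done separately from the joint fit.

CTLs (`E`) infiltrate at rate `s0` per unit tumor volume from day 0
(the day of transfer), expand at `se`, die at `dE`, kill tumor cells at
`ke` per CTL (split across compartments by their volume fractions), and
secrete IFNG (`I`), which disappears at `di`.  The IFNG concentration
`I/V` arrests the G1→S-G2-M transition through `(1 + ki·I/V)⁻¹`; `1/ki`
is the concentration that halves the transition rate.

Four immune checkpoints — PDCD1 (`P`), its ligand CD274 (`PL`), LAG3
(`L`) and HAVCR2 (`H`) — are induced in proportion to
`E·(1 + kA·I/V)` and decay at rates `dp, dpl, dl, dt`.  The per-CTL
checkpoint load defines the exhaustion level

    R = kl·L/E + kt·H/E + kp·(P/E)·(PL/V),

and CTL activity `α = (1 + kex·R)⁻¹` multiplies killing, expansion and
IFNG secretion.  `α = 1` for unexhausted CTLs and halves at
`R = 1/kex`.  We deliberately use the decreasing form: the complement
`1 − (1+kex·R)⁻¹` would assign *zero* effector function to unexhausted
CTLs and *increasing* function with exhaustion, which contradicts the
intended biology; the decreasing form is the one consistent with a
declining activity course.  `kA` and `kex` are structurally
non-identifiable and fixed to 1 before any fitting; model variants
(`none`, `lag3_only`, `havcr2_only`, `pdcd1_only`, `all`) zero the
excluded exhaustion weights while the checkpoint ODEs (which are
observed) remain active.

Edge conventions: `R = 0` when `E = 0` (no CTLs means no exhausted
CTLs); killing fractions are 0 when `S + G = 0`; input interpolants are
clamped to their terminal knots outside the knot range.

### A note on the reference parameter estimate

The packaged reference estimate (the full-model, HAVCR2-dominant best
fit: `se = 8.41`, `dE = 0.80`, `di = 3.61`, `ki = 4.40`, `ke = 100`,
`kt = 1.37`, …) produces a trajectory in which killing eradicates the
simulated tumor within ~3 days (V falls by ~8 orders of magnitude
before regrowing at the basal rate once the CTL wave has passed).
Because the state equations are homogeneous of degree one, no choice of
initial volume or unit convention avoids this: exhaustion develops too
slowly, relative to the CTL expansion rate, to throttle a killing rate
of 100/CTL/day in time.  The qualitative CTL/IFNG course is still the
expected one (E rises then falls; I peaks no later than E).  All
self-recovery experiments shipped with the package use this estimate
as-is; experiments that need a surviving tumor (per-image correlation,
model-selection recovery) construct documented milder ground truths.

## Simulation

The public simulator integrates with scipy's stiff-capable LSODA at
`rtol = 1e-8`, `atol = 1e-10` (the likelihood must be smooth for
optimisation); small negative undershoots are clamped to zero.
Likelihood fitting, grid search and posterior sampling evaluate the
same right-hand sides through a numba-compiled adaptive Dormand-Prince
5(4) driver that steps exactly onto the infiltration switch (t = 0) and
every output time; a test requires the two integration paths to agree.
The compiled driver declares failure (rather than looping) when the
error controller underflows — this happens only for parameter
combinations that drive the tumor extinct at enormous per-capita rates,
and such points enter the objective as a large finite penalty.

The input-forced mode replaces the CTL and IFNG equations with
piecewise-linear interpolants of measured means and integrates only the
two tumor equations with `α = 1`; it is the substrate of the
(ke, ki) grid search.

## Observables and likelihood

Eight observables enter one Gaussian log likelihood,
`logL = −½ Σ (y_m(t_j) − ȳ_mj)²/σ²_mj`, over all included points
simultaneously: CTL counts (`E`), per-interval volumetric growth rates
(`ln(V(t₂)/V(t₁))/(t₂−t₁)`, reported at interval midpoints), the
S-G2-M:G1 ratio (`S/G`), IFNG expression (`I/V`) and the four
checkpoint expressions (`X/V`).  Expression observables are
baseline-corrected: the untreated condition measures the baseline
(the model's immune block is identically zero there), and the
treated-minus-untreated difference is compared to the model
concentration.  Growth-rate observations from intervals starting on or
after day 10 are excluded from fitting (they derive from a single
2-mouse arm with artificially small spread); exclusion flags carry
reason codes and excluded rows never touch the objective.

Single-sample checkpoint expressions get their standard deviation from
the housekeeping mean-sd regression `σ = 0.054 + 0.29·ȳ`; multi-probe
observables use the across-probe spread with the same regression as a
floor.  For noise-free synthetic data, replicate spread vanishes, so
per-observable floors apply (growth 0.10/day, ratio 0.05, CTL count 1).
These floors only weight the objective; at a noiseless optimum the
likelihood is zero regardless of their values.

## Fitting

Parameters are log10-transformed (bounds span up to six orders of
magnitude) and optimised inside their boxes: degradation rates
`di, dl, dt, dp, dpl ∈ [0.01, 100]`/day, killing `ke ∈ [0.01, 100]`,
CTL death `dE ∈ [0.01, 10]`, everything else `[10⁻³, 10³]`.  The
multistart strategy draws Latin-hypercube starts (200 by default;
20,000 reproduces the study scale), optimises each locally, then
re-polishes the best three optima with a larger evaluation budget.

The per-start optimiser defaults to trust-region-reflective least
squares on the weighted residual vector rather than bounded
quasi-Newton on the scalar objective: the objective *is* a sum of
squares, and on the rugged surface induced by the collapse dynamics of
the reference estimate L-BFGS-B stalls far from the optimum (best of
200 starts around logL ≈ −70 on noiseless data whose true optimum is
exactly 0), while the least-squares structure lets a large fraction of
starts reach the global basin.  An `lbfgsb` mode is retained for
comparison.  With 200 starts the identifiable parameters
(`dE`, `se`, `ki`, `di`) are recovered to well under 1% from noiseless
synthetic data in about three minutes on one CPU.

Variants are ranked by `AIC = 2k − 2·logL`, where `k` counts the free
parameters of the variant (checkpoint decay rates are always free
because the checkpoints are always observed; zeroed exhaustion weights
are not counted).

## Posterior sampling

Practical identifiability is assessed with an adaptive Metropolis
parallel hierarchical sampler: the main chain targets the posterior
(flat prior on the fitting box in log10 space), `n_aux` auxiliary
chains (default 20) run adaptive Metropolis on tempered versions
(`β_i = 1.5⁻ⁱ`), and every few steps a random adjacent pair proposes an
exchange.  Proposal covariances follow a Haario-style recursion
(`2.38²/d` times the chain's running covariance plus a small jitter)
starting after 200 steps.  The final half of the main chain is
retained.  Defaults are CI-scale (5,000 steps); 100,000 steps with 21
multistart initialisation sets reproduces the study scale.  The
sampler is validated on conjugate toys: posterior means within 3
effective-sample-size standard errors, uniform marginals under a flat
target, healthy acceptance rates (0.1–0.6), and 98% interval coverage
within ±3% over 200 reduced-length replicates.

Credible intervals are empirical 1%/99% quantiles; an interval end
within 1% (of the log10 box span) of a bound is reported as
undetermined — the data do not constrain that side.  Likelihood sweeps
profile one parameter with the rest fixed; posterior-predictive
ensembles simulate retained draws and report per-draw failures without
aborting.

## Synthetic data generator

The generator emulates the study layout: two untreated experiments of
5 mice (volumes on days −1, 1, 3, 5, 7), three treated experiments of
5/5/2 mice (the 2-mouse arm measured to day 14), cryosection imaging on
days 1, 3, 5, 7, 10, 14 (4 images/day), and one pooled expression
sample per timepoint and condition on days 1, 3, 5, 7.  The treated
day-0 volume is 100 mm³; pre-transfer days are back-extrapolated along
the basal exponential.

Noise model (all switchable off for noise-free data): per-mouse
lognormal initial-volume factors (σ = 0.25) scaling whole trajectories
(exact, by homogeneity), iid lognormal measurement noise on volumes
(σ = 0.15), negative-binomial cryosection counts (variance
μ + 0.05·μ², Poisson at zero dispersion) with 10 nuclei counted per
mm³-equivalent, pooled expression samples averaging 3–4 simulated
tumors (lognormal tumor-to-tumor σ = 0.10), Gaussian expression noise
following `σ = 0.054 + 0.29·mean`, and per-sample lognormal
raw-intensity scale factors (σ = 0.15) that the 75th-percentile
normalization removes.  These magnitudes were chosen once as
representative of small-cohort mouse volumetry, count data, and
single-channel arrays.

The probe table carries 4 IFNG probes, one probe per checkpoint,
CTL/IFNG tracker genes (Cd8a, Stat1, Socs1), 150 housekeeping probes
log-spaced over two decades, probes flagged below background in all
samples, and one partially flagged probe.  The dense housekeeping
background pins the per-sample 75th percentile the way a 45k-probe
array would; with a sparse background the signal probes shift the
quantile and inflate the post-normalization sd-vs-mean slope, so the
noise-model self-consistency check regresses on the pre-normalization
matrix.  Preprocessing discards probes flagged zero in *every* sample
and rescales each sample so its 75th percentile equals the
across-sample mean of 75th percentiles; this preserves the data scale,
at the cost that rescaling one raw sample moves the common target, so
invariance holds exactly only up to a single global factor (the
per-sample relative structure is exactly preserved).

What passing tests on these data do and do not show: the generator
reproduces the statistical *structure* of the study (cohort layout,
noise laws, flag filtering, exclusion rules), so recovery results
demonstrate that the pipeline is correct and the stated parameters are
identifiable under that structure.  They do not certify the biological
conclusions on the real data, which include image-segmentation and
array artefacts, inter-experiment batch shifts, and model
misspecification that the generator does not emulate.

## Numerical choices and limitations

- Integrators: LSODA 1e-8/1e-10 public; compiled RK45 with the same
  tolerances for fitting; agreement asserted in tests.
- Grid search ties: `argmax` takes the first maximum in row-major
  (ke-major) order; the default grid is 0–20 at 0.1 (201×201).
- Degenerate inputs: zero-variance correlation inputs, nonpositive
  volumes, empty grids, missing observation times, sub-minimal MCMC
  initial sets, and negative sds are all rejected with specific errors.
- The per-day image summaries drop images without countable G1 nuclei;
  a day with no countable images yields an excluded ratio row.
- Fit quality under the *default* (noisy) generator is not an
  acceptance property; with realistic noise the checkpoint decay rates
  are practically non-identifiable, which is precisely the behaviour
  the sweep and posterior tools are meant to expose.
- Problem sizes in the shipped tests (200 multistart starts, 25-start
  model-selection fits, 5,000-step default chains, 200 reduced-length
  coverage replicates) were chosen as the smallest sizes at which the
  corresponding statistical checks are stable.
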