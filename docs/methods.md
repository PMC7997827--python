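# Methods

This note documents the models, numerical choices and design decisions of
the `mdoe` package, and states what the synthetic studies do and do not
establish about real cultivations.

## Reference process model

The bundled model (`mdoe.model.ReferenceYeastModel`) describes aerobic
fed-batch cultivation and whole-cell biocatalysis of *Saccharomyces
cerevisiae* with fourteen states: five dissolved components (glucose,
ethanol, a lumped nitrogen source, the biocatalysis educt ethyl
acetoacetate EAA, its product ethyl 3-hydroxybutyrate E3HB), six biomass
compartments, reactor volume, and cumulative O₂/CO₂ (mol).

**Pathways.**  Four reactions, each auto-balanced over C/H/O/N at
construction:

| pathway | substrate | catalyst | notes |
|---|---|---|---|
| oxidative growth | glucose | X_pri | biomass yield `Y_XS_ox` is the stoichiometric degree of freedom |
| overflow fermentation | glucose | X_pri | Glc → 2 EtOH + 2 CO₂; switched on above `Glc_crab` (Crabtree effect) |
| ethanol oxidation | ethanol | X_pri | active only after glucose depletion (glucose repression sigmoid) |
| educt reduction | EAA | X_p | EAA + 1/12 Glc + 1/2 H₂O → E3HB + 1/2 CO₂; glucose supplies redox equivalents |

Elemental compositions: glucose C₆H₁₂O₆, ethanol C₂H₆O, EAA C₆H₁₀O₃,
E3HB C₆H₁₂O₃, biomass CH₁.₈O₀.₅N₀.₂, nitrogen source NH₃-equivalent with a
configurable formula H_gO_hN_i.  Yeast extract/peptone media are lumped
into one assimilable nitrogen substrate because the studies feed them
jointly and no separate kinetics are observable.

**Kinetics.**  Uptake rates are Monod terms times products of double
sigmoids.  One shared slope `K_sl` serves both flanks (an optional second
slope is accepted), matching the common parameterization; where only a
single transition is needed the two midpoints coincide.  pH, temperature
and dissolved oxygen are exogenous constant setpoints entering only
through sigmoid modifiers — the experiments this emulates controlled them,
so no titration chemistry, temperature dynamics or gas–liquid transfer is
modeled.

**Compartment wiring.**  The six compartments exchange mass by first-order
transfers gated by stress sigmoids: activation X_s → X_pri (`k_act`),
induction of the product-forming pool X_pri → X_p (`k_pp`, induced by the
presence of educt), inactivation X_pri/X_p → X_i and X_s → X_si
(`k_inact`, accelerating at high ethanol), and mortality of live pools
into X_d (`k_d`, raised up to `f_stress_mort`-fold by ethanol or educt
stress).  New biomass is split `phi_struct` : (1−phi_struct) between the
structural and primary pools.  This wiring is this package's own design;
the compartment roles and the sigmoid-gated transfer structure are the
model family's, but the specific rate laws connecting them are not
published, so any alternative structure can be supplied through the
plug-in contract (state names, parameter bounds, `rhs`,
`derived_observables`).

**Defaults.**  Kinetic defaults are round numbers in the physiological
range for baker's yeast (e.g. `qGlc_ox_max` 0.6 g g⁻¹ h⁻¹ giving
µ ≈ 0.3 h⁻¹ at yield 0.5 g/g; ethanol inhibition centered at 40 g/l; EAA
inhibition above ~0.5–1 g/l; Crabtree threshold 0.8 g/l).  They make the
bundled scenarios behave like the cultivations they emulate (growth to
~50–80 g/l DCW in 48 h; product to ~35–45 g/l) but are not fitted to any
particular dataset — fitting them is precisely the calibration stage's
job.

**Integration.**  `scipy.integrate.solve_ivp` with LSODA, rtol 1e-6,
atol 1e-8.  Feed-profile breakpoints (ramp start/end) partition the
integration; feed pulses are applied between segments as conservative
mixing jumps.  Concentrations are clipped at zero only inside the rate
evaluation; a state more negative than −1e-9 aborts the run.  Feed rates
are accepted in ml/min and converted ×0.06 to l/h.  The linear feed ramp
is evaluated exactly as written, F(t) = F_end/t_end·(t−t_start), which
reaches F_end·(t_end−t_start)/t_end at t_end, not F_end; a
`ramp_convention="reach_Fend_at_tend"` switch rescales the slope for users
who intend the end-point reading.  Conservation checks (volume, carbon)
are verified by the test suite at 1e-6 l and 1e-5 relative; the
pure-dilution oracle is checked at tightened solver tolerance (rtol 1e-9)
so it measures integrator correctness rather than step-control slack.
Both instantaneous (windowed) and cumulative respiratory quotients are
provided; a window without oxygen consumption yields NaN, not an error.

## Monte-Carlo calibration

Each of `n_fits` cycles draws an independent noisy replicate — measured
series (per-point SD, default 5% relative), initial values (5%), the
unobservable biomass-compartment split (10%), and setpoints including feed
rates and feed concentrations (5%) — and refits the free parameters to it,
simulating with the perturbed setpoints.  Negative draws of non-negative
quantities are re-drawn (truncated normal) rather than clipped, so no
probability mass piles up at zero.

The objective is the weighted RMSD pooled over observables.  Because the
plain sum is unit-inconsistent across observables of different scales,
residuals are normalized by each observable's mean measured magnitude
before pooling (switchable off via `normalize=False`; the un-normalized
form is what the metric's unit tests check).  The dense-culture rule
(weight 0.5 for dry cell weight above 100 g/l) multiplies individual
squared residuals.

The optimizer is Nelder–Mead with box bounds, 3 start points by default
(nominal plus 10%-jittered copies), best RMSD kept.  A zero iteration
budget returns the start point with its objective value.  Ensemble
summaries use the type R-7 quantile (linear interpolation at
h = (n−1)p + 1), implemented directly because the 10/90% interval bounds
are defined through it; it coincides with R's default and numpy's
`linear` method.

The reference adaptation counts of the emulated studies (116 and 240) are
computational-budget choices, kept as configurable defaults; the bundled
recovery experiment uses 30 fits, 1 start and 100 simplex iterations per
fit — sizes chosen so a desk-scale run finishes in minutes while still
giving stable 10/90% quantiles from 30 ensemble members.  On the synthetic
growth study this recovers five kinetic parameters with ~4% median error
and interval coverage of the truth well above the nominal 80%.

## Design planning and Monte-Carlo evaluation

Candidates are the k cluster centers of k-means (scikit-learn, k-means++
seeding, 10 restarts) run on a uniform random cloud in min–max scaled
coordinates, so factor units do not dominate the Euclidean metric (whether
the original procedure scaled is unstated; scaling is the defensible
choice).  Defaults: k = 29, 10⁶ cloud points; tests and the acceptance
script use 4·10³–10⁵ points since the contract is distributional, not
count-exact.  Centers are convex combinations of in-bounds points and
therefore in-bounds; with a feasibility predicate the cloud is
rejection-filtered and a feasible fraction below 0.1% is an error.

Parameter draws for design evaluation use `scipy.stats.qmc.LatinHypercube`
over the ensemble's per-parameter [q10, q90] intervals — one draw per
equal-width stratum per parameter, permuted across parameters.  Drawing
independently per dimension follows the stated procedure and ignores
ensemble correlations; `resample_members=True` instead resamples whole
fitted vectors when correlation preservation matters.  Failed or
non-finite simulations are excluded from the response quantiles but
counted; more than 20% failures flags the design point.  The growth-study
response defaults to dry cell weight at 48 h (`value_at_time`); the
maximum over time is available where "maximum concentration" is the
stated goal, as in the biocatalysis study.

## Desirability ranking

Linear min–max rescaling only (no Derringer–Suich shapes): d(r̄ᵢ)
anchored at the candidate set's own min/max, d(νᵢ) inverted, combined
with w₁ = 0.8, w₂ = 0.2 (w₁+w₂=1 enforced).  Degenerate anchors (all
values equal) yield d ≡ 1 with a warning rather than 0/0.  Ranking ties
break by lower experiment id for reproducibility.  The quadratic response
surface (OLS on 1, linear, two-way interaction and square terms) is
fitted for visualization and contour export only; selection always uses
the raw Dᵢ of the simulated candidates.

## Synthetic studies and their limits

The generator simulates a ground-truth parameter set, samples observables
every 3 h over 48 h and applies the noise model, emulating two study
shapes: growth optimization (pH + linear glucose/nitrogen feed ramps,
biomass response; factor bounds pH 3–7, F_Glc 0.1–1 ml/min, F_N
0.05–0.6 ml/min) and biocatalysis (constant EAA/glucose/nitrogen feeds,
product response with educt inhibition).  Initial states and feed
compositions (400 g/l glucose, 120 g/l assimilable N equivalent, 800 g/l
EAA, 1.5 l start volume, 2 g/l start DCW for growth / 45 g/l for
biocatalysis) are chosen as typical bench-scale values.

What passing tests show: the pipeline recovers known parameters from data
with realistic noise, its conservation laws close, its design stage
out-fills random designs, and its ranking finds a constructed optimum.
What they do not show: adequacy of the reference model for any real
strain or medium — real data carry structured (non-Gaussian,
autocorrelated) errors, model misfit and unmodeled physiology (gas
transfer limits, pH drift, mixing) that the independent-normal noise
model deliberately omits.

## Numerical and degenerate-input conventions

R-7 quantiles with p outside [0,1] or empty samples are errors; R² of a
zero-variance measurement set is NaN (undefined marker).  k = n_random
returns the cloud itself.  An LHS interval with q10 = q90 produces a
constant column.  Tie-breaks, seeds and stage sub-streams derive from one
master seed via `numpy.random.SeedSequence.spawn`, making every artifact a
pure function of (config, seed) — repeated runs are byte-identical.

## Known limitations

- The compartment-transfer rate laws are plausible but unvalidated; use
  the plug-in contract to substitute a validated structure.
- Local, derivative-free fitting with few multi-starts can settle in
  local minima for strongly correlated parameter subsets; the ensemble
  spread then reflects optimizer scatter as well as data noise.
- Independent per-dimension LHS ignores parameter correlations (see
  `resample_members`).
- No surrogate acceleration: evaluation cost is k × n_sims mechanistic
  simulations.
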