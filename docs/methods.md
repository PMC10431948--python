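# Methods

## The model

A well-mixed oxygraph cell is described by mass-action kinetics over three
groups of species: the hemoglobin ligation states of the chosen model
variant, the oxidase sink, and cell/air O2. Every reaction is elementary
and at most bimolecular — apparent higher-order steps (four O2 binding to
one tetramer) are decomposed into sequential bimolecular reactions, which
is also the physical origin of the "sequential cooperativity" the
minimalist model isolates: a single shared site affinity, fed through four
obligatorily sequential steps, already produces a sigmoid saturation
curve and a Hill slope near 2.

Units are µM for concentrations, s⁻¹ and µM⁻¹s⁻¹ for rate constants.
Association rates are fixed at a diffusion-limited order of magnitude
(default `k_on` = 100 µM⁻¹s⁻¹, configurable); only dissociation rates, the
MWC allosteric constant L, and optionally the total heme concentration are
refined when fitting. Stepwise *macroscopic* association constants are
therefore Kn = k_on/k_off_n.

Model variants:

* **minimalist** — one (k_on, k_off) for all four steps; no conformational
  species.
* **adair** — independent k_off per step (4 refined parameters).
* **perutz** — T affinity on steps 1–2, R affinity on steps 3–4 (2 refined
  parameters). The T→R switch at ligation 2 is much faster than binding
  turnover, so the doubly liganded state is represented by the single
  merged species TR_O2. An explicit T2 ⇌ R2 pair with any *finite*
  interconversion equilibrium q would give K2 = K_T(1+q) and
  K3 = K_R·q/(1+q), spoiling the defining collapse K1=K2, K3=K4; the
  merged species is the q-consistent fast limit and keeps the collapse
  exact.
* **mwc** — parallel T and R chains, each a minimalist chain with its own
  affinity, interconverting at every ligation level. The interconversion
  toward T runs at a fixed fast rate k_TR = 10³ s⁻¹ and the reverse rate
  at level n is set to k_TR/L_n with L_n = L·cⁿ and c = k_off_R/k_off_T
  (= KT/KR), so the allosteric ladder holds exactly with a single refined
  L and detailed balance is satisfied around every binding/interconversion
  cycle. Note this two-state form is the "two minimalist tetramers in
  equilibrium" construction: its chains carry *no* binomial statistical
  factors, so the c → 1 limit is the minimalist sigmoid, not a hyperbola,
  and L → 0 gives the pure R chain.
* **independent_sites** — a macrostate chain with statistical factors
  (forward 4,3,2,1 × k_on, reverse 1,2,3,4 × k_off); its equilibrium curve
  is exactly hyperbolic and it serves as the non-cooperative reference for
  the cooperativity gain.

The cell ensemble appends E + O ⇌ EO → E + W and O ⇌ AIR. The water-forming
step is implemented irreversibly — it is physically irreversible and its
reverse rate is numerically immaterial. The oxidase binding rates default
to k_on_E = 10³ µM⁻¹s⁻¹, k_off_E = 100 s⁻¹, putting the apparent
K_M = (k_off_E + k_cat)/k_on_E around 0.1 µM: well below the µM range, so
the closed-phase decline is linear at k_cat·[E]total until anaerobiosis,
where the flux vanishes naturally as [O] → 0 (no artificial clamp beyond
non-negativity of the solver state). AIR is a constant-concentration
reservoir; the exchange O ⇌ AIR with equal first-order constants k_air
relaxes cell O2 exponentially toward air saturation.

## Protocol integration

A run has three phases: quiescent closed cell; respiring closed cell from
`t_respiration_on` (succinate); open, respiration-inhibited cell from
`t_open` (antimycin + stopper removal). Phase switching is done by
restarting the stiff solver (LSODA with an analytically assembled
Jacobian) exactly at the boundaries rather than by smooth switching
functions, making phase edges bit-reproducible. Default tolerances are
rtol 1e-8 / atol 1e-10; halving them moves the nominal trace by well under
1e-3 µM. The initial hemoglobin distribution is the scheme's own binding
equilibrium at the initial O2 (the cell equilibrates with air, stirred,
before the experiment starts); the closed-form equilibrium used here (and
for all equilibrium curves) is obtained by propagating detailed balance
along the reaction graph, which is exact for every shipped topology.

Default protocol (the nominal scenario): 183 µM initial and air O2
(air-saturated buffer at 37 °C), 50 µM heme (12.5 µM tetramer), 0.05 µM
oxidase, k_cat = 5 s⁻¹ (closed-phase slope 0.25 µM/s, anaerobiosis shortly
before reopening), k_air = 0.015 s⁻¹, events at 50 s and 1000 s, 1 Hz
sampling to 1400 s. Values not dictated by the experimental description
(k_cat, k_air, event times, sampling rate) were chosen once to reproduce
the familiar oxygraph trace shape — a ~15 min run reaching anaerobiosis
with a few hundred seconds of reoxygenation — and are all configurable.

## Fitting

`fit_trace` minimises Σ(observed − simulated)² over the free parameters,
jointly across deoxygenation and reoxygenation (a phase mask can restrict
this), with scipy's bounded trust-region reflective least squares.
Rate-like parameters are optimised as logarithms (positivity; the four
Adair k_off values span six orders of magnitude in the reference column).
Finite-difference steps are set to 1e-3 on the log scale, well above the
ODE-solver noise floor, otherwise numerical gradients stall in shallow
directions. A small seeded multi-start (default 5 starts, log-normal
perturbations of the initial values) guards against local minima; the
best-sse solution is reported together with sse, R², residuals and
convergence diagnostics, and trial simulations that fail are penalised
rather than aborting the search. `calibrate_background` estimates k_cat
from the linear closed-phase slope and k_air from the open-phase
exponential relaxation of an Hb-free trace; these are then fixed in
Hb-containing fits, mirroring two-stage experimental practice.

## ODC analysis

Fractional saturation pools conformations by ligation level:
S = Σ n·[pool_n]/(4·Σ[pool_n]). PO2 in mmHg uses α = 1.223 µM/mmHg,
derived from 183 µM air-saturated O2 at 37 °C against a humidified-air
PO2 of ≈149.7 mmHg (configurable; all internal computation stays in µM).

* **Adair fit** — nonlinear least squares on log K1..K4 (seeded
  multi-start, LM); requires ≥8 points spanning S from below 0.2 to above
  0.8. Its half-saturation (found by Brent bracketing on [0, 10⁴] µM to
  1e-6 µM) is reported as KD_Hill and converted to P50.
* **Hill slope** — regression of log10(S/(1−S)) on log10(PO2) over the
  window |S − 0.5| ≤ 0.2.
* **Crossover KDs** — adjacent-ligation member curves of a conformational
  family (T, R, or all states) are intersected by linear interpolation in
  each phase window; the cell O2 at the crossings estimates the family's
  dissociation constant, since at binding equilibrium [Hb_n] = [Hb_{n+1}]
  exactly at O2 = 1/K. Crossings whose concentration is below 1e-6 of the
  family's peak are integrator round-off in the anaerobic tail and are
  discarded. With diffusion-limited binding the deox and reox crossovers
  agree to well under 1%.
* **Cooperativity gain** — rms of S − x/(x + x50) over the curve's own
  sample points, requiring the curve to span S < 0.1 to S > 0.9. For
  trajectory-derived (possibly two-branch) ODCs, x50 is taken from the
  Adair fit of all points; for closed-form curves the exact root can be
  supplied. Equilibrium curves are evaluated by default on a uniform grid
  over 0–183 µM (0.5 µM spacing) — the experimentally accessible range;
  cgain values quoted for equilibrium curves refer to that grid, and only
  the ordering across models and the ~0.69 minimalist/MWC ratio are
  grid-robust.
* **Allosteric ladder** — L_n = L·cⁿ, with c computed as KT/KR from the
  refined two-state constants (their ratio, not a separately rounded c, is
  what keeps the ladder self-consistent at printed precision).

## Synthetic data and what it does (not) show

The generator reproduces the study conditions: the nominal protocol above,
the per-model reference constants (minimalist K = 0.0360 µM⁻¹; Adair
0.0368/0.0002/2.2237/0.1730; Perutz KT = 0.0168, KR = 0.0818; MWC
KT = 0.0191, KR = 0.1787, L = 504.6), and additive iid Gaussian noise on
the O2 reading with σ = 0.5 µM by default, which puts a correct model's
sse in the few-hundred µM² range over a 1400-point trace — the order seen
on real oxygraph fits. It does not emulate electrode response time,
drift, light-scattering artefacts or succinate depletion, so passing
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to instrument systematics.

Parameter recovery (generate → fit → compare) is exact to ≤0.001% at
σ = 0: the estimator machinery is unbiased and the models are structurally
identifiable. At σ = 0.5 µM the minimalist and Perutz parameters are
recovered within ~1%, but two quantities are *practically*
non-identifiable from a single trace at this noise level: the Adair
k_off_2/k_off_3 pair (the reference K2 = 0.0002 µM⁻¹ means the doubly
liganded state is essentially never populated, so only weak combinations
of these rates touch the trace) and, more mildly, the MWC allosteric
constant L (~15% excursions). In both cases the fitted optimum reaches the
noise-floor sse *below* the sse of the true parameters, i.e. the
deviations lie along flat directions of the likelihood, not in optimizer
failure. This is a property of the experiment, not of the code, and is a
useful caveat when interpreting single-trace fits of the richer models.

A related observation: at diffusion-limited binding rates (k_on =
100 µM⁻¹s⁻¹) hemoglobin equilibrates within milliseconds, so the deox and
reox branches of the simulated ODC coincide to ~1e-4 in S — consistent
with both phases plotting on a single curve experimentally. Hysteresis
between the branches appears only when per-site binding is slowed (e.g.
reading the default association rate as 0.1 µM⁻¹s⁻¹, the alternative unit
interpretation left configurable), and vanishes again in the quasi-static
limit; the test suite demonstrates both regimes. Likewise the
non-equilibrium ODC of any model converges pointwise (max |ΔS| ≤ 0.01) to
its closed-form equilibrium binding polynomial when the protocol is slowed
100-fold.

## Numerical choices and limitations

* Stiff integration: LSODA, analytic Jacobian, rtol 1e-8 / atol 1e-10
  (fits use 1e-7/1e-9 for speed); negative states beyond ~1e3·atol raise.
* Root-finds bracketed on [0, 10⁴] µM, xtol 1e-6 µM.
* Degenerate inputs: zero hemoglobin keeps all Hb reactions with zero
  concentration (no special-casing); a flat species "peaks" at the window
  boundary; an absent curve crossing is reported as absent, not an error.
* No CO2/pH/2,3-DPG heterotropic effects (stripped Hb), no intracellular
  diffusion, no biphasic Hb mixtures, no Bayesian uncertainty
  quantification — single-point estimates with residual diagnostics only.
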