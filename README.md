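# hbodc — non-equilibrium hemoglobin oxygen dissociation curves

`hbodc` determines hemoglobin (Hb) oxygen dissociation curves (ODCs) under
*non-equilibrium* conditions, the way they arise in an open-cell oxygraph
experiment: a Clark electrode records cell O2 while mitochondrial
respiration drives the cell to anaerobiosis (succinate addition; linear O2
decline through cytochrome *c* oxidase) and, after respiration is inhibited
and the stopper removed, O2 diffuses back in from air. Hemoglobin present in
the cell bends the trace — a concave tail as Hb releases O2 near
anaerobiosis, a slowed early reoxygenation as Hb reloads — and a global
kinetic fit of a mass-action model to that single trace recovers the full
saturation-vs-PO2 relation without any optical measurement. The approach is
relevant both for low-cost hemoglobinopathy screening (P50, Hill
coefficient from one respirometry trace) and for the mechanistic question
of where Hb cooperativity comes from when O2 exchange is not at
equilibrium.

## Models

All models are networks of elementary (at most bimolecular) reversible
mass-action reactions over the tetramer's ligation states, coupled to a
shared cell ensemble: the oxidase sink E + O ⇌ EO → E + W (sub-µM apparent
K_M, so the closed-phase decline is linear at rate k_cat·[E]) and a
first-order O ⇌ AIR exchange active while the cell is open. Concentrations
are µM, bimolecular rates µM⁻¹s⁻¹.

* **minimalist** — Hb ⇌ HbO2 ⇌ … ⇌ Hb(O2)4 with one k_on/k_off pair for all
  four steps (a single stepwise association constant K = k_on/k_off).
* **adair** — the same chain with an independent k_off per step
  (stepwise constants K1…K4, Kn = [Hb(O2)n]/([Hb(O2)n−1][O2])).
* **perutz** — two-state *sequential*: T affinity for steps 1–2, R affinity
  for steps 3–4, with the doubly liganded species TR_O2 representing the
  fast T→R switch, so K1=K2 and K3=K4 by construction.
* **mwc** — two-state *concerted*: parallel T0…T4 and R0…R4 chains, each
  with a single affinity (KT, KR), interconverting at every ligation level
  n with [Tn]/[Rn] = L_n = L·cⁿ, c = KT/KR. Equivalently: two minimalist
  tetramers in conformational equilibrium.
* **independent_sites** — four independent identical sites (statistical
  factors 4,3,2,1 / 1,2,3,4), whose equilibrium curve is exactly the
  hyperbola S = x/(x + k_off/k_on); the non-cooperative reference.

From a fitted trajectory the package derives the ODC
(S = Σ n·[Hb(O2)n] / 4·[Hb]total vs cell O2), the Hill plot
log(S/(1−S)) vs log PO2 and its slope n_H at half saturation, Adair
constants and P50 from a nonlinear least-squares fit of the Adair equation,
crossover dissociation constants (the cell O2 at which adjacent ligation
states of a conformational family have equal concentration — at binding
equilibrium exactly 1/K of that family), the allosteric ladder L_n = L·cⁿ,
and the **cooperativity gain**

    cgain = rms( S(x) − x/(x + x50) )

— the root-mean-square deviation of a curve from the same-P50
independent-sites hyperbola; zero iff the curve is hyperbolic.

## Worked example

Simulate the nominal experiment (183 µM initial O2, 50 µM heme stripped
Hb, ~0.05 µM oxidase, respiration from 50 s, cell reopened at 1000 s,
1 Hz sampling) with the two-state concerted model and analyse the ODC:

```bash
hbodc simulate --config examples/nominal_mwc.yaml
hbodc odc      --config examples/nominal_mwc.yaml
cat hbodc_out/mwc/odc.json
```

```json
{
  "p50_mmhg": 21.80,
  "kd_hill_uM": 26.66,
  "hill_coefficient": 2.81,
  "adair_K_uM_inv": {"K1": 0.0194, "K2": 0.0220, "K3": 0.0427, "K4": 0.1179},
  "kd_crossover_uM": {"T": {"deox": 52.36, "reox": 52.37},
                      "R": {"deox": 5.59, "reox": 5.37}},
  "cgain": 0.145
}
```

(numbers abridged from the actual output): the non-equilibrium ODC is
half-saturated at ~26.7 µM O2 (P50 ≈ 21.8 mmHg at 1.223 µM/mmHg), the Hill
coefficient is 2.8, the Adair constants rise K1 < K2 < K3 < K4 as expected
for a cooperative tetramer, and the T- and R-family crossover KDs sit at
1/KT ≈ 52 µM and 1/KR ≈ 5.6 µM. The same pipeline with
`examples/nominal_minimalist.yaml` — one shared affinity, no conformational
change at all — still gives a sigmoid ODC (n_H ≈ 1.98, cgain ≈ 0.10): about
70% of the cooperativity gain of the two-state models arises from the
*sequential* binding constraint alone.

A parameter-recovery experiment (generate a noisy trace from known rate
constants, refit, compare) runs as:

```bash
hbodc recover --config examples/nominal_minimalist.yaml
```

which for the minimalist model at σ = 0.5 µM noise reports the dissociation
rate recovered to 0.5% with R² = 0.99994 and sse ≈ 352 µM².

`hbodc fit --config <cfg> trace.csv` fits any model to an observed trace
CSV (columns `time_s,o2_uM`) by bounded trust-region least squares on log
rate constants, jointly over both phases, with a seeded multi-start.

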