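# Methods

## Model structure and assumptions

The simulator integrates a flow-limited (perfusion-limited) compartmental
system for two chemical layers, the parent bisphenol and its glucuronide.
Compartments: stomach and gut lumen (transit, parent only), gut wall,
liver, kidney, blood, lumped slowly and rapidly perfused tissues, and —
in human models only — thyroid and a gonadal compartment (testes in male
models, breasts in the woman model). Tissue densities are taken as
1 kg/L, so organ volumes are volume fractions × body weight. Blood is a
single well-mixed pool; arterial/venous distinction is not resolved.
Blood-flow fractions over the perfused compartments sum to 1, and the ODE
right-hand side uses the *sum* of compartment flows as total perfusion so
that molar balance survives parameter perturbation.

Key mechanistic choices:

- **Gastric emptying** is first-order with rate ln2/GEst into the
  absorbing lumen.
- **Absorption** is first-order, k_a = 2·P_eff/R for a cylindrical lumen
  of radius R, converted to 1/h. The gut wall is a perfused Kp compartment
  whose venous effluent drains into the liver (portal flow).
- **Metabolism** occurs only in the liver (intestinal glucuronidation and
  hepatic sulfation are out of scope): rate = Vmax·S/(Km+S) or the
  substrate-inhibition form, with S the liver venous blood concentration
  (C_liver/Kp_liver). Using total rather than unbound concentration is a
  simplification; with the high intrinsic clearances involved the liver is
  flow-limited and the distinction has little influence on systemic
  predictions.
- **Enterohepatic circulation**: the fraction EHCr of the glucuronide
  leaving the liver is diverted to bile; bile transfer to the lumen is
  instantaneous and complete, and luminal deconjugation to the parent is
  likewise instantaneous and complete (mole-for-mole). Recirculated parent
  competes between reabsorption (k_a) and fecal transit.
- **Renal elimination**: parent by filtration GFR·fu; glucuronide by
  filtration GFR·fu_g plus active secretion QK·EHCr·(V_kidney/V_liver),
  reusing EHCr as a surrogate for canalicular-type efflux activity scaled
  to the renal context.
- **Fecal output**: unabsorbed and recycled luminal material exits with a
  first-order whole-gut transit rate, default 0.05 1/h (mean residence
  ~20 h), so fecal excretion of unabsorbed material is near-complete by
  48 h. A faster small-intestinal rate would be wrong here because the
  lumen state feeds feces directly.

Units: amounts nmol, volumes L, flows L/h, time h, concentrations nM
(doses are converted as ng/kg × bw / MW_parent).

## Parameters

| Parameter | Units | Default source | Notes |
|---|---|---|---|
| bw, cardiac output, organ volume/flow fractions | kg, L/h, – | `physiology.csv` | standard reference physiologies (ICRP-style) |
| GEst | h | 0.4 (human), 0.25 (rat) | gastric emptying half-time |
| GFR | L/h | 7.5 (man), scaled by model | glomerular filtration |
| bile flow | L/day | 0.7 (adults) | used only in the bile-to-plasma diagnostic |
| Papp | 1e-6 cm/s | `papp_synthetic.csv` | pooled mean over in vitro + QSAR sources |
| Sun regression | – | slope 0.4926, intercept −0.1454 | config, `sun_regression.json` |
| intestinal radius R | cm | 1.75 (man) | k_a = 2·P_eff/R |
| Kp, fu | – | `kp_synthetic.csv`, `fu_synthetic.csv` | inputs, not computed; breast = 0.245×adipose |
| Vmax, Km, Ki | nmol/min/mg, µM | `kinetics_synthetic.csv` | scaled by 107.3 / 143 / 32 mg protein per g liver |
| SFg | – | UGT2B15 abundance ratio | child and toddler share the early-childhood class |
| EHCr | – | MW-calibrated from rat anchors | male 0.70/0.68 (BPA/BPF), female 0.75/0.72 |
| k_transit | 1/h | 0.05 | fecal transit, see above |

## Numerical choices

LSODA with rtol 1e-8 and an absolute tolerance scaled to the administered
amount (1e-10 per nmol dosed); dose events are exact discontinuities
(integration restarts with the dose added to the stomach state). Output is
interpolated on a fixed grid (default 0.01 h; coarser grids are used for
screening/Monte Carlo where a <0.1% Cmax shift was verified). Molar
balance closes to ~1e-13 relative; the simulator raises if any state goes
materially negative. tmax ties resolve to the earliest grid time; AUC is
trapezoidal and reported in nM·day.

Kinetic fitting converts depletion curves to interval finite-difference
rates paired with interval-mean substrate (an exponential-free, assumption
-light reading of "loss over time"); this is second-order accurate, so
recovery error scales with sampling interval — the noiseless-recovery
guarantee (<0.1%) holds for sampling dense relative to the depletion rate.
Fits use bounded multi-start least squares (starts: Vmax₀ = max rate,
Km₀ = median S, Ki₀ = 10·max S, ±scale variations); R² = 1 − SSE/SST on
rates, ties between rate laws break toward Michaelis–Menten. The Nalimov
test runs iteratively at α = 0.05 with a packaged critical-value table,
removing one extreme value at a time and never reducing a sample below 3.

EHCr fitting is monotone bisection on [0, 1] (tolerance 1e-3) matching the
simulated blood concentration at the late target time, with a guard that
the predicted-to-observed Cmax ratio not drift by more than 1.25-fold from
its value at the incoming parameter; identifiability requires a target
time in the terminal phase where the trace still resolves above solver
tolerance (the self-recovery tests use 12 h after a 10 mg/kg rat dose).
MW calibration interpolates linearly on *glucuronide* MW (the species
undergoing biliary transport; the calibration column is configurable) and
clips to [0, 1].

## Sensitivity and uncertainty

Local coefficients are normalized forward differences (+1%; central
optional). Morris screening uses radial trajectories (default 10) on a
4-level grid with Δ = p/(2(p−1)); eFAST drives the parameter of interest
at the maximal frequency (N−1)/(2M) with interference order M = 4 and the
complement at low frequencies, estimating first-order indices from the
driver harmonics and total-order from the low-frequency band. Both engines
are validated against analytic variance decompositions of separable test
functions (agreement within 0.05). The eFAST subset is chosen from the
Morris ranking; the default output functional is blood AUC(0–4 h).

Monte Carlo draws each listed parameter from truncated-normal (fractions)
or lognormal (kinetic constants) distributions parameterized by CV, then
projects every draw onto the constraints: EHCr clipped to [0, 1], and the
organ-volume and blood-flow fraction vectors rescaled multiplicatively to
their baseline sums (the simplest projection that keeps the stated sums
constant). Summaries are per-time-point Q1/median/Q3. All randomness flows
through a single seeded generator; equal seeds give bit-identical output.

## Synthetic data and what the tests show

The fixture generators produce (a) substrate-depletion curves integrated
from a chosen rate law with multiplicative Gaussian noise and (b) rat
blood concentration–time data simulated from the rat model itself with a
known EHCr. They emulate the *structure* of the real inputs — not assay
artifacts such as protein binding in incubations, analytical limits of
quantification, inter-animal variability, or model misspecification.
Passing recovery tests therefore demonstrates that the fitting chains are
correct and self-consistent, not that the model family is an adequate
description of real bisphenol disposition.

The packaged chemical-property values (MW, logP, pKa) are standard; the
Papp, Kp/fu, kinetic-constant, ontogeny and variability tables are
synthetic placeholders (marked in their filenames and headers) chosen to
be physiologically plausible and to preserve qualitative orderings (BPB
glucuronidated fastest and BPS slowest; BPM with by far the highest
tissue partitioning; EHCr anchors above 0.63 with female > male). Absolute
predictions with these tables — e.g. the worked-example clearance and
excretion numbers — characterize the placeholder configuration, not any
measured system, and shift accordingly when user tables are supplied.

## Known limitations

- Single well-mixed blood pool; no separate arterial/venous or plasma
  compartments (the bile-to-plasma diagnostic treats blood as plasma).
- Luminal deconjugation is instantaneous and complete; a finite
  deconjugation/reabsorption kinetic would damp the recirculation loop.
- Metabolism uses total liver venous concentration (no fu_inc correction).
- No dermal/inhalation routes, pregnancy or elderly physiologies,
  intestinal glucuronidation, sulfation, or mixture co-exposure.
- Clearance diagnostics follow fixed conventions (0–24 h AUC windows;
  QL = the liver's direct arterial supply parameter in CL_bile = QL·EHCr;
  f_app uses the parent blood AUC) — alternative conventions change the
  reported numbers.
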