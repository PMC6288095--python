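# Methods

`nephrosim` is a closed-loop, lumped-parameter model of renal hemodynamics
and Na+/water homeostasis, reparameterizable across human, rat, and mouse,
extended with SGLT2-coupled glucose/Na+ reabsorption, glomerular albumin
handling, and pressure-driven adaptation/injury dynamics. Its purpose is
to simulate the disease trajectories of the db/db and db/db-UNX
(uninephrectomized) mouse models of diabetic kidney disease —
hyperfiltration, eventual GFR decline, and progressive albuminuria — from
mechanistic first principles, with the same equations across species and
only parameter values changing.

## Model structure

### Glomerular filtration

Single-nephron GFR follows Starling's law,

    SNGFR = K_f (P_gc − P_Bow − π_go-avg),      GFR = SNGFR · N_active,

with K_f the per-nephron ultrafiltration coefficient, P_gc glomerular
capillary pressure, P_Bow Bowman's-space pressure, and π_go-avg the mean
capillary oncotic pressure. SNGFR is floored at zero (filtration
equilibrium).

The renal vasculature is one preafferent resistance vessel feeding
N parallel nephrons: MAP → R_prea → R_aff → glomerulus → R_eff → R_peri →
vein (0 mmHg). Filtrate leaves the plasma stream at the glomerulus;
because ~99% of it is reabsorbed, the peritubular segment carries renal
blood flow minus urine output. The algebraic system in (RBF, SNGFR) is
solved by a damped Newton method (scipy `root`/hybr) at every evaluation
of the slow dynamics ("quasi-static inner solve"): minute-scale
circulation transients are irrelevant on the weeks scale of disease
progression, and eliminating them removes the stiffness they would cause.

**Oncotic closure.** π(C) is the Landis–Pappenheimer quadratic
(2.1·C + 0.16·C², mmHg, C in g/dl of total protein). The capillary
average is the flow-integral along the capillary (concentration
C₀/(1−FF·x) with x the filtered fraction of plasma flow):

    π_avg = 2.1·C₀·(−ln(1−FF)/FF) + 0.16·C₀²/(1−FF).

The integral average was chosen over the simpler arithmetic mean of the
two capillary ends because the latter is infeasible at the rat operating
point (filtration fraction ≈ 0.41 puts the end-average above the total
pressure budget, forcing a negative Bowman pressure); the integral
average keeps all three species feasible. Filtration fraction is guarded
at 0.9 (physiological-range error).

**Bowman's pressure.** P_Bow scales with tubular flow around its
calibrated nominal value, as a 50/50 blend of tubule inflow (SNGFR) and
proximal-tubule outflow. The outflow term encodes tubular backpressure:
when proximal reabsorption rises in diabetes, downstream tubular flow and
hence P_Bow fall, which raises net filtration pressure — one of the three
mechanisms (with TGF and Na+ retention) by which hyperfiltration is
achieved. The inflow term keeps P_Bow monotone in filtration, which makes
the glucose-plateau response band a clean envelope. Hematocrit is fixed
at 0.45 for all species (RBF ↔ plasma-flow conversion), configurable.

### Tubular transport

Glucose: filtered load is SNGFR·C_glu; reabsorption capacity is
RT_G·SNGFR (the renal threshold RT_G is therefore a concentration);
reabsorbed = min(filtered, capacity) and the excess is excreted. Urinary
glucose appears exactly when plasma glucose exceeds RT_G.

Proximal Na+: a fixed non-SGLT2 fraction (0.76) of the filtered load,
plus the SGLT2-coupled term equal to the *molar* glucose reabsorption
rate (1 Na+ per glucose, glucose MW 180 g/mol). SGLT1 is neglected as
small. At nominal glucose (90 mg/dl) the total proximal fraction is
0.76 + (90/18)/140 ≈ 0.796.

Distal segments reabsorb fixed fractions of their Na+ inflow: loop of
Henle 0.80 and distal convoluted tubule 0.50 (free closure parameters of
this implementation), and a collecting-duct fraction calibrated per
species so that baseline urinary Na+ equals intake exactly (mouse 0.52,
rat 0.81, human 0.78). Water: proximal reabsorption is isotonic (same
fraction as Na+); the loop reabsorbs Na+ without water (diluting
segment); a single calibrated distal water fraction closes urine volume
to water intake.

Albumin: filtered load K_albumin·SNGFR·C_albumin with C_albumin = 0.6·C_p
(plasma albumin is not tabulated separately; the fraction is
configurable). The proximal tubule recovers η_albumin = 0.99 of the
filtered load up to an absolute per-nephron capacity RC_albumin =
2.5×10⁻⁶ mg/min, beyond which the excess is excreted; urinary albumin
excretion (UAER) is therefore piecewise-linear and convex in the filtered
load with a kink where η·filtered = RC. η_albumin was calibrated once so
the healthy mouse sits in the wild-type range (~50 µg/day, below
100 µg/day); RC_albumin is interpreted per nephron (it is tabulated as
species-conserved, which a whole-kidney capacity could not be when
nephron numbers differ 200-fold), with a configuration switch.

### Systemic homeostasis

Two fluid states close the loop: the extracellular Na+ store and the ECF
volume. d(Na)/dt = intake − urinary excretion; d(ECF)/dt = water intake −
urine volume. Plasma Na+ is their ratio; blood volume is 0.25·ECF
(fixed partition, configurable); cardiac output is a saturating
increasing function of blood volume anchored at the species baseline
(CO = CO_nom·(1 + 0.8·tanh((V/V_nom − 1)/0.8))); MAP = CO·R_tpr with
venous pressure 0. ECF_nom is not tabulated in the source material and is
set to 15 L (human), 55 ml (rat), 5 ml (mouse) — ~20% of body weight.

Five bounded regulatory signals, each a tanh sigmoid anchored at 1 at the
calibrated baseline:

| signal | input | acts on | gain/width |
|---|---|---|---|
| TGF | macula-densa Na+ flow | afferent resistance (+) | 0.3 / 0.3 |
| myogenic | arterial pressure | preafferent resistance (+) | 0.5 / 0.25 |
| RIHP natriuresis | arterial pressure | DCT+CD Na+ fractions (−) | 0.68 / 0.35 |
| vasopressin | plasma Na+ | distal water fraction (+) | 0.9 / 0.02 |
| aldosterone-like | macula-densa flow deficit | CD Na+ fraction (+) | 0.1 / 0.5 |

Only the anchoring and signs are structural; the gain magnitudes are
free parameters of this implementation, calibrated once against the
published simulation outcomes (chiefly the 40 mmHg arterial-pressure rise
of the no-adaptation diabetic counterfactual) and then frozen. The
RAAS axis is reduced to the single small-gain aldosterone-like signal; no
pharmacological interventions are modeled. The RIHP pressure-natriuresis
signal is the integral controller of the loop: it guarantees that
long-run Na+ excretion tracks intake under any bounded forcing.

### Adaptation and injury

The damage signal is the relative glomerular pressure excess
GP_damage = max(P_gc/P_gc,0 − 1, 0), with P_gc,0 each species' healthy
baseline (mouse 37.5 mmHg). Five slow states respond:

* afferent dilatation ΔD_aa: rate (ΔD_max − ΔD)·max(BG−90,0)/τ_daa,
  ceiling 25%; the afferent resistance scales as 1/(1+ΔD)⁴ (Poiseuille);
* hypertrophy ΔSA: rate (ΔSA_max − ΔSA)·GP_damage/τ_SA, ceiling 50%;
* glomerulosclerosis ΔPerm: same form, ceiling 100%, ~53× slower
  (τ_perm/τ_SA = 4×10⁴/750);
* nephron loss ΔNephrons: (1 − ΔN)·GP_damage/τ_nephronLoss;
* sieving damage ΔK_albumin: a pure (non-saturating) integrator
  GP_damage/τ_albumin, additive on K_albumin,0 = 6×10⁻⁴.

K_f = K_f,0·(1 + ΔSA − ΔPerm) (clamped at 0) rises early and then falls —
the characteristic ultrafiltration-coefficient peak. All five states are
irreversible. Time constants are kept in the tabulated dimensionless
units; `time_unit_weeks = 3×10⁻⁴` converts them to weeks and was fixed by
requiring hypertrophy to reach ≥95% of its ceiling by week 12 of the
diabetic protocol (it reaches 99.6%), preserving the tabulated ratios.
Two constants are not tabulated and were calibrated once:
τ_nephronLoss = 1.5×10⁵, chosen so db/db GFR peaks near week 11–12 and
then declines slowly while the uninephrectomized arm declines to roughly
wild-type GFR by weeks 22–24 without a runaway pressure spiral; and
τ_albumin = 10⁷, much larger than every other time constant (ΔK_albumin
is an absolute increment on a 6×10⁻⁴ baseline, so small values of the
state are already large sieving changes), chosen so the db/db arm shows
moderate proteinuria (~230 µg/day at week 20) and the UNX arm overt
proteinuria (~16 mg/day).

### Calibration (per species)

Closed-form, executed at load time; idempotent:

1. R_tpr = MAP/CO (zero venous pressure).
2. SNGFR is the anchor; net filtration pressure = SNGFR/K_f,0; with the
   oncotic closure this fixes P_Bow,nom = P_gc − π_avg − NFP (error if
   ≤ 0: infeasible targets).
3. The tabulated preafferent and peritubular resistances split the
   pressure profile: R_aff = (MAP − P_gc)/RBF − R_prea and R_eff closes
   the downstream drop with the peritubular stream carrying RBF − urine.
   (For the mouse the resulting series sum reproduces the tabulated total
   renal vascular resistance to 1%.)
4. Collecting-duct Na+ and distal water fractions close excretion to
   intake exactly; all regulatory signals are anchored at 1.

Because the baseline is a steady state by construction, a wild-type
simulation is flat to machine precision, and the steady-state solver
reproduces the phenotype targets exactly. Note the published phenotype
table is not exactly Eq.-2-consistent for the human (GFR 105 ml/min vs
SNGFR 55 nl/min × 2×10⁶ nephrons = 110 ml/min); anchoring SNGFR, this
implementation's human GFR is 110 ml/min.

### Disease protocols

Blood glucose ramps from 90 mg/dl along a normalized logistic reaching
95% of the plateau (default 500 mg/dl, band 250–600) at week 10, the
shape chosen to match the composite longitudinal data; the exact forcing
shape is a modeling choice, constrained only by the plateau. Na+ and
water intake multipliers (1.5× and 5×) follow the same ramp. RT_G tracks
glucose, clipped to [180, 400] mg/dl, so urinary glucose stays minimal
below 400 mg/dl. Uninephrectomy is a discrete event (default week 8)
that halves the active nephron count and changes nothing else; the
integration is split into legs at the event. The slow system (7 states)
is integrated with BDF, rtol 10⁻⁷; halving the output step and
tightening tolerances changes week-20 GFR and UAER by <0.5%.

The glucose-band sweep is computed under a fully adapted glomerulus
(dilatation and hypertrophy fixed at their ceilings, injury dynamics
off, each arm started from its adapted steady state) — the stated
conditions of the published response-range envelope. Under those
conditions the response is monotone in the glucose plateau and the
250/600 arms bracket the 500 trajectory pointwise for GFR, P_gc, and
MAP. With dynamic injury the ordering can transiently invert by <1%
(faster dilatation at higher glucose), which is why the band is defined
at the adapted state.

Note on saturation ordering: with the tabulated constants, hypertrophy
(drive GP_damage/750) saturates *before* afferent dilatation (drive
(BG−90)/4×10⁶ ≈ 10⁻⁴ at plateau) under the diabetic protocol; both
saturate long before sclerosis. The robust, tested ordering is
adaptive-before-sclerotic.

## Synthetic composite data

`generate_synthetic_composite` emulates a multi-study longitudinal
GFR/UAER dataset around a simulated trajectory: a lognormal animal-level
random effect (scale 0.15) shared across weeks plus lognormal
observation noise (scale 0.10), biweekly sampling, n animals (default
10), seeded. It emulates between-animal/between-study *scatter* only: it
does not emulate assay floors, dropout, litter effects, or the
heterogeneity of glucose trajectories across studies, so a successful
parameter recovery on synthetic data shows identifiability under the
model's own assumptions, not robustness to real-data pathologies.

`fitting.DiseaseTrajectoryModel` refits injury time constants by
Levenberg–Marquardt least squares on log-residuals of the per-week
geometric-mean GFR and UAER. Joint recovery of (τ_perm, τ_nephronLoss)
from 10 synthetic animals is typically within 5–15%; the dominant error
source is the unmodeled common level shift from the animal random effect
(standard error ≈ 0.15/√10 ≈ 5% on both outcomes), which occasional
seeds can amplify beyond 20%.

## Numerical choices and degenerate inputs

* Inner solves warm-start from the previous time step; on failure a
  ladder of default starts is tried, then a convergence error with the
  residual vector is raised.
* The proximal Na+ fraction is clamped at 0.98 and total proximal
  reabsorption at the filtered load (logged); filtration fraction is
  clamped at 0.89 inside the solver residual and guarded at 0.9 in the
  oncotic closure.
* SNGFR is floored at 0 (filtration equilibrium); K_f is clamped ≥ 0;
  injury states are clipped to their intervals inside the right-hand
  side, and the integrator never overshoots them (property-tested against
  the closed-form exponential solutions to <10⁻⁶ relative error).
* Tied glucose threshold: at C_glu = RT_G exactly, excretion is 0.

## Known limitations

* End-stage behavior: sustained glomerular hypertension is a positive
  feedback (nephron loss → higher P_gc → faster loss). In the
  uninephrectomized arm the model approaches decompensation near the end
  of the 24-week horizon (MAP climbing toward the CO-saturation ceiling);
  trajectories beyond that horizon are not meaningful.
* The regulation gains are identified only jointly, by the calibration
  outcomes above; individual gains are not claimed to be measured
  quantities.
* No inflammation/growth-factor mechanisms, no RAAS pharmacology, no
  transporter-level kinetics, no potassium or acid–base handling; injury
  is driven by glomerular pressure alone.
* Fluid handling defends plasma Na+ within ~1–2 mmol/L rather than
  exactly; osmotic diuresis from glycosuria is not modeled.
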