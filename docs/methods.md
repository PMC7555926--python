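# Methods

## The model

`axotrace` simulates motor-axon excitability with a two-compartment
active-membrane model: a node of Ranvier and its internode, coupled by the
Barrett–Barrett conductance `G_BB` that represents the current pathways
through and under the myelin sheath.  The node carries transient Na⁺
(gates m³h), persistent Na⁺ (a fraction `f_NaP` of the total Na⁺
conductance, gate p³), slow K⁺ (s), fast K⁺ (n⁴) and leak; the internode
carries slow and fast K⁺, the hyperpolarization-activated HCN current
(gate q) and leak.  The Na⁺/K⁺ pump contributes a voltage-independent net
outward current `I_pump` split between compartments by `f_pump_node`
(default 0.0075, proportional to the nodal share of capacitance; the
split is a configuration choice, not an inference).  Driving forces are
ohmic, `G·(V−E)`; the calibration step absorbs the difference from a
GHK-flux formulation.  Units are self-consistent: mV, ms, pA, nS, pF.

The model always runs *unclamped*: after any parameter change the resting
potential of both compartments is re-solved (Newton iteration on the
steady-state currents, derivative tolerance 1e−6 mV/ms) and all gates are
re-equilibrated before any protocol is simulated.  This allows conductance
or pump perturbations to act partly through their effect on resting
membrane potential, which is essential to the pump-current analysis.

### Gating kinetics

Rates are config-defined `(form, A, B, C)` triples per gate family
(transient Na⁺ activation m and inactivation h, persistent Na⁺ p, slow K⁺
s, fast K⁺ nf, HCN q), with three functional forms: `linoid`
(`A(V−B)/(1−exp(−(V−B)/C))`, analytic limit `A·C` at `V = B`), `sigmoid`
(`A/(1+exp(−(V−B)/C))`) and `expg` (`A·exp((V−B)/C)`).  Fast Na⁺
activation uses mirrored exponential pairs (Borg–Graham form); h uses a
*saturating* sigmoid pair with independent forward/backward ceilings, so
that inactivation at spike voltages proceeds at a finite rate (a few
1/ms).  Without that saturation the inactivation time constant collapses
to microseconds at depolarized potentials and action potentials barely
overshoot 0 mV, which makes the 0 mV spike criterion fragile.  Slow K⁺,
fast K⁺ and HCN use complementary sigmoid pairs (voltage-independent time
constant), appropriate for gates whose kinetics should not accelerate
during the brief spike.  Each family carries a Q10; at the reference
temperature (37 °C default) the scaling is neutral.

The default parameter set in `data/default_axon.yml` is a calibration
artifact, not a measurement: it was obtained by fitting the
control-group excitability indices (see below) subject to qualitative
constraints — a single, clearly overshooting action potential per
suprathreshold stimulus and return to rest with no afterdischarge.
E_K ≈ −95 mV corresponds to [K⁺]ₒ ≈ 3–4 mM at 37 °C.  Because every
calibration index is a percentage, the index targets pin only conductance
*ratios*; the absolute scale (capacitances, conductances and baseline pump
current jointly) is a separate choice and is set for a small rat motor
axon, with a 1-ms nodal threshold near 40 pA — the scale at which a
15 pA pump-current change is an electrophysiologically meaningful
perturbation.  Rescaling all of these quantities together leaves every
percentage index exactly unchanged.

### Numerics

Integration uses a staggered semi-implicit scheme standard for
Hodgkin–Huxley threshold work: gates advance by exponential Euler against
voltage-indexed rate tables (0.05 mV grid, linear interpolation), then
the two potentials advance by a backward-Euler solve of the 2×2 linear
system with conductances frozen at the new gate values.  The scheme is
unconditionally stable, bitwise deterministic, and steps exactly onto
every stimulus edge; the default step is 0.01 ms (an argument, with
thresholds converging well below the bisection bracket when halved).  An adaptive stiff solver was
rejected: threshold tracking needs ~10⁵ short integrations per fit, and
the fixed-step scheme is orders of magnitude faster at equal threshold
accuracy (thresholds converge well below the 0.5 % bisection bracket as
dt is halved).

## Threshold tracking

"Threshold" is the minimal 1-ms current that elicits an action potential —
nodal potential crossing 0 mV within 3 ms of test onset — located by
bisection to a relative bracket of 0.5 % by default (fitting and
calibration runs tighten it to 7×10⁻⁴) and reported as the bracket
midpoint.  In a single-axon model the
response is all-or-none, so this replaces the experimental
40 %-of-maximal compound-potential tracking target.  The battery:

* **Strength–duration**: thresholds at 0.2–1.0 ms durations; Weiss-law
  regression of charge on duration gives rheobase (slope) and the
  strength–duration time constant (intercept/slope).
* **Threshold electrotonus**: 100 ms conditioning at ±20/±40 % of the
  control threshold, test pulses at log-spaced delays to 200 ms, threshold
  reduction in % of control; TEd 10–20 ms is the mean reduction of the
  +40 % curve over delays 10–20 ms.
* **Current–threshold (I/V)**: 200 ms conditioning from +50 % to −100 % in
  10 % steps, still on while the test pulse is delivered at its end; the
  resting slope is Δ(conditioning level)/Δ(threshold reduction) between
  the ±10 % points.
* **Recovery cycle**: 1 ms supramaximal (2× threshold) conditioning
  stimulus, test thresholds at interstimulus intervals from 2.5 ms
  (protocol minimum) to 200 ms.  Refractoriness = threshold change at
  2.5 ms; superexcitability = threshold *reduction* at 5 ms (positive =
  more excitable — with this sign the control group sits near zero and
  the cafeteria group clearly above it, matching the reported group
  difference); subexcitability = the maximum threshold increase over
  10–100 ms, floored at zero.

All percentages are relative to the unconditioned control threshold of
the same run.  Delay/interval lattices are config-exposed
(`ProtocolLattices`); the printed constraints (minimum interstimulus
interval 2.5 ms, 100 ms electrotonus, 200 ms I/V and recovery span, index
definitions at 2.5/5/10–20 ms) are honored by the defaults, while the
remaining lattice points are log-spaced choices.

## Fitting

The discrepancy between two excitability datasets is a weighted sum of
per-paradigm mean squared errors, `D = Σ_p w_p·mean_i(y_sim − y_rec)²`,
with y the percentage threshold change (100·log10(threshold) for the
strength–duration curve, making it scale-free) and paradigm weights
0.5 : 1 : 1 : 3 for SD : TE : I/V : RC.  The weight-only form is the
default; per-point variance normalization is a documented alternative a
caller can implement by rescaling curves.

Optimization is derivative-free (Nelder–Mead with an explicit 0.25-step
initial simplex, or bounded Brent for single parameters), in transformed
coordinates: conductances and capacitances move in log-space (positivity
structural), the pump current in units of 10 pA, `f_NaP` box-bounded in
[0, 1].  Multi-start is seeded; the first start is always the incoming
parameter set, so a fit can only improve on it.  Two fitting modes:

* `calibrate_baseline` fits index targets (group mean, scaled by the
  printed SEM) — published group data are index tables, so the baseline
  is calibrated against indices rather than full curves;
* `fit_parameters`/`single_parameter_scan` minimize the curve discrepancy
  from a calibrated baseline, with warm starts so that nested parameter
  sets are never worse than their sub-fits.

The single-parameter scan ranks each candidate membrane parameter by the
percentage discrepancy reduction its lone re-fit achieves; the
second-parameter analysis reports the incremental gain of each additional
parameter on top of the best single one, and is run once per dataset
(mirroring how the group-mean analysis is reported).

## Study statistics

Pure-function metabolic indices: HOMA-IR = insulin (mU/L) × glucose
(mmol/L)/22.5; TyG = ln(triglycerides (mg/dL) × glucose (mg/dL)/2); Lee
index = weight^(1/3)/naso-anal length (the sometimes-printed 0.33
exponent is available as a switch; on rat-scale values it sits ~2 %
lower, and 1/3 reproduces the published group values, so 1/3 is the
default).  Published TyG group values (9.87/10.30) are not reproducible
from the printed formula with the printed group means (which give ≈8.5);
the formula is implemented as printed and the inconsistency left as is.
The glucose-tolerance AUC is the trapezoid over the 0–180 min lattice.

Correlations use the exact t-transform `t = r·√(n−2)/√(1−r²)` with n−2
degrees of freedom, two-sided (Pearson on values, Spearman on midranks);
group comparisons run Shapiro–Wilk on each group and use the unpaired
t-test when both pass at α = 0.05, otherwise the two-sided Mann–Whitney
U.  Zero-variance groups route to Mann–Whitney.  The cohort pipeline
pairs superexcitability with each metabolic measure, choosing Pearson
unless either variable fails normality; p-values are unadjusted by
default (`--fdr` applies Benjamini–Hochberg).

The 50 % paw-withdrawal threshold uses the up–down (Dixon) staircase over
the 10-filament 0.4–15 g von Frey set, starting at 2 g: positive
responses step down, negative step up, and testing stops four stimuli
after the first response change or at either end of the set.  Runs that
stay positive to the weakest filament are assigned 0.4 g; runs negative
to the strongest are assigned 15 g.  Interior patterns are interpolated
as `10^(x_f + k·δ)` with x_f the log of the final filament, δ the mean
log-spacing, and the pattern coefficient k derived from a brute-force
probit maximum-likelihood oracle (ψ(g) = Φ((log g − log θ)/σ), σ = δ);
the oracle itself is exposed as an alternative estimator, and the k table
is generated from it on first use and cached.

## Synthetic cohort

Two diet groups (n = 14 each by default) are drawn from multivariate
normals whose means and SDs default to the study-scale summary statistics
(SD reconstructed from SEM at n = 14; fields without published spreads —
fat mass, lean mass, insulin — use realistic rat-scale values stated in
`cohort.DEFAULT_FIELD_STATS`).  Pairwise correlation targets between
superexcitability and the metabolic block are *pooled-cohort* values; the
generator inverts the pooled-covariance decomposition (within-group plus
between-group mean separation) to find the within-group correlation that
reproduces each pooled target, clips unattainable values at ±0.95 with a
log message, repairs the within-group matrix to the nearest positive
semi-definite one by eigenvalue clipping (also logged, and exposed as
`CohortConfig.realized_correlation`), and draws via Cholesky.  Values are
floored at 1 % of the group mean so masses and concentrations stay
positive.

Glucose excursions follow baseline + A·(t/t_peak)·exp(1−t/t_peak) on the
study lattice {0, 15, …, 180} min with Gaussian noise (the t = 0 point is
the rat's fasting glucose exactly); cafeteria-group parameters produce
higher areas under the curve.  Von Frey response sequences are drawn from
the probit psychometric with a per-rat latent threshold (log-normal per
group) and follow the up–down rules exactly.  "Recorded" excitability
curves run the full battery and multiply every measured threshold —
control threshold included — by exp(ε), ε ~ N(0, (noise_sd/100)²), then
recompute the percentage curves, as a real tracker would.

What the generator does *not* emulate: longitudinal growth and intake
trajectories, measurement dropout, within-animal repeat variability, or
any skew in the per-rat superexcitability distribution.  Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes
— not that the assumptions hold for any particular real dataset.

## Problem sizes and tolerances

Baseline calibration uses the reduced index lattice (only the thresholds
the five indices are defined on, ≈20 per evaluation), a 7×10⁻⁴ bisection
bracket, two seeded Nelder–Mead starts and a 400-evaluation budget per
start.  Curve fits in scans use bounded Brent with ≈20 evaluations per
candidate.  The pump-recovery study uses 10 seeds at 1 % log-threshold
noise on the full protocol lattices.  These sizes were chosen so the full
analysis reruns in minutes on one core; all of them are arguments, not
constants.

## Known limitations

* The model is a single axon; compound-action-potential phenomena
  (stimulus–response slope, amplitude dimensions) have no analogue here.
* Ion concentrations are static; the pump is a constant current, so
  activity-dependent pump modulation is out of scope.
* The calibrated parameter set is one point in a degenerate manifold —
  index targets constrain five numbers, the model has many more degrees
  of freedom.  No claim is made that the calibrated coefficients equal
  those of any published fitting software.
* The action potential overshoots to ≈+20–45 mV, lower than textbook
  nodal recordings; this does not affect threshold behaviour, which is
  what the battery measures.
* In this model a reduced pump current depolarizes the axon and slightly
  *decreases* 5 ms superexcitability (the classical membrane-potential
  dependence), monotonically over the whole admissible pump range.  A
  pump-only re-fit against the cafeteria-group indices therefore moves the
  pump in the right direction (down, driven by the refractoriness
  increase) but cannot reproduce that group's raised superexcitability;
  extensive searches over the model's conductances, kinetics and reversal
  potentials bound the attainable pump-to-superexcitability sensitivity
  two orders of magnitude below what a +2.8 % swing per −15 pA would
  require.  Reproducing that coupling evidently needs mechanisms outside
  this architecture (e.g. pump–concentration coupling or non-ohmic
  fluxes).
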