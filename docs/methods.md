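# Methods

## Model structure and assumptions

The body is represented as nine perfusion-limited tissue compartments
(fat, liver, brain, kidney, muscle, skin, vessel-rich tissue, skeleton,
red marrow) connected in parallel between an arterial and a venous blood
pool.  Perfusion-limited means tissue uptake is instantaneous relative to
blood delivery, so the venous outflow of tissue T carries
`C_T / P_T`, where `P_T` is the equilibrium tissue:blood partition
coefficient.  Lungs and heart close the circulation as a zero-volume
pass-through: arterial blood receives the pooled venous return unchanged.

State variables are the tissue concentrations, the two blood
concentrations, and the cumulative amount metabolized:

* non-metabolizing tissue: `V_T dC_T/dt = Q_T (C_A − C_T/P_T)`
* liver additionally loses `RAM = V_max · C_VL / (K_m + C_VL)` with
  `C_VL = C_liver / P_liver` — the well-stirred, flow-limited reading in
  which the venous-equilibrium concentration drives the enzyme.  This is
  the only reading that reproduces the planned-schedule plateau
  (~4.1 mg/L) from the default constants.
* venous blood: `V_ven dC_ven/dt = Σ_T Q_T C_T/P_T − Q_tot C_ven + r(t)`,
  where `r(t)` is the iv input (infusions and boluses enter venous blood);
* arterial blood: `V_art dC_art/dt = Q_tot (C_ven − C_art)`.

`Q_tot` is the sum of the per-tissue flows (390.0 L/h at reference), not
the nominal cardiac output (401.7 L/h); using the per-tissue flows for
the venous→arterial transfer keeps compartment-level mass balance exact
without inventing a shunt for the missing 11.7 L/h.  The nominal cardiac
output is retained as metadata and as a validation bound (tissue flows
may not exceed it by more than 5%).

The observed "plasma concentration" is identified with the venous blood
compartment; the blood:plasma ratio is taken as 1 (protein binding is
8–12%, and no ratio is reported for 5-FU).  Whether published
concentrations are arterial or venous is generally unstated; in this
model the two blood pools coincide at an infusion steady state (the
liver's venous-equilibrium concentration sits `rate/Q_liver` below them),
so the choice matters only transiently, and venous is assumed throughout.

## Parameters

| group | values | notes |
|---|---|---|
| tissue volumes (L) | fat 18.2, liver 1.8, brain 1.45, kidney 0.31, muscle 0.40·bw, skin 0.0371·bw, vessel-rich 2.6, skeleton 6.9, red marrow 1.2 | only muscle and skin scale with body weight; all others stay at the 73-kg reference |
| tissue flows (L/h) | 19.5, 99.5, 46.8, 74.1, 65.8, 20, 44.8, 7.8, 11.7 | fixed, independent of body weight |
| partition coefficients | 0.20, 0.92, 1.35, 0.98, 2.19, 10.04, 0.98, 0.63, 0.92 | taken as given (produced upstream by a biologically-based algorithm); the skin value 10.04 and muscle 2.19 are surprising for log K_ow −0.89 but are used verbatim and remain overridable |
| blood | 5.3 L total at 73 kg, scaled linearly with bw; 1/3 arterial, 2/3 venous | ICRP-style reference values; absent from the source parameter table |
| metabolism | V_max 1221.7 mg/h, K_m 11.7 mg/L | population-PK means; an alternative K_m of 11.1 mg/L circulates in the same literature and is available via config — the parameter table of record wins |
| dosing | mg/m² doses resolved via BSA (default 1.8 m², DuBois formula available) | |

Inter-subject variability is exposed only as a multiplicative scale on
V_max (`--vmax-scale`, config `vmax_scale`): the literature clearance
confidence interval has no published mapping onto these constants, so
variability bands are illustrative rather than calibrated.

## Numerics

The ODE system is integrated with LSODA (via `scipy.integrate.odeint`),
piecewise between input-rate breakpoints so the solver never steps across
a rate discontinuity.  An iv bolus is realized as a 1-minute constant-rate
infusion, avoiding discontinuous initial conditions while preserving
bolus kinetics on the 0.1-h scale.  Default tolerances are rtol 1e-8,
atol 1e-10 mg/L; the output grid is fixed (0.01 h during infusions,
0.05 h after) rather than solver-chosen, so trapezoidal integrals are
reproducible.  The first hour after every rate change keeps the fine
spacing: the post-pulse distribution transient (venous time constant
~0.01 h) otherwise dominates the trapezoidal AUC error on short pulses.

Three checks guard every simulation: concentrations more negative than
1e-6 mg/L abort with an error (smaller excursions are clipped to zero);
the final mass balance `|dose − in_body − metabolized|/dose` must be
within 0.1%; and solver failures name the offending regimen.  The
closed-form infusion steady state (`C_V = rate·K_m/(V_max − rate)`,
`C_A = C_V + rate/Q_liver`) is used in the tests as an independent oracle:
simulated plateaus agree with it to well under 0.5%.

Cohort work uses a throughput preset (rtol 1e-6, atol 1e-8, grid
0.02/0.1 h): per-patient AUC and C_ss agree with the dense default grid
to better than 0.1% (property-tested), at several-fold lower cost.  The
full-profile AUC horizon integrates until the venous concentration falls
below 0.1% of its peak; the washout window is sized from the mass dosed
above metabolic capacity and doubled as needed, so schedules whose
infusion rate exceeds V_max (which accumulate drug zero-order) are still
integrated to washout.

## Exposure metrics

* `auc(profile, t0, t1)` — trapezoid on the fixed grid, with interpolated
  off-grid endpoints; adjacent intervals split at a grid point add exactly.
* `css_observed` — mean venous concentration over the final 10% of a
  constant-rate infusion, flagged non-plateau when the relative slope
  exceeds 1%/h.  Steady state is considered reached only for infusions of
  at least 5 h; shorter administrations report the peak in the C_ss slot
  with a `no_plateau` flag (a convention this package chooses — no
  steady state exists for a bolus, yet cohort analyses need one exposure
  value per patient).
* `css_from_auc` — the identity C_ss = AUC/infusion time, applied (as the
  source TDM studies did) to whole-course AUCs.  This slightly overstates
  C_ss because pre-plateau hours are included; no correction is applied,
  matching field practice.
* `fraction_of_steady_state` / `predict_css_from_cdyn` — the early-sampling
  rule.  One hour into a 24-h infusion the model puts the venous
  concentration at ~52% of the plateau, which is the quantitative basis
  for forecasting C_ss as twice the 1-h sample.

## Cohort analysis

`binned_fraction` uses right-open bins of width 1 mg/L anchored at 0
(matching how concentration ranges are reported clinically); empty bins
carry an undefined (NaN) fraction.  `fit_stump` performs the exhaustive
depth-1 CART search: both features (C_ss, AUC), candidate thresholds at
midpoints of consecutive distinct sorted values, Gini impurity decrease
as the criterion, minimum leaf size 1, ties broken toward the C_ss
feature and then the smaller threshold.  Single-class input yields a
documented degenerate majority model rather than an exception.  The fit
is verified in the tests against a brute-force enumeration oracle and
cross-checked against scikit-learn's CART implementation.

## Synthetic data

Neither clinical dataset behind the analysis is published at the
individual level, so two seeded generators stand in.

`make_ma_like_cohort` emulates a dosing/outcome cohort of 138 patients
(86 life-threatening / 52 non-life-threatening).  Dose rate and infusion
duration are drawn log-uniformly over 50–2000 mg/h and 0.25–96 h —
ranges chosen to straddle both the published dose-rate/dose cut-offs and
the 6 mg/L concentration boundary, and to decorrelate C_ss from AUC
(long low-rate vs short high-rate regimens).  Each candidate is simulated
through the identical exposure pathway the cohort analysis uses, labeled
life-threatening iff its modeled C_ss (or peak, for short administrations)
exceeds the true threshold of 6 mg/L, flipped with probability 0.02, and
accepted while its class quota is open.  The real cohort's joint
dose/duration distribution is unknown; these ranges are this package's
choice and outputs are labeled synthetic.

With 2% independent label flips, an expected 2.8 labels per cohort are
wrong.  When a flip happens to hit a record adjacent to the 6 mg/L gap,
the Gini-optimal split moves to a neighboring gap — a property of any
exhaustive single-split fit, not of this implementation — so
threshold-recovery holds in roughly 9 of 10 seeded cohorts rather than
always; the recovered split stays within a few tenths of a mg/L of the
true threshold in those cases, and the C_ss-over-AUC feature choice is
recovered essentially always.

`make_auc_study_like` emulates 321 whole-course AUCs at 1000 mg/m² per
24 h (94 with non-life-threatening toxicity, mean ± SD 82.2 ± 21.8
mg·h/L; 227 without, 58.3 ± 21.0), as truncated normals on 9.5–126.3
mg·h/L.  Two deliberate choices: the location parameter is moment-matched
so the *truncated* mean equals the target group mean (the published
statistics describe the observed sample, not a latent parent normal);
and the no-toxicity SD uses 21.0, consistent with the published IQR
(44.2–72.7) under approximate normality — the alternative printed value
(68.1) is irreconcilable with both the IQR and the range for n = 227 and
would make the truncated distribution effectively uniform.

What the generators do not emulate: real covariance between dose choice
and patient state (doses are independent of body weight and of each
other), per-patient clearance variability (all patients share V_max and
K_m), measurement error in concentrations, and the source cohorts' exact
dose/duration mix.  Passing tests therefore demonstrate that the pipeline
recovers structure it is designed to recover under realistic sampling —
not that the clinical datasets themselves would yield the same numbers.

## Known limitations

* Single parent compound: no tissue-specific DPD expression, prodrugs,
  metabolites, circadian enzyme rhythms, or tumor compartments; DPD-deficient
  patients (prevalence below 1% for therapeutically relevant variants) are
  out of scope.
* Body-weight scaling touches only muscle, skin and blood volumes; organ
  flows stay at reference values, so extreme body weights stretch the
  model's validity.
* The partition-coefficient set is taken as given; the tissue types are
  pluggable for users who compute their own.
* Variability bands scale V_max only and are not calibrated to any
  published clearance distribution.
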