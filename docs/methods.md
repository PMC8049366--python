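# Methods

## Scope and data flow

`mirdkit` analyses whole-body PET biodistribution studies of short-lived
radiotracers. Inputs are extracted per-organ time–activity tables (fraction
of injected activity, FIA, versus minutes post-injection), venous
blood/plasma sample tables, and an S-value table for a reference phantom;
image reconstruction and VOI delineation are upstream and out of scope.
The pipeline runs: decay handling → sums-of-exponentials fitting →
residence times (with a dynamic bladder model) → MIRD organ doses →
ICRP-103 effective dose, in parallel with the blood-side pharmacokinetics.

## Time–activity modelling

Curves are fitted in the **decay-corrected domain** and physical decay is
added analytically at integration (τ = Σ Aᵢ/(λᵢ+λ_p), minutes → hours).
Fitting raw curves instead would fold λ_p into every rate and condition the
problem worse; the domain is recorded on each fitted model so decay can
never be applied twice. Model order (1–3 terms) is selected by the
small-sample corrected Akaike criterion with ties resolved toward fewer
terms; a residual floor of (10⁻¹² × data scale)² per point makes
numerically exact fits of different orders tie, again preferring fewer
terms. Fits are nonnegativity-constrained trust-region least squares with
multi-start: rate combinations are drawn from a fixed log-spaced grid
(plus λ = 0 to represent plateaus such as long-term bone retention) and
amplitudes solved by NNLS before joint refinement at tolerance 1e-14. The
procedure is deterministic and seedless. Beyond the last scan the model
extrapolates itself; no physical-decay-only tail is forced.

λ = 0 terms are permitted in fitting; integration handles them through λ_p
alone, and a model with a genuinely undecaying term in the raw domain is
rejected as divergent.

## Dynamic bladder model

Decay-corrected bladder content between voids grows as
f·(e^(−λ_b t_k) − e^(−λ_b t)) from the last void at t_k; physical activity
is that content times e^(−λ_p t); the bladder empties completely every T_v
(default 3.5 h). Per-cycle integrals are closed-form and the cycle series
is summed until the increment falls below 1e-10 of the running total. The
T_v → ∞ limit is f·λ_b/((λ_b+λ_p)·λ_p) — 0.429 h at f = 1, T_b = 191 min —
and T_v → 0 voids everything. The filling parameters (f, λ_b) are fitted
from the observed bladder curve as B(t) = f·(1 − e^(−λ_b t)); the excreted
fraction can also be derived as 1 minus the non-bladder plateau retention
and overridden in configuration.

## Remainder of body

The remainder is computed by subtraction, the standard MIRD route: the
whole-body curve (pointwise sum of all source curves, including the bladder
as observed, i.e. un-voided) is fitted and integrated, and the source-organ
TIACs are subtracted. Direct fitting of the sampled remainder curve — a
difference of many exponentials — is used only as a fallback when curves do
not share a time grid; at a 6-point schedule it carries ~1% integration
error that the subtraction route avoids. Because whole-body FIA cannot
exceed 1, the whole-body TIAC is capped at the physical mean life
(T_p/ln2 = 1.635 h for ⁶⁸Ga); noisy fits may otherwise overshoot it
slightly. The invariant Σ τ ≤ T_p/ln2 is asserted on every pipeline run.

## Dose engine and effective dose

D(target) = Σ_source τ·S(target←source) with τ in hours and S in
mSv/(MBq·h), giving μSv/MBq; the engine is linear in τ and takes any
S-value CSV (a synthetic toy phantom ships for tests — it is labelled
synthetic and represents no published phantom). For a pure
positron/photon emitter the radiation weighting factor is 1, so absorbed
and equivalent dose coincide numerically.

Effective dose uses the bundled ICRP-103 weights (they sum to 1 exactly)
with the conventional mappings: colon = mean of left and right colon,
gonads = testes on a male phantom, bone surface = osteogenic cells, and
remainder = arithmetic mean of the 13 male remainder tissues. Weighted
tissues absent from a dose report are substituted by the whole-body dose
(default) or dropped with weight renormalisation; with no policy an error
is raised. The colon mapping deliberately excludes the rectum: the
mass-weighted ICRP colon used by some codes includes it, but the two-colon
mean is the policy consistent with the published coefficient range this
package checks itself against. E always lies within the [min, max] organ
dose when weights sum to 1, and this is asserted.

## Blood pharmacokinetics

All PK runs on decay-corrected data (biologic, not effective, parameters).
The plasma:blood ratio and protein-bound percentage are per-sample
arithmetic with mean ± SD. The parent fraction is a monotone
exponential-plus-plateau fit, clipped to [0, 1] on evaluation — anchoring a
steep two-point decline (79% at 1 min, 4% at 10 min) can push amplitude +
plateau slightly above 1 at t = 0, and the clipped region ends before the
first venous sample. Metabolite correction is the pointwise product of
total plasma activity and f_parent(t), which never increases a
concentration.

The terminal slope is log-linear least squares on samples from
`tail_start` (default 60 min, past the fast distribution phase). AUC₀→∞
uses linear-up/log-down trapezoids, log-linear back-extrapolation from the
first two samples to t = 0, and a C_last/λ tail; the extrapolated fraction
is recorded and results above 50% are flagged unreliable. A plain linear
trapezoid and a model-based AUC (analytic integral of a fitted exponential
sum) are selectable; the model route is exact when the kinetics truly are
multi-exponential, while sample-based trapezoids carry ~0.2% discretisation
error at the 13-point venous schedule. Clearance is injected activity over
AUC (plasma analyte), in mL/min. The very low "total radioactivity"
clearance seen in such studies reflects long-lived radiometabolites
dominating late plasma activity; the package treats only the ordering
CL_parent > CL_total as meaningful.

## Synthetic subject generator

The generator emulates the study conditions of a six-subject cohort: 80 kg
body weight, 162 MBq injected, the 6-scan whole-body schedule
(1–200 min, frames 30–360 s) and 13-point venous schedule (2–240 min).
Renal excretion removes f_u = 0.85 of the injected activity at rate
ln2/191 min⁻¹; organ washout amplitudes are invented to match the
qualitative early heart/liver/kidney pattern with small long-lived bone
retention; the remainder of body closes the mass balance exactly
(Σ organs + remainder + bladder + voided = 1 at every instant, before
noise). Urine volume grows as 50 mL + 1.25 mL/min, putting the peak
bladder SUV near 114; the dehydration outlier halves urine production
(volume 30 mL + 0.625 mL/min), roughly doubling the bladder SUV while
leaving organ kinetics untouched. Plasma is biexponential
(12 kBq/mL·e^(−ln2/4·t) + 4 kBq/mL·e^(−ln2/106.9·t)), whole blood is
plasma/1.7, the parent fraction is anchored at 79.2%/4.3% (1/10 min) with
a 2% plateau, and protein binding drifts linearly 13.3% → 42.7% over
240 min. Noise is multiplicative mean-one lognormal, σ = 3% at a 60 s PET
frame scaled by (frame/60 s)^(−1/2), and a constant 3% for γ-counter
samples — a simple stand-in for counting statistics. By default no voids
occur during the session (subjects imaged continuously).

What the generator does **not** emulate: partial-volume and spill-over
effects, VOI delineation error, inter-subject kinetic variability beyond
parameter overrides, arterial–venous differences, and any receptor-binding
(compartmental) structure. Passing recovery tests therefore demonstrates
the correctness of the fitting and integration machinery under the stated
noise model, not robustness to every artefact of real PET data.

Ground truths are closed-form (organ TIACs, remainder, bladder integral,
total-activity AUC); the parent AUC uses adaptive quadrature because the
clipped parent fraction is piecewise. Recovery tests use 50 replicates at
the default noise level and compare medians; noise-free recovery is exact
to ~1e-12 for TIACs and to <0.1% for total-activity clearance and
half-life (via the model-based AUC; the trapezoid route is documented
above). Problem sizes throughout the suite (50 replicates, 100-model
oracle sweeps, 100-seed property sweeps) were chosen to keep the full test
run to a few minutes while giving stable medians.

## Numerical and interface choices

* Times are minutes post-injection (mid-frame); activities are FIA
  normalized at t = 0; concentrations are kBq/mL; TIACs are hours; doses
  μSv/MBq; effective dose mSv/MBq; administered doses reported to
  2 significant figures (full precision retained internally).
* Organ names are matched case- and punctuation-insensitively, with alias
  tables for the usual phantom naming variants; unresolvable names raise
  errors listing the candidates.
* Human-readable tables round TIACs to 4 d.p., organ doses to 1 d.p. and
  effective dose to 3 d.p.; JSON keeps full precision, and all CSV writers
  use shortest round-trip float representation so write→read is lossless.
* The pipeline manifest records the config hash and seed; identical config
  and seed reproduce outputs byte-for-byte.

## Known limitations

* The bladder filling fit assumes a single excretion rate and no voids
  during the imaging session; fractionated or interrupted sessions need
  explicit void times.
* The effective dose is computed on a single (male) phantom with a
  substitution policy for absent tissues, not the ICRP sex-averaged
  two-phantom construction.
* Urinary-void-based estimation of urinary clearance is exposed only
  through the voids table of the simulator; no published void data exist
  to validate it against.
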