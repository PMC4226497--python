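# Methods

## Model

The lung is lumped into five first-order compartments over the counts of a
deposited radiolabeled probe: a ciliated central sub-compartment `L_M`, a
non-ciliated central sub-compartment `L_N`, a distal compartment `D`
(small/intermediate airways plus alveoli), and two unobserved sinks,
trachea `T` and blood `B`. Initial conditions come from the first imaging
frame: `L_M(0) = FFCA·c0`, `L_N(0) = (1−FFCA)·c0`, `D(0) = p0`, where `c0`
is the central-ROI count, `p0` the peripheral count (whole-lung minus
central), and FFCA the fraction of functional ciliated airway. A further
10% of the *inhaled* dose is booked to the trachea
(`T(0) = 0.10/0.90·(c0+p0)`); since `T` and `B` never enter an observable,
this choice affects only mass-balance bookkeeping, and total mass is
conserved by construction.

Fluxes: MCC moves counts from `L_M` to `T` at `k_LT` (min⁻¹); absorption
moves counts to `B` from the central region at `k_LB` and from the distal
region at `k_DB`. The optional Case-2 route moves counts from `D` to `L_M`
at `k_DL` (zero in the selected structure: distal MCC is too slow to
resolve over an 80-minute study, and freeing it destroys identifiability —
see below). The particle probe (Tc-SC) has `k_LB = k_DB = 0` identically;
the small-molecule probe (In-DTPA) shares `k_LT`, FFCA (and `k_DL`) with
the particle, because both deposit from the same aerosol and ride the same
mucus.

The system is linear, so `solve_compartments` evaluates the exact
matrix-exponential solution (`expm(A t) x0`); the observable curves use
explicit scalar exponentials, with the `b → a` degenerate limit of the
Case-2 coupling term handled analytically. A generic numerical integrator
(`scipy.integrate.solve_ivp` at `rtol 1e-10`) serves as the independent
cross-check in the tests and the acceptance script; agreement is at the
1e-7 relative level over random parameter draws.

Observables: whole-lung retention `(L_M+L_N+D)/(c0+p0)`, central retention
`(L_M+L_N)/c0`, and absorption = particle retention − small-molecule
retention. All fitting uses whole-lung retention (the clinical analyses
present lung-level curves); central-ROI retention is computed and exposed
but not fit by default.

## Estimation

Two sequential stages, mirroring the clinical procedure:

1. `(k_LT, FFCA)` minimize the pooled squared residuals between each
   subject's frame-0-normalized Tc-SC whole-lung retention and the model
   curve with that subject's own frame-0 deposition; all subjects and all
   frames of a group are pooled (N = 80·n points).
2. `(k_LB, k_DB)` minimize the pooled residuals of the per-subject
   absorption series with stage-1 estimates frozen.

Defaults: unweighted residuals (an inverse-variance Poisson weighting is
available via `weights="poisson"`; the clinical weighting factor is not
recoverable, so weights of 1 are the default), bounds `[0, 1] min⁻¹` on
rates and `[0, 1]` on FFCA, initialization `k_LT=0.03, FFCA=0.5,
k_LB=0.005, k_DB=0.01, k_DL=0.001`, and 5 multistart launches (the default
start plus 4 log-normally jittered starts, seeded by `random_state`) with
best-RSS selection. The saline inhalation at study minute 10 is not
modelled as a parameter switch; one parameter set describes a group/day.
Isotope decay correction (half-lives 6.01 h for Tc-99m, 67.3 h for In-111)
is available behind a flag and off by default, on the assumption that
deposited counts are already decay-corrected.

Confidence intervals use the standard nonlinear-regression covariance
`s²(JᵀWJ)⁻¹` with `s² = RSS/(N−k)` and a Student-t quantile. A
rank-deficient `JᵀWJ` raises an unidentifiability error; fits degrade this
to infinite CIs with a warning so degenerate data (e.g. flat retention)
still return a result. A parameter whose CI half-width exceeds 5× its
estimate is flagged practically unidentifiable — the expected outcome for
`k_DL`, whose nominal estimate collapses to the zero bound on data without
a distal MCC route.

Prediction envelopes evaluate the model at every combination of
{lower, nominal, upper} per fitted parameter (3^k curves, k ≤ 5), clip
FFCA to [0, 1] and rates to ≥ 0, and take pointwise extremes; the nominal
curve is bit-identical to the point-estimate curve. Group contrasts use a
Wald z on the difference of estimates with pooled standard errors.

Model-structure selection refits each candidate (nominal; Case 1 with
`k_LB ≡ 0`; Case 2 freeing `k_DL` in stage 1) and ranks by the
Gaussian-error AIC, `N ln(RSS) + 2k`, pooling both stages' residuals into
a single RSS with the shared per-probe N and counting only regressed
parameters in k (4, 3 and 5 respectively). Per-stage AICs are also
reported. Zero RSS is rejected as degenerate: on exactly noise-free data
the RSS reaches machine epsilon and log-RSS comparisons become
meaningless, so structure-ranking properties are exercised on data with
counting noise.

## Synthetic data

`simulate_scan_dataset` emulates the study design: 80 one-minute frames,
two probes per subject, a central/peripheral deposition split (defaults
`c0 = p0 = 5·10⁴` counts — order-of-magnitude for a lung ROI in a dynamic
scintigraphy frame; the true magnitudes are not published and are
configurable), Poisson counting noise applied independently to the central
and peripheral expectations per probe (so whole = central + peripheral
exactly, preserving the nested-ROI convention), and inter-subject
variability as unit-mean log-normal factors on rate constants and a
logit-normal perturbation on FFCA (delta-method-matched to the requested
CV; default CV 0.2). Built-in group parameter sets carry the published
`k_LT` and `k_DB` estimates for the four clinical groups (non-CF, CF on
isotonic/hypertonic saline, pediatric CF) with group sizes 9/12/11/9;
FFCA and `k_LB` values are not printed in the source tables, so the
defaults encode the qualitative findings (FFCA high in health, depressed
in CF, partially restored by hypertonic saline; `k_LB ≈ k_DB` at baseline
and insensitive to hypertonic saline).

What the generator does *not* emulate: temporal correlation of counts from
the persistence of the same deposited particles across frames (frames are
independent Poisson draws around the model mean), ROI misregistration,
scatter/crosstalk between the two isotope windows, and any intra-subject
parameter drift (e.g. a response to the minute-10 saline). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under idealized counting statistics, not robustness to those
clinical artifacts.

`simulate_image_stack` emulates the in vitro assay: 10 frames, an active
region (contiguous block or speckled pixels) whose intensity alternates
with a set amplitude frame to frame, plus Gaussian sensor noise
everywhere, returning the ground-truth mask.

## In vitro assay

Per pixel, the activity metric is the mean absolute successive-frame
intensity difference (computed in float, so unsigned integer frames cannot
wrap), the most literal reading of "average change in pixel intensity";
the threshold is the grand pixel mean of that metric over untreated
control cultures (a per-culture mean-of-means variant is available), and
the functional fraction is the proportion of pixels strictly above
threshold. Color frames are reduced by BT.601 luminance; no registration
or illumination normalization is applied by default (an optional per-frame
mean subtraction exists).

Two properties of this thresholding rule matter for interpretation. First,
if the controls are *static* (pure sensor noise), the threshold sits at
the centre of the noise distribution and ≈50% of inactive pixels exceed it
by symmetry — ground truth cannot be recovered that way, and a test
documents the effect. Recovery tests therefore use control cultures that
are themselves half active at the same flicker amplitude, which places the
grand-mean baseline midway between the static and flickering pixel
populations; there the assay recovers generator active fractions 0.1–0.9
to within 0.02 at amplitudes ≥ 5× the noise SD. Second, the absolute
threshold depends on the control population, so in vitro fractions are
comparable only against a common baseline. The in vitro pixel fraction and
the in vivo FFCA model parameter are kept as distinct quantities
throughout.

## Numerical choices and problem sizes

Tolerances: optimizer `xtol = ftol = gtol = 1e-12`; closed-form vs
integrator agreement asserted at rel. 1e-6 (measured ~1e-7); noise-free
parameter recovery asserted at 1e-4 (measured ~1e-14). Ties at the assay
threshold count as non-functional. Degenerate inputs (flat series, zero
frame-0 counts, single-frame stacks, zero RSS) raise typed errors or
documented warnings rather than silent results. Simulation-based checks
use 100 replicates for recovery/coverage, 50 for structure recovery, 20
for `k_DL` identifiability, and 128×128×10 stacks for the assay — sizes
chosen so the full suite runs in well under a minute of compute while
leaving Monte-Carlo error far below the asserted margins.

## Known limitations

* **Anticonservative CIs.** Because every frame of a subject is divided by
  the same noisy frame-0 count, residuals within a subject share a common
  multiplicative error, violating the independence assumption behind
  `s²(JᵀJ)⁻¹`; the absorption stage additionally ignores stage-1
  uncertainty. Measured coverage of the 95% CIs under Poisson study
  conditions is ~0.4–0.85 depending on the parameter (near-nominal when
  the frame-0 normalizer is exact). The construction is retained because
  it is the standard one for this analysis; treat the CIs as lower bounds
  on uncertainty.
* **Central/distal absorption split is sloppy.** With only the whole-lung
  observable, `k_LB` and `k_DB` are nearly collinear (their sum is
  determined ~8× more precisely than their difference), and the sloppy
  direction carries a noise-induced nonlinear-LS bias that grows as FFCA
  falls (≈ +14% on `k_DB` for CF-like parameter sets at 10⁵-count
  statistics). Fitting the central ROI jointly would condition the split
  but is deliberately not the default observable.
* **Structure selection near the boundary.** The correlated residuals also
  inflate the apparent RSS gain of the superfluous `k_DL`, so the nominal
  structure wins the AIC comparison in ~85% of replicates rather than the
  ~92% an iid-noise boundary argument predicts.
* The generator omissions listed above; AVI reading requires an imageio
  codec plugin; AICc/BIC are not implemented (not used in this analysis).
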