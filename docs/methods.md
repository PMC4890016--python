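# Methods

This note documents the models, numerical choices and known limitations of
`facedcm`. It states how quantities are computed; every empirical number it
mentions is produced by the test suite or `scripts/acceptance.py`.

## Generative model

Neural dynamics over the six regions (EVC, OFA, FFA × both hemispheres)
follow the bilinear form

    dz/dt = (A + Σⱼ uⱼ Bʲ) z + s_C · C u

with endogenous coupling A (Hz), modulations Bʲ of the coupling by
experimental input uⱼ, and driving inputs C. The inputs are the five block
boxcars `RVF`, `LVF`, `faces`, `faces|RVF`, `faces|LVF` on a microtime grid
(default TR/16).

**Driving-input scale `s_C = 1/16`.** The software generation in which the
group parameter tables used by the cohort generator were estimated applies
a 1/16 factor to the driving term (a convention historically tied to the 16
microtime bins per scan). The tables' driving strengths (~0.7–0.9 Hz) are
only physiologically interpretable under that convention: with `s_C = 1`
they push steady-state neural activity to z ≈ 1.5–4, the haemodynamic
model deep into saturation (±10 % BOLD and worse), and the free-energy
landscape into multimodality. With `s_C = 1/16` the same numbers produce
sub-percent responses in the quasi-linear regime. `neural_derivative`
exposes the bare equation (no scale); `simulate_bold`, `integrate_batch`
and `DCM` take `driving_scale` (default `DRIVING_SCALE = 1/16`) so the
convention is explicit and overridable. Simulation and inversion always use
the same convention, and modulatory effects use the unscaled inputs.

Each region's activity drives a balloon/windkessel model — vasodilatory
signal s, inflow f, venous volume v, deoxyhaemoglobin q:

    ds/dt = z − κ s − γ (f − 1)        df/dt = s
    τ dv/dt = f − v^{1/α}              τ dq/dt = f E(f,E₀)/E₀ − v^{1/α} q/v

with E(f,E₀) = 1 − (1−E₀)^{1/f}, and BOLD (percent) =
100 V₀ [k₁(1−q) + k₂(1−q/v) + k₃(1−v)], k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2.
Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, E₀ = 0.4,
V₀ = 0.04 — the classical constants, overridable per region. During
inversion only τ and E₀ are free (as log-scale deviations); the others are
fixed, mirroring common practice for this model generation.

**Integration.** Fixed-step RK4 at the microtime resolution. The flow pair
(s, f) is linear and integrated in linear space; v and q are integrated in
log space so the stiff windkessel terms cannot drive them negative, with
flow rectified at a small floor (0.01) where it enters the metabolic
terms. States are saturated at generous non-physiological bounds
(|z| ≤ 50, |log v| ≤ 5, …) so that an unstable candidate parameter set
during inversion yields finite, terrible predictions — which the ascent
rejects — rather than overflow. A numba kernel mirrors the numpy
arithmetic exactly (tested to 1e-14); the numpy path is the fallback.
Step-halving changes noiseless output by under 1e-4 of the response
amplitude at the default resolution.

## Paradigm and GLM

Blocks of 10 scans (TR 1.45 s → 14.5 s) per condition, each followed by an
equal fixation block; 7 repetitions of the 6 conditions split over 3 runs
interleaved by 42 rest scans. Pseudo-randomization is a uniform shuffle
rejected until no condition occurs three times consecutively; the seed is
recorded in the design. Lead-in/lead-out scan counts are free
configuration (the published total scan count is not exactly decomposable
into blocks + breaks, so the generator does not guess).

The canonical HRF is the double-gamma (peak 6 s, undershoot 16 s,
peak:undershoot 6) normalized to unit sum; condition regressors are
convolved at microtime and sampled at scan onsets. High-pass filtering
regresses out the discrete-cosine components with period above 128 s from
both data and design. The face contrast [2·F]−[O+S] uses weights
(1, 1, −½, −½, −½, −½) over (F_LVF, F_RVF, O_LVF, O_RVF, S_LVF, S_RVF) —
face betas minus half the four control betas, zero-sum; the weights are an
argument so an alternative scaling can be chosen. ROI summary series are
first eigenvariates (first left singular vector scaled by σ₁/√n_voxels,
sign aligned with the mean voxel series).

## Model space

All 96 models share the endogenous skeleton — reciprocal intrahemispheric
EVC↔OFA, OFA↔FFA, EVC↔FFA in both hemispheres; reciprocal interhemispheric
OFA↔OFA and FFA↔FFA; no EVC↔EVC or heterotopic links; driving inputs
RVF→EVC_L and LVF→EVC_R — and differ in their modulations: six families by
the set of intrahemispheric forward sites modulated (B = {EVC→OFA,
OFA→FFA}, F = all three are anchored; A, C, D, E default to the remaining
graded subsets and are configurable), crossed with 4 × 4 context
combinations. Lateralized contexts (S, F×S) place the RVF (or faces|RVF)
input on left-hemisphere sites and the left→right interhemispheric links,
LVF mirror-imaged; F places `faces` bilaterally and on all four
interhemispheric links; F+S is the union.

## Variational-Laplace inversion

Gaussian prior and posterior (Laplace approximation); the negative free
energy

    F = accuracy − complexity
      = Σ_r [ (N/2) h_r − (λ_r/2)(‖y_r−g(μ)‖² + tr(Σ J_rᵀJ_r)) ] − (N·R/2) log 2π
        − ½ (μ−μ₀)ᵀ S₀⁻¹ (μ−μ₀) − ½ tr(S₀⁻¹Σ) + ½ log |Σ|/|S₀| + p/2
        − Σ_r (h_r−h₀)²/(2 v_h)

is ascended over the posterior mean μ by damped Gauss–Newton steps, with
per-region log noise precisions h_r updated by scalar Newton between
steps. Sensitivities J come from central finite differences (step 1e-4)
batched through the integrator, so one Jacobian costs a single forward
pass over 2p+1 parameter vectors. Each iteration evaluates a ladder of
five Levenberg–Marquardt damping values in one batched pass and moves to
the best candidate; if the recomputed F at the new point falls below the
best retained F, the step is reverted and damping increased, so the
retained F never decreases. Convergence: improvement < 1e-4 nats (the
iteration cap defaults to 128). Seeded multi-start (`n_starts`) is
available but off by default.

Priors ("tight shrinkage"): zero-mean Gaussians with variance 1/16 on the
masked A off-diagonal and B entries, 1 on C, 1/256 around −0.5 Hz on the
A diagonal, 1/64 on the log-scale haemodynamic deviations; the noise
hyperprior is N(h₀, 16) with h₀ set from the data variance. A zero prior
variance pins a parameter. Data and predictions are mean-centred per
region by default (extracted series are mean-centred).

## Model comparison and averaging

Random-effects BMS uses the variational Dirichlet-multinomial scheme
(α₀ = 1 per model) with exceedance probabilities from 10⁵ seeded Dirichlet
draws. Family-level BMS sets the per-model prior to 1/(family size)
(uniform over families) and aggregates sampled model frequencies within
families; singleton families reproduce model-level BMS exactly. The
between-group frequency comparison evaluates the variational evidence
bound of a pooled Dirichlet model against independent per-group
Dirichlets at equal prior odds and reports p(equal | data). Occam's window
retains models with evidence ratio exp(F_i − F_best) > 0.05; subject-level
BMA averages posterior means over the window with weights ∝ exp(F_i −
F_best), imputing zero for parameters structurally absent from a model.

## Group statistics, LI, pupillometry

T-tests are corrected by Benjamini–Hochberg FDR within each parameter
class (endogenous; modulatory per input; driving); zero-variance
parameters are flagged and skipped. The 2×2 and 3-way mixed ANOVAs use the
classical split-plot sums-of-squares decomposition with separate error
strata per within-factor combination and no sphericity correction (the
two-level factors need none; the three-level stimulus factor uses
uncorrected df). The lateralization index resamples each side's
suprathreshold values (default threshold: half the overall maximum;
n_boot = 10 000) and reports the 25 %-trimmed mean of the bootstrap LI
distribution; a side emptied by thresholding degenerates to LI = ±1.
Pupil preprocessing is fixed-order — cubic-spline blink interpolation
(edge blinks extended with the nearest valid sample first), z-normalization
over all samples of the session, 50-ms centred box smoothing — and the
block metric is the mean over [onset+9 s, onset+11 s) minus the mean over
[onset, onset+50 ms), with half-open, left-aligned sample windows.

## Synthetic cohorts

Subjects draw every structurally present parameter from a Gaussian with
their group's published mean and between-subject s.d.; self-connections
are truncated below −0.05 Hz, and whole draws are rejected until the
endogenous system is stable (max Re eig(A) < −0.05 Hz) — Gaussian tails of
the printed s.d.s occasionally produce unstable systems no real subject
could exhibit. Default generating models are the two winning families,
family B (context S/F) for right-handers and family F (S/F) for
left-handers, which makes family-recovery experiments meaningful.
Noise is i.i.d. Gaussian per region with s.d. = (noiseless signal s.d.)/SNR,
default SNR 1. For recovery experiments the generator can moment-match:
the underlying standard-normal draws are standardized so the sample
reproduces the group mean and s.d. exactly — a variance-reduction choice
that makes a ten-subject experiment measure estimator bias rather than
sampling noise.

Pupil traces are a per-block square response (amplitude per stimulus
category and group; the handedness difference is confined to face blocks)
convolved with a 500-ms half-cosine onset, plus 1/f noise and
Poisson-placed blink annotations. LI voxel sets draw per-hemisphere value
distributions whose means realize a target LI per region and group (FFA
right-lateralized in right-handers, near-symmetric in left-handers; OFA
right-lateralized in both), jittered per subject.

What the generator does *not* emulate: scanner drift and motion,
physiological noise structure, regional HRF variability, eye movements,
spatial structure of activation. Passing recovery tests therefore show the
estimator works under the model's own assumptions at the stated SNR — not
that it is robust to real-data artefacts.

## Experiment scales

The canned experiments reduce session length so everything runs on one
CPU in minutes: parameter recovery uses 10 subjects × 240-scan sessions
(2 repetitions per condition, single run) at SNR 1 with moment-matched
draws; family recovery uses 6 left-handers × 240-scan sessions, families
B and F × the four {S,F}² context combos, with haemodynamics fixed at
their generating defaults during those inversions.

## Known limitations

* Families B and F are close to observationally equivalent under the
  left-hander generating parameters: EVC and OFA activity differ by one
  first-order lag and are nearly collinear over 14.5-s blocks, so family
  B's OFA→FFA face modulation absorbs most of the EVC→FFA effect.
  Truth-initialized inversions put the per-subject evidence margin for the
  generating family at only a few nats even at full session length, so
  family-level selection on synthetic cohorts favours F clearly but not
  with exceedance ≈ 1.
* Tight shrinkage priors bias individual estimates toward zero at SNR 1;
  cohort means under-recover strong parameters by roughly 10 %.
* Subjects whose draws land near the stability margin have long-memory
  dynamics and a narrow free-energy basin; their fits occasionally settle
  in a worse optimum (multi-start helps only sometimes).
* The free energy uses the standard Laplace form with point-estimated
  noise hyperparameters; no protected exceedance probabilities.
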