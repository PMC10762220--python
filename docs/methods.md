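# Methods

This note documents the models implemented in `revpet`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Task model

The paradigm is a two-forced-choice probabilistic reversal-learning
task: 250 trials, of which the first 150 form a stable phase with
action A rewarded with probability 0.8 (B with 0.2), followed by a
volatile phase in which the best action flips at trial 151 and every
25 trials thereafter (reversal trials 151, 176, 201, 226). A win pays
3 currency units. Each trial spends a fixed 6 s on events (2 s
response window, 2 s fixation, 2 s outcome) plus an inter-trial
interval (ITI) in [1, 13] s.

**ITI construction.** The source design pseudorandomises ITIs so that
every 25-trial block lasts exactly 5 min; the exact procedure is not
public, so `generate_schedule` uses a documented stand-in: ITIs are
drawn uniformly on [1, 13] s from a seeded generator, shifted by a
common constant to make the block total exact, then clipped to the
bounds with the residual redistributed over non-saturated ITIs until
the total is exact to the last floating-point bit. The per-block ITI
budget (150 s for default timing) keeps the target mean (6 s) well
inside the bounds, so the adjustment always converges; infeasible
configurations (block duration unattainable given event durations and
ITI bounds) raise a configuration error up front.

## Behavioral model

A single-learning-rate delta-rule model with softmax choice:

- value update (chosen action only): `Q ← Q + α (r − Q)`, reward coded
  r ∈ {0, 1}, prediction error `δ = r − Q`, absRPE = |δ|;
- choice rule: `p(A) = logistic(β (Q_A − Q_B))`, computed through the
  logistic of the value difference so that no overflow occurs even at
  β·ΔQ ≈ 700;
- initial values `q_init = 0.5` for both actions (uninformative
  midpoint; rewards live in {0, 1}).

**Estimation.** Parameters are estimated per session by maximum
likelihood with L-BFGS-B under bounds α ∈ [0, 1], β ∈ [0, 30], from 10
seeded random starting points; the lowest negative log-likelihood
wins, a convergence flag is carried on the result, and refitting at
the returned parameters reproduces the reported likelihood exactly.
This is a deliberately dependency-light, deterministic substitute for
hierarchical Bayesian estimation; the recovery tests (median
|α̂ − α| < 0.15 and |β̂ − β| < 2 on 250-trial sessions over an
interior parameter grid) bound what the point estimates can claim.
β values of real subjects are heavy-tailed; near β = 0 choices carry
almost no information about α, which is why recovery guarantees are
stated for interior parameter values only.

**Summaries.** Perseverance errors count consecutive post-reversal
choices of the previously best action, ending at the first choice of
the new best action (0 if the first post-reversal choice already
switched). The post-reversal absRPE summary is the mean of |δ| over a
25-trial window starting at the reversal (window length exposed as a
parameter); a window that would not fit in the session raises rather
than silently truncating.

## TAC simulation

The target tissue follows the one-tissue reference-region model with a
time-varying efflux term:

    dC_T/dt = R1 dC_R/dt + k2 C_R − [k2a + γ B(t)] C_T,

with `k2a = k2 / (1 + BP_ND)` and B(t) a unit-peak gamma variate
`((t−t_d)/(t_p−t_d))^a exp(a(1 − (t−t_d)/(t_p−t_d)))` that is zero
before its onset t_d and exactly 1 at its peak t_p. Default target
kinetics are R1 = 1.0, k2 = 0.35/min, BP_ND = 2.5 — typical striatal
[¹¹C]Raclopride values. The reference input is an analytic
bi-exponential `A (e^{−at} − e^{−bt})` (uptake b = 1.5/min, washout
a = 0.04/min, peak activity 30 arbitrary units), standing in for a
cerebellar grey-matter curve; any smooth positive curve can be
configured. The ODE is integrated by classic RK4 at 0.5 s resolution,
averaged over the 53-frame acquisition (6×10, 6×20, 6×40, 9×60,
26×120 s = 68 min), and corrupted with zero-mean Gaussian noise of
variance `noise_scale² · C(t) / Δt(min)` — the standard
frame-duration scaling for decay-corrected PET. Negative post-noise
activities are clipped at zero and counted in the returned truth
record.

**Noise levels.** The analysis in the field operates on denoised data
(spatial HYPR filtering plus temporal smoothing), and the generator's
defaults represent that regime: `noise_scale = 0.05` for ROI-level
(cluster-averaged) TACs (≈0.9% coefficient of variation in late 2-min
frames) and 0.1 for single-voxel grids (≈1.7%). Raw single-voxel
raclopride TACs are several times noisier; simulating them would be a
statement about un-denoised data that this package does not model.
The release magnitude γ for a wanted peak occupancy is available in
closed form (`gamma_for_peak_occupancy`), since at the basis peak
`BP = k2/(k2a + γ) − 1`.

**What the generator does not emulate.** No image-space structure
(point-spread function, partial volume, motion), no attenuation or
scatter residuals, no head-motion-correlated artefacts, no arterial
input variability, and the reference region is noiseless by default
(a large cerebellar ROI). Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not
robustness to every artefact of real acquisitions.

## Kinetic estimation

Fits use the multilinear operational form of the reference-tissue
model, `C_T = R1 C_R + k2 ∫C_R − k2a ∫C_T`, with running integrals by
cumulative trapezoid over frame midpoints anchored at (0, 0) (checked
against fine-grid quadrature to <0.5% on smooth curves). With the
reference clearance k2′ fixed, `k2 = R1 k2′` and the baseline design
has two columns; k2′ itself is estimated once from the unconstrained
three-column fit on a large, displacement-free region (the
"whole-striatum" surrogate in simulations) and then held fixed. Least
squares is weighted by frame duration (configurable), the standard
weighting for decay-corrected data. Rank-deficient designs (constant
TACs, target identical to reference in the unconstrained form) raise a
singular-fit error rather than returning garbage.

The displacement model appends `−γ ∫B(s) C_T(s) ds` for each of 5
basis functions with onset at the reversal (2280 s of scan time: task
onset 480 s + 30 min stable phase), sharpness exponent 1, and peak
offsets {1, 2, 4, 8, 12} min — a fast-to-slow span consistent with
release peaking within ~2 min while leaving slower shapes available.
The basis minimising residual sum of squares wins (ties break toward
the earliest peak). γ is constrained non-negative: because only one
coefficient is constrained, the constrained optimum is either the
interior unconstrained solution or the γ = 0 boundary, i.e. the
baseline fit, which is returned flagged (`gamma_clamped`).

Model comparison uses the extra-sum-of-squares F statistic with
p = 2 (baseline) vs 3 (release) parameters over 53 frames, and the
conventional F > 9.55 mask is the default threshold for declaring
displacement; the threshold is a configuration constant, the F
computation itself is general. Empirically, at the generator's voxel
noise level, null TACs exceed the mask in well under 5% of replicates
while a 12%-peak-occupancy release is detected in >80% of voxels —
the phantom calibration checked by the acceptance tests.

Dynamic binding potential and occupancy follow directly from the
fitted parameters: `BP_ND(t) = k2 / (k2a + γB(t)) − 1` and
`Occ(t) = (BP_pre − BP_ND(t)) / BP_pre × 100`, with BP_pre the mean
over a pre-reversal window (default 480–2280 s: task onset to first
reversal) and the peak taken over a post-reversal window (default
2280–2880 s). The "predicted path" is the operational equation
evaluated with the fitted R1 and baseline efflux only (release term
zeroed) — the counterfactual no-release curve; for release data it
runs above the observed TAC after the reversal.

**Temporal smoothing.** The three-frame kernel (0.25, 0.50, 0.25) is
provided with edge renormalisation (constant curves are preserved
exactly). It is not applied inside the fitting path: smoothing
correlates neighbouring residuals, which inflates the null exceedance
of the F mask under the independence assumption of the F statistic
(about 9% observed in simulation, against ≈2% unsmoothed), and the
generator's noise defaults already represent smoothed data.

**Voxelwise analysis.** Voxel grids are plain (nx, ny, nz, n_frames)
arrays (no anatomical space or registration is modelled). The
two-step procedure masks voxels at F > 9.55, averages the TAC over the
mask, and refits on the average — this reduces single-voxel noise, and
the refit's parameter variance is verified in tests to be below that
of single-voxel fits. An empty mask is a valid, explicitly reported
outcome (`roi_fit = None`).

## Group inference

- `pearson_corr`: r with two-sided p from the t transform (df = n−2)
  and a Fisher-z 95% CI; constant inputs are an error, not a NaN.
- `linreg`: OLS with intercept; optional quadratic term for a single
  predictor, exposing the quadratic t (the inverted-U check between
  learning rate and total reward uses its sign).
- `perm_one_sample`: one-sample sign-flip permutation test with the
  add-one p convention; with multiple variables, family-wise error is
  controlled by the max-statistic null distribution (a documented
  substitute for image-space cluster enhancement with the same
  family-wise error target). p-values are invariant to rescaling and
  exactly reproducible given the seed.
- `bayes_paired_t`: paired t with the default JZS Bayes factor —
  effect size δ ~ Cauchy(0, r), r = √2/2 — computed by adaptive
  quadrature over the scale mixture, split at the prior scale for
  stability; verified against an independent implementation to three
  significant figures over t ∈ [0, 10], n ∈ {10, 26, 50}. Published
  Bayes factors from other software are context, not targets, because
  prior scales differ between tools.

## Cohort pipeline

`run_cohort` composes the stages for a simulated cohort (default
n = 26). Population distributions: α ~ Beta matched to mean 0.38,
SD 0.26; β ~ lognormal (median 2, σ = 0.8) truncated at 20 — a heavy
right tail as seen in human fits. The generative coupling rule makes
each subject's true peak occupancy linear in their learning rate,
`Occ_i = clip(4 + 22 α_i + N(0, 4), 1, 35)` percent (mean ≈ 12.4% at
the α mean), so the group analyses have a known directional truth:
occupancy correlates positively with fitted α and — through the
model-intrinsic link between α and post-reversal absRPE — negatively
with absRPE magnitude. The slope/noise values are a generative choice
for directional tests, not an estimate of the human effect size.
Every subject receives independent seeded streams (agent choices,
outcomes, TAC noise, fit restarts) derived from the master seed;
identical configurations produce byte-identical reports, and any stage
failure aborts with a stage-labelled error.

## Problem sizes used by the checks

The acceptance tests run at desk scale by choice: the behavioral
recovery grid uses interior α ∈ {0.3, 0.5, 0.7} × β ∈ {3, 5} with 50
sessions per point; kinetic recovery uses 40 noisy ROI replicates;
F-mask calibration uses 150 null replicates plus a 6×6×6 phantom with
a 2×2×2 release block; permutation type-I uses 400 null cohorts of 26
subjects at 1000 sign-flips each; the demo cohort is a single seeded
26-subject run.

## Known limitations

- The estimator is per-session MLE, not hierarchical; shrinkage
  benefits of partial pooling are absent, and β is only weakly
  identified for near-random responders.
- Only the winning two-parameter behavioral model is implemented; no
  model-comparison machinery (the alternative candidate models'
  equations are not public).
- The F > 9.55 mask is taken as a conventional constant; its nominal
  α depends on the true error degrees of freedom, which smoothing or
  weighting change. The package reports calibration empirically
  instead of deriving it.
- Occupancy peaks estimated under noise inherit a mild selection
  effect from maximising over time and basis shape; at the default
  ROI noise this stays within ±3 percentage points (median) for a 12%
  release.
- Voxel grids are abstract arrays; no spatial statistics beyond the
  max-statistic permutation correction are provided.
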