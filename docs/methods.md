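# Methods

## Scope

`cmrquant` implements the quantitative image-analysis chain of a
cardiac-MR characterisation study of a nonhuman-primate heart-failure
model — T1/ECV mapping, dual-bolus Fermi-deconvolution perfusion, echo
classification, cohort statistics — together with the synthetic data
needed to validate it.  Echo acquisition physics, feature-tracking strain
(GLS), late-gadolinium-enhancement reading, and any k-space-level MR
simulation are out of scope; stress pharmacology is represented only as a
higher ground-truth flow (the dobutamine target of a ≥ 25% heart-rate
increase is a simulator parameter, not a model).

## Signal models

### MOLLI inversion recovery

Continuously sampled inversion recovery follows the apparent 3-parameter
model `S(TI) = A − B·exp(−TI/T1*)`, acquired as magnitude.  The true T1 is
recovered with the Look-Locker correction `T1 = T1*(B/A − 1)`.  The
simulator inverts the same algebra: A is the equilibrium magnetisation
(1.0), B/A = 2 for an ideal inversion (configurable), and
`T1* = T1/(B/A − 1)`, which makes noise-free round trips exact.  Effective
inversion times of a scheme group are `ti_min[g] + k·RR`; the default
minima are 100 ms for the first inversion and +80 ms per later inversion
(100/180/260 ms), chosen so that all inversion groups sample distinct TIs
at a fixed RR — with identical minima the 2nd and 3rd groups of 4(1)3(1)2
would duplicate TIs and carry no extra information.  Recovery-beat counts
are part of the scheme and freely configurable (the protocol raises them
at the ~150 bpm heart rate of macaques); they do not enter the TI algebra.

Noise is additive Gaussian on the signed signal before the magnitude is
taken, so SNR = A/σ.  SNR 30 is used as the default imaging condition and
SNR 20 as the stress condition for end-to-end checks.

### Fit

Per pixel, polarity is restored by negating the k earliest-TI samples for
every k = 0..n−1, fitting the signed model, and keeping the minimum-RSS
candidate.  For speed each candidate is first screened by variable
projection (for fixed T1* the model is linear in A and B, so a closed-form
solve over an 80-point geometric T1* grid in [50, 5000] ms ranks the
candidates), and near-optimal candidates are polished by bounded
trust-region least squares (tolerances 1e−14, ≤ 200 evaluations).  Fits
with B/A ≤ 1, T1* at the search bounds, or non-positive T1 are flagged
invalid and excluded from ROI means, never clipped.

### ECV

`ECV = (1 − Hct)·ΔR1_myo/ΔR1_blood` with `ΔR1 = 1/T1_post − 1/T1_pre`.
Blood ΔR1 comes from an ROI mean over the blood pool rather than
pixel-wise blood values (robust to inflow artifacts).  Contrast
equilibrium is assumed at the post-contrast time point; the 15–20 min
timing dependence is not modelled.  Hematocrit is a fraction in code;
CSV values above 1 are interpreted as percent and converted on read.
Pixels with ECV outside [0, 1] are flagged invalid and counted.

### Perfusion

Tissue concentration is `C_t(t) = (AIF ⊛ R)(t)·dt` (causal rectangle-rule
convolution on the frame grid, one frame per heartbeat, default 0.4 s at
150 bpm, 70 frames).  The impulse response is the Fermi function

    R(t) = F·(1 + exp(−w/k)) / (1 + exp((t − τ0 − w)/k)),  t ≥ τ0;  0 before,

normalised so R(τ0) = F exactly.  That normalisation pins the amplitude
degeneracy between F, w and k at onset, and by residue-function theory the
initial response height is flow: F (1/s) × 60 is myocardial blood flow in
ml/min/g.  Signal is converted to concentration as relative enhancement
`(S − S̄0)/S̄0` over ≥ 3 baseline frames — the linear-signal premise that
motivates the dual-bolus design, whereby the AIF is measured from the
0.01 mmol/kg bolus and multiplied by the 9× dose ratio to match the
0.09 mmol/kg tissue bolus.

The deconvolution is bounded least squares over (F, τ0, w, k) with
F ∈ [0, 10/60 s⁻¹], τ0 ∈ [0, 10 s], w ∈ [0, 30 s], k ∈ [0.05, 10 s].
Because the hard onset makes the cost only piecewise smooth in τ0 (samples
switch on and off as τ0 crosses the frame grid), τ0 is profiled over a
frame-step grid whose window is seeded by the AIF–tissue cross-correlation
lag; at each candidate the amplitude is solved in closed form (the model
is linear in F) and (w, k) fit smoothly; the winner is then polished over
all four parameters and kept only if the polish improves the fit.  Fits
exceeding the 10 ml/min/g sanity bound or failing to converge are flagged.
MPR is computed per subject (or per pixel) as stress/rest flow; published
group MPR values are treated as means of per-subject ratios.

## Synthetic data

The phantom is a three-label short-axis slice (background, LV blood-pool
disc, myocardial annulus) with tissue parameters constant per label;
default truths sit at the 1.5 T healthy regime (native myocardium 1200 ms,
blood 1600 ms; post-contrast 600/400 ms; Hct 0.51) and the per-group
demo phantoms set post-contrast myocardial T1 so the true ECV equals each
group's published mean exactly.  The AIF is a gamma-variate bolus
`A(t−t0)^α·exp(−(t−t0)/β)` (defaults α = 2.5, β = 1.5 s, arrival 2 s —
a typical compact first-pass bolus at this frame rate).

Cohorts draw every variable independently as Gaussian at the published
group means/SDs (three groups of 10: healthy, HFpEF, HFrEF), with three
exceptions: hematocrit is clipped into (0, 1); MPR is derived per subject
as stress/rest; and ECV can optionally be given a linear age slope within
group so that age adjustment has a real confound to remove.  Perfusion
variables are absent for HFrEF, mirroring the safety exclusion of stress
testing in that group.  What the generator deliberately does not emulate:
between-variable covariance (only marginal moments are published), scanner
artefacts (motion, banding, dark-rim, saturation), and any non-Gaussian
tails — so passing tests demonstrate correctness of the estimators and
statistics under the published study conditions, not robustness to real
acquisition artefacts.

## Statistics

Classification applies the cynomolgus-specific thresholds (EF < 65% →
HFrEF; else ≥ 2 diastolic criteria → HFpEF).  One-way ANOVA is classical
(Welch deliberately not applied, matching the named method; the degenerate
all-equal case is defined as F = 0, p = 1).  Age adjustment is ANCOVA
`value ~ group + age` with the group effect tested by the Type-II
extra-sum-of-squares F and adjusted means evaluated at the grand-mean age;
partial correlation uses the residual method with a t test on n − 3
degrees of freedom.  ROC analysis is empirical with midrank tie handling
(AUC equals the normalised Mann–Whitney U); the operating point maximises
Youden's J with ties broken toward the lowest cutoff, and an AUC below 0.5
is reported with an orientation note rather than silently flipped.
p-values are raw and two-sided; no multiple-testing correction is applied
(the report carries the number of tests performed instead).

## Problem sizes and determinism

Round-trip and end-to-end checks run on a 48×48 phantom (annulus ≈ 200
pixels) and the pipeline demo on 48×48 or 32×32; replicate statistics use
1,000 simulated cohorts (300 for the null-calibration check).  These sizes
put Monte-Carlo error well below the tolerances being asserted while
keeping a full run in minutes on one core.  All stochastic steps take a
`numpy` `default_rng` seed and are bit-reproducible; the pipeline writes a
manifest with SHA-256 checksums of every output, and a rerun with the same
seeds reproduces the checksums exactly.

## Known limitations

* No motion correction, inversion-efficiency calibration beyond B/A, or
  shMOLLI/SASHA variants; no model-independent deconvolution alternative.
* The Fermi parameterisation fixes the flow readout at R(τ0); software
  that normalises the Fermi response differently will report flows that
  agree only up to that convention.
* Adjusted group means are model predictions at the grand-mean age; other
  adjustment conventions yield different adjusted values, so published
  age-adjusted columns are not claimed to be reproduced exactly.
* DICOM support is read-only and limited to series carrying per-frame
  InversionTime/TriggerTime; NIfTI + JSON sidecar is the native format.
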