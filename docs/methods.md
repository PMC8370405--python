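# Methods

This note documents the models, defaults and design choices behind
`neuroloop`, and what the synthetic validation does and does not establish.

## Task space and Gaussian-process model

The search space is a discrete 7 × 3 lattice: seven cognitive/language tasks
ordered along one axis (Overt Naming, Auditory Comprehension, Semantic
Judgement, Verbal Learning, Calculation, Go/No-Go, Encoding — a
configuration input; the ordering encodes prior similarity between tasks)
and three difficulty levels along the other. Kernel coordinates are the raw
lattice integers; the two axes are not rescaled, and anisotropy is carried
entirely by per-dimension lengthscales, which keeps lengthscales
interpretable in grid units.

The surrogate is a zero-mean GP with squared-exponential kernel and fixed
hyperparameters (no within-run optimization — a real-time constraint):

| parameter | default | units / meaning |
|---|---|---|
| ℓ_task | 1.5 | grid units; correlation length along the task axis |
| ℓ_difficulty | 1.0 | grid units |
| σ_f² | 1.0 | prior signal variance |
| σ_n² | 0.25 | observation noise variance on the standardized scale |
| κ | 2.0 | UCB exploration weight (constant, not a schedule) |
| standardize_y | on | centre/scale observations before fitting |

The posterior is the exact conjugate solution via Cholesky with escalating
jitter on numerical failure. With standardization, the de-standardized
posterior mean is an affine function of the raw observations whose linear
operator does not depend on the values (the scale cancels); the reliability
permutation test exploits this identity to vectorize thousands of GP refits
exactly. Note that with standardization the reported posterior sd is scaled
by the data spread, so the textbook "posterior sd ≤ prior sd" bound holds on
the standardized scale (and verbatim when standardization is off).

A run is 16 iterations: 4 burn-in conditions drawn uniformly at random with
replacement, then GP-UCB argmax with exact ties broken uniformly at random.
Repeat selections are allowed and accumulate as independent observations.
With 10 equilibration TRs (TR = 2 s) and 52 s iterations
(5 s instruction + 3 s rest + 34 s task + 10 s rest) a run lasts 14.2 min.

## GLM engine

The forward BOLD model and estimator share one design convention: one boxcar
per completed task block, convolved with a canonical double-gamma HRF
(response gamma peaking at 6 s, undershoot at 16 s, 1:6 amplitude ratio,
sampled at TR), plus an intercept and a centred linear drift. Instruction
and pre-task rest are unmodelled baseline. Estimation is plain OLS — no
prewhitening; serial correlation is part of the simulator's challenge, not
the estimator's job. After block *t* the GLM is refit on all scans acquired
so far with *t* task regressors, and the value passed to the optimizer is
the just-completed block's β_FPN − β_DMN. The first fit happens only after
the last burn-in block; earlier blocks' contrasts are back-filled from that
fit. HRF tails legitimately spill across block boundaries, so the simulated
run signal is assembled at run level (per-block amplitudes times full-length
regressors), which makes the noiseless forward-then-invert round trip exact
to machine precision.

## Synthetic cohort

The generator replaces the scanner and the participants while preserving the
statistical structure the analyses assume.

**Contrast surfaces.** All controls share a canonical surface: baseline
−0.2, a ridge of amplitude 0.8 peaking over Semantic Judgement, Calculation
and Encoding (Gaussian bumps of width 1.5 grid units — deliberately equal to
the GP task lengthscale, since the task ordering exists precisely to make
the response smooth at that scale), plus 0.3 per difficulty level; each
control adds a smooth GP perturbation of amplitude 0.1. A patient with
severity *s* ∈ [0, 1] attenuates the canonical component by (1 − 0.5 s) and
draws an idiosyncratic smooth perturbation of amplitude 0.1 + 0.6 s, so
severity 0 reduces exactly to a control draw and higher severity yields both
weaker dissociation and more heterogeneous profiles.

**Observation noise.** Per-block contrast noise is Gaussian with sd 0.08 for
controls, scaled by (1 + 5 s) for patients. No per-block noise level is
empirically constrained, so these two values were calibrated once against
the reported between-run reliability medians of the in-vivo paradigm this
simulator emulates (≈ 0.9 for controls, ≈ 0.7 for patients) and then
frozen; simulated medians are ≈ 0.88 and ≈ 0.70. The
severity-scaled term reflects that more severely affected patients produce
noisier single-block estimates, and it is what reproduces the control >
patient reliability ordering. In BOLD mode the time-course noise is AR(1)
(coefficient 0.3) plus a linear drift.

**Behaviour.** Per-trial accuracy follows a psychometric curve with a
forced-choice guessing floor: p = 1/K + (1 − 1/K)·sigmoid(η), with η linear
in group, severity, difficulty, a per-task offset and a per-subject random
intercept (sd 0.3). The floor matters: without it an impaired subject's
accuracy falls below chance, which is impossible when guessing among K
options and would corrupt the above-chance AUROC analyses. Defaults put an
easy control condition at ≈ 0.92 accuracy and a severe patient on a hard
condition near the floor. Three degenerate task behaviours from the study
are emulated: Verbal Learning's offset (−8) pins both groups at chance;
Overt Naming produces no keypad responses (trials coded incorrect, RT
missing); the easiest Auditory Comprehension level is always correct.
Reaction times are log-normal with group/severity/difficulty shifts,
truncated at a 3.5 s response window. Severity and log lesion volume are
correlated at 0.5.

**What the generator does not emulate:** voxel-level images, motion and
physiological noise, learning/fatigue across runs, run-order effects, and
any coupling between behavioural errors and the BOLD signal within a block.
Passing tests therefore establish internal validity of the algorithms and
the statistical machinery under the stated generative assumptions — not
performance on real scanner data.

## Statistical analyses

**AUROC vs chance.** The chance distribution permutes, within each block
independently, the response sequence against the answer sequence (1000
permutations), preserving each subject's response pattern, and pools all
subjects' permuted mean accuracies. AUROC uses the rank-sum formulation with
half-weight ties. The lower 95% bound is the 5th percentile of AUROCs over
bootstrap resamples of subjects (default 10 000); significance requires it
to exceed 0.5. The level of this criterion is assessed against the marginal
null in which both the chance sample and the empirical accuracies are drawn
fresh — conditioning on a single finite chance sample makes the apparent
level fluctuate several points in either direction. Conditions with no
computable chance level (Overt Naming; easiest Auditory Comprehension) are
reported as explicit missing results.

**Reliability.** Observed statistic: Spearman correlation between the two
runs' 21-point profiles per subject. Null: within each subject, permute the
run-2 values against their sampled conditions (the condition multiset is
preserved — this keeps the sampling design and destroys only the spatial
structure), refit the GP with identical hyperparameters, recompute the
correlation; 10 000 permutations, drawn independently per subject.
Group evidence is the median Fisher-z (clipped at |ρ| = 1 − 10⁻⁶); per
permutation only the maximum of the two group medians enters the null
(max-statistic family-wise correction); p values are one-sided with the +1
correction, so never exactly zero.

**Dissimilarity.** Profiles collapsed over both runs (one GP fit on all 32
observations), distance 1 − Spearman. Two pooled-variance t statistics
(Welch optional), both oriented controls-minus-patients: control-within vs
patient-within entries, and the control-by-patient block vs patient-within.
The null relabels subjects (10 000 permutations); the alternative "patients
more dissimilar" is the lower tail. Classical MDS double-centres −½ J D² J;
eigenvector sign is fixed by orienting each coordinate so the patient mean
exceeds the control mean (correlation magnitudes are unaffected). DBSCAN
runs on the precomputed distances with eps 0.3 (1 − ρ units) and min_pts 3 —
the study reports neither, so both are configuration. Behaviour association
correlates coordinate 1 with the condition-adjusted mean accuracy (grand
mean plus the subject's average deviation from per-condition means — a
fixed-effects stand-in for a mixed-model random intercept, used because the
adaptive sampling confounds raw means with condition difficulty), plus a
patients-only and a lesion-partialled variant (correlation of OLS
residuals); p values come from shuffling the behaviour vector against fixed
coordinates (50 000 permutations, lower tail) with Benjamini–Hochberg
correction across the reported family.

**Normalization.** Modified z = 0.6745 (x − median) / MAD against the
control distribution, per condition; |z| > 1.96 flags a deviating condition
(a deliberately liberal threshold; 3.5 is the conservative convention). MAD
of zero yields an undefined-score marker rather than a value. Accuracy is
normalized only where more than 7 controls contribute; other conditions are
reported as missing, never dropped silently.

## Numerical and testing choices

Permutation p values always use (1 + #{null ≥ observed}) / (1 + N).
Seeds derive from one master seed through named `SeedSequence` child
streams, so every stage is independently reproducible and study reruns are
byte-identical. Degenerate inputs (constant profiles, zero MAD, rank
deficient designs, empty observation sets) raise typed errors or return
explicit NaN markers as documented per function.

Test problem sizes are chosen so the whole suite runs in about a minute on
one core: type-I checks use 500 null replicates with 100–500 permutations;
structural checks use 100 simulated cohorts at the full default size (14
controls, 11 patients, two 16-iteration runs each) in direct-observation
mode; the BOLD + incremental-GLM path is exercised separately, including an
exact noiseless round trip over the whole grid. The full pipeline at default
scale with full permutation counts (1000 / 10 000 / 10 000 / 50 000)
completes in a few seconds because the GP-refit null is evaluated through
the exact affine-operator identity rather than naive refits.

## Known limitations

- The generator's canonical surface and effect sizes are stylized; only the
  reliability medians were calibrated to reported values, everything else is
  structural.
- The recovery and efficiency figures are specific to the default noise
  level; severity-scaled noise degrades patient profile recovery by design
  (controls ≈ 0.92, patients ≈ 0.58 fraction reaching ρ ≥ 0.7 on full
  cohorts).
- The percentile bootstrap lower bound and the constant-κ UCB rule are the
  study's conventions, kept as-is rather than replaced by BCa intervals or
  an iteration-dependent exploration schedule.
- LME-based analyses, equivalence testing, scanner I/O and voxel-level
  processing are out of scope.
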