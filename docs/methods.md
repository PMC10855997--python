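# Methods

This note documents the models, conventions and design choices behind
`oculopheno`, in the order the pipeline runs. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic cohort generator

The generator is first-class code, not a fixture: it defines the study
conditions under which every downstream stage is validated.

**Phenotype calibration.** Patients are drawn from four latent phenotypes
with mixing proportions 100:12:12:16 (≈ 71.4 / 8.6 / 8.6 / 11.4%). Each
phenotype is parameterized by a 12-entry standardized mean-shift vector
over the analysis indicators (RNFL; VG/EC/AS/MG latency; EC/AS/MG error;
AS/MG FEP; VDI_R/VDI_L); the default vectors are the published
four-profile mean estimates (e.g. VDI_R +6.519 for the efferent-cognitive
phenotype, AS error +7.415 for the cognitive-control phenotype, RNFL
−1.085 for the afferent-processing-speed phenotype). Controls are drawn
with zero shift.

**Raw-scale anchors.** z-space shifts map to raw metrics through
control anchors (mean, SD) per indicator, chosen so control medians land
near published control descriptives (VG latency ≈ 170 ms, VDI ≈ 1.03,
antisaccade error ≈ 7%). Anchors are calibration plumbing, not normative
ground truth. Error-rate and FEP anchors place the zero bound ≥ 2.4
control SDs below the control mean: a closer bound measurably shrinks the
*estimated* control SD through clipping and thereby inflates large
standardized shifts (a 0.5% SD shrink moves a 7.4-SD shift by ≈ 0.04), so
bounds are kept far from the bulk and the within-phenotype distributions
are effectively Gaussian with unit z-scale SD.

**Two generation paths.** (a) *Indicator path*: the 12 indicators drawn
directly on the raw scale — used for large-n factor-structure and
mixture-recovery runs, where trace synthesis adds cost but no information.
(b) *Trace path*: per-trial binocular gaze traces at 500 Hz whose planted
behaviour (latency, mechanistic error trials, landing error, adduction
slowing) reproduces the participant's drawn indicator values; this path
feeds the saccade-extraction stage exactly as recorded data would.

**Task designs.** VG: 24 trials, targets ±5/±10°. AS: 48 trials. EC: 48
trials, 850 ms fixation, 500 ms arrow cue, 75% cue validity. MG: 500 ms
target cue, 1500/2500 ms delay, response at fixation offset, 500 ms
feedback; the MG trial count is not fixed by the task diagrams — 24 by
default, configurable. Fixation (800 ms), response window (800 ms) and
refixation (500 ms) durations are package defaults.

**Saccade waveform.** Raised-cosine position profile with main-sequence
kinematics: peak velocity Vmax·(1 − exp(−A/C)), Vmax = 500°/s, C = 14°
(plausible human values; only relative structure matters downstream).
Error trials are mechanistic — a reflexive look at the forbidden target
(AS), a cue-directed look during the delay (MG), a cue-congruent
wrong-direction saccade (EC) — so the *scoring rules*, not labels,
produce error rates. Dysconjugacy scales the adducting eye's primary
amplitude and peak velocity by 1/gain at fixed duration, with the residual
completed by an exponential post-saccadic drift (τ = 100 ms), emulating
the adduction slowing of internuclear ophthalmoplegia. Positional noise is
boxcar-filtered Gaussian (default SD 0.1°), temporally correlated like
oculomotor drift rather than white.

**What the generator does not emulate.** Vertical/torsional movements,
blinks, pupil artefacts, nystagmus, calibration drift, head motion, and
real within-profile skew/heterogeneity of indicator distributions (the
generator's within-phenotype distributions are Gaussian with unit z-SD;
real profile SDs vary by indicator). Passing tests therefore demonstrate
correctness of the *machinery* under the declared statistical structure,
not robustness to every artefact of recorded data.

**MAR missingness.** A contiguous enrolment block of patients loses all
three MG indicators (emulating a temporary protocol change); the mask
depends only on enrolment position, hence missing-at-random.

## Saccade detection and scoring

Velocity is computed by smoothed central differences (5-sample moving
average by default). Events are runs of |v| ≥ 30°/s extended outward to
the nearest local velocity minima, with extension stopped once speed
falls below a 10°/s offset floor — without the floor, the slow adduction
glissade of a dysconjugate saccade is absorbed into the event and merges
it with the following refixation. Events closer than 20 ms merge; events
shorter than 8 ms or smaller than 0.5° are dropped. All thresholds are
configurable (`DetectionParams`); defaults follow common
video-oculography practice.

Scoring conventions (the original task-specific rules are not public;
these are explicit package conventions): saccades within 80 ms of the go
signal are anticipatory and ignored for VG/AS/MG; EC has no lower cutoff
because a valid predictive cue legitimately permits very short latencies.
AS errors are target-directed first saccades; MG errors are delay-period
saccades > 2° toward the cue; EC errors are first saccades opposite the
target. A trial with no response-window saccade counts in the trial total
but in neither the latency set nor the error numerator. Participant
latency summarizes as the **mean** over correct trials (median is a
reasonable alternative; mean is the declared choice). FEP is
100·|final gaze − goal| / |target amplitude| on correct AS/MG trials.

Monocular scoring uses the right eye by default (configurable, mirroring
the use of the unaffected eye under observable dysconjugacy). The VDI is
peak-velocity-based on first-pass saccades (amplitude-ratio variant by
configuration).

## Derived measures

The latency-adjustment regression is fitted on the pooled
controls-plus-patients sample by default (configurable to controls-only):
a common fit keeps patient and control values on one comparable scale.
Adjusted latency = residual + fitted value at the fit-sample mean VG
latency, preserving the millisecond scale (profile-mean magnitudes of
adjusted latencies then remain interpretable); the transform is
idempotent and leaves adjusted values uncorrelated with VG latency.

RNFL uses a normative reference (defaults 97 ± 10 μm — documented
placeholders, since controls have no OCT). Severity boundaries at z = 1,
2, 3 are left-open (a boundary value falls in the lower category);
RNFL is inverted (impaired below −1).

## Multiple imputation

Chained equations with predictive mean matching (5 donors), m = 25
datasets and 10 cycles by default (the pipeline's own default is m = 5,
which keeps full-pipeline runs brisk while leaving the module default at
the more conservative 25). Backed by statsmodels' MICE machinery; scoped
seeding makes runs reproducible. Pooling follows Rubin's rules. The LPA
stage fits each completed dataset separately, selects K per dataset, and
reports the modal K with means pooled over agreeing datasets — simpler
than an integrated MI mixture likelihood, and a declared deviation. The
`pairwise` strategy (complete-case for the mixture) is the sensitivity
path.

## Exploratory factor analysis

ML estimation on the correlation matrix by uniqueness-profiled likelihood:
for fixed uniquenesses Ψ the optimal loadings come from the leading
eigenpairs of Ψ^(−1/2) S Ψ^(−1/2), leaving a smooth bounded optimization
over Ψ (L-BFGS-B, analytic gradient, multi-start from the standard
(1 − m/2p)/diag(S⁻¹) start). Uniquenesses are bounded at 0.005; solutions
at or near the bound are flagged as Heywood cases. The minimized
discrepancy agrees with R's `factanal` to ~1e-6 on shared inputs (tested).

Oblique rotation is oblimin/quartimin via the gradient-projection
algorithm; factors are ordered by explained variance and sign-fixed so
each column's dominant loading is positive. Fit indices use the plain ML
χ² = (n−1)·F_min against the independence baseline (−ln|S| on the
correlation metric); **robust (mean/variance-adjusted) corrections are
not implemented** and all outputs are labelled "ML (non-robust)". With
df = 0, TLI and RMSEA are reported absent.

The default indicator set is the nine ocular-motor variables
(VG/EC/AS/MG latency, EC/AS/MG error, AS/MG FEP); whether dysconjugacy
indices belong in the factor model is genuinely ambiguous, so the set is
configurable and VDI is excluded by default. The factor sweep clips to
the Ledermann identification bound for the supplied p.

A caution established while testing: on independence-structured data the
global ML solution can be a spurious single-indicator Heywood factor
riding a sampling-noise direction — reference ML implementations return
the identical solution — so a flagged Heywood factor on weakly structured
data should be read as "no substantive factor", not as signal.

## Latent profile analysis

Gaussian mixture with profile-specific means and a shared diagonal
covariance (the common default in mixture-modelling software;
class-varying diagonal available by configuration). Parameters per model:
K·d means + d variances + (K−1) weights. Multi-start protocol: 250 random
starts (means seeded at jittered data points), 20 burn-in EM iterations,
the best 50 run to convergence (relative LL change < 1e-8); the
replication count of the best final log-likelihood is reported and a
count of 1 warns that the optimum may be local. Profiles are canonically
ordered by descending weight, making all reported quantities invariant to
component permutation. Standard errors in reports are posterior-weighted
within-profile SDs over √n, labelled ML (non-robust); robust (sandwich)
standard errors are not implemented.

Relative entropy: 1 − Σ(−p ln p)/(n ln K). BLRT: observed
2(LL_K − LL_{K−1}) against parametric bootstrap replicates from the
fitted (K−1) model, p = (1 + #{boot ≥ obs})/(n_boot + 1); a bootstrap
refit whose statistic is negative (an EM undershoot) is retried with
doubled starts then clamped to zero, and more than 10% unresolved
failures abort. Model selection is lexicographic and declared: smallest
K attaining the minimal BIC, ties toward smaller K; a BLRT disagreeing at
K+1 is logged as a warning rather than overriding BIC. Bootstrap count
defaults to 100.

## Post-hoc statistics

Kruskal–Wallis is tie-corrected with η² = (H − k + 1)/(n − k), clipped at
zero — the form that reproduces both published omnibus effect sizes from
their printed H, k and n. Dunn's z-tests use pooled ranks with the tie
correction; the adjustment method is configurable (Holm by default —
the original adjustment is unstated). The two-sample effect size is the
rank-biserial correlation 1 − 2U/(n₁n₂), reported in place of a
conventional d and labelled as such; both the rank-sum W and
Mann–Whitney U parameterisations are emitted because printed W values do
not disambiguate them. Spearman matrices use pairwise-complete
observations with a 3-pair minimum.

## Pipeline, determinism and problem sizes

A single master seed is split into per-stage seeds via NumPy's
`SeedSequence.spawn`; rerunning an identical configuration reproduces
byte-identical tables (digest-checked in tests). The run manifest records
the config hash, stage seeds, package version, warnings (Heywood,
non-replicated LL, low class probability) and output digests.

Problem sizes used by the validation suite are the package's declared
study conditions: mixture recovery runs at n = 1000 patients against
4000 simulated controls (a large control pool keeps control-SD estimation
error small relative to the recovery bands — with only 25 controls the
±6.5 SD dysconjugacy shift would inherit several tenths of a z-unit of
pure scaling noise); BLRT type-I calibration runs at n = 200, d = 4 with
99 bootstraps and 100 replicates at reduced fitting effort (8 starts, 2
final); factor recovery at n = 5000. The descriptive pipeline default
remains the study-sized 140 patients / 25 controls.

## Known limitations

* Robust (sandwich/satorra-bentler-type) corrections for non-normality
  are not implemented anywhere; all fit statistics are plain ML and
  labelled so.
* The mixture assumes conditional independence given profile (diagonal
  covariance); correlated residuals within profile would be absorbed into
  extra profiles.
* Profile-mean recovery at n = 1000 carries irreducible sampling noise of
  ~0.11 z-units per small-profile cell; recovery bands tighter than ~0.3
  on the max over all cells are seed-sensitive.
* The generator's mechanistic error model yields binomial trial-level
  error counts; real error rates are over-dispersed.
* Visual acuity is simulated phenotype-independent and enters only the
  post-hoc stage, never the mixture.
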