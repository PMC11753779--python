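# Methods

This note documents the models, numerical choices, and limitations behind
`sstpipe`. The package re-creates, on fully synthetic data with known ground
truth, the analysis chain of a multi-dataset stop-signal fMRI study: task
simulation → behavioural QC → ROI first-level GLMs → subject fixed effects →
dataset-aware group mixed effects with FDR and Bayes-factor evidence.

## Task simulation: the independent horse race

Each trial presents a lateralised go stimulus; on a fraction of trials
(25% in all five shipped designs) a stop signal follows after the
stop-signal delay (SSD). The simulator implements the independent race
model: a go process with ex-Gaussian finishing time
`T_go ~ Normal(mu, sigma) + Exp(tau)` races a stop process that finishes at
`SSD + T_stop`, with `T_stop` ex-Gaussian as well. The response is emitted
iff the go process wins. Setting `stop_sigma = stop_tau = 0` makes the stop
latency deterministic and equal to the true SSRT, which gives
parameter-recovery tests an exact target and a closed-form oracle: with a
deterministic latency `L`, `p(respond | ssd) = F_go(ssd + L)` with `F_go`
the ex-Gaussian CDF (`scipy.stats.exponnorm`).

Choices that the race model itself does not pin down:

- **Go omissions** are a Bernoulli failure of the go process to finish
  (probability `p_go_omission`). On a stop trial an omitted go process
  means an automatic successful stop.
- **Choice errors** flip the response side with probability
  `p_choice_error`, independent of timing.
- **Trigger failures** of the stop process are not modelled (probability
  0, not configurable): the implemented race has no trigger-failure term.
- **Negative finishing-time draws** are resampled (truncation at 0) with a
  cap of 100 redraws, after which the draw is clamped and logged. With
  realistic parameters this path is never taken.
- **Onsets** follow a uniformly jittered inter-trial interval
  (default 4 ± 1 s); the source designs do not record their ITIs.
- **Stop-trial count** is `round(total_trials × stop_fraction)` with ties
  toward more stop trials; all shipped designs give integers except
  Miletic_7T (342 × 0.25 = 85.5 → 86).
- **Staircase assignment** is round-robin over the design's interleaved
  staircases in order of stop-trial occurrence.

### Staircases

Each staircase starts at its design's starting SSD and moves by ±50 ms
(down after a failed stop, up after a successful stop), clipped to the
design's SSD range. This tracks the SSD at which the subject responds on
half of the stop trials, so long sessions converge to ~50% stopping
accuracy — the package's headline calibration check (50% ± 2% at ≥20,000
stop trials).

The five shipped designs carry the task/acquisition parameters of the
emulated corpus: TRs of 2.0/2.0/2.0/1.38/3.0 s, total trials
384/128/384/200/342, 25% stop trials, 4/2/4/1/2 staircases, and SSD ranges
100–250, 0–1000, 0–900, 50–900, 0–900 ms. Starting SSDs are not recorded in
that corpus. A generic `DatasetDesign` defaults to the mid-range, but the
shipped wide-range presets set explicit starts of 200–250 ms (the
conventional task choice): starting at 450–500 ms would spend a third of a
short session walking the staircase down and distort accuracy summaries.
Aron_3T (100–250 ms) keeps its mid-range start of 175 ms.

### Default race parameters

Per-dataset defaults use an ex-Gaussian go process with sigma 60 ms and
tau 100 ms — a typical choice-RT spread — and a `go_mu` placed so the
median go RT lands at the corpus' values (423–626 ms); the deterministic
stop latency equals each dataset's reported SSRT (189–256 ms); omission and
choice-error probabilities are at the corpus' low per-dataset rates (≤2%).
Under these defaults, full-length simulated sessions reproduce accuracies
near 50%, plausible SSDs, and failed-stop RTs faster than go RTs. One known
artefact: Aron_3T's narrow 100–250 ms SSD range genuinely ceilings its
staircase under these RT parameters, pinning its stopping accuracy near
60%, so roughly a tenth of simulated Aron subjects trip the
stopping-accuracy exclusion; the other datasets exclude ~0%.

## Behavioural summaries and SSRT

Medians are computed over observed RTs only. The SSRT uses the integration
method with go-omission replacement: omitted go trials are assigned the
slowest observed go RT; the go-RT distribution — including choice-error
responses, per the consensus convention — is sorted ascending, and the stop
process' completion time is the RT at rank `ceil(N × p(respond|signal))`
(the source text says "the nth RT" without a rounding rule; `ceil` is the
consensus-guide convention). SSRT subtracts the **mean** SSD; the median
SSD is also reported since summary tables in this literature print either.
`p(respond|signal)` at 0 or 1 leaves the SSRT undefined (such subjects fail
the QC anyway).

Exclusion criteria (strict inequalities): (1) go omissions > 10%;
(2) stopping accuracy < 35% or > 65%; (3) go accuracy < 95%; (4) mean
failed-stop RT longer than mean go RT. Go accuracy is computed over
responded go trials — omissions are already governed by criterion 1.

The failed-stop vs go RT comparison is a paired t-test on subject medians
plus a JZS Bayes factor on the differences (Cauchy prior scale 0.707, the
conventional behavioural default); the SSRT–go-RT association is a Pearson
correlation with a JZS regression Bayes factor.

## Synthetic BOLD

Each ROI series is `baseline + Σ_c (X_c β_c + Ẋ_c β̇_c) + drift + AR(1)
noise`, where `X_c` are the same convolved condition regressors the
analysis uses. Drift is a sinusoid (default amplitude 2, period 300 s,
random phase) rather than a polynomial so that the high-pass filter's
attenuation is analytically checkable; the AR(1) noise uses innovation SD
`sigma` and lag-1 coefficient `phi` started from stationarity. Optional
voxel blocks scale the ROI signal by each voxel's membership probability
and add independent white noise — the fixture for probability-weighted
extraction and tSNR. Synthetic confounds (six motion-like sinusoids, FD-
and DVARS-like positive noise) are low-amplitude smooth stand-ins; their
generative structure is a package decision, as the consumed nuisance set in
real pipelines is not something this package recomputes.

The ROI roster covers the study's 11 regions (IFG, M1, preSMA, caudate,
GPe, GPi, putamen, SN, STN, Tha, VTA) × 2 hemispheres with membership
probabilities drawn once from U(0.5, 1). What the generator does **not**
emulate: spatial structure and anatomy, physiological (cardiac/
respiratory) noise, susceptibility effects, inter-regional correlation, and
any nonlinearity or regional variation of the haemodynamic response.
Passing tests therefore demonstrate the correctness of the estimation
chain, not robustness to those real-data complications.

## HRF and regressors

The canonical double-gamma HRF is the difference of two gamma densities
(peak delay 6 s, undershoot delay 16 s, unit dispersions, peak:undershoot
6:1, 32 s support), peak-normalised to 1 against a dense reference grid so
its shape does not depend on the caller's sampling. Events are modelled as
zero-duration impulses (the source designs state no event duration), placed
on a 0.1 s oversampling grid, convolved, and sampled at volume times; the
temporal-derivative column convolves with the finite-difference derivative
(step 0.1 s). Under stop-signal locking, FS/SS onsets shift by their SSD.

## First-level GLM

The design matrix holds the three condition regressors and their temporal
derivatives, then nuisance columns, then an intercept. Data and all
non-constant regressors pass through the same discrete-cosine high-pass
filter: all DCT components with period longer than the cutoff (default
128 s) are projected out, which is verified equivalent to including those
components as nuisance regressors. Prewhitening is single-lag AR(1): the
coefficient comes from the lag-1 autocorrelation of OLS residuals, both
sides of the model are quasi-differenced (first row scaled by
`sqrt(1 − phi²)`), and OLS is re-run. This is a deliberate, testable
simplification of FSL FILM's Tukey-tapered autocovariance estimation; the
ROI variant of FILM already runs with its spatial regularisation off, and
at ROI scale a single-lag model captures the bulk of the serial
correlation. Contrasts (FS>GO, FS>SS, SS>GO) weight canonical columns only;
derivative terms get weight 0 (their handling in the source analyses is
unstated). `z = Φ⁻¹(F_t(t; dof))` computed tail-symmetrically for
stability. Runs combine within subject by inverse-variance fixed effects.

ROI extraction is the probability-weighted mean over voxels (weights
normalised to sum 1) — operating directly on the extracted series
reproduces, at the estimation level, inputting region-homogeneous images to
a voxel-wise engine. tSNR is temporal mean over sample SD (ddof 1); the
corrected variant divides by the voxel volume in mm³, removing the trivial
resolution advantage when comparing acquisitions.

## Group inference

Subject-level contrast estimates enter a two-stage mixed model with the
five datasets as variance groups: within dataset *g*, `y_i = mu_g + b_i +
e_i` with known `var(e_i) = varcope_i` and `b_i ~ N(0, tau²_g)` estimated
by REML with `tau² ≥ 0` (the boundary is compared explicitly). Subjects are
weighted `1/(varcope_i + tau²_g)`; the overall effect is the **unweighted**
mean of dataset means — the dummy-variable formulation estimates datasets
separately and then combines, and equal weighting keeps the largest dataset
from dominating. The effect's variance propagates from the weighted-mean
variances; `z = effect/SE` with two-sided normal p. This approximates the
Bayesian variance estimation of FSL FLAME 1; a null-calibration suite
verifies the type-I error of `|z| > 1.96` stays within [0.04, 0.06] at the
corpus' group sizes (14/97/17/31/15).

Multiple comparisons are controlled per contrast family (all ROI ×
hemisphere cells of one contrast) with Benjamini–Hochberg at q = 0.05. The
reported z threshold is the smallest |z| among rejected cells — the value a
reader needs to threshold a result map.

### Bayes factors

Evidence per cell is a JZS Bayes factor with Cauchy prior scale 0.25 on the
standardized effect — fMRI effect sizes are typically small, so the
conventional 0.707 would over-penalise the alternative. The full mixed
model (trial type + dataset + subject) vs null (dataset + subject) is
reduced to a tractable form: the subject random effect is absorbed by the
within-subject condition differencing that produces the contrast estimates,
and dataset enters as a nuisance block under both hypotheses. The grand
effect is the unweighted mean of dataset means, its standard error uses the
within-dataset residual variance on `N − G` degrees of freedom, and the
resulting t feeds the one-dimensional JZS integral (mixing variable `g`
with inverse-gamma prior) with effective sample size `G²/Σ(1/n_g)`, which
collapses to the standard one-sample JZS Bayes factor when G = 1. The
quadrature is adaptive with relative tolerance 1e-10 and raises rather than
returning a value if it fails to converge to 1e-8; tests cross-check it
against Monte-Carlo integration of the same integrand (agreement within 1%)
and against an independent reference implementation (pingouin, to 1e-6).
The correlation Bayes factor integrand is evaluated in log space and
integrated piecewise over decades because its tail stretches across many
orders of magnitude as |r| → 1.

log₁₀ BF values map onto a modified Jeffreys ladder — anecdotal (0–0.5),
moderate (0.5–1), strong (1–1.5), very strong (1.5–2), extreme (>2), signed
toward H1 or H0, exactly 0 labelled "no evidence" — with intervals
half-open on the side away from zero.

## Pipeline and problem sizes

`run_pipeline` executes simulate → QC → first-level → fixed effects →
group → report deterministically from a seeded `StudyConfig`; per-subject
seeds derive from the study seed by hashing, so no stage shares or mutates
global RNG state, and a rerun is table-identical. The report carries the
config hash and package version. The shipped demo sizes (4–6 subjects per
dataset, full per-dataset trial counts, 12 voxels per ROI) keep a full
study run under a few seconds while exercising every stage; the calibration
suites use the sizes stated above (20,000 stop trials for staircase
convergence, 2,500 stop trials per SSRT recovery cell, 10,000 replicates
for group-level error rates).

## Known limitations

- The race model has no trigger failures, no context dependence, and no
  RT–SSD interactions beyond the race itself.
- AR(1) prewhitening under-corrects data whose serial correlation is not
  first-order; FILM's tapered autocovariance is out of scope.
- The group model is empirical-Bayes-flavoured REML, not FLAME's posterior;
  with very small datasets (n < 10) its z can run slightly liberal.
- The JZS contrast Bayes factor is a one-dimensional reduction of the full
  random-effects model; it conditions on the dataset blocking rather than
  integrating over random dataset effects.
- Voxel blocks share a single ROI signal; there is no spatial noise
  structure, so probability-weighted extraction is exercised only in its
  averaging role.
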