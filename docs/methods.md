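# Methods

## Model

The package implements an event-based model (EBM) of disease
progression. The disease is a fixed sequence S of N biomarker events;
an event E_i is the transition of biomarker i from a healthy
distribution P(x|¬E_i) to a diseased distribution P(x|E_i). Each
subject sits at a latent stage k ∈ {0..N}: the first k events of S have
occurred. For cross-sectional data X = {x_ij} the data likelihood of an
ordering is

P(X|S) = Π_j [ 1/(N+1) Σ_k Π_{i≤k} P(x_{j,s(i)}|E) Π_{i>k} P(x_{j,s(i)}|¬E) ].

Assumptions: a single ordering shared by all patients; conditional
independence of biomarkers given the stage; a uniform stage prior; and
cross-sectionally identifiable healthy/diseased components per marker.
Only patient rows enter ordering inference — the patient population is
assumed clinically distinct from controls, which is also what licenses
anchoring the healthy mixture component on controls.

## Per-biomarker mixtures

For each region a two-component Gaussian mixture is fitted by
expectation–maximization to the pooled patient + control sample by
default (the anchored healthy component needs control mass; a
patients-only switch exists). Constraints are enforced by projection
after every M-step:

- the healthy mean is clamped to the Student-t 95% CI of the control
  mean, the healthy SD to the chi-square 95% CI of the control SD
  (exact small-sample intervals; the interval construction is a package
  decision);
- the mixing proportion θ (healthy weight) is clamped to configured
  bounds — [0, 1] by default, per-region overrides available for
  markers that barely discriminate (e.g. a θ > 0.5 floor);
- SDs are floored at 1e-8 (numerical properness), and at 1e-3 for the
  diseased component in the weak cross-validation mode.

Initialization is deterministic and separation-seeking: the healthy
component starts at the control fit; the diseased one at the mean/SD of
values outside the control 95% band, falling back to a 2-SD downward
shift. Convergence: log-likelihood gain < 1e-6 or 500 iterations.

A fit is flagged **collapsed** when θ is within 1e-3 of 0 or 1, or when
the smaller component retains less than two observations' worth of
responsibility mass — a two-parameter Gaussian carried by fewer points
has degenerated onto outliers, which is precisely the biologically
unrealistic solution the exclusion rule below is meant to remove. On
data with no diseased signal, plain EM often leaves a spurious
overlapping second component rather than driving θ to the boundary;
the effective-mass test catches the degenerate outcomes that a pure
θ-threshold cannot.

Robustification: the mixture is refitted on B = 1000 bootstrap
resamples, collapsed replicates are excluded, and the element-wise
median of the surviving parameters (with the retained count) is
reported. All B replicates are run as one vectorized EM over a (B, n)
matrix with per-replicate convergence freezing, so each replicate's
result is identical to a stand-alone fit.

No μ_D < μ_H ordering constraint is imposed by default; a FA-like
strict-decrease option is available but off, since the likelihood alone
decides component roles.

## Ordering inference

All likelihoods are computed in the natural-log domain with
log-sum-exp; per-component log densities are floored at log of the
smallest positive normal double (≈ −708) with a logged warning, so a
single extreme outlier cannot produce −∞.

- **Greedy ascent**: from random start permutations, repeatedly accept
  the best improving pairwise swap until none improves; best of 10
  restarts initializes the chain.
- **MCMC**: Metropolis over permutations; proposal swaps two distinct
  positions chosen uniformly; acceptance min(1, likelihood ratio) under
  a uniform prior over orderings. Defaults: 100,000 iterations, 10,000
  burn-in — package decisions, all configurable. The MAP is the
  highest-likelihood ordering visited anywhere in the chain; ties go to
  the first ordering encountered, deterministic under the seed.
- **PVD**: V[i, p] = fraction of post-burn-in samples placing event i
  at position p, rows indexed by a reference ordering (the MAP by
  default). Every sample is a permutation, so V is doubly stochastic.

## Cross-validation

B = 10,000 bootstrap replicates by default: patients and controls are
resampled with replacement *within group* (group sizes preserved — the
pooled-resampling alternative is not what a case-control design
suggests), control Gaussians and mixtures are refitted per replicate
with a single direct EM under weak constraints (θ ∈ [0.01, 0.99],
σ_D ≥ 0.001), and the most likely ordering is re-estimated by greedy
ascent with 5 restarts (a full-MCMC replicate would add nothing, since
only the per-replicate ML ordering is accumulated). Replicate failures
are logged and skipped; more than 50% failures aborts. The resulting
PVD overstates ordering uncertainty relative to the MCMC PVD — that
conservatism is the point of the procedure, and is verified by
comparing mean row entropies. The CV PVD's reference ordering defaults
to the full-data ML ordering through the same direct-fit path and can
be overridden (e.g. with the MCMC MAP) for side-by-side display.

## Staging and classification

Each subject (patients and controls alike) receives the
maximum-likelihood stage argmax_k of the staged product along the MAP
ordering, with ties resolved to the lowest stage (conservative toward
healthy). All biomarkers are retained even if weakly discriminative.
A cut-off c turns staging into a classifier (diseased iff stage ≥ c);
sensitivity is non-increasing and specificity non-decreasing in c by
construction.

## Age correction

A per-region ordinary least-squares line of value on age is fitted on
controls only; the fitted slope is regressed out of every subject,
anchored at the control mean age so values keep their FA scale and the
control mean per region is unchanged. Residualization is idempotent:
refitting on residualized controls gives zero slopes. Subjects with
missing age are rejected (no imputation anywhere in the package).

## Synthetic cohorts

The generator realizes the model's own generative process: controls
draw every region from Normal(μ_H, σ_H); each patient draws a latent
stage k from a stage distribution (uniform on {0..N} by default,
matching the staging prior), then draws the first k ordered regions
from Normal(μ_D, σ_D) and the rest from Normal(μ_H, σ_H). Optional
linear age slopes and additive site offsets are layered on afterwards.
A single RNG stream is consumed subject-by-subject, region-by-region,
so cohorts are byte-reproducible from the seed. The latent truth is
returned separately (and written to a sidecar file by the CLI), never
into the biomarker table.

Default parameters are plausible FA-scale stand-ins, not measured
values — no per-tract effect sizes are published for this disease:
healthy means 0.42–0.68 by tract family (projection/commissural tracts
high, long association fibers lower), σ_H = 0.025, σ_D = 0.030, and a
diseased shift of 3 healthy SDs (FA decreases with white-matter
damage). What the generator deliberately omits: between-region noise
correlation, longitudinal trajectories, heterogeneous orderings across
patients, and non-Gaussian FA artifacts. Passing tests therefore
demonstrate that the inference machinery recovers the truth *when the
model is correctly specified*; they say nothing about robustness to
model misspecification on real MRI data.

## Validation experiments and problem sizes

The test-suite and `scripts/acceptance.py` experiments use these
scales, chosen so the whole battery runs on a laptop-class single core
in minutes:

- exhaustive-oracle agreement: 20 cohorts, N = 5 regions, 150/130
  subjects, 3-SD separation, B = 50 mixture bootstraps, 10,000 MCMC
  iterations — the sampled MAP must equal the brute-force argmax over
  all 120 orderings;
- ordering recovery: 20 cohorts, N = 11, 150/130, 2.5-SD separation,
  full defaults (B = 1000, 100,000 iterations) — normalized Kendall
  distance of MAP vs truth;
- mixture recovery: 50 replicates of n = 280 from a well-separated
  known mixture (0.55/0.02 healthy, 0.42/0.025 diseased, θ = 0.5) with
  the control anchor fitted on 2000 healthy draws, so the experiment
  isolates the patient-sample information limit. At n = 280 the
  sampling SE of θ and σ_D is ≈ 6% of their values, so the 10% recovery
  band sits at ≈ 1.7 SE — the experiment probes the estimator's
  efficiency frontier, and rates near 90% are the information-theoretic
  ceiling, not an implementation deficit;
- MCMC calibration: N = 3 with all densities equal (posterior exactly
  uniform); frequencies of the 6 orderings are compared to 1/6 using
  batch-means Monte-Carlo standard errors, which account for the
  autocorrelation of the transposition walk;
- cross-validation conservatism: one 3-SD cohort, CV with B = 100
  replicates vs a 100,000-iteration MCMC PVD, compared by mean row
  entropy;
- staging: on a 2.5-SD recovery cohort, agreement of assigned vs truth
  stages within ±1 and the stage-1 cut-off's sensitivity/specificity.
  Under a uniform stage distribution ≈ 1/12 of patients truly have no
  events, capping attainable sensitivity at ≈ 0.92.

## Known limitations

- Projected EM is not guaranteed monotone in the constrained likelihood
  at every step (clamping can cross level sets); in practice it
  converges and, with constraints disabled, matches an unconstrained
  reference EM's optimum to < 1e-6 (tested).
- The stage-conditional independence assumption ignores spatially
  correlated FA noise; on real data the PVD is accordingly expected to
  be over-confident, which is why the bootstrap cross-validation view
  is produced alongside it.
- A single ordering is assumed for the whole cohort; no
  subtype-and-stage extension is provided.
- Stages are ordinal model indices, not calendar time.
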