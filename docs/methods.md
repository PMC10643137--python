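# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the order data flows through it.

## Trajectory model and linking

A trajectory is an ordered sequence of positions (µm) at a uniform frame
interval Δt (s), in the native dimensionality of the experiment (3D for
single-molecule double-helix-PSF data, 2D for tracked genomic loci). The
two data regimes the defaults target are 20 ms exposure (freely diffusing
plus bound molecules; localization precision ≈ 60 nm) and 500 ms exposure
(motion blurring suppresses fast molecules, enriching for chromatin-bound
ones; precision ≈ 34 nm).

Linking connects detections in **consecutive** frames within a search
radius (0.8 µm at 20 ms, 0.5 µm at 500 ms). Candidate pairs are resolved
greedily in ascending distance, each endpoint used once — equivalent to
optimal matching in the sparse under-labelled regime the method assumes.
No gap closing is done by default; a `max_gap` option joins chain ends
across skipped frames (radius scaled by the number of frames bridged) and
fills the gap by linear interpolation so downstream code can keep the
consecutive-frame invariant. Fragments shorter than two points are
discarded; analysis-level duration filters (e.g. keep 500 ms trajectories
longer than 5 s) are applied downstream, not at linking time.

## Window features

Every stride-1 window of 11 frames yields four parameters. The window
TA-MSD at lag ℓ averages squared displacements over **all** in-window
pairs ℓ frames apart; lags run 1..5 (about half the window — the usual
bias/variance compromise for short windows).

- **α** — ordinary-least-squares slope of log MSD vs log(ℓΔt).
  Two corrections, both optional and on by default where indicated:
  1. *Static-error correction* (`WindowConfig.loc_sd`, default 0 — set it
     to the measured precision): localization noise adds the constant
     2·dim·σ² to every MSD lag, flattening the log-log curve and biasing
     α toward 0; the constant is subtracted before the fit. Windows whose
     corrected MSD is not positive at a fitted lag are flagged degenerate
     (α = NaN) and excluded from mixture fitting rather than imputed.
  2. *Small-sample bias correction* (`alpha_bias_correction`, default on):
     because E[log m] = log M − Var(m)/(2M²) and the TA-MSD variance grows
     with lag, the raw slope is biased low (about −0.07 for Brownian
     motion at these window sizes). The per-lag variance follows in
     closed form from the fractional-Gaussian-noise covariance, so the
     correction is evaluated at a first-pass α estimate and the slope
     refitted (a precomputed grid over α ∈ [0.05, 2] keeps this cheap).
     After correction the mean window α is unbiased to < 0.01 across
     α ∈ {0.4, 0.7, 1.0}. The pure OLS operation remains available
     unchanged for exact-MSD inputs.
- **D_app** = MSD(1)/(2·dim·Δt) — the minimal-lag estimator, least biased
  by subdiffusive curvature. It deliberately **includes** the noise floor
  σ²/t (a separate `precision_floor` operation reports that bound:
  0.06²/0.02 = 0.18 µm²/s at 20 ms, 0.034²/0.5 ≈ 0.002 µm²/s at 500 ms);
  measured coefficients below the floor have no biophysical meaning.
- **Lc** — RMS distance of window points from their centroid: a
  transparent, dimension-consistent measure of the spatial scale explored,
  isolated behind one operation so another estimator can be substituted.
- **‖V‖** — norm of (last − first)/((w−1)Δt), the mean per-frame
  displacement vector divided by Δt.

2D and 3D features are never pooled (the pooling operation refuses mixed
dimensionality): the parameters are not comparable across dimensionality.

## Stage-1 mixture classification

Valid windows pooled over all trajectories are z-scored per feature (the
four parameters have incommensurate units) and fitted with a
full-covariance Gaussian mixture (EM; k-means++ initialization from the
supplied seed, 10 restarts, best likelihood kept; covariance
regularization 1e-6). Rows are put in a canonical lexicographic order
before fitting so the result is invariant to input permutation. The
confined component is the one with the smaller mean D_app (ties: smaller
mean α), which makes labels canonical under component relabelling. An
overlap diagnostic compares the mixture's BIC against a single-Gaussian
fit; a two-component fit that does not beat one component is flagged
degenerate.

Each frame takes the posterior of the window centred on it; the first and
last (w−1)/2 frames take the nearest window's posterior. A frame is
confined iff P > 0.5 — a tie is unconfined, reading the "P > 1 − P" rule
strictly. State fractions are reported both window-weighted and
trajectory-weighted (majority rule over a trajectory's assigned frames);
the aggregation the underlying method intended is not stated, so both are
first-class.

## Stage-2 substates (500 ms data)

Trajectories lasting more than 5 s are kept. Stage 1 splits bound windows
into slow (S) and fast classes; Stage 2 fits a two-component 1D Gaussian
mixture to the **α values of fast windows only** — F1 is the
lower-α (condensed) and F2 the higher-α (decondensed) component, ordered
by mean. The S proportion is the slow share of windows; F1/F2 split the
fast share by the fitted weights. Drift is reported alongside F2 calls
(the decondensed state shows directional movement) but does not enter the
Stage-2 fit. Bootstrap percentile CIs (default 1,000 resamples, seeded;
refits initialized at the point estimate) cover means, SDs, weights and
the three proportions. Posterior ties go to F1.

## Kinetics

Association dwells are maximal unconfined runs flanked on both sides by
confined frames (dissociation: roles swapped); runs touching a trajectory
end or an unassigned frame are censored. The default fit is maximum
likelihood on uncensored durations, λ = 1/mean, with the exact 95% CI
from 2λΣd ~ χ²(2n); a right-censoring-aware variant (λ = events / total
observed time) is provided. Goodness of fit is a one-sample KS test
against the fitted exponential. Histogram least-squares is deliberately
avoided: binning is an unstated free parameter.

Dissociation analysis is implemented but unreliable for factors that stay
bound longer than photobleaching allows observation; the supported route
is the time-lapse model. With integration time t_int and lapse τ, the
per-frame survival probability is exp(−(k_bleach·t_int + k_off·τ)), so
observed track lengths are geometric; a joint ML fit across ≥ 2 lapse
conditions (bounded L-BFGS-B; CIs from the numerical observed-information
matrix) identifies both rates. When the k_off interval includes 0 the fit
is flagged bleach-dominated — residence time has no measurable effect at
the probed lapses, and only a lower bound on the residence time is
implied. A single condition raises an unidentifiability error naming both
parameters.

## Simulator

Ground truth for every estimator above:

- *brownian*: Gaussian increments, variance 2DΔt per axis.
- *fbm*: exact-covariance fractional Gaussian noise via Davies–Harte
  circulant embedding (Cholesky fallback when the embedding is not
  nonnegative definite, e.g. very short paths), Hurst H = α/2, one-step
  increment variance 2DΔt — so D is the *apparent* (lag-1) coefficient
  and the lag-ℓ MSD is 2·dim·D·Δt·ℓ^α. Validated against the analytic
  autocovariance at lags 1–10.
- *confined_ou*: exact discretization of an Ornstein–Uhlenbeck process,
  parameterized by stationary SD per axis and relaxation time.
- *directed*: Brownian plus constant velocity.
- *switching*: continuous-time Markov chain over sub-specs with
  exponential holding times, sampled onto the frame grid; each step's
  increment follows the state at the step's start, fBM memory resets at
  switches, and an OU state re-centres where the molecule binds.

Localization noise is added per frame (optionally z-anisotropic, since
axial precision differs in practice); photobleaching truncates tracks by
a geometric draw; a detection-gap probability — optionally applied only
above a per-frame displacement threshold, emulating motion-blur loss of
fast molecules — splits tracks the way a frame-to-frame linker would.
Full intra-exposure averaging is out of scope.

### Benchmark scenarios (the study conditions)

- `stage1_20ms`: Δt = 20 ms, 60 nm noise; 55% bound (fBM α = 0.5,
  D_app = 0.43 µm²/s) vs free (Brownian, D_app = 1.3 µm²/s); default 500
  tracks of 31 frames. These mobility scales follow the two states the
  segmentation is meant to separate in fast-exposure data.
- `stage2_500ms`: Δt = 0.5 s, 34 nm noise; S/F1/F2 at 67/26/7% with
  α = 0.59/0.60/0.89 and D_app = 0.006/0.018/0.018 µm²/s. F2 additionally
  carries a 0.2 µm/s directed velocity in a random direction — it is
  generated as a *directed* high-α state, the clear directional
  excursions characteristic of decondensed chromatin motion. Because of
  that deterministic component the *measured* window exponent of F2
  centres near 1.1–1.2 rather than at the nominal 0.89; the recovery
  criterion is on the state **proportions**, which the two-stage fit
  returns within ±3 points at 10⁴ windows. Track length defaults to
  31 frames (15.5 s, comfortably past the 5 s duration filter).
- `timelapse`: the lapse ladder {0.5, 2.5, 8, 32} s at t_int = 0.5 s,
  defaults k_off = 0.01 s⁻¹ and k_bleach = 0.5 per unit exposure.
- `locus2d`: the stage-2 mixture in 2D, emulating tracked enhancer loci.

What the generator does **not** emulate: intra-exposure motion blur as an
image-formation process, detection-intensity fluctuations, localization
ambiguity in dense fields, state-dependent localization precision, and
chromatin-context correlations between states. Passing the benchmark
therefore shows estimator and classifier correctness under the stated
motion models, not robustness to every imaging artefact of real data.

## ABC links

Coordinates are 0-based half-open throughout; the TSS is the strand-aware
5′ end. Promoters are ±1 kb of a TSS overlapping (≥ 1 bp) an H3K4me3
peak; genes with several TSS yield several promoters. H3K27ac peaks are
merged when their gap is strictly < 500 bp (bookended intervals always
merge), merged peaks shorter than 500 bp are dropped, peaks overlapping a
promoter are dropped, and the master element list is the union of the
survivors and the promoters. Activity is the mean per-base H3K27ac signal
over the element.

Contacts live in a symmetric 5 kb-binned sparse matrix (plain triplet TSV
plus a JSON header sidecar). The distance-decay exponent γ is the
negative log-log slope of the genome-average contact vs distance over
10 kb–5 Mb. A bin pair is *poorly covered* when either anchor bin's
marginal coverage falls below the 5th percentile of its chromosome
(configurable — the cutoff is not externally specified); such pairs are
imputed from the fitted curve exp(intercept)·d^(−γ), anchoring the
power law to the matrix's own decay. Pseudocounts are 0 by default:
imputation, not pseudocounts, handles sparsity.

Scores are normalized per promoter over all candidate elements within
5 Mb on the same chromosome (trans pairs are never candidates; the
promoter's own element is excluded from its candidate set, since a
self-link is not an enhancer–promoter pair). Strong links are those at or
above the pooled (all-conditions) 90th-percentile score; ties at the
threshold are kept, so the strong set may slightly exceed the nominal
decile, and the realized threshold is reported. Link IDs are
(promoter, element, promoter position); categories are common (above
threshold in every condition) or condition-unique. Link-length
comparisons use a two-sided Mann–Whitney U test (a rank test in place of
any parametric alternative), counting each link ID once. Enrichment
against gene-regulation labels (an input table, not computed here) is a
χ² test on the category × label contingency with per-cell fold
enrichment observed/expected; a warning recommends an exact test when an
expected count falls below 1.

## Reproducibility plumbing

A single master seed fans out to per-stage seeds via SHA-256 of
(seed, stage name), all below 2³¹. Run manifests record the package
version, the config hash (SHA-256 of the canonical JSON), and input file
checksums. Same seed + same inputs → byte-identical outputs (floats are
written with `%.17g` and read back with round-trip parsing).

## Known limitations

- The window estimators are documented proxies chosen for transparency;
  each is isolated behind a single operation for later substitution.
- The α bias correction assumes fGn statistics; for deterministic
  (purely ballistic) windows it is slope-neutral only in the limit, so
  exact-power-law identities are stated for the uncorrected OLS operation.
- Hard slow/fast assignment before the Stage-2 fit leaves a small
  (< 2-point) leakage bias between S and F1 at realistic overlap.
- The time-lapse CIs use the observed-information approximation, which is
  conservative near the k_off = 0 boundary (by design: the boundary case
  is exactly the bleach-dominated diagnostic).
- Hi-C normalization, compartment and TAD calling are out of scope; the
  contact matrix is consumed as given.
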