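# chromodyn

Toolkit for two linked questions about chromatin regulators such as the
NuRD (nucleosome remodeling and deacetylase) complex:

1. **How do single molecules move?** Segmentation of 3D (or 2D) single-
   particle-tracking trajectories into chromatin-bound (confined) and
   freely diffusing (unconfined) intervals, resolution of bound-state
   substates, and extraction of binding kinetics — with a validated
   trajectory simulator providing ground truth for every estimator.
2. **Which enhancers talk to which promoters?** An activity-by-contact
   (ABC) model that scores promoter–regulatory-element pairs from Hi-C
   contacts and H3K27ac signal, calls strong links, and compares link sets
   between conditions (e.g. wild-type vs knockout).

It is aimed at groups doing live-cell single-molecule imaging (HaloTag/
JF dyes, double-helix PSF or 2D tracking) combined with Hi-C and
ChIP-seq/CUT&RUN profiling.

## The core methods

**Trajectory segmentation.** For a sliding window of 11 consecutive
frames, four biophysical parameters are computed:

- the anomalous exponent *α* — the log–log slope of the time-averaged MSD
  over lags 1..5 (MSD ∝ t^α; α ≈ 1 free diffusion, α < 1 subdiffusive,
  α > 1 directed), with a small-sample bias correction and optional
  static-localization-error correction;
- the apparent diffusion coefficient *D*<sub>app</sub> = MSD(Δt) / (2·dim·Δt);
- the localization length *L*<sub>c</sub> — RMS distance of window points
  from their centroid;
- the drift magnitude ‖**V**‖ — norm of the window-averaged velocity.

A two-component full-covariance Gaussian mixture over the standardized 4D
feature space classifies every window; each frame takes the posterior
*P* of the window centred on it and is called confined when *P* > 1 − *P*.
For slow (500 ms exposure) data a second stage fits a 1D Gaussian mixture
to the α values of the fast windows, resolving the slow state S and two
fast substates F1 (condensed) and F2 (decondensed, high drift).

Dwell-time kinetics: association times are maximal unconfined runs flanked
by confined frames, fitted by maximum likelihood with λ = 1/⟨T⟩ and exact
χ² confidence intervals. When photobleaching truncates observation, the
time-lapse model exp(−(k_bleach·t_int + k_off·τ)) over several lapse times
τ separates the unbinding rate from the bleaching rate.

**ABC links.** For promoter *p* and element *r*,

    ABC(p, r) = A_r · C(p, r) / Σ_{s ∈ N(p)} A_s · C(p, s)

with N(p) all candidate elements within 5 Mb, A the mean per-base H3K27ac
signal and C the 5 kb-binned Hi-C contact (power-law imputation
C ∝ d^−γ for poorly covered bins). Strong links are the top decile of the
pooled two-condition score distribution; links are categorized as
condition-unique or common by ID, compared by genomic length (rank test)
and tested for enrichment against gene-regulation labels (χ²).

## Worked example

Simulate a 20 ms-exposure benchmark (freely diffusing molecules at
D<sub>app</sub> ≈ 1.3 µm²/s mixed with chromatin-bound fBM at α = 0.5,
D<sub>app</sub> ≈ 0.43 µm²/s, 60 nm localization noise), then segment it:

```sh
chromodyn simulate --scenario stage1_20ms --seed 3 --n-tracks 80 --out-dir sim/
chromodyn segment --trajs sim/trajectories.csv --truth sim/truth.csv \
    --seed 3 --out-dir seg/
cat seg/report.json
```

```json
{
 "fractions_windows": {
  "confined": 0.5592741935483871,
  "unconfined": 0.4407258064516129
 },
 "fractions_trajectories": {
  "confined": 0.55,
  "unconfined": 0.45
 },
 "degenerate": false,
 "frame_accuracy": 0.9826612903225806
}
```

The confined fraction (~56% of windows, 55% of trajectories) recovers the
generator's bound fraction, and 98% of frames are labelled correctly
against the simulation's ground truth. `seg/labels.csv` holds the
per-frame posteriors and labels; `seg/state_means.csv` the fitted state
parameters (the confined component shows the lower D_app and α).

The same pattern drives the other subcommands: `substates` (two-stage
S/F1/F2 analysis), `kinetics` (dwell times and λ), `abc-call` /
`abc-compare` (link scoring and condition comparison). Every run writes a
manifest with the config hash and input checksums; identical seeds give
byte-identical outputs.

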