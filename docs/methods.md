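# Methods

This note documents the models and procedures frostspec implements, the
defaults that matter, the synthetic-data generator's assumptions, and the
numerical/design choices made where the underlying methodology leaves the
design open.

## Index construction (LTRI)

The index is built on the n × 6 panel of SPAD, SS, MDA, CAT, POD, SOD by
correlation-matrix PCA of the z-scored variables (sd with n−1 denominator).

- **Loading convention.** `pca_correlation` emits correlation-scale factor
  loadings, eigenvector · √λ. Under this convention the linear combination
  coefficients LCC = loading/√λ are exactly the unit eigenvector entries,
  which is the only convention that reproduces the reference coefficient
  tables end to end. The per-variable squared loadings sum (over all
  components) to 1 and each loading column has squared norm λ.
- **Component retention.** Kaiser rule (λ > 1) by default; `top_k` and a
  cumulative-contribution threshold are available.
- **Composite coefficients.** CSC_i = Σ_j LCC_ij · VC_j / CVC_m with VC the
  variance contribution (percent) of each retained component and CVC_m their
  cumulative sum. When the chain is driven from printed tables, the printed
  (rounded) VC/CVC values are used as given rather than recomputed, so the
  worked example reproduces the published arithmetic exactly.
- **Normalization.** w = CSC / Σ|CSC|: signs preserved, Σ|w| = 1. This is
  the "percentage method" reading that reproduces the reference weights.
- **Orientation.** Eigenvector signs are arbitrary. Within a component,
  the largest-|loading| entry is made positive; after normalization the
  fitted index is additionally oriented so the SPAD weight is positive.
  Chlorophyll falls under cold stress, so this makes lower index values mean
  greater damage. Orientation is a model-level convention only; when
  coefficients are computed from explicitly supplied loading tables the
  signs follow the tables.
- **Scoring.** New samples are standardized with the fitted panel's
  means/sds and scored as Σ w_i z_i. Scores are therefore invariant to
  affine rescaling of any raw component when the model is refit.

A known arithmetic subtlety: the reference table chain yields −0.332 for
the CAT entry of the first component (−0.562/√2.862), and only that value
propagates consistently to the composite coefficient −0.398. The package
follows the arithmetic.

## Synthetic-data generator

The generator emulates the study design — 2 cultivars × 6 treatments
(25 °C / 4 °C / −4 °C for 8 or 12 h) × 16 plants = 192 samples — and the
response structure the analysis assumes:

- **Biochemistry.** Each component is its treatment-cell mean plus Gaussian
  noise, clipped at a small epsilon (1e−3) for positivity. Default mean
  curves respect the observed trends (SPAD decreasing with stress severity
  CK8 < CK12 < C8 < C12 < F8 < F12; SS and MDA increasing; CAT/POD/SOD
  peaking under chilling and declining under freezing) and keep essentially
  all draws (≥99% per component) inside the observed min–max envelopes.
  Cell means and noise sds are free configuration, validated against the
  trend flags. Cultivar offsets default to zero (cultivars are pooled
  downstream).
- **Spectra.** Reflectance = smooth vegetation baseline (sigmoid red-edge
  rise from ~0.12 visible to ~0.57 NIR) minus component-linked Gaussian
  absorption features, then per-sample affine scatter a·s + b
  (a ∈ [0.97, 1.03], b ∈ [−0.01, 0.01]) and i.i.d. band noise (sd 0.003).
  The affine scatter is exactly the distortion class MSC removes, which
  makes preprocessing testable. Feature depth is linear in the component's
  position within its observed range; the chlorophyll feature sits at
  665 nm (width 35 nm, depth up to 0.15), with further features at
  540/715/800/890/960 nm. Bands within one width of any center are recorded
  as the planted "informative set".
- **Cubes.** Small H × W × B fixtures: a central leaf block carrying a
  given spectrum plus pixel noise on a dark background, with the mask
  stored, for testing threshold segmentation and ROI averaging.

What the generator does **not** emulate: radiative transfer (no
PROSPECT-style leaf optics), instrument artifacts beyond affine scatter and
white noise, cultivar-specific biology, or nonlinear component–reflectance
links. Passing tests therefore demonstrate correctness of the pipeline's
machinery and its statistical calibration on data satisfying its own
assumptions — not field performance on real leaves.

Because the spectra are linear in the six components plus removable scatter,
recovery benchmarks on synthetic data are easy by construction (full-band
PLS reaches Rp² ≈ 0.98 at default noise); they are signal-recovery checks,
not performance claims.

## Preprocessing

- Black/white correction C = (R − D)/(W − D), elementwise, with an explicit
  zero-denominator error naming the offending position; optional clipping to
  [0, 1] behind a flag (default off).
- ROI: pixels whose mean-over-bands intensity exceeds a threshold (default
  Otsu); per-band mean over the mask.
- MSC: per-spectrum least-squares fit s ≈ b·ref + a, corrected = (s − a)/b.
  The default reference is the mean of the corrected set; when correcting
  held-out spectra the calibration-set mean should be passed explicitly.
  Slope magnitudes below 1e−8 raise a degenerate-spectrum error.
- Savitzky–Golay via `scipy.signal.savgol_filter(mode="interp")` (local
  polynomial per window; terminal windows extrapolated). Defaults window 11,
  order 2 — not dictated by the methodology, chosen as the common
  chemometric default and configurable.
- First derivative: forward difference over Δx, output length B−1 with
  midpoint wavelengths as its axis. Δx defaults to the mean axis spacing
  (≈3.49 nm at 176 bands over 397–1008 nm).
- Chain order: MSC → S-G → 1stD (scatter removal before smoothing before
  differencing), configurable.

## Wavelength selection

All selectors operate on a native NIPALS PLS1 (below) and are deterministic
given their seed; diagnostics (RMSE paths, retention schedules, reliability
vectors) are returned for replay.

- **SPA** (defaults: chain lengths 1–30, 20 random starting columns).
  Chains grow by adding the column with the largest residual norm after
  projection onto the chain's span (verified step-by-step against an
  explicit Gram–Schmidt oracle). Each chain prefix is scored by
  multiple-linear-regression RMSE on a held-out 30% split; the global
  minimum wins.
- **CARS** (defaults: 300 Monte-Carlo runs, 10-fold CV, ≤10 PLS components,
  80% calibration subsampling). Retention ratios follow r_i = a·e^(−k·i)
  with endpoints fixed at r_1 = 1 and a final retained count of 2 (for
  B = 176, r_N = 2/176); each run keeps the top-weight variables by
  |PLS coefficient| (enforced decay) and then resamples within that count
  proportionally to weight (adaptive reweighted sampling). The subset with
  minimal CV-RMSE over runs is returned.
- **UVE** (defaults: 5 PLS components, one appended noise variable per real
  band at 1e−10 of signal magnitude, cutoff 0.99, leave-one-out over the
  calibration samples). Reliability c_j = mean(b_j)/sd(b_j) over the
  resampled coefficient matrix; real variables are kept when |c_j| exceeds
  the cutoff quantile of |c| over the noise block. The PLS fits inside UVE
  autoscale columns: with centered-only fits the tiny noise columns cannot
  influence the latent space while real columns do, which inflates null
  false-retention to ~2–3×; autoscaling restores exchangeability between
  noise and uninformative real variables so the quantile threshold is
  calibrated (measured ≈0.9% retention under a null response at cutoff
  0.99). A Monte-Carlo resampling mode (700 draws of 80%) is available
  behind a flag.

## Regression families

PLS is implemented natively (NIPALS, single response, centered and
optionally autoscaled; iteration cap 500 at tolerance 1e−6; coefficient
vector exposed on the raw scale for the selectors; degenerate problems fall
back to an intercept-only model). Defaults per family (shipped in
`data/model_defaults.yaml`): PLS 2 components; SVM polynomial kernel
(degree 3), C = 1, tol 1e−3; RF 200 trees, min leaf 5, full bootstrap;
BP one hidden layer of 32 units, plain SGD, lr 0.01, batch 64, 400 epochs;
CNN three same-padded ReLU convolutions (16/32/64 channels, kernel 3), one
max-pool (2), dropout 0.5, dense output, Adam lr 0.001, 400 epochs, inputs
row-L2-normalized; LSTM 20 hidden units over the band sequence, dropout
0.5, Adam lr 0.001, 40 epochs. SVM/RF/BP are backed by scikit-learn; the
CNN and LSTM are plain-numpy implementations with hand-derived gradients
(validated against finite differences to ~1e−10) and internal response
standardization. CNN kernel/channel/pool sizes and the BP width are
package choices where the methodology names only the layer structure.
No early stopping anywhere: epoch counts are fixed.

## Evaluation protocol

k-fold random partition in which the first k−1 folds take ⌈n/k⌉ samples:
at n = 192, k = 5 this yields four folds of 39 and one of 36, and the
maximal-size folds are the evaluated repeats — 39 test / 153 training
samples per repeat, metrics averaged over the four repeats. R² uses the
evaluated set's own mean; RMSE is the root mean squared residual;
RPD = 1/√(1 − Rp²), which equals SD(y_test)/RMSEP on the same set (checked
to 1e−10). RMSEV comes from an inner 80/20 split of each calibration fold.
Band selection is refit per repeat on calibration rows by default
(leakage-safe); a "once" mode selects a single subset on all samples.
The full grid is 7 targets (six components + LTRI) × 4 band treatments
(CARS/SPA/UVE/NONE) × 6 families = 168 cells; per-cell failures are
recorded without aborting the grid, and the per-target best model is the
maximal-Rp² cell with ties broken by lower RMSEP (equivalently by RPD,
which is monotone in Rp²).

## Problem sizes in the shipped test suite

The generator's defaults are the study conditions (192 samples × 176
bands) and are used wherever the check concerns them (design counts,
envelopes, wavelength axis, CV arithmetic). Model-grid and
selector-recovery exercises run on reduced instances as the package's
desk-scale choice: the 168-cell grid on 60 samples × 40 bands with reduced
network epochs and selection fit once on the calibration partition;
recovery benchmarks on 120 bands with narrowed (10 nm) absorption features
so the planted informative set spans ~25% of the axis — with the default
20–35 nm widths the planted set covers over half the axis and an
overlap-versus-random comparison has no statistical power regardless of
selector quality. Calibration and recovery claims use 50 seeds with a
pooled binomial test (UVE null retention) and a permutation test against
size-matched random subsets (p < 0.05).

## Known limitations

- The fitted index is only guaranteed monotone in stress severity insofar
  as the monotone components dominate the retained PCA structure. In the
  zero-noise limit of the generator the enzyme block is perfectly
  internally correlated and rise-then-fall by construction, so the index
  bends upward again at the freezing end; controls still separate cleanly
  from all stressed groups. Real panels, with imperfect enzyme
  correlation, sit between these regimes.
- The numpy CNN/LSTM are faithful small reference implementations, not
  performance-tuned learners; at reduced epochs on small synthetic sets
  they underperform PLS on linear targets, as expected.
- UVE's "Leave-One-Out" resample count is interpreted as leave-one-out
  over calibration samples; the Monte-Carlo mode exists for resampling
  counts exceeding n.
- Whether preprocessing/selection variants should differ per target is
  left to configuration; the pipeline applies one chain to all targets.
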