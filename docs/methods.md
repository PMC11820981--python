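# Methods

This note documents the models and procedures implemented in `imsnose`,
the assumptions behind them, the defaults and why, and what the synthetic
validation does and does not demonstrate.

## Data model

A measurement is an `IMSMap`: an `n_ret × n_drift` intensity matrix with a
strictly increasing drift axis (ms) and retention axis (s). Datasets are
ordered collections of maps sharing one classification problem; after
alignment all maps share identical axes. Modelling uses the *full-matrix*
representation: maps are unrolled row-major with retention as the slow
axis, so a feature-space vector reshapes back into map coordinates with a
single `reshape` — this is what makes VIP maps cheap. I/O is plain CSV
(header row = drift axis, first column = retention axis) or an HDF5
container (`/samples/<id>` groups with intensity and axis datasets, label
attributes, sample order stored at the root). Proprietary acquisition
formats are out of scope; conversion is the user's responsibility. Axis
units are fixed at the I/O boundary (ms drift, s retention).

## Denoising

Savitzky–Golay filtering with polynomial order 2 and a 9-point window,
applied per drift spectrum. SG is the appropriate filter class here
because classification rides on peak *positions*: a centred local
polynomial fit preserves position and height up to its order. Interior
points use the standard convolution (via `scipy.signal.savgol_filter`);
the first/last 4 points are refit on the truncated window with the same
order, so the output keeps the input length without mirror artefacts.
Both parameters are exposed (`sg.order`, `sg.window`); the window is an
independent setting, not derived from peak widths.

## Baseline correction (AsLS)

Per spectrum, the baseline minimises an asymmetrically weighted residual
plus a second-difference smoothness penalty:

    S(b) = Σ wᵢ (yᵢ − bᵢ)² + λ Σ (Δ²bᵢ)²,
    wᵢ = p  if yᵢ > bᵢ,   wᵢ = 1 − p  if yᵢ < bᵢ.

Defaults λ = 1e5, p = 5e-3. Implementation notes:

* Δ² is the standard (n−2)×n second-difference operator; the normal
  equations `(W + λDᵀD) b = W y` are pentadiagonal, symmetric positive
  definite, and solved with a banded Cholesky (`solveh_banded`), O(n) per
  iteration. A dense direct solve is kept as a test oracle only.
* Weights start at 1 (the first pass is an ordinary Whittaker-type
  smooth); iteration stops when the weight vector stops changing or after
  `max_iter = 10` passes. On realistic spectra the discrete weight update
  settles in 4–8 iterations. An optional relative L1 threshold (`w_tol`)
  exists for very long spectra; the default demands exact stability.
* The tie `yᵢ = bᵢ` gets weight p (the asymmetric rule covers only strict
  inequalities; the case has measure zero).
* `p = 0.5` with λ → 0 degenerates to an ordinary least-squares fit that
  follows the signal — a useful sanity limit, tested.
* No clipping of negative residuals after subtraction: the classifier
  centres the data anyway, and clipping would bias peak shapes.
* Repeated application is *approximately* idempotent: a second pass
  subtracts a baseline sitting near the lower envelope of the remaining
  noise, i.e. shifts the spectrum by roughly two noise standard
  deviations. This is inherent to an asymmetric fit, not a defect; it is
  why the pipeline applies the correction exactly once.

## Alignment

The reactant-ion peak (RIP) is the alignment anchor: it is always present,
always the same species, and therefore tracks multiplicative drift-axis
distortion from temperature/pressure changes. Per spectrum:

* RIP detection: argmax inside a search window (default 4–9 ms), refined
  by a 3-point parabolic fit (the grid step limits integer-index
  precision); an apex on the window edge skips refinement with a warning;
  a flat window is a detection failure.
* Correction factor `k_c = t_ref / t_RIP` with `t_ref = 6.488 ms`. The
  spectrum's axis is multiplied by `k_c` and intensities are linearly
  re-interpolated onto the common reference grid, zero-filled outside
  (zero is the post-baseline background level).
* Robustness: rows where the RIP is missing or weaker than 10% of the
  map's median apex (pre-injection rows; heavily depleted rows where
  analytes consume the reactant ions) reuse the sample-median `k_c`
  rather than failing the whole map. The fallback can be disabled, in
  which case the failing retention row is named in the error.
* Alignment runs after baseline correction (the RIP must dominate its
  window); the stages are independently callable so other orders are
  possible.

Retention alignment translates the axis so the injection point is 0 s.
The injection point is detected operationally as the earliest retention
row whose RIP apex reaches 50% of the map's median RIP apex — before
injection the drift tube carries no reactant-ion current, so the RIP
"switches on" at injection. An explicit `injection_time` always wins. At
the dataset level all maps are then re-gridded onto a common retention
axis (the first map's), zero-filled at the borders.

Warping refinements (COW/PTW/Icoshift) and reduced-mobility (K₀)
representation are deliberately not implemented.

## PLS-DA

Classification is PLS2 regression of the mean-centred feature matrix onto
one-hot class membership, fitted by NIPALS with X-deflation only
(regressing the original Y on the mutually orthogonal scores is
equivalent to deflating Y and keeps the code simpler). No autoscaling:
with full-matrix spectral data the variance structure *is* the signal;
scaling every pixel to unit variance would amplify empty background.
Inner iteration tolerance is 1e-10 on the weight change with a 500
iteration cap; rank exhaustion truncates the model with a warning.
Prediction assigns the class with the largest predicted membership, ties
breaking to the lowest class index (deterministic). New-sample scores are
computed by sequential deflation, so a model fitted with A components
yields the predictions of every smaller model for free — the internal
cross-validation exploits this to score a whole LV grid from one fit per
fold.

VIP scores use the standard Wold formulation
`VIP_j = sqrt(J · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)` with
`SS_a = (t_aᵀt_a)‖q_a‖²`, so mean squared VIP is exactly 1 and the
conventional importance threshold is 1. For interpretation the VIP
vectors of the external-validation models are averaged and reshaped into
map coordinates.

## Double cross-validation

Per repeat (default 10): a stratified random split into training
(126 of 180) and test (54; 18 per class) portions; stratified 5-fold CV
within the training portion scores every LV in the grid (default 1–20);
the LV maximising mean internal accuracy is chosen, ties to the smallest
LV (parsimony); the model is refit on the full training portion and
scored once on the untouched test portion. Centring is always computed
from the data a model is fitted on — test samples never influence
fitting, centring or LV selection. Stratification is the default because
a balanced design with integer per-class test counts implies it; it is a
config switch. All randomness derives from one master seed via per-repeat
substreams, so results are bit-for-bit reproducible. Accuracy is the
overall fraction of correctly labelled samples. Grid entries exceeding
the training-fold rank are skipped with a warning.

The ablation experiment preprocesses the *raw* dataset with one stage
omitted at a time (the same seeds drive the splits, so comparisons are
paired) and reports each variant's internal accuracy curve, its maximum,
and the *plateau LV*: the smallest LV whose accuracy is within one
accuracy point (0.01) of the curve maximum — a plateau needs a numeric
rule and one point is at the resolution of a 25-sample fold. When an
alignment stage is omitted, maps are stacked by grid index (axes
relabelled to the first map's), as an uncorrected analysis would do.

## Synthetic data generator

The generator emulates the phenomena each pipeline stage corrects, with a
per-sample truth channel:

* **RIP** — a Gaussian column at 6.488 ms (σ 0.08 ms), amplitude 10,
  gated off before the injection time and depleted where analytes elute
  (`amplitude × (1 − depletion·s_r)`, `s_r` the row's normalised analyte
  signal, depletion 0.3 by default) — reactant-ion charge is consumed by
  analytes.
* **Analyte peaks** — 2D Gaussians at fixed positions in nominal
  coordinates; the default catalogue has 12 peaks, 3 with class-dependent
  amplitudes (contrasts of roughly ±20–30% that rank the three classes
  differently, so no single peak separates everything). Typical widths:
  several seconds × ~0.1 ms.
* **Baseline** — a per-sample smooth surface: a RIP-tail-like exponential
  decay plus three broad humps at *random* drift positions, each slowly
  modulated along retention, scaled by `baseline_amp = 2.0`. The random
  bump positions matter: they make each sample's background point in a
  fresh direction of feature space, so no small latent basis can span the
  nuisance — exactly why baseline correction buys model parsimony. Early
  designs with fixed-shape baselines were absorbed by 2–3 latent
  variables and showed no accuracy cost, which does not reflect real
  slow background drift.
* **Drift jitter** — the axis is multiplied by `g ~ N(1, 0.01)`; this is
  precisely the distortion the `k_c` correction inverts, making recovery
  sharply identifiable (`k_c → 1/g`).
* **Retention offsets** — the injection time (and with it all elution)
  shifts by `N(0, 2 s)` per sample on a shared instrument-clock axis.
  This realisation (content shift + detectable injection onset) was
  chosen over relabelling the axis values because an axis relabel leaves
  no operational injection point to detect and would make the
  no-alignment ablation variant ill-defined.
* **Noise** — additive white Gaussian, σ 0.08.

Defaults: grid 200 × 600 over 4–14 ms × 0–240 s (a reduced version of the
instrument's 1300 × 3000 raster; the full size is a config choice), three
classes of 60 samples. Tests and the acceptance script run the study at
36 × 300 (16 rows for the pure-alignment checks); the per-class counts,
split sizes and CV design are kept at full scale. The amplitude/noise
levels are order-of-magnitude choices — the instrument's true noise
spectrum and baseline magnitudes are not published — set so that the
synthetic study reproduces the qualitative regime reported for real data:
full preprocessing plateaus at 5–6 latent variables, omitting baseline
correction costs both parsimony (plateau beyond 15 LVs) and accuracy
(plateau ≈ 90% vs ~100%), omitting denoising costs almost nothing, and
the full-vs-raw complexity gap is ≈ 4–5 latent variables.

### What passing tests do and do not show

The generator is a phenomenological emulation, not an instrument
simulation: no ion chemistry, charge competition, proton-affinity
ordering, chromatographic tailing, or correlated (1/f, acoustic) noise.
Synthetic results demonstrate that each algorithm recovers exactly the
distortion class it models (multiplicative drift scaling, additive smooth
baselines, injection shifts) and that the validation scheme is leak-free
and calibrated (label permutations score at chance). They do not certify
classification accuracy on real olive-oil data, where peak shapes,
baseline structure and class differences are richer.

## Numerical choices and degenerate inputs

* AsLS system solved in upper banded form; positive definiteness holds
  for any non-negative weights with λ > 0.
* Parabolic apex refinement is clipped to ±half a grid step and skipped
  when the three-point stencil is not strictly concave.
* Interpolation beyond the rescaled drift span fills with 0.
* Flat spectra: RIP detection raises; AsLS returns the flat baseline;
  PLS fitting raises on zero-variance X.
* Ties: argmax prediction → lowest class index; LV selection → smallest
  LV; AsLS weight at `y = b` → p.
* Approximate AsLS idempotence (≈ 2 noise s.d. per extra pass) is
  documented above; the pipeline applies it once.

## Known limitations

* Alignment assumes the RIP is the dominant feature in its search window
  after baseline correction; fails (by design, loudly) on negative-mode
  data without a RIP analogue.
* Injection detection needs a visible RIP onset; instruments that start
  recording after injection require an explicit `injection_time`.
* The plateau-LV rule (within 1 point of max) is resolution-limited on
  small validation folds.
* Full-scale (1300 × 3000) maps are supported by the data structures but
  double CV at that size is compute- and memory-hungry; the reduced grid
  is the intended desk-scale operating point.
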