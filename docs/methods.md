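# Methods

## Model

A tumor is observed as integer voxel counts `H(A, V)` on a fixed grid of
ADC bins `A` (default 100 uniform bins over 0–3.0×10⁻³ mm²/s) crossed
with one or more imaging visits `V`. The generative model is a
nonnegative linear mixture with Poisson bin noise:

    H(A,V) ~ Poisson( Σ_k P(A,V | C=k) · Q_k )

Each component `P(·|k)` is a probability mass function over the full
(bin, visit) grid (components may span visits; this is how multi-time
point information enters) and carries a class label: *control* for
behaviour learnable from untreated tumors (viable tissue, spontaneous
necrosis, natural-history growth), *treatment* for additional behaviour
only seen under therapy. Weights `Q_k ≥ 0` are voxel counts, free per
tumor. The fit criterion is the extended Poisson likelihood
`L = Σ (H log M − M)`; because every component sums to one, the maximum
satisfies `Σ_k Q_k = Σ H` (total voxel conservation) exactly wherever
the model has support.

Assumptions: voxels are independent draws from the tumor's habitat
mixture (an optional effective-sample-size deflation hook exists for
spatially correlated data but is off by default); habitats are shared
across tumors while their proportions vary; treatment only *adds*
behaviour — it never edits the control shapes.

## Training

**Stage 1 (control).** Components are estimated from the control cohort
by EM. One iteration uses the standard multiplicative updates for
Poisson/KL factorisation of count matrices — both the weight and the
shape update are exact M-steps from the same responsibilities, so the
likelihood is non-decreasing every iteration. Shapes are initialised
from a symmetric Dirichlet (α = 1) over occupied bins; weights start at
`total/K`. Default 20 random restarts (seed-controlled), convergence at
a relative likelihood change below 1e−8 or 2000 iterations. Components
whose shapes become near-parallel (cosine > 0.999) are merged after
fitting; linear mixture models are commonly degenerate and merging
stabilises the weight covariance.

**Model order.** For each candidate K the model is retrained with one
tumor held out; the held-out tumor is scored by a weights-only refit and
its fit value √(χ²/d.f.). The selected K is the smallest whose median
held-out fit value is ≤ 1.2 with no outliers (an outlier is a held-out
fit above mean + 3 SD of the leave-one-out distribution). A model is
reported *sufficient* when it passes this plus a Bland–Altman residual
check: standardised residuals r = (obs − exp)/√exp on pooled cells must
have |mean| < 0.1 and SD within [0.8, 1.2] in every
expectation-magnitude quintile — i.e. residuals are Poisson-consistent
across the dynamic range. The thresholds are configurable; the defaults
encode "fit value near 1, no structure left in the residuals".

**Stage 2 (treatment).** The control shapes are frozen bit-for-bit;
only new treatment-labelled shapes and all weights are free. Treatment
component count is selected by the same leave-one-out procedure over a
range starting at zero, so a treated cohort that the control model
already explains gains no components at all.

Treatment shapes are additionally restricted to grid cells where the
treated cohort demonstrates excess over the control model. With ~10
training tumors and ~200 grid cells, an unrestricted free shape absorbs
diffuse Poisson noise from control-dense cells (the in-sample
likelihood gain of a free shape is ≈ one half per free cell, so the
contamination is systematic, not incidental); on fresh tumors that
contamination inflates QT by ~20% and destroys the calibration of the
error bars. The restriction operationalises the defining property of
the second stage — treatment components describe only behaviour absent
from the control model. Two passes are used: (1) cells where the pooled
standardised residual of control-only fits exceeds z = 2, dilated by 2
ADC bins; a provisional one-component treatment shape is fitted there;
(2) cells where the data exceed the control *part* of that provisional
fit at z = 2, dilated by 1 bin (the second pass recovers low-excess
mode shoulders that the first pass misses because control-only fits
over-attribute mass to control). With this step, end-to-end recovery of
injected effect sizes at the default synthetic study conditions is
essentially unbiased (median relative error ≈ 2–3%, 2σ coverage
0.93–0.98 across seeds).

## Per-tumor assessment

A tumor is assessed by a weights-only EM refit against the fixed
components. Counts in cells where no component has mass cannot be
explained; they are excluded and reported (`unexplained_count`).

- `QT = Σ_t Q_t` — treatment-attributed voxels, a lower bound on the
  affected volume.
- `σ(QT)` — from the observed Fisher information of the extended
  Poisson likelihood over the weights (shapes fixed):
  `I_kl = Σ_i H_i P_ik P_il / M_i²`, covariance its (pseudo-)inverse,
  σ² the sum of the treatment block. Validated against a nonparametric
  bootstrap (per-bin Poisson resampling of the observed histogram,
  which matches the extended-likelihood noise model) to within 20%.
- `Z = QT/σ`, defined as 0 when QT = 0; one-sided normal p-value;
  responder at Z > 3 (configurable).
- Bayes posteriors `P(C=t | A,V) = M_t/(M_c+M_t)` per cell; the fitted
  expectation decomposes into affected (`Σ_t P Q_t`) and unaffected
  sub-distributions that sum cell-wise to the fit and integrate to QT
  and QC.
- Summary parameters of any (sub-)distribution: count-weighted
  bin-center mean; 95th percentile defined as the smallest bin center
  whose cumulative mass fraction reaches 0.95 (a discrete quantile —
  exact for point masses and within one bin width of the
  sorted-sample percentile, which is the appropriate resolution for
  binned data); volume = total mass × voxel volume (mm³).
- The conventional comparator: two-sample Welch t-tests between cohort
  parameter lists (two-sided).

Goodness-of-fit uses Pearson χ² per degree of freedom with adjacent
bins pooled until each pooled cell has expectation ≥ 5 (Poisson χ²
validity); d.f. = pooled cells − number of fitted weights.

## Power calculations

Attainable per-tumor significance as a function of the independent
voxel count `Qtotal = QT + QC`:

    Z = sqrt( Qtotal · ( T* − (1 − T* − C*)² / (4 C*) ) )

with ambiguity terms `T* = ⟨P(C=t|A,V)⟩` averaged over the
treatment-attributed model mass and symmetrically `C*` (this averaging
measure makes perfectly separated distributions give exactly
T* = C* = 1). Z grows with √Qtotal exactly; overlap between control and
treated distributions (T*, C* below 1) discounts it, and the bracket is
clipped at zero in pathological high-ambiguity regimes. The formula is
an approximation: against the exact Fisher-information Z for a
two-component model it is accurate to a few percent in low-ambiguity
settings with treatment-dominant mass and degrades toward ~20%
overprediction as the class distributions merge. It is isolated in one
function (`lpmadc.power.predict_z`) so an alternative reading can be
swapped in; a Monte Carlo validation in the test suite pins the
implemented reading to full-pipeline simulations within 15%.

Cohort-size design: the probability of observing at least one responder
among N tumors when a fraction F respond is the binomial sum
`Σ_{r=1..N} C(N,r) F^r (1−F)^{N−r}`, implemented with the full binomial
coefficient (it equals `1 − (1−F)^N`; the closed-form identity is
asserted in tests to 1e−12). `min_cohort_for_confidence` inverts it for
the smallest adequate N.

## Monte Carlo cohort simulation

Simulated tumors are synthesised from fitted base tumors: a random pair
is drawn from the relevant pool, each mixing weight is drawn uniformly
on the interval between the pair's values and then scaled by a uniform
factor in [1−d, 1+d] with d ≤ 0.5, so realised weights never deviate by
more than half of the enclosing pair's values; bin counts are Poisson
around the mixed expectation. Treatment cohorts hold `n`
responder-derived (base fits with Z > 3) and `N − n` control-derived
tumors; null cohorts and each cohort's paired comparator are built from
control pairs only. Detection methods scored per p-threshold: per-tumor
LPM (one-sided p from Z), cohort-combined LPM (`ΣQT/√Σσ²`), and Welch
t-tests of visit-to-visit change in volume, mean ADC and 95th
percentile against the paired control cohort. Outputs are tidy
TPR/FPR tables; FPR is reported as NaN (flagged), never silently zero,
when no null cohorts exist.

## Synthetic ground truth

The generator emulates the structure the model targets, with exact
bookkeeping of every injected effect:

- Control habitats (defaults): *viable* tissue, a gamma-shaped ADC mode
  at 0.8×10⁻³ mm²/s (SD 0.2×10⁻³), mass split 55/45 across two visits;
  *necrotic*/natural-history tissue at 1.35→1.45×10⁻³ with a growing
  visit share (40/60). Per-tumor habitat proportions are Dirichlet
  (α = 4), producing the non-Gaussian between-tumor heterogeneity that
  defeats cohort t-tests.
- Treatment habitat: therapy-induced cell death raises ADC, so
  responders move a known number of voxels `QT_true` into a
  2.0×10⁻³ mm²/s mode confined to the post-baseline visit. The affected
  fraction per responder is uniform on 30–70% (centred on half the
  tumor, matching the typical extent of detected responses).
- Default study layout: 15 control + 9 treated tumors, two visits,
  2000 voxels per tumor, all treated tumors responding. Bin counts are
  Poisson; everything is deterministic given a seed.

What it does **not** emulate: spatial voxel correlations (counts are
independent Poisson draws, so real-data effective sample sizes may be
smaller than voxel counts), acquisition noise in the upstream ADC fit,
registration/segmentation error, and drift of habitat shapes between
tumors (shapes are shared exactly; real cohorts only approximate this).
Passing tests therefore demonstrate the statistical machinery is
calibrated under the model's own assumptions, not that those
assumptions hold for any given scanner or tumor line. Harder overlap
(high-ambiguity) regimes can be produced by moving the treated mode
toward the necrotic mode in `TruthConfig`.

## Numerical choices

- EM tolerance 1e−8 relative (1e−10 for weights-only refits),
  max 2000 iterations; 20 restarts by default (unit and acceptance
  tests use 6–10 restarts and reduced K ranges to keep runtimes in
  seconds — problem sizes chosen as the smallest at which the checked
  statistics stabilise).
- Weight covariance by matrix inverse, falling back to the Moore-Penrose
  pseudo-inverse (with finite-ness check) for singular information
  matrices, e.g. duplicate components.
- χ² floor 5 expected counts per pooled cell; pooling walks bins in
  grid order and merges a trailing remainder into the last group.
- Bin convention: half-open [low, high), last bin closed; out-of-range
  values are tallied as overflow and never silently dropped.
- Negative voxel-wise ADC fits are clipped to 0 and flagged.
- Histogram CSVs are written with shortest-roundtrip float text and
  read with round-trip parsing so grids survive I/O bit-exactly (model
  and data grids must match exactly).

## Known limitations

- σ(QT) propagates weight uncertainty only; uncertainty in the trained
  component shapes is not included. The support-restriction step keeps
  the resulting optimism small at the default study scale (coverage
  0.93–0.98), but for much smaller training cohorts the error bars will
  be anti-conservative.
- The method quantifies *how much* of a tumor changed, not *where*:
  per-voxel classification confidence is too low for spatial response
  maps, which are out of scope.
- QT is a lower bound: treatment effects that mimic control behaviour
  in the ADC distribution are attributed to control components by
  construction.
- Leave-one-out selection needs ≥ 3 tumors per cohort; below that the
  treatment component count must be fixed by hand.
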