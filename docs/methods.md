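# Methods

This note documents the models and procedures implemented in `pigait`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic cohort generator does and does not emulate.

## Dynamic-similarity normalization

Two locomotor behaviours are dynamically similar when one maps onto the
other by a single factor α for all lengths, β for all times, and γ for all
forces; under constant gravity this requires β = √α and γ = α³ (mass scales
with volume). The package normalizes voluntary walking with midstance hip
height *h* as the length scale — a dynamic measure of functional limb
length that links directly to the inverted-pendulum mechanism of walking —
giving `V/√(hg)`, `L/h`, and `F·√(h/g)`; forces are expressed in body
weights. Gravity defaults to 9.81 m/s² and is overridable. Relative limb
phases are reported against left-hind touchdown as the reference limb (a
package convention; the reference choice only rotates phases).

Caveat inherited from the science: *h* itself matures (the limb extends
over the first day), so within-category age contrasts of normalized
variables mix size removal with partial masking of postural maturation.
Between-category contrasts at matched age are not affected by this, which
is why the group comparisons are the primary consumers of the normalized
data.

## Joint kinematics

Each joint-angle cycle θ(t), sampled uniformly on cycle fractions [0, 1)
anchored at touchdown, is decomposed as
`c_n = (1/N) Σ_k θ(t_k)·exp(−i2πnk/N)` with H = 8 harmonics retained
(configurable). Reconstruction is `θ(t) = c₀ + 2 Σ Re(c_n e^{i2πnt})`;
round trips on band-limited input are exact to floating point, and
Parseval's identity is used as an internal oracle in tests.

The "amplitude" of a joint oscillation is defined as the RMS amplitude
`A = √(2 Σ_{n≥1} |c_n|²)` — for a pure cosine of half-range a this equals
a/√2. This definition follows from the affine-superimposition view of the
coefficient domain (mean and amplitude are affine parameters; what remains
after removing them is shape). A half peak-to-peak alternative can be
swapped in by replacing `affine_split`. The shape vector `c_n/A` then
satisfies `2 Σ |shape_n|² = 1`; a constant trace has A = 0 and an all-zero
shape. Shape coefficients are phase-sensitive by construction: cyclically
shifting a trace by Δ rotates harmonic n by `exp(−i2πnΔ)`. Because all
cycles are anchored at touchdown, no additional phase normalization is
applied by default; this keeps genuine timing differences visible to the
coordination analysis.

The pooled 6 × 16 = 96 shape values per stride enter a column-centered PCA
(no per-column standardization — the values are already commensurate and
unit-free); 12 components are retained as coordination variables, with a
fixed sign convention (largest-magnitude loading element positive) for
reproducibility. Amplitude-normalized shape values (not raw coefficients)
are used, since the mean and amplitude already live in the postural block.

Group comparisons (6 mean angles, 6 ranges of motion, 12 PCs) use the
conjugate Bayesian linear model described below with a group indicator;
the reported difference is the group coefficient posterior (B − A), with a
95% central credible interval and the residual scale.

## Permutation SPM for GRF curves

Stance-phase curves are linearly resampled onto 51 nodes (50 intervals).
For the two-group comparison the package uses nonparametric permutation
SPM rather than random-field-theory SPM: the pointwise pooled-variance
t-field is thresholded at the (1 − α) quantile of the permutation
distribution of max|t| under group-label exchange. This targets the same
cluster-wise inference while dropping the Gaussian smoothness assumptions,
and it is self-contained. When the number of distinct relabelings is at
most the requested permutation count the distribution is enumerated
exactly, making small-sample results deterministic. Suprathreshold
clusters receive p-values by ranking their peak |t| in the same max-|t|
distribution. Stance halves can be analyzed separately via
`split_stance_halves` (the midpoint node belongs to both halves — a
documented, deliberate duplication). Medio-lateral forces are out of
scope.

## Muscle capacity and allometry

PCSA = mass / (density × fibre length) with density 1060 kg/m³; limb
capacity is 0.3 MPa × Σ PCSA over the dissected extensor muscles,
expressed in body weights. Under isometry PCSA ∝ BM^(2/3), so BW-capacity
∝ BM^(−1/3) — the generator reproduces this and the tests verify the
exponent exactly on noise-free cohorts.

Huxley's model `part = a·BM^b` is fitted by OLS on
`log(part) = log a + b·log BM` (closed-form, exactly recovers noise-free
power laws); the 95% CI on b is the normal-theory slope interval. A
raw-space nonlinear least-squares variant is available behind
`log_space=False`; log-space is the default because multiplicative
(lognormal) error is the natural error model for masses and the fit is
reproducible in closed form. The isometry test asks whether the CI
contains b = 1.

## Bayesian trait prediction

Each stride is summarized by 34 features in a fixed order: sex, 9
dimensionless spatiotemporal variables (Froude speed, relative stride
length, fore/hind relative step lengths, relative frequency, fore/hind
duty factors, diagonal and ipsilateral phases), 12 postural variables
(6 mean angles + 6 amplitudes), and 12 coordination PCs whose loadings are
frozen from the training set. Dimensionless features are the default
(consistent with the dynamic-similarity framework); raw-unit features
remain possible for sensitivity analysis by normalizing with h = 1.

The per-target model is Bayesian linear regression with identity link and
Gaussian likelihood: predictors standardized, response standardized,
N(0, σ²) priors on standardized slopes (unit prior precision), a vague
prior on the intercept (precision 0.25) and an Inverse-Gamma(0.1, 0.1)
prior on σ². These conjugate choices keep the full posterior —
coefficients, residual scale, and posterior predictive (Student-t) — in
closed form: summaries are exactly reproducible with zero Monte-Carlo
error, and the 90% central predictive intervals are calibrated on
well-specified data (verified at ±3 pp over 500 held-out strides). The
price of conjugacy is an Inverse-Gamma rather than half-Normal scale
prior and O(p/n) shrinkage of coefficients toward zero; with ~300 training
strides and 34 features the shrinkage bias is below 2% and is accounted
for in test tolerances.

Predicted-minus-actual differences are summarized per group, with the
fractions of over- and under-predictions. The age-stall experiment trains
the age model on AGA strides of a cross-sectional cohort and measures how
often the age of SGA strides beyond the stall boundary is underestimated;
with the stall disabled the fraction sits near 50% (no bias), with a full
4 h stall it rises well above it. Because each cross-sectional subject
contributes one age, the fraction is a high-variance statistic at
realistic cohort sizes; tests therefore average it over replicate cohorts.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes:

- **Design**: 14 AGA + 11 SGA subjects, longitudinal recordings at
  0, 1, 2, 6, 8, 24, 26, 28, 96 h postpartum, 3 strides per recording
  (all configurable; a cross-sectional mode draws one age per subject
  uniformly from 1–10 h).
- **Size**: AGA birth mass Normal(1.4, 0.15) kg, SGA Normal(0.7, 0.08) kg —
  a ~50% category gap with SGA below the 0.8 kg convention. Segment
  lengths scale isometrically (∝ BM^(1/3)) from a 1.4 kg reference
  animal. Body-part masses follow 0.41·BM^1.02 (front), 0.38·BM^1.16
  (hind), 0.20·BM (head) with 5% lognormal noise.
- **Posture/maturation**: midstance hip height
  `h = k·BM^(1/3)·(1 + m(t))·(1 − flexion penalty)` with k = 0.20 m·kg^(−1/3)
  and a 6% penalty for the systematically more crouched SGA posture.
  The maturation law is a saturating exponential
  `m(t) = 0.28·(1 − e^{−(t−1)/τ})` for t > 1 h, zero before, with τ chosen
  so 90% of the plateau is reached at 8 h. The 1 h onset makes the
  *measured* 1 h → 28 h increase equal the full 28% plateau, matching how
  the postural change is quantified against the first measurement age; at
  8 h the profile value is 0.252 = 0.9 × 0.28. An optional stall freezes
  m(t) at its value at the stall age (SGA only).
- **Gait**: mature dimensionless targets (Froude speed 0.35, relative
  stride length 1.45, duty factors 0.68/0.66, lateral-sequence phases)
  with an immaturity deficit proportional to 1 − m(t)/plateau and a small
  linear age trend in Froude speed; absolutes follow from h, and
  V = L·F holds exactly. Noise is multiplicative lognormal (4% on
  dimensionless variables, 1.5% on h).
- **Joint cycles**: configurable Fourier template banks (plausible
  quadruped-walk shapes, ≤ 8 harmonics — not digitized from any
  recording), with maturation expressed as mean-angle extension at the
  proximal joints and static SGA offsets at the knee (−11°) and tarsal
  (−6°). Noise lives in the coefficient domain (per-stride mean-angle
  jitter, per-subject static postural offsets, amplitude jitter) so every
  generated trace stays exactly band-limited. Keeping knee/tarsal free of
  maturation gain makes their group contrast identical to the configured
  offset and keeps the age model from loading on category-offset
  features.
- **GRFs**: vertical curves `sin(πs) + 0.25·sin(3πs)` (double hump),
  scaled so per-limb stance-average × duty factor sums to 1 BW over four
  limbs (exact on the discrete grid before noise); fore limbs carry 60% of
  body weight, so fore peaks exceed hind peaks. Fore-aft curves are a
  single braking-to-propulsion sine with zero net impulse.
- **Muscles/energetics**: extensor banks with mass ∝ BM and fibre length
  ∝ BM^(1/3); blood glucose doubling by 4 h in AGA but flat in SGA, and
  declining liver glycogen in AGA only, as numeric covariates.

All draws flow from named substreams of one root seed (subjects, strides,
joints, GRFs, muscles, parts, energetics), so adding a stage never
perturbs earlier draws and identical config + seed gives byte-identical
CSV output.

**What the generator does not emulate**: multibody dynamics or any
physical consistency between kinematics and GRFs beyond the imposed
summary structure; within-stride autocorrelated measurement noise;
suckling competition or litter structure; inter-joint coordination changes
with age (coordination PCs differ between groups only if configured).
Passing tests therefore demonstrate that the estimators recover the
effects the generator encodes at realistic noise — not that real piglet
data would show those effects.

## Numerical choices and degenerate inputs

- Fourier decomposition requires a uniform grid with ≥ 2H + 1 samples
  (else an aliasing error); c₀'s imaginary part is discarded (it is zero
  to floating point for real input).
- Constant traces: amplitude 0, all-zero shape, RoM 0. Zero-variance
  variables in the posture comparison yield a degenerate flag instead of
  an interval.
- PCA of an all-identical shape matrix returns zero scores and identity
  loadings rather than dividing by zero variance.
- The stance-half split assigns the midpoint node to both halves.
- Permutation SPM warns when permutations < 1/α and errors on mismatched
  grids; with ≤ requested relabelings it enumerates exactly.
- Strides with missing or non-positive hip height are dropped from
  normalization with a logged warning, never silently.

## Problem sizes

Test and acceptance runs use cohorts of 8–58 subjects and a few hundred
strides, 200 replicates for allometric recovery, 100 null replicates ×
1000 permutations for the SPM error-rate check, and 500 held-out strides
for interval calibration — sizes at which every Monte-Carlo tolerance
asserted in the tests is comfortably resolved.
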