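# Methods

## Model

The package treats "health" as a graded quantity for people below every
disease threshold.  Given `n` diseases, each defined by upper thresholds on
a subset of five risk factors (disease present when *any* listed factor is
≥ its threshold), a cohort partitions into `2**n` physiological states.
For every (state, factor) pair with at least two subjects a univariate KDE
is fitted; the per-factor risk is the ratio of the healthy-state density to
the sum of all fitted state densities, restricted to the healthy range
`[x_i, y_i)`, and the subject index is the product of the five per-factor
risks.

Assumptions worth being explicit about:

- **Independence across factors.** The product form treats the five
  per-factor risks as independent; SBP and DBP in particular are strongly
  correlated in practice and the index does not correct for that.  The
  method is implemented as defined.
- **Thresholds are the disease definition.** No diagnosis codes enter;
  disease status, and therefore the state partition, is derived purely
  from the measured values with a `>=` comparison.  A value exactly at a
  threshold is diseased and gets component risk exactly 0 (the healthy
  range is closed at the top).
- **Ratios, not calibrated probabilities.** R_i(t) is a relative density
  ratio among the states represented in the training cohort; its magnitude
  depends on how much the state densities overlap.  Only the ordering
  within a fitted model, the [0, 1] bounds and the threshold zero rule are
  portable across cohorts.

## Density estimation

- Kernels: uniform, triangular, biweight, Epanechnikov, Gaussian, cosine —
  all symmetric, unit-mass; the compact five vanish outside |u| ≤ 1.
- Bandwidth (default): the normal-reference rule
  `h = 0.9 · min(σ̂, IQR/1.34) · n^(−1/5)`, with the n−1 standard deviation
  and type-7 (linear interpolation) quartiles.  These conventions are
  pinned for bit-reproducibility and match R's `bw.nrd0` (the test suite
  cross-checks against it).  A degenerate sample (zero spread) falls back
  to `0.9·|mean|·n^(−1/5)`, or a 1e-6 floor when the mean is zero too, with
  a warning.
- AMISE machinery: the objective `¼h⁴μ₂²R(f) + R(K)/(nh)` and its
  closed-form minimiser are exposed (`amise_value`, `amise_bandwidth`) for
  callers who can supply the density curvature `R(f)` externally — with a
  Gaussian kernel and normal-reference curvature this reduces to
  Silverman's `(4/3)^(1/5) σ n^(−1/5)`.  `R(f)` is never estimated from the
  data: plugging in an estimate needs a pilot bandwidth of its own, which
  is exactly the regress the rule-of-thumb default avoids.
- Kernel choice: all six kernels are fitted with the *same* bandwidth; each
  is scored by the sum of absolute deviations, at the sample points,
  from a reference density computed by leave-one-out Gaussian KDE at half
  the bandwidth (double resolution).  The minimal score wins; ties break
  deterministically in the kernel order above.  Both the reference and the
  metric are replaceable via the `reference` argument.  A consequence of
  sharing one bandwidth across shapes: the Gaussian candidate is
  effectively the smoothest, so on smooth unimodal data the selector tends
  to prefer the smooth *compact* kernels (cosine/Epanechnikov) that sit
  closer to the sharper reference.  Selection on fewer than 10 points is
  permitted but warned about.

## Risk ratio conventions

- `y_i` is the smallest threshold governing factor i across the configured
  diseases; `x_i` is the minimum value observed in the healthy stratum.
- `R_i(t) = 0` for `t ≥ y_i` (closed top, matching the `>=` disease rule).
- Below `x_i` the default ("strict") mode also returns 0 — the ratio is
  only trusted where healthy data exist.  This deliberately scores
  unusually *low* values as maximal risk, which is clinically debatable
  (a low FPG is not hyperglycemia); `extrapolate_low=True` instead extends
  the density ratio below `x_i`.  The ambiguity is inherent to defining the
  index on the observed healthy range.
- A zero denominator inside the range (possible with compact kernels in
  data gaps) yields 0, logged at debug level: no probability mass, no
  evidence of health.
- States with fewer than two subjects are dropped from the denominator
  (KDE undefined) with a logged warning rather than imputed.
- Components are reported at 4 decimal places in user-facing tables and
  carried at full precision internally; model JSON round-trips floats
  exactly.
- Risk curves are evaluated on a 512-point even grid over
  `[x_i − 5% span, y_i + 5% span]` by default and clamped to [0, 1] (a
  no-op for the raw ratio).  Curves are *not* forced monotone: the ratio
  estimator wiggles where state densities overlap, and no isotonic
  smoothing is applied by default.

## Intervention evaluation

`intervention_effect` shifts each healthy subject's factor vector by the
supplied deltas (clamping at a 1e-6 floor with a warning if a shift would
make a value non-positive) and re-scores.  Because "a mean X% change" is
ambiguous, both conventions are always reported: the mean of per-subject
relative changes (subjects with a zero before-index are excluded and
counted) and the relative change of the mean index.  Note that lowering
factor values can *raise* or lower the index depending on where the
subject sits relative to the healthy density's mode; no sign is asserted
in general.

## Synthetic cohort generator

The generator emulates a mixed screening cohort: factor vectors are
log-normal (clinical factors are positive and right-skewed) coupled by a
Gaussian copula, with latent per-disease propensities (independent
Bernoulli, default probability 0.3) adding log-scale shifts to the
factors each disease governs.  Values are rounded to 0.1 units; state
labels are then *derived* by thresholding, never assigned, so labels and
values cannot disagree.  Defaults: healthy medians 90 (FPG), 165 (T-CHO),
95 (TG) mg/dL, 114/71 mmHg (SBP/DBP); log-sd 0.12/0.12/0.30/0.09/0.09;
shifts +0.30 (SBP, DBP) for hypertension, +0.35/+0.70 (T-CHO, TG) for
hyperlipidemia, +0.50 (FPG) for hyperglycemia; SBP–DBP correlation 0.65,
T-CHO–TG 0.35, others ≤ 0.20.  These were chosen once to give clinically
plausible medians and skew and to populate all eight states comfortably at
the default cohort size of 2000 subjects (each state ≥ 10; the generator
redraws up to 25 times and errors naming the deficient state otherwise).
One `numpy` Generator seeded from the single config seed drives everything;
identical configs give byte-identical CSVs.

What the generator does **not** emulate: real-world factor–factor
dependence beyond a fixed copula, age/sex structure, measurement error,
longitudinal drift, or the moments of any specific population.  Tests
passing on synthetic cohorts therefore certify the *mechanics* of the
method (partitioning, fitting, ratio, product, thresholds, determinism),
not its clinical calibration on real data.

## Problem sizes and numerics

The reference configuration throughout (tests, acceptance script) is a
2000-subject cohort; fitting the full 8 × 5 density grid with six-kernel
selection takes well under a minute on one CPU because all kernel sums are
vectorised (an O(n²) pairwise matrix per stratum, largest stratum ≈ 700).
Quadrature tolerances: kernel unit mass to 1e-6, fitted KDE unit mass to
1e-3 on a ±6h support-covering grid; the vectorised evaluator agrees with
a naive double loop to 1e-10.

## Known limitations

- The index has no uncertainty quantification; none is defined for it.
- Magnitudes of R_i depend on cohort composition (state mix and overlap),
  so indices are comparable within one fitted model only.
- The worked-example component risks shipped in `examples.py` were produced
  by the original analysis on a non-redistributable cohort; only their
  product structure and the threshold zero rule are recomputable here.
- Strict-mode behaviour below the observed healthy minimum (risk 0) is a
  modelling convention, not a clinical claim.
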