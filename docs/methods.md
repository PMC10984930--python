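# Methods

## Model

The classifier is instance-based over a hybrid decision table. All
structure flows from one distance and one threshold rule.

**Hybrid distance.** For records x, y and condition attributes split into
numeric and categorical kinds,

    d(x, y) = [ Σ_num w_i (|x_i − y_i| / 4σ_i)²  +  Σ_cat w_i L_i² ]^{1/2}

- σ_i is the population standard deviation (divisor n) of attribute i over
  the *training* partition only, never refitted on test data. A constant
  attribute has σ_i = 0 and contributes 0 (it carries no discriminating
  information; this also avoids division by zero). The 4σ divisor maps a
  four-standard-deviation difference to a unit term, bounding outlier
  leverage.
- L_i is the Levenshtein edit distance between the two string values
  (Wagner–Fischer dynamic programming; the empty-string base case gives
  the other string's length). By default each L_i is divided by the longer
  string of the pair, mapping it into [0, 1] so string and numeric terms
  are commensurate; `normalize_lev=False` restores raw edit counts.
- w_i are user-supplied nonnegative attribute weights, default 1. No
  weight-learning procedure is provided; weights are configuration.

The single-radical combination of both kinds is a design choice: the
defining cases are stated separately per kind and a symmetric
sum-of-squares is the only combination that reduces exactly to the pure
numeric and pure categorical forms. With all σ_i = 1/4 and unit weights
the numeric part is plain Euclidean distance.

**Adaptive threshold.** Distances from a query to the training table give

    δ = min_D + r · R_D ,    R_D = max − min,

read as "range" in the standard statistical sense. `r = 0` keeps only the
argmin set (nearest-neighbor granules, purely local); `r ≥ 1` swallows the
table (purely global). The default `r = 0.002` is the radius the method's
evaluation settles on. Membership uses `distance ≤ δ`, so ties at the
threshold are inside and neighborhoods are never empty.

**Approximations.** Granulating a labeled table builds each record's
neighborhood against the full table, self included — so min_D = 0 and
δ = r·R_D. Record i is in `lower(c)` when its granule is entirely class c,
in `upper(c)` when the granule touches c; the boundary region is
∪upper − ∪lower. Self-inclusion is deliberate: granules are defined over
the whole universe, and excluding self would make lower approximations
unstable (a record could fail to certify its own class).

**Classification.** A test query (self absent) takes the plurality class
of its neighborhood. Vote ties break by (1) smaller mean member distance
among tied classes, then (2) lexicographically smallest label — an
invented but deterministic cascade; the underlying method specifies only
majority voting. At r = 0 this reduces to 1-NN with plurality over the
argmin tie set.

## Evaluation harnesses

- `evaluate_kfold`: stratified folds (k = 10 default) with a caller seed;
  falls back to unstratified folds when some class has fewer than k
  members. σ is refitted on each training split (no leakage).
  Stratification is a variance-reduction choice at small n.
- `evaluate_holdout`: one seeded shuffle; first n_train rows train, next
  n_test test.
- `radius_sweep`: one k-fold evaluation per radius on identical folds
  (same seed), so differences are attributable to r alone.

## Synthetic data

`generate_hybrid_dataset` draws class-conditional data: numeric attribute
j has class-k mean `k · separation / √m` (m numeric attributes) and unit
standard deviation, so the Euclidean distance between adjacent class
centers equals `separation` regardless of dimensionality. Categorical
attributes emit the class's canonical token (a random 5-letter string)
with probability `cat_fidelity`, else a uniform decoy from a per-attribute
pool of `n_classes + 3` tokens; decoys therefore sit at *graded* edit
distances from canonical tokens, exercising the graded string metric
rather than match/mismatch. Labels flip to a different class with
probability `label_noise`. Defaults (n = 200, 4 numeric + 2 categorical
attributes, 2 classes, separation 3, fidelity 0.9, no label noise) are a
realistic moderate-difficulty tabular world chosen once.

What the generator does **not** emulate: correlated attributes, class
imbalance, non-Gaussian numeric marginals, and missing values. A green
test on this world certifies the algorithmic contracts (distance laws,
approximation set identities, monotone responses to noise/overlap), not
clinical performance on real cohorts.

`simulate_tremor_signal` emulates one tri-axial accelerometer at 62.5 Hz:
each axis is `amplitude · sin(2π f t + φ_axis)` with phases 0, 2π/3, 4π/3
plus white Gaussian noise. The 5 Hz default tremor frequency is a
physiological convention (resting tremor is conventionally 4–6 Hz), not a
measured value; duration defaults to 4 s (250 samples).
`extract_fft_features` uses a rectangular window and a one-sided spectrum
scaled so total power equals the time-domain mean square (Parseval);
features per axis are dominant frequency, total power, and band-power
fractions over non-overlapping `[lo, hi)` bands within Nyquist (defaults
0–3, 3–7, 7–12, 12–31.25 Hz). The testbed-analogue experiment uses
amplitude 1.0 vs 0.0 with noise σ = 0.2 — a 5× amplitude-to-noise gap —
and 30 signals per class. Real tremor data differs in nonstationarity,
harmonics, movement artifacts and multi-sensor placement; the analogue
establishes only that the pipeline plumbing separates separable spectra.

## Numerical and degenerate-input choices

- Missing values: numeric → column mean over non-missing entries (error if
  a column is entirely missing); categorical → literal token `"?"`,
  handled gracefully by the edit distance thereafter.
- CSV kind inference: a column is numeric only when 100% of non-missing
  cells parse as reals — avoids silently coercing coded categories like
  "1a". Inference is idempotent across write/read round trips.
- Categorical comparison is case-sensitive with no trimming beyond CSV
  field parsing, for determinism.
- Record identity is the 0-based row index in file order; all index sets
  (neighborhood members, approximations) refer to it.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  harness result is bit-identical across runs at a fixed seed.
- Complexity: classification of one query is O(n·m) distance work against
  n training records with m attributes; table granulation is all-pairs,
  O(n²·m), with categorical work amortized over distinct tokens.

## Known limitations

- No attribute reduction / dependency-based feature selection; attribute
  subsets are accepted by the neighborhood machinery but never searched.
- No learned attribute weights; no alternative string metrics.
- Dense ARFF only (no sparse dialect), headered UTF-8 CSV only.
- The boundary region can collapse to ∅ at very small r (every granule is
  its own record) and grow to the whole universe at large r on any
  mixed-class table; interpret it only relative to the radius used.
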