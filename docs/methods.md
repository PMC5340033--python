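# Methods

## The dissimilarity metric

A repertoire is summarized as a vector of non-negative counts over a fixed
feature universe (V, D or J genes or families; the union of features
observed across the compared repertoires, with explicit zeros). The RDI
between repertoires is the average, over repeated subsampling rounds, of
the Euclidean distance between their depth-equalized, normalized,
optionally arcsinh-transformed count vectors.

Key properties and conventions:

* **Subsampling is without replacement** (multivariate hypergeometric over
  the pooled elements). A repertoire whose total equals the subsample size
  is passed through unchanged, so its realization is fixed across rounds.
* **Global per-round subsampling**: in each round every repertoire is
  subsampled once and all pairs are compared on that shared realization,
  which makes the matrix internally consistent; the alternative
  (independent subsampling per pair) would give the same means but an
  inconsistent matrix.
* **Self-distance is defined as 0.** Two independent subsamples of the same
  repertoire would *not* give 0; the diagonal is a convention, and the
  null-split machinery quantifies the actual within-repertoire level.
* **Normalization then transform**: counts are scaled to sum to
  `norm_constant` (default 500) after subsampling; `asinh` (no cofactor) is
  applied to the normalized values. With the transform, RDI tracks average
  |log2 fold change|; without it, average percent change.
* **Distance modes**: `euclidean` (default) and `rmsd` =
  euclidean / sqrt(n_features). They differ by a constant the calibration
  absorbs; the mode is recorded in the matrix and checked at convert time.
* RDI values are only comparable across matrices computed with equal
  settings (subsample size, constant, transform, mode); `DistanceMatrix`
  carries these and `CalibrationModel.check_settings` enforces them.

Tunable parameters: `subsample_size` ("auto" = smallest repertoire;
determines the depth at which all repertoires are compared),
`norm_constant` (arbitrary scale, 500), `n_iterations` (100; Monte-Carlo
averaging of subsample noise — means are unbiased at any value, variance
shrinks with more rounds), `transform`, `distance_mode`, `seed`.

## Gene-call handling

IMGT-style calls (`IGHV1-2*02`) collapse to gene (`IGHV1-2`, allele suffix
stripped) or family (`IGHV1`, text before the first dash) level.
Multi-assignments (comma-separated candidates) resolve to the first
candidate when all candidates agree at the requested level and are dropped
otherwise: fractional counting would break the integrality that
without-replacement subsampling requires, and how the original annotation
pipelines resolved multi-assignments is not standardized — this rule is
this package's convention. Clone-level versus molecule-level counting is
decided entirely by the input table (one row per clone or per molecule);
the package never deduplicates.

## Simulation model

Simulated repertoires are multinomial draws from probability vectors over
a fixed gene pool. The default baseline is a 50-feature geometric-decay
vector (p ∝ 0.9^i), mimicking the steeply uneven segment usage of heavy-
chain and TCR repertoires; any baseline can be supplied, and calibration
derives its baseline from the data (average of per-repertoire frequency
vectors, renormalized). Perturbations act multiplicatively on the log2
scale, `p_fc ∝ p_base · 2^r` renormalized to sum 1, with `r` i.i.d.
Normal(0, σ²). The distribution of `r` is a modeling choice; because every
downstream use keys on the *realized* deviation of each perturbed vector —
mean |log2(p_fc/p_base)| or mean percent change, computed after
renormalization, over features with positive baseline probability — the
choice only affects how the deviation axis is covered. Zero-probability
baseline features stay zero and are excluded from deviation averages.
`perturbation_with_deviation` rescales a drawn perturbation by a 1-D root
find so the realized deviation hits a requested value exactly.

What the generator does **not** emulate: sequencing error, chimeras, UMI
structure, clonal lineage correlations, or genotype-driven presence/absence
of segments. Passing tests therefore show the metric and calibration
behave correctly for multinomial sampling from fixed usage profiles; on
real data, clonal expansion and annotation error add variance the
simulation does not represent.

## Calibration

For a given count table, the calibration matches its feature count and its
row sizes: each simulated dataset's size cycles through the real
repertoires' totals, so the subsampling machinery sees the same size
structure (and the same averaging of subsample noise) as the real
comparisons the model will be applied to. `n_perturb` (default 2000)
perturbed vectors span nominal deviations from 0 to `max_log2fc` (default
8, i.e. up to 256-fold average change); the nominal ladder mixes a
log-spaced half (resolution near 0, where the response curve bends) and a
uniform half (upper range). Each perturbed dataset's RDI is averaged over
comparisons to `n_baseline` (default 20) baseline datasets; the pairwise
RDI values among the baseline datasets are retained as the deviation-0
null sample.

The forward map (deviation → expected RDI) is a weighted cubic smoothing
spline (GCV-selected penalty) with two boundary safeguards:

* the null-sample values enter the fit as weighted anchor points at
  deviation 0 — they are direct measurements of the curve there;
* the fit uses data mirrored about 0. Reversing a perturbation leaves the
  distance distribution unchanged, so the true curve is even in the
  deviation with zero slope at 0; an asymmetric fit anticipates the rise
  and systematically undershoots the anchor.

The fitted spline is evaluated on a dense 1024-point grid, projected onto
monotone non-decreasing values (isotonic regression), and a microscopic
strictly-increasing ramp (span × 1e-7 over the grid) breaks flat ties so
the piecewise-linear map is numerically invertible; forward and inverse
interpolate the same grid, making inverse-of-forward exact to interpolation
precision on the fitted interior. A fit left flat by the projection raises
a calibration error (more perturbation vectors or a wider deviation range
needed).

Conversion clamps: observed RDI below the curve's value at deviation 0
maps to 0 ("no change", flagged `low_clamp`); above the fitted range, to
the maximum fitted deviation (`high_clamp`).

**Local spread (the ladder).** Residuals of the fitted points are summarized
by a sliding-window SD along the deviation axis (window = 10% of points,
minimum 20, linearly interpolated between window centers). Windows never
split groups of tied deviations — the deviation-0 anchors are not in
exchangeable order, and a partial group gives a biased SD. The ladder
reports (deviation, expected RDI, local SD) and approximates each band as
Normal; the raw null sample is kept in the model for empirical
alternatives, including the add-one-smoothed null tail fraction
(count(null ≥ observed)+1)/(n+1).

## Benchmark experiments and statistical choices

* **Depth confound** (30 replicates from one pool, sizes 3000–12,000):
  pairwise distances sharing a repertoire are correlated (each
  repertoire's particular parent draw shifts all its pairs), so a naive
  regression of all 435 pairs on size is severely anti-conservative. The
  test regresses each repertoire's mean distance to all others on its own
  size with an HC3 robust standard error; pair-level noise averages out
  and the test holds close to its nominal 5% size. The naive
  frequency-space distance shows a strongly significant negative slope
  under the same test; RDI does not.
* **Null-split alignment**: each split RDI is standardized by its size's
  deviation-0 band and the pooled z-sample is compared to the unit normal
  via the density overlap coefficient (integral of the pointwise minimum
  of the two densities), with the sample summarized by a matching normal.
  The band is Gaussian by construction, so this is the like-for-like
  comparison; a raw histogram overlap at ~40 splits per size is dominated
  by binning noise.
* Problem sizes used by the test suite and acceptance script (the
  package's own scaled protocol; the library defaults mirror the full
  one): calibrations with 200 perturbation vectors (500 for the per-size
  null-split ladders) × 20 baselines; 50 recovery replicates per deviation
  at 2000 sequences × 50 genes; 200 splits of a 100,000-sequence pool at
  small sides 1000–50,000; 30 replicates per size/deviation cell in the
  scaling experiment.

## Known limitations

* RDI is a *relative* measure; only the calibrated fold-change scale is
  comparable across datasets, and then only when the calibration's
  settings (features, sizes, transform) match the matrix being converted.
* The Gaussian ladder band is an approximation; tails of the null sample
  are available for exact empirical statements.
* Deviation estimates saturate where the response curve flattens (large
  deviations at small depths); `high_clamp` flags conversions there.
* The slope test for the depth confound is an honest 5%-level test: on a
  small fraction of seeds a flat metric will still show a nominally
  significant slope.
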