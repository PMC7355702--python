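# Methods

## The model

SSIR treats variable selection as a family of exact enrichment tests on
discretized chromatographic data. The data model has three layers:

**Grid.** The (time, m/z) plane is tiled by half-open cells. Time bins are
[t₀, t₀+Δt); mass windows are [c−r, c+r) around centers c forming an
arithmetic sequence. Both conventions are left-closed, so a register on a
boundary lands deterministically in exactly one cell and no register can be
double-counted. A register outside the declared coverage window is dropped
(and counted); the dropped signal also does not enter the normalization
mean, so late eluters or internal standards outside the window cannot
distort a sample's scale. Defaults: 6–17 min, Δt = 1/3 min, centers
49.0–170.0 amu in 0.5-amu steps, r = 0.25 amu → 33 × 243 = 8019 nodes.

**Binary code.** Each sample's node sums are reduced to a low/high string.
"Top 1 %" is implemented as a rank rule — exactly k = ⌈f·n⌉ nodes are high —
rather than an interpolated quantile, because the rank rule is exact,
deterministic and well-defined for small n. Ties at the cutoff go to the
lower node index. The percentile is taken **per sample** by default (each
sample is normalized per sample, and each sample is codified as its own
string); a pooled scope is available via `percentile_scope`. Constant
columns are uninformative and removed; bit-identical columns are collapsed
under their lowest-index member, and the grouping is kept as an invertible
map so the final report can expand representatives back to every node they
stand for.

**Enrichment null.** A rule of order r is a conjunction of r (node, level)
conditions; it selects the samples matching all of them. Under the null
hypothesis that the rule is an a-priori random extractor, the class count
among n selected samples is hypergeometric, and the p-value is the exact
upper tail P(X ≥ k). This is computed with integer combinatorics
(`math.comb` + `Fraction`), not floating-point summation, so threshold
comparisons are bit-reproducible; results are memoized since rule streams
revisit the same (N, K, n, k) tuples constantly. Both class directions are
scored per rule and the smaller p retained. The hypergeometric complement
symmetry — "high enriches class 1" and "low enriches class 0" have exactly
equal p — is asserted as a property test, and ties between such twins are
broken toward the high level so a variable's reported direction is the
class its *high* state enriches.

Selection applies a raw threshold (default 5·10⁻⁴) with no
multiple-testing correction: the threshold itself is the tunable
false-selection control, and the permutation-null measurement in the
acceptance script quantifies the realized family-wise rate under the study
conditions. Selected variables are ranked by ascending p, then node index.

A practical floor worth knowing: with n₁ + n₀ balanced samples the
smallest attainable p-value is 1/C(n₁+n₀, n₁); at the default threshold a
balanced design needs at least 7 + 7 samples before *any* selection is
possible (1/C(14,7) ≈ 2.9·10⁻⁴).

**Classification.** PCA consumes the selected variables' pre-dichotomization
intensity sums. Autoscaling (correlation matrix) is the default because
selected variables span very different raw magnitudes yet are expected to
contribute comparably; covariance mode (`scaling_mode="center"`) is kept as
an option. Loading signs are fixed (largest-magnitude entry positive) for
run-to-run reproducibility. The discriminant is Fisher's linear rule,
w ∝ S_pooled⁻¹(μ₁ − μ₀), with a midpoint threshold — with one component it
degenerates to a midpoint cut on PC1.

## Rule orders and cost

Order-1 rules (each node alone, both levels) are the default and are
scored directly. Orders 2–3 enumerate C(m, r)·2^r conjunctions over m
representatives with bit-packed sample masks (Python integers, `bit_count`),
skipping any conjunction containing a condition with zero marginal support.
Order 2 at m ≈ 240 costs ~10⁵ evaluations (sub-second); order 3 costs
~10⁸ and is only advisable after aggressive degeneracy reduction.

## Leave-one-out protocol

Each fold refits the entire pipeline — normalization, binarization cuts,
constant/degenerate node sets, rule p-values, PCA, discriminant — on the
n−1 retained raw runs. The held-out sample is then normalized **by its own
in-window mean** (per-sample normalization is self-contained, so no
training statistic is needed), accumulated on the grid, reduced to the
fold's selected variables and projected and classified. Binarization plays
no role at prediction time because classification operates on intensity
sums. A fold with an empty selection is recorded as `predicted = -1`
("no model"), never silently dropped. Two consequences are tested
explicitly: scaling any single sample's raw intensities by 10⁶ leaves the
whole cross-validation report byte-identical (normalization absorbs the
scale; the fold never sees its held-out sample), and injecting arbitrary
content into a held-out sample leaves its fold's fitted model unchanged.

## Synthetic data generator

The generator emulates unit-resolution centroided GC-MS volatile profiles:

- **Compounds** elute as Gaussian peaks (σ = 0.04 min ≈ 5-s peaks) sampled
  every 0.005 min; each has a sparse stick spectrum at integer m/z with
  fixed relative abundances.
- **Background**: 30 class-independent compounds per dataset, retention
  drawn uniformly over the window, 3–6 fragments, apex amplitudes lognormal
  around 1000 (geometric SD e^0.8) — wide enough that the top-1 % cut sits
  inside the background amplitude distribution, which is what makes
  constant-node removal and degeneracy grouping non-trivial.
- **Markers** (default preset): two treatment-generated furanic-style
  compounds (fragments 51/67/95/96/97 at ~7.2 min and 53/109/110 at
  ~10.5 min; class-0 apex 250, class effect ×20) and one treatment-removed
  compound (51/78 at ~9.2 min; class-0 apex 5000, effect ×0.05). The
  effects are deliberately an order of magnitude beyond the noise — the
  preset models a *strong* treatment signature, the regime in which the
  method is claimed to work. Marker retention times sit at bin centers so
  each peak concentrates in one time bin.
- **Noise**: per-compound-per-sample multiplicative lognormal (CV 0.2),
  one additive exponential baseline register per scan (scale 20), and a
  per-sample global scale factor drawn from [0.5, 2] that the pipeline's
  normalization must absorb (asserted exactly, floor disabled).
- **m/z jitter**: Gaussian (SD 0.05 amu) clipped to ±0.24 amu, so sticks
  never leak into neighboring windows; half-integer mass windows therefore
  stay empty and are discarded by the constant filter — an emergent
  behavior the tests check rather than impose.

The manifest lists, per marker, the grid nodes of fragments with relative
abundance ≥ 0.2 and the enriched class. Weaker fragments may or may not
surface above the percentile cut, so they are not promised; recovery is
scored against the manifest only.

What the generator does **not** model: retention drift between samples
(the pipeline performs no alignment, and its real-data robustness to drift
larger than a time bin is untested here), detector saturation, co-elution
at shared fragments beyond random ion collisions, isotope envelopes, and
profile-mode peak shapes. Passing the synthetic study therefore
demonstrates the machinery is correct and leak-free under the stated
conditions, not that any particular real dataset will separate.

## Numerical choices and degenerate inputs

- p-values exact (rational) → float only at the API boundary; arguments
  violating 0 ≤ k ≤ min(n, K) ≤ N raise.
- Grid binning guards against float drift at bin edges (a time equal to an
  edge opens the next bin, exactly).
- All-zero in-window intensity or an empty window → explicit error
  (normalization undefined).
- All-constant binary code → empty result with a warning; empty selection →
  `NoSignificantVariables`, not a silent empty model.
- Constant variable under autoscaling → error naming the variable.
- Coincident class means → explicit degenerate-discriminant error;
  singular pooled covariance → error suggesting fewer components.
- mzML: MS1 only, 32/64-bit float arrays, zlib or uncompressed; retention
  unit read from the unit accession, defaulting to seconds → minutes.

## Problem sizes used in the shipped studies

The test suite and acceptance script run the 10 + 10-sample preset (ten
seeded replicates, ~10⁴ registers per sample), a 100-permutation null, and
exhaustive p-value verification for all designs with N ≤ 12. These sizes
make every study reproducible on a laptop in seconds while keeping each
measured quantity away from its decision boundary by a comfortable margin.

## Known limitations

- Two classes only; multi-level (non-binary) discretization and
  multi-category extensions of the rule engine are out of scope.
- No retention-time alignment; the grid assumes drift ≪ time-bin width.
- Order-3 enumeration is exponential in spirit; it is provided but not the
  default.
- The per-sample percentile scope and the rank-rule tie-break are
  conventions chosen for determinism; pooled scope is available but the
  two can select different node sets on borderline data.
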