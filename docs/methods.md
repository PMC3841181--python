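# Methods

## The analysis model

The pipeline treats an individual's secondary-metabolite profile as a fixed
chemical fingerprint observable through LC/MS, and a cohort as a mixture of
*chemotypes* — compound suites shared by groups of individuals. Two parallel
partitions of the cohort are compared: chemo-groups derived from the
fingerprints, and phylogroups provided by genetic analysis. The scientific
question is whether the two partitions delimit the same units, and how to
classify the cases where they do not.

### TCM fingerprints

A centroided acquisition is a sequence of scans (retention time, m/z and
intensity arrays). The total chromatogram mass (TCM) spectrum aggregates
all intensity at each nominal mass over an RT window:

- Nominal mass is `floor(m/z)`, with half-open bins `[m, m+1)`. For the
  default window m/z 200–500 this yields exactly 300 bins; an inclusive
  convention would give 301 and is not used.
- The RT window defaults to 2–17 min (`rt_start` is configurable, e.g.
  2.5 min; both conventions appear in practice and the choice must be
  reported with results).
- Aggregation is `sum` by default; `mean` divides by the number of scans in
  the window — a per-individual scalar, so the two modes give proportional
  fingerprints and *identical* downstream correlation matrices. This
  equivalence is tested, which is why the pipeline does not need to resolve
  "summed" vs "averaged" phrasing ambiguities.

### Baseline correction

Correction is per nominal-mass channel, before binning:

- `per_bin_min` (default, parameter-free): subtract the channel's minimum
  over the RT window. Removes any constant offset exactly.
- `rolling_min`: subtract a running minimum over a centered RT window
  (default 1 min). For a linear drift `d` the residual is bounded by
  `d × window`. A 1 ns-scale tolerance on window edges keeps scans sitting
  exactly on an edge inside the window despite float grid arithmetic.

Residuals are clipped at zero (detector intensities are nonnegative).
Note that min-subtraction of a noisy channel leaves a positive residual with
expectation ≈ |min of n noise draws|; because every channel in the
acquisition window carries noise, this residual is approximately uniform
across bins and is absorbed by the correlation's per-vector centering.

### Chemo-group delimitation

- Similarity is the Pearson product-moment correlation of the TCM vectors.
  Correlation compares *shapes*: multiplying an individual's fingerprint by
  any positive constant (extract concentration, injection volume) changes
  nothing downstream. Spearman is available as a config option.
- Clustering is agglomerative on distance `d = 1 − r` (range [0, 2]),
  average linkage by default (complete and single offered). The
  agglomeration is implemented in-package so that equal-height ties merge
  the pair with the lexicographically smallest cluster-representative ids;
  with individuals processed in sorted-id order this makes merge heights
  and group memberships exactly invariant to input order. Average-linkage
  heights are verified against a brute-force O(n³) re-agglomeration oracle
  and against scipy's implementation.
- Chemo-groups are the maximal subtrees whose internal merges all lie at or
  below the cut height `1 − threshold`; the default threshold is 0.3
  similarity (an arbitrary but fixed convention; the number of groups is
  non-decreasing in the threshold, which is property-tested). Negative
  correlations are kept as-is.
- Group labels `CG1, CG2, …` follow first-member appearance order.

### PCA and separation calls

PCA is computed on the column-centered fingerprint matrix without variance
scaling (scikit-learn, full SVD). Explained variances use the (n−1)
denominator and sum to the total variance of the centered matrix; the
leading axis is verified against an explicit eigendecomposition. Requests
beyond the achievable rank are truncated with a warning.

Group separation in the first `dims` PCs (default 2) is the ratio of the
between-centroid distance to the pooled mean member-to-own-centroid
distance. Defaults `s_sep = 2` ("separated") and `s_overlap = 1`
("overlapping") leave an explicit indeterminate band rather than forcing a
binary call; coincident groups are overlapping by definition (0/0 → 0).

### Concordance and the exception taxonomy

The report contains the chemo × genetic cross-tabulation over co-scored
individuals (individuals present in only one labelling are excluded and
listed, never silently dropped), mapping-cardinality fractions binned as
{1, 2, ≥ 3} with exact detail, and the adjusted Rand index. ARI is the
package's chosen chance-corrected agreement summary and is labelled as a
package operationalization in the output; it is verified against an
all-pairs counting oracle, including exhaustively over all partition pairs
of a 5-element set.

The exception screen enumerates:

- **split phylogroup** (one phylogroup, ≥ 2 chemo-groups): each chemo-pair
  within the phylogroup is adjudicated in PC space — overlapping →
  `not-differentiated` (the chemical split is an artifact of the
  correlation cut), separated → `distinct-chemotypes`.
- **shared chemistry** (one chemo-group, ≥ 2 phylogroups): separated →
  `convergent` (independent acquisition of the same suite); overlapping →
  `single-origin-candidate` when the phylogroups are adjacent on a supplied
  tree (their combined tips form a clade) or when no tree is given, else
  `unresolved`. "Closely related" is operationalized as tree adjacency
  because no quantitative definition is standard.

### Genetic bookkeeping

Tree inference, alignment and model selection are consumed from published
tools, not reimplemented. The module provides:

- **Concatenation**: individuals must be present in ≥ `min_genes` (default
  2) of the gene partitions; absent genes are padded with `?`; source gaps
  (`-`) are preserved; both count as missing downstream. Total length is
  always the sum of partition lengths (515 + 461 + 627 = 1603 for an
  ANT/16S/COI design). Exclusions are returned as a manifest.
- **SNP ambiguity coding**: heterozygous sites (1-based positions) are
  replaced by the two-base IUPAC code; re-application raises because the
  coded symbol is no longer a plain base.
- **Posterior-sample accounting**: samples per run =
  `generations / sample_freq` (+1 with the generation-zero state); burn-in
  per run discards `floor(burnin_frac × samples)`. This per-run floor
  convention with generation zero included is the only one that yields
  144,008 retained trees for 8 × 20 M generations sampled every 1000 with
  10% burn-in, which is why it is the default; both flags are explicit.
- **p-distance phylogroups**: single-linkage clusters at a substitution
  threshold, skipping sites missing or ambiguous in either sequence, with a
  minimum shared-site requirement (default 50) that errors by pair.

## The synthetic cohort generator

`simulate` emulates what the analysis assumes about the data:

- A compound elutes as an unnormalized Gaussian kernel
  `exp(−(t − rt_center)² / 2σ²)` (so `base_abundance` is the apex intensity)
  and deposits intensity on nominal fragment masses (offset +0.3 from the
  integer so floor-binning is genuinely exercised), all within m/z 200–500.
- Per-individual abundance is lognormal with mean 1 and CV `abundance_cv`
  (multiplicative, befitting a scale-free similarity), with smaller
  per-compound lognormal jitter (`compound_cv`).
- The acquisition is a uniform scan grid over `rt_window` (default 0–17 min
  at 0.05 min); every individual records the *full* unit-mass channel grid,
  so baseline (`level + drift × t`) and zero-truncated Gaussian detector
  noise appear on all 300 channels. Dense emission matters: it makes shared
  baseline/noise offsets uniform across bins (hence removable by the
  correlation's centering) and gives PCA a stable noise floor.
- Genetic labels attach per individual through `genetic_map`
  (chemotype → phylogroup(s); round-robin when one chemotype maps to
  several) and optionally `nuclear_map` (phylogroup → nuclear cluster).
- An optional star-phylogeny sequence sampler emits per-gene alignments
  (phylogroup-level divergence plus private mutations; slower rates for
  nuclear markers are expressed by passing a smaller divergence), enough to
  exercise the p-distance delimitation end-to-end.

### Scenario presets

Preset parameters were designed from the geometry of the statistics they
must exhibit, then frozen:

- `concordant`: four disjoint compound suites, one phylogroup each, modest
  noise (CV 0.15, noise 0.3). The pipeline recovers the truth partition
  with ARI 1 and an empty exception list.
- `convergent_chemistry`: two chemotypes share a suite with mirrored
  proportion vectors (their cross-correlation stays above the 0.3 cut, so
  the dendrogram merges them) while a low abundance CV keeps the PC clouds
  tight and far apart (separation ratio ≫ 2 → `convergent`). A third,
  disjoint chemotype anchors the contrast.
- `lumped_nuclear`: the concordant design plus a nuclear map in which one
  cluster covers two phylogroups, producing a nonzero cardinality-2
  fraction in the nuclear × mitochondrial cross-tab.
- `split_phylogroup`: one phylogroup spans two *minor* chemotypes whose
  shapes differ (cross-correlation ≈ 0.1, so the cut splits them) but whose
  absolute signal is small next to two dominant anchor chemotypes that span
  PC1–2. In that plane the minor clouds sit near the origin with
  noise-floor scatter, so the split is `not-differentiated`. Sixteen
  individuals per chemotype are used because the noise-driven
  centroid-to-spread ratio behaves like a Rayleigh variable with scale
  `sqrt(2/n)`: the probability of a spurious "separated/indeterminate" call
  falls from ~4% at n = 8 to ~0.2% at n = 16.

### What the simulator does not model

No isotope envelopes, adduct series, MS² fragmentation chemistry, RT drift
between runs (no alignment/warping is implemented either), detector
saturation, or realistic diterpene fragment patterns. Passing tests
therefore demonstrate the *statistical* correctness of the pipeline under
its stated model — Gaussian peaks, multiplicative abundance, additive
noise — not robustness to instrument artifacts real cohorts may carry.
Abundance distributions are free configuration, not calibrated to any
measured cohort.

## Numerical choices

- Dendrogram cut uses a 1e-12 slack on the cut height; similarity matrices
  are symmetrized and their diagonal pinned to exactly 1 on construction.
- Float64 values round-trip exactly through both on-disk formats
  (`%.17g` text, 64-bit little-endian base64 in mzML); readers use
  pandas' `float_precision="round_trip"`.
- The mzML layer is a minimal reader/writer for MS1 centroid spectra
  (32/64-bit floats, optional zlib, minute- or second-valued scan times);
  vendor formats, MSn and indexed wrappers are out of scope.
- Pipeline outputs are deterministic byte-for-byte under a fixed config and
  seed: per-individual random streams are spawned from a root seed
  sequence, all writers use fixed float formats, and JSON is key-sorted.
  Each run directory carries a manifest with a config hash.

## Problem sizes

Default test and reproduction runs use cohorts of 18–64 individuals with
301-scan, 300-channel acquisitions, chosen as comfortably representative of
a field study of this shape (the motivating cohort profiled 54 animals)
while keeping the full suite fast on a laptop.

## Known limitations

- The original chemometric software's proprietary "clustering coefficients"
  are not documented; this package fixes a transparent correlation +
  average-linkage reimplementation, and published dendrograms may differ in
  detail.
- The split/shared verdicts depend on the PC plane retained (`dims = 2` by
  default) and the `s_sep`/`s_overlap` conventions; the indeterminate band
  is reported rather than hidden.
- Whether PCA should be computed on the whole cohort or per subset is a
  genuine analysis choice; the library supports subsetting the spectra list
  before `pca`, and the report records only what it was given.
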