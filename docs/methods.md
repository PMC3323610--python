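# Methods

## Problem and model

A well image from a zebrafish-embryo screen shows one organism on a
light background, frequently obscured by nanoparticle deposits and
chorion (eggshell) fragments. The task is a three-class decision —
hatched, unhatched, dead — that drives the assay endpoints (hatching
rate, mortality rate). The package treats it as supervised image
classification on hand-crafted grayscale descriptors: no segmentation of
the organism is attempted, which is what makes the approach robust to
arbitrary embryo position and orientation.

## Descriptors

All descriptors consume an 8-bit grayscale image (16-bit sources are
mapped by round(v/257); scaling rather than truncation preserves the
full dynamic range). Coordinates are row-major with the origin top-left.
When an image side is not divisible by a partition, the remainder pixels
(< 8 px) are absorbed by the last block row/column — deterministic and
resampling-free.

**Edge histograms (LEHD, GSEHD).** The image is split into 4×4 blocks,
each tiled by an 8×8 grid of image-blocks (1024 per image). An
image-block is reduced to its 2×2 sub-block means (a0, a1; a2, a3) and
filtered with the five MPEG-7 edge kernels — vertical (1,−1,1,−1),
horizontal (1,1,−1,−1), 45° (√2,0,0,−√2), 135° (0,√2,−√2,0),
non-directional (2,−2,−2,2). The strongest |response| is assigned iff it
exceeds a threshold T (default 11; both T and the 8×8 grid are
`EdgeConfig` parameters — the conventions of the reference MPEG-7
implementation are not published, so these are documented defaults, not
asserted facts). Per-block relative frequencies quantize to integers in
[0, 7] by min(⌊8f⌋, 7), a monotone rule that is exactly testable. The
semi-global histogram averages the *pre-quantization* frequencies over
16 block groups — whole image, 4 rows, 4 columns, 4 corner quadrants,
center 2×2, top half, bottom half — and then quantizes. A literal
"image + five 4-block groups" reading would give 30 bins, not the stated
80; the 16-group layout honors the dimension and is configurable
(`AggregationLayout`) for anyone preferring another grouping.

**Edge count.** The number of assigned image-blocks (0–1024) is the
quality statistic: deposits and debris create edges everywhere, so
images at ≥ 170 edges go to the stress partition. The threshold is the
triage default and a parameter of `qc_filter`; triage routes, it never
deletes.

**Color descriptors.** CHD is the plain 16-bin histogram (bin width 16;
bins sum to width×height). RCD is the 8×8 matrix of block mean
intensities, row-major. CLD applies the orthonormal 2-D DCT-II to that
matrix and keeps the first 15 zig-zag coefficients, unquantized — the
downstream Z-score removes scale anyway. SCD builds the 8-bin histogram
(width 32), normalizes to relative frequencies and applies a full
3-level averaging Haar transform (pairwise averages and half-differences;
output: overall average, then details coarsest→finest). This
averaging convention is exactly invertible, which is what the tests
assert; which 8 of the 256 standard scalable-color coefficients the
grayscale case corresponds to is not documented anywhere authoritative,
so the realization keeps the "Haar-encoded histogram" semantics at the
stated dimension.

## Normalization and leakage

Z-scores use the population (divide-by-n) standard deviation — the
convention is unstated in most references; population keeps the
two-point fixture {−1, 1} exact. Constant components map to 0 rather
than dividing by zero. Statistics are learned on training rows only and
travel with the persisted model; inside cross-validation they are re-fit
per training split, so held-out rows can never influence the scaling
that is applied to them (property-tested with an injected outlier).

## Classifier and model selection

One-against-one decomposition: 3 binary Gaussian-kernel SVMs (libsvm via
scikit-learn, tolerance 1e-3), majority vote, ties broken by the largest
summed signed decision value (standard one-vs-one practice and
deterministic). Hyperparameters: coarse log₂ grid C ∈ 2^{−5..15 step 2},
γ ∈ 2^{−15..3 step 2} (110 points), then a refined grid over
[C/4, 4C] × [γ/4, 4γ] with 30 equal *linear* units per axis (31 points
inclusive) — linear spacing is the only reading under which an optimum
like C = 5 is reachable on a [2¹, 2⁵] axis. Grid ties resolve to the
smallest C, then the smallest γ. Cross-validation is stratified (fold
sizes stable for class counts in the few hundreds) with a documented
seed; the per-subset wrapper search reuses one seeded fold split so the
63 subset accuracies are comparable. Subset ties prefer fewer
components, then the lexicographically smaller code. The grid scorer
precomputes per-fold pairwise distance matrices and exponentiates the
kernel once per γ, sharing it across all C values — algebraically
identical to refitting each point, and cross-checked in the tests
against the plain per-point cross-validation path. The k-NN baseline
uses Euclidean distance on the same normalized features, k = 10, with
vote ties going to the nearest neighbor among the tied classes.

## Evaluation conventions

Confusion matrices have **rows = predicted, columns = true** (many
libraries transpose this). Class precision is therefore a row statistic,
class recall a column statistic, and the false-positive rate of a class
is 100% − precision. Display values round half-up to 2 decimals; full
precision is kept internally. Metrics with empty denominators are
reported as undefined, never as 0. The stress test is pure prediction on
images disjoint (by id) from the training manifest; overlap is an error,
not a warning.

## Self-organizing map

Batch training with a Gaussian neighborhood: every epoch assigns samples
to best-matching cells and replaces each codebook with the
neighborhood-weighted mean; the radius decays linearly from max(grid)/2
to 1 over 50 epochs. Defaults (15×15 grid, schedule, seed) are free
configuration — batch mode was chosen because it is deterministic under
a seed, which online training is not without extra bookkeeping. Cells
are colored [R, G, B] = [N_dead, N_hatched, N_unhatched]/N (empty cells
white). Primary clusters come from k-means on the codebook vectors (10
restarts, centroid-lexicographic relabeling for determinism); merging
clusters into metaclusters is user input, mirroring how adjacent
same-phenotype clusters are read off such maps by eye. Cluster quality
assigns each (merged) cluster its majority phenotype (ties go to
phenotype order and are flagged) and reports per-cluster precision,
per-phenotype recall, and the overall correctly-grouped fraction.

## Synthetic data

The generator emulates the structure the classifier relies on, not the
appearance of real micrographs: a 696×520 8-bit frame, background 200,
and one organism — hatched: a curved tapering larva (length 300–340 px,
body intensity 68–78, free orientation, may clip the frame edge);
unhatched: a bright chorion annulus (radius 88–98 px, intensity 226–238)
enclosing a curled dark embryo arc (intensity 84–94); dead: an irregular
dark disk (radius 72–82 px, intensity 52–60, low-order harmonic boundary
wobble). Sizes vary narrowly because 72-h zebrafish morphology is
stereotyped — chorion diameter and larva length change by a few percent
between individuals — and each structure's intensity stays inside one
16-wide histogram bin (dead mass bin 3, larva bin 4, embryo bin 5,
background bin 12, ring bin 14), so a clean image shows clean intensity
modes and class-conditional structure survives unsupervised as well as
supervised analysis. Noise: dark speckles (default 40 per
image, drawn sequentially so a lower count is a prefix of the same
deposit sequence), thin bright arcs (default 3), a linear illumination
gradient (±10), and Gaussian blur (σ = 1). The defaults put clean images
at roughly 80–130 edges — below the 170 triage threshold — while the
stress partition multiplies the noise amounts by 4 (≈ 200–260 edges,
above it). All randomness derives from one seed via spawned
sub-sequences; generation of one image never consults another.

What passing on synthetic plates does **not** show: the default classes
are far more separable than real bright-field data (the end-to-end
benchmark saturates near 100% where the real-data regime is ~97%), there
is no edema phenotype, no focus variation, no well-to-well illumination
correlation, and no dose–response structure. The synthetic results
validate the machinery — descriptor arithmetic, selection, evaluation —
not a claim about real-image accuracy.

## Problem sizes and numerical choices

The end-to-end benchmark in the test suite uses 100 images per class
(n = 300), a size at which the wrapper's 63 coarse grid searches finish
in a few minutes while leaving cross-validation folds with 30 test
images each. Descriptor oracle equivalence is asserted exactly for
integer descriptors and at 1e-9 for real-valued ones; Haar and
normalization round-trips at 1e-10–1e-12. Degenerate inputs are errors,
not silent defaults: empty subset codes, images too small for their edge
partition, empty stress sets, k exceeding the cell or sample count.

## Known limitations

- The exact conventions of the reference MPEG-7 implementation (edge
  threshold, image-block count, scalable-color coefficient subset) are
  unpublished; this package documents its own and exposes them as
  configuration.
- Solver-level duplication of any particular SVM implementation is not
  asserted; accuracies are the contract, decision values are not.
- The SOM layout itself is seed- and data-dependent; only its quality
  arithmetic and determinism are guaranteed.
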