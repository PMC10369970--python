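# Methods notes

This note records the modeling assumptions, parameter choices and numerical
conventions behind the package, and what the synthetic-data tests do and do
not establish.

## Coordinates and the bin grid

All coordinates are 0-based half-open internally; BED is read/written
natively and wiggle fixedStep conversion (1-based) happens only inside the
signal reader/writer. Signal, score and state tracks live on a 25 bp grid:
position `p` maps to bin `p // 25`, and a bin's representative
("center", 13th) nucleotide is `25*i + 12`. Bins not covered by an input
file read as signal 0 — real imputed tracks are dense, so this matters only
for sparse synthetic inputs. The bedGraph writer merges runs of equal
values; readers accept merged and unmerged forms, and round-trips are
bitwise exact (values are serialized with `repr`).

## Label extraction

Thresholds follow each rule's wording strictly: *exceeding* 1 and *under*
−1 for tiled-MPRA scores (scores of exactly ±1 are neutral), *under* 0.05
for p-values (p = 0.05 is neutral), *above* 4 or 1 for peak thresholds.
The signed-extremum convention defines the tile score: the signed value at
the 5 bp interval with maximal |score|, first position on ties; regions
below −1 are excluded as likely repressive rather than labeled. The
"center" of an even-length interval is `start + length // 2`, applied
uniformly to constructs, peaks and elements. Top-fraction peak selection
keeps `ceil(f*N)` peaks and includes all peaks tied at the cutoff score,
so membership is stable under reordering of equal scores. Background
neutral sampling draws exactly `3 × n_activating` positions (configurable)
uniformly over non-excluded bases via bounded rejection sampling from an
explicit seeded generator. CRISPRi labeling applies the direction/outlier
filters (beta < 0, no outlier flag) or power/direction filters before the
"significant for any gene" rule; elements with no surviving record are
neutral in the per-locus screen mode (they were tested and not
significant) but dropped in the element–gene aggregation mode, where the
surviving-pair universe defines the tested set.

## Feature pipeline

Window features sample the signal at offsets −1000..+1000 bp in 25 bp
steps (81 values per mark); offsets off a chromosome read 0, matching the
track contract. Per-mark PCA centers but does not scale the 81 features —
standardization of all assembled features happens afterwards — and keeps
the top 3 components with a deterministic sign convention (the
largest-magnitude loading entry is made positive), so fitted transforms
are identical across linear-algebra backends. Rank-deficient inputs
zero-pad the missing components and are flagged. Binary and one-hot
columns are standardized along with everything else; zero-variance columns
map to 0 rather than dividing by a vanishing scale. Feature order is
frozen: per-mark PC1–3, per-mark center signal, per-mark peak indicator,
state one-hot — `5M + K` columns, 85 at M = 12, K = 25. PCA and
standardizer are only ever fitted on training rows; evaluation code
assembles test features with train-fitted transforms, and a test asserts
the distinction is real.

## Experts

Members are L2 logistic regressions (C = 1, lbfgs, tol 1e-6, 1000
iterations, refit once with doubled iterations and flagged if
non-convergent), each on an independent bootstrap resample of size N;
single-class resamples are redrawn. Per-sample weights implement
w(activating) = n_neutral, w(neutral) = 3·n_activating, which fixes the
weighted activating share at 1/4 identically — the deliberate 1:3
effective ratio keeps expert scores comparable across datasets of very
different sizes and makes high scores mean high activity rather than
"above this dataset's base rate". Ensemble prediction averages member
probabilities (not votes): the score is meant to be a class-membership
probability, and averaging preserves that reading. Within-dataset
evaluation uses stratified 4:1 partitions, 20 by default, refitting all
transforms per partition and redrawing partitions whose test side is
single-class (logged through the redraw counter). Cell-type holdout trains
experts only on other cell types' datasets and additionally partitions the
genome into 5 kb chunks assigned to test with probability 0.25, so
training and test loci never share a chunk; the combined score is the
plain mean over surviving experts. Baselines: the raw single-mark signal
at the reference nucleotide used directly as a score, and a chromatin-state
table mapping each state to its training positive fraction (unseen states
fall back to the global fraction). AUROC uses the midrank Mann–Whitney
formulation.

## Scoring and normalization

Genomewide scoring extracts features at every bin's center nucleotide in
batches and is bit-identical to pointwise prediction (asserted by an
oracle test). ChromScore is the per-bin arithmetic mean of expert tracks.
Quantile normalization samples n positions (default 1e5 in code paths
exercised here; the procedure is size-agnostic and the reference
operating point is 10 million), sorts each expert's sampled scores,
takes the per-rank median across experts as the reference distribution,
and maps each expert's 1000 equal-mass quantile bins to the median
reference value over the ranks in the bin. Values outside the sampled
range clamp to the edge bins — the mapping is monotone, rank-preserving,
and distribution-equalizing up to bin resolution.

## ChromScoreHMM

Binarization takes, per expert and cell type, the `ceil(0.02·N)`-th
largest genomewide score as the threshold and calls every bin at or above
it; ties therefore can only widen the called set. Constant tracks binarize
to all-zero. The HMM has K states (default 15) and one Bernoulli emission
parameter per state and expert; observation likelihoods are products of
independent Bernoullis. Training is standard Baum–Welch with scaled
forward–backward recursions over all (cell type, chromosome) sequences
under one shared parameter set; there is no likelihood-change stopping
criterion — training always runs `max_iter` iterations (default 200).
Full-batch EM has the usual non-decreasing likelihood guarantee, asserted
per iteration in tests; an optional per-iteration random subset of
sequences (batch_size, e.g. 128) is available for fidelity to training on
random cell-type/chromosome subsets, at the cost of that guarantee.
Emissions are clamped to [1e-6, 1−1e-6] to avoid log-domain degeneracies.
Initialization is seeded-random (stochastic π and A, emissions uniform in
(0.05, 0.95)); nothing in the procedure depends on a specific initializer
beyond the seed being recorded. Decoding is per-bin posterior argmax
(ties to the lowest state index) rather than Viterbi — the two differ, and
marginal decoding matches the segmentation semantics of per-bin state
assignment. States are renumbered by decreasing mean emission (stable
sort), a pure relabeling that leaves likelihoods unchanged. Grouping
rules: multi-expert (≥2 emissions ≥0.20), single-expert (exactly one
≥0.90, all others <0.10), no-expert (all <0.001); states matching no rule
are labeled `unclassified` explicitly rather than forced into a group.

## Enrichment analyses

Overlap enrichment works in bin units: an interval overlaps a bin if it
covers ≥1 bp of it, fold(state) = (state's overlap fraction)/(genome
overlap fraction), and the mixture identity Σ genome%·fold = 1 holds to
1e-9. Annotations covering zero bins report missing folds, never 0. TSS
profiles use symmetric offsets with negative-strand windows flipped so
positive offsets point into the gene body; window positions off a
chromosome are dropped from the averages. Expression correlations use
log2(RPKM+1), per-offset Pearson across genes within a cell type averaged
over cell types, reported missing under 3 usable points. Repeat
enrichments rank sampled positions into equal-count score quantiles
(default 200) and divide each quantile's overlap fraction by the sampled
background. Pairwise track correlations share one position sample across
all pairs; constant tracks yield missing correlations. Group-mean
correlation summaries exclude caller-specified groups by name. Every
sampler takes an explicit generator and is seed-deterministic.

## The synthetic world

`fixtures.make_world` plants non-overlapping elements (default 200 on
2 × 2 Mb chromosomes, 3 cell types, ≥5 kb spacing) with strength uniform
in [0.5, 1], a per-cell-type activity mask (each element active in a
random non-empty subset, p = 0.6 per cell type), and a 15% repressed
fraction. Rendering adds a strength-scaled Gaussian bump (σ = 500 bp,
chosen so the 2 kb feature window sees the full bump) to the first three
"activating" marks at active elements and to the last "repressive" mark at
repressed ones, over background noise (σ = 0.1, truncated at 0); peaks are
±250 bp around responsive elements, and states mark active (state 1) and
repressed (state 2) neighborhoods with the remaining states cycling over
background. Assay readouts are monotone in planted strength with additive
noise, emitted in exactly the labelers' schemas. The default scale runs
the full pipeline in well under a minute on one CPU.

What passing tests show: the pipeline recovers a planted, low-noise,
shared-across-cell-types chromatin→activity rule (holdout AUROC > 0.9)
and collapses to chance on permuted labels. What they do not show:
performance on real chromatin, whose signal is non-Gaussian,
long-range-correlated, confounded with accessibility and copy number, and
whose assay readouts disagree with each other far more than these
generators do. Absolute AUROCs on synthetic worlds are not comparable to
AUROCs on real data.

## Problem sizes in tests

The test suite uses the default world for the end-to-end checks and
smaller worlds (1 chromosome, 0.1–0.3 Mb, 2–4 marks) for unit tests. The
end-to-end holdout uses 5 spatial-partition repetitions with 10-member
ensembles and the permuted-label control uses 20 partitions — repetition
and ensemble counts are evaluation problem sizes, not modeled quantities;
the weight rule, thresholds and feature definitions are always the
defaults above. HMM parameter recovery is checked at T = 50,000 with a
3-state, 4-track model and 40 EM iterations, where emissions and
transitions come back within 0.05 after optimal state matching.

## Design choices where the design was open

- CLI surface: three subcommands (`simulate`, `run`, `validate-config`)
  over a library-first API; individual pipeline stages are one-call library
  functions, and `run` chains them with provenance (resolved config and
  seeds in the manifest).
- Member aggregation by probability averaging; vote counting discards the
  calibration that motivates bagging here.
- Posterior-argmax decoding rather than Viterbi (documented above).
- Quantile-bin edge handling: out-of-range values clamp to edge bins.
- Partition redraw on single-class test sets, bounded and logged.
- Zero-fill for uncovered track positions.

## Known limitations

- No sequence-derived features by design; the framework is sequence-free.
- bigWig/tabix I/O is not implemented; text formats only.
- The HMM trains one shared parameter set (concatenated mode) only; no
  per-cell-type models.
- Baum–Welch with subsampled batches loses the monotonicity guarantee and
  is provided for fidelity, not as the default.
- Hierarchical-clustering heatmap rendering is out of scope; correlation
  matrices and summaries are computed, plotting is left to the caller.
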