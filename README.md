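# chromactivity

Predicting regulatory activity from chromatin marks, and annotating the
genome with it.

Functional characterization assays — MPRAs, STARR-seq, HiDRA, CRISPRi
screens — measure whether a genomic sequence can activate transcription, but
each assay covers limited loci in a handful of cell types. Chromatin-mark
data (imputed signal tracks, peak calls, chromatin-state segmentations), by
contrast, are available uniformly across >100 cell types. This package
bridges the two: it harmonizes heterogeneous assay readouts into binary
*activating* vs *neutral* labels, trains one "expert" classifier per
dataset on chromatin features, scores the genome at 25 bp resolution in any
cell type, averages the experts into a single **ChromScore** track, and
segments the genome into **ChromScoreHMM** states with a multivariate
Bernoulli-emission hidden Markov model. It is aimed at computational
biologists who want per-cell-type regulatory activity potential tracks, or
who want to desk-test this class of pipeline on synthetic data with planted
ground truth.

## The model

**Labels.** Each dataset family has its own rule: tiled-MPRA regions are
labeled by the signed score $S_{\text{absmax}}$ at the position of maximum
absolute activity ($S>1$ activating, $-1\le S\le 1$ neutral, $S<-1$
dropped as repressive); construct assays by $p<0.05$; STARR-seq peak calls
by the top 10% of output/input fold change (with 3 random background
neutrals per activating region); HiDRA driver elements by RNA/DNA ratio
$>1$; CRISPRi element–gene records by adjusted $p<0.05$ for any target
gene after direction/power/outlier filters.

**Features (85).** For each reference nucleotide and each of $M=12$ marks:
the signal sampled every 25 bp across a 2 kb window (81 values) reduced to
its top 3 principal components, plus the raw signal value at the
nucleotide and a binary peak indicator; a one-hot encoding of the 25-state
chromatin-state annotation completes $5M + 25 = 85$ columns. PCA and
standardization are always fit on training partitions only.

**Experts.** A bagging ensemble of 100 L2-regularized logistic regressions
($C=1$), each fit on a bootstrap resample with class weights
$w(\text{act}) = n_{\text{neu}}$, $w(\text{neu}) = 3\,n_{\text{act}}$, so
the weighted activating share is exactly $1/4$ in every dataset. The
expert score is the mean member probability; **ChromScore** is the mean
over experts at each 25 bp bin (scored at the bin's 13th nucleotide).
Expert distributions can be quantile-normalized onto a shared per-rank
median reference (1000 bins).

**ChromScoreHMM.** Each expert track is binarized at its top-2% threshold;
a $K=15$ state HMM with independent Bernoulli emissions per (state,
expert) is trained by Baum–Welch over all (cell type, chromosome)
sequences sharing one parameter set, decoded by per-bin posterior argmax,
and states are renumbered by decreasing mean emission. Emission rows
classify states as multi-expert (≥2 experts ≥0.20), single-expert (one
≥0.90, others <0.10) or no-expert (all <0.001).

Downstream analyses: overlap fold enrichments in 25 bp bin units,
strand-aware TSS profiles (24 kb windows), per-offset Pearson correlation
with $\log_2(\text{RPKM}+1)$ expression, repeat-element enrichment across
200 score quantiles, pairwise track correlations, and per-state score
distributions.

## Worked example

The package needs no external data: the `fixtures` module generates a
synthetic genome with planted regulatory elements whose chromatin tracks,
peak calls, states and assay readouts are rendered from the planted truth.
Run the full pipeline on such a world:

```bash
chromactivity run --out demo --seed 1 --n-models 10 --k 5 \
    --hmm-max-iter 30 --n-elements 60 --chrom-length 600000
```

which prints

```
hidra/CT1: median AUROC 1.000 (136 regions)
hidra/CT2: median AUROC 1.000 (116 regions)
hidra/CT3: median AUROC 1.000 (136 regions)
HMM state groups: ['multi_expert', 'unclassified', 'no_expert', 'no_expert', 'no_expert']
```

Each line is one synthetic dataset's median held-out AUROC over stratified
4:1 train/test partitions — 1.0 here because at low noise the planted
mark-to-activity rule is fully recoverable. The state groups summarize the
learned HMM emissions: one state captures bins where several experts'
top-2% calls coincide (the multi-expert regulatory state), while most of
the genome falls into no-expert background states. The output directory
contains the expert and ChromScore bedGraph tracks, binarized calls, the
HMM model TSV, per-cell-type segmentation BEDs and an overlap-enrichment
table.

Library use mirrors the CLI: `fixtures.make_world` /
`make_labeled_dataset` build inputs, `experts.train_expert` /
`evaluate_within_dataset` / `evaluate_cell_type_holdout` fit and evaluate,
`scoring.score_genome` / `chromscore` / `build_normalization_map` produce
tracks, `scorehmm.binarize_tracks` / `baum_welch` / `decode` /
`classify_states` build the annotation, and `enrichment.*` run the
analyses.

## Layout

```
src/chromactivity/
  core_io.py     genome assembly, bedGraph/wiggle/BED/TSV I/O on the 25 bp grid
  labeling.py    per-assay label extraction rules
  features.py    window PCA, peak/state features, standardization
  experts.py     bagging ensembles, class weights, evaluation schemes, baselines
  scoring.py     genomewide scoring, ChromScore, quantile normalization
  scorehmm.py    binarization, Bernoulli-emission HMM, state ordering/grouping
  enrichment.py  overlap folds, TSS profiles, expression/repeat/correlation analyses
  fixtures.py    synthetic worlds with planted ground truth
  cli.py         thin command-line orchestration
```

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
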