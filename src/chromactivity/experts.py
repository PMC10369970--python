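"""Per-dataset expert classifiers and their evaluation.

An expert is a bagging ensemble of weighted L2 logistic regressions (100
members by default, regularization C=1) trained on one dataset's
activating/neutral labels.  The class-weight rule w(activating)=n_neutral,
w(neutral)=3*n_activating fixes the weighted activating share at 0.25 for
every dataset, so the ensemble's probability output emphasizes the high
regulatory-activity end of the scale consistently across datasets.

Evaluation schemes: stratified within-dataset train/test partitions, and a
cell-type holdout in which the experts trained in other cell types score a
held-out cell type's loci, combined with a spatial 5 kb-chunk genome
partition to keep nearby training and test loci apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from chromactivity.core_io import (
    GenomeAssembly,
    IntervalSet,
    SignalTrack,
    StateAnnotation,
)
from chromactivity.features import (
    FeatureMatrix,
    MarkPCA,
    Standardizer,
    assemble_features,
    fit_feature_transforms,
    fit_standardizer,
)
from chromactivity.labeling import LabeledRegion

ACTIVATING, NEUTRAL = "activating", "neutral"


# ---------------------------------------------------------------------------
# class weights


@dataclass(frozen=True)
class ClassWeights:
    """Label weights with a fixed weighted activating share of 1/4."""

    w_activating: float
    w_neutral: float

    def weighted_activating_share(self, n_activating: int, n_neutral: int) -> float:
        a = self.w_activating * n_activating
        return a / (a + self.w_neutral * n_neutral)


def make_class_weights(n_activating: int, n_neutral: int) -> ClassWeights:
    """w(activating) = n_neutral and w(neutral) = 3*n_activating.

    For any positive counts the weighted activating mass is
    n_neutral*n_activating out of a total 4*n_neutral*n_activating: an
    effective activating:neutral ratio of 1:3 regardless of dataset size.
    """
    if n_activating <= 0 or n_neutral <= 0:
        raise ValueError("both label counts must be positive")
    return ClassWeights(w_activating=float(n_neutral),
                        w_neutral=3.0 * float(n_activating))


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class ExpertConfig:
    n_models: int = 100
    C: float = 1.0
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-6


@dataclass
class LogisticMember:
    coef: np.ndarray
    intercept: float
    converged: bool = True

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ExpertEnsemble:
    dataset_id: str
    members: list[LogisticMember]
    standardizer: Standardizer
    pcas: list[MarkPCA]
    feature_names: list[str]
    seed: int
    cell_type: str = ""


def _fit_member(X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                cfg: ExpertConfig) -> LogisticMember:
    # sklearn's default penalty is the L2 norm.
    model = LogisticRegression(
        C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter, tol=cfg.tol,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y, sample_weight=sample_weight)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = LogisticRegression(
                    C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter * 2,
                    tol=cfg.tol,
                )
                model.fit(X, y, sample_weight=sample_weight)
    return LogisticMember(model.coef_.ravel().copy(),
                          float(model.intercept_[0]), converged)


def train_expert(features: FeatureMatrix, labels: np.ndarray,
                 cfg: ExpertConfig | None = None,
                 pcas: list[MarkPCA] | None = None,
                 dataset_id: str = "", cell_type: str = "") -> ExpertEnsemble:
    """Train a bagging ensemble on an (unstandardized) feature matrix.

    ``labels`` is a boolean/0-1 vector (1 = activating).  Each member is
    fitted on an independent bootstrap resample of the full training set
    with the dataset-level class weights applied per sample.  The
    standardizer is fitted here on the training matrix; ``pcas`` are the
    window PCA transforms already used to build ``features`` and are
    carried along so the ensemble can be applied genomewide.
    """
    cfg = cfg or ExpertConfig()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 examples of each class")
    weights = make_class_weights(int(y.sum()), int((y == 0).sum()))
    per_sample = np.where(y == 1, weights.w_activating, weights.w_neutral)
    standardizer = fit_standardizer(features.values, features.feature_names)
    X = standardizer.transform(features.values)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    members = []
    for _ in range(cfg.n_models):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        members.append(_fit_member(X[idx], y[idx], per_sample[idx], cfg))
    return ExpertEnsemble(dataset_id, members, standardizer,
                          list(pcas or []), list(features.feature_names),
                          cfg.seed, cell_type)


def predict_expert(ensemble: ExpertEnsemble, features: FeatureMatrix) -> np.ndarray:
    """Mean of member activating-class probabilities, in [0, 1]."""
    if features.feature_names != ensemble.feature_names:
        raise ValueError("feature order does not match the ensemble")
    X = ensemble.standardizer.transform(features.values)
    probs = np.stack([m.predict_proba(X) for m in ensemble.members])
    return probs.mean(axis=0)


# ---------------------------------------------------------------------------
# metrics


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC with midrank tie handling (Mann-Whitney U formulation)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined for a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# datasets and evaluation


@dataclass
class LabeledDataset:
    """One functional-characterization dataset bound to its cell type's
    chromatin feature inputs."""

    dataset_id: str
    cell_type: str
    regions: list[LabeledRegion]
    tracks: list[SignalTrack]
    peaks: list[IntervalSet]
    ann: StateAnnotation

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label == ACTIVATING for r in self.regions], dtype=int)


@dataclass
class EvaluationResult:
    dataset_id: str
    scheme: str  # "within_dataset" | "cell_type_holdout"
    aurocs: list[float] = field(default_factory=list)

    @property
    def median_auroc(self) -> float:
        return float(np.median(self.aurocs))


@dataclass
class EvaluationConfig:
    n_partitions: int = 20
    test_fraction: float = 0.2
    seed: int = 0
    expert: ExpertConfig = field(default_factory=ExpertConfig)


def stratified_split(labels: np.ndarray, test_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving the label ratio within one example."""
    y = np.asarray(labels).astype(int)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _fit_and_score(dataset: LabeledDataset, train_idx: np.ndarray,
                   test_idx: np.ndarray, cfg: ExpertConfig) -> float:
    """Fit transforms and ensemble on the train rows only; AUROC on test."""
    train_regions = [dataset.regions[i] for i in train_idx]
    test_regions = [dataset.regions[i] for i in test_idx]
    y = dataset.labels
    pcas = fit_feature_transforms(train_regions, dataset.tracks)
    train_X = assemble_features(train_regions, dataset.tracks, dataset.peaks,
                                dataset.ann, pcas)
    test_X = assemble_features(test_regions, dataset.tracks, dataset.peaks,
                               dataset.ann, pcas)
    ensemble = train_expert(train_X, y[train_idx], cfg, pcas,
                            dataset.dataset_id, dataset.cell_type)
    return auroc(predict_expert(ensemble, test_X), y[test_idx])


def evaluate_within_dataset(dataset: LabeledDataset,
                            cfg: EvaluationConfig | None = None) -> EvaluationResult:
    """Stratified 4:1 train/test evaluation, repeated over random
    partitions; transforms and ensemble are refitted per partition.  A
    partition whose test side is single-class is redrawn."""
    cfg = cfg or EvaluationConfig()
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("dataset has a single class")
    rng = np.random.default_rng(cfg.seed)
    result = EvaluationResult(dataset.dataset_id, "within_dataset")
    drawn = 0
    while len(result.aurocs) < cfg.n_partitions:
        drawn += 1
        if drawn > 10 * cfg.n_partitions:
            raise RuntimeError("too many single-class partitions redrawn")
        train_idx, test_idx = stratified_split(y, cfg.test_fraction, rng)
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            continue
        member_cfg = ExpertConfig(**{**cfg.expert.__dict__,
                                     "seed": int(rng.integers(2**31))})
        result.aurocs.append(_fit_and_score(dataset, train_idx, test_idx,
                                            member_cfg))
    return result


# ---------------------------------------------------------------------------
# spatial partitioning and cell-type holdout


@dataclass
class SpatialPartition:
    """Genome divided into fixed-size chunks, each assigned train or test."""

    assembly: GenomeAssembly
    chunk_bp: int
    test_chunks: dict[str, np.ndarray]  # boolean per chunk

    def is_test(self, chrom: str, position: int) -> bool:
        return bool(self.test_chunks[chrom][position // self.chunk_bp])


def spatial_partition(assembly: GenomeAssembly, chunk_bp: int = 5000,
                      p_test: float = 0.25,
                      rng: np.random.Generator | None = None) -> SpatialPartition:
    """Assign each ``chunk_bp`` chunk independently to test with
    probability ``p_test``; loci inherit their chunk's assignment."""
    rng = np.random.default_rng() if rng is None else rng
    chunks = {}
    for chrom, length in assembly.chromosomes:
        n = -(-length // chunk_bp)
        chunks[chrom] = rng.random(n) < p_test
    return SpatialPartition(assembly, chunk_bp, chunks)


def evaluate_cell_type_holdout(datasets: list[LabeledDataset],
                               held_out_cell_type: str,
                               cfg: EvaluationConfig | None = None
                               ) -> dict[str, EvaluationResult]:
    """Score a held-out cell type's datasets with experts trained elsewhere.

    For each repetition the genome is spatially partitioned into 5 kb
    chunks (3:1 train:test).  Experts are trained on the train-chunk loci
    of every dataset from the *other* cell types, then applied — through
    the held-out cell type's chromatin tracks — to the test-chunk loci of
    each held-out dataset; the combined score is the mean over experts.
    """
    cfg = cfg or EvaluationConfig()
    held = [d for d in datasets if d.cell_type == held_out_cell_type]
    train_sets = [d for d in datasets if d.cell_type != held_out_cell_type]
    if not held:
        raise ValueError(f"no datasets in held-out cell type {held_out_cell_type!r}")
    if not train_sets:
        raise ValueError("no training datasets outside the held-out cell type")
    rng = np.random.default_rng(cfg.seed)
    results = {d.dataset_id: EvaluationResult(d.dataset_id, "cell_type_holdout")
               for d in held}
    for _rep in range(cfg.n_partitions):
        part = spatial_partition(held[0].tracks[0].assembly, rng=rng)
        ensembles = []
        for ds in train_sets:
            idx = np.array([
                i for i, r in enumerate(ds.regions)
                if not part.is_test(r.chrom, r.ref_nucleotide)
            ])
            y = ds.labels[idx]
            if len(np.unique(y)) < 2:
                continue
            regions = [ds.regions[i] for i in idx]
            pcas = fit_feature_transforms(regions, ds.tracks)
            X = assemble_features(regions, ds.tracks, ds.peaks, ds.ann, pcas)
            member_cfg = ExpertConfig(**{**cfg.expert.__dict__,
                                         "seed": int(rng.integers(2**31))})
            ensembles.append((
                train_expert(X, y, member_cfg, pcas, ds.dataset_id, ds.cell_type),
                pcas,
            ))
        if not ensembles:
            raise RuntimeError("no surviving training experts in repetition")
        for ds in held:
            idx = np.array([
                i for i, r in enumerate(ds.regions)
                if part.is_test(r.chrom, r.ref_nucleotide)
            ])
            if idx.size == 0 or len(np.unique(ds.labels[idx])) < 2:
                continue
            regions = [ds.regions[i] for i in idx]
            scores = np.zeros(idx.size)
            for ensemble, pcas in ensembles:
                X = assemble_features(regions, ds.tracks, ds.peaks, ds.ann, pcas)
                scores += predict_expert(ensemble, X)
            scores /= len(ensembles)
            results[ds.dataset_id].aurocs.append(auroc(scores, ds.labels[idx]))
    return results


# ---------------------------------------------------------------------------
# baselines


@dataclass
class ChromatinStateBaseline:
    """Maps a chromatin state to the training fraction of positive labels."""

    state_scores: np.ndarray  # length K, 1-indexed states at [k-1]
    global_fraction: float

    def score(self, ann: StateAnnotation, chrom: str, position: int) -> float:
        return float(self.state_scores[ann.state_at(chrom, position) - 1])


def chromatin_state_baseline(train_regions: list[LabeledRegion],
                             train_labels: np.ndarray,
                             ann: StateAnnotation) -> ChromatinStateBaseline:
    """Per-state positive-label fraction on the training partition; states
    unseen in training fall back to the global positive fraction."""
    y = np.asarray(train_labels).astype(int)
    global_frac = float(y.mean()) if y.size else 0.0
    totals = np.zeros(ann.K)
    positives = np.zeros(ann.K)
    for r, label in zip(train_regions, y):
        k = ann.state_at(r.chrom, r.ref_nucleotide)
        totals[k - 1] += 1
        positives[k - 1] += label
    with np.errstate(invalid="ignore"):
        scores = np.where(totals > 0, positives / np.maximum(totals, 1),
                          global_frac)
    return ChromatinStateBaseline(scores, global_frac)


def single_mark_baseline(track: SignalTrack,
                         regions: list[LabeledRegion]) -> np.ndarray:
    """Raw signal value at each reference nucleotide, used directly as a
    score with no fitting."""
    return np.array([track.value_at(r.chrom, r.ref_nucleotide) for r in regions])
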