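"""Chromatin feature extraction around reference nucleotides.

Per mark, the signal within a 2 kb window is sampled every 25 bp (81
values), reduced to its top three principal components, and joined by the
raw signal value at the reference nucleotide and a binary peak indicator.
A one-hot chromatin-state encoding completes the vector, for ``5*M + K``
columns: 85 with the standard 12 marks and a 25-state annotation.  All
transforms (PCA, standardization) are fit on training rows only and
applied unchanged to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chromactivity.core_io import IntervalSet, SignalTrack, StateAnnotation
from chromactivity.labeling import LabeledRegion

WINDOW_BP = 2000
STEP_BP = 25
#: Window samples per mark: offsets -1000, -975, ..., 0, ..., +1000.
N_WINDOW_FEATURES = WINDOW_BP // STEP_BP + 1
N_PCS = 3


def extract_signal_window(track: SignalTrack, chrom: str, ref_nucleotide: int,
                          window_bp: int = WINDOW_BP,
                          step_bp: int = STEP_BP) -> np.ndarray:
    """Signal values at ``step_bp`` offsets across a window centered on the
    reference nucleotide; offsets off the chromosome read as 0."""
    half = window_bp // 2
    offsets = np.arange(-half, half + 1, step_bp)
    vec = track.data[chrom]
    positions = ref_nucleotide + offsets
    bins = positions // STEP_BP
    valid = (positions >= 0) & (bins < vec.shape[0])
    out = np.zeros(offsets.shape[0])
    out[valid] = vec[bins[valid]]
    return out


@dataclass
class MarkPCA:
    """Top-3 principal components of one mark's 81 window features."""

    mark_name: str
    mean_vector: np.ndarray
    loadings: np.ndarray  # (3, n_window_features), rows orthonormal
    explained_variance_fraction: np.ndarray
    rank_deficient: bool = False

    def transform(self, window: np.ndarray) -> np.ndarray:
        """Project a (mean-centered) window onto the three loadings."""
        return (np.atleast_2d(window) - self.mean_vector) @ self.loadings.T


def fit_mark_pca(window_matrix: np.ndarray, mark_name: str = "") -> MarkPCA:
    """Fit a centered (unscaled) PCA and keep the top three components.

    The sign of each loading is fixed by making its largest-magnitude entry
    positive, so results are reproducible across linear-algebra backends.
    If the data have rank < 3 the missing components are zero-padded and
    the model flagged rank-deficient.
    """
    X = np.asarray(window_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need at least 4 rows to fit the window PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered matrix == eigendecomposition of the covariance.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    n_keep = min(N_PCS, rank)
    loadings = np.zeros((N_PCS, X.shape[1]))
    explained = np.zeros(N_PCS)
    for i in range(n_keep):
        v = vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        loadings[i] = v
        explained[i] = var[i] / total if total > 0 else 0.0
    return MarkPCA(mark_name, mean, loadings, explained,
                   rank_deficient=n_keep < N_PCS)


def apply_mark_pca(pca: MarkPCA, window: np.ndarray) -> np.ndarray:
    return pca.transform(window).ravel() if np.asarray(window).ndim == 1 \
        else pca.transform(window)


def peak_indicator(peaks: IntervalSet, chrom: str, ref_nucleotide: int) -> int:
    """1 iff some peak interval contains the reference nucleotide."""
    return int(peaks.contains(chrom, ref_nucleotide))


def state_onehot(ann: StateAnnotation, chrom: str, ref_nucleotide: int) -> np.ndarray:
    vec = np.zeros(ann.K)
    vec[ann.state_at(chrom, ref_nucleotide) - 1] = 1.0
    return vec


@dataclass
class Standardizer:
    """Per-feature centering/scaling fitted on a training matrix.

    Zero-variance features are flagged and mapped to all-zeros rather than
    dividing by zero.
    """

    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    zero_variance: np.ndarray  # boolean mask

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        Z[:, self.zero_variance] = 0.0
        return Z


def fit_standardizer(X: np.ndarray, feature_names: list[str] | None = None) -> Standardizer:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    zero_var = std < 1e-12
    scale = np.where(zero_var, 1.0, std)
    return Standardizer(mean, scale, list(feature_names), zero_var)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    return s.transform(X)


@dataclass
class FeatureMatrix:
    """Region-by-feature matrix with a frozen column order.

    Columns run per-mark PC1..PC3, then per-mark center signal, then
    per-mark peak indicator, then the state one-hot block.
    """

    values: np.ndarray
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def feature_names(mark_names: list[str], K: int) -> list[str]:
    names = [f"{m}_pc{i + 1}" for m in mark_names for i in range(N_PCS)]
    names += [f"{m}_signal" for m in mark_names]
    names += [f"{m}_peak" for m in mark_names]
    names += [f"state_{k + 1}" for k in range(K)]
    return names


def extract_window_matrix(regions: list[LabeledRegion],
                          track: SignalTrack) -> np.ndarray:
    """N x 81 window matrix for one mark over a list of regions."""
    return np.stack([
        extract_signal_window(track, r.chrom, r.ref_nucleotide) for r in regions
    ])


def assemble_features(regions: list[LabeledRegion],
                      tracks: list[SignalTrack],
                      peaks: list[IntervalSet],
                      ann: StateAnnotation,
                      pcas: list[MarkPCA]) -> FeatureMatrix:
    """Assemble the full feature matrix in the frozen column order.

    ``pcas`` must have been fitted on the training partition of the same
    region universe; this function never refits anything.
    """
    if not len(tracks) == len(peaks) == len(pcas):
        raise ValueError(
            f"mark count mismatch: {len(tracks)} tracks, {len(peaks)} peak "
            f"sets, {len(pcas)} PCA models"
        )
    n, m = len(regions), len(tracks)
    pc_block = np.zeros((n, N_PCS * m))
    signal_block = np.zeros((n, m))
    peak_block = np.zeros((n, m))
    for j, (track, peakset, pca) in enumerate(zip(tracks, peaks, pcas)):
        windows = extract_window_matrix(regions, track)
        pc_block[:, N_PCS * j : N_PCS * (j + 1)] = pca.transform(windows)
        for i, r in enumerate(regions):
            signal_block[i, j] = track.value_at(r.chrom, r.ref_nucleotide)
            peak_block[i, j] = peak_indicator(peakset, r.chrom, r.ref_nucleotide)
    state_block = np.stack([
        state_onehot(ann, r.chrom, r.ref_nucleotide) for r in regions
    ]) if n else np.zeros((0, ann.K))
    values = np.hstack([pc_block, signal_block, peak_block, state_block])
    marks = [t.mark_name or f"mark{j + 1}" for j, t in enumerate(tracks)]
    return FeatureMatrix(values, feature_names(marks, ann.K))


def fit_feature_transforms(train_regions: list[LabeledRegion],
                           tracks: list[SignalTrack]) -> list[MarkPCA]:
    """Fit one window PCA per mark on the training regions."""
    return [
        fit_mark_pca(extract_window_matrix(train_regions, t),
                     t.mark_name or f"mark{j + 1}")
        for j, t in enumerate(tracks)
    ]
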