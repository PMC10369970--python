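"""ChromScoreHMM: binarized expert tracks and a Bernoulli-emission HMM.

Expert score tracks are binarized so the top 2% of 25 bp bins per track are
1 and the rest 0.  A K-state hidden Markov model with multivariate
independent-Bernoulli emissions — one emission parameter per (state,
expert) — is learned by Baum-Welch over the concatenated (cell type,
chromosome) sequences, all sharing one parameter set.  Decoding assigns
each bin its maximum-posterior state, and states are renumbered in
decreasing order of mean emission probability.  Each state's emission row
classifies it as a multi-expert, single-expert or no-expert state.

The forward-backward recursions use per-position scaling, so likelihoods
are returned in the log domain and remain finite for long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chromactivity.core_io import GenomeAssembly, SignalTrack, StateAnnotation

EMISSION_CLAMP = 1e-6

#: Emission-probability cutoffs for the state grouping rules.
MULTI_EXPERT_MIN = 0.20
SINGLE_EXPERT_MIN = 0.90
SINGLE_EXPERT_OTHER_MAX = 0.10
NO_EXPERT_MAX = 0.001


# ---------------------------------------------------------------------------
# binarization


@dataclass
class BinaryCalls:
    """Top-fraction binary calls: per cell type and chromosome, a T x M
    0/1 matrix with one column per expert."""

    expert_ids: list[str]
    data: dict[str, dict[str, np.ndarray]]  # cell_type -> chrom -> T x M
    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)

    def sequences(self) -> list[np.ndarray]:
        """All (cell type, chromosome) observation matrices, in a stable
        order for concatenated HMM training."""
        return [
            self.data[ct][chrom]
            for ct in sorted(self.data)
            for chrom in self.data[ct]
        ]


def binarize_tracks(tracks_by_cell: dict[str, list[SignalTrack]],
                    top_fraction: float = 0.02) -> BinaryCalls:
    """Binarize score tracks at the top-``top_fraction`` threshold.

    Per expert and cell type the threshold is the score of the
    ``ceil(f*N)``-th highest bin genomewide; bins scoring at or above it
    are 1.  Ties at the threshold are all included, so the ones-fraction
    can exceed ``top_fraction`` on tied tracks.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    cell_types = sorted(tracks_by_cell)
    expert_ids = [t.mark_name for t in tracks_by_cell[cell_types[0]]]
    data: dict[str, dict[str, np.ndarray]] = {}
    thresholds = {}
    for ct in cell_types:
        tracks = tracks_by_cell[ct]
        if [t.mark_name for t in tracks] != expert_ids:
            raise ValueError(f"cell type {ct}: expert set/order mismatch")
        assembly = tracks[0].assembly
        binarized_cols = []
        for track in tracks:
            allv = track.concatenated()
            k = int(np.ceil(top_fraction * allv.size))
            threshold = np.sort(allv)[::-1][k - 1]
            if np.all(allv == allv[0]):
                # Degenerate constant track: no meaningful top fraction.
                threshold = np.inf
            thresholds[(ct, track.mark_name)] = float(threshold)
            binarized_cols.append({
                chrom: (track.data[chrom] >= threshold).astype(np.uint8)
                for chrom in assembly.names
            })
        data[ct] = {
            chrom: np.stack([col[chrom] for col in binarized_cols], axis=1)
            for chrom in assembly.names
        }
    return BinaryCalls(expert_ids, data, thresholds)


# ---------------------------------------------------------------------------
# model


@dataclass
class HMMModel:
    """K-state HMM with independent Bernoulli emissions over M tracks."""

    pi: np.ndarray  # (K,)
    A: np.ndarray   # (K, K), rows stochastic
    E: np.ndarray   # (K, M), Bernoulli parameters
    expert_ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.E.shape[1]

    def validate(self) -> None:
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution does not sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows do not sum to 1")
        if np.any((self.E < 0) | (self.E > 1)):
            raise ValueError("emission parameters outside [0, 1]")


def init_hmm(K: int, M: int, seed: int = 0) -> HMMModel:
    """Random valid model: Dirichlet-ish stochastic pi/A, emissions drawn
    uniformly in (0.05, 0.95)."""
    if K < 2 or M < 1:
        raise ValueError("need K >= 2 states and M >= 1 tracks")
    rng = np.random.default_rng(seed)
    pi = rng.random(K) + 0.1
    pi /= pi.sum()
    A = rng.random((K, K)) + 0.1
    A /= A.sum(axis=1, keepdims=True)
    E = rng.uniform(0.05, 0.95, size=(K, M))
    return HMMModel(pi, A, E)


def _emission_probs(model: HMMModel, seq: np.ndarray) -> np.ndarray:
    """B[t, k] = prod_m E[k,m]^o_tm (1-E[k,m])^(1-o_tm), via logs."""
    O = np.asarray(seq, dtype=float)
    E = np.clip(model.E, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
    logB = O @ np.log(E).T + (1.0 - O) @ np.log1p(-E).T
    return np.exp(logB)


def forward_backward(model: HMMModel, seq: np.ndarray
                     ) -> tuple[np.ndarray, float]:
    """Scaled forward-backward pass.

    Returns per-position state posteriors (rows summing to 1) and the log
    likelihood of the observation sequence under the model.
    """
    gamma, _, loglik = _forward_backward_full(model, seq)
    return gamma, loglik


def _forward_backward_full(model: HMMModel, seq: np.ndarray):
    B = _emission_probs(model, seq)
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    alpha[0] = model.pi * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ model.A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (model.A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # Expected transition counts for Baum-Welch reestimation:
    # sum_t xi_t = A  *  sum_t outer(alpha_t, B_{t+1} beta_{t+1} / c_{t+1}).
    if T > 1:
        weighted = (B[1:] * beta[1:]) / c[1:, None]
        xi_sum = model.A * (alpha[:-1].T @ weighted)
    else:
        xi_sum = np.zeros((K, K))
    return gamma, xi_sum, float(np.log(c).sum())


@dataclass
class BaumWelchConfig:
    """Training options.

    With ``batch_size=None`` every sequence enters every iteration and the
    total log-likelihood is non-decreasing (standard EM guarantee).  With a
    finite batch size, a random subset of sequences is used per iteration
    (faithful to training on random cell-type/chromosome subsets) and
    monotonicity no longer holds.  There is no likelihood-change stopping
    rule; training always runs ``max_iter`` iterations.
    """

    max_iter: int = 200
    batch_size: int | None = None
    seed: int = 0


def baum_welch(model: HMMModel, sequences: list[np.ndarray],
               cfg: BaumWelchConfig | None = None
               ) -> tuple[HMMModel, list[float]]:
    """Concatenated Baum-Welch: all sequences share one parameter set.

    Returns the trained model and the per-iteration total log-likelihood
    history (computed on the sequences entering each iteration, before the
    update).
    """
    cfg = cfg or BaumWelchConfig()
    if not sequences:
        raise ValueError("no training sequences")
    model.validate()
    rng = np.random.default_rng(cfg.seed)
    pi, A, E = model.pi.copy(), model.A.copy(), model.E.copy()
    K, M = model.K, model.M
    history = []
    for _it in range(cfg.max_iter):
        if cfg.batch_size is not None and cfg.batch_size < len(sequences):
            idx = rng.choice(len(sequences), size=cfg.batch_size, replace=False)
            batch = [sequences[i] for i in idx]
        else:
            batch = sequences
        cur = HMMModel(pi, A, E, model.expert_ids)
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gamma_trans_acc = np.zeros(K)  # sum of gamma over t < T-1
        gamma_acc = np.zeros(K)
        emit_acc = np.zeros((K, M))
        total_ll = 0.0
        for seq in batch:
            gamma, xi_sum, ll = _forward_backward_full(cur, seq)
            total_ll += ll
            pi_acc += gamma[0]
            xi_acc += xi_sum
            gamma_trans_acc += gamma[:-1].sum(axis=0)
            gamma_acc += gamma.sum(axis=0)
            emit_acc += gamma.T @ np.asarray(seq, dtype=float)
        history.append(total_ll)
        pi = pi_acc / pi_acc.sum()
        A = xi_acc / np.maximum(gamma_trans_acc[:, None], 1e-300)
        A /= A.sum(axis=1, keepdims=True)
        E = emit_acc / np.maximum(gamma_acc[:, None], 1e-300)
        E = np.clip(E, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
    return HMMModel(pi, A, E, model.expert_ids), history


def decode(model: HMMModel, seq: np.ndarray) -> np.ndarray:
    """Per-bin maximum-posterior state (1-indexed; ties take the lowest
    state index).  This mirrors posterior decoding rather than Viterbi:
    each bin is assigned independently from its marginal posterior."""
    gamma, _ = forward_backward(model, seq)
    return np.argmax(gamma, axis=1).astype(np.int32) + 1


def segment_genome(model: HMMModel, calls: BinaryCalls,
                   assembly: GenomeAssembly) -> dict[str, StateAnnotation]:
    """Decode every cell type's binarized tracks into a segmentation."""
    out = {}
    for ct, per_chrom in calls.data.items():
        data = {chrom: decode(model, seq) for chrom, seq in per_chrom.items()}
        out[ct] = StateAnnotation(assembly, data, model.K)
    return out


# ---------------------------------------------------------------------------
# state ordering and grouping


def order_states(model: HMMModel) -> HMMModel:
    """Renumber states in decreasing order of mean emission probability.

    The permutation is applied consistently to pi, A (rows and columns)
    and E, so sequence likelihoods are unchanged.  Equal means keep their
    original relative order (stable sort).
    """
    means = model.E.mean(axis=1)
    order = np.argsort(-means, kind="stable")
    return HMMModel(model.pi[order], model.A[np.ix_(order, order)],
                    model.E[order], model.expert_ids)


def classify_states(model: HMMModel) -> list[str]:
    """Group each state by its emission row.

    multi_expert: at least two experts with emission >= 0.20.
    single_expert: exactly one expert >= 0.90 and every other < 0.10.
    no_expert: all emissions < 0.001.
    Anything else is "unclassified".
    """
    groups = []
    for row in model.E:
        high = row >= MULTI_EXPERT_MIN
        if np.all(row < NO_EXPERT_MAX):
            groups.append("no_expert")
        elif (np.sum(row >= SINGLE_EXPERT_MIN) == 1
              and np.sum(row >= SINGLE_EXPERT_OTHER_MAX) == 1):
            groups.append("single_expert")
        elif high.sum() >= 2:
            groups.append("multi_expert")
        else:
            groups.append("unclassified")
    return groups


# ---------------------------------------------------------------------------
# text I/O


def write_binarized(calls: BinaryCalls, directory) -> None:
    """Emit binary calls in the binarized text layout: one file per
    (cell type, chromosome) with a two-line header and tab-separated
    expert columns."""
    import os

    os.makedirs(directory, exist_ok=True)
    for ct in sorted(calls.data):
        for chrom, mat in calls.data[ct].items():
            path = os.path.join(directory, f"{ct}_{chrom}_binary.txt")
            with open(path, "w") as fh:
                fh.write(f"{ct}\t{chrom}\n")
                fh.write("\t".join(calls.expert_ids) + "\n")
                np.savetxt(fh, mat, fmt="%d", delimiter="\t")


def write_model(model: HMMModel, path) -> None:
    """Serialize a model as TSV blocks (pi, A, E)."""
    with open(path, "w") as fh:
        fh.write("# initial\n")
        fh.write("\t".join(repr(float(x)) for x in model.pi) + "\n")
        fh.write("# transitions\n")
        for row in model.A:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
        fh.write("# emissions\t" + "\t".join(model.expert_ids) + "\n")
        for row in model.E:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_model(path) -> HMMModel:
    pi_rows, a_rows, e_rows = [], [], []
    expert_ids: list[str] = []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# initial"):
                section = "pi"
            elif line.startswith("# transitions"):
                section = "A"
            elif line.startswith("# emissions"):
                section = "E"
                expert_ids = [x for x in line.split("\t")[1:] if x]
            elif line:
                row = [float(x) for x in line.split("\t")]
                {"pi": pi_rows, "A": a_rows, "E": e_rows}[section].append(row)
    return HMMModel(np.array(pi_rows[0]), np.array(a_rows), np.array(e_rows),
                    expert_ids)
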