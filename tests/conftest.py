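import itertools

import numpy as np
import pytest

from chromactivity.core_io import GenomeAssembly
from chromactivity.fixtures import WorldConfig, make_world


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world shared by the slower integration tests."""
    cfg = WorldConfig(n_chroms=1, chrom_length=300_000, n_elements=30,
                      n_cell_types=2, seed=7)
    return make_world(cfg)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_auroc(scores, labels) -> float:
    """All-pairs counting AUROC: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def enumerate_log_likelihood(model, seq) -> float:
    """Exact HMM likelihood by summing over every hidden state path."""
    seq = np.asarray(seq)
    T, K = seq.shape[0], model.K
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t in range(T):
            for m in range(model.M):
                e = model.E[path[t], m]
                p *= e if seq[t, m] else (1 - e)
        total += p
    return float(np.log(total))


def enumerate_posteriors(model, seq) -> np.ndarray:
    """Exact per-position state posteriors by path enumeration."""
    seq = np.asarray(seq)
    T, K = seq.shape[0], model.K
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t in range(T):
            for m in range(model.M):
                e = model.E[path[t], m]
                p *= e if seq[t, m] else (1 - e)
        for t in range(T):
            post[t, path[t]] += p
    return post / post.sum(axis=1, keepdims=True)


def best_state_permutation(E_true, E_est):
    """Permutation of estimated states minimizing max emission error."""
    K = E_true.shape[0]
    best, best_err = None, np.inf
    for perm in itertools.permutations(range(K)):
        err = np.abs(E_est[list(perm)] - E_true).max()
        if err < best_err:
            best, best_err = list(perm), err
    return best
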