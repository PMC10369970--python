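"""Genomewide expert score tracks, ChromScore and quantile normalization.

Each expert scores the genome at 25 bp resolution by extracting features at
every bin's center nucleotide (the 13th base).  ChromScore is the per-bin
mean of the expert tracks.  For analyses that compare expert distributions
directly, each expert's scores are quantile-normalized onto a shared
reference built from the per-rank median across experts at a large random
sample of genomic locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chromactivity.core_io import (
    GenomeAssembly,
    IntervalSet,
    SignalTrack,
    StateAnnotation,
)
from chromactivity.experts import ExpertEnsemble, predict_expert
from chromactivity.features import assemble_features
from chromactivity.labeling import LabeledRegion

#: A score track is a SignalTrack whose values live in [0, 1].
ScoreTrack = SignalTrack


def score_genome(ensemble: ExpertEnsemble, tracks: list[SignalTrack],
                 peaks: list[IntervalSet], ann: StateAnnotation,
                 batch_bins: int = 20000) -> ScoreTrack:
    """Score every 25 bp bin of the assembly with one expert.

    Features are extracted at each bin's center nucleotide ``25*i + 12``
    using the ensemble's own PCA transforms, then passed through its
    standardizer and members.
    """
    if not ensemble.pcas:
        raise ValueError("ensemble carries no window PCA transforms")
    assembly = tracks[0].assembly
    data = {}
    for chrom in assembly.names:
        n = assembly.n_bins(chrom)
        out = np.empty(n)
        for lo in range(0, n, batch_bins):
            hi = min(lo + batch_bins, n)
            regions = [
                LabeledRegion(chrom, GenomeAssembly.bin_center(i), "neutral")
                for i in range(lo, hi)
            ]
            X = assemble_features(regions, tracks, peaks, ann, ensemble.pcas)
            out[lo:hi] = predict_expert(ensemble, X)
        data[chrom] = out
    return ScoreTrack(assembly, data, mark_name=ensemble.dataset_id,
                      cell_type=ensemble.cell_type)


def chromscore(expert_tracks: list[ScoreTrack]) -> ScoreTrack:
    """Per-bin arithmetic mean of the expert score tracks."""
    if not expert_tracks:
        raise ValueError("need at least one expert track")
    assembly = expert_tracks[0].assembly
    data = {}
    for chrom in assembly.names:
        vecs = [t.data[chrom] for t in expert_tracks]
        if len({v.shape for v in vecs}) != 1:
            raise ValueError(f"{chrom}: track length mismatch")
        data[chrom] = np.mean(vecs, axis=0)
    return ScoreTrack(assembly, data, mark_name="chromscore",
                      cell_type=expert_tracks[0].cell_type)


# ---------------------------------------------------------------------------
# quantile normalization


@dataclass
class NormalizationMap:
    """Mapping from each expert's score quantile bins to reference medians.

    ``boundaries[e]`` holds the lower edges of the 1000 equal-mass quantile
    bins of expert ``e``'s sampled score distribution; ``reference[e]``
    holds the cross-expert per-rank median score at each bin.
    """

    expert_ids: list[str]
    boundaries: dict[str, np.ndarray]
    reference: dict[str, np.ndarray]
    n_bins: int

    def normalize_values(self, expert_id: str, values: np.ndarray) -> np.ndarray:
        """Replace each value by its quantile bin's reference median."""
        edges = self.boundaries[expert_id]
        # searchsorted on the interior edges gives bin = #edges <= value,
        # clamped into [0, n_bins-1]; out-of-range values take edge bins.
        bins = np.searchsorted(edges[1:], np.asarray(values, dtype=float),
                               side="right")
        bins = np.clip(bins, 0, self.n_bins - 1)
        return self.reference[expert_id][bins]


def sample_positions(assembly: GenomeAssembly, n_sample: int,
                     excluded: IntervalSet | None,
                     rng: np.random.Generator) -> list[tuple[str, int]]:
    """Uniform random genomic positions outside the excluded regions."""
    lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    out: list[tuple[str, int]] = []
    for _ in range(1000):
        if len(out) >= n_sample:
            break
        need = n_sample - len(out)
        picks = rng.choice(len(weights), size=need, p=weights)
        offsets = rng.random(need)
        for j in range(need):
            chrom, clen = assembly.chromosomes[int(picks[j])]
            pos = int(offsets[j] * clen)
            if excluded is not None and excluded.contains(chrom, pos):
                continue
            out.append((chrom, pos))
    if len(out) < n_sample:
        raise RuntimeError("excluded regions too dense to sample positions")
    return out[:n_sample]


def build_normalization_map(expert_tracks: list[ScoreTrack],
                            n_sample: int = 100_000,
                            excluded: IntervalSet | None = None,
                            n_bins: int = 1000,
                            rng: np.random.Generator | None = None) -> NormalizationMap:
    """Build the shared quantile-normalization map from sampled scores.

    Scores for all experts are read at the same ``n_sample`` random
    positions; each expert's sorted sample defines its quantile bins, and
    the per-rank median across experts defines the reference distribution
    every expert is mapped onto.
    """
    if n_sample < n_bins:
        raise ValueError("n_sample must be at least n_bins")
    rng = np.random.default_rng() if rng is None else rng
    assembly = expert_tracks[0].assembly
    positions = sample_positions(assembly, n_sample, excluded, rng)
    sorted_scores = {}
    for track in expert_tracks:
        values = np.array([track.value_at(c, p) for c, p in positions])
        sorted_scores[track.mark_name] = np.sort(values)
    # Reference: median across experts at each rank.
    ranked = np.stack(list(sorted_scores.values()))
    reference_by_rank = np.median(ranked, axis=0)
    expert_ids = [t.mark_name for t in expert_tracks]
    boundaries, reference = {}, {}
    bin_of_rank = np.minimum(
        (np.arange(n_sample) * n_bins) // n_sample, n_bins - 1
    )
    for eid in expert_ids:
        srt = sorted_scores[eid]
        first_rank = np.searchsorted(bin_of_rank, np.arange(n_bins), side="left")
        boundaries[eid] = srt[np.minimum(first_rank, n_sample - 1)]
        # Reference value of a bin: median of the reference distribution
        # over the ranks falling in that bin.
        ref = np.empty(n_bins)
        for b in range(n_bins):
            lo = first_rank[b]
            hi = first_rank[b + 1] if b + 1 < n_bins else n_sample
            ref[b] = np.median(reference_by_rank[lo:hi])
        reference[eid] = ref
    return NormalizationMap(expert_ids, boundaries, reference, n_bins)


def normalize_track(track: ScoreTrack, nmap: NormalizationMap) -> ScoreTrack:
    """Map a track's values through its expert's quantile-bin reference."""
    if track.mark_name not in nmap.boundaries:
        raise KeyError(f"no normalization mapping for {track.mark_name!r}")
    data = {
        chrom: nmap.normalize_values(track.mark_name, vec)
        for chrom, vec in track.data.items()
    }
    return ScoreTrack(track.assembly, data, mark_name=track.mark_name,
                      cell_type=track.cell_type)
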