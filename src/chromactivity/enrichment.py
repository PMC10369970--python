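"""Enrichment and distribution analyses over score tracks and segmentations.

Overlap fold enrichments are computed in 25 bp bin units: an interval
overlaps a bin if it covers at least one of its bases, and
fold(state) = (fraction of the state's bins overlapping the annotation) /
(fraction of all genome bins overlapping it).  TSS-anchored profiles,
expression correlations, repeat-element score-quantile enrichments, track
correlation matrices and per-state score distributions follow the same
bin-grid conventions; all sampling is driven by an explicit generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chromactivity.core_io import (
    BIN_BP,
    GenomeAssembly,
    IntervalSet,
    SignalTrack,
    StateAnnotation,
)
from chromactivity.scoring import sample_positions


def overlap_fold_enrichment(ann: StateAnnotation,
                            annotation: IntervalSet) -> pd.DataFrame:
    """Per-state overlap fold enrichment of an annotation, in bin units.

    Returns a frame indexed by state with columns ``genome_fraction``
    (share of genome bins in the state), ``overlap_fraction`` (share of
    the state's bins overlapping the annotation) and ``fold``.  If the
    annotation covers zero bins the folds are missing (NaN), never 0.
    """
    masks = annotation.bin_mask(ann.assembly)
    states = ann.concatenated()
    overlap = np.concatenate([masks[c] for c in ann.assembly.names])
    n_total = states.size
    annot_fraction = overlap.mean() if n_total else 0.0
    rows = []
    for k in range(1, ann.K + 1):
        in_state = states == k
        n_state = int(in_state.sum())
        state_overlap = float(overlap[in_state].mean()) if n_state else np.nan
        if annot_fraction > 0 and n_state:
            fold = state_overlap / annot_fraction
        else:
            fold = np.nan
        rows.append({
            "state": k,
            "genome_fraction": n_state / n_total,
            "overlap_fraction": state_overlap,
            "fold": fold,
        })
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# TSS-anchored profiles


def _tss_offsets(window_bp: int, step_bp: int) -> np.ndarray:
    half = window_bp // 2
    return np.arange(-half, half + 1, step_bp)


def tss_profile(source: StateAnnotation | SignalTrack, tss: IntervalSet,
                window_bp: int = 24000, step_bp: int = 200) -> pd.DataFrame:
    """Positional profile around TSSs, strand-aware.

    For a segmentation, rows are offsets and columns states, holding the
    frequency of each state at that offset across genes.  For a score
    track, a single ``mean_score`` column holds the per-offset mean.  On
    negative-strand genes offsets are flipped so positive offsets always
    point into the gene body.  Window positions off a chromosome are
    excluded from the averages.
    """
    offsets = _tss_offsets(window_bp, step_bp)
    is_ann = isinstance(source, StateAnnotation)
    assembly = source.assembly
    if is_ann:
        counts = np.zeros((offsets.size, source.K))
    else:
        sums = np.zeros(offsets.size)
    valid = np.zeros(offsets.size)
    for site in tss:
        if site.strand not in ("+", "-"):
            raise ValueError(f"TSS at {site.chrom}:{site.start} lacks strand")
        signed = offsets if site.strand == "+" else -offsets
        positions = site.start + signed
        clen = assembly.length(site.chrom)
        ok = (positions >= 0) & (positions < clen)
        for i in np.flatnonzero(ok):
            if is_ann:
                counts[i, source.state_at(site.chrom, int(positions[i])) - 1] += 1
            else:
                sums[i] += source.value_at(site.chrom, int(positions[i]))
            valid[i] += 1
    if is_ann:
        with np.errstate(invalid="ignore"):
            freq = counts / valid[:, None]
        out = pd.DataFrame(freq, index=offsets,
                           columns=[f"state_{k + 1}" for k in range(source.K)])
    else:
        with np.errstate(invalid="ignore"):
            out = pd.DataFrame({"mean_score": sums / valid}, index=offsets)
    out.index.name = "offset"
    return out


def expression_correlation(tracks_by_cell: dict[str, SignalTrack],
                           tss: IntervalSet, expr: pd.DataFrame,
                           window_bp: int = 24000,
                           step_bp: int = BIN_BP) -> pd.Series:
    """Per-offset Pearson correlation between scores and log expression.

    ``tss`` intervals must carry gene names matching ``expr``'s index and
    strands; ``expr`` holds RPKM per cell type (columns matching
    ``tracks_by_cell``).  Correlations use log2(RPKM+1), are computed per
    cell type across genes at each offset (negative-strand windows
    mirrored), and are averaged over cell types.
    """
    offsets = _tss_offsets(window_bp, step_bp)
    sites = [s for s in tss if s.name is not None and s.name in expr.index]
    if len(sites) < 3:
        raise ValueError("need at least 3 genes with expression values")
    per_cell = []
    for ct, track in tracks_by_cell.items():
        logx = np.log2(expr.loc[[s.name for s in sites], ct].to_numpy(float) + 1)
        score_mat = np.full((len(sites), offsets.size), np.nan)
        for gi, site in enumerate(sites):
            signed = offsets if site.strand == "+" else -offsets
            positions = site.start + signed
            clen = track.assembly.length(site.chrom)
            ok = (positions >= 0) & (positions < clen)
            for i in np.flatnonzero(ok):
                score_mat[gi, i] = track.value_at(site.chrom, int(positions[i]))
        r = np.full(offsets.size, np.nan)
        for i in range(offsets.size):
            col = score_mat[:, i]
            use = ~np.isnan(col)
            if use.sum() < 3:
                continue
            x, y = col[use], logx[use]
            if x.std() == 0 or y.std() == 0:
                continue
            r[i] = np.corrcoef(x, y)[0, 1]
        per_cell.append(r)
    stacked = np.stack(per_cell)
    mean_r = np.full(offsets.size, np.nan)
    has_any = ~np.all(np.isnan(stacked), axis=0)
    mean_r[has_any] = np.nanmean(stacked[:, has_any], axis=0)
    return pd.Series(mean_r, index=pd.Index(offsets, name="offset"), name="r")


def categorize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Classify genes per cell type: ``high`` iff log2(RPKM+1) > 1,
    ``low`` iff log2(RPKM+1) < 0.01, else ``mid``."""
    logx = np.log2(expr + 1)
    out = pd.DataFrame("mid", index=expr.index, columns=expr.columns)
    out = out.mask(logx > 1, "high").mask(logx < 0.01, "low")
    return out


# ---------------------------------------------------------------------------
# score-quantile repeat enrichments


def repeat_quantile_enrichment(track: SignalTrack,
                               repeats: dict[str, IntervalSet],
                               n_quantiles: int = 200,
                               n_sample: int = 100_000,
                               rng: np.random.Generator | None = None,
                               excluded: IntervalSet | None = None) -> pd.DataFrame:
    """Fold enrichment of repeat classes across score quantiles.

    Random positions are scored and grouped into ``n_quantiles``
    equal-count score quantiles (by rank); for each repeat class,
    fold(q) = (overlap fraction within quantile q) / (overlap fraction
    over all sampled positions).  Classes with zero background overlap are
    reported missing.
    """
    if n_sample < n_quantiles:
        raise ValueError("n_sample must be at least n_quantiles")
    rng = np.random.default_rng() if rng is None else rng
    positions = sample_positions(track.assembly, n_sample, excluded, rng)
    scores = np.array([track.value_at(c, p) for c, p in positions])
    order = np.argsort(scores, kind="stable")
    quantile = np.empty(n_sample, dtype=int)
    quantile[order] = (np.arange(n_sample) * n_quantiles) // n_sample
    out = {}
    for cls, ivals in repeats.items():
        hit = np.array([ivals.contains(c, p) for c, p in positions])
        background = hit.mean()
        folds = np.full(n_quantiles, np.nan)
        if background > 0:
            for q in range(n_quantiles):
                inq = quantile == q
                if inq.any():
                    folds[q] = hit[inq].mean() / background
        out[cls] = folds
    frame = pd.DataFrame(out)
    frame.index.name = "quantile"
    return frame


# ---------------------------------------------------------------------------
# track correlations and distributions


def track_correlation_matrix(tracks: list[SignalTrack],
                             n_sample: int = 500_000,
                             excluded: IntervalSet | None = None,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations between tracks at one shared random
    position sample.  Constant tracks yield missing correlations."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    rng = np.random.default_rng() if rng is None else rng
    positions = sample_positions(tracks[0].assembly, n_sample, excluded, rng)
    names = [t.mark_name or f"track{i}" for i, t in enumerate(tracks)]
    values = np.stack([
        np.array([t.value_at(c, p) for c, p in positions]) for t in tracks
    ])
    stds = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    for i, s in enumerate(stds):
        if s == 0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
    np.fill_diagonal(corr, np.where(stds > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=names, columns=names)


def group_mean_correlations(corr: pd.DataFrame, groups: dict[str, str],
                            exclude_groups: tuple[str, ...] = ()) -> pd.DataFrame:
    """Mean correlation within and between named track groups, optionally
    dropping listed groups from the summary."""
    keep = [n for n in corr.index
            if groups.get(n) is not None and groups[n] not in exclude_groups]
    labels = sorted({groups[n] for n in keep})
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for ga in labels:
        for gb in labels:
            vals = [
                corr.loc[a, b]
                for a in keep if groups[a] == ga
                for b in keep if groups[b] == gb and a != b
            ]
            if vals:
                out.loc[ga, gb] = float(np.nanmean(vals))
    return out


def score_distribution_by_state(track: SignalTrack, ann: StateAnnotation,
                                n_sample: int = 100_000,
                                rng: np.random.Generator | None = None,
                                excluded: IntervalSet | None = None) -> pd.DataFrame:
    """Sampled per-state score summaries (n, mean, quartiles)."""
    rng = np.random.default_rng() if rng is None else rng
    positions = sample_positions(track.assembly, n_sample, excluded, rng)
    scores = np.array([track.value_at(c, p) for c, p in positions])
    states = np.array([ann.state_at(c, p) for c, p in positions])
    rows = []
    for k in range(1, ann.K + 1):
        vals = scores[states == k]
        if vals.size == 0:
            rows.append({"state": k, "n": 0, "mean": np.nan, "q25": np.nan,
                         "median": np.nan, "q75": np.nan})
        else:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append({"state": k, "n": vals.size, "mean": vals.mean(),
                         "q25": q25, "median": med, "q75": q75})
    return pd.DataFrame(rows).set_index("state")


def select_variable_loci(tracks_by_cell: dict[str, SignalTrack],
                         min_difference: float = 0.25,
                         n_loci: int = 20_000,
                         rng: np.random.Generator | None = None) -> list[tuple[str, int]]:
    """Uniformly sample loci whose score range across cell types is at
    least ``min_difference``.  Returns fewer than ``n_loci`` positions
    (possibly none, with a warning) when few loci qualify."""
    if len(tracks_by_cell) < 2:
        raise ValueError("need at least two cell types")
    rng = np.random.default_rng() if rng is None else rng
    tracks = list(tracks_by_cell.values())
    assembly = tracks[0].assembly
    qualifying: list[tuple[str, int]] = []
    for chrom in assembly.names:
        stacked = np.stack([t.data[chrom] for t in tracks])
        spread = stacked.max(axis=0) - stacked.min(axis=0)
        for b in np.flatnonzero(spread >= min_difference):
            qualifying.append((chrom, GenomeAssembly.bin_center(int(b))))
    if not qualifying:
        import warnings

        warnings.warn("no loci meet the cross-cell-type difference threshold")
        return []
    if len(qualifying) <= n_loci:
        return qualifying
    idx = rng.choice(len(qualifying), size=n_loci, replace=False)
    return [qualifying[i] for i in sorted(idx)]
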