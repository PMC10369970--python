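"""Harmonize functional-characterization readouts into binary labels.

Each supported assay family (densely tiled MPRA with per-5 bp activity
scores, construct-level MPRA p-values, STARR-seq peak calls, HiDRA driver
elements, CRISPRi element-gene screens) is converted into
:class:`LabeledRegion` records: a reference nucleotide, a binary
activating/neutral label and the source dataset.  Thresholds follow each
assay's convention and are strict or inclusive exactly as worded in the
per-dataset rules ("exceeding", "under", "above", "below").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromactivity.core_io import GenomeAssembly, Interval, IntervalSet

SHARPR_STEP_BP = 5


@dataclass(frozen=True)
class LabeledRegion:
    """A reference nucleotide with a binary activity label."""

    chrom: str
    ref_nucleotide: int
    label: str  # "activating" | "neutral"
    dataset_id: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("activating", "neutral"):
            raise ValueError(f"label must be activating/neutral, got {self.label!r}")
        if self.ref_nucleotide < 0:
            raise ValueError("negative reference nucleotide")


@dataclass(frozen=True)
class SharprRegion:
    """A tiled MPRA region with activity scores at 5 bp intervals."""

    chrom: str
    start: int
    end: int
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = (self.end - self.start) // SHARPR_STEP_BP
        if len(self.scores) != expected:
            raise ValueError(
                f"expected {expected} scores for a {self.end - self.start} bp "
                f"region at 5 bp steps, got {len(self.scores)}"
            )


@dataclass(frozen=True)
class ElementGeneRecord:
    """One tested element-gene pair from a CRISPRi screen."""

    chrom: str
    start: int
    end: int
    gene: str
    adjusted_p: float
    beta: float = float("nan")
    effect_change: float = float("nan")
    power_ok: bool = True
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError(f"adjusted_p {self.adjusted_p} outside [0, 1]")


@dataclass
class LabelRuleConfig:
    """Per-dataset labeling cutoffs.

    Defaults carry the standard rule set: MPRA tile scores call a region
    activating above 1 with a neutral band of [-1, 1]; peak-based assays
    keep the top 10% of peaks; three neutral background positions are drawn
    per activating region; p-value rules use alpha = 0.05.
    """

    activating_threshold: float = 1.0
    neutral_band: tuple[float, float] = (-1.0, 1.0)
    top_fraction: float = 0.10
    neutral_per_activating: int = 3
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.neutral_per_activating < 1:
            raise ValueError("neutral_per_activating must be >= 1")


def interval_center(start: int, end: int) -> int:
    """Center base of an interval; even lengths take ``start + length//2``."""
    return start + (end - start) // 2


# ---------------------------------------------------------------------------
# tiled-MPRA (per-5bp activity score) labeling


def sharpr_region_score(region: SharprRegion) -> tuple[float, int]:
    """Signed score at the position of maximum absolute activity.

    Returns ``(s_absmax, argmax_bin)`` where ``argmax_bin`` indexes the
    5 bp interval with maximal ``|score|`` (first occurrence on ties) and
    ``s_absmax`` is the signed score there.
    """
    if not region.scores:
        raise ValueError("empty score vector")
    scores = np.asarray(region.scores, dtype=float)
    argmax = int(np.argmax(np.abs(scores)))
    return float(scores[argmax]), argmax


def label_sharpr(regions: list[SharprRegion], cfg: LabelRuleConfig,
                 dataset_id: str = "", cell_type: str = "") -> list[LabeledRegion]:
    """Label tiled regions by their signed peak activity score.

    Scores above the activating threshold are activating; scores inside the
    neutral band (inclusive) are neutral; regions below the band — likely
    repressive — are dropped.  The reference nucleotide is the center base
    of the peak 5 bp interval.
    """
    lo, hi = cfg.neutral_band
    out = []
    for region in regions:
        s, argmax = sharpr_region_score(region)
        if s > cfg.activating_threshold:
            label = "activating"
        elif lo <= s <= hi:
            label = "neutral"
        else:  # below the band: repressive, excluded from training
            continue
        ref = region.start + SHARPR_STEP_BP * argmax + SHARPR_STEP_BP // 2
        out.append(LabeledRegion(region.chrom, ref, label, dataset_id, cell_type))
    return out


def sharpr_regions_from_table(table: pd.DataFrame) -> list[SharprRegion]:
    """Build :class:`SharprRegion` objects from a ``sharpr``-schema table."""
    regions = []
    for row in table.itertuples(index=False):
        scores = tuple(float(x) for x in str(row.scores).split(","))
        regions.append(SharprRegion(row.chrom, int(row.start), int(row.end), scores))
    return regions


# ---------------------------------------------------------------------------
# construct-level p-value labeling


def label_by_pvalue(records: pd.DataFrame, alpha: float = 0.05,
                    dataset_id: str = "", cell_type: str = "") -> list[LabeledRegion]:
    """Constructs with activity p-value strictly under ``alpha`` are
    activating; the rest are neutral.  The reference nucleotide is the
    construct center."""
    p = records["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    out = []
    for row, pv in zip(records.itertuples(index=False), p):
        label = "activating" if pv < alpha else "neutral"
        ref = interval_center(int(row.start), int(row.end))
        out.append(LabeledRegion(row.chrom, ref, label, dataset_id, cell_type))
    return out


# ---------------------------------------------------------------------------
# peak-based labeling (STARR-seq style)


def label_top_fraction(peaks: IntervalSet, fraction: float = 0.10,
                       dataset_id: str = "", cell_type: str = "") -> list[LabeledRegion]:
    """The top ``ceil(fraction * N)`` peaks by score become activating.

    Ties at the rank boundary are included (every peak scoring at least the
    cutoff), so membership is stable under reordering of equal scores.  The
    reference nucleotide is the peak center.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scored = [iv for iv in peaks if iv.score is not None]
    if not scored:
        return []
    scores = np.array([iv.score for iv in scored], dtype=float)
    k = int(np.ceil(fraction * len(scored)))
    cutoff = np.sort(scores)[::-1][k - 1]
    return [
        LabeledRegion(iv.chrom, iv.center, "activating", dataset_id, cell_type)
        for iv in scored
        if iv.score >= cutoff
    ]


def label_threshold_peaks(peaks: IntervalSet, threshold: float,
                          dataset_id: str = "", cell_type: str = "") -> list[LabeledRegion]:
    """Peaks scoring strictly above ``threshold`` become activating."""
    return [
        LabeledRegion(iv.chrom, iv.center, "activating", dataset_id, cell_type)
        for iv in peaks
        if iv.score is not None and iv.score > threshold
    ]


def sample_neutral_background(assembly: GenomeAssembly, excluded: IntervalSet,
                              n_activating: int, per_activating: int = 3,
                              rng: np.random.Generator | None = None,
                              restrict_to: IntervalSet | None = None,
                              dataset_id: str = "", cell_type: str = "",
                              max_attempts: int = 1000) -> list[LabeledRegion]:
    """Draw ``per_activating`` neutral background positions per activating
    region, uniformly over the genome (or over ``restrict_to`` intervals),
    rejecting positions inside ``excluded``.
    """
    if per_activating < 1:
        raise ValueError("per_activating must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_target = n_activating * per_activating
    if restrict_to is not None and len(restrict_to):
        ivals = list(restrict_to)
        lengths = np.array([iv.length for iv in ivals], dtype=float)
        weights = lengths / lengths.sum()
    else:
        ivals = None
        lengths = np.array(
            [length for _, length in assembly.chromosomes], dtype=float
        )
        weights = lengths / lengths.sum()
    out: list[LabeledRegion] = []
    for _ in range(max_attempts):
        if len(out) >= n_target:
            break
        # Draw a batch, reject excluded positions, repeat.
        need = n_target - len(out)
        picks = rng.choice(len(weights), size=need, p=weights)
        offsets = rng.random(need)
        for idx in range(need):
            if ivals is not None:
                iv = ivals[int(picks[idx])]
                chrom = iv.chrom
                pos = iv.start + int(offsets[idx] * iv.length)
            else:
                chrom, clen = assembly.chromosomes[int(picks[idx])]
                pos = int(offsets[idx] * clen)
            if excluded.contains(chrom, pos):
                continue
            out.append(LabeledRegion(chrom, pos, "neutral", dataset_id, cell_type))
    if len(out) < n_target:
        raise RuntimeError(
            f"could not draw {n_target} background positions in "
            f"{max_attempts} rounds; excluded set too dense"
        )
    return out[:n_target]


# ---------------------------------------------------------------------------
# CRISPRi element-gene labeling


def label_crispr_elements(records: list[ElementGeneRecord], alpha: float = 0.05,
                          mode: str = "gasperini", dataset_id: str = "",
                          cell_type: str = "") -> list[LabeledRegion]:
    """Label candidate elements from CRISPRi element-gene significance.

    ``gasperini`` mode keeps records with a negative expression regression
    coefficient (beta < 0) and no outlier flag; ``fulco`` mode keeps
    records with adequate detection power and a negative expression change.
    An element is activating iff at least one surviving record for it has
    adjusted p below ``alpha``.  In ``gasperini`` mode elements whose
    records are all filtered are labeled neutral (they were tested and not
    significant); in ``fulco`` mode such elements are dropped, since the
    surviving-pair universe defines the tested set.
    """
    if mode not in ("gasperini", "fulco"):
        raise ValueError(f"unknown mode {mode!r}")
    by_element: dict[tuple[str, int, int], list[ElementGeneRecord]] = {}
    surviving: dict[tuple[str, int, int], list[ElementGeneRecord]] = {}
    for rec in records:
        key = (rec.chrom, rec.start, rec.end)
        by_element.setdefault(key, []).append(rec)
        if mode == "gasperini":
            keep = (rec.beta < 0) and not rec.outlier_flag
        else:
            keep = rec.power_ok and (rec.effect_change < 0)
        if keep:
            surviving.setdefault(key, []).append(rec)
    out = []
    for key in by_element:
        survivors = surviving.get(key, [])
        if not survivors:
            if mode == "fulco":
                continue  # dropped: no usable pair for this element
            label = "neutral"
        elif any(rec.adjusted_p < alpha for rec in survivors):
            label = "activating"
        else:
            label = "neutral"
        chrom, start, end = key
        ref = interval_center(start, end)
        out.append(LabeledRegion(chrom, ref, label, dataset_id, cell_type))
    return out


def element_gene_records_from_table(table: pd.DataFrame,
                                    mode: str) -> list[ElementGeneRecord]:
    """Build element-gene records from a ``gasperini``/``fulco`` table."""
    records = []
    for row in table.itertuples(index=False):
        kw = dict(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            gene=str(row.gene), adjusted_p=float(row.adjusted_p),
        )
        if mode == "gasperini":
            kw["beta"] = float(row.beta)
            kw["outlier_flag"] = bool(row.outlier_gene)
        else:
            kw["power_ok"] = bool(row.power_ok)
            kw["effect_change"] = float(row.effect_change)
        records.append(ElementGeneRecord(**kw))
    return records


# ---------------------------------------------------------------------------
# output helpers


def labels_to_intervals(labels: list[LabeledRegion]) -> IntervalSet:
    """Represent labeled reference nucleotides as 1 bp BED intervals."""
    return IntervalSet(
        Interval(lr.chrom, lr.ref_nucleotide, lr.ref_nucleotide + 1, lr.label)
        for lr in labels
    )


def label_manifest(labels: list[LabeledRegion]) -> pd.DataFrame:
    """Per-dataset counts of activating and neutral regions."""
    rows = {}
    for lr in labels:
        key = (lr.dataset_id, lr.cell_type)
        counts = rows.setdefault(key, {"activating": 0, "neutral": 0})
        counts[lr.label] += 1
    return pd.DataFrame(
        [
            {"dataset_id": d, "cell_type": c, **counts}
            for (d, c), counts in sorted(rows.items())
        ]
    )
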