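"""Synthetic worlds with planted regulatory elements.

The generator builds a small genome, plants non-overlapping regulatory
elements with per-cell-type activity, and renders the chromatin inputs the
rest of the package consumes: per-mark 25 bp signal tracks where active
elements produce Gaussian-shaped bumps in the activating marks (repressed
elements in a designated repressive mark), peak calls over the bumps, and a
chromatin-state annotation driven by the locally dominant mark.  Assay
readout tables (tiled-MPRA score vectors, construct p-values, STARR-seq
peaks, RNA/DNA ratio elements, CRISPRi element-gene records) are rendered
as monotone functions of planted strength plus noise, in the exact schemas
the labelers expect, with the ground truth retained for every record.

What this emulates: the signal-to-activity relationship that the expert
models must learn, and the statistical shape of each assay's readout.
What it does not emulate: sequence content, read-level noise, or the
long-range correlation structure of real chromatin.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromactivity.core_io import (
    BIN_BP,
    GenomeAssembly,
    Interval,
    IntervalSet,
    SignalTrack,
    StateAnnotation,
    read_record_table,
)
from chromactivity.labeling import (
    LabeledRegion,
    LabelRuleConfig,
    element_gene_records_from_table,
    label_by_pvalue,
    label_crispr_elements,
    label_sharpr,
    label_threshold_peaks,
    label_top_fraction,
    sample_neutral_background,
    sharpr_regions_from_table,
)

def activating_marks(n_marks: int) -> tuple[int, ...]:
    """Indices of the marks that respond to active elements (up to three,
    always disjoint from the repressive mark)."""
    return tuple(range(min(3, max(n_marks - 1, 1))))


def repressive_mark(n_marks: int) -> int:
    """Index of the mark elevated at repressed elements (the last mark)."""
    return n_marks - 1
#: Gaussian bump width (standard deviation) in bp — roughly a quarter of
#: the 2 kb feature window, so windows see the whole bump.
BUMP_SIGMA_BP = 500
PEAK_HALFWIDTH_BP = 250

ASSAYS = ("sharpr", "pvalue", "starr_peaks", "hidra", "crispr")


@dataclass(frozen=True)
class PlantedElement:
    chrom: str
    center: int
    strength: float  # in (0, 1]
    active_in: tuple[bool, ...]  # per cell type
    repressed: bool = False


@dataclass
class WorldConfig:
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_elements: int = 200
    n_cell_types: int = 3
    n_marks: int = 12
    K_states: int = 25
    repressed_fraction: float = 0.15
    min_spacing_bp: int = 5000
    noise: float = 0.1  # background signal standard deviation
    seed: int = 0


@dataclass
class PlantedWorld:
    cfg: WorldConfig
    assembly: GenomeAssembly
    elements: list[PlantedElement]

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.cfg.n_cell_types)]

    def active_elements(self, cell_type: str) -> list[PlantedElement]:
        ct = self.cell_types.index(cell_type)
        return [e for e in self.elements
                if not e.repressed and e.active_in[ct]]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for e in self.elements:
            row = {"chrom": e.chrom, "center": e.center,
                   "strength": e.strength, "repressed": e.repressed}
            for i, ct in enumerate(self.cell_types):
                row[f"active_{ct}"] = e.active_in[i]
            rows.append(row)
        return pd.DataFrame(rows)


def make_world(cfg: WorldConfig | None = None) -> PlantedWorld:
    """Plant non-overlapping elements on a toy genome, deterministically.

    Elements keep at least ``min_spacing_bp`` between centers; each
    non-repressed element is active in a random non-empty subset of cell
    types with strength uniform in [0.5, 1].
    """
    cfg = cfg or WorldConfig()
    if cfg.chrom_length < 20_000:
        raise ValueError("chromosomes must be at least 10x the feature window")
    need = cfg.n_elements * cfg.min_spacing_bp
    usable = cfg.n_chroms * (cfg.chrom_length - 4000)
    if need > usable:
        raise ValueError("element density infeasible for this genome size")
    rng = np.random.default_rng(cfg.seed)
    assembly = GenomeAssembly(tuple(
        (f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chroms)
    ))
    per_chrom = np.array_split(np.arange(cfg.n_elements), cfg.n_chroms)
    elements: list[PlantedElement] = []
    for ci, idx in enumerate(per_chrom):
        n = len(idx)
        if n == 0:
            continue
        # Evenly spaced slots with random jitter keep spacing guaranteed.
        margin = 2000
        slots = np.linspace(margin, cfg.chrom_length - margin, n + 1)
        span = slots[1] - slots[0]
        jitter = rng.uniform(0, max(span - cfg.min_spacing_bp, 1), size=n)
        centers = (slots[:-1] + jitter).astype(int)
        for center in centers:
            repressed = rng.random() < cfg.repressed_fraction
            active = rng.random(cfg.n_cell_types) < 0.6
            if not active.any():
                active[rng.integers(cfg.n_cell_types)] = True
            elements.append(PlantedElement(
                chrom=f"chr{ci + 1}", center=int(center),
                strength=float(rng.uniform(0.5, 1.0)),
                active_in=tuple(bool(a) for a in active),
                repressed=repressed,
            ))
    return PlantedWorld(cfg, assembly, elements)


# ---------------------------------------------------------------------------
# chromatin rendering


def _cell_rng(world: PlantedWorld, cell_type: str, salt: int = 0) -> np.random.Generator:
    ct = world.cell_types.index(cell_type)
    return np.random.default_rng(
        np.random.SeedSequence([world.cfg.seed, ct, salt])
    )


def render_tracks(world: PlantedWorld, cell_type: str
                  ) -> tuple[list[SignalTrack], list[IntervalSet], StateAnnotation]:
    """Render one cell type's 12 signal tracks, peak calls and states.

    Active elements add a strength-scaled Gaussian bump to the activating
    marks; repressed elements do the same for the repressive mark.  Peaks
    are called around bump centers for the responsive marks.  The state
    annotation assigns state 1 near active elements, state 2 near
    repressed ones, and cycles the remaining states over background bins,
    so state identity alone carries a learnable activity signal.
    """
    cfg = world.cfg
    ct = world.cell_types.index(cell_type)
    rng = _cell_rng(world, cell_type, salt=1)
    sigma_bins = BUMP_SIGMA_BP / BIN_BP
    mark_names = [f"mark{m + 1}" for m in range(cfg.n_marks)]
    data = {
        m: {c: rng.normal(0.0, cfg.noise, world.assembly.n_bins(c)).clip(min=0)
            for c in world.assembly.names}
        for m in range(cfg.n_marks)
    }
    peak_lists: dict[int, list[Interval]] = {m: [] for m in range(cfg.n_marks)}
    for e in world.elements:
        responds = e.active_in[ct] and not e.repressed
        marks = activating_marks(cfg.n_marks) if responds else (
            (repressive_mark(cfg.n_marks),) if e.repressed else ()
        )
        if not marks:
            continue
        n_bins = world.assembly.n_bins(e.chrom)
        center_bin = e.center // BIN_BP
        lo = max(center_bin - 80, 0)
        hi = min(center_bin + 81, n_bins)
        span = np.arange(lo, hi)
        bump = e.strength * np.exp(-0.5 * ((span - center_bin) / sigma_bins) ** 2)
        for m in marks:
            data[m][e.chrom][lo:hi] += bump
            peak_lists[m].append(Interval(
                e.chrom, max(e.center - PEAK_HALFWIDTH_BP, 0),
                min(e.center + PEAK_HALFWIDTH_BP, cfg.chrom_length),
            ))
    tracks = [
        SignalTrack(world.assembly, data[m], mark_name=mark_names[m],
                    cell_type=cell_type)
        for m in range(cfg.n_marks)
    ]
    peaks = [IntervalSet(sorted(peak_lists[m], key=lambda iv: (iv.chrom, iv.start)))
             for m in range(cfg.n_marks)]
    # States: 1 = active-element neighborhood, 2 = repressed neighborhood,
    # 3..K cycle deterministically over the background.
    states = {}
    for chrom in world.assembly.names:
        n = world.assembly.n_bins(chrom)
        vec = 3 + (np.arange(n) // 40) % max(cfg.K_states - 2, 1)
        vec = vec.astype(np.int32)
        states[chrom] = vec
    for e in world.elements:
        center_bin = e.center // BIN_BP
        lo = max(center_bin - 10, 0)
        hi = min(center_bin + 11, world.assembly.n_bins(e.chrom))
        if e.repressed:
            states[e.chrom][lo:hi] = 2
        elif e.active_in[ct]:
            states[e.chrom][lo:hi] = 1
    ann = StateAnnotation(world.assembly, states, cfg.K_states)
    return tracks, peaks, ann


# ---------------------------------------------------------------------------
# assay rendering


def render_assay(world: PlantedWorld, cell_type: str, assay: str,
                 noise: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Render a readout table for one assay family, in its labeler schema.

    Readouts are monotone in planted strength (for elements active in the
    cell type) plus Gaussian/uniform noise.  The returned frame has passed
    through the schema validator, so it is exactly what the corresponding
    labeler consumes.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; choose from {ASSAYS}")
    ct = world.cell_types.index(cell_type)
    rng = np.random.default_rng(
        np.random.SeedSequence([world.cfg.seed, ct, 1000 + ASSAYS.index(assay), seed])
    )
    rows = []
    for ei, e in enumerate(world.elements):
        active = e.active_in[ct] and not e.repressed
        signal = e.strength if active else 0.0
        if assay == "sharpr":
            # 300 bp region tiled at 5 bp: 60 scores, bump at the center.
            start = e.center - 150
            offsets = (np.arange(60) - 29.5) * 5
            profile = 2.5 * signal * np.exp(-0.5 * (offsets / 75) ** 2)
            if e.repressed:
                profile -= 2.0 * e.strength * np.exp(-0.5 * (offsets / 75) ** 2)
            profile += rng.normal(0, noise, 60)
            rows.append({
                "chrom": e.chrom, "start": start, "end": start + 300,
                "scores": ",".join(f"{x:.4f}" for x in profile),
            })
        elif assay == "pvalue":
            p = rng.uniform(0, 0.04) if active else rng.uniform(0.05, 1.0)
            if rng.random() < noise:  # assay failure flips the readout
                p = rng.uniform(0, 1)
            rows.append({
                "chrom": e.chrom, "start": e.center - 100,
                "end": e.center + 100, "p_value": round(p, 6),
                "construct_id": f"construct{ei}",
            })
        elif assay == "starr_peaks":
            score = 4.0 * signal + rng.normal(0, noise)
            rows.append({
                "chrom": e.chrom, "start": e.center - 200,
                "end": e.center + 200, "score": round(float(score), 6),
                "peak_id": f"peak{ei}",
            })
        elif assay == "hidra":
            ratio = 0.5 + 3.0 * signal + rng.normal(0, noise)
            rows.append({
                "chrom": e.chrom, "start": e.center - 150,
                "end": e.center + 150, "rna_dna_ratio": round(float(ratio), 6),
                "element_id": f"element{ei}",
            })
        else:  # crispr
            for gi in range(2):
                p = (rng.uniform(0, 0.04) if active and gi == 0
                     else rng.uniform(0.05, 1.0))
                beta = (-abs(rng.normal(0.5, 0.2)) if active
                        else rng.normal(0, 0.2))
                rows.append({
                    "chrom": e.chrom, "start": e.center - 150,
                    "end": e.center + 150, "gene": f"gene{ei}_{gi}",
                    "adjusted_p": round(p, 6), "beta": round(float(beta), 6),
                    "outlier_gene": bool(rng.random() < 0.02),
                    "power_ok": bool(rng.random() > 0.05),
                    "effect_change": round(float(np.sign(beta) * abs(rng.normal(0.2, 0.1))), 6),
                })
    table = pd.DataFrame(rows)
    schema = {"pvalue": "pvalue", "sharpr": "sharpr",
              "starr_peaks": "starr_peaks", "hidra": "hidra",
              "crispr": "gasperini"}[assay]
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_record_table(buf, schema)


def label_assay(world: PlantedWorld, cell_type: str, assay: str,
                table: pd.DataFrame, seed: int = 0,
                cfg: LabelRuleConfig | None = None) -> list[LabeledRegion]:
    """Run the matching labeler on a rendered assay table, drawing neutral
    background positions where the assay only yields activating labels."""
    cfg = cfg or LabelRuleConfig()
    dataset_id = f"{assay}/{cell_type}"
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, seed]))
    if assay == "sharpr":
        regions = sharpr_regions_from_table(table)
        return label_sharpr(regions, cfg, dataset_id, cell_type)
    if assay == "pvalue":
        return label_by_pvalue(table, cfg.alpha, dataset_id, cell_type)
    if assay == "crispr":
        records = element_gene_records_from_table(table, "gasperini")
        return label_crispr_elements(records, cfg.alpha, "gasperini",
                                     dataset_id, cell_type)
    if assay == "starr_peaks":
        peaks = IntervalSet(
            Interval(r.chrom, int(r.start), int(r.end), score=float(r.score))
            for r in table.itertuples(index=False)
        )
        activating = label_top_fraction(peaks, cfg.top_fraction,
                                        dataset_id, cell_type)
    else:  # hidra
        peaks = IntervalSet(
            Interval(r.chrom, int(r.start), int(r.end),
                     score=float(r.rna_dna_ratio))
            for r in table.itertuples(index=False)
        )
        activating = label_threshold_peaks(peaks, 1.0, dataset_id, cell_type)
    neutral = sample_neutral_background(
        world.assembly, excluded=IntervalSet(),
        n_activating=len(activating),
        per_activating=cfg.neutral_per_activating, rng=rng,
        dataset_id=dataset_id, cell_type=cell_type,
    )
    return activating + neutral


def make_labeled_dataset(world: PlantedWorld, cell_type: str,
                         assay: str = "hidra", noise: float = 0.05,
                         seed: int = 0):
    """Convenience: render chromatin and an assay for one cell type and
    bundle them as a training-ready dataset."""
    from chromactivity.experts import LabeledDataset

    tracks, peaks, ann = render_tracks(world, cell_type)
    table = render_assay(world, cell_type, assay, noise=noise, seed=seed)
    regions = label_assay(world, cell_type, assay, table, seed=seed)
    return LabeledDataset(f"{assay}/{cell_type}", cell_type, regions,
                          tracks, peaks, ann)


# ---------------------------------------------------------------------------
# HMM simulation


def simulate_hmm(model, T: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample a hidden path from pi/A and observations from the Bernoulli
    emissions; returns (T x M observations, hidden path of state indices
    0-based)."""
    rng = np.random.default_rng(seed)
    K, M = model.K, model.M
    path = np.empty(T, dtype=np.int32)
    path[0] = rng.choice(K, p=model.pi)
    for t in range(1, T):
        path[t] = rng.choice(K, p=model.A[path[t - 1]])
    obs = (rng.random((T, M)) < model.E[path]).astype(np.uint8)
    return obs, path
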