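"""Genome model and I/O for binned signal tracks, intervals and segmentations.

All coordinates are handled internally as 0-based half-open; the wiggle
fixedStep reader/writer is the only place 1-based arithmetic occurs.  Signal
and state tracks live on a fixed 25 bp bin grid: the bin of genomic position
``p`` is ``p // 25`` and the center (13th) nucleotide of bin ``i`` is
``25*i + 12``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Width of the genome bin grid in base pairs.
BIN_BP = 25


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class SchemaError(ValueError):
    """A record table is missing required columns or carries bad values."""


# ---------------------------------------------------------------------------
# genome assembly


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths hosting the 25 bp bin grid."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        """Number of 25 bp bins on ``chrom`` (last bin may be partial)."""
        return math.ceil(self.length(chrom) / BIN_BP)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_of(self, position: int) -> int:
        return position // BIN_BP

    @staticmethod
    def bin_center(bin_index: int) -> int:
        """Center nucleotide (the 13th base) of a 25 bp bin."""
        return BIN_BP * bin_index + BIN_BP // 2


def read_chrom_sizes(path) -> GenomeAssembly:
    """Read a two-column chrom-sizes file into a :class:`GenomeAssembly`."""
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom length'")
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
            chroms.append((parts[0], length))
    return GenomeAssembly(tuple(chroms))


def write_chrom_sizes(assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for name, length in assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with optional BED6 annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Center base; for even lengths, ``start + length // 2``."""
        return self.start + self.length // 2


class IntervalSet:
    """An ordered collection of intervals with point/overlap queries."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = list(intervals)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        # Per chromosome: interval starts sorted ascending paired with the
        # running maximum of ends, so point containment is a searchsorted
        # plus one comparison.
        if self._index is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            index = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                starts = np.array([p[0] for p in pairs], dtype=np.int64)
                ends = np.array([p[1] for p in pairs], dtype=np.int64)
                index[chrom] = (starts, np.maximum.accumulate(ends))
            self._index = index
        return self._index

    def contains(self, chrom: str, position: int) -> bool:
        """True iff some interval contains ``position`` (half-open)."""
        index = self._build_index()
        if chrom not in index:
            return False
        starts, max_ends = index[chrom]
        hi = int(np.searchsorted(starts, position, side="right"))
        # Intervals before `hi` start at or before `position`; one of them
        # contains it iff the running max of their ends passes `position`.
        return hi > 0 and int(max_ends[hi - 1]) > position

    def bin_mask(self, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
        """Boolean mask per chromosome: bin True iff some interval covers
        at least 1 bp of it."""
        masks = {
            chrom: np.zeros(assembly.n_bins(chrom), dtype=bool)
            for chrom in assembly.names
        }
        for iv in self.intervals:
            if iv.chrom not in masks:
                continue
            first = iv.start // BIN_BP
            last = (iv.end - 1) // BIN_BP
            n = masks[iv.chrom].shape[0]
            masks[iv.chrom][max(first, 0) : min(last + 1, n)] = True
        return masks

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)


def read_intervals(path) -> IntervalSet:
    """Read BED3+ text; optional name/score/strand columns are captured."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 else None
            intervals.append(Interval(parts[0], start, end, name, score, strand))
    return IntervalSet(intervals)


def write_intervals(ivals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in ivals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand is not None:
                fields += [iv.name or ".", _fmt(iv.score) if iv.score is not None else "0", iv.strand]
            elif iv.score is not None:
                fields += [iv.name or ".", _fmt(iv.score)]
            elif iv.name is not None:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# signal tracks


@dataclass
class SignalTrack:
    """Real-valued signal on the 25 bp bin grid of an assembly."""

    assembly: GenomeAssembly
    data: dict[str, np.ndarray]
    mark_name: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        for chrom in self.assembly.names:
            if chrom not in self.data:
                self.data[chrom] = np.zeros(self.assembly.n_bins(chrom))
        for chrom, values in self.data.items():
            expected = self.assembly.n_bins(chrom)
            if values.shape != (expected,):
                raise ValueError(
                    f"{chrom}: track length {values.shape} != {expected} bins"
                )
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite signal values")

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, **kw) -> "SignalTrack":
        return cls(assembly, {}, **kw)

    @classmethod
    def constant(cls, assembly: GenomeAssembly, value: float, **kw) -> "SignalTrack":
        data = {
            c: np.full(assembly.n_bins(c), float(value)) for c in assembly.names
        }
        return cls(assembly, data, **kw)

    def value_at(self, chrom: str, position: int) -> float:
        """Signal of the bin containing ``position``; 0 off the chromosome."""
        if position < 0:
            return 0.0
        vec = self.data[chrom]
        b = position // BIN_BP
        return float(vec[b]) if b < vec.shape[0] else 0.0

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.assembly.names])


def read_signal_track(path, assembly: GenomeAssembly, mark_name: str = "",
                      cell_type: str = "") -> SignalTrack:
    """Read a bedGraph or wiggle-fixedStep file into a binned track.

    bedGraph intervals must align to the 25 bp grid; wiggle blocks must use
    ``step=span=25`` with 1-based starts on the grid.  Bins not covered by
    the file read as 0.
    """
    data = {c: np.zeros(assembly.n_bins(c)) for c in assembly.names}
    mode = None  # "wig" once a fixedStep header is seen, else bedGraph
    chrom = None
    pos = 0  # 0-based bp cursor within a wiggle block
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                attrs = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                chrom = attrs.get("chrom")
                if chrom not in data:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                start1 = int(attrs.get("start", 1))
                step = int(attrs.get("step", 1))
                span = int(attrs.get("span", 1))
                if step != BIN_BP or span != BIN_BP:
                    raise FormatError(
                        f"{path}:{lineno}: fixedStep requires step=span={BIN_BP}"
                    )
                pos = start1 - 1
                if pos % BIN_BP != 0:
                    raise FormatError(
                        f"{path}:{lineno}: start {start1} not on the 25 bp grid"
                    )
                continue
            if mode == "wig":
                b = pos // BIN_BP
                if b >= data[chrom].shape[0]:
                    raise FormatError(f"{path}:{lineno}: value past chromosome end")
                data[chrom][b] = float(line)
                pos += BIN_BP
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c not in data:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {c!r}")
            clen = assembly.length(c)
            if s % BIN_BP != 0 or (e % BIN_BP != 0 and e != clen):
                raise FormatError(
                    f"{path}:{lineno}: interval {s}-{e} not aligned to the "
                    f"{BIN_BP} bp grid"
                )
            if e > clen:
                raise FormatError(f"{path}:{lineno}: interval past chromosome end")
            data[c][s // BIN_BP : (e + BIN_BP - 1) // BIN_BP] = v
    return SignalTrack(assembly, data, mark_name=mark_name, cell_type=cell_type)


def write_score_track(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal-valued bins."""
    with open(path, "w") as fh:
        for chrom in track.assembly.names:
            values = track.data[chrom]
            clen = track.assembly.length(chrom)
            for start_bin, end_bin, value in _runs(values):
                start = start_bin * BIN_BP
                end = min(end_bin * BIN_BP, clen)
                fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def _runs(values: np.ndarray):
    """Yield (start_bin, end_bin, value) runs of equal consecutive values."""
    if values.size == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield int(lo), int(hi), float(values[lo])


# ---------------------------------------------------------------------------
# state annotations


@dataclass
class StateAnnotation:
    """Per-bin chromatin state indices in 1..K on the 25 bp grid."""

    assembly: GenomeAssembly
    data: dict[str, np.ndarray]
    K: int
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.state_names:
            self.state_names = [str(k) for k in range(1, self.K + 1)]
        if len(self.state_names) != self.K:
            raise ValueError("state_names length != K")
        for chrom in self.assembly.names:
            vec = self.data.get(chrom)
            if vec is None:
                raise ValueError(f"no states for chromosome {chrom}")
            if vec.shape != (self.assembly.n_bins(chrom),):
                raise ValueError(f"{chrom}: state vector length mismatch")
            if vec.min() < 1 or vec.max() > self.K:
                raise ValueError(f"{chrom}: state index outside 1..{self.K}")

    def state_at(self, chrom: str, position: int) -> int:
        return int(self.data[chrom][position // BIN_BP])

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.assembly.names])


def read_segmentation(path, K: int, assembly: GenomeAssembly) -> StateAnnotation:
    """Read a dense 4-column BED segmentation (ChromHMM-style).

    Intervals must tile each chromosome without gaps or overlaps and align
    to the 25 bp grid; the state index is the leading integer of the name
    column (e.g. ``"3_Enh"`` is state 3).
    """
    per_chrom: dict[str, list[tuple[int, int, int]]] = {
        c: [] for c in assembly.names
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need 4 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in per_chrom:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            state = int(parts[3].split("_")[0])
            if not 1 <= state <= K:
                raise FormatError(
                    f"{path}:{lineno}: state {state} outside 1..{K}"
                )
            per_chrom[chrom].append((start, end, state))
    data = {}
    for chrom in assembly.names:
        rows = sorted(per_chrom[chrom])
        clen = assembly.length(chrom)
        vec = np.zeros(assembly.n_bins(chrom), dtype=np.int32)
        cursor = 0
        for start, end, state in rows:
            if start != cursor:
                raise FormatError(
                    f"{path}: gap or overlap at {chrom}:{start} "
                    f"(expected start {cursor})"
                )
            if start % BIN_BP != 0 or (end % BIN_BP != 0 and end != clen):
                raise FormatError(
                    f"{path}: interval {chrom}:{start}-{end} off the 25 bp grid"
                )
            vec[start // BIN_BP : (end + BIN_BP - 1) // BIN_BP] = state
            cursor = end
        if cursor != clen:
            raise FormatError(
                f"{path}: {chrom} tiled only to {cursor} of {clen} bp"
            )
        data[chrom] = vec
    return StateAnnotation(assembly, data, K)


def write_segmentation(ann: StateAnnotation, path) -> None:
    """Write a dense 4-column BED, merging runs of equal states."""
    with open(path, "w") as fh:
        for chrom in ann.assembly.names:
            vec = ann.data[chrom]
            clen = ann.assembly.length(chrom)
            for lo, hi, state in _runs(vec):
                start = lo * BIN_BP
                end = min(hi * BIN_BP, clen)
                k = int(state)
                fh.write(f"{chrom}\t{start}\t{end}\t{k}_{ann.state_names[k - 1]}\n")


# ---------------------------------------------------------------------------
# record tables

#: Required/optional columns for each functional-characterization schema.
#: ``sharpr`` rows carry a comma-separated vector of 5 bp activity scores;
#: ``gasperini``/``fulco`` rows are element-gene records from CRISPRi screens.
RECORD_SCHEMAS: dict[str, dict[str, Sequence[str]]] = {
    "sharpr": {
        "required": ("chrom", "start", "end", "scores"),
        "optional": (),
    },
    "pvalue": {
        "required": ("chrom", "start", "end", "p_value"),
        "optional": ("construct_id",),
    },
    "starr_peaks": {
        "required": ("chrom", "start", "end", "score"),
        "optional": ("peak_id",),
    },
    "hidra": {
        "required": ("chrom", "start", "end", "rna_dna_ratio"),
        "optional": ("element_id",),
    },
    "gasperini": {
        "required": ("chrom", "start", "end", "gene", "adjusted_p", "beta",
                     "outlier_gene"),
        "optional": (),
    },
    "fulco": {
        "required": ("chrom", "start", "end", "gene", "adjusted_p",
                     "power_ok", "effect_change"),
        "optional": (),
    },
}

_NUMERIC_COLUMNS = {
    "start", "end", "p_value", "score", "rna_dna_ratio", "adjusted_p",
    "beta", "effect_change",
}
_BOOL_COLUMNS = {"outlier_gene", "power_ok"}


def read_record_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV assay table and validate it against a named schema.

    Missing values are allowed only in optional columns; boolean columns
    accept ``True/False`` and ``1/0``.
    """
    if schema not in RECORD_SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; known: {sorted(RECORD_SCHEMAS)}"
        )
    spec = RECORD_SCHEMAS[schema]
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in spec["required"] if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: schema {schema!r} missing required columns {missing}"
        )
    for col in table.columns:
        if col in _NUMERIC_COLUMNS:
            table[col] = pd.to_numeric(table[col], errors="coerce")
        elif col in _BOOL_COLUMNS:
            table[col] = table[col].map(
                {"True": True, "False": False, "1": True, "0": False}
            )
    bad = [c for c in spec["required"] if table[c].isna().any()]
    if bad:
        raise SchemaError(
            f"{path}: missing values in required columns {bad}"
        )
    if "adjusted_p" in spec["required"]:
        p = table["adjusted_p"]
        if ((p < 0) | (p > 1)).any():
            raise SchemaError(f"{path}: adjusted_p outside [0, 1]")
    return table
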