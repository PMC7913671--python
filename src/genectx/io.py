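"""Standard-format readers/writers and the shared coordinate model.

All coordinates are 0-based, half-open internally. GFF3 (1-based,
inclusive) is converted on read; BED and bedGraph pass through unchanged.
Strand is one of ``"+"``, ``"-"`` or ``"."`` (unstranded); ``"."`` in
files maps to unstranded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: default bin size (bp) for coverage tracks; the source experiments do not
#: fix one, so it is configuration everywhere a track is read or simulated
DEFAULT_BIN_SIZE = 50


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(ValueError):
    """A record violates the coordinate model (bounds, strand, layout)."""


# ---------------------------------------------------------------------------
# coordinate model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate frame for
    every interval and track in the pipeline."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, lengths: dict[str, int] | Sequence[tuple[str, int]]) -> "GenomeLayout":
        items = lengths.items() if isinstance(lengths, dict) else lengths
        return cls(tuple((str(n), int(l)) for n, l in items))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """A located, stranded feature with a class label.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def validate(self, layout: GenomeLayout) -> "GenomicInterval":
        if self.chrom not in layout:
            raise ValidationError(f"unknown chromosome {self.chrom!r}")
        if self.end > layout.length(self.chrom):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {layout.length(self.chrom)}"
            )
        return self

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def tss(self) -> int:
        """Stranded 5' end (the TSS for a gene interval)."""
        if self.strand == "-":
            return self.end - 1
        return self.start


@dataclass(frozen=True)
class TandemRepeatRecord:
    """A tandem-repeat region with its motif (period) length and
    alignment score; ``repeat_class`` is set by classification."""

    interval: GenomicInterval
    motif_length: int
    score: float
    repeat_class: str | None = None  # "short" or "long"

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValidationError(f"motif_length must be >= 1, got {self.motif_length}")


@dataclass
class CoverageTrack:
    """Per-chromosome binned signal (occupancy counts or ChIP coverage).

    ``values[chrom]`` has ``ceil(length / bin_size)`` entries; the last
    bin may be truncated at the chromosome end. Raw coverage is
    non-negative; set ``is_ratio`` for log-ratio tracks, which may carry
    any real value.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    is_ratio: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValidationError(f"bin_size must be >= 1, got {self.bin_size}")
        for chrom, length in self.layout.chromosomes:
            expected = n_bins(length, self.bin_size)
            vec = self.values.setdefault(chrom, np.zeros(expected))
            if len(vec) != expected:
                raise ValidationError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )
        if not self.is_ratio:
            for chrom, vec in self.values.items():
                if np.any(vec < 0):
                    raise ValidationError(
                        f"{chrom}: negative values in a non-ratio track"
                    )

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int, is_ratio: bool = False) -> "CoverageTrack":
        return cls(layout, bin_size, {}, is_ratio=is_ratio)

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.layout,
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            is_ratio=self.is_ratio,
        )

    def same_grid(self, other: "CoverageTrack") -> bool:
        return self.layout == other.layout and self.bin_size == other.bin_size

    def genome_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.names])

    def total_signal(self) -> float:
        """Sum of value x covered-bases over all bins."""
        total = 0.0
        for chrom, length in self.layout.chromosomes:
            widths = bin_widths(length, self.bin_size)
            total += float(np.dot(self.values[chrom], widths))
        return total

    def mean(self) -> float:
        return self.total_signal() / self.layout.total_length


def n_bins(length: int, bin_size: int) -> int:
    return math.ceil(length / bin_size)


def bin_widths(length: int, bin_size: int) -> np.ndarray:
    nb = n_bins(length, bin_size)
    widths = np.full(nb, bin_size, dtype=float)
    if length % bin_size:
        widths[-1] = length % bin_size
    return widths


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------


def parse_gff3(path: str | Path, layout: GenomeLayout) -> list[GenomicInterval]:
    """Read a GFF3 file into intervals (coordinates converted to 0-based
    half-open; feature type -> ``label``, ``ID=`` attribute -> ``id``).

    Raises :class:`ParseError` naming the line number for malformed
    lines, :class:`ValidationError` for coordinates outside the layout.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {lineno}: bad coordinate order {start1}..{end1}")
            fid = ""
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("ID="):
                    fid = part[3:]
                    break
            if strand not in STRANDS:
                strand = "."
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand, ftype, fid).validate(layout)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
            intervals.append(iv)
    return intervals


def write_gff3(path: str | Path, intervals: Iterable[GenomicInterval], source: str = "genectx") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.label or 'region'}\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID={iv.id}\n"
            )


def read_bed(path: str | Path, layout: GenomeLayout | None = None, label: str = "") -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open, passed through)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            iv = GenomicInterval(chrom, start, end, strand, label, name)
            if layout is not None:
                iv = iv.validate(layout)
            intervals.append(iv)
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph / fixed-step wig)
# ---------------------------------------------------------------------------


def read_track(
    path: str | Path,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    is_ratio: bool = False,
) -> CoverageTrack:
    """Read a bedGraph or fixed-step wig into a binned track.

    Source values are rebinned by coverage-weighted mean: each source
    interval distributes ``value x overlap_bases`` into the bins it
    touches, and each bin is divided by its width, so uncovered bases
    count as 0 and total signal (value x bases) is conserved. Overlapping
    bedGraph intervals are an error; negative values are rejected unless
    ``is_ratio``.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if first.startswith(("fixedStep", "variableStep")):
        spans = _read_wig_spans(path)
    else:
        spans = _read_bedgraph_spans(path)
    return _rebin(spans, layout, bin_size, is_ratio)


def _read_bedgraph_spans(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 fields")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _read_wig_spans(path: Path) -> pd.DataFrame:
    rows = []
    chrom, pos, step, span = "", 0, 1, 1
    mode = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                mode = line.split()[0]
                params = dict(p.split("=", 1) for p in line.split()[1:])
                if "chrom" not in params:
                    raise ParseError(f"line {lineno}: wig declaration missing chrom")
                chrom = params["chrom"]
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                pos = int(params.get("start", 1)) - 1  # wig is 1-based
                continue
            if not mode:
                raise ParseError(f"line {lineno}: data before wig declaration")
            parts = line.split()
            if mode == "variableStep":
                pos = int(parts[0]) - 1
                value = float(parts[1])
            else:
                value = float(parts[0])
            rows.append((chrom, pos, pos + span, value))
            if mode == "fixedStep":
                pos += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _rebin(spans: pd.DataFrame, layout: GenomeLayout, bin_size: int, is_ratio: bool) -> CoverageTrack:
    track = CoverageTrack.zeros(layout, bin_size, is_ratio=is_ratio)
    if len(spans) == 0:
        return track
    if not is_ratio and (spans["value"] < 0).any():
        raise ValidationError("negative values in a non-ratio track")
    for chrom, grp in spans.groupby("chrom", sort=False):
        if chrom not in layout:
            raise ValidationError(f"unknown chromosome {chrom!r} in track")
        length = layout.length(chrom)
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(f"{chrom}: overlapping intervals in coverage file")
        if starts[0] < 0 or ends[-1] > length:
            raise ValidationError(f"{chrom}: interval outside chromosome bounds")
        acc = np.zeros(n_bins(length, bin_size))
        vals = grp["value"].to_numpy()
        for s, e, v in zip(starts, ends, vals):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                acc[b0] += v * (e - s)
                continue
            acc[b0] += v * ((b0 + 1) * bin_size - s)
            acc[b1] += v * (e - b1 * bin_size)
            if b1 - b0 > 1:
                acc[b0 + 1 : b1] += v * bin_size
        track.values[chrom] = acc / bin_widths(length, bin_size)
    return track


def write_bedgraph(path: str | Path, track: CoverageTrack, precision: int = 6) -> None:
    """Write a track as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom, length in track.layout.chromosomes:
            vals = np.round(track.values[chrom], precision)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for b0, b1 in zip(starts, ends):
                v = vals[b0]
                if v == 0 and not track.is_ratio:
                    continue
                s = b0 * track.bin_size
                e = min(b1 * track.bin_size, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# tandem-repeat tables
# ---------------------------------------------------------------------------


def read_tandem_repeat_table(path: str | Path) -> list[TandemRepeatRecord]:
    """Read tandem-repeat regions from a Tandem Repeats Finder ``.dat``
    file or a TSV with columns ``chrom, start, end, period, score``.

    ``.dat`` coordinates are 1-based inclusive and converted; TSV
    coordinates are taken as 0-based half-open.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    if "Sequence:" in text or "Parameters:" in text:
        return _parse_trf_dat(text)
    return _parse_repeat_tsv(text)


def _parse_trf_dat(text: str) -> list[TandemRepeatRecord]:
    records: list[TandemRepeatRecord] = []
    chrom = ""
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line.startswith("Sequence:"):
            chrom = line.split(None, 1)[1].split()[0]
            continue
        if not line or not line[0].isdigit():
            continue
        parts = line.split()
        if len(parts) < 8:
            raise ParseError(f"line {lineno}: TRF record needs >= 8 fields")
        if not chrom:
            raise ParseError(f"line {lineno}: TRF record before any Sequence header")
        start1, end1 = int(parts[0]), int(parts[1])
        if start1 > end1:
            raise ValidationError(f"line {lineno}: start > end in TRF record")
        period, score = int(parts[2]), float(parts[7])
        records.append(
            TandemRepeatRecord(
                GenomicInterval(chrom, start1 - 1, end1, label="tandem_repeat"),
                motif_length=period,
                score=score,
            )
        )
    return records


def _parse_repeat_tsv(text: str) -> list[TandemRepeatRecord]:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    df.columns = [c.lower() for c in df.columns]
    for col in ("chrom", "start", "end", "period"):
        if col not in df.columns:
            raise ParseError(f"repeat table missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            raise ValidationError(f"repeat record {row.chrom}:{row.start}-{row.end} has start >= end")
        records.append(
            TandemRepeatRecord(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end), label="tandem_repeat"),
                motif_length=int(row.period),
                score=float(getattr(row, "score", 0.0)),
            )
        )
    return records


def write_tandem_repeat_table(path: str | Path, records: Iterable[TandemRepeatRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tperiod\tscore\n")
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.motif_length}\t{r.score:g}\n"
            )
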