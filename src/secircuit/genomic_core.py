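"""Genome coordinate model, interval algebra, and standard-format I/O.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
1-based formats (GTF) are converted at the reader boundary.  Signal is
interpreted as a density per base, so the quantity of signal in a region is
``value * width`` summed over overlapped track segments ("area under the
peak").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SignalTrack",
    "read_intervals",
    "write_bed",
    "read_signal",
    "write_bedgraph",
    "read_gtf",
    "write_gtf",
    "read_bed12_genes",
    "read_fasta",
    "write_fasta",
    "interval_signal",
    "overlap_stats",
    "merge_intervals",
    "subtract_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit, score and name."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative peak score {self.score}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS/TES (0-based base positions).

    ``tss`` is the transcription start regardless of orientation, so
    ``tss < tes`` on the + strand and ``tss > tes`` on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        """Exclusive end of the gene span."""
        return max(self.tss, self.tes) + 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class SignalTrack:
    """Non-negative piecewise-constant coverage over a genome.

    Stored per chromosome as parallel sorted arrays (starts, ends, values)
    of disjoint segments; gaps read as zero.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (starts, ends, values) in data.items():
                self._add_chrom(chrom, np.asarray(starts, dtype=np.int64),
                                np.asarray(ends, dtype=np.int64),
                                np.asarray(values, dtype=np.float64))

    def _add_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray,
                   values: np.ndarray) -> None:
        if len(starts) == 0:
            return
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(values < 0):
            raise ValueError(f"negative signal value on {chrom}")
        if np.any(starts >= ends):
            raise ValueError(f"empty or inverted segment on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping segments on {chrom}")
        self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._data:
            z = np.empty(0, dtype=np.int64)
            return z, z, np.empty(0, dtype=np.float64)
        return self._data[chrom]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        """Build from (chrom, start, end, value) records; overlaps rejected."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls()
        for chrom, recs in per_chrom.items():
            arr = np.array(recs, dtype=np.float64).reshape(-1, 3)
            track._add_chrom(chrom, arr[:, 0].astype(np.int64),
                             arr[:, 1].astype(np.int64), arr[:, 2])
        return track

    @classmethod
    def from_pieces(cls, pieces: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        """Build from possibly-overlapping pieces summed additively.

        A boundary sweep resolves the pieces into disjoint segments; zero
        segments are dropped.
        """
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in pieces:
            if end <= start:
                continue
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls()
        for chrom, recs in per_chrom.items():
            arr = np.asarray(recs, dtype=np.float64)
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            values = arr[:, 2]
            bounds = np.unique(np.concatenate([starts, ends]))
            acc = np.zeros(len(bounds) - 1, dtype=np.float64)
            lo = np.searchsorted(bounds, starts)
            hi = np.searchsorted(bounds, ends)
            for a, b, v in zip(lo, hi, values):
                acc[a:b] += v
            keep = acc != 0.0
            if np.any(acc < 0):
                raise ValueError("negative resolved signal")
            seg_starts = bounds[:-1][keep]
            seg_ends = bounds[1:][keep]
            seg_vals = acc[keep]
            # merge equal-valued adjacent segments
            if len(seg_starts):
                brk = np.flatnonzero(
                    (seg_starts[1:] != seg_ends[:-1]) | (seg_vals[1:] != seg_vals[:-1])
                )
                first = np.concatenate([[0], brk + 1])
                last = np.concatenate([brk, [len(seg_starts) - 1]])
                track._add_chrom(chrom, seg_starts[first], seg_ends[last], seg_vals[first])
        return track

    def area(self, region: GenomicInterval) -> float:
        """Signal area (value × overlap width) over ``region``; 0 off-track."""
        starts, ends, values = self.segments(region.chrom)
        if len(starts) == 0:
            return 0.0
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        return float(np.sum((e - s) * values[lo:hi]))

    def mean_density(self, region: GenomicInterval) -> float:
        return self.area(region) / region.width

    def total(self) -> float:
        return float(sum(np.sum((e - s) * v) for s, e, v in self._data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = SignalTrack()
        for chrom, (s, e, v) in self._data.items():
            out._add_chrom(chrom, s.copy(), e.copy(), v * factor)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][i], other._data[c][i])
            for c in self._data for i in range(3)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_error(path, lineno, msg):
    return ValueError(f"{path}:{lineno}: {msg}")


def read_intervals(path: str | Path, format: str = "BED") -> list[Peak]:
    """Read peaks from a BED3/BED5 or ENCODE narrowPeak file.

    narrowPeak summits are column 10 (offset from start; −1 means absent).
    """
    fmt = format.lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, f"expected >=3 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise _parse_error(path, lineno, f"bad score {fields[4]!r}") from None
            summit = None
            if fmt == "narrowpeak":
                if len(fields) < 10:
                    raise _parse_error(path, lineno, "narrowPeak requires 10 columns")
                if len(fields) > 6 and fields[6] not in (".", ""):
                    score = float(fields[6])  # signalValue preferred over int score
                offset = int(fields[9])
                if offset != -1:
                    summit = start + offset
            try:
                peaks.append(Peak(interval, score=score, name=name, summit=summit))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path, narrowpeak: bool = False) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if narrowpeak:
                offset = -1 if p.summit is None else p.summit - p.start
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                    f"{p.score:g}\t-1\t-1\t{offset}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\n")


def read_signal(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise _parse_error(path, lineno, "bedGraph requires 4 columns")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise _parse_error(path, lineno, "malformed bedGraph record") from None
            if start >= end:
                raise _parse_error(path, lineno, "start >= end")
            if value < 0:
                raise _parse_error(path, lineno, f"negative value {value}")
            records.append((chrom, start, end, value))
    try:
        return SignalTrack.from_records(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_gtf(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GTF (1-based closed; converted here)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise _parse_error(path, lineno, "GTF requires 9 columns")
            if fields[2] != feature:
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = {}
            for item in fields[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, raw = item.partition(" ")
                attrs[key] = raw.strip().strip('"')
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise _parse_error(path, lineno, "missing gene_id attribute")
            start0, end0 = start1 - 1, end1  # to 0-based half-open
            if strand == "+":
                tss, tes = start0, end0 - 1
            elif strand == "-":
                tss, tes = end0 - 1, start0
            else:
                raise _parse_error(path, lineno, f"bad strand {strand!r}")
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes,
                                   name=attrs.get("gene_name", gene_id)))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "secircuit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name or g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (TSS = start for +, end−1 for −)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _parse_error(path, lineno, "BED gene models require >=6 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            if strand == "+":
                tss, tes = start, end - 1
            elif strand == "-":
                tss, tes = end - 1, start
            else:
                raise _parse_error(path, lineno, f"bad strand {strand!r}")
            genes.append(GeneModel(name, chrom, strand, tss, tes, name=name))
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (desk-scale) FASTA into a dict of upper-case sequences."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width])
                fh.write("\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def interval_signal(track: SignalTrack, region: GenomicInterval) -> float:
    """Area under the signal over ``region`` (density × width summed)."""
    return track.area(region)


def merge_intervals(intervals: Iterable[GenomicInterval],
                    gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals whose gap (start_next − end_prev) is ≤ ``gap``."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def subtract_intervals(interval: GenomicInterval,
                       holes: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Remove ``holes`` from ``interval``, returning the remaining parts."""
    parts: list[GenomicInterval] = []
    cursor = interval.start
    relevant = sorted(
        (h for h in holes if h.chrom == interval.chrom
         and h.end > interval.start and h.start < interval.end),
        key=lambda h: h.start,
    )
    for h in relevant:
        if h.start > cursor:
            parts.append(GenomicInterval(interval.chrom, cursor, h.start))
        cursor = max(cursor, h.end)
    if cursor < interval.end:
        parts.append(GenomicInterval(interval.chrom, cursor, interval.end))
    return parts


def overlap_stats(a: Sequence[Peak | GenomicInterval],
                  b: Sequence[Peak | GenomicInterval],
                  min_bp: int = 1) -> tuple[list[tuple[int, int]], float]:
    """Pairs of overlapping (a_index, b_index) peaks and the fraction of ``a``
    overlapped by at least one ``b`` peak (≥ ``min_bp`` shared bases).

    Raises ``ValueError`` when ``a`` is empty (fraction undefined).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if len(a) == 0:
        raise ValueError("overlap fraction undefined for empty query set")

    def _iv(x) -> GenomicInterval:
        return x.interval if isinstance(x, Peak) else x

    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, pb in enumerate(b):
        iv = _iv(pb)
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for chrom in b_by_chrom:
        b_by_chrom[chrom].sort()

    pairs: list[tuple[int, int]] = []
    hit = np.zeros(len(a), dtype=bool)
    for i, pa in enumerate(a):
        iv = _iv(pa)
        cands = b_by_chrom.get(iv.chrom, [])
        starts = [c[0] for c in cands]
        import bisect
        k = bisect.bisect_left(starts, iv.end)
        for s, e, j in cands[:k]:
            if min(e, iv.end) - max(s, iv.start) >= min_bp:
                pairs.append((i, j))
                hit[i] = True
    return pairs, float(hit.mean())
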