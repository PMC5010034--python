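"""Read-level methylation I/O: CpG maps, per-read call parsing, deduplication
and 4-CpG segment pattern extraction.

Coordinates are 0-based half-open throughout. A CpG position is the
coordinate of the C of the CG dinucleotide on the forward strand; calls made
on reverse-strand reads are projected onto the forward C of the same dyad
(the standard Bismark convention).
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGMap",
    "ReadMethCalls",
    "Segment",
    "PatternCluster",
    "build_cpg_map",
    "parse_read_calls",
    "read_calls_tsv",
    "write_calls_tsv",
    "iter_sam_read_calls",
    "dedup_reads",
    "extract_segments",
    "segment_meth_levels",
    "read_clusters_tsv",
    "write_clusters_tsv",
]

_CG_RE = re.compile("CG")

METHYLATED = "M"
UNMETHYLATED = "U"


@dataclass(frozen=True)
class CpGMap:
    """Ordered forward-strand CpG cytosine coordinates for one chromosome."""

    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("CpG positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, position: int) -> bool:
        i = bisect_left(self.positions, position)
        return i < len(self.positions) and self.positions[i] == position

    def index(self, position: int) -> int:
        i = bisect_left(self.positions, position)
        if i == len(self.positions) or self.positions[i] != position:
            raise KeyError(f"{self.chrom}:{position} is not a CpG position")
        return i

    def in_span(self, start: int, end: int) -> tuple[int, ...]:
        """CpG positions with start <= pos < end."""
        lo = bisect_left(self.positions, start)
        hi = bisect_left(self.positions, end)
        return self.positions[lo:hi]


@dataclass(frozen=True)
class ReadMethCalls:
    """One read's CpG methylation calls, on forward-strand coordinates.

    ``calls`` holds ``(cpg_position, state)`` pairs with state 'M' or 'U';
    ambiguous calls are dropped at parse time.  ``length`` is the aligned
    reference span, used in the duplicate key.
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    calls: tuple[tuple[int, str], ...]
    length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        pos = [p for p, _ in self.calls]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("call positions must be strictly increasing")
        if any(s not in (METHYLATED, UNMETHYLATED) for _, s in self.calls):
            raise ValueError("states must be M or U")

    @property
    def dedup_key(self) -> tuple[str, int, str, int]:
        return (self.chrom, self.start, self.strand, self.length)


@dataclass(frozen=True)
class Segment:
    """Four consecutive CpGs from a CpGMap; span is [first, last_C+2)."""

    chrom: str
    cpg_positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != 4:
            raise ValueError("a segment holds exactly 4 CpG positions")

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        # include both bases of the last CG dinucleotide
        return self.cpg_positions[-1] + 2

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PatternCluster:
    """Multiset of 4-character M/U patterns observed at one 4-CpG segment."""

    segment: Segment
    patterns: dict[str, int] = field(default_factory=dict)

    def add(self, pattern: str, count: int = 1) -> None:
        if len(pattern) != 4 or any(c not in "MU" for c in pattern):
            raise ValueError(f"bad pattern {pattern!r}")
        self.patterns[pattern] = self.patterns.get(pattern, 0) + count

    @property
    def depth(self) -> int:
        return sum(self.patterns.values())

    def meth_counts(self) -> np.ndarray:
        """Per-read methylated-CpG counts k in 0..4, one entry per read."""
        out = []
        for pat, n in sorted(self.patterns.items()):
            out.extend([pat.count(METHYLATED)] * n)
        return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# CpG map construction

def build_cpg_map(reference_fasta: str | Path | Mapping[str, str]) -> dict[str, CpGMap]:
    """Scan a reference for forward-strand CG dinucleotides.

    Accepts a FASTA path (read through pyfaidx) or a mapping of chrom ->
    sequence, and returns one :class:`CpGMap` per chromosome.
    """
    if isinstance(reference_fasta, Mapping):
        seqs = {c: str(s) for c, s in reference_fasta.items()}
    else:
        from pyfaidx import Fasta

        with Fasta(str(reference_fasta)) as fa:
            seqs = {name: str(fa[name][:]) for name in fa.keys()}
    out = {}
    for chrom, seq in seqs.items():
        positions = tuple(m.start() for m in _CG_RE.finditer(seq.upper()))
        out[chrom] = CpGMap(chrom=chrom, positions=positions)
    return out


# ---------------------------------------------------------------------------
# Per-read call parsing

class UnsupportedRecordError(ValueError):
    """Alignment record lacks the methylation-call information we need."""


def _decode_xm(
    read_id: str,
    chrom: str,
    start: int,
    strand: str,
    xm: str,
    ref_positions: Sequence[int | None],
    cpg_map: CpGMap,
) -> ReadMethCalls:
    """Decode a Bismark XM-style per-base call string.

    'Z' = methylated CpG, 'z' = unmethylated CpG; other codes (CHG/CHH,
    unknown) are ignored for CpG calls.  ``ref_positions`` maps each read
    base to its reference coordinate (None for insertions).  Reverse-strand
    calls sit on the G of the dyad and are shifted to the forward C.
    """
    calls: dict[int, str] = {}
    for code, refpos in zip(xm, ref_positions):
        if refpos is None or code not in "Zz":
            continue
        pos = refpos if strand == "+" else refpos - 1
        if pos in cpg_map:
            calls[pos] = METHYLATED if code == "Z" else UNMETHYLATED
    aligned = [p for p in ref_positions if p is not None]
    length = (max(aligned) - min(aligned) + 1) if aligned else 0
    return ReadMethCalls(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        start=start,
        calls=tuple(sorted(calls.items())),
        length=length,
    )


def parse_read_calls(alignment_record, cpg_map: CpGMap) -> ReadMethCalls:
    """Extract CpG calls from a pysam ``AlignedSegment`` with an XM tag."""
    rec = alignment_record
    if not rec.has_tag("XM"):
        raise UnsupportedRecordError(
            f"read {rec.query_name}: no XM methylation-call tag"
        )
    strand = "-" if rec.is_reverse else "+"
    return _decode_xm(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        start=rec.reference_start,
        strand=strand,
        xm=rec.get_tag("XM"),
        ref_positions=rec.get_reference_positions(full_length=True),
        cpg_map=cpg_map,
    )


def iter_sam_read_calls(
    sam_path: str | Path, cpg_maps: Mapping[str, CpGMap]
) -> Iterator[ReadMethCalls]:
    """Yield :class:`ReadMethCalls` for every mapped record in a SAM/BAM."""
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.reference_name not in cpg_maps:
                continue
            yield parse_read_calls(rec, cpg_maps[rec.reference_name])


def read_calls_tsv(path: str | Path) -> list[ReadMethCalls]:
    """Read the plain per-read call TSV.

    Columns: read_id, chrom, start, strand, length, calls where calls is a
    comma-separated ``pos:state`` list ('.' if the read covers no CpG).
    """
    reads = []
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for row in df.itertuples(index=False):
        calls: tuple[tuple[int, str], ...] = ()
        if row.calls and row.calls != ".":
            calls = tuple(
                (int(p), s)
                for p, s in (item.split(":") for item in row.calls.split(","))
            )
        reads.append(
            ReadMethCalls(
                read_id=row.read_id,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                calls=calls,
                length=int(row.length),
            )
        )
    return reads


def write_calls_tsv(reads: Iterable[ReadMethCalls], path: str | Path) -> None:
    rows = []
    for r in reads:
        calls = ",".join(f"{p}:{s}" for p, s in r.calls) or "."
        rows.append((r.read_id, r.chrom, r.start, r.strand, r.length, calls))
    pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "strand", "length", "calls"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Deduplication and segment extraction

def dedup_reads(reads: Iterable[ReadMethCalls]) -> list[ReadMethCalls]:
    """Drop presumed PCR duplicates.

    At most one read is retained per (chrom, start, strand, length) key; the
    first read encountered wins.  Idempotent.
    """
    seen: set[tuple[str, int, str, int]] = set()
    out = []
    for r in reads:
        key = r.dedup_key
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def extract_segments(
    reads: Iterable[ReadMethCalls],
    cpg_map: CpGMap | Mapping[str, CpGMap],
) -> list[PatternCluster]:
    """Slide a 4-CpG window along every read and cluster patterns by locus.

    For each read, every run of 4 *consecutive* map CpGs that the read calls
    unambiguously contributes one 4-character pattern to that segment's
    cluster.  A read whose calls skip a map CpG inside a window (ambiguous
    or uncovered call) is excluded from that window only.
    """
    maps: Mapping[str, CpGMap]
    if isinstance(cpg_map, CpGMap):
        maps = {cpg_map.chrom: cpg_map}
    else:
        maps = cpg_map
    clusters: dict[tuple[str, tuple[int, ...]], PatternCluster] = {}
    for read in reads:
        cmap = maps.get(read.chrom)
        if cmap is None or len(read.calls) < 4:
            continue
        states = dict(read.calls)
        positions = [p for p, _ in read.calls]
        idx = [cmap.index(p) for p in positions]
        for j in range(len(idx) - 3):
            if idx[j + 3] - idx[j] != 3:
                continue  # a map CpG inside the window lacks a call
            window = tuple(positions[j : j + 4])
            pattern = "".join(states[p] for p in window)
            key = (read.chrom, window)
            cluster = clusters.get(key)
            if cluster is None:
                cluster = PatternCluster(Segment(read.chrom, window))
                clusters[key] = cluster
            cluster.add(pattern)
    return [clusters[k] for k in sorted(clusters)]


# ---------------------------------------------------------------------------
# Methylation levels

UNDEFINED = float("nan")


def segment_meth_levels(
    cluster: PatternCluster,
    ch_calls: Sequence[tuple[int, str]] | None = None,
) -> tuple[float, float]:
    """(mCG level, mCH level) over the segment span.

    mCG level = methylated CpG calls / all CpG calls contributing to the
    cluster's patterns.  mCH uses per-read CH-context calls restricted to the
    span when provided, else NaN.  Zero calls give NaN, never 0.
    """
    total = 4 * cluster.depth
    if total == 0:
        mcg = UNDEFINED
    else:
        meth = sum(pat.count(METHYLATED) * n for pat, n in cluster.patterns.items())
        mcg = meth / total
    if ch_calls is None:
        return mcg, UNDEFINED
    start, end = cluster.segment.span
    in_span = [s for p, s in ch_calls if start <= p < end]
    if not in_span:
        return mcg, UNDEFINED
    mch = sum(s == METHYLATED for s in in_span) / len(in_span)
    return mcg, mch


# ---------------------------------------------------------------------------
# Cluster TSV round-trip

def write_clusters_tsv(clusters: Iterable[PatternCluster], path: str | Path) -> None:
    rows = []
    for c in clusters:
        seg = c.segment
        pats = ";".join(f"{p}:{n}" for p, n in sorted(c.patterns.items()))
        rows.append(
            (
                seg.chrom,
                seg.start,
                seg.end,
                ",".join(map(str, seg.cpg_positions)),
                pats,
                c.depth,
            )
        )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cpg_positions", "patterns", "depth"]
    ).to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path: str | Path) -> list[PatternCluster]:
    clusters = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for row in df.itertuples(index=False):
        seg = Segment(row.chrom, tuple(int(p) for p in row.cpg_positions.split(",")))
        cluster = PatternCluster(seg)
        for item in row.patterns.split(";"):
            pat, n = item.split(":")
            cluster.add(pat, int(n))
        clusters.append(cluster)
    return clusters
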