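"""Small shared interval utilities (0-based half-open, BED conventions)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

BED3 = tuple[str, int, int]


def read_bed(path: str | Path, extra_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Read a BED file into a DataFrame with chrom/start/end + extras.

    ``extra_cols`` names columns 4, 5, ... (e.g. ("name", "score", "strand")).
    """
    names = ["chrom", "start", "end", *extra_cols]
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=names,
        usecols=range(len(names)),
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(intervals: Iterable[BED3]) -> list[BED3]:
    """Merge strictly overlapping intervals per chromosome.

    Abutting intervals ([a,b) and [b,c)) share no base and stay separate.
    Output is sorted and non-overlapping; invariant to input order.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    out: list[BED3] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def build_trees(intervals: Iterable[BED3]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def overlaps_any(
    trees: dict[str, IntervalTree], chrom: str, start: int, end: int
) -> bool:
    """True if [start, end) overlaps any stored interval by >= 1 bp."""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))
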