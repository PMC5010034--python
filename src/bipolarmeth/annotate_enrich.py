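"""Regulatory annotation of CSM regions and GWAS-variant enrichment.

Covers: promoter construction (2 kb upstream of the TSS, split by CpG-island
overlap), chromatin-state classification of merged histone-peak regions,
gene association within 10 kb of TSSs, aggregate pCSM-frequency profiles
around TSSs, and a circular-permutation test for the enrichment of
disease/trait-associated SNPs inside CSM regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bipolar_detect import BipolarCall, CSMRegion
from .intervals import build_trees, merge_intervals, overlaps_any
from .methcall_io import Segment

__all__ = [
    "RegulatoryElement",
    "EnrichmentResult",
    "build_promoters",
    "classify_elements",
    "associate_genes",
    "tss_profile",
    "gwas_enrichment",
    "rank_traits",
]

PROMOTER_SIZE = 2_000
GENE_WINDOW = 10_000
REGION_EXTENSION = 100
SNP_PROXIMITY = 100
N_ITER = 10_000

ELEMENT_CLASSES = (
    "active_promoter_CGI",
    "active_promoter_nonCGI",
    "active_enhancer",
    "poised_enhancer",
)


@dataclass(frozen=True)
class RegulatoryElement:
    chrom: str
    start: int
    end: int
    element_class: str


@dataclass(frozen=True)
class EnrichmentResult:
    trait: str
    observed_count: int
    null_counts: tuple[int, ...]
    p_value: float
    sample_id: str = ""


# ---------------------------------------------------------------------------
# Promoters

def build_promoters(
    tss: pd.DataFrame,
    cgi: Sequence[tuple[str, int, int]] | pd.DataFrame,
    promoter_size: int = PROMOTER_SIZE,
) -> pd.DataFrame:
    """Strand-aware promoters (2 kb upstream of each TSS) with CGI status.

    ``tss`` needs columns chrom, pos, strand, gene_id.  A promoter is CGI
    when it overlaps any CpG island by >= 1 bp.
    """
    if isinstance(cgi, pd.DataFrame):
        cgi = list(cgi[["chrom", "start", "end"]].itertuples(index=False, name=None))
    trees = build_trees(cgi)
    rows = []
    for row in tss.itertuples(index=False):
        if row.strand == "+":
            start, end = max(0, row.pos - promoter_size), row.pos
        else:
            start, end = row.pos + 1, row.pos + 1 + promoter_size
        status = "CGI" if overlaps_any(trees, row.chrom, start, end) else "nonCGI"
        rows.append((row.gene_id, row.chrom, start, end, row.strand, status))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "cgi_status"]
    )


# ---------------------------------------------------------------------------
# Chromatin-state classification

def classify_elements(
    h3k4me1: Sequence[tuple[str, int, int]],
    h3k4me3: Sequence[tuple[str, int, int]],
    h3k27ac: Sequence[tuple[str, int, int]],
    cgi: Sequence[tuple[str, int, int]] = (),
) -> list[RegulatoryElement]:
    """Label merged histone-peak regions by modification occupancy.

    Precedence: H3K4me3 present -> active promoter (CGI vs non-CGI by CpG
    island overlap); else H3K27ac -> active enhancer; else H3K4me1 -> poised
    enhancer.  The three peak sets are first merged into merged-peak
    regions; labels are mutually exclusive per region.
    """
    all_peaks = list(h3k4me1) + list(h3k4me3) + list(h3k27ac)
    merged = merge_intervals(all_peaks)
    t_me1 = build_trees(h3k4me1)
    t_me3 = build_trees(h3k4me3)
    t_ac = build_trees(h3k27ac)
    t_cgi = build_trees(cgi)
    out = []
    for chrom, start, end in merged:
        has_me3 = overlaps_any(t_me3, chrom, start, end)
        has_ac = overlaps_any(t_ac, chrom, start, end)
        has_me1 = overlaps_any(t_me1, chrom, start, end)
        if has_me3:
            cls = (
                "active_promoter_CGI"
                if overlaps_any(t_cgi, chrom, start, end)
                else "active_promoter_nonCGI"
            )
        elif has_ac:
            cls = "active_enhancer"
        elif has_me1:
            cls = "poised_enhancer"
        else:  # unreachable: every merged region came from some peak
            continue
        out.append(RegulatoryElement(chrom, start, end, cls))
    return out


# ---------------------------------------------------------------------------
# Gene association and TSS profiles

def _segment_spans(segments: Iterable[Segment | tuple]) -> list[tuple[str, int, int]]:
    spans = []
    for s in segments:
        if isinstance(s, Segment):
            spans.append((s.chrom, s.start, s.end))
        else:
            spans.append(tuple(s))
    return spans


def associate_genes(
    csm_segments: Iterable[Segment | tuple],
    eligible_segments: Iterable[Segment | tuple],
    tss: pd.DataFrame,
    window: int = GENE_WINDOW,
) -> tuple[list[str], list[str]]:
    """(foreground, background) gene lists.

    Foreground: genes with >= 1 CSM segment within ``window`` bp of the TSS;
    background: genes with >= 1 eligible 4-CpG segment within the window.
    """
    csm_trees = build_trees(_segment_spans(csm_segments))
    elig_trees = build_trees(_segment_spans(eligible_segments))
    fg, bg = [], []
    for row in tss.itertuples(index=False):
        lo, hi = max(0, row.pos - window), row.pos + window + 1
        if overlaps_any(elig_trees, row.chrom, lo, hi):
            bg.append(row.gene_id)
            if overlaps_any(csm_trees, row.chrom, lo, hi):
                fg.append(row.gene_id)
    return fg, bg


def tss_profile(
    calls: Sequence[BipolarCall],
    promoters: pd.DataFrame,
    tss: pd.DataFrame,
    flank: int = 5_000,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Aggregate pCSM frequency in distance bins around TSSs, split by
    promoter CGI status.

    Every eligible segment is assigned, per TSS within ``flank``, to a
    strand-oriented bin by its midpoint (negative = upstream); the per-bin
    frequency is bipolar segments / eligible segments.  Bins with no
    eligible segment are NaN.
    """
    status = promoters.set_index("gene_id")["cgi_status"].to_dict()
    edges = np.linspace(-flank, flank, n_bins + 1)
    counts: dict[str, np.ndarray] = {
        "CGI": np.zeros((2, n_bins)), "nonCGI": np.zeros((2, n_bins))
    }
    by_chrom: dict[str, list[BipolarCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.segment.chrom, []).append(c)
    for row in tss.itertuples(index=False):
        grp = status.get(row.gene_id)
        if grp is None:
            continue
        for call in by_chrom.get(row.chrom, []):
            mid = (call.segment.start + call.segment.end) // 2
            dist = mid - row.pos
            if row.strand == "-":
                dist = -dist
            if not -flank <= dist < flank:
                continue
            b = min(int((dist + flank) / (2 * flank) * n_bins), n_bins - 1)
            counts[grp][0, b] += 1
            counts[grp][1, b] += call.is_bipolar
    rows = []
    for b in range(n_bins):
        center = (edges[b] + edges[b + 1]) / 2
        for grp in ("CGI", "nonCGI"):
            n_elig, n_bip = counts[grp][0, b], counts[grp][1, b]
            freq = n_bip / n_elig if n_elig else float("nan")
            rows.append((b, center, grp, int(n_elig), freq))
    return pd.DataFrame(
        rows, columns=["bin", "center", "cgi_status", "n_eligible", "pcsm_frequency"]
    )


# ---------------------------------------------------------------------------
# GWAS SNP enrichment by circular permutation

def _union_bounds(
    intervals: list[tuple[int, int]], chrom_len: int
) -> np.ndarray:
    """Flattened sorted boundaries of the interval union on a circular
    chromosome; wrapped intervals are split at the origin."""
    flat: list[tuple[int, int]] = []
    for s, e in intervals:
        length = min(e - s, chrom_len)
        s %= chrom_len
        e2 = s + length
        if e2 <= chrom_len:
            flat.append((s, e2))
        else:
            flat.append((s, chrom_len))
            flat.append((0, e2 - chrom_len))
    merged: list[tuple[int, int]] = []
    for s, e in sorted(flat):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return np.asarray([b for iv in merged for b in iv], dtype=np.int64)


def _count_in_union(bounds: np.ndarray, positions: np.ndarray) -> int:
    if bounds.size == 0 or positions.size == 0:
        return 0
    idx = np.searchsorted(bounds, positions, side="right")
    return int(np.count_nonzero(idx % 2 == 1))


def gwas_enrichment(
    regions: Sequence[CSMRegion | tuple],
    snp_table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    n_iter: int = N_ITER,
    extension: int = REGION_EXTENSION,
    proximity: int = SNP_PROXIMITY,
    seed: int = 0,
    sample_id: str = "",
    shifts: str = "random",
) -> list[EnrichmentResult]:
    """Permutation test of SNP overlap with (extended) CSM regions.

    Regions are extended by ``extension`` bp on both sides; a SNP counts
    when within ``proximity`` bp of an extended region (inclusive).  The
    null shifts all regions of a chromosome jointly by one uniform offset
    along the circularized chromosome, preserving region count, lengths and
    spacing; p = (1 + #{null >= observed}) / (1 + n_iter) (add-one so finite
    iterations never report p = 0).

    ``shifts='all'`` enumerates every offset of the (single) chromosome
    instead of sampling — the exhaustive reference for small inputs.

    ``snp_table`` needs columns chrom, pos (1-based), trait; each trait's
    SNPs are deduplicated by (chrom, pos).
    """
    margin = extension + proximity
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        chrom, start, end = (
            (r.chrom, r.start, r.end) if isinstance(r, CSMRegion) else tuple(r)[:3]
        )
        # inclusive proximity: [start - margin, end + margin]
        by_chrom.setdefault(chrom, []).append((start - margin, end + margin + 1))
    for chrom in by_chrom:
        if chrom not in chrom_sizes:
            raise KeyError(f"no size for chromosome {chrom}")

    snp_pos: dict[str, dict[str, np.ndarray]] = {}
    for trait, grp in snp_table.groupby("trait"):
        uniq = grp.drop_duplicates(subset=["chrom", "pos"])
        if uniq.empty:
            warnings.warn(f"trait {trait!r} has no SNPs; skipped")
            continue
        snp_pos[trait] = {
            chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64) - 1)  # to 0-based
            for chrom, sub in uniq.groupby("chrom")
        }

    chroms = sorted(by_chrom)
    if shifts == "all":
        if len(chroms) != 1:
            raise ValueError("exhaustive shifts require a single chromosome")
        L = chrom_sizes[chroms[0]]
        offsets = np.arange(L, dtype=np.int64)[:, None]
        n_null = L
    elif shifts == "random":
        rng = np.random.default_rng(seed)
        offsets = np.column_stack(
            [rng.integers(0, chrom_sizes[c], size=n_iter) for c in chroms]
        )
        n_null = n_iter
    else:
        raise ValueError("shifts must be 'random' or 'all'")

    # per-iteration union bounds per chromosome
    null_bounds = []
    for it in range(n_null):
        bounds = {}
        for ci, chrom in enumerate(chroms):
            L = chrom_sizes[chrom]
            off = int(offsets[it, ci])
            shifted = [(s + off, e + off) for s, e in by_chrom[chrom]]
            bounds[chrom] = _union_bounds(shifted, L)
        null_bounds.append(bounds)
    obs_bounds = {
        chrom: _union_bounds(by_chrom[chrom], chrom_sizes[chrom])
        for chrom in chroms
    }

    results = []
    for trait in sorted(snp_pos):
        positions = snp_pos[trait]
        observed = sum(
            _count_in_union(obs_bounds[c], positions[c])
            for c in positions if c in obs_bounds
        )
        null = np.empty(n_null, dtype=np.int64)
        for it in range(n_null):
            null[it] = sum(
                _count_in_union(null_bounds[it][c], positions[c])
                for c in positions if c in null_bounds[it]
            )
        p = (1 + int(np.count_nonzero(null >= observed))) / (1 + n_null)
        results.append(
            EnrichmentResult(
                trait=trait,
                observed_count=int(observed),
                null_counts=tuple(int(x) for x in null),
                p_value=p,
                sample_id=sample_id,
            )
        )
    return results


def rank_traits(
    results: Iterable[EnrichmentResult],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Rank traits by the number of samples in which they are significant,
    ties broken by mean p (ascending).

    ``correction='bh'`` applies Benjamini-Hochberg within each sample before
    counting; the default counts raw p <= alpha.
    """
    df = pd.DataFrame(
        [(r.trait, r.sample_id, r.p_value) for r in results],
        columns=["trait", "sample_id", "p_value"],
    )
    if df.empty:
        return pd.DataFrame(columns=["trait", "n_significant", "mean_p"])
    if correction == "bh":
        from scipy.stats import false_discovery_control

        df["p_adj"] = df.groupby("sample_id")["p_value"].transform(
            lambda p: false_discovery_control(p, method="bh")
        )
        df["sig"] = df["p_adj"] <= alpha
    elif correction is None:
        df["sig"] = df["p_value"] <= alpha
    else:
        raise ValueError("correction must be None or 'bh'")
    agg = (
        df.groupby("trait")
        .agg(n_significant=("sig", "sum"), mean_p=("p_value", "mean"))
        .reset_index()
    )
    return agg.sort_values(
        ["n_significant", "mean_p", "trait"], ascending=[False, True, True]
    ).reset_index(drop=True)
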