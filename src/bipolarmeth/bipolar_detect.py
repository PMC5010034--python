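"""Bipolar (cell-subset specific) methylation calls on 4-CpG pattern clusters.

A cluster of per-read 4-CpG patterns is *bipolar* when its reads resolve
into a hypomethylated and a hypermethylated component, each carrying a
non-trivial share of the molecules — the signature of a locus methylated in
one cell subset and unmethylated in another within a mixed tissue.

The classifier models the per-read methylated-CpG count k in {0..4} as a
mixture of Beta-Binomial components (4 trials per read):

* ``dp_gibbs`` (default) — Dirichlet-process mixture fit by collapsed Gibbs
  sampling (concentration alpha=1, Beta(1/2, 1/2) base measure).  After
  burn-in, bipolarity is the posterior majority vote across retained sweeps.
* ``em_bic`` — finite binomial mixtures K=1..3 fit by EM, model chosen by
  BIC.  Deterministic, no sampling.
* ``lrt_oracle`` — exhaustive threshold-partition two-component maximum
  likelihood with a BIC gate; the slow reference path used for testing.

All methods are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .intervals import build_trees, merge_intervals, overlaps_any, read_bed
from .methcall_io import PatternCluster, Segment

__all__ = [
    "BipolarCall",
    "CSMRegion",
    "CSMProfile",
    "prefilter",
    "classify_bipolar",
    "filter_calls",
    "merge_regions",
    "pcsm_frequency",
    "profile_correlation",
    "write_calls_table",
]

FULLY_METHYLATED = "MMMM"
FULLY_UNMETHYLATED = "UUUU"

# default bipolarity thresholds; the prefilter is the only part the source
# procedure pins down, these bracket "completely (un)methylated" components
# with tolerance for conversion error
HYPO_MAX = 0.25
HYPER_MIN = 0.75
W_MIN = 0.10

N_TRIALS = 4  # CpGs per segment read


@dataclass(frozen=True)
class BipolarCall:
    segment: Segment
    is_bipolar: bool
    component_means: tuple[float, ...]
    component_weights: tuple[float, ...]
    hypo_weight: float
    hyper_weight: float
    method: str
    depth: int
    prefilter_passed: bool

    def __post_init__(self) -> None:
        if self.component_weights and abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.is_bipolar and not self.prefilter_passed:
            raise ValueError("a bipolar call requires a passed prefilter")


@dataclass(frozen=True)
class CSMRegion:
    chrom: str
    start: int
    end: int
    n_segments: int
    sample_id: str = ""


@dataclass
class CSMProfile:
    """Per-segment bipolar status for one sample over a shared universe.

    ``status`` maps a segment key (chrom, 4 CpG positions) to True/False;
    segments without adequate coverage in this sample are simply absent.
    """

    sample_id: str
    status: dict[tuple[str, tuple[int, ...]], bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Prefilter

def prefilter(cluster: PatternCluster, min_depth: int = 10) -> bool:
    """Depth >= min_depth with at least one fully methylated AND one fully
    unmethylated read present concurrently."""
    return (
        cluster.depth >= min_depth
        and cluster.patterns.get(FULLY_METHYLATED, 0) >= 1
        and cluster.patterns.get(FULLY_UNMETHYLATED, 0) >= 1
    )


# ---------------------------------------------------------------------------
# Collapsed Gibbs for the DP Beta-Binomial mixture

_TABLE_SIZE = 4096
_LG_HALF = [math.lgamma(i + 0.5) for i in range(_TABLE_SIZE)]
_LG_INT = [0.0] + [math.lgamma(i) for i in range(1, _TABLE_SIZE)]
_LOG_CHOOSE4 = np.log([math.comb(4, k) for k in range(5)])
_LOG_CHOOSE4_L = _LOG_CHOOSE4.tolist()


def _log_predictive(k: int, s: int, f: int) -> float:
    """log P(new read has count k | cluster with S methylated, F unmethylated
    calls) under Binomial(4, p) likelihood and Beta(1/2, 1/2) prior on p.

    = log C(4,k) + log B(1/2+S+k, 1/2+F+4-k) - log B(1/2+S, 1/2+F)
    """
    return (
        _LOG_CHOOSE4_L[k]
        + _LG_HALF[s + k]
        + _LG_HALF[f + 4 - k]
        - _LG_INT[s + f + 5]
        - _LG_HALF[s]
        - _LG_HALF[f]
        + _LG_INT[s + f + 1]
    )


def _state_is_bipolar(
    sizes: Sequence[int], sums: Sequence[int], n: int,
    hypo_max: float, hyper_min: float, w_min: float,
) -> tuple[bool, float, float]:
    """Check one Gibbs state for a hypo and a hyper component.

    Component mean is the posterior mean (S + 1/2) / (4m + 1); weight m/n.
    Returns (bipolar, hypo weight, hyper weight).
    """
    hypo_w = hyper_w = 0.0
    for m, s in zip(sizes, sums):
        if m == 0:
            continue
        mean = (s + 0.5) / (4 * m + 1.0)
        w = m / n
        if mean <= hypo_max:
            hypo_w += w
        elif mean >= hyper_min:
            hyper_w += w
    return (hypo_w >= w_min and hyper_w >= w_min), hypo_w, hyper_w


def _dp_gibbs(
    counts: np.ndarray,
    rng: np.random.Generator,
    alpha: float,
    n_sweeps: int,
    burn_in: int,
    hypo_max: float,
    hyper_min: float,
    w_min: float,
) -> tuple[bool, list[int], list[int]]:
    """Collapsed Gibbs over cluster assignments; returns the posterior
    majority bipolar vote plus the final sweep's cluster (sizes, sums)."""
    n = len(counts)
    assign = np.zeros(n, dtype=np.int64)  # start all in one cluster
    sizes = [n]
    sums = [int(counts.sum())]
    votes = 0
    n_votes = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            k = int(counts[i])
            c = assign[i]
            sizes[c] -= 1
            sums[c] -= k
            # candidate log-weights: existing clusters then a new one
            logw = [
                math.log(m) + _log_predictive(k, s, 4 * m - s) if m > 0 else -math.inf
                for m, s in zip(sizes, sums)
            ]
            logw.append(math.log(alpha) + _log_predictive(k, 0, 0))
            top = max(logw)
            w = [math.exp(x - top) for x in logw]
            u = rng.random() * sum(w)
            acc = 0.0
            choice = len(w) - 1
            for j, wj in enumerate(w):
                acc += wj
                if u <= acc:
                    choice = j
                    break
            if choice == len(sizes):
                sizes.append(0)
                sums.append(0)
            assign[i] = choice
            sizes[choice] += 1
            sums[choice] += k
        # drop empty clusters to keep the candidate list short
        keep = [j for j, m in enumerate(sizes) if m > 0]
        remap = {j: r for r, j in enumerate(keep)}
        sizes = [sizes[j] for j in keep]
        sums = [sums[j] for j in keep]
        assign = np.asarray([remap[c] for c in assign], dtype=np.int64)
        if sweep >= burn_in:
            bip, _, _ = _state_is_bipolar(
                sizes, sums, n, hypo_max, hyper_min, w_min
            )
            votes += bip
            n_votes += 1
    return votes * 2 > n_votes, sizes, sums


# ---------------------------------------------------------------------------
# Finite binomial mixture via EM + BIC

def _binom_mix_loglik(counts: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    k = counts[:, None]
    comp = (
        _LOG_CHOOSE4[counts][:, None]
        + k * np.log(np.clip(p, 1e-12, None))[None, :]
        + (4 - k) * np.log(np.clip(1 - p, 1e-12, None))[None, :]
    )
    return float(np.logaddexp.reduce(comp + np.log(w)[None, :], axis=1).sum())


def _em_fit(
    counts: np.ndarray, p0: np.ndarray, w0: np.ndarray,
    max_iter: int = 200, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    p, w = p0.copy(), w0.copy()
    ll = -np.inf
    for _ in range(max_iter):
        k = counts[:, None]
        logr = (
            _LOG_CHOOSE4[counts][:, None]
            + k * np.log(np.clip(p, 1e-12, None))[None, :]
            + (4 - k) * np.log(np.clip(1 - p, 1e-12, None))[None, :]
            + np.log(np.clip(w, 1e-12, None))[None, :]
        )
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        r /= r.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0)
        w = nk / nk.sum()
        # posterior-mean update with the Beta(1/2,1/2) prior keeps p off 0/1
        p = (r.T @ counts + 0.5) / (4 * nk + 1.0)
        new_ll = _binom_mix_loglik(counts, p, w)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return p, w, ll


def _em_bic(
    counts: np.ndarray, k_max: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Fit K=1..k_max binomial mixtures, return (means, weights) of the
    BIC-best model.  Initialisation is deterministic (quantile spread)."""
    n = len(counts)
    best = None
    for K in range(1, k_max + 1):
        qs = (np.arange(K) + 0.5) / K
        p0 = np.clip(np.quantile(counts / 4.0, qs), 0.02, 0.98)
        w0 = np.full(K, 1.0 / K)
        p, w, ll = _em_fit(counts, p0, w0)
        n_params = 2 * K - 1
        bic = -2 * ll + n_params * math.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, p, w)
    _, p, w = best
    return p, w


# ---------------------------------------------------------------------------
# Exhaustive two-component threshold oracle

def _lrt_oracle(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best two-component fit over every threshold partition of k, refined
    by EM; falls back to one component when BIC prefers it."""
    n = len(counts)
    p1 = np.array([(counts.sum() + 0.5) / (4 * n + 1.0)])
    ll1 = _binom_mix_loglik(counts, p1, np.array([1.0]))
    best2 = None
    for t in range(1, 5):
        lo = counts[counts < t]
        hi = counts[counts >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        p0 = np.array(
            [(lo.sum() + 0.5) / (4 * len(lo) + 1.0),
             (hi.sum() + 0.5) / (4 * len(hi) + 1.0)]
        )
        w0 = np.array([len(lo) / n, len(hi) / n])
        p, w, ll = _em_fit(counts, p0, w0)
        if best2 is None or ll > best2[0]:
            best2 = (ll, p, w)
    if best2 is None:
        return p1, np.array([1.0])
    ll2, p2, w2 = best2
    bic1 = -2 * ll1 + 1 * math.log(n)
    bic2 = -2 * ll2 + 3 * math.log(n)
    if bic2 < bic1:
        return p2, w2
    return p1, np.array([1.0])


# ---------------------------------------------------------------------------
# Public classifier

def classify_bipolar(
    cluster: PatternCluster,
    seed: int = 0,
    method: str = "dp_gibbs",
    *,
    min_depth: int = 10,
    hypo_max: float = HYPO_MAX,
    hyper_min: float = HYPER_MIN,
    w_min: float = W_MIN,
    alpha: float = 1.0,
    n_sweeps: int = 200,
    burn_in: int = 100,
    depth_cap: int = 500,
) -> BipolarCall:
    """Classify one prefiltered cluster as bipolar or not.

    Raises ``ValueError`` if the cluster does not pass the prefilter; callers
    decide what to do with non-eligible clusters.
    """
    if not prefilter(cluster, min_depth=min_depth):
        raise ValueError("classify_bipolar requires a cluster passing the prefilter")
    counts = np.sort(cluster.meth_counts())  # sort: order-invariance by construction
    rng = np.random.default_rng(np.random.SeedSequence((seed, _cluster_key(cluster))))
    if len(counts) > depth_cap:
        counts = np.sort(rng.choice(counts, size=depth_cap, replace=False))
    n = len(counts)

    if method == "dp_gibbs":
        is_bip, sizes, sums = _dp_gibbs(
            counts, rng, alpha, n_sweeps, burn_in, hypo_max, hyper_min, w_min
        )
        order = np.argsort([(s + 0.5) / (4 * m + 1.0) for m, s in zip(sizes, sums)])
        means = tuple(
            (sums[j] + 0.5) / (4 * sizes[j] + 1.0) for j in order
        )
        weights = tuple(sizes[j] / n for j in order)
    elif method in ("em_bic", "lrt_oracle"):
        fit = _em_bic(counts) if method == "em_bic" else _lrt_oracle(counts)
        p, w = fit
        order = np.argsort(p)
        means = tuple(float(p[j]) for j in order)
        weights = tuple(float(w[j]) for j in order)
        is_bip = _components_bipolar(means, weights, hypo_max, hyper_min, w_min)
    else:
        raise ValueError(f"unknown method {method!r}")

    hypo_w = sum(w for m, w in zip(means, weights) if m <= hypo_max)
    hyper_w = sum(w for m, w in zip(means, weights) if m >= hyper_min)
    return BipolarCall(
        segment=cluster.segment,
        is_bipolar=bool(is_bip),
        component_means=means,
        component_weights=weights,
        hypo_weight=hypo_w,
        hyper_weight=hyper_w,
        method=method,
        depth=cluster.depth,
        prefilter_passed=True,
    )


def _components_bipolar(
    means: Sequence[float], weights: Sequence[float],
    hypo_max: float, hyper_min: float, w_min: float,
) -> bool:
    hypo = sum(w for m, w in zip(means, weights) if m <= hypo_max)
    hyper = sum(w for m, w in zip(means, weights) if m >= hyper_min)
    return hypo >= w_min and hyper >= w_min


def _cluster_key(cluster: PatternCluster) -> int:
    """Stable per-segment stream key so per-cluster RNG does not depend on
    processing order."""
    import zlib

    seg = cluster.segment
    tag = f"{seg.chrom}:{','.join(map(str, seg.cpg_positions))}"
    return zlib.crc32(tag.encode())


# ---------------------------------------------------------------------------
# Filtering, merging, summarising

def filter_calls(
    calls: Iterable[BipolarCall],
    sex_chroms: Sequence[str] = ("chrX", "chrY"),
    imprinted_bed: str | Path | Sequence[tuple[str, int, int]] | None = None,
) -> list[BipolarCall]:
    """Drop calls on excluded chromosomes or overlapping imprinted regions.

    Imprinted loci show parent-of-origin allele-specific methylation that
    mimics bipolarity without reflecting cell-subset differences.
    """
    if imprinted_bed is None:
        intervals: list[tuple[str, int, int]] = []
    elif isinstance(imprinted_bed, (str, Path)):
        df = read_bed(imprinted_bed)
        intervals = list(df[["chrom", "start", "end"]].itertuples(index=False, name=None))
    else:
        intervals = list(imprinted_bed)
    trees = build_trees(intervals)
    excluded = set(sex_chroms)
    out = []
    for call in calls:
        seg = call.segment
        if seg.chrom in excluded:
            continue
        if overlaps_any(trees, seg.chrom, seg.start, seg.end):
            continue
        out.append(call)
    return out


def merge_regions(
    bipolar_segments: Iterable[Segment], sample_id: str = ""
) -> list[CSMRegion]:
    """Merge overlapping bipolar segments into maximal CSM regions."""
    segs = list(bipolar_segments)
    merged = merge_intervals((s.chrom, s.start, s.end) for s in segs)
    # count contributing segments per merged region
    out = []
    for chrom, start, end in merged:
        n = sum(
            1 for s in segs if s.chrom == chrom and s.start < end and s.end > start
        )
        out.append(CSMRegion(chrom, start, end, n_segments=n, sample_id=sample_id))
    return out


def pcsm_frequency(
    calls: Iterable[BipolarCall], eligible_clusters: Sequence[PatternCluster]
) -> float:
    """Fraction of eligible (>=10x) segments called bipolar after filtering."""
    n_eligible = len(eligible_clusters)
    if n_eligible == 0:
        return float("nan")
    n_bipolar = sum(c.is_bipolar for c in calls)
    return n_bipolar / n_eligible


def profile_correlation(
    profiles: Sequence[CSMProfile],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of bipolar-status vectors + dendrogram
    leaf order from average-linkage clustering on 1 - r.

    r is computed on segments with a defined status in both samples; pairs
    with < 2 shared segments raise, zero-variance vectors give NaN.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    # deterministic tie-breaks downstream: sort samples lexicographically
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(profiles[i].status) & set(profiles[j].status))
            if len(shared) < 2:
                raise ValueError(
                    f"profiles {ids[i]} and {ids[j]} share fewer than 2 segments"
                )
            x = np.array([profiles[i].status[k] for k in shared], dtype=float)
            y = np.array([profiles[j].status[k] for k in shared], dtype=float)
            if x.std() == 0 or y.std() == 0:
                rij = np.nan
            else:
                rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
    corr = pd.DataFrame(r, index=ids, columns=ids)
    dist = 1.0 - np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    return corr, [ids[i] for i in order]


def write_calls_table(calls: Iterable[BipolarCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        seg = c.segment
        rows.append(
            (
                seg.chrom, seg.start, seg.end,
                ",".join(map(str, seg.cpg_positions)),
                c.depth, int(c.is_bipolar), c.method,
                ";".join(f"{m:.4f}" for m in c.component_means),
                ";".join(f"{w:.4f}" for w in c.component_weights),
                f"{c.hypo_weight:.4f}", f"{c.hyper_weight:.4f}",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "cpg_positions", "depth", "is_bipolar",
            "method", "component_means", "component_weights",
            "hypo_weight", "hyper_weight",
        ],
    ).to_csv(path, sep="\t", index=False)
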