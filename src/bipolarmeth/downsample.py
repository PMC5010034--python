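"""Down-sampling normalization of sequencing depth across methylomes.

The chance of observing a bipolar pattern at a 4-CpG segment grows with
depth, so raw bipolar-segment frequencies are not comparable between
samples sequenced to different depths.  The normalization restricts to
segments covered >= min_depth in *all* samples, finds each segment's
minimum depth D_min across samples, repeatedly subsamples every sample's
cluster down to D_min, and reports the fraction of repeats in which the
segment is (still) called bipolar — the *detection probability*.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bipolar_detect import classify_bipolar, prefilter
from .methcall_io import PatternCluster

__all__ = [
    "CommonSegmentSet",
    "DetectionEstimate",
    "common_segments",
    "downsample_cluster",
    "detection_probability",
    "normalized_frequency",
]

SegKey = tuple[str, tuple[int, ...]]


def _seg_key(cluster: PatternCluster) -> SegKey:
    seg = cluster.segment
    return (seg.chrom, tuple(seg.cpg_positions))


@dataclass
class CommonSegmentSet:
    """Segments covered >= min_depth in every sample, with per-sample depth
    and the per-segment minimum depth D_min."""

    min_depth: int
    depths: dict[SegKey, dict[str, int]] = field(default_factory=dict)

    @property
    def segments(self) -> list[SegKey]:
        return sorted(self.depths)

    def d_min(self, key: SegKey) -> int:
        return min(self.depths[key].values())


@dataclass(frozen=True)
class DetectionEstimate:
    segment: SegKey
    sample: str
    detection_probability: float
    n_repeats: int


def common_segments(
    cluster_sets: Mapping[str, Sequence[PatternCluster]],
    min_depth: int = 10,
) -> CommonSegmentSet:
    """Intersect eligible segments across samples."""
    if len(cluster_sets) < 2:
        raise ValueError("need at least two samples")
    per_sample: dict[str, dict[SegKey, int]] = {
        sample: {
            _seg_key(c): c.depth
            for c in clusters
            if c.depth >= min_depth
        }
        for sample, clusters in cluster_sets.items()
    }
    keys = set.intersection(*(set(d) for d in per_sample.values()))
    out = CommonSegmentSet(min_depth=min_depth)
    if not keys:
        import warnings

        warnings.warn("no segment is covered in all samples at this depth")
    for key in keys:
        out.depths[key] = {s: per_sample[s][key] for s in cluster_sets}
    return out


def _stream_rng(
    seed: int, sample: str, key: SegKey, repeat: int | None = None
) -> np.random.Generator:
    """Per-(segment, sample[, repeat]) RNG stream derived from a master seed,
    so adding samples or segments does not perturb existing results."""
    tag = f"{sample}|{key[0]}:{','.join(map(str, key[1]))}"
    entropy = [seed, zlib.crc32(tag.encode())]
    if repeat is not None:
        entropy.append(repeat)
    return np.random.default_rng(np.random.SeedSequence(tuple(entropy)))


def downsample_cluster(
    cluster: PatternCluster,
    target_depth: int,
    rng: np.random.Generator | int,
) -> PatternCluster:
    """Uniform subsample of reads without replacement down to target_depth."""
    if target_depth > cluster.depth:
        raise ValueError(
            f"target depth {target_depth} exceeds cluster depth {cluster.depth}"
        )
    if target_depth == cluster.depth:
        return PatternCluster(cluster.segment, dict(cluster.patterns))
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    expanded = [p for pat, n in sorted(cluster.patterns.items()) for p in [pat] * n]
    chosen = rng.choice(len(expanded), size=target_depth, replace=False)
    out = PatternCluster(cluster.segment)
    for i in chosen:
        out.add(expanded[i])
    return out


def detection_probability(
    cluster: PatternCluster,
    target_depth: int,
    n_repeats: int = 100,
    seed: int = 0,
    sample: str = "",
    mode: str = "full",
    classifier_kwargs: dict | None = None,
) -> DetectionEstimate:
    """Fraction of down-sampling repeats in which the segment is called
    bipolar at target_depth.

    mode 'full' reruns prefilter + mixture classifier on every subsample;
    'prefilter' checks only the >=1 fully-methylated + >=1 fully-unmethylated
    (and depth) gate, for which an exact hypergeometric answer exists.
    """
    if mode not in ("full", "prefilter"):
        raise ValueError("mode must be 'full' or 'prefilter'")
    kwargs = dict(classifier_kwargs or {})
    kwargs.setdefault("min_depth", min(10, target_depth))
    key = _seg_key(cluster)
    hits = 0
    for rep in range(n_repeats):
        rng = _stream_rng(seed, sample, key, rep)
        sub = downsample_cluster(cluster, target_depth, rng)
        if not prefilter(sub, min_depth=kwargs["min_depth"]):
            continue
        if mode == "prefilter":
            hits += 1
        else:
            call = classify_bipolar(sub, seed=seed, **kwargs)
            hits += call.is_bipolar
    return DetectionEstimate(
        segment=key,
        sample=sample,
        detection_probability=hits / n_repeats,
        n_repeats=n_repeats,
    )


def normalized_frequency(
    estimates: Iterable[DetectionEstimate],
    aggregation: str = "mean",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sample normalized bipolar frequency over the common segment set.

    'mean' averages detection probabilities; 'count' reports the fraction of
    segments with detection probability > threshold.
    """
    df = pd.DataFrame(
        [
            (e.sample, e.detection_probability)
            for e in estimates
        ],
        columns=["sample", "p"],
    )
    if df.empty:
        return pd.DataFrame(columns=["sample", "frequency", "n_segments"])
    if aggregation == "mean":
        agg = df.groupby("sample")["p"].agg(["mean", "size"])
    elif aggregation == "count":
        agg = df.assign(hit=df["p"] > threshold).groupby("sample")["hit"].agg(
            ["mean", "size"]
        )
    else:
        raise ValueError("aggregation must be 'mean' or 'count'")
    agg.columns = ["frequency", "n_segments"]
    return agg.reset_index()
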