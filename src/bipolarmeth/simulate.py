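"""Synthetic data with the statistical structure the detection method assumes.

The bulk-read generator emulates a mixed cell population: every molecule
originates from one cell subset, and a cell-subset specific methylated (CSM)
segment has a high methylation probability in one subset and a low one in
the other, while uniform segments share a single probability across subsets.
The hairpin generator emits read pairs from double-stranded molecules with
planted per-dyad strand states, loop-adapter read-through and bisulfite
conversion failures.  Truth tables accompany every output so downstream
operations can be scored without re-deriving ground truth.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hairpin import HAIRPIN_ADAPTER, DyadCall, HairpinReadPair, revcomp
from .methcall_io import CpGMap, PatternCluster, ReadMethCalls, Segment

__all__ = [
    "SimConfig",
    "SubsetModel",
    "BulkSim",
    "HairpinSim",
    "simulate_genome",
    "simulate_bulk_reads",
    "simulate_hairpin_pairs",
    "simulate_snps",
    "write_fastq",
    "write_sam",
]

BASES = np.array(list("ACGT"))

# Illumina TruSeq adapter stub seen on 3' read-through past a short insert
SEQ_ADAPTER = "AGATCGGAAGAGCACACGTCT"


@dataclass
class SimConfig:
    """Shared generator knobs.  Defaults are the study conditions used
    throughout the test suite."""

    genome_length: int = 100_000
    cpg_density: float = 0.02
    read_length: int = 120
    depth: int = 20
    conversion_failure_rate: float = 0.003  # 99.7% conversion
    duplicate_rate: float = 0.0
    dyad_asymmetry_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cpg_density", "conversion_failure_rate",
            "duplicate_rate", "dyad_asymmetry_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SubsetModel:
    """Two-subset mixture: CSM segments have subset-specific methylation
    probabilities (p_hi in one subset, p_lo in the other), uniform segments
    share ``uniform_p`` across subsets.  Mixing proportion is drawn per
    segment from ``mixing_range``."""

    p_hi: float = 0.95
    p_lo: float = 0.05
    uniform_p: float = 0.5
    mixing_range: tuple[float, float] = (0.3, 0.7)
    within_read_correlation: float = 0.0


# ---------------------------------------------------------------------------
# Genome

@dataclass
class SimGenome:
    sequences: dict[str, str]
    cpg_maps: dict[str, CpGMap]
    tss: pd.DataFrame
    cgi: list[tuple[str, int, int]]
    imprinted: list[tuple[str, int, int]]
    peaks: dict[str, list[tuple[str, int, int]]]


def _random_sequence(length: int, cpg_density: float, rng: np.random.Generator) -> str:
    """Random sequence whose only CG dinucleotides are the planted ones,
    at an expected rate of ``cpg_density`` per base."""
    out: list[str] = []
    plant_p = cpg_density / (1 - cpg_density) if cpg_density < 1 else 1.0
    while len(out) < length:
        if rng.random() < plant_p and len(out) + 2 <= length:
            out.append("C")
            out.append("G")
        else:
            b = str(rng.choice(BASES))
            # avoid creating an accidental CG (and a C that the next planted
            # CG's C would not disturb but a random G would complete)
            while (out and out[-1] == "C" and b == "G"):
                b = str(rng.choice(BASES))
            out.append(b)
    return "".join(out[:length])


def simulate_genome(
    config: SimConfig,
    chroms: Sequence[str] = ("chr1",),
    n_genes: int = 20,
    n_cgi: int = 10,
    n_imprinted: int = 5,
    n_peaks: int = 15,
) -> SimGenome:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    sequences = {
        c: _random_sequence(config.genome_length, config.cpg_density, rng)
        for c in chroms
    }
    from .methcall_io import build_cpg_map

    cpg_maps = build_cpg_map(sequences)
    L = config.genome_length
    tss_rows = []
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        pos = int(rng.integers(5_000, max(5_001, L - 5_000)))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append((chrom, pos, strand, f"gene{i}"))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene_id"])

    def random_intervals(n: int, lo: int, hi: int) -> list[tuple[str, int, int]]:
        out = []
        for _ in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            width = int(rng.integers(lo, hi))
            start = int(rng.integers(0, max(1, L - width)))
            out.append((chrom, start, start + width))
        return out

    cgi = random_intervals(n_cgi, 300, 1_500)
    imprinted = random_intervals(n_imprinted, 500, 3_000)
    peaks = {
        mark: random_intervals(n_peaks, 200, 2_000)
        for mark in ("H3K4me1", "H3K4me3", "H3K27ac")
    }
    return SimGenome(sequences, cpg_maps, tss, cgi, imprinted, peaks)


# ---------------------------------------------------------------------------
# Bulk bisulfite reads

@dataclass
class BulkSim:
    reads: list[ReadMethCalls]
    segments: pd.DataFrame  # chrom, cpg_positions, is_csm, p_hi, p_lo, mixing
    read_truth: pd.DataFrame  # read_id, segment_index, subset, is_duplicate
    cpg_map: CpGMap

    def truth_segments(self) -> list[Segment]:
        return [
            Segment(r.chrom, tuple(int(p) for p in r.cpg_positions.split(",")))
            for r in self.segments.itertuples(index=False)
        ]


def simulate_bulk_reads(
    model: SubsetModel,
    config: SimConfig,
    n_csm_segments: int = 50,
    n_uniform_segments: int = 50,
    chrom: str = "chr1",
    cpg_spacing: int = 10,
    segment_gap: int = 200,
) -> BulkSim:
    """Reads over well-separated 4-CpG segments from a two-subset mixture.

    Segments are laid out left to right, each with 4 CpGs ``cpg_spacing``
    apart and ``segment_gap`` bp to the next segment, so every read covers
    exactly one segment.  Each read draws its subset from the segment's
    mixing proportion; CpG states are Bernoulli with the subset's
    probability (optionally with a shared within-read draw), a conversion
    failure flips U to M, and duplicates re-emit an existing read under a
    new id at the configured rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    n_seg = n_csm_segments + n_uniform_segments
    is_csm = np.zeros(n_seg, dtype=bool)
    is_csm[:n_csm_segments] = True
    rng.shuffle(is_csm)

    positions: list[int] = []
    seg_rows = []
    cursor = 100
    for i in range(n_seg):
        cpgs = tuple(cursor + j * cpg_spacing for j in range(4))
        positions.extend(cpgs)
        mixing = float(rng.uniform(*model.mixing_range))
        if is_csm[i]:
            # which subset is the hypermethylated one alternates randomly
            hi_first = bool(rng.random() < 0.5)
            p_a = model.p_hi if hi_first else model.p_lo
            p_b = model.p_lo if hi_first else model.p_hi
        else:
            p_a = p_b = model.uniform_p
        seg_rows.append(
            (chrom, ",".join(map(str, cpgs)), bool(is_csm[i]), p_a, p_b, mixing)
        )
        cursor = cpgs[-1] + segment_gap
    cpg_map = CpGMap(chrom, tuple(positions))
    segments = pd.DataFrame(
        seg_rows,
        columns=["chrom", "cpg_positions", "is_csm", "p_subset_a", "p_subset_b", "mixing"],
    )

    reads: list[ReadMethCalls] = []
    truth_rows = []
    read_n = 0
    for i, seg in enumerate(segments.itertuples(index=False)):
        cpgs = [int(p) for p in seg.cpg_positions.split(",")]
        start = cpgs[0] - 2
        length = cpgs[-1] + 2 - start
        for d in range(config.depth):
            subset = "a" if rng.random() < seg.mixing else "b"
            p = seg.p_subset_a if subset == "a" else seg.p_subset_b
            if model.within_read_correlation > 0 and rng.random() < model.within_read_correlation:
                state = rng.random() < p
                states = [state] * 4
            else:
                states = list(rng.random(4) < p)
            # bisulfite conversion failure: an unmethylated C escapes
            # conversion and reads as methylated
            states = [
                True if (not s and rng.random() < config.conversion_failure_rate)
                else s
                for s in states
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            read_id = f"read{read_n}"
            read_n += 1
            calls = tuple(
                (pos, "M" if s else "U") for pos, s in zip(cpgs, states)
            )
            # stagger starts by read index so distinct molecules never share
            # a dedup key; only injected duplicates collide
            reads.append(
                ReadMethCalls(
                    read_id=read_id, chrom=chrom, strand=strand,
                    start=start - d, calls=calls, length=length + d,
                )
            )
            truth_rows.append((read_id, i, subset, False))
    # injected PCR duplicates: exact copies under fresh ids
    if config.duplicate_rate > 0 and reads:
        n_dup = int(round(config.duplicate_rate * len(reads)))
        for j in range(n_dup):
            src = reads[int(rng.integers(len(reads)))]
            read_id = f"dup{j}"
            reads.append(
                ReadMethCalls(
                    read_id=read_id, chrom=src.chrom, strand=src.strand,
                    start=src.start, calls=src.calls, length=src.length,
                )
            )
            truth_rows.append((read_id, -1, "dup", True))
    read_truth = pd.DataFrame(
        truth_rows, columns=["read_id", "segment_index", "subset", "is_duplicate"]
    )
    return BulkSim(reads, segments, read_truth, cpg_map)


def clusters_from_bulk(sim: BulkSim) -> list[PatternCluster]:
    """Ground-truth pattern clusters (duplicates excluded), bypassing the
    extraction pipeline — for tests that target the classifier alone."""
    by_seg: dict[int, PatternCluster] = {}
    segs = sim.truth_segments()
    calls_by_read = {r.read_id: r for r in sim.reads}
    for row in sim.read_truth.itertuples(index=False):
        if row.is_duplicate:
            continue
        read = calls_by_read[row.read_id]
        pattern = "".join(s for _, s in read.calls)
        cluster = by_seg.setdefault(
            row.segment_index, PatternCluster(segs[row.segment_index])
        )
        cluster.add(pattern)
    return [by_seg[i] for i in sorted(by_seg)]


# ---------------------------------------------------------------------------
# Hairpin read pairs

@dataclass
class HairpinSim:
    pairs: list[HairpinReadPair]
    molecules: pd.DataFrame  # molecule_id, length, is_spike, dyads "pos:T:B,..."
    config: SimConfig

    def truth_dyads(self, include_spike: bool = False) -> list[DyadCall]:
        out = []
        for row in self.molecules.itertuples(index=False):
            if row.is_spike and not include_spike:
                continue
            if row.dyads == ".":
                continue
            for item in row.dyads.split(","):
                pos, top, bottom = item.split(":")
                out.append(DyadCall(row.molecule_id, int(pos), top, bottom))
        return out


def _convert(
    seq: str,
    methylated: set[int],
    failure_rate: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert a strand: C -> T unless methylated (or the
    conversion fails)."""
    out = []
    for i, b in enumerate(seq):
        if b == "C" and i not in methylated:
            out.append("C" if rng.random() < failure_rate else "T")
        else:
            out.append(b)
    return "".join(out)


def simulate_hairpin_pairs(
    config: SimConfig,
    n_molecules: int = 500,
    methylation_level: float = 0.7,
    insert_range: tuple[int, int] = (50, 100),
    hairpin_seq: str = HAIRPIN_ADAPTER,
    hairpin_cpg_density: float = 0.05,
    spike_in_fraction: float = 0.0,
    neighbor_correlation: float = 1.0,
) -> HairpinSim:
    """Read pairs from double-stranded molecules with planted dyad states.

    With probability ``neighbor_correlation`` a molecule draws a single
    top-strand state shared by all its dyads (somatic methylation is bimodal
    and strongly correlated between neighboring CpGs); otherwise each dyad's
    top state is an independent Bernoulli(methylation_level) draw.  The
    bottom strand copies the top state except with probability
    ``config.dyad_asymmetry_rate``, independently per dyad.  Spike-in
    molecules are fully unmethylated on both strands (the conversion-rate
    control).  Read 1 runs 5'->3' from the top arm into the loop adapter;
    read 2 reads the bottom arm in its own orientation.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 303)))
    pairs: list[HairpinReadPair] = []
    mol_rows = []
    for mi in range(n_molecules):
        is_spike = rng.random() < spike_in_fraction
        length = int(rng.integers(insert_range[0], insert_range[1] + 1))
        seq = _random_sequence(length, hairpin_cpg_density, rng)
        dyad_pos = [i for i in range(length - 1) if seq[i : i + 2] == "CG"]
        top_meth: set[int] = set()
        bottom_meth: set[int] = set()  # positions on the bottom strand (5'->3')
        dyad_items = []
        correlated = rng.random() < neighbor_correlation
        shared_top = bool(rng.random() < methylation_level)
        for p in dyad_pos:
            if is_spike:
                top_m = bottom_m = False
            else:
                top_m = shared_top if correlated else bool(
                    rng.random() < methylation_level
                )
                bottom_m = (not top_m) if rng.random() < config.dyad_asymmetry_rate else top_m
            if top_m:
                top_meth.add(p)
            if bottom_m:
                # bottom strand 5'->3' is revcomp(seq); its C for this dyad
                # sits at index length - 1 - (p + 1)
                bottom_meth.add(length - 2 - p)
            dyad_items.append(f"{p}:{'M' if top_m else 'U'}:{'M' if bottom_m else 'U'}")
        conv_top = _convert(seq, top_meth, config.conversion_failure_rate, rng)
        conv_bottom = _convert(
            revcomp(seq), bottom_meth, config.conversion_failure_rate, rng
        )
        conv_hairpin = _convert(hairpin_seq, set(), config.conversion_failure_rate, rng)
        # read 1 runs through the top arm into the loop (and beyond, for
        # short inserts); read 2 reads the bottom arm in its own orientation
        # from the loop junction, running into the sequencing adapter
        conv_adapter = _convert(SEQ_ADAPTER, set(), config.conversion_failure_rate, rng)
        r1 = (conv_top + conv_hairpin + conv_bottom)[: config.read_length]
        r2 = (conv_bottom + conv_adapter)[: config.read_length]
        mol_id = f"mol{mi}"
        pairs.append(HairpinReadPair(read1=r1, read2=r2, pair_id=mol_id))
        mol_rows.append(
            (mol_id, length, is_spike, ",".join(dyad_items) or ".")
        )
    molecules = pd.DataFrame(
        mol_rows, columns=["molecule_id", "length", "is_spike", "dyads"]
    )
    return HairpinSim(pairs, molecules, config)


# ---------------------------------------------------------------------------
# GWAS SNPs

def simulate_snps(
    regions: Sequence[tuple[str, int, int]],
    chrom_sizes: dict[str, int],
    n_enriched_traits: int = 5,
    n_null_traits: int = 20,
    snps_per_trait: int = 50,
    effect: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP table (chrom, pos 1-based, trait) + per-trait truth.

    Null traits draw positions uniformly over the genome; enriched traits
    place a fraction ``effect`` of their SNPs uniformly inside regions.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    cum = sizes / sizes.sum()
    rows = []
    truth = []
    region_list = list(regions)

    def uniform_snp() -> tuple[str, int]:
        ci = int(rng.choice(len(chroms), p=cum))
        return chroms[ci], int(rng.integers(0, chrom_sizes[chroms[ci]])) + 1

    for t in range(n_enriched_traits + n_null_traits):
        enriched = t < n_enriched_traits
        trait = f"{'enriched' if enriched else 'null'}_trait_{t}"
        truth.append((trait, enriched))
        for _ in range(snps_per_trait):
            if enriched and region_list and rng.random() < effect:
                chrom, start, end = region_list[int(rng.integers(len(region_list)))]
                pos = int(rng.integers(start, end)) + 1
            else:
                chrom, pos = uniform_snp()
            rows.append((chrom, pos, trait))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "trait"])
    truth_df = pd.DataFrame(truth, columns=["trait", "is_enriched"])
    return snps, truth_df


# ---------------------------------------------------------------------------
# Writers for standard formats

def write_fastq(pairs: Sequence[HairpinReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.read1)
            q2 = p.qual2 or "I" * len(p.read2)
            f1.write(f"@{p.pair_id}/1\n{p.read1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.read2}\n+\n{q2}\n")


def write_sam(
    reads: Sequence[ReadMethCalls],
    sequences: dict[str, str],
    path,
) -> None:
    """Minimal SAM with Bismark-style XM tags reconstructed from the calls.

    The read sequence is taken from the reference (bisulfite changes are
    irrelevant to downstream parsing, which uses the XM tag only).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c, "LN": len(s)} for c, s in sorted(sequences.items())
        ],
    }
    chrom_index = {c: i for i, c in enumerate(sorted(sequences))}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = chrom_index[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            seq = sequences[r.chrom][r.start : r.start + r.length]
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            xm = ["."] * len(seq)
            for pos, state in r.calls:
                # reverse-strand calls sit on the G of the dyad
                at = pos - r.start if r.strand == "+" else pos + 1 - r.start
                if 0 <= at < len(seq):
                    xm[at] = "Z" if state == "M" else "z"
            a.set_tag("XM", "".join(xm))
            out.write(a)
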