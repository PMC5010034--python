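"""Hairpin bisulfite sequencing analysis.

A hairpin library ligates a loop adapter joining the two strands of one DNA
molecule, so a read pair carries the bisulfite-converted top arm (read 1)
and bottom arm (read 2) of the *same* molecule.  Reconstructing the original
molecule gives, at every CpG dyad, the methylation state of both strands —
the substrate for methylation *fidelity* (fraction of dyads with symmetric
states) and for strand-symmetry analysis of multi-CpG patterns.

Bisulfite chemistry: unmethylated C reads as T; methylated C is retained.
On the bottom arm the same conversions appear as G→A once the arm is
reverse-complemented into the top-strand frame, so alignment and adapter
matching treat query-C vs read-T and query-G vs read-A as compatible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HairpinReadPair",
    "ArmAlignment",
    "RecoveredMolecule",
    "DyadCall",
    "WindowSymmetry",
    "HAIRPIN_ADAPTER",
    "revcomp",
    "trim_hairpin",
    "align_arms",
    "recover_molecule",
    "methylation_level",
    "methylation_fidelity",
    "window_symmetry",
    "aggregate_by_feature",
    "conversion_rate",
]

# biotinylated loop adapter; the internal biotin-dT reads as T
HAIRPIN_ADAPTER = "GGCCAGCTGCAAGTGAAGCAGCTGGCCT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MIN_IDENTITY = 0.9


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HairpinReadPair:
    read1: str
    read2: str
    qual1: str = ""
    qual2: str = ""
    pair_id: str = ""
    trimmed1: bool = False
    trimmed2: bool = False


@dataclass(frozen=True)
class DyadCall:
    """One CpG dyad's strand states; position is the forward-strand C."""

    chrom: str
    position: int
    top_state: str
    bottom_state: str

    @property
    def symmetric(self) -> bool:
        return self.top_state == self.bottom_state


@dataclass
class RecoveredMolecule:
    molecule_id: str
    original_sequence: str
    arm_identity: float
    dyads: list[DyadCall] = field(default_factory=list)
    chrom: str = ""
    offset: int = 0

    def called_dyads(self) -> list[DyadCall]:
        return [d for d in self.dyads if "." not in (d.top_state, d.bottom_state)]


@dataclass
class WindowSymmetry:
    window_size: int
    n_windows: int
    n_symmetric: int
    n_asymmetric: int

    @property
    def symmetric_fraction(self) -> float:
        return self.n_symmetric / self.n_windows if self.n_windows else float("nan")

    @property
    def asymmetric_fraction(self) -> float:
        return self.n_asymmetric / self.n_windows if self.n_windows else float("nan")


# ---------------------------------------------------------------------------
# Adapter / hairpin trimming

def _compatible(q: str, r: str, tolerance: str) -> bool:
    """Bisulfite-tolerant base comparison (query vs read).

    'ct': a query C may read as T (forward-orientation converted sequence);
    'ga': a query G may read as A (the same conversions seen in reverse
    complement).  Allowing both at once would make half the alphabet a
    wildcard and produce spurious adapter hits.
    """
    if q == r:
        return True
    if tolerance == "ct":
        return q == "C" and r == "T"
    return q == "G" and r == "A"


def _find_suffix_match(
    read: str,
    query: str,
    max_mismatch_frac: float,
    min_overlap: int,
    tolerance: str = "ct",
) -> int | None:
    """Earliest read position where a prefix of ``query`` matches the read
    suffix with at most ``max_mismatch_frac`` mismatches; None if no hit."""
    read = read.upper()
    query = query.upper()
    n = len(read)
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(query), n - start)
        if overlap < min_overlap:
            break
        allowed = int(max_mismatch_frac * overlap)
        mismatches = 0
        ok = True
        for i in range(overlap):
            if not _compatible(query[i], read[start + i], tolerance):
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return start
    return None


def trim_hairpin(
    pair: HairpinReadPair,
    adapter_seq: str = "",
    hairpin_seq: str = HAIRPIN_ADAPTER,
    max_mismatch_frac: float = 0.10,
    min_overlap: int = 8,
) -> HairpinReadPair:
    """Remove 3' read-through into the hairpin loop or sequencing adapter.

    Both orientations of each query are searched, since read 2 sees the
    reverse complement of what read 1 sees.  Untrimmable reads pass through.
    """
    forward = [q for q in (hairpin_seq, adapter_seq) if q]
    queries = [(q, "ct") for q in forward] + [(revcomp(q), "ga") for q in forward]
    out = HairpinReadPair(
        read1=pair.read1, read2=pair.read2,
        qual1=pair.qual1, qual2=pair.qual2, pair_id=pair.pair_id,
    )
    for attr, qattr, flag in (("read1", "qual1", "trimmed1"),
                              ("read2", "qual2", "trimmed2")):
        read = getattr(out, attr)
        cut = len(read)
        for q, tol in queries:
            hit = _find_suffix_match(read, q, max_mismatch_frac, min_overlap, tol)
            if hit is not None and hit < cut:
                cut = hit
        if cut < len(read):
            setattr(out, attr, read[:cut])
            qual = getattr(out, qattr)
            if qual:
                setattr(out, qattr, qual[:cut])
            setattr(out, flag, True)
    return out


# ---------------------------------------------------------------------------
# Needleman-Wunsch arm alignment

@dataclass
class ArmAlignment:
    aligned_top: str
    aligned_bottom: str  # read 2 reverse-complemented into the top frame
    score: int
    identity: float


def _nw_compatible(a: str, b: str) -> bool:
    """Top arm base vs revcomp(bottom arm) base.

    Top-strand C→T conversion: top T over bottom-frame C.  Bottom-strand
    conversion appears as G→A in the revcomp frame: top G over bottom A.
    """
    return a == b or (a == "T" and b == "C") or (a == "G" and b == "A")


def _make_aligner(match: int, mismatch: int, gap: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            mat[x, y] = match if x == y else mismatch
    mat["N", "N"] = mismatch  # N never certifies identity
    # bisulfite-compatible pairs (top frame vs revcomp-bottom frame)
    mat["T", "C"] = match
    mat["G", "A"] = match
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_arms(
    pair: HairpinReadPair,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> ArmAlignment:
    """Global (Needleman-Wunsch) alignment of read 1 against revcomp(read 2).

    Linear gap penalty; bisulfite-compatible columns score as matches and
    count as identical for the identity fraction.  Terminal overhang columns
    are trimmed before the identity is computed.
    """
    a = pair.read1.upper()
    b = revcomp(pair.read2.upper())
    if not a or not b:
        raise ValueError("cannot align an empty arm")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    top_s = str(aln[0])
    bot_s = str(aln[1])
    nw_score = int(aln.score)
    # trim terminal overhangs (columns where one side is a gap)
    lo = 0
    hi = len(top_s)
    while lo < hi and ("-" in (top_s[lo], bot_s[lo])):
        lo += 1
    while hi > lo and ("-" in (top_s[hi - 1], bot_s[hi - 1])):
        hi -= 1
    top_s, bot_s = top_s[lo:hi], bot_s[lo:hi]
    cols = len(top_s)
    if cols == 0:
        identity = 0.0
    else:
        good = sum(
            1 for x, y in zip(top_s, bot_s)
            if x != "-" and y != "-" and _nw_compatible(x, y)
        )
        identity = good / cols
    return ArmAlignment(top_s, bot_s, nw_score, identity)


# ---------------------------------------------------------------------------
# Molecule recovery

class LowIdentityError(ValueError):
    """Arm identity below the recovery threshold; the pair is rejected."""


def recover_molecule(
    alignment: ArmAlignment,
    molecule_id: str = "",
    chrom: str = "",
    offset: int = 0,
    min_identity: float = MIN_IDENTITY,
) -> RecoveredMolecule:
    """Resolve the original double-stranded sequence and per-dyad states.

    At each aligned column the original base follows from the
    bisulfite-complementary pair: a bottom-frame C pins the original base to
    C (top read C = methylated, T = unmethylated); a top G pins it to G
    (bottom-frame G = methylated bottom C, A = unmethylated).  Dyads are
    CG dinucleotides of the recovered sequence; states that cannot be read
    from a strand are '.' (uncalled).
    """
    if alignment.identity < min_identity:
        raise LowIdentityError(
            f"arm identity {alignment.identity:.3f} < {min_identity}"
        )
    top = alignment.aligned_top
    bot = alignment.aligned_bottom
    original = []
    col_of_base = []  # alignment column for each recovered base
    for col, (x, y) in enumerate(zip(top, bot)):
        if x == "-" and y == "-":
            continue
        if y == "C":  # bottom frame retains C only where the original was C
            base = "C"
        elif x == "G":
            base = "G"
        elif x == y and x != "-":
            base = x
        elif x == "-":
            base = y
        elif y == "-":
            base = x
        else:
            base = "N"
        original.append(base)
        col_of_base.append(col)
    seq = "".join(original)
    mol = RecoveredMolecule(
        molecule_id=molecule_id,
        original_sequence=seq,
        arm_identity=alignment.identity,
        chrom=chrom or molecule_id or "molecule",
        offset=offset,
    )
    for i in range(len(seq) - 1):
        if seq[i] != "C" or seq[i + 1] != "G":
            continue
        c_col = col_of_base[i]
        g_col = col_of_base[i + 1]
        t = top[c_col]
        top_state = "M" if t == "C" else "U" if t == "T" else "."
        bq = bot[g_col]
        bottom_state = "M" if bq == "G" else "U" if bq == "A" else "."
        mol.dyads.append(
            DyadCall(mol.chrom, offset + i, top_state, bottom_state)
        )
    return mol


def process_pairs(
    pairs: Iterable[HairpinReadPair],
    adapter_seq: str = "",
    hairpin_seq: str = HAIRPIN_ADAPTER,
    min_identity: float = MIN_IDENTITY,
) -> tuple[list[RecoveredMolecule], int]:
    """Trim, align and recover every pair; returns (molecules, n_rejected).

    Pairs are rejected when an arm is empty after trimming or the arm
    identity falls below ``min_identity``.
    """
    molecules = []
    rejected = 0
    for pair in pairs:
        trimmed = trim_hairpin(pair, adapter_seq=adapter_seq, hairpin_seq=hairpin_seq)
        if not trimmed.read1 or not trimmed.read2:
            rejected += 1
            continue
        aln = align_arms(trimmed)
        try:
            mol = recover_molecule(
                aln, molecule_id=pair.pair_id, min_identity=min_identity
            )
        except LowIdentityError:
            rejected += 1
            continue
        molecules.append(mol)
    return molecules, rejected


def read_fastq_pairs(r1_path, r2_path) -> list[HairpinReadPair]:
    """Load paired FASTQ into HairpinReadPair records (ids from read 1)."""
    from Bio import SeqIO

    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        out.append(
            HairpinReadPair(
                read1=str(rec1.seq),
                read2=str(rec2.seq),
                qual1="".join(
                    chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                ),
                qual2="".join(
                    chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                ),
                pair_id=rec1.id.removesuffix("/1"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fidelity, level, window symmetry

def methylation_fidelity(dyads: Sequence[DyadCall]) -> float:
    """Fraction of fully-called CpG dyads with identical strand states."""
    called = [d for d in dyads if "." not in (d.top_state, d.bottom_state)]
    if not called:
        return float("nan")
    return sum(d.symmetric for d in called) / len(called)


def methylation_level(dyads: Sequence[DyadCall]) -> float:
    """Methylated strand-calls over all strand-calls at CpG dyads (both
    strands counted individually)."""
    states = [
        s for d in dyads for s in (d.top_state, d.bottom_state) if s != "."
    ]
    if not states:
        return float("nan")
    return sum(s == "M" for s in states) / len(states)


def window_symmetry(
    molecules: Iterable[RecoveredMolecule], w: int
) -> WindowSymmetry:
    """Strand symmetry of w adjacent CpG dyads within single molecules.

    A window is *symmetric* when both strands carry the same uniform pattern
    (all-M/all-M or all-U/all-U), *asymmetric* when both strands are uniform
    but opposite; mixed windows count in n_windows only.
    """
    if not 1 <= w <= 4:
        raise ValueError("window size must be in 1..4")
    n_windows = n_sym = n_asym = 0
    for mol in molecules:
        dyads = mol.called_dyads()
        for i in range(len(dyads) - w + 1):
            win = dyads[i : i + w]
            n_windows += 1
            tops = {d.top_state for d in win}
            bots = {d.bottom_state for d in win}
            if len(tops) != 1 or len(bots) != 1:
                continue
            if tops == bots:
                n_sym += 1
            else:
                n_asym += 1
    return WindowSymmetry(w, n_windows, n_sym, n_asym)


# ---------------------------------------------------------------------------
# Feature aggregation and conversion rate

def aggregate_by_feature(
    dyads: Sequence[DyadCall],
    features: pd.DataFrame,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-bin mean methylation level and fidelity along stranded features.

    ``features`` needs chrom/start/end/strand columns.  Each feature is cut
    into ``n_bins`` equal bins ordered 5'→3' along its strand; every dyad
    falling in a feature is assigned by fractional position.  Bins with no
    dyads report NaN.
    """
    by_chrom: dict[str, list[DyadCall]] = {}
    for d in dyads:
        by_chrom.setdefault(d.chrom, []).append(d)
    level_calls: list[list[str]] = [[] for _ in range(n_bins)]
    fid_calls: list[list[bool]] = [[] for _ in range(n_bins)]
    for row in features.itertuples(index=False):
        length = row.end - row.start
        if length < n_bins:
            warnings.warn(
                f"feature {row.chrom}:{row.start}-{row.end} shorter than "
                f"{n_bins} bins; skipped"
            )
            continue
        for d in by_chrom.get(row.chrom, []):
            if not row.start <= d.position < row.end:
                continue
            frac = (d.position - row.start) / length
            if getattr(row, "strand", "+") == "-":
                frac = 1.0 - frac - 1.0 / length  # orient 5'->3'
            b = min(int(frac * n_bins), n_bins - 1)
            for s in (d.top_state, d.bottom_state):
                if s != ".":
                    level_calls[b].append(s)
            if "." not in (d.top_state, d.bottom_state):
                fid_calls[b].append(d.symmetric)
    rows = []
    for b in range(n_bins):
        lev = (
            sum(s == "M" for s in level_calls[b]) / len(level_calls[b])
            if level_calls[b] else float("nan")
        )
        fid = (
            sum(fid_calls[b]) / len(fid_calls[b]) if fid_calls[b] else float("nan")
        )
        rows.append((b, len(fid_calls[b]), lev, fid))
    return pd.DataFrame(rows, columns=["bin", "n_dyads", "level", "fidelity"])


def conversion_rate(spike_in_dyads: Sequence[DyadCall]) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in control.

    Every strand-call on the spike-in comes from an unmethylated C, so a
    retained C (an M call) is a conversion failure:
    rate = converted / total C calls.
    """
    states = [
        s for d in spike_in_dyads for s in (d.top_state, d.bottom_state)
        if s != "."
    ]
    if not states:
        return float("nan")
    return sum(s == "U" for s in states) / len(states)
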