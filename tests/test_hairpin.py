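import math

import numpy as np
import pandas as pd
import pytest

from bipolarmeth.hairpin import (
    HAIRPIN_ADAPTER,
    ArmAlignment,
    DyadCall,
    HairpinReadPair,
    LowIdentityError,
    aggregate_by_feature,
    align_arms,
    conversion_rate,
    methylation_fidelity,
    methylation_level,
    recover_molecule,
    revcomp,
    trim_hairpin,
    window_symmetry,
)
from bipolarmeth.simulate import SEQ_ADAPTER


def nw_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Independent quadratic DP for the global alignment score."""
    n, m = len(a), len(b)
    prev = [gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [gap * i] + [0] * m
        for j in range(1, m + 1):
            x, y = a[i - 1], b[j - 1]
            s = match if (
                x == y or (x == "T" and y == "C") or (x == "G" and y == "A")
            ) else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def truth_lookup(hairpin_sim):
    truth = {}
    for row in hairpin_sim.molecules.itertuples(index=False):
        dyads = {}
        if row.dyads != ".":
            for item in row.dyads.split(","):
                p, a, b = item.split(":")
                dyads[int(p)] = (a, b)
        truth[row.molecule_id] = (row.length, row.is_spike, dyads)
    return truth


class TestTrim:
    def test_exact_hairpin_suffix_removed(self):
        insert = "ATTGATTAGTTAGGATTA"
        pair = HairpinReadPair(read1=insert + HAIRPIN_ADAPTER, read2=insert)
        out = trim_hairpin(pair)
        assert out.read1 == insert and out.trimmed1
        assert out.read2 == insert and not out.trimmed2

    def test_converted_hairpin_suffix_removed(self):
        insert = "ATTGATTAGTTAGGATTA"
        converted = HAIRPIN_ADAPTER.replace("C", "T")
        out = trim_hairpin(HairpinReadPair(read1=insert + converted, read2=insert))
        assert out.read1 == insert

    def test_partial_overlap_below_min_untouched(self):
        insert = "ATTGATTAGTTAGGATTA"
        pair = HairpinReadPair(read1=insert + HAIRPIN_ADAPTER[:5], read2=insert)
        out = trim_hairpin(pair)
        assert out.read1 == insert + HAIRPIN_ADAPTER[:5]

    def test_simulated_insert_lengths_recovered(self, hairpin_sim):
        truth = truth_lookup(hairpin_sim)
        n_checked = 0
        for pair in hairpin_sim.pairs[:300]:
            out = trim_hairpin(pair, adapter_seq=SEQ_ADAPTER)
            length = truth[pair.pair_id][0]
            # read 1 runs insert -> hairpin; trimming must recover the insert
            assert len(out.read1) == length
            n_checked += 1
        assert n_checked == 300


class TestAlign:
    def test_identical_arms(self):
        seq = "ATTGGATCGAATTCCGGATA"
        aln = align_arms(HairpinReadPair(read1=seq, read2=revcomp(seq)))
        assert aln.identity == 1.0
        assert aln.score == len(seq)

    def test_two_incompatible_positions_of_twenty(self):
        a = "ATTGGATCGAATTCCGGATA"
        b = list(a)
        b[3] = "C"   # G over C: incompatible (only G/A is tolerated)
        b[10] = "G"  # A over G: incompatible in this orientation
        b = "".join(b)
        aln = align_arms(HairpinReadPair(read1=a, read2=revcomp(b)))
        assert aln.identity == pytest.approx(18 / 20)

    def test_bisulfite_compatible_columns_count_as_identity(self):
        a = "TTTGGATTGAATTTTGGATA"  # C->T converted everywhere
        b = "CTTGGATCGAATTCCGGATA"  # bottom frame retains the Cs
        aln = align_arms(HairpinReadPair(read1=a, read2=revcomp(b)))
        assert aln.identity == 1.0

    def test_empty_arm_raises(self):
        with pytest.raises(ValueError):
            align_arms(HairpinReadPair(read1="", read2="ACGT"))

    def test_scores_match_independent_dp_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n1, n2 = rng.integers(15, 45, size=2)
            a = "".join(rng.choice(list("ACGT"), n1))
            b = "".join(rng.choice(list("ACGT"), n2))
            aln = align_arms(HairpinReadPair(read1=a, read2=revcomp(b)))
            assert aln.score == nw_oracle(a, b)


class TestRecover:
    def test_symmetric_methylated_dyad(self):
        aln = ArmAlignment("ACGT", "ACGT", 4, 1.0)
        mol = recover_molecule(aln, molecule_id="m")
        (dyad,) = mol.dyads
        assert (dyad.top_state, dyad.bottom_state) == ("M", "M")
        assert mol.original_sequence == "ACGT"

    def test_asymmetric_dyad_top_unmethylated(self):
        # top strand converted (T), bottom frame retains C and methylated G
        aln = ArmAlignment("ATGT", "ACGT", 2, 1.0)
        mol = recover_molecule(aln, molecule_id="m")
        (dyad,) = mol.dyads
        assert (dyad.top_state, dyad.bottom_state) == ("U", "M")
        assert mol.original_sequence == "ACGT"

    def test_bottom_unmethylated_reads_as_A(self):
        aln = ArmAlignment("ACGT", "ACAT", 2, 1.0)
        (dyad,) = recover_molecule(aln, molecule_id="m").dyads
        assert (dyad.top_state, dyad.bottom_state) == ("M", "U")

    def test_low_identity_rejected(self):
        aln = ArmAlignment("ACGT", "ACGT", 4, 0.85)
        with pytest.raises(LowIdentityError):
            recover_molecule(aln)

    def test_recovered_states_match_simulator_truth(self, hairpin_sim, recovered):
        molecules, rejected = recovered
        truth = truth_lookup(hairpin_sim)
        assert rejected <= len(hairpin_sim.pairs) * 0.01
        n_match = n_total = 0
        for mol in molecules:
            length, _, dyads = truth[mol.molecule_id]
            assert len(mol.original_sequence) == length
            for d in mol.called_dyads():
                n_total += 1
                n_match += dyads.get(d.position) == (d.top_state, d.bottom_state)
        assert n_total > 0
        assert n_match / n_total >= 0.99


class TestFidelity:
    def test_examples(self):
        dyads = [
            DyadCall("m", 0, "M", "M"),
            DyadCall("m", 5, "U", "U"),
            DyadCall("m", 9, "M", "U"),
        ]
        assert methylation_fidelity(dyads) == pytest.approx(2 / 3)
        assert methylation_fidelity([DyadCall("m", 0, "M", "M")] * 4) == 1.0
        assert math.isnan(methylation_fidelity([]))
        assert methylation_level(dyads) == pytest.approx(3 / 6)

    def test_fidelity_equals_one_minus_w1_asymmetry_exactly(self, recovered):
        molecules, _ = recovered
        dyads = [d for m in molecules for d in m.called_dyads()]
        ws = window_symmetry(molecules, 1)
        assert ws.n_symmetric + ws.n_asymmetric == ws.n_windows
        assert methylation_fidelity(dyads) == pytest.approx(
            1.0 - ws.asymmetric_fraction, abs=1e-12
        )


class TestWindowSymmetry:
    def mol(self, top, bottom):
        m = [
            DyadCall("m", i * 3, t, b) for i, (t, b) in enumerate(zip(top, bottom))
        ]
        from bipolarmeth.hairpin import RecoveredMolecule

        out = RecoveredMolecule("m", "", 1.0)
        out.dyads = m
        return out

    def test_w1_discordant_dyad_is_asymmetric(self):
        ws = window_symmetry([self.mol("M", "U")], 1)
        assert (ws.n_windows, ws.n_symmetric, ws.n_asymmetric) == (1, 0, 1)

    def test_w2_uniform_same_is_symmetric(self):
        ws = window_symmetry([self.mol("MM", "MM")], 2)
        assert (ws.n_windows, ws.n_symmetric, ws.n_asymmetric) == (1, 1, 0)

    def test_w2_mixed_bottom_is_neither(self):
        ws = window_symmetry([self.mol("MM", "MU")], 2)
        assert (ws.n_windows, ws.n_symmetric, ws.n_asymmetric) == (1, 0, 0)

    def test_w2_uniform_opposite_is_asymmetric(self):
        ws = window_symmetry([self.mol("MM", "UU")], 2)
        assert ws.n_asymmetric == 1

    def test_symmetric_fraction_decreases_with_window(self, recovered):
        molecules, _ = recovered
        fracs = [
            window_symmetry(molecules, w).symmetric_fraction for w in (1, 2, 3, 4)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestAggregate:
    def test_uniform_dyads_give_flat_profile(self):
        dyads = [DyadCall("chr1", p, "M", "M") for p in range(100, 300)]
        features = pd.DataFrame(
            [("chr1", 100, 300, "+")], columns=["chrom", "start", "end", "strand"]
        )
        prof = aggregate_by_feature(dyads, features, n_bins=20)
        assert (prof["level"] == 1.0).all()
        assert (prof["fidelity"] == 1.0).all()

    def test_empty_bins_are_nan(self):
        dyads = [DyadCall("chr1", p, "M", "M") for p in range(100, 200)]
        features = pd.DataFrame(
            [("chr1", 100, 300, "+")], columns=["chrom", "start", "end", "strand"]
        )
        prof = aggregate_by_feature(dyads, features, n_bins=20)
        assert prof["level"].iloc[:10].notna().all()
        assert prof["level"].iloc[10:].isna().all()

    def test_minus_strand_reverses_binning(self):
        dyads = [DyadCall("chr1", p, "M", "M") for p in range(100, 200)]
        features = pd.DataFrame(
            [("chr1", 100, 300, "-")], columns=["chrom", "start", "end", "strand"]
        )
        prof = aggregate_by_feature(dyads, features, n_bins=20)
        assert prof["level"].iloc[10:].notna().all()
        assert prof["level"].iloc[:10].isna().all()

    def test_short_feature_skipped_with_warning(self):
        features = pd.DataFrame(
            [("chr1", 0, 5, "+")], columns=["chrom", "start", "end", "strand"]
        )
        with pytest.warns(UserWarning, match="skipped"):
            prof = aggregate_by_feature([], features, n_bins=20)
        assert prof["level"].isna().all()


class TestConversionRate:
    def test_examples(self):
        dyads = [DyadCall("spike", i, "U", "U") for i in range(500)]
        assert conversion_rate(dyads) == 1.0
        # 3 retained C calls out of 1000
        dyads[0] = DyadCall("spike", 0, "M", "U")
        dyads[1] = DyadCall("spike", 1, "M", "M")
        assert conversion_rate(dyads) == pytest.approx(0.997)
        assert conversion_rate([DyadCall("s", 0, "M", "M")]) == 0.0
        assert math.isnan(conversion_rate([]))

    def test_simulated_spike_in_recovers_conversion_rate(self, hairpin_sim, recovered):
        molecules, _ = recovered
        spike_ids = set(
            hairpin_sim.molecules.loc[hairpin_sim.molecules.is_spike, "molecule_id"]
        )
        spike_dyads = [
            d for m in molecules if m.molecule_id in spike_ids
            for d in m.called_dyads()
        ]
        n_calls = 2 * len(spike_dyads)
        rate = conversion_rate(spike_dyads)
        se = math.sqrt(0.997 * 0.003 / n_calls)
        assert abs(rate - 0.997) <= 3 * se + 1e-9
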