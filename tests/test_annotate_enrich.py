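import numpy as np
import pandas as pd
import pytest

from bipolarmeth.annotate_enrich import (
    EnrichmentResult,
    associate_genes,
    build_promoters,
    classify_elements,
    gwas_enrichment,
    rank_traits,
    tss_profile,
)
from bipolarmeth.bipolar_detect import classify_bipolar
from bipolarmeth.methcall_io import PatternCluster, Segment


def make_call(chrom, start, bipolar=True):
    cpgs = (start, start + 10, start + 20, start + 30)
    pats = {"MMMM": 5, "UUUU": 5} if bipolar else {"MMUU": 8, "MMMM": 1, "UUUU": 1}
    return classify_bipolar(
        PatternCluster(Segment(chrom, cpgs), pats), seed=1, method="em_bic"
    )


class TestPromoters:
    def test_strand_aware_and_cgi_status(self):
        tss = pd.DataFrame(
            [("chr1", 5000, "+", "g1"), ("chr1", 5000, "-", "g2")],
            columns=["chrom", "pos", "strand", "gene_id"],
        )
        cgi = [("chr1", 3500, 3600)]
        prom = build_promoters(tss, cgi).set_index("gene_id")
        assert (prom.loc["g1", "start"], prom.loc["g1", "end"]) == (3000, 5000)
        assert (prom.loc["g2", "start"], prom.loc["g2", "end"]) == (5001, 7001)
        assert prom.loc["g1", "cgi_status"] == "CGI"
        assert prom.loc["g2", "cgi_status"] == "nonCGI"


class TestClassifyElements:
    # occupancy: (H3K4me1, H3K4me3, H3K27ac) -> expected class
    TRUTH = {
        (False, False, False): None,
        (True, False, False): "poised_enhancer",
        (False, True, False): "active_promoter",
        (False, False, True): "active_enhancer",
        (True, True, False): "active_promoter",
        (True, False, True): "active_enhancer",
        (False, True, True): "active_promoter",
        (True, True, True): "active_promoter",
    }

    @pytest.mark.parametrize("occupancy", sorted(TRUTH))
    def test_all_occupancy_combinations(self, occupancy):
        me1, me3, ac = occupancy
        peak = [("chr1", 100, 200)]
        elements = classify_elements(
            peak if me1 else [], peak if me3 else [], peak if ac else [], cgi=[]
        )
        expected = self.TRUTH[occupancy]
        if expected is None:
            assert elements == []
        else:
            (el,) = elements
            got = el.element_class.replace("_nonCGI", "").replace("_CGI", "")
            assert got == expected

    def test_promoter_split_by_cgi(self):
        peak = [("chr1", 100, 200)]
        (el,) = classify_elements([], peak, [], cgi=[("chr1", 150, 160)])
        assert el.element_class == "active_promoter_CGI"
        (el,) = classify_elements([], peak, [], cgi=[("chr1", 500, 600)])
        assert el.element_class == "active_promoter_nonCGI"

    def test_overlapping_peaks_merge_before_labelling(self):
        elements = classify_elements(
            [("chr1", 100, 250)], [("chr1", 200, 300)], [], cgi=[]
        )
        (el,) = elements
        assert (el.start, el.end) == (100, 300)
        assert el.element_class == "active_promoter_nonCGI"

    def test_random_peaks_match_truth_table_oracle(self):
        rng = np.random.default_rng(33)

        def peaks():
            return [
                ("chr1", int(s), int(s) + int(rng.integers(50, 400)))
                for s in rng.integers(0, 50_000, 40)
            ]

        me1, me3, ac = peaks(), peaks(), peaks()
        elements = classify_elements(me1, me3, ac, cgi=[])
        for el in elements:
            def hits(peaks):
                return any(s < el.end and el.start < e for _, s, e in peaks)

            if hits(me3):
                expected = "active_promoter_nonCGI"
            elif hits(ac):
                expected = "active_enhancer"
            else:
                assert hits(me1)
                expected = "poised_enhancer"
            assert el.element_class == expected


class TestAssociateGenes:
    TSS = pd.DataFrame(
        [("chr1", 50_000, "+", "near"), ("chr1", 200_000, "+", "far")],
        columns=["chrom", "pos", "strand", "gene_id"],
    )

    def test_within_and_beyond_window(self):
        csm = [("chr1", 45_000, 45_040)]  # 5 kb upstream of 'near'
        eligible = csm + [("chr1", 185_000, 185_040)]  # 15 kb from 'far'
        fg, bg = associate_genes(csm, eligible, self.TSS)
        assert fg == ["near"]
        assert bg == ["near"]

    def test_random_placements_match_interval_oracle(self):
        rng = np.random.default_rng(44)
        tss = pd.DataFrame(
            [("chr1", int(p), "+", f"g{i}") for i, p in
             enumerate(rng.integers(20_000, 500_000, 40))],
            columns=["chrom", "pos", "strand", "gene_id"],
        )
        csm = [("chr1", int(s), int(s) + 40) for s in rng.integers(0, 500_000, 60)]
        eligible = csm + [
            ("chr1", int(s), int(s) + 40) for s in rng.integers(0, 500_000, 200)
        ]
        fg, bg = associate_genes(csm, eligible, tss, window=10_000)

        def near(segments, pos):
            return any(
                s <= pos + 10_000 and e >= pos - 10_000 + 1 for _, s, e in segments
            )

        exp_bg = [r.gene_id for r in tss.itertuples(index=False) if near(eligible, r.pos)]
        exp_fg = [
            r.gene_id for r in tss.itertuples(index=False)
            if near(eligible, r.pos) and near(csm, r.pos)
        ]
        assert bg == exp_bg
        assert fg == exp_fg


class TestTssProfile:
    def setup_method(self):
        self.tss = pd.DataFrame(
            [("chr1", 10_000, "+", "g1"), ("chr1", 40_000, "+", "g2")],
            columns=["chrom", "pos", "strand", "gene_id"],
        )
        self.prom = build_promoters(self.tss, [("chr1", 8_500, 9_000)])

    def test_no_bipolar_segments_gives_zero_profile(self):
        calls = [make_call("chr1", 10_000 + off, bipolar=False) for off in range(-400, 400, 100)]
        prof = tss_profile(calls, self.prom, self.tss, flank=1000, n_bins=4)
        observed = prof.dropna(subset=["pcsm_frequency"])
        assert (observed["pcsm_frequency"] == 0).all()

    def test_all_bipolar_gives_unit_profile(self):
        calls = [make_call("chr1", 10_000 + off) for off in range(-400, 400, 100)]
        prof = tss_profile(calls, self.prom, self.tss, flank=1000, n_bins=4)
        observed = prof.dropna(subset=["pcsm_frequency"])
        assert (observed["pcsm_frequency"] == 1).all()

    def test_cgi_and_noncgi_separated(self):
        # bipolar near the CGI promoter (g1), eligible-only near g2
        calls = [make_call("chr1", 9_900)] + [
            make_call("chr1", 39_900, bipolar=False)
        ]
        prof = tss_profile(calls, self.prom, self.tss, flank=1000, n_bins=2)
        cgi = prof[prof.cgi_status == "CGI"].dropna(subset=["pcsm_frequency"])
        non = prof[prof.cgi_status == "nonCGI"].dropna(subset=["pcsm_frequency"])
        assert (cgi["pcsm_frequency"] == 1).all()
        assert (non["pcsm_frequency"] == 0).all()


class TestGwasEnrichment:
    def test_exhaustive_enumeration_matches_independent_oracle(self):
        L = 1000
        regions = [("c1", 100, 160), ("c1", 700, 730)]
        snps = pd.DataFrame(
            {"chrom": ["c1"] * 5, "pos": [150, 420, 705, 910, 55], "trait": ["t"] * 5}
        )
        ext, prox = 10, 10
        (res,) = gwas_enrichment(
            regions, snps, {"c1": L}, shifts="all", extension=ext, proximity=prox
        )
        # oracle: literal count per shift with inclusive distance
        margin = ext + prox
        pos0 = [p - 1 for p in snps["pos"]]

        def count(offset):
            n = 0
            for p in pos0:
                hit = False
                for _, s, e in regions:
                    lo, hi = s - margin + offset, e + margin + offset
                    if lo <= p <= hi or lo <= p + L <= hi or lo <= p - L <= hi:
                        hit = True
                n += hit
            return n

        observed = count(0)
        null = [count(o) for o in range(L)]
        expected_p = (1 + sum(c >= observed for c in null)) / (1 + L)
        assert res.observed_count == observed
        assert res.p_value == pytest.approx(expected_p)

    def test_extreme_enrichment_gives_minimal_p(self):
        L = 100_000
        regions = [("c1", 50_000, 50_002)]
        snps = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [50_001, 50_002], "trait": ["t", "t"]}
        )
        (res,) = gwas_enrichment(
            regions, snps, {"c1": L}, n_iter=100, extension=0, proximity=0, seed=9
        )
        assert res.observed_count == 2
        assert res.p_value == pytest.approx(1 / 101)

    def test_null_shifts_preserve_region_count_and_lengths(self):
        from bipolarmeth.annotate_enrich import _union_bounds

        L = 10_000
        regions = [(0, 100), (2_000, 2_400), (9_950, 9_990)]
        base = _union_bounds(list(regions), L)
        total = sum(base[1::2] - base[::2])
        for off in (0, 1, 57, 5_000, 9_999):
            b = _union_bounds([(s + off, e + off) for s, e in regions], L)
            assert len(b) % 2 == 0
            assert sum(b[1::2] - b[::2]) == total

    def test_empty_trait_skipped_with_warning(self):
        snps = pd.DataFrame({"chrom": [], "pos": [], "trait": []})
        res = gwas_enrichment([("c1", 0, 10)], snps, {"c1": 100}, n_iter=10)
        assert res == []


class TestRankTraits:
    def test_recurrence_outranks_single_sample(self):
        results = []
        for s in ("s1", "s2", "s3"):
            results.append(EnrichmentResult("recurrent", 5, (0,), 0.01, s))
            results.append(
                EnrichmentResult("occasional", 5, (0,), 0.01 if s == "s1" else 0.8, s)
            )
        ranked = rank_traits(results)
        assert list(ranked["trait"]) == ["recurrent", "occasional"]
        assert ranked.loc[0, "n_significant"] == 3

    def test_no_significant_traits_ordered_by_mean_p(self):
        results = [
            EnrichmentResult("worse", 1, (0,), 0.9, "s1"),
            EnrichmentResult("better", 1, (0,), 0.3, "s1"),
        ]
        ranked = rank_traits(results)
        assert list(ranked["trait"]) == ["better", "worse"]
        assert (ranked["n_significant"] == 0).all()

    def test_simulated_enriched_traits_occupy_top_ranks(self):
        from bipolarmeth.simulate import simulate_snps

        sizes = {"chr1": 500_000}
        rng = np.random.default_rng(6)
        regions = [
            ("chr1", int(s), int(s) + 300) for s in rng.integers(0, 490_000, 40)
        ]
        snps, truth = simulate_snps(
            regions, sizes, n_enriched_traits=4, n_null_traits=30,
            snps_per_trait=60, effect=0.6, seed=6,
        )
        results = gwas_enrichment(regions, snps, sizes, n_iter=500, seed=6)
        ranked = rank_traits(results)
        top = set(ranked.head(4)["trait"])
        enriched = set(truth.loc[truth.is_enriched, "trait"])
        assert top == enriched
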