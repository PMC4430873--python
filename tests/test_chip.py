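import numpy as np
import pandas as pd
import pytest

from myctargets import chip
from myctargets.annotation import GeneRecord, GenomeAnnotation, reverse_complement
from myctargets.chip import (
    ConsensusSite,
    PeakRecord,
    PeakSet,
    TagSet,
    build_consensus_sites,
    call_peaks_naive,
    filter_specific_peaks,
    overlap_counts,
    region_read_ratio,
    scan_ebox,
    select_validation_regions,
    subsample_tags,
    tss_distance_profile,
)

from conftest import make_peak


def make_tags(positions, chrom="c", condition="specific_naive"):
    positions = np.asarray(positions, dtype=np.int64)
    return TagSet(
        condition,
        np.array([chrom] * len(positions), dtype=object),
        positions,
        np.array(["+"] * len(positions), dtype=object),
    )


def random_peakset(rng, n, exp="e1", L=100_000, max_w=500, cond="specific_naive"):
    peaks = []
    for _ in range(n):
        s = int(rng.integers(0, L - max_w))
        e = s + int(rng.integers(50, max_w))
        peaks.append(
            PeakRecord(
                "c", s, e, int(rng.integers(s, e)),
                float(rng.uniform(0, 40)), float(rng.uniform(0, 10)), exp,
            )
        )
    return PeakSet(exp, cond, peaks)


class TestSubsample:
    def test_full_sample_is_identity_multiset(self):
        ts = make_tags([5, 1, 9, 3, 3, 7, 2, 8, 0, 4])
        out = subsample_tags(ts, 10, seed=0)
        assert sorted(out.positions) == sorted(ts.positions)

    def test_fixed_seed_reproducible(self):
        ts = make_tags(np.arange(10))
        a = subsample_tags(ts, 4, seed=7)
        b = subsample_tags(ts, 4, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_tags(make_tags([1, 2, 3]), 4, seed=0)

    def test_per_chromosome_proportions(self, rng):
        # 10k tags over two chromosomes 70/30, subsample 1k: proportions
        # within exact binomial 99% bounds
        n = 10_000
        chroms = np.where(rng.random(n) < 0.7, "c1", "c2").astype(object)
        ts = TagSet("x", chroms, rng.integers(0, 10**6, n), np.array(["+"] * n, dtype=object))
        out = subsample_tags(ts, 1000, seed=3)
        p = (out.chroms == "c1").mean()
        from scipy import stats

        p_true = (ts.chroms == "c1").mean()
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, p_true) / 1000
        assert lo <= p <= hi


class TestNaiveCaller:
    SIZES = {"c": 200_000}

    def test_planted_pileup_yields_one_peak(self, rng):
        bg = rng.integers(0, 200_000, 5000)
        pile = rng.normal(100_000, 30, 500).astype(np.int64)
        ps = call_peaks_naive(make_tags(np.concatenate([bg, pile])), None, self.SIZES)
        assert len(ps) == 1
        p = ps.peaks[0]
        assert p.start <= 100_000 <= p.end
        assert p.significant
        assert abs(p.summit - 100_000) < 200

    def test_treatment_equals_background_no_peaks(self, rng):
        false_peaks = 0
        for _ in range(20):
            tags = make_tags(rng.integers(0, 200_000, 5000))
            ps = call_peaks_naive(tags, tags, self.SIZES)
            false_peaks += len(ps)
        assert false_peaks <= 2  # BH false-positive allowance over 20 null runs

    def test_two_pileups_split_and_merge(self, rng):
        bg = rng.integers(0, 200_000, 5000)
        far = np.concatenate(
            [rng.normal(50_000, 20, 400), rng.normal(51_200, 20, 400)]
        ).astype(np.int64)
        ps = call_peaks_naive(make_tags(np.concatenate([bg, far])), None, self.SIZES)
        assert len(ps) == 2
        near = np.concatenate(
            [rng.normal(50_000, 20, 400), rng.normal(50_080, 20, 400)]
        ).astype(np.int64)
        ps2 = call_peaks_naive(make_tags(np.concatenate([bg, near])), None, self.SIZES)
        assert len(ps2) == 1

    def test_empty_treatment_empty_peakset(self):
        ps = call_peaks_naive(make_tags([]), None, self.SIZES)
        assert len(ps) == 0


class TestSpecificityFilter:
    def test_control_overlap_removed(self):
        myc = PeakSet("m", "specific_naive", [
            make_peak("c", 100, 200), make_peak("c", 500, 600), make_peak("c", 900, 1000),
        ])
        igg = PeakSet("i", "igg_naive", [make_peak("c", 150, 250, exp="i")])
        out = filter_specific_peaks(myc, [igg])
        assert [(p.start, p.end) for p in out.peaks] == [(500, 600), (900, 1000)]

    def test_excluded_chromosome_removed_without_control(self):
        myc = PeakSet("m", "specific_naive", [
            make_peak("Uextra", 100, 200), make_peak("c", 100, 200),
        ])
        out = filter_specific_peaks(myc, [], excluded_chroms=["Uextra"])
        assert [p.chrom for p in out.peaks] == ["c"]

    def test_idempotent(self, rng):
        myc = random_peakset(rng, 50, "m")
        ctrl = [random_peakset(rng, 30, "i")]
        once = filter_specific_peaks(myc, ctrl)
        twice = filter_specific_peaks(once, ctrl)
        assert once.peaks == twice.peaks

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            myc = random_peakset(rng, int(rng.integers(1, 200)), "m")
            ctrls = [
                random_peakset(rng, int(rng.integers(0, 100)), f"i{k}")
                for k in range(int(rng.integers(1, 4)))
            ]
            got = filter_specific_peaks(myc, ctrls)
            expected = [
                p
                for p in myc.peaks
                if not any(
                    p.chrom == q.chrom and p.start < q.end and q.start < p.end
                    for cs in ctrls
                    for q in cs.peaks
                )
            ]
            assert got.peaks == [
                PeakRecord(p.chrom, p.start, p.end, p.summit, p.fdr_percent, p.score, "m")
                for p in expected
            ]


class TestConsensus:
    def test_rescue_by_overlap(self):
        a = make_peak("c", 100, 300, fdr=5.0, exp="A")
        b = make_peak("c", 250, 400, fdr=20.0, exp="B")
        sites = build_consensus_sites([PeakSet("A", "specific_naive", [a]),
                                       PeakSet("B", "specific_naive", [b])])
        assert len(sites) == 1
        site = sites[0]
        assert site.significant and len(site.member_peaks) == 2
        assert (site.start, site.end) == (100, 400)

    def test_lone_nonsignificant_peak_site(self):
        a = make_peak("c", 100, 300, fdr=20.0)
        sites = build_consensus_sites([PeakSet("e1", "specific_naive", [a])])
        assert len(sites) == 1 and not sites[0].significant

    def test_single_linkage_chain(self):
        a = make_peak("c", 100, 300, exp="A")
        b = make_peak("c", 250, 500, exp="B")
        c = make_peak("c", 450, 700, exp="C")  # disjoint from a
        sites = build_consensus_sites(
            [PeakSet(x, "specific_naive", [p]) for x, p in zip("ABC", (a, b, c))]
        )
        assert len(sites) == 1 and len(sites[0].member_peaks) == 3

    def test_representative_summit_tiebreak(self):
        a = make_peak("c", 100, 300, fdr=5.0, summit=150, score=2.0)
        b = make_peak("c", 200, 400, fdr=5.0, summit=350, score=9.0, exp="B")
        sites = build_consensus_sites([PeakSet("e1", "specific_naive", [a]),
                                       PeakSet("B", "specific_naive", [b])])
        assert sites[0].representative_summit == 350  # equal FDR -> higher score

    def test_partition_property(self, rng):
        sets = [random_peakset(rng, 100, x) for x in "AB"]
        sites = build_consensus_sites(sets)
        members = [id(p) for s in sites for p in s.member_peaks]
        assert len(members) == len(set(members)) == sum(len(ps) for ps in sets)

    def test_matches_networkx_components_oracle(self, rng):
        import networkx as nx

        for _ in range(20):
            sets = [
                random_peakset(rng, int(rng.integers(1, 150)), x) for x in "ABC"
            ]
            sites = build_consensus_sites(sets)
            allp = [p for ps in sets for p in ps.peaks]
            G = nx.Graph()
            G.add_nodes_from(range(len(allp)))
            for i in range(len(allp)):
                for j in range(i + 1, len(allp)):
                    a, b = allp[i], allp[j]
                    if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                        G.add_edge(i, j)
            comps = {
                frozenset((allp[i].chrom, allp[i].start, allp[i].end, allp[i].experiment_id)
                          for i in comp)
                for comp in nx.connected_components(G)
            }
            got = {
                frozenset((p.chrom, p.start, p.end, p.experiment_id) for p in s.member_peaks)
                for s in sites
            }
            assert got == comps


class TestOverlapCounts:
    def test_disjoint_sets(self):
        a = PeakSet("A", "specific_naive", [make_peak("c", 0, 100, exp="A")])
        b = PeakSet("B", "specific_naive", [make_peak("c", 500, 600, exp="B")])
        assert overlap_counts([a, b]) == {("A",): 1, ("B",): 1, ("A", "B"): 0}

    def test_identical_sets_all_intersection(self):
        a = PeakSet("A", "specific_naive", [make_peak("c", 0, 100, exp="A")])
        b = PeakSet("B", "specific_naive", [make_peak("c", 0, 100, exp="B")])
        counts = overlap_counts([a, b])
        assert counts[("A", "B")] == 1 and counts[("A",)] == 0

    def test_cells_sum_to_site_count(self, rng):
        sets = [random_peakset(rng, 100, x) for x in "ABC"]
        counts = overlap_counts(sets)
        assert sum(counts.values()) == len(build_consensus_sites(sets))

    def test_more_than_three_sets_unsupported(self, rng):
        sets = [random_peakset(rng, 5, x) for x in "ABCD"]
        with pytest.raises(ValueError):
            overlap_counts(sets)


def make_site(chrom, start, end, summit=None, significant=True):
    if summit is None:
        summit = (start + end) // 2
    return ConsensusSite(chrom, start, end, [], significant, summit)


class TestTssProfile:
    def test_all_sites_contain_tss(self):
        ann = GenomeAnnotation([GeneRecord("g", "c", 1000, 2000, "+")], {"c": 10_000})
        sites = [make_site("c", 900, 1100), make_site("c", 950, 1050)]
        prof = tss_distance_profile(sites, ann)
        assert prof["all_percent"].iloc[0] == 100.0

    def test_two_bin_example(self):
        # one site 50 nt from a TSS, one 5,500 nt away
        ann = GenomeAnnotation([GeneRecord("g", "c", 10_000, 11_000, "+")], {"c": 50_000})
        sites = [make_site("c", 9_000, 9_949), make_site("c", 3_000, 4_500)]
        prof = tss_distance_profile(sites, ann)
        as_dict = dict(zip(prof["bin"], prof["all_percent"]))
        assert as_dict["[0,100)"] == 50.0
        assert as_dict["[5000,6000)"] == 50.0

    def test_percentages_sum_to_100(self, sim_bundle, e2e_results):
        prof = tss_distance_profile(e2e_results["sites"], sim_bundle["ann"])
        assert prof["all_percent"].sum() == pytest.approx(100.0)

    def test_promoter_planted_sites_beat_random(self, sim_bundle, rng):
        """Simulated sites sit at promoters, so their near-TSS share must
        exceed that of random intervals."""
        ann = sim_bundle["ann"]
        truth = sim_bundle["truth"]
        sites = [
            make_site(r.chrom, int(r.start), int(r.end), int(r.summit))
            for r in truth.true_sites.itertuples()
        ]
        prof = tss_distance_profile(sites, ann)
        L = sim_bundle["cfg"].chrom_length
        rand_sites = [
            make_site("chr1", s := int(rng.integers(0, L - 300)), s + 300)
            for _ in range(len(sites))
        ]
        rand_prof = tss_distance_profile(rand_sites, ann)
        assert (
            prof.attrs["share_within_100_all"] > rand_prof.attrs["share_within_100_all"]
        )


class TestEboxScan:
    def test_motif_at_summit(self):
        seq = "A" * 200 + "CACGTG" + "A" * 200
        assert scan_ebox(seq, 200)

    def test_window_boundaries(self):
        # start at summit+49 is inside [summit-50, summit+50); +50 is not
        for offset, expected in [(49, True), (50, False), (-50, True), (-51, False)]:
            summit = 300
            start = summit + offset
            seq = "A" * start + "CACGTG" + "A" * 400
            assert scan_ebox(seq, summit) is expected, offset

    def test_reverse_complement_invariance(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(rng.choice(bases, size=1000))
            summit = int(rng.integers(60, 940))
            mirrored = reverse_complement(seq)
            assert scan_ebox(seq, summit) == scan_ebox(mirrored, len(seq) - 1 - summit)

    def test_matches_bruteforce_enumeration(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=10_000))
        for _ in range(100):
            summit = int(rng.integers(0, 10_000))
            brute = any(
                seq[s : s + 6] == "CACGTG"
                for s in range(max(0, summit - 50), min(len(seq), summit + 50))
            )
            assert scan_ebox(seq, summit) == brute

    def test_summit_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_ebox("ACGT", 4)


class TestRegionReadRatio:
    def test_ratio_arithmetic(self, rng):
        naive = make_tags(rng.integers(1000, 2000, 120))
        depleted = make_tags(rng.integers(1000, 2000, 100), condition="specific_depleted")
        df = region_read_ratio([("c", 1000, 2000)], naive, depleted)
        assert df.loc[0, "n_naive"] == 120 and df.loc[0, "n_depleted"] == 100
        assert df.loc[0, "ratio"] == pytest.approx(1.2)

    def test_zero_depleted_guard(self):
        naive = make_tags([10, 20, 30, 40, 50])
        depleted = make_tags([5000], condition="specific_depleted")
        df = region_read_ratio([("c", 0, 100)], naive, depleted)
        assert df.loc[0, "ratio"] == 5.0

    def test_matches_bruteforce_membership(self, rng):
        npos = rng.integers(0, 10_000, 2000)
        dpos = rng.integers(0, 10_000, 2000)
        naive, depleted = make_tags(npos), make_tags(dpos, condition="x")
        regions = [
            ("c", s := int(rng.integers(0, 9000)), s + int(rng.integers(10, 1000)))
            for _ in range(100)
        ]
        df = region_read_ratio(regions, naive, depleted)
        for (_, s, e), row in zip(regions, df.itertuples()):
            assert row.n_naive == int(((npos >= s) & (npos < e)).sum())
            assert row.n_depleted == int(((dpos >= s) & (dpos < e)).sum())


class TestValidationRegionSelection:
    def make_regions(self, n, ratio=1.0):
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 500,
                "n_naive": np.arange(n)[::-1] + 1,
                "n_depleted": np.arange(n)[::-1] + 1,
                "ratio": ratio,
            }
        )

    def test_every_fiftieth_from_hundred(self):
        sel = select_validation_regions(self.make_regions(100))
        assert len(sel) == 2
        assert sel["n_naive"].tolist() == [100, 50]  # ranks 1 and 51

    def test_ratio_boundary_inclusive(self):
        df = self.make_regions(2)
        df.loc[0, "ratio"] = 1.20
        df.loc[1, "ratio"] = 1.21
        sel = select_validation_regions(df, step=1)
        assert len(sel) == 1 and sel.loc[0, "ratio"] == 1.20

    def test_own_site_overlap_excluded(self):
        df = self.make_regions(3)
        own = [make_site("c", 1100, 1200)]  # overlaps region [1000, 1500)
        sel = select_validation_regions(df, own, step=1)
        assert len(sel) == 2 and 1000 not in sel["start"].tolist()

    @pytest.mark.parametrize("n", [1, 49, 50, 51, 149, 150])
    def test_selection_count_is_ceil(self, n):
        sel = select_validation_regions(self.make_regions(n))
        assert len(sel) == -(-n // 50)


class TestSiteRecovery:
    def test_planted_sites_recovered_and_sticky_removed(self, sim_bundle, e2e_results):
        """End-to-end binding half: >=90% of planted sites become significant
        consensus sites, <=10% of significant sites are unplanted, and every
        sticky region is eliminated by control subtraction."""
        truth = sim_bundle["truth"]
        sig = e2e_results["sig_sites"]

        def overlaps(site, row):
            return site.chrom == row.chrom and site.start < row.end and row.start < site.end

        recovered = sum(
            any(overlaps(s, r) for s in sig) for r in truth.true_sites.itertuples()
        )
        assert recovered >= 0.9 * len(truth.true_sites)
        unplanted = sum(
            not any(overlaps(s, r) for r in truth.true_sites.itertuples()) for s in sig
        )
        assert unplanted <= 0.1 * len(sig)
        sticky_left = sum(
            any(overlaps(s, r) for r in truth.sticky_regions.itertuples()) for s in sig
        )
        assert sticky_left == 0
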