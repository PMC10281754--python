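"""Interval algebra: consensus, classification, point intersection,
state enrichment, variant prioritization — all against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from devqtl.errors import DomainError
from devqtl.genomic_intervals import (
    GenomicInterval, PeakCollection, ProxySNV, classify_shared_unique,
    consensus_peaks, intersect_points, merge_intervals, prioritize_variants,
    read_bed, state_enrichment, write_bed,
)

CHROM = "chrT"
L = 300  # toy contig length for per-base oracles


def iv(start, end, label=""):
    return GenomicInterval(CHROM, start, end, label)


def random_sample(rng, group, sample_id, n_iv=5, lo=0, hi=L, max_len=40):
    ivs = []
    for _ in range(int(rng.integers(1, n_iv + 1))):
        s = int(rng.integers(lo, hi - 2))
        e = int(rng.integers(s + 1, min(hi, s + max_len) + 1))
        ivs.append(iv(s, e))
    return PeakCollection(sample_id, group, ivs)


def coverage_vector(samples):
    """Per-base sample coverage on [0, L), counting each sample once per base."""
    cov = np.zeros(L, dtype=int)
    for s in samples:
        mask = np.zeros(L, dtype=bool)
        for r in s.intervals:
            mask[r.start:r.end] = True
        cov += mask
    return cov


def runs_at_least(cov, k):
    """Maximal [start, end) runs where cov >= k (the per-base oracle)."""
    hits = cov >= k
    out = []
    start = None
    for i, h in enumerate(hits):
        if h and start is None:
            start = i
        elif not h and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, L))
    return out


class TestMergeNormalization:
    def test_merge_is_idempotent_and_order_invariant(self, rng):
        ivs = [iv(int(s), int(s) + int(w))
               for s, w in zip(rng.integers(0, 250, 20), rng.integers(1, 40, 20))]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        rng.shuffle(ivs)
        assert merge_intervals(ivs) == merged

    def test_empty_interval_rejected(self):
        with pytest.raises(DomainError):
            GenomicInterval(CHROM, 10, 10)


class TestConsensusPeaks:
    def test_three_identical_samples(self):
        samples = [PeakCollection(f"s{i}", "FH", [iv(100, 200)]) for i in range(3)]
        assert consensus_peaks(samples, 2) == [iv(100, 200)]

    def test_worked_staircase(self):
        samples = [PeakCollection("a", "FH", [iv(0, 10)]),
                   PeakCollection("b", "FH", [iv(5, 15)]),
                   PeakCollection("c", "FH", [iv(12, 20)])]
        assert consensus_peaks(samples, 2) == [iv(5, 10), iv(12, 15)]

    def test_k_out_of_range_raises(self):
        samples = [PeakCollection("a", "FH", [iv(0, 10)])]
        with pytest.raises(DomainError):
            consensus_peaks(samples, 2)
        with pytest.raises(DomainError):
            consensus_peaks(samples, 0)

    def test_mixed_groups_rejected(self):
        with pytest.raises(DomainError):
            consensus_peaks([PeakCollection("a", "FH", [iv(0, 10)]),
                             PeakCollection("b", "AK", [iv(0, 10)])], 1)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 7))
            samples = [random_sample(rng, "FK", f"s{i}") for i in range(n)]
            k = int(rng.integers(1, n + 1))
            got = [(r.start, r.end) for r in consensus_peaks(samples, k)]
            assert got == runs_at_least(coverage_vector(samples), k)

    def test_k1_is_union_and_kn_is_intersection(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 6))
            samples = [random_sample(rng, "AH", f"s{i}") for i in range(n)]
            cov = coverage_vector(samples)
            union = [(r.start, r.end) for r in consensus_peaks(samples, 1)]
            inter = [(r.start, r.end) for r in consensus_peaks(samples, n)]
            assert union == runs_at_least(cov, 1)
            assert inter == runs_at_least(cov, n)
            merged = merge_intervals([r for s in samples for r in s.intervals])
            assert union == [(r.start, r.end) for r in merged]


class TestClassifySharedUnique:
    def test_identical_sets_all_four(self):
        sets = [[iv(10, 50), iv(100, 140)]] * 4
        counts, labeled = classify_shared_unique(*sets)
        assert counts == {"all_four": 2, "fetal_unique": 0,
                          "aged_unique": 0, "other": 0}
        assert all(r.label == "all_four" for r in labeled)

    def test_planted_one_per_category(self):
        shared, fetal, aged = iv(10, 20), iv(50, 60), iv(90, 100)
        counts, _ = classify_shared_unique(
            [shared, fetal], [shared, fetal], [shared, aged], [shared, aged])
        assert counts == {"all_four": 1, "fetal_unique": 1,
                          "aged_unique": 1, "other": 0}

    def test_empty_aged_sets(self):
        counts, _ = classify_shared_unique([iv(0, 10)], [iv(20, 30)], [], [])
        assert counts["fetal_unique"] == 2
        assert counts["all_four"] == counts["aged_unique"] == 0

    def test_partial_overlap_is_other(self):
        # region overlaps FH and AH but not FK/AK -> neither unique nor all-four
        counts, _ = classify_shared_unique([iv(0, 10)], [], [iv(5, 15)], [])
        assert counts == {"all_four": 0, "fetal_unique": 0,
                          "aged_unique": 0, "other": 1}

    def test_total_bases_conserved(self, rng):
        for _ in range(30):
            sets = [[r for s in [random_sample(rng, g, "x")] for r in s.intervals]
                    for g in ("FH", "FK", "AH", "AK")]
            _, labeled = classify_shared_unique(*sets)
            union = merge_intervals([r for ivs in sets for r in ivs])
            assert sum(len(r) for r in labeled) == sum(len(r) for r in union)

    def test_matches_brute_force_labels(self, rng):
        for _ in range(60):
            sets = {g: random_sample(rng, g, "x").intervals
                    for g in ("FH", "FK", "AH", "AK")}
            _, labeled = classify_shared_unique(**{k.lower(): v for k, v in sets.items()})
            masks = {}
            for g, ivs in sets.items():
                m = np.zeros(L, dtype=bool)
                for r in ivs:
                    m[r.start:r.end] = True
                masks[g] = m
            for region in labeled:
                hit = {g: masks[g][region.start:region.end].any() for g in sets}
                if all(hit.values()):
                    expected = "all_four"
                elif (hit["FH"] or hit["FK"]) and not (hit["AH"] or hit["AK"]):
                    expected = "fetal_unique"
                elif (hit["AH"] or hit["AK"]) and not (hit["FH"] or hit["FK"]):
                    expected = "aged_unique"
                else:
                    expected = "other"
                assert region.label == expected


class TestIntersectPoints:
    def test_coordinate_convention(self):
        # 1-based point 100 is 0-based base 99
        assert intersect_points([("p", CHROM, 100)], [iv(99, 100)])[0][3]
        assert intersect_points([("p", CHROM, 100)], [iv(100, 200)])[0][3] == []
        assert intersect_points([("p", CHROM, 100)], [iv(0, 99)])[0][3] == []
        assert intersect_points([("p", CHROM, 100)], [iv(0, 100)])[0][3]

    def test_unknown_chromosome_is_a_miss_not_an_error(self):
        name, chrom, pos, hits = intersect_points(
            [("p", "chrZ", 5)], [iv(0, 10)])[0]
        assert hits == []

    def test_position_below_one_raises(self):
        with pytest.raises(DomainError):
            intersect_points([("p", CHROM, 0)], [iv(0, 10)])

    def test_matches_brute_force(self, rng):
        intervals = [iv(int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 280, 200),
                                     rng.integers(1, 25, 200))]
        points = [(f"p{i}", CHROM, int(p)) for i, p in
                  enumerate(rng.integers(1, L + 1, 1000))]
        got = intersect_points(points, intervals)
        for name, chrom, pos, hits in got:
            expected = [r for r in intervals if r.start <= pos - 1 < r.end]
            assert sorted(hits) == sorted(expected)


class TestStateEnrichment:
    def _half_half_states(self):
        return [iv(0, 150, "Enh"), iv(150, 300, "Quies")]

    def test_uniform_peaks_fold_near_one(self, rng):
        states = self._half_half_states()
        starts = rng.integers(0, 290, 400)
        peaks = [iv(int(s), int(s) + 10) for s in starts]
        res = state_enrichment(peaks, states).set_index("state")
        assert res.loc["Enh", "fold"] == pytest.approx(1.0, abs=0.2)
        assert res.loc["Quies", "fold"] == pytest.approx(1.0, abs=0.2)

    def test_concentrated_peaks_fold_ten(self):
        states = [iv(0, 30, "Enh"), iv(30, 300, "Quies")]  # Enh is 10% of genome
        peaks = [iv(s, s + 2) for s in range(0, 28, 3)]
        res = state_enrichment(peaks, states).set_index("state")
        assert res.loc["Enh", "fold"] == pytest.approx(10.0)

    def test_binomial_p_matches_independent_computation(self, rng):
        states = self._half_half_states()
        peaks = [iv(int(s), int(s) + 5) for s in rng.integers(0, 140, 30)]
        peaks += [iv(int(s), int(s) + 5) for s in rng.integers(150, 290, 10)]
        res = state_enrichment(peaks, states).set_index("state")
        expected = stats.binomtest(30, 40, 0.5, alternative="two-sided").pvalue
        assert res.loc["Enh", "p"] == pytest.approx(expected, abs=1e-12)

    def test_maximal_overlap_assignment(self):
        states = [iv(0, 100, "Enh"), iv(100, 300, "Tx")]
        peak = iv(90, 130)  # 10 bp in Enh, 30 bp in Tx
        res = state_enrichment([peak], states).set_index("state")
        assert res.loc["Tx", "n_peaks"] == 1
        assert res.loc["Enh", "n_peaks"] == 0

    def test_uncovered_peak_is_unannotated(self):
        states = [iv(0, 100, "Enh")]
        res = state_enrichment([GenomicInterval("chrZ", 0, 10)], states)
        assert res.set_index("state").loc["unannotated", "n_peaks"] == 1


class TestPrioritizeVariants:
    def _sets(self):
        shared, fetal, aged, partial = iv(10, 20), iv(40, 50), iv(70, 80), iv(100, 110)
        return ([shared, fetal, partial], [shared, fetal],
                [shared, aged, partial], [shared, aged])

    def test_low_ld_excluded(self):
        out = prioritize_variants([ProxySNV("rs1", CHROM, 15, 0.75)], *self._sets())
        assert len(out) == 0

    def test_boundary_ld_excluded(self):
        # rule is strict: r2 must exceed 0.8
        out = prioritize_variants([ProxySNV("rs1", CHROM, 15, 0.8)], *self._sets())
        assert len(out) == 0

    def test_classes_match_hand_enumeration(self):
        proxies = [
            ProxySNV("rs_all", CHROM, 15, 0.9),      # in shared region
            ProxySNV("rs_fet", CHROM, 45, 0.9),      # fetal sets only
            ProxySNV("rs_age", CHROM, 75, 0.9),      # aged sets only
            ProxySNV("rs_par", CHROM, 105, 0.9),     # FH + AH only
            ProxySNV("rs_out", CHROM, 250, 0.9),     # open nowhere -> dropped
        ]
        out = prioritize_variants(proxies, *self._sets()).set_index("rsid")
        assert out.loc["rs_all", "class"] == "all_tissues"
        assert out.loc["rs_fet", "class"] == "fetal_only"
        assert out.loc["rs_age", "class"] == "aged_only"
        assert out.loc["rs_par", "class"] == "partial"
        assert "rs_out" not in out.index
        assert len(out) == 4

    def test_ld_r2_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            ProxySNV("rs1", CHROM, 15, 1.2)


def test_bed_round_trip(tmp_path, rng):
    ivs = merge_intervals([iv(int(s), int(s) + int(w))
                           for s, w in zip(rng.integers(0, 250, 10),
                                           rng.integers(1, 30, 10))])
    labeled = [GenomicInterval(r.chrom, r.start, r.end, "cls") for r in ivs]
    p = tmp_path / "x.bed"
    write_bed(labeled, p)
    again = read_bed(p, label_col=True)
    assert again == labeled
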