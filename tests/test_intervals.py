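"""Interval algebra: subtraction, merging, consensus, gene assignment."""
from __future__ import annotations

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clipfoot.intervals import (
    ConsensusFootprint,
    GenomeAnnotation,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    closest_feature,
    consensus_footprints,
    genic_region_proportions,
    merge,
    read_bed,
    subtract,
    write_bed,
)
from conftest import mask_of, mask_to_intervals, random_interval_set


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    def test_rejects_invalid_spans(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_overlap_and_distance(self):
        a, b = iv(0, 100), iv(40, 60)
        assert a.overlap(b) == 20
        assert a.distance(b) == 0
        assert iv(0, 10).distance(iv(30, 40)) == 20
        assert iv(0, 10).distance(iv(10, 20)) == 0  # book-ended
        assert iv(0, 10).overlap(iv(5, 8, chrom="chr2")) == 0


class TestSubtract:
    def test_splits_interval_around_blocker(self):
        out = subtract(IntervalSet([iv(0, 100)]), IntervalSet([iv(40, 60)]))
        assert [(x.start, x.end) for x in out] == [(0, 40), (60, 100)]

    def test_empty_b_is_identity(self):
        a = IntervalSet([iv(5, 10), iv(0, 3)])
        assert [(x.start, x.end) for x in subtract(a, IntervalSet())] \
            == [(0, 3), (5, 10)]

    def test_total_cover_vanishes(self):
        out = subtract(IntervalSet([iv(10, 20)]), IntervalSet([iv(0, 50)]))
        assert len(out) == 0

    def test_self_subtraction_is_empty(self, rng):
        a = random_interval_set(rng, 30)
        assert len(subtract(a, a)) == 0

    def test_fragments_inherit_score_and_name(self):
        a = IntervalSet([iv(0, 100, score=7.0, name="p1")])
        out = subtract(a, IntervalSet([iv(40, 60)]))
        assert all(f.score == 7.0 and f.name == "p1" for f in out)

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_interval_set(rng, int(rng.integers(1, 40)))
            b = random_interval_set(rng, int(rng.integers(0, 40)))
            got = mask_of(subtract(a, b))
            want = mask_of(a) & ~mask_of(b)
            assert np.array_equal(got, want)


class TestMerge:
    def test_book_ended_intervals_are_combined(self):
        out = merge(IntervalSet([iv(0, 10), iv(10, 20)]))
        assert [(x.start, x.end) for x in out] == [(0, 20)]

    def test_disjoint_intervals_unchanged(self):
        out = merge(IntervalSet([iv(0, 10), iv(20, 30)]))
        assert [(x.start, x.end) for x in out] == [(0, 10), (20, 30)]

    def test_gap_parameter_bridges_nearby_intervals(self):
        out = merge(IntervalSet([iv(0, 10), iv(15, 20)]), gap=5)
        assert [(x.start, x.end) for x in out] == [(0, 20)]

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = random_interval_set(rng, int(rng.integers(1, 50)))
            got = merge(a)
            assert np.array_equal(mask_of(got), mask_of(a))
            # output is minimal: disjoint, non-book-ended, sorted
            for x, y in zip(got, list(got)[1:]):
                assert x.end < y.start

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                    min_size=1, max_size=30))
    def test_merge_is_idempotent(self, spans):
        a = IntervalSet([iv(s, s + w) for s, w in spans])
        once = merge(a)
        assert merge(once) == once


class TestAgainstBedtools:
    """Cross-check the from-scratch kernel against the interval tool the
    field uses, on a seeded random instance."""

    @pytest.fixture(autouse=True)
    def _need_bedtools(self):
        try:
            subprocess.run(["bedtools", "--version"], capture_output=True,
                           check=True)
        except (OSError, subprocess.CalledProcessError):  # pragma: no cover
            pytest.skip("bedtools unavailable")

    def _run(self, args, stdin_files):
        res = subprocess.run(args, capture_output=True, text=True, check=True)
        return res.stdout

    def test_subtract_and_merge_agree_with_bedtools(self, tmp_path, rng):
        a = random_interval_set(rng, 40)
        b = random_interval_set(rng, 25)
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a.sorted(), pa)
        write_bed(b.sorted(), pb)
        out = subprocess.run(
            ["bedtools", "subtract", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True).stdout
        theirs = [(l.split("\t")[0], int(l.split("\t")[1]), int(l.split("\t")[2]))
                  for l in out.strip().splitlines() if l]
        ours = [(x.chrom, x.start, x.end) for x in subtract(a, b)]
        assert sorted(ours) == sorted(theirs)

        merged_in = tmp_path / "sorted.bed"
        write_bed(a.sorted(), merged_in)
        out = subprocess.run(
            ["bedtools", "merge", "-i", str(merged_in)],
            capture_output=True, text=True, check=True).stdout
        theirs = [(l.split("\t")[0], int(l.split("\t")[1]), int(l.split("\t")[2]))
                  for l in out.strip().splitlines() if l]
        ours = [(x.chrom, x.start, x.end) for x in merge(a)]
        assert ours == theirs


class TestConsensus:
    def reps(self, *lists):
        return [IntervalSet([iv(s, e) for s, e in lst]) for lst in lists]

    def test_two_of_three_with_ample_overlap_is_retained(self):
        reps = self.reps([(100, 150)], [(120, 170)], [(500, 520)])
        fps = consensus_footprints(reps, min_support=2, min_overlap=2)
        assert len(fps) == 1
        assert fps[0].support == 2
        assert (fps[0].region.start, fps[0].region.end) == (100, 170)

    def test_single_base_overlap_confers_no_support(self):
        # second replicate's 1-nt sliver overlaps the candidate by exactly
        # 1 nt: not enough under the strict more-than-1-nt reading, so the
        # candidate has support 1 and is dropped at min_support=2 ...
        reps = self.reps([(100, 150)], [(149, 150)], [(500, 520)])
        fps = consensus_footprints(reps, min_support=2, min_overlap=2)
        assert fps == []
        # ... while a 2-nt overlap qualifies and the candidate is retained
        reps = self.reps([(100, 150)], [(148, 150)], [(500, 520)])
        fps = consensus_footprints(reps, min_support=2, min_overlap=2)
        assert len(fps) == 1 and fps[0].support == 2

    def test_full_agreement_keeps_everything_at_support_n(self):
        rep = [(10, 40), (100, 130), (500, 560)]
        fps = consensus_footprints(self.reps(rep, rep, rep, rep))
        assert len(fps) == 3
        assert all(fp.support == 4 for fp in fps)

    def test_permutation_invariance(self, rng):
        reps = [random_interval_set(rng, 20) for _ in range(3)]
        a = consensus_footprints(reps)
        b = consensus_footprints(reps[::-1])
        assert [(f.region, f.support) for f in a] \
            == [(f.region, f.support) for f in b]

    def test_monotone_in_support_and_overlap(self, rng):
        reps = [random_interval_set(rng, 25) for _ in range(4)]
        base = len(consensus_footprints(reps, min_support=2, min_overlap=2))
        assert len(consensus_footprints(reps, min_support=3)) <= base
        assert len(consensus_footprints(reps, min_overlap=10)) <= base

    def test_requires_enough_replicates(self):
        with pytest.raises(ValueError):
            consensus_footprints([IntervalSet([iv(0, 10)])], min_support=2)


class TestClosestFeature:
    def make_annotation(self):
        genes = [
            GeneModel("geneA", "chr1", "+", 1000, 2000,
                      {"CDS": [(1000, 2000)]}),
            GeneModel("geneB", "chr1", "+", 3000, 4000,
                      {"CDS": [(3000, 4000)]}),
        ]
        return GenomeAnnotation(genes, {"chr1": 10_000})

    def test_interval_inside_gene_distance_zero(self):
        ann = self.make_annotation()
        [(genes, d)] = closest_feature(IntervalSet([iv(1500, 1550)]), ann)
        assert genes == ("geneA",) and d == 0

    def test_equidistant_tie_reports_both_lexicographically(self):
        ann = self.make_annotation()
        # midpoint gap: gene A ends 2000, gene B starts 3000
        [(genes, d)] = closest_feature(IntervalSet([iv(2400, 2600)]), ann)
        assert genes == ("geneA", "geneB") and d == 400

    def test_missing_chrom_is_flagged_not_raised(self):
        ann = self.make_annotation()
        [(genes, d)] = closest_feature(
            IntervalSet([iv(0, 10, chrom="chrZ")]), ann)
        assert genes == () and d is None

    def test_matches_all_pairs_scan(self, rng):
        genes = []
        pos = 0
        for i in range(15):
            pos += int(rng.integers(100, 400))
            end = pos + int(rng.integers(200, 600))
            genes.append(GeneModel(f"g{i:02d}", "chr1", "+", pos, end,
                                   {"CDS": [(pos, end)]}))
            pos = end
        ann = GenomeAnnotation(genes, {"chr1": pos + 1000})
        queries = random_interval_set(rng, 40, length=pos + 900)
        results = closest_feature(queries, ann)
        for q, (got_genes, got_d) in zip(queries, results):
            dists = {g.gene_id: q.distance(g.span) for g in genes}
            want = min(dists.values())
            want_genes = tuple(sorted(g for g, d in dists.items()
                                      if d == want))
            assert got_d == want and got_genes == want_genes


class TestGenicRegionProportions:
    def annotation(self):
        g = GeneModel("g1", "chr1", "+", 0, 1000, {
            "five_prime_utr": [(0, 100)],
            "CDS": [(100, 300), (500, 700)],
            "intron": [(300, 500)],
            "three_prime_utr": [(700, 1000)],
        })
        return GenomeAnnotation([g], {"chr1": 5000})

    def test_all_intronic_input_is_pure_intron(self):
        ann = self.annotation()
        props = genic_region_proportions(
            IntervalSet([iv(310, 330), iv(400, 450)]), ann)
        assert props == {"intron": 1.0}

    def test_majority_base_rule(self):
        ann = self.annotation()
        # 30 nt in CDS (270..300), 10 nt in intron (300..310)
        props = genic_region_proportions(IntervalSet([iv(270, 310)]), ann)
        assert props == {"CDS": 1.0}

    def test_exact_tie_uses_precedence(self):
        ann = self.annotation()
        # 20 nt in CDS, 20 nt in intron -> CDS by precedence
        props = genic_region_proportions(IntervalSet([iv(280, 320)]), ann)
        assert props == {"CDS": 1.0}

    def test_intergenic_excluded_from_denominator(self):
        ann = self.annotation()
        props = genic_region_proportions(
            IntervalSet([iv(2000, 2100), iv(150, 170)]), ann)
        assert props == {"CDS": 1.0}

    def test_all_intergenic_returns_empty(self):
        ann = self.annotation()
        assert genic_region_proportions(
            IntervalSet([iv(2000, 2100)]), ann) == {}


class TestIO:
    def test_bed_round_trip(self, tmp_path):
        s = IntervalSet([
            iv(0, 10, score=5.0, name="a"),
            iv(20, 30, score=1.25, name="b", strand="-"),
            GenomicInterval("chr2", 7, 9, "+", 3.0, "c", count=4),
        ])
        path = tmp_path / "x.bed"
        write_bed(s, path)
        back = read_bed(path)
        assert [(x.chrom, x.start, x.end, x.strand, x.score, x.name, x.count)
                for x in back] \
            == [(x.chrom, x.start, x.end, x.strand, x.score, x.name, x.count)
                for x in s]

    def test_annotation_tsv_round_trip(self, tmp_path):
        g = GeneModel("g1", "chr1", "-", 10, 500, {
            "three_prime_utr": [(10, 60)],
            "CDS": [(60, 200), (320, 440)],
            "intron": [(200, 320)],
            "five_prime_utr": [(440, 500)],
        })
        ann = GenomeAnnotation([g], {"chr1": 1000})
        path = tmp_path / "ann.tsv"
        ann.to_tsv(path)
        assert GenomeAnnotation.from_tsv(path) == ann


class TestConsensusFootprintInvariants:
    def test_support_bounds_enforced(self):
        with pytest.raises(ValueError):
            ConsensusFootprint(iv(0, 10), support=0, n_replicates=3)
        with pytest.raises(ValueError):
            ConsensusFootprint(iv(0, 10), support=4, n_replicates=3)
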