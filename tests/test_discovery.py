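import numpy as np
import pytest

from mirscout.discovery import (
    Cluster,
    GenomeHit,
    assign_class,
    build_clusters,
    compute_mfei,
    discover,
    extract_windows,
    infer_star,
    map_tags,
    select_candidate,
    trim_and_choose,
    validate_hairpin,
)
from mirscout.fold import FoldResult, fold, reverse_complement
from mirscout.preprocess import SequenceTag
from mirscout.synthetic import make_hairpin_locus
from oracles import naive_map

MATURE = "AAAACGTCTTATAATTTGGAG"
SEQ_A = "ACGTAGCTAGGCATCGATCGA"
SEQ_B = "TTGACCGATCGATCGTAGCTA"


def tag(seq, total=10, lib="L1"):
    return SequenceTag(seq=seq, counts={lib: total})


def hit(seq, chrom="chr1", start=0, strand="+", total=10):
    return GenomeHit(tag=tag(seq, total), chrom=chrom, start=start, strand=strand)


class TestMapTags:
    def test_low_abundance_not_mapped(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        genome = {"chr1": "A" * 100 + seq + "A" * 100}
        assert map_tags([tag(seq, total=4)], genome) == []
        assert len(map_tags([tag(seq, total=5)], genome)) == 1

    def test_excess_genome_hits_discards_tag(self):
        genome = {"chr1": ("TTTT" + SEQ_A) * 17}
        assert map_tags([tag(SEQ_A)], genome) == []
        genome16 = {"chr1": ("TTTT" + SEQ_A) * 16}
        assert len(map_tags([tag(SEQ_A)], genome16)) == 16

    def test_both_strands_counted_and_reported(self):
        genome = {"chr1": SEQ_A + "TTTT" + reverse_complement(SEQ_A)}
        hits = map_tags([tag(SEQ_A)], genome)
        assert [(h.start, h.strand) for h in hits] == [(0, "+"), (25, "-")]

    def test_agrees_with_naive_substring_oracle(self, rng):
        genome = {"chr%d" % c: "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
                  for c in (1, 2)}
        for _ in range(10):
            c = "chr%d" % rng.integers(1, 3)
            pos = int(rng.integers(0, 4970))
            seq = genome[c][pos:pos + 21]
            got = sorted((h.chrom, h.start, h.strand)
                         for h in map_tags([tag(seq)], genome))
            assert got == naive_map(genome, seq)

    def test_n_in_genome_never_matches(self):
        genome = {"chr1": SEQ_A.replace("G", "N", 1) + "TTTT"}
        assert map_tags([tag(SEQ_A)], genome) == []


class TestBuildClusters:
    def test_gap_over_200_splits_chain(self):
        hits = [hit(MATURE, start=0), hit(MATURE, start=21 + 250)]
        assert len(build_clusters(hits)) == 2

    def test_gap_at_200_keeps_chain(self):
        hits = [hit(MATURE, start=0), hit(MATURE, start=21 + 200)]
        assert len(build_clusters(hits)) == 1

    def test_five_nonoverlapping_tags_rejected(self):
        hits = [hit(MATURE, start=i * 50) for i in range(5)]
        assert build_clusters(hits) == []
        assert len(build_clusters(hits[:4])) == 1

    def test_strand_fraction_at_90pct_accepted(self):
        hits = sorted(
            [hit(MATURE, start=i * 10, strand="+") for i in range(9)]
            + [hit(MATURE, start=95, strand="-")],
            key=lambda h: h.start)
        clusters = build_clusters(hits)
        assert len(clusters) == 1 and clusters[0].majority_strand == "+"

    def test_strand_fraction_below_90pct_rejected(self):
        hits = sorted(
            [hit(MATURE, start=i * 10, strand="+") for i in range(8)]
            + [hit(MATURE, start=85, strand="-"),
               hit(MATURE, start=95, strand="-")],
            key=lambda h: h.start)
        assert build_clusters(hits) == []


class TestSelectCandidate:
    def test_most_abundant_wins(self):
        hits = [hit(SEQ_A, start=0, total=50), hit(SEQ_B, start=30, total=7)]
        cluster = Cluster("chr1", hits, "+")
        assert select_candidate(cluster).tag.seq == SEQ_A

    def test_tie_broken_by_smaller_sequence(self):
        hits = [hit(SEQ_B, start=0, total=10), hit(SEQ_A, start=30, total=10)]
        cluster = Cluster("chr1", hits, "+")
        assert select_candidate(cluster).tag.seq == min(SEQ_A, SEQ_B)

    def test_single_hit_cluster(self):
        h = hit(SEQ_A)
        assert select_candidate(Cluster("chr1", [h], "+")) is h

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            select_candidate(Cluster("chr1", [], "+"))


class TestExtractWindows:
    def test_unclipped_window_length(self, rng):
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        h = hit(chrom[400:421], start=400)
        windows = extract_windows({"chr1": chrom}, h, [75])
        seq, span, (c, s, e, strand) = windows[0]
        assert len(seq) == 75 + 21 + 75
        assert (s, e) == (325, 496)
        assert seq[span[0]:span[1]] == h.tag.seq

    def test_clipped_at_chromosome_start(self, rng):
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        h = hit(chrom[10:31], start=10)
        seq, span, (c, s, e, strand) = extract_windows({"chr1": chrom}, h, [75])[0]
        assert s == 0 and len(seq) == 10 + 21 + 75
        assert seq[span[0]:span[1]] == h.tag.seq

    def test_minus_strand_window_oriented_to_candidate(self, rng):
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        insert = reverse_complement(SEQ_A)
        chrom = chrom[:300] + insert + chrom[321:]
        h = hit(SEQ_A, start=300, strand="-")
        seq, span, _loc = extract_windows({"chr1": chrom}, h, [50])[0]
        assert seq[span[0]:span[1]] == SEQ_A

    def test_ladder_windows_cover_planted_precursor(self):
        locus = make_hairpin_locus(MATURE, arm_len=34, loop_len=8, seed=1)
        chrom = "T" * 300 + locus.precursor_seq + "T" * 300
        m_start = 300 + locus.mature_span[0]
        h = hit(MATURE, start=m_start)
        windows = extract_windows({"chr1": chrom}, h)
        assert any(locus.precursor_seq in seq for seq, _sp, _l in windows)


class TestValidateHairpin:
    def test_canonical_precursor_passes_all_four_checks(self):
        locus = make_hairpin_locus(MATURE, arm_len=34, loop_len=8, seed=1)
        checks = validate_hairpin(fold(locus.precursor_seq), locus.mature_span)
        assert checks["pass"]
        assert all(checks[k] for k in ("c1_mismatch_run", "c2_pairing_window",
                                       "c3_min_length", "c4_paired_fraction"))

    def test_short_hairpin_fails_length_check(self):
        stem = "GCGCATGGATCCGATAGCGATCGATA"  # 26 nt arm -> 60 nt hairpin
        seq = stem + "GAAAACTC" + reverse_complement(stem)
        assert len(seq) == 60
        checks = validate_hairpin(fold(seq), (0, 21))
        assert not checks["c3_min_length"] and not checks["pass"]

    def test_unpaired_mature_window_fails_pairing_check(self):
        # hairpin of 80 nt whose mature region sits in unpaired flank
        stem = "GCGCATGGATCCGATAGCG"
        seq = "A" * 25 + stem + "GAAAACTC" + reverse_complement(stem) + "A" * 9
        checks = validate_hairpin(fold(seq), (0, 21))
        assert not checks["c2_pairing_window"] and not checks["pass"]

    def test_mature_span_outside_sequence_rejected(self):
        fr = fold("ACGT" * 20)
        with pytest.raises(ValueError):
            validate_hairpin(fr, (70, 95))


class TestTrimAndChoose:
    def _window(self, flank_left, flank_right, locus):
        seq = flank_left + locus.precursor_seq + flank_right
        m0 = len(flank_left) + locus.mature_span[0]
        span = (m0, m0 + 21)
        return (seq, span, ("chr1", 0, len(seq), "+"))

    def test_unpaired_flanks_removed(self):
        locus = make_hairpin_locus(MATURE, arm_len=34, loop_len=8, seed=1)
        w = self._window("T" * 60, "T" * 60, locus)
        fr, span, (c, s, e, st) = trim_and_choose([w])
        assert len(fr.seq) <= len(locus.precursor_seq) + 10
        assert "T" * 20 not in fr.seq

    def test_most_stable_window_chosen(self):
        weak = make_hairpin_locus(MATURE, arm_len=34, loop_len=8, seed=1)
        strong = make_hairpin_locus(MATURE, arm_len=44, loop_len=8, seed=2)
        w1 = self._window("T" * 10, "T" * 10, weak)
        w2 = self._window("T" * 10, "T" * 10, strong)
        chosen, _span, _loc = trim_and_choose([w1, w2])
        assert chosen.mfe == min(fold(w[0]).mfe for w in (w1, w2)) or \
            len(chosen.seq) >= len(weak.precursor_seq)
        # the deeper criterion: picked MFE equals the lower of the two
        alt = trim_and_choose([w1])[0]
        assert chosen.mfe <= alt.mfe

    def test_all_windows_invalid_returns_none(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        assert trim_and_choose([(seq, (20, 41), ("chr1", 0, 60, "+"))]) is None

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            trim_and_choose([])


class TestComputeMfei:
    @pytest.mark.parametrize("mfe,length,gc,amfe,mfei", [
        (-40.0, 100, 50.0, 40.0, 0.8),
        (-30.0, 100, 30.0, 30.0, 1.0),
        (-70.2, 90, 60.0, 78.0, 1.3),
    ])
    def test_formula(self, mfe, length, gc, amfe, mfei):
        a, m = compute_mfei(mfe, length, gc)
        assert a == pytest.approx(amfe)
        assert m == pytest.approx(mfei)

    def test_scale_consistency(self):
        """Doubling length at identical per-base energy leaves both indices
        unchanged."""
        a1, m1 = compute_mfei(-40.0, 100, 50.0)
        a2, m2 = compute_mfei(-80.0, 200, 50.0)
        assert (a1, m1) == (a2, m2)

    def test_mfei_threshold_classifies_likely_precursor(self):
        _a, mfei = compute_mfei(-40.0, 100, 50.0)
        assert mfei > 0.7  # above the precursor/other-RNA discrimination line

    def test_zero_gc_rejected(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 100, 0.0)


class TestInferStar:
    def test_perfect_stem_star_matches_geometry(self):
        locus = make_hairpin_locus(MATURE, arm_len=34, loop_len=8,
                                   n_bulges=0, seed=1)
        fr = fold(locus.precursor_seq)
        assert infer_star(fr, locus.mature_span) == locus.star_span

    def test_planted_star_recovered_with_bulges(self):
        locus = make_hairpin_locus(MATURE, arm_len=36, loop_len=9,
                                   n_bulges=2, seed=4)
        fr = fold(locus.precursor_seq)
        span = infer_star(fr, locus.mature_span)
        assert fr.seq[span[0]:span[1]] == locus.star_seq

    def test_unpaired_mature_gives_none(self):
        fr = FoldResult(seq="A" * 80, structure="." * 80, mfe=0.0)
        assert infer_star(fr, (10, 31)) is None


class TestAssignClass:
    def test_star_present_in_any_library_gives_class_I(self):
        tags = [tag(SEQ_A, total=1)]
        assert assign_class(SEQ_A, tags) == "I"

    def test_star_absent_gives_class_II(self):
        assert assign_class(SEQ_A, [tag(SEQ_B, total=1000)]) == "II"

    def test_no_star_sequence_gives_class_II(self):
        assert assign_class(None, [tag(SEQ_A)]) == "II"


class TestDiscoverEndToEnd:
    def test_reported_candidates_reverify(self, demo_study, demo_candidates):
        """Every reported precursor occurs in the genome at its locus, the
        mature maps inside it, and the recorded checks re-verify."""
        cands, _stats = demo_candidates
        assert cands
        for c in cands:
            chrom, s, e, strand = c.locus
            genomic = demo_study.genome[chrom][s:e]
            if strand == "-":
                genomic = reverse_complement(genomic)
            assert genomic == c.precursor.seq
            m0, m1 = c.mature_span
            assert c.precursor.seq[m0:m1] == c.mature_seq
            rechecked = validate_hairpin(c.precursor, c.mature_span)
            assert rechecked == c.checks and rechecked["pass"]
            assert c.randfold_p <= 0.1
            assert c.amfe == pytest.approx(abs(c.precursor.mfe)
                                           / len(c.precursor.seq) * 100)
            assert c.mfei == pytest.approx(c.amfe / c.gc_percent)

    def test_deduplication_merges_identical_matures(self):
        locus = make_hairpin_locus(MATURE, arm_len=34, loop_len=8,
                                   n_bulges=1, seed=5)
        spacer = "TTTTACCCTTTGGGATCAGGACCCTTTAAGGGACTA" * 30
        chrom = ("T" * 400 + locus.precursor_seq + spacer
                 + locus.precursor_seq + "T" * 400)
        tags = [tag(MATURE, total=50)]
        cands = discover(tags, {"chr1": chrom}, seed=0)
        assert len(cands) == 1
        assert len(cands[0].extra_loci) == 1

    def test_validation_verdicts_backend_independent(self):
        """Generator-built canonical and defective fixtures get the same
        verdict under the internal and the Vienna backend."""
        from mirscout.fold import fold_vienna

        good = make_hairpin_locus(MATURE, arm_len=34, loop_len=8, seed=1)
        stem = "GCGCATGGATCCGATAGCGATCGATA"
        bad_seq = stem + "GAAAACTC" + reverse_complement(stem)  # 60 nt
        for fold_fn in (fold, fold_vienna):
            ok = validate_hairpin(fold_fn(good.precursor_seq), good.mature_span)
            assert ok["pass"]
            ko = validate_hairpin(fold_fn(bad_seq), (0, 21))
            assert not ko["pass"]
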