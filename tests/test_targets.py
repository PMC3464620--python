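import math
from fractions import Fraction

import numpy as np
import pytest

from mirscout.fold import _BASE_CODE, _PAIR_INDEX, _STACK, reverse_complement
from mirscout.synthetic import build_target_site, plant_target_sites, random_transcripts
from mirscout.targets import (
    RULE_NAMES,
    average_targets_per_mirna,
    duplex_mfe,
    go_enrichment,
    rules_pass,
    scan_transcripts,
    score_duplex,
)
from oracles import brute_duplex_verdicts, hypergeom_upper_tail

MATURE = "AAAACGTCTTATAATTTGGAG"


def oracle_stack_energy(pair_a, pair_b):
    """Stack term lookup for the brute-force oracle, reading the packaged
    table through the pair-type indices directly."""
    pa = _PAIR_INDEX[_BASE_CODE[pair_a[0]], _BASE_CODE[pair_a[1]]]
    pb = _PAIR_INDEX[_BASE_CODE[pair_b[0]], _BASE_CODE[pair_b[1]]]
    if pa < 0 or pb < 0:
        return None
    return float(_STACK[pa, pb])


class TestScoreDuplex:
    def test_perfect_complement_scores_zero_mismatches(self):
        aln = score_duplex(MATURE, reverse_complement(MATURE))
        assert aln.mismatch_total == 0.0
        assert aln.mfe_ratio == pytest.approx(1.0)
        assert set(aln.classes) == {"WC"}

    def test_single_gu_counts_half(self):
        aln = score_duplex(MATURE, build_target_site(MATURE, [(6, "GU")]))
        assert aln.mismatch_total == 0.5
        assert aln.classes[5] == "GU"

    def test_mixed_mismatches_sum(self):
        site = build_target_site(MATURE, [(2, "other"), (18, "other"),
                                          (6, "GU"), (7, "GU")])
        aln = score_duplex(MATURE, site)
        assert aln.mismatch_total == 3.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(MATURE, "ACGT")


class TestRulesPass:
    def test_perfect_duplex_passes(self):
        ok, trace = rules_pass(score_duplex(MATURE, reverse_complement(MATURE)))
        assert ok and all(v for _n, v in trace)

    @pytest.mark.parametrize("pattern,failed_rule", [
        ([(10, "other")], "R4_cleavage_wc"),
        ([(11, "other")], "R4_cleavage_wc"),
        ([(5, "other"), (6, "other")], "R3_adjacent_2_12"),
        ([(2, "other"), (14, "other"), (16, "other"),
          (18, "other"), (20, "other")], "R1_total"),
    ])
    def test_designed_violations_fail_expected_rule(self, pattern, failed_rule):
        aln = score_duplex(MATURE, build_target_site(MATURE, pattern))
        ok, trace = rules_pass(aln)
        assert not ok
        assert dict(trace)[failed_rule] is False

    def test_gu_cleavage_site_configurable(self):
        site = build_target_site(MATURE, [(10, "GU")])  # position 10 is T
        aln = score_duplex(MATURE, site)
        assert not rules_pass(aln)[0]
        ok_gu, trace = rules_pass(aln, allow_gu_cleavage_site=True)
        assert dict(trace)["R4_cleavage_wc"] is True

    def test_monotone_destructive(self, rng):
        """Adding a mismatch to a passing alignment never flips a failing
        rule to passing."""
        for _ in range(30):
            mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            site = reverse_complement(mirna)
            _ok1, t1 = rules_pass(score_duplex(mirna, site))
            pos = int(rng.integers(21))
            mutated = list(site)
            mutated[pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[pos]]
            _ok2, t2 = rules_pass(score_duplex(mirna, "".join(mutated)))
            for (name, v1), (_n, v2) in zip(t1, t2):
                if not v1:
                    assert not v2, name

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Rule engine matches first-principles predicate evaluation on
        random 21-mer pairs (biased toward near-complements so every rule
        gets exercised)."""
        n_checked = 0
        for _ in range(2000):
            mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            site = list(reverse_complement(mirna))
            for _m in range(int(rng.integers(0, 6))):
                p = int(rng.integers(21))
                site[p] = "ACGT"[int(rng.integers(4))]
            site = "".join(site)
            ok, trace = rules_pass(score_duplex(mirna, site))
            expected = brute_duplex_verdicts(mirna, site, oracle_stack_energy)
            assert tuple(v for _n, v in trace) == expected
            assert ok == all(expected)
            n_checked += 1
        assert n_checked == 2000


class TestDuplexMfe:
    def test_perfect_ratio_exactly_one(self):
        aln = score_duplex(MATURE, reverse_complement(MATURE))
        assert aln.duplex_mfe == aln.perfect_mfe < 0

    def test_internal_mismatch_strictly_destabilises(self):
        site = build_target_site(MATURE, [(11, "other")])
        aln = score_duplex(MATURE, site)
        assert aln.mfe_ratio < 1.0

    def test_hand_summed_toy_duplex(self):
        """4 consecutive pairs GC,CG,AU,UA: energy is the sum of the three
        stack-table entries read off by hand."""
        mirna, site = "GCAT", "ATGC"
        expected = (float(_STACK[2, 1])   # GC on CG
                    + float(_STACK[1, 0])  # CG on AU
                    + float(_STACK[0, 3]))  # AU on UA
        assert duplex_mfe(mirna, site) == pytest.approx(expected)


class TestScanTranscripts:
    def test_planted_perfect_site_found_at_offset(self):
        txs = random_transcripts(5, 300, seed=11)
        planted, truth = plant_target_sites(txs, MATURE, seed=12, mature_id="m")
        report = scan_transcripts({"m": MATURE}, planted)
        df = report.to_frame()
        (mid, tid, pos, _pat) = truth[0]
        assert [(r["transcript"], r["site_start"]) for _i, r in df.iterrows()] \
            == [(tid, pos)]

    def test_cleavage_site_mismatch_never_reported(self):
        txs = random_transcripts(5, 300, seed=13)
        planted, _truth = plant_target_sites(
            txs, MATURE, mismatch_pattern=[(10, "other")], seed=14, mature_id="m")
        assert scan_transcripts({"m": MATURE}, planted).to_frame().empty

    def test_average_targets_per_mirna_definition(self):
        txs = random_transcripts(4, 300, seed=15)
        planted, _t = plant_target_sites(txs, MATURE, seed=16, mature_id="m1")
        report = scan_transcripts({"m1": MATURE, "m2": "ACGT" * 5 + "A"}, planted)
        df = report.to_frame()
        with_hits = df["mirna"].nunique()
        assert report.targets_per_mirna() == len(df) / with_hits

    def test_catalog_average_helper(self):
        assert average_targets_per_mirna(895, 373) == pytest.approx(2.4, abs=0.01)
        assert average_targets_per_mirna(1975, 483) == pytest.approx(4.09, abs=0.01)


class TestGoEnrichment:
    def test_exact_combinatorial_case(self):
        universe = [f"g{i}" for i in range(20)]
        annotation = {g: ["GO:X"] for g in universe[:5]}
        df = go_enrichment(universe[:5], annotation, universe)
        assert df.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5))

    def test_term_covering_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        annotation = {g: ["GO:ALL"] for g in universe}
        df = go_enrichment(universe[:3], annotation, universe)
        assert df.loc[0, "p"] == 1.0

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        annotation = {"g9": ["GO:Y"]}
        df = go_enrichment(universe[:3], annotation, universe)
        assert df.loc[0, "p"] == pytest.approx(
            float(hypergeom_upper_tail(0, 10, 1, 3)))

    def test_matches_exact_oracle_to_1e12(self, rng):
        """Hypergeometric p equals exact factorial arithmetic to 1e-12
        relative error across random configurations with N <= 200."""
        for _ in range(40):
            N = int(rng.integers(10, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            targets = universe[:n]
            annotation = {g: ["GO:T"] for g in
                          rng.choice(universe, size=K, replace=False)}
            df = go_enrichment(targets, annotation, universe)
            k = int(df.loc[0, "k"])
            exact = float(hypergeom_upper_tail(k, N, K, n))
            assert df.loc[0, "p"] == pytest.approx(exact, rel=1e-12)

    def test_targets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(["x"], {}, ["a", "b"])

    def test_bh_adjustment_across_terms(self):
        universe = [f"g{i}" for i in range(50)]
        annotation = {}
        for g in universe[:10]:
            annotation.setdefault(g, []).append("GO:A")
        for g in universe[40:]:
            annotation.setdefault(g, []).append("GO:B")
        df = go_enrichment(universe[:10], annotation, universe).set_index("term")
        assert df.loc["GO:A", "p_bh"] <= 2 * df.loc["GO:A", "p"]
        assert (df["p_bh"] >= df["p"] - 1e-15).all()
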