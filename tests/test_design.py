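"""Synonymous redesign: pause insertion/removal, synonymy guarantees."""

import itertools

import numpy as np
import pytest

from ribodesign import (
    AttenuationSite,
    DesignConfig,
    Orf,
    Threshold,
    insert_pause,
    raw_profile,
    remove_all_pauses,
    remove_pause,
    smooth,
    verify_synonymy,
    detect_minima,
)
from ribodesign._codons import CODON_TO_AA, SENSE_CODONS, synonyms
from ribodesign.design import SubstitutionPlan

from conftest import brute_smooth, random_orf, random_rates


def build_orf(codons, orf_id="d"):
    return Orf(id=orf_id, dna="".join(codons))


def fast_background(rates, length, rng=None):
    """Codons of fast (rate >= 0.5), non-Leu amino acids, ATG first."""
    pool = [
        c
        for c in SENSE_CODONS
        if rates[c] >= 0.5 and CODON_TO_AA[c] != "L" and len(synonyms(c)) > 1
    ]
    rng = rng or np.random.default_rng(0)
    return ["ATG"] + [pool[i] for i in rng.integers(len(pool), size=length - 1)]


class TestInsertPause:
    def test_single_leu_swapped_to_cta_at_preferred_offset(self, ecoli):
        codons = fast_background(ecoli, 200)
        codons[129] = "CTG"  # codon 130 = domain end 100 + offset 30
        plan = insert_pause(build_orf(codons), 100, ecoli)
        assert [(e.codon_pos, e.old_codon, e.new_codon) for e in plan.edits] == [
            (130, "CTG", "CTA")
        ]
        assert plan.edits[0].reason == "insert_pause"

    def test_nearest_leu_wins_ties_to_smaller_position(self, ecoli):
        codons = fast_background(ecoli, 200)
        codons[124], codons[134] = "CTC", "CTT"  # codons 125 and 135, both 5 aa away
        plan = insert_pause(build_orf(codons), 100, ecoli)
        assert [(e.codon_pos, e.new_codon) for e in plan.edits] == [(125, "CTA")]

    def test_existing_cta_means_site_already_slow(self, ecoli):
        codons = fast_background(ecoli, 200)
        codons[129] = "CTA"
        codons[139] = "CTG"
        plan = insert_pause(build_orf(codons), 100, ecoli)
        assert plan.edits == ()
        assert plan.result_dna == "".join(codons)

    def test_window_outside_orf_rejected(self, ecoli):
        with pytest.raises(ValueError, match="outside"):
            insert_pause(build_orf(fast_background(ecoli, 100)), 90, ecoli)

    def test_met_trp_only_window_has_no_slowdown(self, ecoli):
        codons = fast_background(ecoli, 30) + ["ATG", "TGG"] * 35
        cfg = DesignConfig(offset_range_aa=(20, 30), preferred_offset_aa=25)
        with pytest.raises(ValueError, match="no synonymous slow-down"):
            insert_pause(build_orf(codons), 15, ecoli, cfg)

    def test_leu_free_window_matches_exhaustive_search(self):
        """Greedy slowest-synonym fallback reaches the optimum of a
        brute-force enumeration over a short (<=10 codon) window."""
        rng = np.random.default_rng(42)
        cfg = DesignConfig(
            offset_range_aa=(20, 29), preferred_offset_aa=25, max_codons_per_site=3
        )
        for trial in range(25):
            rates = random_rates(rng)
            codons = fast_background(rates, 120, rng)
            orf = build_orf(codons)
            plan = insert_pause(orf, 30, rates, cfg)
            # oracle: enumerate all <=3-subsets of window codons 50..59,
            # each edited position set to any synonym
            def window_min_full(cs):
                sm = brute_smooth([rates[c] for c in cs], 19)
                return min(v for p, v in sm.items() if 50 <= p <= 59)

            best = window_min_full(codons)
            for k in range(1, 4):
                for positions in itertools.combinations(range(50, 60), k):
                    choice_sets = [
                        [s for s in synonyms(codons[p - 1])] for p in positions
                    ]
                    for combo in itertools.product(*choice_sets):
                        trial_codons = list(codons)
                        for p, c in zip(positions, combo):
                            trial_codons[p - 1] = c
                        best = min(best, window_min_full(trial_codons))
            achieved = window_min_full(plan.result_dna[i : i + 3] for i in range(0, len(plan.result_dna), 3))
            assert achieved == pytest.approx(best)
            assert len(plan.edits) <= 3

    def test_strictly_lowers_window_smoothed_min_or_empty(self, ecoli):
        rng = np.random.default_rng(7)
        for trial in range(20):
            codons = fast_background(ecoli, 200, rng)
            if rng.uniform() < 0.5:
                codons[int(rng.integers(120, 171))] = rng.choice(["CTG", "CTC", "CTT", "TTG"])
            orf = build_orf(codons)
            plan = insert_pause(orf, 100, ecoli)
            if not plan.edits:
                continue
            before = smooth(raw_profile(orf, ecoli), 19)
            after = smooth(raw_profile(Orf(id="a", dna=plan.result_dna), ecoli), 19)
            win = [p for p in before.smoothed_positions() if 120 <= p <= 170]
            assert min(after.smoothed_at(p) for p in win) < min(
                before.smoothed_at(p) for p in win
            )


class TestRemovePause:
    def test_slow_codons_swapped_to_fastest_synonyms(self, ecoli):
        codons = fast_background(ecoli, 60)
        codons[20:23] = ["CTA", "CAT", "TCG"]
        site = AttenuationSite(
            start_codon=21, end_codon=23, argmin_codon=22, depth=0.1, threshold=0.5
        )
        plan = remove_pause(build_orf(codons), site, ecoli)
        swaps = {e.old_codon: e.new_codon for e in plan.edits}
        assert swaps["CTA"] == "CTG"
        assert set(swaps) == {"CTA", "CAT", "TCG"}
        for old, new in swaps.items():
            assert new == ecoli.fastest_synonym(old)
            assert CODON_TO_AA[new] == CODON_TO_AA[old]

    def test_all_fastest_site_needs_no_edits(self, ecoli):
        codons = ["ATG"] + [ecoli.fastest_synonym(c) for c in fast_background(ecoli, 60)[1:]]
        site = AttenuationSite(
            start_codon=10, end_codon=30, argmin_codon=20, depth=0.1, threshold=0.99
        )
        plan = remove_pause(build_orf(codons), site, ecoli)
        assert plan.edits == ()

    def test_post_edit_rates_match_per_position_max_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            rates = random_rates(rng)
            orf = random_orf(rng, 80)
            site = AttenuationSite(
                start_codon=10, end_codon=60, argmin_codon=30, depth=0.0, threshold=1.1
            )
            plan = remove_pause(orf, site, rates)
            new_codons = [plan.result_dna[i : i + 3] for i in range(0, len(plan.result_dna), 3)]
            for pos in range(10, 61):
                expected = max(rates[c] for c in synonyms(orf.codons()[pos - 1]))
                assert rates[new_codons[pos - 1]] == pytest.approx(expected)

    def test_never_decreases_any_raw_rate_in_site(self, ecoli):
        rng = np.random.default_rng(5)
        orf = random_orf(rng, 100)
        site = AttenuationSite(
            start_codon=5, end_codon=95, argmin_codon=50, depth=0.0, threshold=0.4
        )
        plan = remove_pause(orf, site, ecoli)
        before = raw_profile(orf, ecoli).raw
        after = raw_profile(Orf(id="a", dna=plan.result_dna), ecoli).raw
        assert (after >= before - 1e-12).all()

    def test_requires_a_threshold(self, ecoli):
        site = AttenuationSite(start_codon=2, end_codon=4, argmin_codon=3, depth=0.1)
        with pytest.raises(ValueError, match="threshold"):
            remove_pause(build_orf(fast_background(ecoli, 30)), site, ecoli)


class TestRemoveAllPauses:
    def _orf_with_dips(self, ecoli, rng):
        # dips of slow codons whose amino acids all have fast synonyms,
        # so acceleration can fully erase the sites
        slow_pool = ["CTA", "AGG", "GCC", "GTC", "CGG"]
        codons = fast_background(ecoli, 240, rng)
        for center in (60, 160):
            for k, i in enumerate(range(center - 9, center + 10)):
                codons[i] = slow_pool[k % len(slow_pool)]
        return build_orf(codons)

    def test_closure_rerunning_detection_finds_no_more_sites(self, ecoli):
        rng = np.random.default_rng(31)
        orf = self._orf_with_dips(ecoli, rng)
        thr = Threshold(value=0.45)
        before = detect_minima(smooth(raw_profile(orf, ecoli), 19), thr)
        assert len(before) == 2
        plan = remove_all_pauses(orf, thr, ecoli)
        after = detect_minima(
            smooth(raw_profile(Orf(id="a", dna=plan.result_dna), ecoli), 19), thr
        )
        assert len(after) <= len(before)
        assert after == []

    def test_uniform_orf_yields_empty_plan(self, ecoli):
        orf = build_orf(fast_background(ecoli, 100))
        plan = remove_all_pauses(orf, Threshold(value=0.2), ecoli)
        assert plan.edits == ()

    def test_merged_plan_equals_union_of_per_site_plans(self, ecoli):
        rng = np.random.default_rng(32)
        orf = self._orf_with_dips(ecoli, rng)
        thr = Threshold(value=0.45)
        merged = remove_all_pauses(orf, thr, ecoli)
        sites = detect_minima(smooth(raw_profile(orf, ecoli), 19), thr)
        union = []
        for s in sites:
            union.extend(remove_pause(orf, s, ecoli, threshold=thr).edits)
        assert sorted(merged.edits, key=lambda e: e.codon_pos) == sorted(
            union, key=lambda e: e.codon_pos
        )


class TestVerifySynonymy:
    def test_printed_worked_pair(self):
        src = Orf(id="m9", dna="ATGAAACCCCGCACGGTGCCG")
        plan = SubstitutionPlan(orf_id="m9", edits=(), result_dna="ATGAAACCACGAACAGTACCA")
        assert verify_synonymy(src, plan)

    def test_identity(self):
        src = Orf(id="x", dna="ATGAAACCC")
        assert verify_synonymy(src, SubstitutionPlan(orf_id="x", edits=(), result_dna=src.dna))

    def test_nonsynonymous_single_nucleotide_change(self):
        src = Orf(id="x", dna="ATGAAACCC")
        plan = SubstitutionPlan(orf_id="x", edits=(), result_dna="ATGCAACCC")
        assert not verify_synonymy(src, plan)

    def test_length_mismatch_rejected(self):
        src = Orf(id="x", dna="ATGAAACCC")
        with pytest.raises(ValueError, match="length"):
            verify_synonymy(src, SubstitutionPlan(orf_id="x", edits=(), result_dna="ATGAAA"))


class TestPlanInvariants:
    def test_round_trip_dominance(self, ecoli):
        """insert_pause then remove_pause restores rates to >= original."""
        rng = np.random.default_rng(77)
        for _ in range(10):
            codons = fast_background(ecoli, 200, rng)
            codons[int(rng.integers(125, 166))] = "CTG"
            orf = build_orf(codons)
            plan = insert_pause(orf, 100, ecoli)
            site = AttenuationSite(
                start_codon=120, end_codon=170, argmin_codon=140, depth=0.0, threshold=1.1
            )
            back = remove_pause(Orf(id="b", dna=plan.result_dna), site, ecoli)
            orig = raw_profile(orf, ecoli).raw
            restored = raw_profile(Orf(id="c", dna=back.result_dna), ecoli).raw
            assert (restored >= orig - 1e-12).all()

    def test_ddg_guard_reports_warnings_without_dropping_edits(self, ecoli):
        big_shift_engine = lambda rna: -10.0 * rna.count("UA")  # wildly sequence-sensitive
        codons = fast_background(ecoli, 200)
        codons[129] = "CTG"
        orf = Orf(id="g", dna="".join(codons), upstream="A" * 30)
        plan = insert_pause(orf, 100, ecoli, engine=big_shift_engine)
        assert len(plan.edits) == 1
        assert plan.edits[0].local_ddG is not None
        assert plan.warnings  # |ddG| exceeds the 2 kcal/mol guard
        quiet = insert_pause(orf, 100, ecoli, engine=lambda rna: 0.0)
        assert quiet.warnings == ()

    def test_duplicate_edit_positions_rejected(self):
        from ribodesign.design import Edit

        with pytest.raises(ValueError, match="position"):
            SubstitutionPlan(
                orf_id="x",
                edits=(Edit(3, "CTG", "CTA", "insert_pause"), Edit(3, "CTG", "CTC", "insert_pause")),
                result_dna="ATG",
            )
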