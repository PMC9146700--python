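"""Event calling, uniqueness patterns, coding effects, tallies."""

import pytest

from mitotrio.align import AnchoredMSA
from mitotrio.compare import VariantEvent, call_events, classify_pattern, tally
from mitotrio.mitio import CircularSeq, Feature, FeatureClass, MitoGenome, Strand
from mitotrio.synth import CONSPECIFIC, REFERENCE, TARGET


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("A", "T", "T"), "unique_target"),
            (("C", "C", "T"), "diagnostic_pair"),
            (("C", "T", "C"), "unique_other1"),
            (("A", "C", "G"), "all_distinct"),
            (("AT", "AT", "-"), "diagnostic_pair"),
        ],
    )
    def test_trio_patterns(self, alleles, expected):
        assert classify_pattern(alleles) == expected

    def test_without_conspecific_designation(self):
        assert classify_pattern(("C", "C", "T"), conspecific_index=None) == "unique_other2"

    def test_invariant_site_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(("A", "A", "A"))


def _tiny_msa_and_annotation():
    #            0123456789012345
    t = "ATGATTAAATAAGGCC"
    rows = (
        "ATGATTAAATAAGG--CC",
        "ATGTTTAAATAAGGATCC",
        "ATGTTTAAATAAGGATCC",
    )
    msa = AnchoredMSA("t", ("t", "c", "r"), rows)
    ann = MitoGenome(
        CircularSeq("t", t),
        [Feature("nd2", FeatureClass.PCG, Strand.LIGHT, 1, 12)],
    )
    return msa, ann


class TestCallEvents:
    def test_substitution_and_indel_events(self):
        msa, ann = _tiny_msa_and_annotation()
        events = call_events(msa, ann)
        assert len(events) == 2
        sub, indel = events
        assert sub.kind == "substitution" and sub.span == (3, 3)
        assert sub.pattern == "unique_target"
        assert sub.alleles == {"t": "A", "c": "T", "r": "T"}
        assert indel.kind == "indel" and indel.span == (14, 15)
        assert indel.alleles == {"t": "-", "c": "AT", "r": "AT"}
        assert indel.pattern == "unique_target"
        assert indel.region_class is FeatureClass.INTERGENIC

    def test_missense_direction_and_codon_translation(self):
        msa, ann = _tiny_msa_and_annotation()
        sub = call_events(msa, ann)[0]
        # codon 2: target ATT (Ile) vs others TTT (Phe); unique events read others->target
        assert sub.effect == "missense"
        assert sub.aa_change == "F->I"

    def test_identical_rows_give_no_events(self):
        s = "ATGAAATTTAAA"
        msa = AnchoredMSA("a", ("a", "b", "c"), (s, s, s))
        ann = MitoGenome(CircularSeq("a", s), [])
        assert call_events(msa, ann) == []

    def test_annotation_sequence_mismatch_rejected(self):
        msa, _ = _tiny_msa_and_annotation()
        wrong = MitoGenome(CircularSeq("t", "AAAA"), [])
        with pytest.raises(ValueError):
            call_events(msa, wrong)

    def test_event_partition_covers_all_variable_columns(self, analysis):
        msa = analysis.msa
        cols = set()
        for e in analysis.report.events:
            run = set(range(e.span[0], e.span[1] + 1))
            assert not (cols & run)  # disjoint
            cols |= run
        variable = {
            c for c in range(msa.ncols)
            if len({r[c] for r in msa.rows}) > 1
        }
        assert cols == variable


class TestAgainstLedger:
    def test_every_planted_event_recovered_exactly(self, analysis, trio):
        _genomes, ledger = trio
        called = {
            (e.positions[TARGET], tuple(sorted(e.alleles.items()))): e
            for e in analysis.report.events
        }
        assert len(analysis.report.events) == len(ledger.events)
        for pe in ledger.events:
            ce = called.get((pe.positions[TARGET], tuple(sorted(pe.alleles.items()))))
            assert ce is not None, f"event at {pe.base_pos} not recovered"
            assert ce.pattern == pe.pattern
            assert ce.region_class == pe.region_class
            assert ce.region_name == pe.region_name
            if pe.effect != "NA":
                assert ce.effect == pe.effect
            if pe.aa_change:
                assert ce.aa_change == pe.aa_change

    def test_study_shaped_tallies(self, analysis):
        rep = analysis.report
        tr = rep.pair_totals[(TARGET, REFERENCE)]
        tc = rep.pair_totals[(TARGET, CONSPECIFIC)]
        assert (tr, tc) == (64, 59)
        assert rep.pair_by_region[(TARGET, REFERENCE)] == {
            "tRNA": 4, "PCG": 24, "rRNA": 11, "control": 14, "intergenic": 11,
        }
        assert rep.pattern_totals["diagnostic_pair"] == 23
        by_pat = {}
        for e in rep.missense:
            by_pat[e.pattern] = by_pat.get(e.pattern, 0) + 1
        assert by_pat == {"unique_target": 8, "diagnostic_pair": 3}

    def test_uniqueness_algebra(self, analysis):
        """|pair(T,C)| + |pair(T,R)| - |pair(C,R)| == 2 * |unique_T| without
        all-distinct sites."""
        rep = analysis.report
        lhs = (rep.pair_totals[(TARGET, CONSPECIFIC)]
               + rep.pair_totals[(TARGET, REFERENCE)]
               - rep.pair_totals[(CONSPECIFIC, REFERENCE)])
        assert lhs == 2 * rep.pattern_totals["unique_target"]

    def test_effect_invariant_under_reanchoring(self, trio):
        """Swapping which genome anchors the msa preserves substitution effects."""
        from mitotrio.pipeline import run_trio

        genomes, ledger = trio
        # un-rotate the conspecific so both runs share one coordinate frame
        consp = genomes[CONSPECIFIC].rotated(-ledger.rotation_offsets[CONSPECIFIC])
        res = run_trio(genomes[TARGET].seq, consp.seq, genomes[REFERENCE])
        swapped = run_trio(consp.seq, genomes[TARGET].seq, genomes[REFERENCE])

        def effects(r):
            return {
                (e.positions[REFERENCE], tuple(sorted(e.alleles.items()))): e.effect
                for e in r.report.events if e.kind == "substitution"
            }

        assert effects(res) == effects(swapped)


class TestTally:
    def test_empty_event_list_all_zero(self):
        rep = tally([], ("a", "b", "c"))
        assert all(v == 0 for v in rep.pair_totals.values())
        assert rep.pattern_totals == {} and rep.missense == []

    def test_column_mode_counts_indel_span(self):
        e_sub = VariantEvent((0, 0), "substitution", {"a": "A", "b": "T", "c": "T"},
                             FeatureClass.INTERGENIC, "IR", "unique_target")
        e_ind = VariantEvent((5, 7), "indel", {"a": "ATT", "b": "-", "c": "-"},
                             FeatureClass.CONTROL, "control_region", "unique_target")
        ev = tally([e_sub, e_ind], ("a", "b", "c"), count_mode="event")
        col = tally([e_sub, e_ind], ("a", "b", "c"), count_mode="column")
        assert ev.pair_totals[("a", "b")] == 2
        assert col.pair_totals[("a", "b")] == 4

    def test_region_breakdown_sums_to_pair_total(self, analysis):
        rep = analysis.report
        for pair, total in rep.pair_totals.items():
            assert sum(rep.pair_by_region[pair].values()) == total

    def test_unknown_count_mode_rejected(self):
        with pytest.raises(ValueError):
            tally([], ("a", "b"), count_mode="sites")
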