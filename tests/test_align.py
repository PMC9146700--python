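"""Banded affine alignment, rotation anchoring, normalisation, anchored merge."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotrio.align import (
    AlignParams,
    AnchoredMSA,
    anchor_merge,
    global_align,
    left_normalize,
    msa_from_pair,
    rotate_to_anchor,
)
from mitotrio.errors import AnchorError
from mitotrio.mitio import CircularSeq
from mitotrio.synth import CONSPECIFIC, TARGET


def _mutate(rng, s, n_sub=10, n_indel=3):
    b = list(s)
    for _ in range(n_sub):
        i = rng.randrange(len(b))
        b[i] = rng.choice("ACGT")
    for _ in range(n_indel):
        i = rng.randrange(len(b))
        if rng.random() < 0.5:
            b.insert(i, rng.choice("ACGT"))
        elif len(b) > 10:
            del b[i]
    return "".join(b)


class TestGlobalAlign:
    def test_identical_sequences_have_no_gap_columns(self):
        aln = global_align("AAATTT", "AAATTT")
        assert aln.rows == ("AAATTT", "AAATTT")
        assert aln.score == 12.0

    def test_forced_gap_lands_leftmost_in_homopolymer(self):
        aln = global_align("AAA", "AA")
        assert aln.rows[1] == "-AA"

    def test_score_symmetry(self):
        rng = random.Random(3)
        a = "".join(rng.choice("ACGT") for _ in range(150))
        b = _mutate(rng, a)
        assert global_align(a, b).score == global_align(b, a).score

    def test_column_count_lower_bound(self):
        rng = random.Random(4)
        a = "".join(rng.choice("ACGT") for _ in range(200))
        b = _mutate(rng, a)
        aln = global_align(a, b)
        assert aln.ncols >= max(len(a), len(b))
        assert global_align(a, a).ncols == len(a)

    def test_ungapping_recovers_inputs(self):
        rng = random.Random(5)
        a = "".join(rng.choice("ACGT") for _ in range(300))
        b = _mutate(rng, a)
        aln = global_align(a, b)
        assert aln.ungapped(0) == a and aln.ungapped(1) == b

    def test_band_doubles_to_cover_large_length_difference(self):
        # a 60 bp insertion forces the path far off the main diagonal
        rng = random.Random(6)
        a = "".join(rng.choice("ACGT") for _ in range(400))
        b = a[:200] + "".join(rng.choice("ACGT") for _ in range(60)) + a[200:]
        aln = global_align(a, b, AlignParams(band=8, band_cap=256))
        assert aln.ungapped(1) == b

    def test_banded_scores_match_independent_full_dp(self):
        """The banded aligner equals an unbanded affine aligner on near-identical pairs."""
        from Bio.Align import PairwiseAligner

        p = AlignParams(band=40)
        oracle = PairwiseAligner(
            mode="global", match_score=p.match, mismatch_score=p.mismatch,
            open_gap_score=p.gap_open, extend_gap_score=p.gap_extend)
        rng = random.Random(11)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(300))
            b = _mutate(rng, a, n_sub=8, n_indel=3)  # >=95% identity
            assert global_align(a, b, p).score == pytest.approx(oracle.score(a, b))


class TestLeftNormalize:
    def test_gap_absorbed_to_run_start(self):
        assert left_normalize("AAA", "A-A") == ("AAA", "-AA")

    def test_microsatellite_deletion_pinned_leftmost(self):
        # deleting one AT from an (AT)3 tract: the gap migrates to the tract start
        ra, rb = left_normalize("CATATATG", "CATAT--G")
        assert rb == "C--ATATG"

    @given(st.text(alphabet="AT-", min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_normalisation_preserves_both_ungapped_rows(self, raw):
        rb = raw
        ra = "".join("A" if c == "-" else c for c in raw)  # no gap/gap columns
        na, nb = left_normalize(ra, rb)
        assert na.replace("-", "") == ra.replace("-", "")
        assert nb.replace("-", "") == rb.replace("-", "")
        # idempotent
        assert left_normalize(na, nb) == (na, nb)


class TestRotateToAnchor:
    def test_self_rotation_recovers_offset(self):
        rng = random.Random(7)
        s = CircularSeq("s", "".join(rng.choice("ACGT") for _ in range(500)))
        rotated, off = rotate_to_anchor(s.rotate(100), s)
        assert off == 400 and rotated.residues == s.residues

    def test_identical_sequences_offset_zero(self):
        s = CircularSeq("s", "ACGTACGTACGTACGTACGTACGTACGT" * 3)
        _, off = rotate_to_anchor(s, s)
        assert off == 0

    def test_planted_rotation_recovered(self, trio):
        genomes, ledger = trio
        tgt = genomes[TARGET].seq
        con = genomes[CONSPECIFIC].seq
        rotated, off = rotate_to_anchor(con, tgt)
        r = ledger.rotation_offsets[CONSPECIFIC]
        assert (off + r) % len(con) == 0  # undoes the planted rotation
        assert rotated.residues == genomes[CONSPECIFIC].rotated(-r).seq.residues

    def test_divergent_sequences_raise_anchor_error(self):
        a = CircularSeq("a", "A" * 200)
        b = CircularSeq("b", "C" * 200)
        with pytest.raises(AnchorError):
            rotate_to_anchor(a, b)


class TestAnchorMerge:
    def test_single_alignment_merge_is_identity(self):
        aln = global_align("ACGTACGTAA", "ACGTACGAA")
        msa = anchor_merge([aln])
        assert msa.rows == aln.rows

    def test_three_identical_sequences_no_gap_columns(self):
        s = "ACGTACGTACGT"
        msa = anchor_merge([global_align(s, s, ids=("r", "b")),
                            global_align(s, s, ids=("r", "c"))])
        assert msa.ncols == len(s) and all("-" not in r for r in msa.rows)

    def test_rows_ungap_to_inputs(self):
        rng = random.Random(9)
        ref = "".join(rng.choice("ACGT") for _ in range(300))
        b = _mutate(rng, ref)
        c = _mutate(rng, ref)
        msa = anchor_merge([global_align(ref, b, ids=("r", "b")),
                            global_align(ref, c, ids=("r", "c"))])
        assert msa.ungapped(0) == ref
        assert msa.ungapped(1) == b and msa.ungapped(2) == c

    def test_mismatched_references_rejected(self):
        with pytest.raises(ValueError):
            anchor_merge([global_align("ACGT", "ACGT"), global_align("TTTT", "TTTT")])

    def test_msa_sanity_bound_on_trio(self, analysis):
        msa = analysis.msa
        longest = max(len(msa.ungapped(i)) for i in range(msa.nrows))
        assert msa.ncols < 1.05 * longest

    def test_planted_events_occupy_contiguous_runs(self, analysis, trio):
        _genomes, ledger = trio
        # every ledger indel appears as one maximal gap run in the msa
        called_indels = [e for e in analysis.report.events if e.kind == "indel"]
        planted_indels = [e for e in ledger.events if e.kind in ("insertion", "deletion")]
        assert len(called_indels) == len(planted_indels)


def test_msa_from_pair_view():
    aln = global_align("ACGTT", "ACGT")
    msa = msa_from_pair(aln)
    assert isinstance(msa, AnchoredMSA) and msa.rows == aln.rows
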