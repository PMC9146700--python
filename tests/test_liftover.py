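"""Annotation projection, rescue, overlap curation, gene-order comparison."""

import pytest

from mitotrio.align import global_align
from mitotrio.liftover import (
    GeneOrder,
    curate_overlaps,
    gene_order_diff,
    named_order,
    project_features,
    rescue_unmapped,
)
from mitotrio.mitio import CircularSeq, Feature, FeatureClass, MitoGenome, Strand
from mitotrio.synth import CONSPECIFIC, REFERENCE, TARGET


class TestProjectFeatures:
    def test_identity_projection_zero_deltas(self, base_genome):
        aln = global_align(base_genome.seq, base_genome.seq, ids=("r", "t"))
        projected, rep = project_features(base_genome, aln)
        assert all(e.status == "projected" and e.delta_start == 0 for e in rep.entries)
        got = [(f.name, f.start, f.end) for f in projected.features]
        want = [(f.name, f.start, f.end) for f in base_genome.features]
        assert got == want

    def test_insertion_inside_gene_lengthens_it_and_shifts_downstream(self, base_genome):
        ref = base_genome
        f = ref.feature("cox3")
        mid = (f.start + f.end) // 2
        s = ref.seq.residues
        ins = "GCGCG"
        target = s[:mid] + ins + s[mid:]
        aln = global_align(ref.seq.residues, target, ids=("r", "t"))
        projected, rep = project_features(ref, aln)
        n = len(projected.seq)
        pf = projected.feature("cox3")
        assert pf.span_length(n) == f.span_length(len(ref.seq)) + len(ins)
        downstream = [e for e in rep.entries if e.ref_span[0] > f.end]
        assert downstream and all(e.delta_start == len(ins) for e in downstream)

    def test_planted_16s_deletion_projects_shorter(self, analysis, trio):
        """A 4 bp in-gene deletion yields a 16S annotation 4 bp shorter than the reference's."""
        genomes, _ = trio
        n_ref = len(genomes[REFERENCE].seq)
        ref_len = genomes[REFERENCE].feature("16S rRNA").span_length(n_ref)
        tgt_len = analysis.target.feature("16S rRNA").span_length(len(analysis.target.seq))
        assert ref_len == 1371 and tgt_len == 1367

    def test_full_transfer_recovers_generator_feature_table(self, analysis, trio):
        genomes, _ = trio
        truth = genomes[TARGET]
        got = {f.name: (f.start, f.end, f.strand) for f in analysis.target.features}
        want = {f.name: (f.start, f.end, f.strand) for f in truth.features}
        assert got == want

    def test_projection_is_monotone(self, analysis):
        feats = [f for f in analysis.target.features]
        starts = [f.start for f in sorted(feats, key=lambda f: f.start)]
        assert starts == sorted(starts)


class TestRescue:
    def test_deleted_trnas_rescued_at_planted_coordinates(self, trio):
        genomes, ledger = trio
        ref = genomes[REFERENCE]
        tgt_truth = genomes[TARGET]
        tgt = MitoGenome(
            tgt_truth.seq,
            [f for f in tgt_truth.features if f.name not in ("tRNA-Ser1", "tRNA-Gln")],
        )
        rescued, rep = rescue_unmapped(tgt, ref, ["tRNA-Ser1", "tRNA-Gln"])
        assert all(e.status == "rescued" for e in rep.entries)
        for name in ("tRNA-Ser1", "tRNA-Gln"):
            want = tgt_truth.feature(name)
            got = rescued.feature(name)
            assert (got.start, got.end) == (want.start, want.end)

    def test_no_failures_leaves_genome_unchanged(self, base_genome):
        out, rep = rescue_unmapped(base_genome, base_genome, [])
        assert rep.entries == [] and out.features == base_genome.features

    def test_feature_absent_from_target_stays_failed(self, base_genome):
        ref = base_genome
        f = ref.feature("tRNA-Met")
        s = ref.seq.residues
        # excise the gene entirely from the target
        target = MitoGenome(
            CircularSeq("t", s[: f.start - 1] + s[f.end :]),
            [],
        )
        out, rep = rescue_unmapped(target, ref, ["tRNA-Met"])
        assert rep.entries[0].status == "failed"
        assert not out.has_feature("tRNA-Met")


def _overlap_genome():
    """A cox1-like gene annotated 5 bp into the downstream tRNA, with an
    in-frame truncated T at the true boundary (the classic artifact)."""
    gene = "ATG" + "ATT" * 5 + "T"  # 19 nt, ends on truncated stop T
    trna = "GGGCCGGGCC"
    seq = gene + trna + "A" * 40
    feats = [
        Feature("cox1", FeatureClass.PCG, Strand.LIGHT, 1, 24),  # 5 bp too long
        Feature("tRNA-Leu1", FeatureClass.TRNA, Strand.LIGHT, 20, 29),
    ]
    return MitoGenome(CircularSeq("ov", seq), feats)


class TestCurateOverlaps:
    def test_truncated_stop_trim_removes_pcg_trna_overlap(self):
        g = _overlap_genome()
        out, actions = curate_overlaps(g)
        assert [a.rule for a in actions] == ["truncated-stop-trim"]
        assert out.feature("cox1").end == 19
        cds = out.feature_seq("cox1")
        assert len(cds) % 3 == 1 and cds.endswith("T")

    def test_curation_is_idempotent(self):
        out1, _ = curate_overlaps(_overlap_genome())
        out2, actions2 = curate_overlaps(out1)
        assert actions2 == []
        assert [(f.name, f.start, f.end) for f in out2.features] == [
            (f.name, f.start, f.end) for f in out1.features
        ]

    def test_atp8_atp6_overlap_preserved(self, base_genome):
        out, actions = curate_overlaps(base_genome)
        assert actions == []
        assert out.feature("atp8").end - out.feature("atp6").start + 1 == 19

    def test_genome_without_overlaps_untouched(self):
        g = MitoGenome(
            CircularSeq("x", "ATGATTTAA" + "C" * 30),
            [Feature("g1", FeatureClass.PCG, Strand.LIGHT, 1, 9)],
        )
        out, actions = curate_overlaps(g)
        assert actions == [] and out.features == g.features


class TestGeneOrder:
    def test_order_vs_itself_has_zero_breakpoints(self):
        order = named_order("apis_mellifera")
        assert gene_order_diff(order, order).n_breakpoints == 0

    def test_rotation_invariance(self):
        order = named_order("apis_mellifera")
        rotated = GeneOrder(order.entries[5:] + order.entries[:5])
        assert gene_order_diff(order, rotated).n_breakpoints == 0

    def test_honeybee_vs_ancestral_insect_rearrangements(self):
        bee = named_order("apis_mellifera")
        anc = named_order("ancestral_insect")
        diff = gene_order_diff(bee, anc)
        assert diff.n_breakpoints > 0
        broken = {g for adj in diff.breakpoints for (g, _s) in adj}
        # the control-region-adjacent tRNA cluster, the Trp/Cys/Tyr cluster
        # and the Asp/Lys swap are all disrupted
        assert {"tRNA-Glu", "tRNA-Ser1"} & broken
        assert {"tRNA-Trp", "tRNA-Cys", "tRNA-Tyr"} & broken
        assert {"tRNA-Asp", "tRNA-Lys"} & broken

    def test_pcg_order_conserved_with_ancestral(self):
        pcgs = {"nd2", "cox1", "cox2", "atp8", "atp6", "cox3", "nd3", "nd5",
                "nd4", "nd4l", "nd6", "cytb", "nd1"}
        bee = named_order("apis_mellifera").restricted(pcgs)
        anc = named_order("ancestral_insect").restricted(pcgs)
        assert gene_order_diff(bee, anc).n_breakpoints == 0

    def test_order_from_genome_starts_at_control_region(self, base_genome):
        order = GeneOrder.of(base_genome)
        assert order.entries[0][0] == "control_region"
        assert len(order.entries) == 38  # 37 genes + control region

    def test_unshared_names_reported_and_excluded(self):
        a = named_order("apis_mellifera")
        b = GeneOrder(tuple(e for e in a.entries if e[0] != "nd2"))
        diff = gene_order_diff(a, b)
        assert diff.only_in_a == ("nd2",)
        assert diff.n_breakpoints == 0  # removing one gene keeps relative order
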