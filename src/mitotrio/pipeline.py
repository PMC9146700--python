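"""End-to-end trio analysis: rotate → align → liftover → compare → distances.

The flow mirrors the comparative-mitogenomics study design: a target
genome (the new assembly) is compared against its conspecific and a
well-annotated reference genome.  The reference's feature table is
lifted onto the target through their pairwise alignment (with rescue of
dropped short features and overlap curation); both pairwise alignments
are merged into a target-anchored MSA; variable sites are called,
classified and tallied; distances and an ABGD partition, the mitotype
marker profile, and the gene-order comparison complete the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from mitotrio import align as _align
from mitotrio import compare as _compare
from mitotrio import liftover as _liftover
from mitotrio import mitotype as _mitotype
from mitotrio import popstruct as _popstruct
from mitotrio.align import AlignParams, AnchoredMSA, PairAlignment
from mitotrio.compare import ComparisonReport
from mitotrio.genetic_code import INVERTEBRATE_MITO, CodonTable, codon_usage_survey
from mitotrio.liftover import TransferReport
from mitotrio.mitio import CircularSeq, MitoGenome, composition, write_genbank
from mitotrio.popstruct import AbgdParams, DistanceMatrix, DistanceParams, Partition


@dataclass
class TrioConfig:
    align_params: AlignParams = field(default_factory=AlignParams)
    dist_params: DistanceParams = field(default_factory=DistanceParams)
    abgd_params: AbgdParams = field(default_factory=AbgdParams)
    count_mode: str = "event"
    rescue_identity: float = 0.85
    table: CodonTable = field(default_factory=lambda: INVERTEBRATE_MITO)

    def describe(self) -> str:
        p, d, a = self.align_params, self.dist_params, self.abgd_params
        return (
            f"align: match={p.match} mismatch={p.mismatch} gap_open={p.gap_open} "
            f"gap_extend={p.gap_extend} band={p.band} cap={p.band_cap}\n"
            f"distance: model={d.model} gamma_shape={d.gamma_shape} deletion={d.deletion}\n"
            f"abgd: prior={a.prior} rel_gap_width={a.rel_gap_width} min_group={a.min_group}\n"
            f"count_mode={self.count_mode} rescue_identity={self.rescue_identity} "
            f"genetic_code=table{self.table.table_id}"
        )


@dataclass
class TrioAnalysis:
    """Everything the end-to-end comparison produces."""

    config: TrioConfig
    target: MitoGenome  # annotated via liftover
    rotations: dict[str, int]
    alignments: dict[str, PairAlignment]
    msa: AnchoredMSA
    transfer: TransferReport
    curation: list
    report: ComparisonReport
    distances: DistanceMatrix
    partition: Partition

    def write_reports(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        prov = "# " + self.config.describe().replace("\n", "\n# ") + "\n"
        (out / "events.tsv").write_text(prov + self.report.to_tsv())
        (out / "transfer.tsv").write_text(prov + self.transfer.to_tsv())
        (out / "distances.phy").write_text(self.distances.to_phylip())
        (out / "partition.tsv").write_text(prov + self.partition.to_tsv())
        (out / "tallies.tsv").write_text(prov + self.tallies_tsv())
        (out / "events.vcf").write_text(
            _compare.events_to_vcf(self.report.events, self.msa, self.target)
        )
        _align.write_gapped_fasta(self.msa, out / "msa.fasta")
        write_genbank(self.target, out / "target.gb")

    def tallies_tsv(self) -> str:
        lines = ["pair\ttotal\t" + "\t".join(
            ["PCG", "tRNA", "rRNA", "control", "intergenic"])]
        for pair, total in self.report.pair_totals.items():
            reg = self.report.pair_by_region[pair]
            lines.append("\t".join(
                [f"{pair[0]}|{pair[1]}", str(total)]
                + [str(reg.get(k, 0)) for k in ("PCG", "tRNA", "rRNA", "control",
                                                "intergenic")]))
        lines.append("")
        for pat, cnt in sorted(self.report.pattern_totals.items()):
            lines.append(f"pattern:{pat}\t{cnt}")
        lines.append(f"missense\t{len(self.report.missense)}")
        return "\n".join(lines) + "\n"


def run_trio(
    target: CircularSeq | MitoGenome,
    conspecific: CircularSeq | MitoGenome,
    reference: MitoGenome,
    config: TrioConfig | None = None,
) -> TrioAnalysis:
    """Run the full comparison; the reference supplies the annotation.

    The conspecific and reference are rotated to the target's origin first,
    so all coordinates in the output are target-anchored.
    """
    cfg = config or TrioConfig()
    tseq = target.seq if isinstance(target, MitoGenome) else target
    cseq = conspecific.seq if isinstance(conspecific, MitoGenome) else conspecific

    crot, c_off = _align.rotate_to_anchor(cseq, tseq)
    rrot_seq, r_off = _align.rotate_to_anchor(reference.seq, tseq)
    ref_rot = reference.rotated(r_off)

    aln_tc = _align.global_align(tseq, crot, cfg.align_params)
    aln_tr = _align.global_align(tseq, rrot_seq, cfg.align_params)

    # liftover wants the annotated genome first
    aln_rt = PairAlignment((aln_tr.ids[1], aln_tr.ids[0]),
                           (aln_tr.rows[1], aln_tr.rows[0]), aln_tr.score)
    projected, transfer = _liftover.project_features(ref_rot, aln_rt)
    failed = [e.name for e in transfer.by_status("failed")]
    if failed:
        projected, rescue_rep = _liftover.rescue_unmapped(
            projected, ref_rot, failed, cfg.rescue_identity)
        transfer.entries = [e for e in transfer.entries if e.status != "failed"]
        transfer.entries.extend(rescue_rep.entries)
    target_annot, curation = _liftover.curate_overlaps(projected, cfg.table)

    msa = _align.anchor_merge([aln_tc, aln_tr])
    events = _compare.call_events(msa, target_annot, cfg.table)
    report = _compare.tally(events, msa.ids, cfg.count_mode)

    D = _popstruct.distance_matrix(msa, cfg.dist_params)
    part = _popstruct.abgd_partition(D, cfg.abgd_params)

    return TrioAnalysis(
        config=cfg,
        target=target_annot,
        rotations={cseq.id: c_off, reference.seq.id: r_off},
        alignments={cseq.id: aln_tc, reference.seq.id: aln_tr},
        msa=msa,
        transfer=transfer,
        curation=curation,
        report=report,
        distances=D,
        partition=part,
    )


def genome_summary(g: MitoGenome, table: CodonTable = INVERTEBRATE_MITO) -> dict:
    """Composition, codon survey, mitotype profile and gene order in one dict."""
    comp = composition(g)
    survey = codon_usage_survey(g, table)
    marker = _mitotype.extract_marker(g)
    profile = _mitotype.drai_profile(marker)
    order = _liftover.GeneOrder.of(g)
    diff = _liftover.gene_order_diff(order, _liftover.named_order("ancestral_insect"))
    return {
        "composition": comp,
        "start_codons": survey.starts,
        "stop_kinds": survey.stops,
        "marker_length": len(marker.sequence),
        "drai_fragments": profile.fragments,
        "gene_order_breakpoints_vs_ancestral": diff.n_breakpoints,
    }


__all__ = ["TrioAnalysis", "TrioConfig", "genome_summary", "run_trio"]
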