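"""Variable-site discovery and classification over an anchored alignment.

Every non-unanimous alignment column belongs to exactly one event:
substitution columns are singleton events; maximal runs of contiguous
columns sharing one gap pattern coalesce into a single indel event.
Events are classified three ways:

* **region** — via the target genome's annotation at the reference
  position (events gapped in the reference attach to the nearest
  upstream reference position);
* **uniqueness pattern** — which genome is the odd one out
  (``unique_target`` / ``unique_other1`` / ``diagnostic_pair`` when the
  non-conspecific third genome differs from the agreeing pair /
  ``all_distinct``);
* **coding effect** — substitutions inside protein genes are translated
  codon-wise from each genome's own sequence (strand-aware) under the
  invertebrate mitochondrial code; indels in protein genes whose length
  is not a multiple of three are frameshifts.

Amino-acid changes are reported others→target for unique-target events
and reference→pair for diagnostic events, matching the conventions of
subspecies-comparison tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from mitotrio.align import AnchoredMSA
from mitotrio.genetic_code import INVERTEBRATE_MITO, CodonTable
from mitotrio.mitio import FeatureClass, MitoGenome, Strand, region_of, revcomp


@dataclass
class VariantEvent:
    """One substitution or indel event in alignment coordinates."""

    span: tuple[int, int]  # 0-based inclusive column range
    kind: str  # substitution | indel
    alleles: dict[str, str]  # genome id -> residue run, or "-"
    region_class: FeatureClass
    region_name: str
    pattern: str
    effect: str = "NA"  # NA | synonymous | missense | frameshift | boundary
    aa_change: str | None = None
    positions: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.span[1] - self.span[0] + 1


def classify_pattern(
    alleles: tuple[str, ...], conspecific_index: int | None = 1
) -> str:
    """Uniqueness pattern of a variable site, target allele first.

    With three genomes: the target odd → ``unique_target``; the third genome
    odd while target and its conspecific agree → ``diagnostic_pair`` (or
    ``unique_other2`` when no conspecific is designated); the middle genome
    odd → ``unique_other1``; no odd one out → ``all_distinct``.
    """
    if len(alleles) < 3:
        raise ValueError("uniqueness patterns need at least three genomes")
    if len(set(alleles)) == len(alleles):
        return "all_distinct"
    if len(set(alleles)) == 1:
        raise ValueError("site is not variable")
    counts = Counter(alleles)
    odd_allele = min(counts, key=lambda a: counts[a])
    odd = alleles.index(odd_allele)
    if odd == 0:
        return "unique_target"
    if odd == len(alleles) - 1 and conspecific_index is not None:
        return "diagnostic_pair"
    return f"unique_other{odd}"


def _cum_positions(msa: AnchoredMSA, i: int) -> np.ndarray:
    """Residue count of row ``i`` up to and including each column."""
    row = np.frombuffer(msa.rows[i].encode(), dtype=np.uint8)
    return np.cumsum(row != ord("-"))


def call_events(
    msa: AnchoredMSA,
    target_annotation: MitoGenome,
    table: CodonTable = INVERTEBRATE_MITO,
    conspecific_index: int | None = 1,
) -> list[VariantEvent]:
    """Partition all non-unanimous columns of the alignment into events.

    ``target_annotation`` must annotate the msa's reference (target) row;
    positions, region classes and coding effects are all expressed in the
    target's coordinate system.
    """
    if msa.ungapped(0) != target_annotation.seq.residues:
        raise ValueError("annotation does not belong to the msa reference sequence")
    rows = msa.rows
    nrows = len(rows)
    ncols = msa.ncols
    mats = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap = ord("-")
    is_gap = mats == gap
    variable = ~np.all(mats == mats[0], axis=0)
    any_gap = is_gap.any(axis=0)
    cums = [_cum_positions(msa, i) for i in range(nrows)]
    events: list[VariantEvent] = []
    c = 0
    while c < ncols:
        if not variable[c]:
            c += 1
            continue
        if not any_gap[c]:
            alleles = {msa.ids[i]: rows[i][c] for i in range(nrows)}
            events.append(_finish_event(msa, target_annotation, (c, c), "substitution",
                                         alleles, cums, is_gap, table, conspecific_index))
            c += 1
            continue
        # coalesce a maximal run of identical gap patterns
        pat = tuple(is_gap[:, c])
        e = c
        while e + 1 < ncols and any_gap[e + 1] and tuple(is_gap[:, e + 1]) == pat:
            e += 1
        alleles = {}
        for i in range(nrows):
            run = rows[i][c : e + 1].replace("-", "")
            alleles[msa.ids[i]] = run if run else "-"
        events.append(_finish_event(msa, target_annotation, (c, e), "indel",
                                    alleles, cums, is_gap, table, conspecific_index))
        c = e + 1
    return events


def _finish_event(msa, ann, span, kind, alleles, cums, is_gap, table,
                  conspecific_index) -> VariantEvent:
    cs, ce = span
    nrows = msa.nrows
    positions = {}
    for i in range(nrows):
        # first residue of the run; for a fully gapped row, the residue before
        if is_gap[i, cs]:
            positions[msa.ids[i]] = int(cums[i][cs])
        else:
            positions[msa.ids[i]] = int(cums[i][cs - 1]) + 1 if cs else 1
    ref_pos = max(1, positions[msa.ids[0]])
    call = region_of(ann, ref_pos)
    pattern = classify_pattern(tuple(alleles[g] for g in msa.ids), conspecific_index)
    ev = VariantEvent(span, kind, alleles, call.fclass, call.name, pattern,
                      positions=positions)
    coding_effect(ev, ann, msa, table)
    return ev


def coding_effect(
    e: VariantEvent,
    g: MitoGenome,
    msa: AnchoredMSA,
    table: CodonTable = INVERTEBRATE_MITO,
) -> VariantEvent:
    """Annotate an event with its predicted effect on the encoded protein.

    Substitutions in a protein gene are evaluated by translating the
    containing codon from every genome's own sequence; the change is reported
    odd-genome-last except for diagnostic events, which read
    reference→conspecific-pair.  Events touching the initiator or terminator
    codons are classed ``boundary``.  The effect is ``NA`` outside protein
    genes and for in-frame indels.
    """
    e.effect, e.aa_change = "NA", None
    if e.region_class is not FeatureClass.PCG:
        return e
    if e.kind == "indel":
        indel_len = max(len(a) for a in e.alleles.values() if a != "-")
        e.effect = "frameshift" if indel_len % 3 else "NA"
        return e
    f = g.feature(e.region_name)
    tid = msa.ids[0]
    p = e.positions[tid]
    k = (p - f.start) if f.strand is Strand.LIGHT else (f.end - p)
    ci, _cp = divmod(k, 3)
    cds_len = f.span_length(len(g.seq))
    ncod = cds_len // 3
    if ci <= 0 or ci >= ncod - 1:
        e.effect = "boundary"
        return e
    # target positions of the codon's three bases, ascending in the genome
    if f.strand is Strand.LIGHT:
        gpos = [f.start + 3 * ci + j for j in range(3)]
    else:
        gpos = [f.end - 3 * ci - j for j in (2, 1, 0)]
    try:
        cols = [msa.col_of(0, q) for q in gpos]
    except ValueError:
        e.effect = "boundary"
        return e
    codons: dict[str, str] = {}
    for i, gid in enumerate(msa.ids):
        tri = "".join(msa.rows[i][c] for c in cols)
        if "-" in tri:
            e.effect = "boundary"
            return e
        codons[gid] = revcomp(tri) if f.strand is Strand.HEAVY else tri
    aas = {gid: table.amino_acid(c) for gid, c in codons.items()}
    odd_gid = _odd_genome(e, msa.ids)
    if odd_gid is None:
        e.effect = "boundary"  # all-distinct site: no pairwise direction
        return e
    rest = [aas[gid] for gid in msa.ids if gid != odd_gid]
    aa_rest, aa_odd = rest[0], aas[odd_gid]
    if aa_rest == aa_odd:
        e.effect = "synonymous"
        return e
    e.effect = "missense"
    if e.pattern == "diagnostic_pair":
        e.aa_change = f"{aa_odd}->{aa_rest}"
    else:
        e.aa_change = f"{aa_rest}->{aa_odd}"
    return e


def _odd_genome(e: VariantEvent, ids: tuple[str, ...]) -> str | None:
    counts = Counter(e.alleles[g] for g in ids)
    if len(counts) != 2:
        return None
    odd_allele = min(counts, key=lambda a: counts[a])
    if counts[odd_allele] != 1:
        return None
    return next(g for g in ids if e.alleles[g] == odd_allele)


# ---------------------------------------------------------------------------
# tallies and reports


@dataclass
class ComparisonReport:
    events: list[VariantEvent]
    ids: tuple[str, ...]
    count_mode: str  # event | column
    pair_totals: dict[tuple[str, str], int] = field(default_factory=dict)
    pair_by_region: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    pattern_totals: dict[str, int] = field(default_factory=dict)
    missense: list[VariantEvent] = field(default_factory=list)

    def to_tsv(self) -> str:
        hdr = ["aln_pos", "kind", "region_class", "region", "pattern", "effect",
               "aa_change"]
        for g in self.ids:
            hdr += [f"{g}_pos", f"{g}_allele"]
        lines = ["\t".join(hdr)]
        for e in self.events:
            row = [str(e.span[0] + 1), e.kind, e.region_class.value, e.region_name,
                   e.pattern, e.effect, e.aa_change or ""]
            for g in self.ids:
                row += [str(e.positions[g]), e.alleles[g]]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def tally(
    events: list[VariantEvent],
    ids: tuple[str, ...],
    count_mode: str = "event",
) -> ComparisonReport:
    """Pairwise and uniqueness tallies over an event list.

    ``count_mode='event'`` counts every event once (a multi-base indel is one
    feature); ``'column'`` counts an indel once per alignment column.  The
    pairwise tally for (a, b) restricts to events where a and b carry
    different alleles; its per-region breakdown sums to the pair total.
    """
    if count_mode not in ("event", "column"):
        raise ValueError("count_mode must be 'event' or 'column'")
    rep = ComparisonReport(events, ids, count_mode)
    weight = (lambda e: 1) if count_mode == "event" else (lambda e: e.width)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            sel = [e for e in events if e.alleles[a] != e.alleles[b]]
            rep.pair_totals[(a, b)] = sum(weight(e) for e in sel)
            reg: dict[str, int] = {}
            for e in sel:
                reg[e.region_class.value] = reg.get(e.region_class.value, 0) + weight(e)
            rep.pair_by_region[(a, b)] = reg
    rep.pattern_totals = dict(Counter(e.pattern for e in events))
    rep.missense = [e for e in events if e.effect == "missense"]
    return rep


def events_to_vcf(events: list[VariantEvent], msa: AnchoredMSA,
                  target: MitoGenome) -> str:
    """Minimal VCF against the target genome (1-based, indels left-aligned)."""
    tid = msa.ids[0]
    others = [g for g in msa.ids if g != tid]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={tid},length={len(target.seq)}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(others),
    ]
    for e in sorted(events, key=lambda e: e.positions[tid]):
        tal = e.alleles[tid]
        if e.kind == "substitution":
            pos, ref = e.positions[tid], tal
            alts, gts = _alt_codes(e, others, ref)
        else:
            pos = max(1, e.positions[tid])
            anchor = target.seq.residues[pos - 1]
            ref = anchor + (tal if tal != "-" else "")
            alts, gts = _alt_codes(e, others, ref, anchor=anchor)
        alt_field = ",".join(alts) if alts else "."
        gt_field = "\t".join(gts)
        lines.append(
            f"{tid}\t{pos}\t.\t{ref}\t{alt_field}\t.\t.\t"
            f"REGION={e.region_name};PATTERN={e.pattern};EFFECT={e.effect}\tGT\t{gt_field}"
        )
    return "\n".join(lines) + "\n"


def _alt_codes(e, others, ref, anchor=""):
    alts: list[str] = []
    gts: list[str] = []
    for g in others:
        al = e.alleles[g]
        allele = (anchor + (al if al != "-" else "")) if anchor else al
        if allele == ref:
            gts.append("0")
        else:
            if allele not in alts:
                alts.append(allele)
            gts.append(str(alts.index(allele) + 1))
    return alts, gts


__all__ = [
    "ComparisonReport", "VariantEvent", "call_events", "classify_pattern",
    "coding_effect", "events_to_vcf", "tally",
]
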