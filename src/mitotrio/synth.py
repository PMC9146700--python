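"""Seeded synthetic mitogenome trios with a planted ground-truth ledger.

The generator emulates the statistical structure of honeybee
mitogenomes: a ~16.4 kb, ~85% AT circular genome carrying 13 protein
genes (valid ORFs under the invertebrate mitochondrial code, one gene
ending on a truncated stop T, atp8/atp6 overlapping by 19 bases in two
frames), 22 tRNAs of 63–78 bp, two rRNAs, intergenic spacers including
the tRNA-Leu–cox2 mitotype marker, and an AT-rich control region — in
the *Apis mellifera* gene arrangement.

From one base genome, :func:`make_trio` derives three siblings (a
target, its conspecific, and a reference/outgroup genome) by planting
substitutions and short indels.  Every planted event alters exactly one
genome, so its uniqueness pattern is known by construction: the target
odd → ``unique_target``, the conspecific odd → ``unique_other1``, the
reference odd → ``diagnostic_pair``.  The
:class:`GroundTruthLedger` records every event with per-genome alleles,
coordinates, expected pattern and expected coding effect; it is the
oracle against which the analysis pipeline is tested.

Indels are placed only where their left-normalised alignment
representation is unambiguous (the planted coordinate is the leftmost
equivalent placement); placements violating this are redrawn.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from mitotrio.genetic_code import INVERTEBRATE_MITO, CodonTable
from mitotrio.liftover import named_order
from mitotrio.mitio import (
    CircularSeq,
    Feature,
    FeatureClass,
    MitoGenome,
    Strand,
    composition,
    revcomp,
)

TARGET = "syn_target"
CONSPECIFIC = "syn_conspecific"
REFERENCE = "syn_reference"
GENOMES = (TARGET, CONSPECIFIC, REFERENCE)

#: pattern implied by which single genome carries the alternate allele
_PATTERN_OF_ODD = {
    TARGET: "unique_target",
    CONSPECIFIC: "unique_other1",
    REFERENCE: "diagnostic_pair",
}

_BASE_WEIGHTS = {"A": 0.43, "T": 0.42, "G": 0.055, "C": 0.095}

#: codon prefixes whose third position is four-fold degenerate under table 5
_FOURFOLD = ("TC", "CT", "GT", "CC", "AC", "GC", "CG", "GG")

_MIN_EVENT_SPACING = 12
# two indels close together in low-complexity sequence can trade against each
# other in an equal-scoring alignment; keep them far enough apart that the
# anchoring matches between them make the planted representation the unique
# optimum even in the AT-repeat-rich control region
_MIN_INDEL_SPACING = 40


# ---------------------------------------------------------------------------
# template


@dataclass(frozen=True)
class GeneSpec:
    name: str
    fclass: FeatureClass
    strand: Strand
    length: int
    spacer_after: int  # intergenic bp following this gene; negative = overlap
    start_codon: str | None = None
    stop: str | None = None  # "TAA" or "T" (truncated)


@dataclass(frozen=True)
class GenomeTemplate:
    """Gene layout in genome order (control region last), plus composition targets."""

    genes: tuple[GeneSpec, ...]
    at_target: float = 0.85
    marker_drai_sites: int = 2  # DraI sites planted in the tRNA-Leu1–cox2 spacer

    def pcgs(self) -> list[GeneSpec]:
        return [g for g in self.genes if g.fclass is FeatureClass.PCG]


_TRNA_LEN = {
    "tRNA-Glu": 66, "tRNA-Ser1": 63, "tRNA-Met": 68, "tRNA-Gln": 63,
    "tRNA-Ala": 67, "tRNA-Ile": 70, "tRNA-Cys": 65, "tRNA-Tyr": 66,
    "tRNA-Trp": 68, "tRNA-Leu1": 71, "tRNA-Asp": 67, "tRNA-Lys": 70,
    "tRNA-Gly": 65, "tRNA-Arg": 64, "tRNA-Asn": 66, "tRNA-Phe": 67,
    "tRNA-His": 65, "tRNA-Pro": 66, "tRNA-Thr": 78, "tRNA-Ser2": 72,
    "tRNA-Leu2": 69, "tRNA-Val": 68,
}

_PCG_LEN = {
    "nd2": 1002, "cox1": 1564, "cox2": 678, "atp8": 159, "atp6": 678,
    "cox3": 780, "nd3": 354, "nd5": 1665, "nd4": 1338, "nd4l": 264,
    "nd6": 498, "cytb": 1149, "nd1": 918,
}

_RRNA_LEN = {"16S rRNA": 1371, "12S rRNA": 786}

_START_CODONS = {
    "nd2": "ATT", "cox1": "ATT", "cox2": "ATG", "atp8": "ATT", "atp6": "ATG",
    "cox3": "ATG", "nd3": "ATT", "nd5": "ATT", "nd4": "ATA", "nd4l": "ATA",
    "nd6": "ATT", "cytb": "ATA", "nd1": "ATC",
}

# junction-specific intergenic spacers; default is 15 bp
_SPACERS = {
    "tRNA-Leu1": 96,   # the tRNA-Leu–cox2 mitotype marker
    "atp8": -19,       # genuine dual-frame overlap with atp6
    "tRNA-Ile": 60,    # IR ahead of nd2
    "cox2": 50,
    "nd3": 55,
    "cytb": 45,
    "nd1": 45,
    "tRNA-Glu": 40,
}

_CR_LEN = 900


def default_template() -> GenomeTemplate:
    """The honeybee-shaped layout: *A. mellifera* arrangement, control region last."""
    order = named_order("apis_mellifera").entries
    # rotate so the genome starts just after the control region and ends with it
    assert order[0][0] == "control_region"
    genome_order = list(order[1:]) + [order[0]]
    genes: list[GeneSpec] = []
    for name, strand in genome_order:
        spacer = _SPACERS.get(name, 15)
        if name == "control_region":
            genes.append(GeneSpec(name, FeatureClass.CONTROL, strand, _CR_LEN, 0))
        elif name in _PCG_LEN:
            stop = "T" if name == "cox1" else "TAA"
            genes.append(GeneSpec(name, FeatureClass.PCG, strand, _PCG_LEN[name],
                                  spacer, _START_CODONS[name], stop))
        elif name in _RRNA_LEN:
            genes.append(GeneSpec(name, FeatureClass.RRNA, strand, _RRNA_LEN[name], spacer))
        else:
            genes.append(GeneSpec(name, FeatureClass.TRNA, strand, _TRNA_LEN[name], spacer))
    return GenomeTemplate(tuple(genes))


# ---------------------------------------------------------------------------
# base genome generation


def _weighted_base(rng: random.Random) -> str:
    return rng.choices("ATGC", weights=[43, 42, 5.5, 9.5])[0]


def _random_stretch(rng: random.Random, n: int) -> str:
    return "".join(_weighted_base(rng) for _ in range(n))


def _codon_pool(table: CodonTable) -> tuple[list[str], list[float]]:
    codons, weights = [], []
    for c, _aa in table.forward.items():
        codons.append(c)
        weights.append(_BASE_WEIGHTS[c[0]] * _BASE_WEIGHTS[c[1]] * _BASE_WEIGHTS[c[2]])
    return codons, weights


def _sample_codons(rng: random.Random, n: int, table: CodonTable) -> list[str]:
    codons, weights = _codon_pool(table)
    return rng.choices(codons, weights=weights, k=n)


def _make_cds(rng: random.Random, spec: GeneSpec, table: CodonTable) -> str:
    """A clean ORF of spec.length: start codon, internal codons, stop (full or T)."""
    if spec.stop == "T":
        assert spec.length % 3 == 1
        n_internal = (spec.length - 1) // 3 - 1
        tail = "T"
    else:
        assert spec.length % 3 == 0
        n_internal = spec.length // 3 - 2
        tail = "TAA"
    return spec.start_codon + "".join(_sample_codons(rng, n_internal, table)) + tail


def _make_atp_overlap(rng: random.Random, t8: GeneSpec, t6: GeneSpec,
                      table: CodonTable) -> tuple[str, str]:
    """atp8 and atp6 CDSs whose last/first 19 nt coincide, both frames clean.

    With atp8 length a multiple of 3, the 19-nt overlap holds the final six
    atp8 codons offset by one against atp6's first 19 nt; atp6[17..19] is the
    atp8 stop TAA and atp6 starts with its own ATG.
    """
    assert t6.start_codon == "ATG" and t8.length % 3 == 0
    # head = the 19 shared nucleotides = atp6[1..19]; in the atp8 frame these
    # are the last base of one codon, five full codons, and the stop TAA
    while True:
        head = ("ATG"
                + "".join(rng.choice("AT") if rng.random() < 0.85 else rng.choice("GC")
                          for _ in range(13))
                + "TAA")
        atp8_codons = [head[i : i + 3] for i in range(1, 16, 3)]  # five, pre-stop
        atp6_codons = [head[i : i + 3] for i in range(3, 16, 3)]
        if not any(c in table.stops for c in atp8_codons + atp6_codons):
            break
    # atp8 = start + free internal codons + two bases of the codon whose third
    # base is head[0] ('A'), + head.  That split codon must not read TAA.
    n_free = t8.length // 3 - 8  # internal codons fully outside the overlap
    free = _sample_codons(rng, n_free, table)
    while True:
        split = _sample_codons(rng, 1, table)[0][:2] + "A"
        if split not in table.stops:
            break
    atp8 = t8.start_codon + "".join(free) + split[:2] + head
    assert len(atp8) == t8.length
    # atp6 = head + 'AA' completing the codon begun by head[18], + codons + stop
    n_rest = (t6.length - 21) // 3 - 1
    atp6 = head + "AA" + "".join(_sample_codons(rng, n_rest, table)) + "TAA"
    assert len(atp6) == t6.length
    return atp8, atp6


def _plant_drai_sites(rng: random.Random, seq: str, k: int) -> str:
    """Return ``seq`` carrying exactly ``k`` TTTAAA sites, at spread positions."""
    s = list(seq.replace("TTTAAA", "TTTAGA"))
    n = len(s)
    if k == 0:
        return "".join(s)
    gap = n // (k + 1)
    for i in range(k):
        p = gap * (i + 1) - 3
        s[p : p + 6] = "TTTAAA"
    out = "".join(s)
    # planting may have re-created an accidental site by juxtaposition
    return out if out.count("TTTAAA") == k else _plant_drai_sites(rng, out, k)


def make_base(
    template: GenomeTemplate | None = None,
    seed: int = 0,
    table: CodonTable = INVERTEBRATE_MITO,
) -> MitoGenome:
    """Generate the deterministic base genome for a given template and seed.

    Every PCG translates cleanly under table 5 with its assigned start codon
    and stop (TAA, or the truncated T for cox1); the atp8/atp6 overlap is a
    genuine dual-frame overlap; the whole-genome AT fraction lands within
    ±2% of the template target.
    """
    t = template or default_template()
    rng = random.Random(seed)
    parts: list[str] = []
    feats: list[Feature] = []
    pos = 1  # next free 1-based position
    cds_cache: dict[str, str] = {}
    t8 = next(g for g in t.genes if g.name == "atp8")
    t6 = next(g for g in t.genes if g.name == "atp6")
    cds_cache["atp8"], cds_cache["atp6"] = _make_atp_overlap(rng, t8, t6, table)

    for spec in t.genes:
        if spec.name == "atp6":
            # the first 19 nt were already emitted as atp8's tail; atp8's
            # negative spacer rewound ``pos`` to the shared start
            start = pos
            end = start + spec.length - 1
            feats.append(Feature(spec.name, spec.fclass, spec.strand, start, end))
            parts.append(cds_cache["atp6"][19:])
            pos = end + 1
        else:
            if spec.fclass is FeatureClass.PCG:
                cds = cds_cache.get(spec.name) or _make_cds(rng, spec, table)
                payload = revcomp(cds) if spec.strand is Strand.HEAVY else cds
            elif spec.fclass is FeatureClass.CONTROL:
                payload = "".join(rng.choices("AT", weights=[51, 46], k=spec.length))
            else:
                payload = _random_stretch(rng, spec.length)
            start, end = pos, pos + spec.length - 1
            feats.append(Feature(spec.name, spec.fclass, spec.strand, start, end))
            parts.append(payload)
            pos = end + 1
        if spec.spacer_after > 0:
            spacer = _random_stretch(rng, spec.spacer_after)
            if spec.name == "tRNA-Leu1":
                spacer = _plant_drai_sites(rng, spacer, t.marker_drai_sites)
            parts.append(spacer)
            pos += spec.spacer_after
        elif spec.spacer_after < 0:
            pos += spec.spacer_after  # overlap: rewind (sequence already shared)

    residues = "".join(parts)
    g = MitoGenome(CircularSeq("syn_base", residues), feats)
    at = composition(g)["at_fraction"]
    if abs(at - t.at_target) > 0.02:
        raise ValueError(f"generated AT fraction {at:.3f} misses target {t.at_target}")
    return g


# ---------------------------------------------------------------------------
# plant specification


@dataclass(frozen=True)
class PlantRequest:
    """``count`` events of one kind in one region class for one odd genome."""

    region: FeatureClass
    pattern: str  # unique_target | unique_other1 | diagnostic_pair
    kind: str = "substitution"  # or "indel"
    effect: str = "NA"  # for PCG substitutions: missense | synonymous
    length: int = 1  # indel length (bp); negative means deletion
    count: int = 1
    feature: str | None = None  # pin the event to one named feature


def default_plant_spec() -> list[PlantRequest]:
    """The study-shaped event spectrum for a synthetic trio.

    Planted so that, counting whole indel events once, the target differs from
    the reference genome at 64 sites (4 tRNA, 24 PCG, 11 rRNA, 14 control
    region, 11 intergenic) and from its conspecific at 59; 23 events are
    diagnostic (carnica-pair vs ligustica-like reference); 8 unique and 3
    diagnostic substitutions are missense.  Includes a 4 bp rRNA deletion
    (the 16S length difference) and AT-motif control-region indels.
    """
    F = FeatureClass
    return [
        # unique to the target: 41 events
        PlantRequest(F.TRNA, "unique_target", count=4),
        PlantRequest(F.PCG, "unique_target", effect="missense", count=8),
        PlantRequest(F.PCG, "unique_target", effect="synonymous", count=7),
        PlantRequest(F.RRNA, "unique_target", count=4),
        PlantRequest(F.RRNA, "unique_target", kind="indel", length=-4, count=1,
                     feature="16S rRNA"),
        PlantRequest(F.CONTROL, "unique_target", count=4),
        PlantRequest(F.CONTROL, "unique_target", kind="indel", length=4, count=2),
        PlantRequest(F.CONTROL, "unique_target", kind="indel", length=-2, count=2),
        PlantRequest(F.CONTROL, "unique_target", kind="indel", length=6, count=1),
        PlantRequest(F.CONTROL, "unique_target", kind="indel", length=-3, count=1),
        PlantRequest(F.INTERGENIC, "unique_target", count=7),
        # diagnostic (reference genome odd): 23 events
        PlantRequest(F.PCG, "diagnostic_pair", effect="missense", count=3),
        PlantRequest(F.PCG, "diagnostic_pair", effect="synonymous", count=6),
        PlantRequest(F.RRNA, "diagnostic_pair", count=4),
        # the small rRNA is the length-variable one across these genomes
        PlantRequest(F.RRNA, "diagnostic_pair", kind="indel", length=1, count=1,
                     feature="12S rRNA"),
        PlantRequest(F.RRNA, "diagnostic_pair", kind="indel", length=-1, count=1,
                     feature="12S rRNA"),
        PlantRequest(F.CONTROL, "diagnostic_pair", count=2),
        PlantRequest(F.CONTROL, "diagnostic_pair", kind="indel", length=2, count=2),
        PlantRequest(F.INTERGENIC, "diagnostic_pair", count=2),
        PlantRequest(F.INTERGENIC, "diagnostic_pair", kind="indel", length=-2, count=1),
        PlantRequest(F.INTERGENIC, "diagnostic_pair", kind="indel", length=1, count=1),
        # unique to the conspecific: 18 events
        PlantRequest(F.TRNA, "unique_other1", count=2),
        PlantRequest(F.PCG, "unique_other1", effect="synonymous", count=4),
        PlantRequest(F.RRNA, "unique_other1", count=2),
        PlantRequest(F.CONTROL, "unique_other1", count=3),
        PlantRequest(F.CONTROL, "unique_other1", kind="indel", length=6, count=1),
        PlantRequest(F.CONTROL, "unique_other1", kind="indel", length=-4, count=1),
        PlantRequest(F.CONTROL, "unique_other1", kind="indel", length=4, count=1),
        PlantRequest(F.CONTROL, "unique_other1", kind="indel", length=-2, count=1),
        PlantRequest(F.INTERGENIC, "unique_other1", count=3),
    ]


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class PlantedEvent:
    eid: int
    kind: str  # substitution | insertion | deletion
    region_class: FeatureClass
    region_name: str
    pattern: str
    effect: str  # NA | synonymous | missense
    aa_change: str | None
    base_pos: int  # 1-based position in the base genome (leftmost, for indels)
    alleles: dict[str, str]  # genome id -> residue run or "-"
    positions: dict[str, int] = field(default_factory=dict)  # per-genome 1-based


@dataclass
class GroundTruthLedger:
    events: list[PlantedEvent]
    rotation_offsets: dict[str, int]
    start_codons: dict[str, str]
    stop_kinds: dict[str, str]
    genome_ids: tuple[str, str, str] = GENOMES

    def by_pattern(self, pattern: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.pattern == pattern]

    def pair_events(self, a: str, b: str) -> list[PlantedEvent]:
        """Events at which genomes ``a`` and ``b`` carry different alleles."""
        return [e for e in self.events if e.alleles[a] != e.alleles[b]]

    def to_tsv(self) -> str:
        hdr = ["eid", "kind", "region_class", "region_name", "pattern", "effect",
               "aa_change", "base_pos"]
        for g in self.genome_ids:
            hdr += [f"{g}_pos", f"{g}_allele"]
        lines = ["\t".join(hdr)]
        for e in self.events:
            row = [str(e.eid), e.kind, e.region_class.value, e.region_name,
                   e.pattern, e.effect, e.aa_change or "", str(e.base_pos)]
            for g in self.genome_ids:
                row += [str(e.positions.get(g, "")), e.alleles[g]]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# trio generation


class _SiteBroker:
    """Hands out mutually distant, unambiguous event sites on the base genome."""

    def __init__(self, base: MitoGenome, rng: random.Random):
        self.base = base
        self.rng = rng
        self.s = base.seq.residues
        self.taken: list[tuple[int, bool]] = []  # (position, is_indel)

    def _far_enough(self, p: int, span: int, is_indel: bool = False) -> bool:
        for q, q_indel in self.taken:
            gap = _MIN_INDEL_SPACING if (is_indel and q_indel) else _MIN_EVENT_SPACING
            if abs(p - q) < gap + span:
                return False
        return True

    def claim(self, p: int, span: int = 1, is_indel: bool = False) -> None:
        self.taken.append((p, is_indel))

    def draw_in(self, feats: list[Feature], span: int, margin: int = 6,
                check=None, tries: int = 4000,
                is_indel: bool = False) -> tuple[int, Feature]:
        for _ in range(tries):
            f = self.rng.choice(feats)
            lo = f.start + margin
            hi = f.end - margin - span
            if hi <= lo:
                continue
            p = self.rng.randrange(lo, hi + 1)
            if not self._far_enough(p, span, is_indel):
                continue
            if check is not None and not check(p):
                continue
            return p, f
        raise ValueError("could not place event; plant spec unsatisfiable in this layout")


def _codon_at(base: MitoGenome, f: Feature, ci: int) -> tuple[str, int]:
    """(codon, genome position of its first CDS base) for 0-based codon ``ci``."""
    cds = base.feature_seq(f)
    codon = cds[3 * ci : 3 * ci + 3]
    if f.strand is Strand.LIGHT:
        gpos = f.start + 3 * ci
    else:
        gpos = f.end - 3 * ci
    return codon, gpos


def _overlap_zone(base: MitoGenome) -> set[int]:
    a8, a6 = base.feature("atp8"), base.feature("atp6")
    return set(range(a6.start, a8.end + 1))


def make_trio(
    base: MitoGenome,
    plant_spec: list[PlantRequest] | None = None,
    seed: int = 0,
    table: CodonTable = INVERTEBRATE_MITO,
    rotate: bool = True,
) -> tuple[dict[str, MitoGenome], GroundTruthLedger]:
    """Derive the synthetic trio from a base genome by planting events.

    Returns the three genomes keyed by :data:`TARGET`, :data:`CONSPECIFIC` and
    :data:`REFERENCE` (the conspecific and reference are emitted rotated by
    recorded random offsets when ``rotate`` is set; the target defines the
    anchor frame) plus the :class:`GroundTruthLedger`.

    An empty plant spec yields three identical genomes.  Unsatisfiable
    requests (a missense in a tRNA, an indel wider than its region) raise
    before any sequence is built.
    """
    spec = default_plant_spec() if plant_spec is None else plant_spec
    for r in spec:
        if r.effect != "NA" and r.region is not FeatureClass.PCG:
            raise ValueError(f"{r.effect} effect requested outside a PCG: {r}")
        if r.kind == "indel" and r.length == 0:
            raise ValueError("indel of length 0")
        if r.kind == "indel" and r.region is FeatureClass.PCG:
            raise ValueError("PCG indels are not part of the emulated spectrum")
        if r.pattern not in _PATTERN_OF_ODD.values():
            raise ValueError(f"unknown pattern {r.pattern!r}")

    rng = random.Random(seed)
    broker = _SiteBroker(base, rng)
    s = base.seq.residues
    feats_by_class: dict[FeatureClass, list[Feature]] = {}
    from mitotrio.mitio import intergenic_gaps

    for f in base.features:
        feats_by_class.setdefault(f.fclass, []).append(f)
    feats_by_class[FeatureClass.INTERGENIC] = [
        g for g in intergenic_gaps(base) if g.span_length(len(base.seq)) >= 8
    ]
    forbidden = _overlap_zone(base)

    events: list[PlantedEvent] = []
    eid = 0
    odd_of = {v: k for k, v in _PATTERN_OF_ODD.items()}

    # place indels first: their mutual-separation requirement is the tightest
    for req in sorted(spec, key=lambda r: r.kind != "indel"):
        feats = feats_by_class.get(req.region, [])
        if req.feature is not None:
            feats = [f for f in feats if f.name == req.feature]
            if not feats:
                raise ValueError(f"no {req.region.value} feature named {req.feature!r}")
        for _ in range(req.count):
            odd = odd_of[req.pattern]
            if req.kind == "substitution" and req.effect == "NA":
                ev = _plant_plain_sub(broker, feats, req, odd, rng, forbidden, eid)
            elif req.kind == "substitution":
                ev = _plant_coding_sub(broker, base, req, odd, rng, forbidden, eid, table)
            else:
                ev = _plant_indel(broker, feats, req, odd, rng, forbidden, eid)
            events.append(ev)
            eid += 1

    events.sort(key=lambda e: e.base_pos)

    # materialise each genome and per-genome coordinates
    genomes: dict[str, MitoGenome] = {}
    rot = {TARGET: 0, CONSPECIFIC: 0, REFERENCE: 0}
    n0 = len(s)
    for gid in GENOMES:
        seq_parts: list[str] = []
        cursor = 1  # next base-genome position to copy
        shift = 0
        shifts: list[tuple[int, int]] = []  # (base_pos, cumulative shift after event)
        for e in events:
            allele = e.alleles[gid]
            base_allele = e.alleles["_base"]
            if allele == base_allele:
                continue
            seq_parts.append(s[cursor - 1 : e.base_pos - 1])
            if e.kind == "substitution":
                seq_parts.append(allele)
                cursor = e.base_pos + 1
            elif e.kind == "deletion":
                cursor = e.base_pos + len(base_allele)
                shift -= len(base_allele)
                shifts.append((e.base_pos, shift))
            else:  # insertion: allele = the inserted run, base allele = "-"
                seq_parts.append(allele)
                cursor = e.base_pos
                shift += len(allele)
                shifts.append((e.base_pos, shift))
        seq_parts.append(s[cursor - 1 :])
        residues = "".join(seq_parts)

        def g_shift(p: int) -> int:
            out = 0
            for bp, sh in shifts:
                if bp <= p:
                    out = sh
            return out

        feats = []
        for f in base.features:
            ds, de = g_shift(f.start - 1), g_shift(f.end)
            feats.append(replace(f, start=f.start + ds, end=f.end + de))
        g = MitoGenome(CircularSeq(gid, residues), feats)
        # per-genome event positions
        for e in events:
            allele = e.alleles[gid]
            if e.kind == "substitution" or allele != "-":
                p = e.base_pos + g_shift(e.base_pos - 1)
            else:  # this genome carries the gap: report the preceding residue
                p = e.base_pos - 1 + g_shift(e.base_pos - 1)
            e.positions[gid] = p
        if rotate and gid != TARGET:
            r = rng.randrange(1, len(residues))
            rot[gid] = r
            g = g.rotated(r)
        genomes[gid] = g

    # drop the private base-allele bookkeeping
    for e in events:
        e.alleles.pop("_base", None)

    start_codons = {}
    stop_kinds = {}
    for f in base.features:
        if f.fclass is FeatureClass.PCG:
            cds = base.feature_seq(f)
            start_codons[f.name] = cds[:3]
            rem = len(cds) % 3
            stop_kinds[f.name] = f"truncated {cds[-rem:]}" if rem else cds[-3:]

    ledger = GroundTruthLedger(events, rot, start_codons, stop_kinds)
    return genomes, ledger


def _alt_base(rng: random.Random, b: str) -> str:
    return rng.choice([x for x in "ACGT" if x != b])


def _plant_plain_sub(broker, feats, req, odd, rng, forbidden, eid) -> PlantedEvent:
    s = broker.s

    def ok(p):
        return p not in forbidden

    p, f = broker.draw_in(feats, span=1, check=ok)
    broker.claim(p)
    ref = s[p - 1]
    alt = _alt_base(rng, ref)
    alleles = {g: (alt if g == odd else ref) for g in GENOMES}
    alleles["_base"] = ref
    return PlantedEvent(eid, "substitution", req.region, f.name, req.pattern,
                        "NA", None, p, alleles)


def _plant_coding_sub(broker, base, req, odd, rng, forbidden, eid, table) -> PlantedEvent:
    pcgs = [f for f in base.features if f.fclass is FeatureClass.PCG]
    for _ in range(4000):
        f = rng.choice(pcgs)
        cds = base.feature_seq(f)
        ncod = len(cds) // 3
        ci = rng.randrange(2, ncod - 2)
        codon, gpos0 = _codon_at(base, f, ci)
        if req.effect == "synonymous":
            if codon[:2] not in _FOURFOLD:
                continue
            cp = 2
            alt_c = _alt_base(rng, codon[2])
        else:
            cp = rng.choice((0, 1))
            alt_c = _alt_base(rng, codon[cp])
        new_codon = codon[:cp] + alt_c + codon[cp + 1 :]
        aa0, aa1 = table.amino_acid(codon), table.amino_acid(new_codon)
        if aa1 == "*":
            continue
        if req.effect == "missense" and aa0 == aa1:
            continue
        if req.effect == "synonymous" and aa0 != aa1:
            continue
        if f.strand is Strand.LIGHT:
            p = gpos0 + cp
            ref_g, alt_g = codon[cp], alt_c
        else:
            p = gpos0 - cp
            ref_g, alt_g = revcomp(codon[cp]), revcomp(alt_c)
        if p in forbidden or not broker._far_enough(p, 1):
            continue
        broker.claim(p)
        # direction: consensus-of-others -> odd genome's amino acid
        aa_change = f"{aa0}->{aa1}" if req.effect == "missense" else None
        if odd == REFERENCE and aa_change:
            # diagnostic convention: ligustica-like -> carnica-like
            aa_change = f"{aa1}->{aa0}"
        alleles = {g: (alt_g if g == odd else ref_g) for g in GENOMES}
        alleles["_base"] = ref_g
        return PlantedEvent(eid, "substitution", req.region, f.name, req.pattern,
                            req.effect, aa_change, p, alleles)
    raise ValueError(f"could not satisfy coding substitution request {req}")


def _plant_indel(broker, feats, req, odd, rng, forbidden, eid) -> PlantedEvent:
    s = broker.s
    L = abs(req.length)
    deletion = req.length < 0

    def ok_del(p):
        # leftmost representation: the gap run must not be left-shiftable,
        # and pin the right side too so the aligner sees a single optimum
        return (s[p - 2] != s[p + L - 2] and s[p + L - 1] != s[p - 1]
                and not any(q in forbidden for q in range(p, p + L)))

    if deletion:
        p, f = broker.draw_in(feats, span=L, check=ok_del, is_indel=True)
        run = s[p - 1 : p + L - 1]
        broker.claim(p, L, is_indel=True)
        alleles = {g: ("-" if g == odd else run) for g in GENOMES}
        alleles["_base"] = run
        return PlantedEvent(eid, "deletion", req.region, f.name, req.pattern,
                            "NA", None, p, alleles)

    # insertion: the run must not be shiftable against its flanks, so the
    # site and the inserted run are drawn jointly
    chosen_run: list[str] = []

    def ok_ins(p):
        if p in forbidden:
            return False
        if req.region is FeatureClass.CONTROL and L % 2 == 0:
            candidates = ["AT" * (L // 2), "TA" * (L // 2)]  # AT-motif copies
        else:
            candidates = ["".join(rng.choice("AT") for _ in range(L)) for _ in range(8)]
        for run in candidates:
            if run[-1] != s[p - 2] and run[0] != s[p - 1]:
                chosen_run[:] = [run]
                return True
        return False

    p, f = broker.draw_in(feats, span=L, check=ok_ins, is_indel=True)
    run = chosen_run[0]
    broker.claim(p, L, is_indel=True)
    alleles = {g: (run if g == odd else "-") for g in GENOMES}
    alleles["_base"] = "-"
    return PlantedEvent(eid, "insertion", req.region, f.name, req.pattern,
                        "NA", None, p, alleles)


__all__ = [
    "CONSPECIFIC", "GENOMES", "GenomeTemplate", "GeneSpec", "GroundTruthLedger",
    "PlantRequest", "PlantedEvent", "REFERENCE", "TARGET", "default_plant_spec",
    "default_template", "make_base", "make_trio",
]
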