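"""Circular mitogenome I/O and coordinate bookkeeping.

Genomes are held as a :class:`CircularSeq` plus an ordered, typed feature
table (:class:`MitoGenome`).  Coordinates are GenBank-style 1-based
inclusive at every public interface; spans may wrap the origin of a
circular sequence (``start > end``).  Internally, slicing converts to
0-based half-open once, in :meth:`CircularSeq.fetch`.

GenBank reading/writing delegates the flat-file dialect to Biopython's
``SeqIO``; this module owns the mapping onto the typed feature table and
the honeybee-specific conventions (control region inference, gene-name
normalisation).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitotrio.errors import MitotrioError, ParseError

_ALPHABET = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return s.translate(_RC)[::-1]


class Strand(str, Enum):
    LIGHT = "light"
    HEAVY = "heavy"


class FeatureClass(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class CircularSeq:
    """A nucleotide sequence with explicit topology.

    ``residues`` must be uppercase over {A,C,G,T,N}; rotation is only
    meaningful (and only permitted) when ``circular`` is true.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains disallowed symbols {sorted(bad)}; "
                "only A,C,G,T,N are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def rotate(self, k: int) -> "CircularSeq":
        """Rotate left by ``k``: the new sequence starts at old position k+1."""
        if not self.circular:
            raise ValueError("cannot rotate a linear sequence")
        k %= len(self)
        return replace(self, residues=self.residues[k:] + self.residues[:k])

    def fetch(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive span [start, end]; wraps if start > end."""
        n = len(self)
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(f"span {start}..{end} outside 1..{n}")
        if start <= end:
            return self.residues[start - 1 : end]
        if not self.circular:
            raise ValueError("wrapped span on a linear sequence")
        return self.residues[start - 1 :] + self.residues[:end]


@dataclass(frozen=True)
class Feature:
    """One annotated region: gene, rRNA, tRNA, control region or intergenic gap."""

    name: str
    fclass: FeatureClass
    strand: Strand
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start means the span wraps the origin
    notes: str = ""

    def wraps(self) -> bool:
        return self.end < self.start

    def span_length(self, seq_len: int) -> int:
        if self.wraps():
            return seq_len - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        if self.wraps():
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionCall:
    """Result of classifying one genome position."""

    fclass: FeatureClass
    name: str
    memberships: tuple[str, ...] = ()


@dataclass
class MitoGenome:
    """A circular sequence plus its ordered feature table."""

    seq: CircularSeq
    features: list[Feature] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.seq)
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValueError(f"feature {f.name} span {f.start}..{f.end} outside 1..{n}")
            if f.wraps() and not self.seq.circular:
                raise ValueError(f"feature {f.name} wraps on a linear sequence")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        named = [f.name for f in self.features if f.fclass is not FeatureClass.INTERGENIC]
        dups = {x for x in named if named.count(x) > 1}
        if dups:
            raise ValueError(f"duplicate feature names: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def feature_seq(self, f: Feature | str) -> str:
        """Strand-resolved sequence of a feature (5'→3' on its coding strand)."""
        if isinstance(f, str):
            f = self.feature(f)
        s = self.seq.fetch(f.start, f.end)
        return revcomp(s) if f.strand is Strand.HEAVY else s

    def rotated(self, k: int) -> "MitoGenome":
        """Rotate the genome left by ``k`` and shift all feature coordinates."""
        n = len(self.seq)
        k %= n

        def shift(p: int) -> int:
            return (p - 1 - k) % n + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in self.features]
        return MitoGenome(self.seq.rotate(k), feats, list(self.notes))


# ---------------------------------------------------------------------------
# composition and region classification


def composition(g: MitoGenome | CircularSeq | str) -> dict:
    """Base counts and GC/AT fractions (N counted separately, excluded from fractions)."""
    if isinstance(g, MitoGenome):
        s = g.seq.residues
    elif isinstance(g, CircularSeq):
        s = g.residues
    else:
        s = g
    counts = {b: s.count(b) for b in "ACGT"}
    n = s.count("N")
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("sequence has no unambiguous residues")
    return {
        **counts,
        "N": n,
        "length": len(s),
        "gc_fraction": (counts["G"] + counts["C"]) / acgt,
        "at_fraction": (counts["A"] + counts["T"]) / acgt,
    }


def intergenic_gaps(g: MitoGenome) -> list[Feature]:
    """Materialise the unannotated gaps between features as intergenic features.

    Gap names record the flanking genes, ``IR(left|right)``; the gap after the
    last feature wraps round to the first when the sequence is circular.
    """
    n = len(g.seq)
    feats = [f for f in g.features if f.fclass is not FeatureClass.INTERGENIC]
    if not feats:
        return [Feature("IR(whole)", FeatureClass.INTERGENIC, Strand.LIGHT, 1, n)]
    covered = [False] * n
    for f in feats:
        if f.wraps():
            for p in range(f.start, n + 1):
                covered[p - 1] = True
            for p in range(1, f.end + 1):
                covered[p - 1] = True
        else:
            for p in range(f.start, f.end + 1):
                covered[p - 1] = True
    gaps: list[Feature] = []
    p = 1
    while p <= n:
        if not covered[p - 1]:
            q = p
            while q < n and not covered[q]:
                q += 1
            end = q if not covered[q - 1] else q - 1
            left = _nearest_feature(g, p, upstream=True)
            right = _nearest_feature(g, end, upstream=False)
            gaps.append(
                Feature(
                    f"IR({left}|{right})", FeatureClass.INTERGENIC, Strand.LIGHT, p, end
                )
            )
            p = end + 1
        else:
            p += 1
    return gaps


def _nearest_feature(g: MitoGenome, pos: int, upstream: bool) -> str:
    """Name of the nearest annotated feature up/downstream of ``pos`` (circularly)."""
    n = len(g.seq)
    feats = [f for f in g.features if f.fclass is not FeatureClass.INTERGENIC]
    if not feats:
        return "none"
    best, bestd = None, None
    for f in feats:
        if upstream:
            d = (pos - f.end) % n
        else:
            d = (f.start - pos) % n
        if bestd is None or d < bestd:
            best, bestd = f, d
    return best.name


def region_of(g: MitoGenome, pos: int) -> RegionCall:
    """Classify a 1-based genome position into its region class and feature.

    Positions covered by more than one annotated feature (the atp8/atp6 style
    overlap) resolve to the feature whose start is nearest upstream; all
    memberships are retained in :attr:`RegionCall.memberships`.  Uncovered
    positions classify as intergenic, named by the flanking genes.
    """
    n = len(g.seq)
    if not (1 <= pos <= n):
        raise ValueError(f"position {pos} outside 1..{n}")
    hits = [
        f
        for f in g.features
        if f.fclass is not FeatureClass.INTERGENIC and f.contains(pos)
    ]
    if hits:
        # nearest upstream start, measured circularly backwards from pos
        best = min(hits, key=lambda f: (pos - f.start) % n)
        return RegionCall(best.fclass, best.name, tuple(f.name for f in hits))
    left = _nearest_feature(g, pos, upstream=True)
    right = _nearest_feature(g, pos, upstream=False)
    return RegionCall(FeatureClass.INTERGENIC, f"IR({left}|{right})")


# ---------------------------------------------------------------------------
# GenBank / FASTA

_KNOWN_KEYS = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene", "source"}

_CONTROL_PAT = re.compile(r"control|AT[- ]rich|A\+T", re.IGNORECASE)


def _norm_gene_name(raw: str) -> str:
    """Normalise GenBank gene/product labels to the short names used here."""
    name = raw.strip()
    low = name.lower().replace(" ", "")
    aliases = {
        "coi": "cox1", "coii": "cox2", "coiii": "cox3",
        "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
        "nad1": "nd1", "nad2": "nd2", "nad3": "nd3", "nad4": "nd4",
        "nad4l": "nd4l", "nad5": "nd5", "nad6": "nd6",
        "cob": "cytb", "atp6": "atp6", "atp8": "atp8",
        "l-rrna": "16S rRNA", "s-rrna": "12S rRNA",
        "rrnl": "16S rRNA", "rrns": "12S rRNA",
    }
    if low in aliases:
        return aliases[low]
    if "16s" in low:
        return "16S rRNA"
    if "12s" in low:
        return "12S rRNA"
    return name


def read_genbank(path: str | Path | io.TextIOBase, infer_control: bool = True) -> MitoGenome:
    """Read a GenBank flat file into a :class:`MitoGenome`.

    ``join()`` locations spanning the origin become wrapped spans.  Unknown
    feature keys are kept as genome notes with a warning.  When no control
    region is annotated and ``infer_control`` is set, the longest unannotated
    gap (>= 200 bp) is synthesised as the ``control_region`` feature so that
    region tallies are reproducible.
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with line info
        raise ParseError(f"malformed GenBank record: {exc}") from exc
    residues = str(rec.seq).upper()
    circular = rec.annotations.get("topology", "circular") == "circular"
    try:
        seq = CircularSeq(rec.id or rec.name, residues, circular)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc

    feats: list[Feature] = []
    notes: list[str] = []
    n = len(seq)
    for sf in rec.features:
        if sf.type in ("source", "gene"):
            continue
        if sf.type not in _KNOWN_KEYS:
            msg = f"unknown feature key {sf.type!r} at {sf.location}; stored as note"
            warnings.warn(msg)
            notes.append(msg)
            continue
        start, end = _span_from_location(sf.location, n)
        strand = Strand.HEAVY if (sf.location.strand or 1) < 0 else Strand.LIGHT
        quals = sf.qualifiers
        label = quals.get("gene", quals.get("product", quals.get("note", ["?"])))[0]
        note = quals.get("note", [""])[0]
        if sf.type == "CDS":
            feats.append(Feature(_norm_gene_name(label), FeatureClass.PCG, strand, start, end, note))
        elif sf.type == "tRNA":
            feats.append(Feature(_norm_gene_name(label), FeatureClass.TRNA, strand, start, end, note))
        elif sf.type == "rRNA":
            feats.append(Feature(_norm_gene_name(label), FeatureClass.RRNA, strand, start, end, note))
        elif sf.type == "D-loop" or _CONTROL_PAT.search(label + " " + note):
            feats.append(Feature("control_region", FeatureClass.CONTROL, strand, start, end, note))
        else:  # misc_feature that is not a control region
            notes.append(f"misc_feature {label!r} {start}..{end} kept as note")
    g = MitoGenome(seq, feats, notes)
    if infer_control and not any(f.fclass is FeatureClass.CONTROL for f in g.features) and feats:
        gaps = intergenic_gaps(g)
        if gaps:
            longest = max(gaps, key=lambda f: f.span_length(n))
            if longest.span_length(n) >= 200:
                g.features.append(
                    replace(longest, name="control_region", fclass=FeatureClass.CONTROL)
                )
                g.features.sort(key=lambda f: (f.start, f.end))
                g.notes.append(
                    f"control_region synthesised over unannotated gap "
                    f"{longest.start}..{longest.end}"
                )
    return g


def _span_from_location(loc, seq_len: int) -> tuple[int, int]:
    """1-based inclusive (start, end); a two-part join over the origin wraps."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[-1].end) == seq_len and int(parts[0].start) == 0:
            # join(X..len, 1..Y): wrapped span
            return int(parts[1].start) + 1, int(parts[0].end)
        return int(parts[0].start) + 1, int(parts[-1].end)
    return int(loc.start) + 1, int(loc.end)


_GB_TYPE = {
    FeatureClass.PCG: "CDS",
    FeatureClass.TRNA: "tRNA",
    FeatureClass.RRNA: "rRNA",
    FeatureClass.CONTROL: "D-loop",
    FeatureClass.INTERGENIC: "misc_feature",
}


def write_genbank(g: MitoGenome, path: str | Path | io.TextIOBase) -> None:
    """Write a :class:`MitoGenome` as a GenBank flat file (canonical feature order)."""
    n = len(g.seq)
    rec = SeqRecord(Seq(g.seq.residues), id=g.seq.id, name=g.seq.id[:16].replace(".", "_"),
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if g.seq.circular else "linear"
    for f in sorted(g.features, key=lambda f: (f.start, f.end)):
        strand = -1 if f.strand is Strand.HEAVY else 1
        if f.wraps():
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, n, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.notes:
            quals["note"] = [f.notes]
        rec.features.append(SeqFeature(loc, type=_GB_TYPE[f.fclass], qualifiers=quals))
    SeqIO.write(rec, path, "genbank")


def read_fasta(path: str | Path | io.TextIOBase, circular: bool = True) -> CircularSeq:
    """Read the first sequence of a FASTA file."""
    try:
        rec = next(SeqIO.parse(path, "fasta"))
    except StopIteration as exc:
        raise ParseError("empty FASTA file") from exc
    try:
        return CircularSeq(rec.id, str(rec.seq).upper(), circular)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_fasta(seqs, path: str | Path | io.TextIOBase, width: int = 70) -> None:
    """Write one or more (id, residues) pairs or CircularSeq objects, wrapped at 70 cols."""
    if isinstance(seqs, CircularSeq):
        seqs = [seqs]
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        for s in seqs:
            sid, res = (s.id, s.residues) if isinstance(s, CircularSeq) else s
            fh.write(f">{sid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


def composition_table(g: MitoGenome) -> str:
    """Human-readable composition summary (the ``mitotrio stats`` payload)."""
    c = composition(g)
    lines = [f"sequence\t{g.seq.id}", f"length\t{c['length']}"]
    for b in "ACGT":
        lines.append(f"{b}\t{c[b]}\t{100 * c[b] / (c['length'] - c['N']):.1f}%")
    if c["N"]:
        lines.append(f"N\t{c['N']}")
    lines.append(f"GC\t{100 * c['gc_fraction']:.1f}%")
    lines.append(f"AT\t{100 * c['at_fraction']:.1f}%")
    return "\n".join(lines)


__all__ = [
    "CircularSeq", "Feature", "FeatureClass", "MitoGenome", "RegionCall", "Strand",
    "composition", "composition_table", "intergenic_gaps", "read_fasta", "read_genbank",
    "region_of", "revcomp", "write_fasta", "write_genbank", "MitotrioError",
]
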