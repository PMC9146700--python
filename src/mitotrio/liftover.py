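"""Annotation transfer through pairwise alignments, plus gene-order comparison.

The feature table of an annotated reference genome is projected onto a
newly assembled target through their pairwise alignment
(:func:`project_features`).  Short features whose projection collapses
(the fate of some tRNAs under coordinate liftover) are rescued by a
local similarity search (:func:`rescue_unmapped`).  Annotated overlaps
are then curated (:func:`curate_overlaps`): a protein gene that appears
to run into a downstream tRNA is trimmed back to a truncated stop codon
when one exists at the boundary — the classic cox1/tRNA-Leu artifact —
while the genuine atp8/atp6 dual-frame overlap is preserved.

Gene orders are compared as circular signed adjacency sets
(:func:`gene_order_diff`), which is rotation-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import edlib

from mitotrio.align import PairAlignment
from mitotrio.genetic_code import INVERTEBRATE_MITO, CodonTable, translate_cds
from mitotrio.errors import IntegrityError
from mitotrio.mitio import CircularSeq, Feature, FeatureClass, MitoGenome, Strand

#: Projected span shorter than this fraction of the reference span counts as failed.
LENGTH_FLOOR = 0.5

#: PCG/PCG overlaps that are genuine dual-frame overlaps, never curated away.
OVERLAP_WHITELIST = frozenset({frozenset({"atp8", "atp6"})})


@dataclass
class FeatureTransfer:
    name: str
    status: str  # projected | rescued | failed
    ref_span: tuple[int, int]
    target_span: tuple[int, int] | None
    delta_start: int | None
    detail: str = ""


@dataclass
class TransferReport:
    entries: list[FeatureTransfer] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)

    def by_status(self, status: str) -> list[FeatureTransfer]:
        return [e for e in self.entries if e.status == status]

    def to_tsv(self) -> str:
        lines = ["feature\tstatus\tref_start\tref_end\ttarget_start\ttarget_end\tdelta\tdetail"]
        for e in self.entries:
            ts, te = e.target_span if e.target_span else ("", "")
            d = "" if e.delta_start is None else str(e.delta_start)
            lines.append(
                f"{e.name}\t{e.status}\t{e.ref_span[0]}\t{e.ref_span[1]}\t{ts}\t{te}\t{d}\t{e.detail}"
            )
        return "\n".join(lines) + "\n"


def project_features(
    ref: MitoGenome, aln: PairAlignment
) -> tuple[MitoGenome, TransferReport]:
    """Project the reference feature table onto the alignment's second sequence.

    Endpoints map through the alignment's column→position maps; an endpoint
    landing in a target gap snaps inward to the nearest aligned column.  A
    feature whose projected span collapses below half its reference length is
    reported as ``failed`` (candidate for :func:`rescue_unmapped`).
    """
    if aln.ungapped(0) != ref.seq.residues:
        raise ValueError("alignment's first sequence is not the reference genome")
    tgt_residues = aln.ungapped(1)
    nt = len(tgt_residues)
    ref_pm = aln.pos_map(0)
    tgt_pm = aln.pos_map(1)
    # column of each 1-based reference position
    ref_cols = {int(p): c for c, p in enumerate(ref_pm) if p}

    def map_pos(pos: int, snap: int) -> int | None:
        """Target position for ref position ``pos``; snap=+1 forward, -1 backward."""
        c = ref_cols[pos]
        while 0 <= c < len(tgt_pm):
            if tgt_pm[c]:
                return int(tgt_pm[c])
            c += snap
        return None

    report = TransferReport()
    feats: list[Feature] = []
    n_ref = len(ref.seq)
    for f in ref.features:
        if f.fclass is FeatureClass.INTERGENIC:
            continue
        ts = map_pos(f.start, +1)
        te = map_pos(f.end, -1)
        ref_len = f.span_length(n_ref)
        ok = ts is not None and te is not None
        if ok:
            tgt_len = (te - ts + 1) if ts <= te else (nt - ts + 1 + te)
        if ok and tgt_len >= LENGTH_FLOOR * ref_len:
            feats.append(replace(f, start=ts, end=te))
            report.entries.append(
                FeatureTransfer(f.name, "projected", (f.start, f.end), (ts, te), ts - f.start)
            )
        else:
            detail = "span collapsed below length floor" if ok else "endpoint unmappable"
            report.entries.append(
                FeatureTransfer(f.name, "failed", (f.start, f.end), None, None, detail)
            )
    target = MitoGenome(CircularSeq(aln.ids[1], tgt_residues, ref.seq.circular), feats)
    return target, report


def rescue_unmapped(
    target: MitoGenome,
    ref: MitoGenome,
    failed: list[str],
    min_identity: float = 0.85,
) -> tuple[MitoGenome, TransferReport]:
    """Re-place features that projection lost, by similarity search in the target.

    Each failed feature's reference sequence is searched against the target
    (infix semantics over the doubled circle, so wrapped placements work); the
    best hit is accepted when its identity reaches ``min_identity`` and it does
    not overlap an existing feature of the same class by more than half.
    """
    report = TransferReport()
    feats = list(target.features)
    n = len(target.seq)
    doubled = target.seq.residues + target.seq.residues
    for name in failed:
        f = ref.feature(name)
        query = ref.seq.fetch(f.start, f.end)  # genome-strand orientation
        res = edlib.align(query, doubled, mode="HW", task="locations")
        dist = res["editDistance"]
        identity = 1.0 - dist / len(query)
        if identity < min_identity or not res["locations"]:
            report.entries.append(
                FeatureTransfer(name, "failed", (f.start, f.end), None, None,
                                f"best identity {identity:.2f} < {min_identity}")
            )
            continue
        s0, e0 = res["locations"][0]
        ts = s0 % n + 1
        te = e0 % n + 1
        cand = replace(f, start=ts, end=te)
        clash = _overlap_clash(cand, feats, n)
        if clash:
            report.entries.append(
                FeatureTransfer(name, "failed", (f.start, f.end), None, None,
                                f"placement overlaps {clash} by >50%")
            )
            continue
        feats.append(cand)
        report.entries.append(
            FeatureTransfer(name, "rescued", (f.start, f.end), (ts, te), None,
                            f"identity {identity:.2f}")
        )
    return MitoGenome(target.seq, feats, list(target.notes)), report


def _overlap_clash(cand: Feature, feats: list[Feature], n: int) -> str | None:
    """Name of an existing same-class feature overlapped by >50%, if any."""
    def cover(f: Feature) -> set[int]:
        if f.wraps():
            return set(range(f.start, n + 1)) | set(range(1, f.end + 1))
        return set(range(f.start, f.end + 1))

    cpos = cover(cand)
    for f in feats:
        if f.fclass is not cand.fclass or f.name == cand.name:
            continue
        if len(cpos & cover(f)) > 0.5 * len(cpos):
            return f.name
    return None


@dataclass
class CurationAction:
    rule: str
    feature: str
    detail: str


def curate_overlaps(
    g: MitoGenome, table: CodonTable = INVERTEBRATE_MITO
) -> tuple[MitoGenome, list[CurationAction]]:
    """Resolve annotation overlaps, trimming PCGs back to truncated stops.

    A protein gene overlapping a tRNA is trimmed so the PCG ends just before
    the tRNA — accepted only if the trimmed CDS then terminates on a truncated
    stop (T or TA) and still translates cleanly; otherwise the action is
    aborted and flagged.  Whitelisted PCG/PCG overlaps (atp8/atp6) are
    preserved untouched.  The operation is idempotent.
    """
    n = len(g.seq)
    feats = {f.name: f for f in g.features if f.fclass is not FeatureClass.INTERGENIC}
    actions: list[CurationAction] = []
    for name, f in list(feats.items()):
        if f.fclass is not FeatureClass.PCG:
            continue
        for oname, o in feats.items():
            if oname == name:
                continue
            ov = _overlap_len(f, o, n)
            if ov <= 0:
                continue
            if o.fclass is FeatureClass.PCG:
                if frozenset({name, oname}) in OVERLAP_WHITELIST:
                    continue
                actions.append(CurationAction(
                    "pcg-pcg-overlap", name,
                    f"unexpected overlap with {oname} by {ov} bases; left untouched"))
                continue
            if o.fclass is not FeatureClass.TRNA:
                continue
            trimmed = _trim_to_truncated_stop(g, f, o, ov, table)
            if trimmed is None:
                actions.append(CurationAction(
                    "trim-aborted", name,
                    f"overlap with {oname} by {ov} bases not resolvable by a truncated stop"))
                continue
            feats[name] = trimmed
            actions.append(CurationAction(
                "truncated-stop-trim", name,
                f"trimmed {ov} bases overlapping {oname}; stop now truncated "
                f"{_tail(g, trimmed)!r}"))
    out = MitoGenome(g.seq, list(feats.values()), list(g.notes))
    return out, actions


def _overlap_len(a: Feature, b: Feature, n: int) -> int:
    def cover(f: Feature) -> set[int]:
        if f.wraps():
            return set(range(f.start, n + 1)) | set(range(1, f.end + 1))
        return set(range(f.start, f.end + 1))
    return len(cover(a) & cover(b))


def _tail(g: MitoGenome, f: Feature) -> str:
    cds = g.feature_seq(f)
    rem = len(cds) % 3
    return cds[-rem:] if rem else cds[-3:]


def _trim_to_truncated_stop(
    g: MitoGenome, pcg: Feature, trna: Feature, ov: int, table: CodonTable
) -> Feature | None:
    """Trim ``pcg`` so it no longer overlaps ``trna``, if a truncated stop results."""
    if pcg.strand is Strand.LIGHT:
        new = replace(pcg, end=trna.start - 1)
    else:
        new = replace(pcg, start=trna.end + 1)
    n = len(g.seq)
    if new.span_length(n) < 3:
        return None
    cds = g.feature_seq(new)
    rem = len(cds) % 3
    if rem == 0 or cds[-rem:] not in table.truncated_stops:
        return None
    try:
        translate_cds(cds, table)
    except IntegrityError:
        return None
    return new


# ---------------------------------------------------------------------------
# gene order


@dataclass(frozen=True)
class GeneOrder:
    """Circular ordered list of (gene name, strand), starting at the control region."""

    entries: tuple[tuple[str, Strand], ...]

    @classmethod
    def of(cls, g: MitoGenome, start_at: str = "control_region") -> "GeneOrder":
        feats = sorted(
            (f for f in g.features if f.fclass is not FeatureClass.INTERGENIC),
            key=lambda f: f.start,
        )
        names = [f.name for f in feats]
        if start_at in names:
            k = names.index(start_at)
            feats = feats[k:] + feats[:k]
        return cls(tuple((f.name, f.strand) for f in feats))

    def genes(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def restricted(self, keep: set[str]) -> "GeneOrder":
        return GeneOrder(tuple(e for e in self.entries if e[0] in keep))


def _signed(entry: tuple[str, Strand]) -> tuple[str, int]:
    return entry[0], 1 if entry[1] is Strand.LIGHT else -1


def _adjacencies(order: GeneOrder) -> set[tuple]:
    """Canonical signed adjacency set of a circular order (orientation-free)."""
    ents = [_signed(e) for e in order.entries]
    k = len(ents)
    out = set()
    for i in range(k):
        x, y = ents[i], ents[(i + 1) % k]
        fwd = (x, y)
        rev = ((y[0], -y[1]), (x[0], -x[1]))
        out.add(min(fwd, rev))
    return out


@dataclass
class OrderDiff:
    breakpoints: list[tuple]  # adjacencies of ``a`` absent from ``b``
    conserved_blocks: list[tuple[str, ...]]
    only_in_a: tuple[str, ...]
    only_in_b: tuple[str, ...]

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)


def gene_order_diff(a: GeneOrder, b: GeneOrder) -> OrderDiff:
    """Rotation-invariant adjacency comparison of two circular gene orders.

    Names not shared are excluded from the adjacency analysis and reported.
    Conserved blocks are maximal runs of ``a`` whose internal adjacencies all
    occur in ``b``.
    """
    ga, gb = set(a.genes()), set(b.genes())
    shared = ga & gb
    ra, rb = a.restricted(shared), b.restricted(shared)
    adj_a, adj_b = _adjacencies(ra), _adjacencies(rb)
    breakpoints = sorted(adj_a - adj_b)

    # conserved-block decomposition: cut ra's circle at every broken adjacency
    ents = [_signed(e) for e in ra.entries]
    k = len(ents)
    blocks: list[tuple[str, ...]] = []
    if k:
        broken = []
        for i in range(k):
            x, y = ents[i], ents[(i + 1) % k]
            rev = ((y[0], -y[1]), (x[0], -x[1]))
            broken.append(min((x, y), rev) not in adj_b)
        cuts = [i for i in range(k) if broken[i]]
        if not cuts:
            blocks = [tuple(n for n, _ in ents)]
        else:
            for t, ib in enumerate(cuts):
                jb = cuts[(t + 1) % len(cuts)]
                blk = []
                i = (ib + 1) % k
                while True:
                    blk.append(ents[i][0])
                    if i == jb:
                        break
                    i = (i + 1) % k
                blocks.append(tuple(blk))
    return OrderDiff(
        breakpoints=breakpoints,
        conserved_blocks=blocks,
        only_in_a=tuple(sorted(ga - gb)),
        only_in_b=tuple(sorted(gb - ga)),
    )


def named_order(key: str) -> GeneOrder:
    """A shipped reference gene order: ``ancestral_insect`` or ``apis_mellifera``."""
    data = json.loads(
        resources.files("mitotrio").joinpath("data/gene_orders.json").read_text()
    )
    if key not in data or key.startswith("_"):
        raise KeyError(key)
    return GeneOrder(tuple((n, Strand(s)) for n, s in data[key]))


__all__ = [
    "CurationAction", "FeatureTransfer", "GeneOrder", "OrderDiff", "TransferReport",
    "curate_overlaps", "gene_order_diff", "named_order", "project_features",
    "rescue_unmapped", "LENGTH_FLOOR", "OVERLAP_WHITELIST",
]
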