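"""The tRNA-Leu–cox2 mitotype marker and its in-silico DraI profile.

In honeybees the intergenic region between cox1 and cox2 — bounded by
the tRNA-Leu copy adjacent to cox1 — distinguishes the matrilineal
evolutionary lineages, classically through the restriction profile left
by DraI (recognition site TTTAAA, cutting between the third T and the
first A): the "DraI test".  This module extracts the marker from an
annotated genome and digests it; assigning a named haplotype requires
comparison against reference haplotypes, for which an optional
exact-match lookup against a user-supplied FASTA is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from mitotrio.mitio import FeatureClass, MitoGenome

DRAI_SITE = "TTTAAA"
_CUT_OFFSET = 3  # DraI cuts TTT^AAA


@dataclass(frozen=True)
class Marker:
    sequence: str
    start: int  # 1-based genome coordinates; start > end+1 impossible, empty allowed
    end: int
    flank_trna: str
    flagged: str = ""  # non-empty when the extraction needed a fallback rule


@dataclass(frozen=True)
class MitotypeProfile:
    marker: str
    cut_positions: tuple[int, ...]  # 1-based offsets within the marker, after the cut
    fragments: tuple[int, ...]  # 5'->3' fragment lengths


def extract_marker(g: MitoGenome, include_trna: bool = False) -> Marker:
    """The intergenic stretch between tRNA-Leu (cox1-adjacent copy) and cox2.

    The flanking tRNA-Leu copy is resolved from the annotation: if several
    tRNA-Leu genes exist, the copy closest downstream of cox1 is used (an
    anticodon note, when present, is respected via the gene naming); the
    choice is flagged in the result.  With ``include_trna`` the tRNA itself
    is included, matching the wider amplicon convention.  An empty marker
    (cox2 immediately follows the tRNA) is valid and flagged.
    """
    cox2 = _require(g, "cox2")
    cox1 = _require(g, "cox1")
    n = len(g.seq)
    leus = [f for f in g.features
            if f.fclass is FeatureClass.TRNA and f.name.startswith("tRNA-Leu")]
    if not leus:
        raise ValueError("genome annotates no tRNA-Leu; cannot extract the marker")
    # circular distance from the end of cox1 forward to the tRNA start
    leu = min(leus, key=lambda f: (f.start - cox1.end) % n)
    flag = "" if len(leus) == 1 else f"cox1-adjacent copy {leu.name} selected"
    start = leu.start if include_trna else (leu.end % n) + 1
    end = (cox2.start - 2) % n + 1
    if (end % n) + 1 == start:
        return Marker("", start, end, leu.name, flag or "empty marker")
    seq = g.seq.fetch(start, end)
    return Marker(seq, start, end, leu.name, flag)


def _require(g: MitoGenome, name: str):
    try:
        return g.feature(name)
    except KeyError:
        raise ValueError(f"genome does not annotate {name!r}") from None


def drai_profile(marker: str | Marker) -> MitotypeProfile:
    """Digest a linear marker sequence at every DraI site (TTT^AAA).

    Fragments are reported 5'→3'; with no site the whole marker is one
    fragment.  Fragment lengths always sum to the marker length.
    """
    seq = marker.sequence if isinstance(marker, Marker) else marker
    cuts: list[int] = []
    i = seq.find(DRAI_SITE)
    while i >= 0:
        cuts.append(i + _CUT_OFFSET)  # 0-based index of the first base after the cut
        i = seq.find(DRAI_SITE, i + 1)
    frags: list[int] = []
    prev = 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(seq) - prev)
    if not seq:
        frags = (0,)
    return MitotypeProfile(seq, tuple(c + 1 for c in cuts), tuple(frags))


def match_haplotype(marker: str | Marker, reference_fasta) -> str | None:
    """Exact-match label from a user-supplied reference-haplotype FASTA.

    Returns the id of the first record whose sequence equals the marker
    (case-insensitive), or None.  Naming beyond exact identity — similarity
    search against public databases — is deliberately out of scope.
    """
    seq = (marker.sequence if isinstance(marker, Marker) else marker).upper()
    for rec in SeqIO.parse(reference_fasta, "fasta"):
        if str(rec.seq).upper() == seq:
            return rec.id
    return None


def profile_tsv(profiles: dict[str, MitotypeProfile]) -> str:
    lines = ["genome\tmarker_length\tn_sites\tfragments"]
    for gid, p in profiles.items():
        lines.append(
            f"{gid}\t{len(p.marker)}\t{len(p.cut_positions)}\t"
            + ",".join(map(str, p.fragments))
        )
    return "\n".join(lines) + "\n"


__all__ = ["DRAI_SITE", "Marker", "MitotypeProfile", "drai_profile",
           "extract_marker", "match_haplotype", "profile_tsv"]
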