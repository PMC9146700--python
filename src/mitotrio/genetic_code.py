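"""Translation under the invertebrate mitochondrial code (NCBI table 5).

Animal mitochondrial protein genes deviate from the standard code —
under table 5, AGA/AGG encode Ser, ATA encodes Met and TGA encodes Trp —
and frequently terminate on an incomplete codon (a bare T or TA at the
gene 3' end) that is completed to TAA by post-transcriptional
polyadenylation.  Both quirks are load-bearing for mitogenome
annotation: an apparent gene overlap can be an artifact of missing the
truncated stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

from mitotrio.errors import IntegrityError
from mitotrio.mitio import FeatureClass, MitoGenome


@dataclass(frozen=True)
class StopReport:
    """How a coding sequence terminates."""

    kind: str  # "full" or "truncated"
    codon: str  # "TAA"/"TAG" or "T"/"TA"


@dataclass(frozen=True)
class CodonTable:
    """Codon→amino-acid map plus initiator and stop sets for one NCBI table."""

    table_id: int
    forward: dict[str, str]
    initiators: frozenset[str]
    stops: frozenset[str]
    truncated_stops: frozenset[str] = frozenset({"T", "TA"})

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "CodonTable":
        t = _BioCodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            initiators=frozenset(t.start_codons),
            stops=frozenset(t.stop_codons),
        )

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid; '*' for a stop codon."""
        codon = codon.upper()
        if codon in self.stops:
            return "*"
        try:
            return self.forward[codon]
        except KeyError:
            raise ValueError(f"not a codon: {codon!r}") from None


#: The invertebrate mitochondrial code, the default throughout the package.
INVERTEBRATE_MITO = CodonTable.from_ncbi(5)


@dataclass(frozen=True)
class Translation:
    protein: str
    initiator_codon: str
    stop: StopReport


def translate_cds(seq: str, table: CodonTable = INVERTEBRATE_MITO) -> Translation:
    """Translate a strand-resolved coding sequence, reporting its terminator.

    The sequence length mod 3 signals the stop type: remainder 0 requires a
    full TAA/TAG terminal codon, remainder 1 a trailing T, remainder 2 a
    trailing TA (complete-by-polyadenylation).  The protein begins with M
    regardless of the initiator codon (the biological convention for
    mitochondrial initiators); the raw initiator is reported alongside.

    Raises
    ------
    IntegrityError
        If an internal stop codon is found (names the codon index), or the
        terminus is inconsistent with the length remainder — both signal
        misannotation or a frameshift.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("coding sequence shorter than one codon")
    rem = len(seq) % 3
    if rem == 0:
        body, tail = seq[:-3], seq[-3:]
        if tail not in table.stops:
            raise IntegrityError(
                f"final codon {tail} is not a stop codon (length % 3 == 0)"
            )
        stop = StopReport("full", tail)
    else:
        body, tail = seq[: -rem], seq[-rem:]
        if tail not in table.truncated_stops:
            raise IntegrityError(
                f"trailing {tail!r} is not a truncated stop (expected T or TA)"
            )
        stop = StopReport("truncated", tail)

    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    if not codons:
        raise ValueError("coding sequence has no codons before the stop")
    aas = []
    for i, c in enumerate(codons):
        aa = table.amino_acid(c)
        if aa == "*":
            raise IntegrityError(f"internal stop codon {c} at codon index {i}")
        aas.append(aa)
    initiator = codons[0]
    aas[0] = "M"  # initiator rendered as (formyl-)Met by convention
    return Translation("".join(aas), initiator, stop)


@dataclass
class CodonSurvey:
    """Start-codon and stop-kind census over a genome's protein genes."""

    starts: dict[str, int] = field(default_factory=dict)
    stops: dict[str, int] = field(default_factory=dict)
    per_gene: dict[str, tuple[str, str]] = field(default_factory=dict)


def codon_usage_survey(g: MitoGenome, table: CodonTable = INVERTEBRATE_MITO) -> CodonSurvey:
    """Tally initiator codons and stop kinds over all protein-coding genes.

    Heavy-strand genes are translated from the reverse complement (handled by
    :meth:`MitoGenome.feature_seq`).  Counts sum to the number of PCGs.
    """
    pcgs = [f for f in g.features if f.fclass is FeatureClass.PCG]
    if not pcgs:
        raise ValueError("genome annotates no protein-coding genes")
    survey = CodonSurvey()
    for f in pcgs:
        tr = translate_cds(g.feature_seq(f), table)
        stop_key = tr.stop.codon if tr.stop.kind == "full" else f"truncated {tr.stop.codon}"
        survey.starts[tr.initiator_codon] = survey.starts.get(tr.initiator_codon, 0) + 1
        survey.stops[stop_key] = survey.stops.get(stop_key, 0) + 1
        survey.per_gene[f.name] = (tr.initiator_codon, stop_key)
    return survey


__all__ = [
    "CodonTable", "CodonSurvey", "INVERTEBRATE_MITO", "StopReport", "Translation",
    "codon_usage_survey", "translate_cds",
]
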