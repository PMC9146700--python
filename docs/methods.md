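# Methods

This note documents the models, conventions and numerical choices the
package implements, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and topology

Mitogenomes are circular. All public interfaces use GenBank-style
1-based inclusive coordinates; spans may wrap the origin (start > end).
Internally slices convert once to 0-based half-open. Rotating a genome
by k and then by length−k is the identity, and every analysis stage is
rotation-invariant because inputs are first rotated to a common anchor:
the conspecific and reference genomes are re-anchored so they begin at
the position homologous to the target's first residue, which keeps the
control region intact at the sequence end.

## Translation (NCBI table 5)

Protein genes are translated under the invertebrate mitochondrial code:
AGA/AGG encode serine, ATA methionine, TGA tryptophan; stops are TAA and
TAG. A coding length ≡ 1 (mod 3) ending in T, or ≡ 2 ending in TA, is
accepted as a truncated stop completed by post-transcriptional
polyadenylation; any other remainder, or any internal stop, raises an
integrity error naming the codon index (these signal misannotation or a
frameshift, and overlap curation relies on them). Proteins are rendered
with an initial M regardless of the initiator codon — the biological
convention for mitochondrial initiators — while the raw initiator is
preserved so start-codon censuses remain computable.

## Pairwise alignment

`align.global_align` is a banded global Gotoh alignment with affine
gaps. Defaults: match +2, mismatch −3, gap open −6, gap extend −1
(a gap of length L costs open + (L−1)·extend). These suit near-identical
mitochondrial DNA; at ≥99.5% identity outside the control region any
sensible scheme yields the same alignment, which is why the defaults are
configurable but not critical. The band is centred on the
corner-to-corner diagonal with half-width 300 columns (covering the
observed length differences between the genomes this tool targets, which
are dominated by control-region length variation of ~100 bp); if the
optimal traceback path touches the band edge the band doubles, up to
2400, then fails loudly. The row recurrence is vectorised; the
within-row horizontal-gap dependency collapses to a running maximum, so
a 16.4 kb pair aligns in about a second.

**Gap normalisation.** After alignment, every gap run is shifted
maximally leftward whenever the opposing row carries the same residue at
both swap columns — the column multiset (and score) is preserved, and
indels in homopolymers and AT microsatellites acquire a canonical
leftmost placement. Event counting is only reproducible across scoring
dialects because of this normalisation; comparisons against published
site tables should use per-genome positions, not raw column indices.

**Anchored merge.** Pairwise alignments sharing their reference row
merge into one column space: each reference position is one column, and
insertions relative to the reference occupy per-pair sub-slots between
reference positions, interleaved deterministically in pair order —
except that *identical* insertion segments from different pairs share
one column block. The exception matters: a deletion in the reference
genome looks like the same insertion in every pair, and splitting it
would turn one event into two artefacts.

## Annotation liftover

Feature endpoints map through the alignment's column maps; endpoints
landing in target gaps snap inward. A projected span shorter than half
its reference length counts as failed and triggers rescue: the
reference sequence of the feature is searched against the doubled
target with infix (edlib) alignment and placed if identity ≥ 0.85 —
the threshold is a package default (the identity under which the
original transfer tool dropped two tRNAs is not published) and is
configurable. A rescue placement overlapping an existing same-class
feature by more than half is rejected with a reason.

Overlap curation trims a protein gene that runs into a tRNA back to the
tRNA boundary only when the trimmed CDS then ends on a truncated stop
and still translates cleanly; the atp8/atp6 dual-frame overlap (19
bases) is whitelisted and never touched. Curation is idempotent.

Gene orders are compared as circular signed adjacency sets (an
adjacency equals its strand-reversed mirror), which makes the
comparison rotation- and orientation-invariant; unshared gene names are
reported and excluded. The shipped `ancestral_insect` and
`apis_mellifera` orders live in `data/gene_orders.json`.

## Event calling and classification

Every non-unanimous MSA column belongs to exactly one event.
Substitution columns are singleton events; maximal runs of contiguous
columns with the same gap pattern form one indel event. The default
tally counts one per event (a 2 bp indel is one feature); `--count-mode
column` counts indels per column instead, since published site totals
are sensitive to this convention.

Uniqueness patterns on a trio (target, conspecific, reference): odd
target → `unique_target`; odd conspecific → `unique_other1`; odd
reference → `diagnostic_pair`; no odd one out → `all_distinct`.

Coding effects: substitutions in a protein gene translate the
containing codon from each genome's own sequence (strand-aware, through
the MSA columns of the codon); identical amino acids → synonymous,
differing → missense. Amino-acid changes read others→target for unique
events and reference→pair for diagnostic events, matching the direction
conventions of subspecies-comparison tables. Indels in protein genes
are frameshifts when their length is not a multiple of three; in-frame
indels carry effect NA (no point change is defined for them). Events
touching initiator or terminator codons, or codons interrupted by gaps,
are classed `boundary`.

## Distances and ABGD

Distances are computed on MSA rows directly (no per-pair re-alignment),
under pairwise deletion: columns gapped or ambiguous in either row of a
pair are dropped for that pair. Gamma rate variation uses the transform
α·(x^(−1/α) − 1) → −ln x as α → ∞, evaluated as α·expm1(−ln(x)/α) for
numerical stability at large α (the naive power form loses ~8 digits at
α = 1e8). Jukes–Cantor with shape α = 1 simplifies to p/(1 − 4p/3),
which the tests pin to 1e-12. The K80 form corrects the transition and
transversion proportions under the same α. Divergence beyond the
model's domain (e.g. p ≥ 3/4 under JC) raises a saturation error rather
than returning a complex or negative value.

ABGD: ranked pairwise distances are scanned for the first significant
gap whose upper edge exceeds the prior maximal intraspecific distance
P; a gap d_i → d_{i+1} is significant when d_{i+1} − d_i >
X·max(d_i, P) with relative width X = 1.5 (the method's canonical
default). Pairs below the gap define a graph whose connected components
are groups; the procedure recurses inside groups of at least 3 (both
knobs configurable). This rule is deterministic, invariant to label
order, and raising P can only coarsen the partition. On a three-genome
within-subspecies trio it returns a single group, as it should.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any real genome's sequence. A template fixes the gene layout
(*A. mellifera* arrangement, control region last), lengths (tRNAs
63–78 bp, rRNAs 1371/786 bp, realistic PCG lengths, a 900 bp control
region, a 96 bp tRNA-Leu–cox2 spacer with two planted DraI sites) and
per-gene start/stop codons (one ATC, three ATG, three ATA, six ATT;
TAA stops except a truncated T on cox1). Sequences draw from an
AT-biased base distribution (A .43, T .42, G .055, C .095); protein
genes are sampled codon-wise with no internal stops; the atp8/atp6
overlap is built so both reading frames are clean across the shared 19
nucleotides. All randomness flows through one seeded generator, so a
seed fully determines the genome; the whole-genome AT fraction is
checked against the 0.85 target (±2%) at generation time.

Trios derive from the base by planting events, each altering exactly
one genome, so pattern and effect are known by construction and every
missense is verified against table 5 before planting. The default
spectrum reproduces the study-shaped tallies (64 = 4 tRNA + 24 PCG +
11 rRNA + 14 CR + 11 IR vs the reference; 59 vs the conspecific; 23
diagnostic; 8 unique and 3 diagnostic missense; a 4 bp 16S deletion
unique to the target; 12S as the ±1 bp length-variable rRNA;
control-region variability carried mostly by AT-motif indels). Those
published headline counts are mutually inconsistent under any single
counting convention (44 unique + 23 diagnostic ≠ 64), so the generator
pins the fully-specified regional breakdown and lets the unique-event
total fall where it must (41); both conventions remain reportable via
the count mode.

**Indel ambiguity.** A planted indel must be recoverable at its planted
coordinate, so placements are constrained to be their own leftmost
normal form (the flanking residues forbid shifting the gap run either
way), and two indel events must be at least 40 bp apart: closer
opposite-sign indels in the AT-repeat-rich control region can trade
against each other in an equal-scoring alignment, making ground truth
ill-defined. Substitution events keep ≥12 bp mutual distance and ≥6 bp
from feature boundaries, which also keeps codon extraction clean.

**What passing does not show.** The generator's events are isolated and
unambiguous by construction; real control regions contain tandem-repeat
expansions whose event decomposition is genuinely ambiguous, and real
annotations carry boundary disagreements that no ledger adjudicates.
Recovery of 100% of planted events therefore validates the machinery
(coordinate bookkeeping, classification, translation), not the claim
that real-data site tallies are convention-free — real pairwise totals
are only reproducible once a counting convention is fixed.

## Problem sizes

The default test and acceptance runs use 16.4 kb genomes, 20 trios for
the recovery suite, 50 pairs of 300 bp for the aligner oracle, and a
33-point p-grid for the distance closed forms; one trio's full pipeline
takes about two seconds, chosen to keep the whole suite comfortably
interactive.

## Known limitations

- The aligner is pairwise-to-reference; true progressive MSA for many
  divergent sequences is out of scope (distances over user-supplied
  alignments are supported instead).
- Mitotype naming beyond exact haplotype identity requires external
  similarity search and is deliberately not implemented.
- The two real-accession checks need the deposited GenBank records
  (`data/real/`); offline they report failure rather than silently
  passing.
- Ambiguity codes other than N are rejected at parse time; genomes with
  IUPAC ambiguity would need pre-cleaning.
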