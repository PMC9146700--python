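"""Banded global pairwise alignment and reference-anchored merging.

Near-identical circular genomes are first rotated to a shared anchor
(:func:`rotate_to_anchor`), then aligned with a banded global
dynamic-programming pass under affine gap scoring
(:func:`global_align`).  The band is centred on the corner-to-corner
diagonal; if the optimal path touches the band edge, the band doubles
automatically up to a cap.  Gap runs are then shifted maximally leftward
while the column multiset is preserved (VCF-style left alignment), which
makes downstream event calling reproducible across scoring dialects.

Pairwise alignments sharing their first (reference) sequence merge into
a single reference-anchored column space (:func:`anchor_merge`):
insertions relative to the reference from different pairs are
interleaved deterministically, in pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitotrio.errors import AnchorError, BandError
from mitotrio.mitio import CircularSeq

NEG = -1e30  # effectively -inf without nan arithmetic


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scores for near-identical mitochondrial DNA.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  The band
    half-width is in columns around the corner-to-corner diagonal; it is
    doubled automatically (up to ``band_cap``) when the optimal path hits
    the band edge.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    band: int = 300
    band_cap: int = 2400


@dataclass
class PairAlignment:
    """Two gapped rows of equal column count; no column is gap/gap."""

    ids: tuple[str, str]
    rows: tuple[str, str]
    score: float

    def __post_init__(self) -> None:
        a, b = self.rows
        if len(a) != len(b):
            raise ValueError("rows differ in column count")
        if any(x == "-" and y == "-" for x, y in zip(a, b)):
            raise ValueError("gap/gap column")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def pos_map(self, i: int) -> np.ndarray:
        """Per-column 1-based sequence position for row ``i`` (0 at gap columns)."""
        row = np.frombuffer(self.rows[i].encode(), dtype=np.uint8)
        isres = row != ord("-")
        out = np.cumsum(isres)
        out[~isres] = 0
        return out

    def col_of(self, i: int, pos: int) -> int:
        """0-based column index holding 1-based position ``pos`` of row ``i``."""
        pm = self.pos_map(i)
        hits = np.nonzero(pm == pos)[0]
        if len(hits) == 0:
            raise ValueError(f"position {pos} not in row {i}")
        return int(hits[0])


# ---------------------------------------------------------------------------
# rotation anchoring


def rotate_to_anchor(
    target: CircularSeq, ref: CircularSeq, k: int = 24, max_trials: int = 64
) -> tuple[CircularSeq, int]:
    """Rotate ``target`` so it starts at the position homologous to ref position 1.

    Seeds with the reference's first ``k``-mer against the doubled target;
    on failure slides to successive reference k-mers, correcting the offset.
    Returns the rotated sequence and the left-rotation offset applied (so
    ``target.rotate(offset)`` reproduces it).
    """
    if not (target.circular and ref.circular):
        raise ValueError("rotation anchoring requires circular sequences")
    n = len(target)
    doubled = target.residues + target.residues
    step = max(1, k // 2)
    for t in range(max_trials):
        off0 = t * step
        if off0 + k > len(ref):
            break
        seed = ref.residues[off0 : off0 + k]
        i = doubled.find(seed)
        if i >= 0:
            offset = (i - off0) % n
            return target.rotate(offset), offset
    raise AnchorError(
        f"no {k}-mer of {ref.id!r} found in {target.id!r} after {max_trials} trials; "
        "sequences too divergent for seeding"
    )


# ---------------------------------------------------------------------------
# banded affine global alignment (Gotoh, row-vectorised)


def _banded_gotoh(a: str, b: str, p: AlignParams, half: int):
    """One banded pass. Returns (score, gapped_a, gapped_b, edge_hit)."""
    m, n = len(a), len(b)
    lo = min(0, n - m) - half
    hi = max(0, n - m) + half
    Wb = hi - lo + 1
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    go, ge = p.gap_open, p.gap_extend

    # traceback codes: 0 from M, 1 from X (vertical), 2 from Y (horizontal)
    tbM = np.zeros((m + 1, Wb), dtype=np.uint8)
    tbX = np.zeros((m + 1, Wb), dtype=np.uint8)
    tbY = np.zeros((m + 1, Wb), dtype=np.uint8)

    M = np.full(Wb, NEG)
    X = np.full(Wb, NEG)
    Y = np.full(Wb, NEG)
    d0 = -lo  # band offset of j=0 at row 0
    M[d0] = 0.0
    # row 0: j >= 1 reachable only through horizontal gaps
    ds = np.arange(Wb)
    j_row0 = lo + ds
    valid0 = (j_row0 >= 1) & (j_row0 <= n)
    Y[valid0] = go + (j_row0[valid0] - 1) * ge
    tbY[0, valid0] = 2
    tbY[0, d0 + 1] = 0  # the first gap column opens from M at the origin

    for i in range(1, m + 1):
        j = i + lo + ds  # sequence-b position at each band offset
        valid = (j >= 0) & (j <= n)
        inb = (j >= 1) & (j <= n)

        # diagonal predecessor sits at the same offset in the previous row
        prev_best = np.maximum(np.maximum(M, X), Y)
        prev_arg = np.where(M >= np.maximum(X, Y), 0, np.where(X >= Y, 1, 2)).astype(np.uint8)
        sub = np.full(Wb, NEG)
        jj = j - 1
        ok = inb
        bj = np.where(ok, np.clip(jj, 0, n - 1), 0)
        sub[ok] = np.where(av[i - 1] == bv[bj[ok]], p.match, p.mismatch)
        Mn = np.where(inb, prev_best + sub, NEG)
        tbM[i] = prev_arg

        # vertical predecessor (i-1, j) sits one offset to the right
        Mu = np.concatenate([M[1:], [NEG]])
        Xu = np.concatenate([X[1:], [NEG]])
        Yu = np.concatenate([Y[1:], [NEG]])
        candM, candX, candY = Mu + go, Xu + ge, Yu + go
        Xn = np.maximum(np.maximum(candM, candX), candY)
        tbX[i] = np.where(candM >= np.maximum(candX, candY), 0,
                          np.where(candX >= candY, 1, 2)).astype(np.uint8)
        Xn = np.where(valid, Xn, NEG)

        # j = 0 boundary cell of this row
        dj0 = -(i + lo)
        if 0 <= dj0 < Wb:
            Mn[dj0] = NEG
            Xn[dj0] = go + (i - 1) * ge
            tbX[i, dj0] = 0 if i == 1 else 1

        # horizontal gaps extend within the row: Y[d] = max(Z[d-1], Y[d-1] + ge)
        # with Z = max(M, X) + go.  The sequential recurrence collapses to a
        # running max of W[k] = Z[k] - k*ge, so the whole row vectorises.
        Z = np.maximum(Mn, Xn) + go
        accW = np.maximum.accumulate(Z - ds * ge)
        Yn = np.full(Wb, NEG)
        tby = np.zeros(Wb, dtype=np.uint8)
        if Wb > 1:
            Yseq = accW[:-1] + (ds[1:] - 1) * ge
            Yn[1:] = Yseq
            opened = Z[:-1] >= np.concatenate([[NEG], Yseq[:-1]]) + ge
            tby[1:] = np.where(
                opened, np.where(Mn[:-1] >= Xn[:-1], 0, 1), 2
            ).astype(np.uint8)
        Yn = np.where(inb, Yn, NEG)
        tbY[i] = tby

        M, X, Y = Mn, Xn, Yn

    df = n - m - lo
    if not (0 <= df < Wb):
        raise BandError("final cell outside band")
    finals = np.array([M[df], X[df], Y[df]])
    state = int(np.argmax(finals))
    score = float(finals[state])

    # traceback
    i, d = m, df
    cols_a: list[str] = []
    cols_b: list[str] = []
    edge_hit = False
    while True:
        j = i + lo + d
        if (j - i == lo or j - i == hi) and not (i == 0 and j == 0) and not (i == m and j == n):
            edge_hit = True
        if i == 0 and j == 0:
            break
        if state == 0:  # M: consumed a_i and b_j
            prev = int(tbM[i, d])
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i -= 1
            state = prev
        elif state == 1:  # X: consumed a_i against a gap; predecessor (i-1, j)
            prev = int(tbX[i, d])
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            d += 1
            state = prev
        else:  # Y: consumed b_j against a gap; predecessor (i, j-1)
            prev = int(tbY[i, d])
            cols_a.append("-")
            cols_b.append(b[j - 1])
            d -= 1
            state = prev
    ga = "".join(reversed(cols_a))
    gb = "".join(reversed(cols_b))
    return score, ga, gb, edge_hit


def global_align(
    a: str | CircularSeq,
    b: str | CircularSeq,
    params: AlignParams | None = None,
    ids: tuple[str, str] | None = None,
) -> PairAlignment:
    """Optimal banded global alignment with affine gaps, left-normalised.

    The band half-width starts at ``params.band`` and doubles automatically
    whenever the optimal path touches the band edge, up to ``params.band_cap``;
    exhaustion raises :class:`BandError`.
    """
    p = params or AlignParams()
    ida, sa = (a.id, a.residues) if isinstance(a, CircularSeq) else ("a", a)
    idb, sb = (b.id, b.residues) if isinstance(b, CircularSeq) else ("b", b)
    if ids is not None:
        ida, idb = ids
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    half = p.band
    while True:
        score, ga, gb, edge = _banded_gotoh(sa, sb, p, half)
        if not edge:
            break
        if half >= p.band_cap:
            raise BandError(
                f"optimal path still touches the band edge at half-width {half}"
            )
        half = min(2 * half, p.band_cap)
    ga, gb = left_normalize(ga, gb)
    aln = PairAlignment((ida, idb), (ga, gb), score)
    assert aln.ungapped(0) == sa and aln.ungapped(1) == sb
    return aln


def left_normalize(ra: str, rb: str) -> tuple[str, str]:
    """Shift every gap run maximally leftward while column identity is preserved.

    A gap run in one row may absorb the residue to its left whenever the other
    row carries the same residue at both swap columns, so the multiset of
    columns — and hence the alignment score — is unchanged.  This pins indels
    in homopolymers and AT microsatellites to a canonical (leftmost) placement.
    """
    A, B = list(ra), list(rb)

    def shift(R: list[str], Q: list[str]) -> bool:
        moved = False
        i = 0
        ncol = len(R)
        while i < ncol:
            if R[i] != "-":
                i += 1
                continue
            s = i
            e = i
            while e + 1 < ncol and R[e + 1] == "-":
                e += 1
            while s > 0 and R[s - 1] != "-" and Q[s - 1] == Q[e]:
                R[e] = R[s - 1]
                R[s - 1] = "-"
                s -= 1
                e -= 1
                moved = True
            i = e + 1 if e >= i else i + 1
        return moved

    while shift(A, B) | shift(B, A):
        pass
    return "".join(A), "".join(B)


# ---------------------------------------------------------------------------
# reference-anchored multiple alignment


@dataclass
class AnchoredMSA:
    """Gapped rows in one column space induced by the reference row."""

    ref_id: str
    ids: tuple[str, ...]  # reference first
    rows: tuple[str, ...]
    _pos_maps: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows differ in column count")
        if self.ids[0] != self.ref_id:
            raise ValueError("reference row must come first")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def pos_map(self, i: int) -> np.ndarray:
        if i not in self._pos_maps:
            row = np.frombuffer(self.rows[i].encode(), dtype=np.uint8)
            isres = row != ord("-")
            out = np.cumsum(isres)
            out[~isres] = 0
            self._pos_maps[i] = out
        return self._pos_maps[i]

    def col_of(self, i: int, pos: int) -> int:
        hits = np.nonzero(self.pos_map(i) == pos)[0]
        if len(hits) == 0:
            raise ValueError(f"position {pos} not in row {i}")
        return int(hits[0])

    def column(self, c: int) -> tuple[str, ...]:
        return tuple(r[c] for r in self.rows)


def anchor_merge(pairs: list[PairAlignment]) -> AnchoredMSA:
    """Merge pairwise alignments sharing their first (reference) row.

    The merged column space holds every reference position plus, between
    consecutive reference positions, one sub-slot per pair for that pair's
    insertions — interleaved deterministically in pair order.  Ungapping any
    row recovers its input sequence exactly.
    """
    if not pairs:
        raise ValueError("no alignments to merge")
    ref = pairs[0].ungapped(0)
    ref_id = pairs[0].ids[0]
    for p in pairs:
        if p.ungapped(0) != ref or p.ids[0] != ref_id:
            raise ValueError("pairwise alignments disagree on the reference")
    R = len(ref)
    npairs = len(pairs)

    # insertions[p][r] = residues of pair p's second row inserted after ref pos r
    insertions: list[list[str]] = []
    ref_col_char: list[list[str]] = []  # pair p's second-row char at each ref position
    for p in pairs:
        ins = [""] * (R + 1)
        at_ref = [""] * R
        r = 0
        for ca, cb in zip(p.rows[0], p.rows[1]):
            if ca == "-":
                ins[r] += cb
            else:
                at_ref[r] = cb
                r += 1
        insertions.append(ins)
        ref_col_char.append(at_ref)

    out_rows = [[] for _ in range(npairs + 1)]  # reference + one row per pair
    for r in range(R + 1):
        # identical insertion segments from different pairs share one column
        # block (a deletion in the reference looks the same from every pair);
        # distinct segments are interleaved in pair order
        seen: list[tuple[str, list[int]]] = []
        for pi in range(npairs):
            seg = insertions[pi][r]
            if not seg:
                continue
            for s, carriers in seen:
                if s == seg:
                    carriers.append(pi)
                    break
            else:
                seen.append((seg, [pi]))
        for seg, carriers in seen:
            out_rows[0].append("-" * len(seg))
            for qi in range(npairs):
                out_rows[qi + 1].append(seg if qi in carriers else "-" * len(seg))
        if r < R:
            out_rows[0].append(ref[r])
            for pi in range(npairs):
                out_rows[pi + 1].append(ref_col_char[pi][r])

    rows = tuple("".join(parts) for parts in out_rows)
    ids = (ref_id,) + tuple(p.ids[1] for p in pairs)
    msa = AnchoredMSA(ref_id, ids, rows)
    for pi, p in enumerate(pairs):
        assert msa.ungapped(pi + 1) == p.ungapped(1)
    return msa


def msa_from_pair(p: PairAlignment) -> AnchoredMSA:
    """View a single pairwise alignment as a two-row anchored MSA."""
    return AnchoredMSA(p.ids[0], p.ids, p.rows)


def write_gapped_fasta(msa: AnchoredMSA | PairAlignment, path, width: int = 70) -> None:
    """Export alignment rows as gapped FASTA."""
    own = isinstance(path, str) or hasattr(path, "__fspath__")
    fh = open(path, "w") if own else path
    try:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


__all__ = [
    "AlignParams", "AnchoredMSA", "PairAlignment", "anchor_merge", "global_align",
    "left_normalize", "msa_from_pair", "rotate_to_anchor", "write_gapped_fasta",
]
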