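"""Pairwise evolutionary distances and ABGD group delimitation.

Distances are computed on alignment rows under pairwise deletion
(columns gapped or ambiguous in either row of a pair are dropped for
that pair).  Available models: raw proportion (p), Jukes–Cantor and
Kimura two-parameter, each with optional gamma rate variation across
sites (shape α; α = ∞ recovers the ungamma'd closed forms):

* JC, gamma:   d = (3α/4)·[(1 − 4p/3)^(−1/α) − 1]
* JC, plain:   d = −(3/4)·ln(1 − 4p/3)
* K80, gamma:  d = (α/2)·[(1−2P−Q)^(−1/α) − 1] + (α/4)·[(1−2Q)^(−1/α) − 1]
* K80, plain:  d = −(1/2)·ln(1−2P−Q) − (1/4)·ln(1−2Q)

with p the mismatch proportion, P/Q the transition/transversion
proportions.

Automatic Barcode Gap Discovery (ABGD) partitions samples at the gap
between intra- and inter-group pairwise distances: ranked distances are
scanned for the first significant gap above the prior maximal
intraspecific divergence P; pairs below the gap define a graph whose
connected components are the groups, and the procedure recurses within
groups.  A gap between consecutive ranked distances d_i < d_{i+1} is
significant when d_{i+1} exceeds the prior and the gap width exceeds
``rel_gap_width`` times max(d_i, P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mitotrio.align import AnchoredMSA
from mitotrio.errors import SaturationError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class DistanceParams:
    model: str = "JC"  # p | JC | K80
    gamma_shape: float = 1.0  # α; math.inf disables gamma correction
    deletion: str = "pairwise"  # pairwise | complete

    def __post_init__(self) -> None:
        if self.model not in ("p", "JC", "K80"):
            raise ValueError(f"unknown model {self.model!r}")
        if not self.gamma_shape > 0:
            raise ValueError("gamma shape must be positive")
        if self.deletion not in ("pairwise", "complete"):
            raise ValueError(f"unknown deletion mode {self.deletion!r}")


def _gamma_transform(x: float, alpha: float) -> float:
    """Gamma-rate analogue of −ln(x): α·(x^(−1/α) − 1); the α→∞ limit is −ln x."""
    if x <= 0:
        raise SaturationError("distance undefined: observed divergence saturated")
    if math.isinf(alpha):
        return -math.log(x)
    # expm1 keeps precision at large alpha, where x^(-1/alpha) approaches 1
    return alpha * math.expm1(-math.log(x) / alpha)


def pairwise_distance(a: str, b: str, params: DistanceParams | None = None) -> float:
    """Model-corrected distance between two gapped aligned rows.

    Pairwise deletion drops every column gapped or 'N' in either row.  Raises
    :class:`SaturationError` when the correction is undefined (e.g. p ≥ 3/4
    under Jukes–Cantor).
    """
    params = params or DistanceParams()
    if len(a) != len(b):
        raise ValueError("rows differ in column count")
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    bad = np.isin(av, np.frombuffer(b"-N", dtype=np.uint8)) | np.isin(
        bv, np.frombuffer(b"-N", dtype=np.uint8)
    )
    av, bv = av[~bad], bv[~bad]
    n = len(av)
    if n == 0:
        raise ValueError("no jointly resolved columns")
    alpha = params.gamma_shape
    diff = av != bv
    p = float(np.mean(diff))
    if params.model == "p":
        return p
    if params.model == "JC":
        return 0.75 * _gamma_transform(1.0 - 4.0 * p / 3.0, alpha)
    # K80: split mismatches into transitions and transversions
    ts = 0
    for x, y in ((b"A", b"G"), (b"C", b"T")):
        xo, yo = x[0], y[0]
        ts += int(np.sum(((av == xo) & (bv == yo)) | ((av == yo) & (bv == xo))))
    P = ts / n
    Q = p - P
    return 0.5 * _gamma_transform(1.0 - 2.0 * P - Q, alpha) + 0.25 * _gamma_transform(
        1.0 - 2.0 * Q, alpha
    )


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise ValueError("negative distances")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.matrix[i, j])

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab + "  " + "  ".join(f"{x:.8f}" for x in row))
        return "\n".join(lines) + "\n"

    def to_long_tsv(self) -> str:
        lines = ["a\tb\tdistance"]
        for i, la in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                lines.append(f"{la}\t{self.labels[j]}\t{self.matrix[i, j]:.8f}")
        return "\n".join(lines) + "\n"


def distance_matrix(
    msa: AnchoredMSA | tuple[tuple[str, str], ...],
    params: DistanceParams | None = None,
) -> DistanceMatrix:
    """All pairwise distances over an alignment's rows.

    Accepts an :class:`AnchoredMSA` or a sequence of (label, gapped row)
    pairs.  Under complete deletion, columns gapped in any row are removed
    once for all pairs.
    """
    params = params or DistanceParams()
    if isinstance(msa, AnchoredMSA):
        items = list(zip(msa.ids, msa.rows))
    else:
        items = list(msa)
    labels = tuple(lab for lab, _ in items)
    rows = [r.upper() for _, r in items]
    if params.deletion == "complete":
        keep = [
            all(r[c] not in "-N" for r in rows) for c in range(len(rows[0]))
        ]
        rows = ["".join(r[c] for c in range(len(r)) if keep[c]) for r in rows]
    k = len(rows)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = pairwise_distance(rows[i], rows[j], params)
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# ABGD


@dataclass(frozen=True)
class AbgdParams:
    prior: float = 1.0e-3  # prior maximal intraspecific distance P
    rel_gap_width: float = 1.5  # X: required gap width relative to max(d_i, P)
    min_group: int = 3  # recursion stops inside groups smaller than this

    def __post_init__(self) -> None:
        if not (self.prior > 0 and self.rel_gap_width > 0):
            raise ValueError("prior and relative gap width must be positive")


@dataclass
class Partition:
    groups: dict[str, int]  # label -> group id (0-based, ordered by first member)
    n_groups: int
    gap_thresholds: list[float] = field(default_factory=list)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, gid in self.groups.items():
            out.setdefault(gid, []).append(lab)
        return out

    def to_tsv(self) -> str:
        lines = ["label\tgroup"]
        for lab, gid in self.groups.items():
            lines.append(f"{lab}\t{gid}")
        return "\n".join(lines) + "\n"


def _first_gap(dists: np.ndarray, params: AbgdParams) -> float | None:
    """Split threshold below the first significant gap, or None."""
    vals = np.unique(dists)
    for i in range(len(vals) - 1):
        lo, hi = float(vals[i]), float(vals[i + 1])
        if hi <= params.prior:
            continue
        if hi - lo > params.rel_gap_width * max(lo, params.prior):
            return lo
    return None


def abgd_partition(D: DistanceMatrix, params: AbgdParams | None = None) -> Partition:
    """Recursive barcode-gap partitioning of a distance matrix.

    Deterministic and invariant to label order.  When no significant gap
    exists anywhere, all samples form a single group.
    """
    params = params or AbgdParams()
    n = len(D.labels)
    if n < 2:
        return Partition({lab: 0 for lab in D.labels}, n_groups=max(1, n))
    order = np.argsort(D.labels)  # canonical processing order
    thresholds: list[float] = []

    def split(idx: list[int]) -> list[list[int]]:
        if len(idx) < 2:
            return [idx]
        sub = D.matrix[np.ix_(idx, idx)]
        tri = sub[np.triu_indices(len(idx), k=1)]
        thr = _first_gap(tri, params)
        if thr is None:
            return [idx]
        thresholds.append(thr)
        # connected components of the below-gap graph (union-find)
        parent = list(range(len(idx)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if sub[i, j] <= thr and find(i) != find(j):
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(len(idx)):
            comps.setdefault(find(i), []).append(idx[i])
        parts = sorted(comps.values(), key=lambda c: min(c))
        if len(parts) == 1:
            return parts
        out: list[list[int]] = []
        for part in parts:
            if len(part) >= params.min_group:
                out.extend(split(part))
            else:
                out.append(part)
        return out

    groups_idx = split([int(i) for i in order])
    # stable group numbering by each group's first label
    groups_idx.sort(key=lambda g: D.labels[min(g, key=lambda i: D.labels[i])])
    mapping: dict[str, int] = {}
    for gid, members in enumerate(groups_idx):
        for i in members:
            mapping[D.labels[i]] = gid
    mapping = {lab: mapping[lab] for lab in D.labels}
    return Partition(mapping, len(groups_idx), thresholds)


def distance_histogram(D: DistanceMatrix, path, bins: int = 40) -> None:
    """Diagnostic histogram of ranked pairwise distances (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tri = D.matrix[np.triu_indices(len(D.labels), k=1)]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(tri, bins=bins, color="#46658a")
    ax.set_xlabel("pairwise distance")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "AbgdParams", "DistanceMatrix", "DistanceParams", "Partition", "abgd_partition",
    "distance_histogram", "distance_matrix", "pairwise_distance",
]
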