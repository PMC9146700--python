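"""Distance models (closed forms, gamma limits) and ABGD partitioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotrio.errors import SaturationError
from mitotrio.popstruct import (
    AbgdParams,
    DistanceMatrix,
    DistanceParams,
    abgd_partition,
    distance_matrix,
    pairwise_distance,
)


def _rows_with_p(n: int, k: int) -> tuple[str, str]:
    """Two rows of n jointly resolved columns with exactly k mismatches."""
    a = "A" * n
    b = "C" * k + "A" * (n - k)
    return a, b


class TestPairwiseDistance:
    @pytest.mark.parametrize("model", ["p", "JC", "K80"])
    def test_identical_rows_distance_zero(self, model):
        d = pairwise_distance("ACGT" * 50, "ACGT" * 50, DistanceParams(model=model))
        assert d == 0.0

    def test_jc_gamma_alpha_one_closed_form(self):
        """At alpha = 1 the JC-gamma correction reduces to p / (1 - 4p/3)."""
        n = 3000
        for k in range(0, int(0.5 * n), 37):
            a, b = _rows_with_p(n, k)
            p = k / n
            d = pairwise_distance(a, b, DistanceParams("JC", gamma_shape=1.0))
            assert d == pytest.approx(p / (1 - 4 * p / 3), abs=1e-12)

    def test_jc_gamma_limit_matches_plain_jc(self):
        """The finite-shape error decays as ln²(1-4p/3)·3/(8α)."""
        n = 3000
        plain = DistanceParams("JC", gamma_shape=math.inf)
        for k in (30, 150, 450, 600):  # p up to 0.2
            a, b = _rows_with_p(n, k)
            p = k / n
            d_inf = pairwise_distance(a, b, plain)
            assert d_inf == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-12)
            assert pairwise_distance(a, b, DistanceParams("JC", 1e8)) == pytest.approx(
                d_inf, abs=1e-9)
            assert pairwise_distance(a, b, DistanceParams("JC", 1e6)) == pytest.approx(
                d_inf, abs=1e-7)

    def test_jc_gamma_monotone_in_p_and_inverse_alpha(self):
        n = 1000
        ds = [pairwise_distance(*_rows_with_p(n, k), DistanceParams("JC", 1.0))
              for k in range(0, 500, 25)]
        assert all(x < y for x, y in zip(ds, ds[1:]))
        a, b = _rows_with_p(n, 200)
        by_alpha = [pairwise_distance(a, b, DistanceParams("JC", alpha))
                    for alpha in (0.25, 0.5, 1.0, 2.0, math.inf)]
        assert all(x > y for x, y in zip(by_alpha, by_alpha[1:]))

    def test_k80_plain_closed_form(self):
        # 2000 columns: 40 transitions (A<->G), 20 transversions (A<->C)
        a = "A" * 2000
        b = "G" * 40 + "C" * 20 + "A" * 1940
        P, Q = 0.02, 0.01
        want = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        got = pairwise_distance(a, b, DistanceParams("K80", math.inf))
        assert got == pytest.approx(want, abs=1e-12)
        # with only transversion-free divergence K80 exceeds JC slightly
        assert got > pairwise_distance(a, b, DistanceParams("JC", math.inf)) - 1e-9

    def test_pairwise_deletion_drops_gapped_columns(self):
        a = "AC-TA-GN"
        b = "ACGT-AGT"
        # jointly resolved columns: A/A, C/C, T? col3 T/T, col6 G/G -> plus none mismatched
        d = pairwise_distance(a, b, DistanceParams("p"))
        assert d == 0.0

    def test_saturation_raises(self):
        a, b = _rows_with_p(100, 80)
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, DistanceParams("JC", 1.0))

    @given(st.integers(min_value=0, max_value=400), st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_column_permutation_invariance(self, k, seed):
        n = 800
        a, b = _rows_with_p(n, k)
        params = DistanceParams("JC", 1.0)
        assert pairwise_distance(a, b, params) == pairwise_distance(b, a, params)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        ap = "".join(a[i] for i in perm)
        bp = "".join(b[i] for i in perm)
        assert pairwise_distance(ap, bp, params) == pairwise_distance(a, b, params)


class TestDistanceMatrix:
    def test_matrix_from_trio_msa(self, analysis):
        D = analysis.distances
        assert np.allclose(D.matrix, D.matrix.T)
        assert np.allclose(np.diag(D.matrix), 0)
        assert (D.matrix[np.triu_indices(3, k=1)] > 0).all()

    def test_phylip_and_long_form_render(self, analysis):
        phy = analysis.distances.to_phylip()
        assert phy.splitlines()[0] == "3"
        assert len(analysis.distances.to_long_tsv().splitlines()) == 4

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


def _cluster_matrix(sizes, within, between, labels=None):
    n = sum(sizes)
    m = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        m[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(m, 0.0)
    labels = labels or tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(tuple(labels), m)


class TestAbgd:
    def test_two_well_separated_clusters(self):
        D = _cluster_matrix([4, 4], within=0.001, between=0.02)
        part = abgd_partition(D, AbgdParams(prior=1e-3))
        assert part.n_groups == 2
        members = part.members()
        assert sorted(map(len, members.values())) == [4, 4]

    def test_uniform_distances_single_group(self):
        D = _cluster_matrix([6], within=0.004, between=0.004)
        assert abgd_partition(D, AbgdParams(prior=1e-3)).n_groups == 1

    def test_label_order_invariance(self):
        rng = np.random.default_rng(0)
        D = _cluster_matrix([4, 3, 5], within=0.0008, between=0.03)
        part = abgd_partition(D)
        perm = rng.permutation(len(D.labels))
        D2 = DistanceMatrix(tuple(D.labels[i] for i in perm),
                            D.matrix[np.ix_(perm, perm)])
        part2 = abgd_partition(D2)
        group_sets = lambda p: {frozenset(m) for m in p.members().values()}
        assert group_sets(part) == group_sets(part2)

    def test_three_clusters_recursive_split(self):
        D = _cluster_matrix([4, 4, 4], within=0.0005, between=0.04)
        assert abgd_partition(D).n_groups == 3

    def test_raising_prior_coarsens_partition(self):
        D = _cluster_matrix([4, 4], within=0.004, between=0.012)
        fine = abgd_partition(D, AbgdParams(prior=1e-3, rel_gap_width=1.2))
        coarse = abgd_partition(D, AbgdParams(prior=2e-2, rel_gap_width=1.2))
        assert coarse.n_groups <= fine.n_groups
        assert coarse.n_groups == 1

    def test_trio_within_subspecies_forms_one_group(self, analysis):
        assert analysis.partition.n_groups == 1
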