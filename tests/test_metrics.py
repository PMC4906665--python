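"""Network-level metrics against independent brute-force oracles.

Each oracle below re-derives the metric from its definition with plain
loops, independently of the vectorized implementations.
"""

import math

import numpy as np
import pytest

from tempoweb import (
    connectance,
    core_periphery,
    interaction_strength_asymmetry,
    metrics_table,
    network_size,
    niche_overlap,
    nodf,
    specialization_h2,
)
from tempoweb.errors import UndefinedMetricError
from tempoweb.io_model import TemporalNetworkSeries
from tempoweb.metrics import metrics_row

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# oracles

def brute_nodf(B):
    B = (np.asarray(B) > 0).astype(int)
    P, A = B.shape
    total = 0.0
    for M in (B, B.T):
        n = M.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                mt_i, mt_j = M[i].sum(), M[j].sum()
                if mt_i > mt_j > 0:
                    shared = int(np.logical_and(M[i], M[j]).sum())
                    total += shared / mt_j
    # each unordered decreasing pair appears exactly once in the double loop
    # (the strict inequality holds for only one ordering)
    return 100.0 * total / (P * (P - 1) / 2 + A * (A - 1) / 2)


def brute_h2(w):
    w = np.asarray(w, dtype=float)
    m = w.sum()

    def ent(masses, tot):
        return -sum((x / tot) * math.log(x / tot) for x in masses if x > 0)

    h2 = ent(w.ravel(), m)
    r, c = w.sum(1), w.sum(0)
    h2max = ent([ri * cj for ri in r for cj in c], m * m)
    # greedy packing, re-derived with explicit lists
    rr, cc = list(r), list(c)
    packed = []
    while max(rr) > 1e-12 and max(cc) > 1e-12:
        i = rr.index(max(rr))
        j = cc.index(max(cc))
        x = min(rr[i], cc[j])
        packed.append(x)
        rr[i] -= x
        cc[j] -= x
    h2min = ent(packed, m)
    if h2max - h2min <= 1e-12:
        return 0.0
    return min(1.0, max(0.0, (h2max - h2) / (h2max - h2min)))


def brute_isa(w):
    w = np.asarray(w, dtype=float)
    vals = []
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if w[i, j] > 0:
                da = w[i, j] / w[:, j].sum()
                dp = w[i, j] / w[i, :].sum()
                vals.append((da - dp) / max(da, dp))
    return float(np.mean(vals))


def brute_horn_mean(w, level="birds"):
    w = np.asarray(w, dtype=float)
    profs = w.T if level == "birds" else w
    out = []
    for i in range(len(profs)):
        for j in range(i + 1, len(profs)):
            x = profs[i] / profs[i].sum()
            y = profs[j] / profs[j].sum()
            num = 0.0
            for xk, yk in zip(x, y):
                if xk + yk > 0:
                    num += (xk + yk) * math.log(xk + yk)
                if xk > 0:
                    num -= xk * math.log(xk)
                if yk > 0:
                    num -= yk * math.log(yk)
            out.append(num / (2 * math.log(2)))
    return float(np.mean(out))


# ---------------------------------------------------------------------------

class TestSizeConnectance:
    def test_examples(self):
        assert network_size(make_matrix(np.ones((3, 4)))) == 7
        assert network_size(make_matrix([[1.0]])) == 2
        assert connectance(make_matrix(np.ones((2, 2)))) == 1.0
        assert connectance(make_matrix([[1, 1], [0, 1]])) == 0.75

    def test_random_against_brute(self, rng):
        for _ in range(20):
            m = random_matrix(rng)
            assert network_size(m) == m.weights.shape[0] + m.weights.shape[1]
            assert connectance(m) == pytest.approx(
                sum(v > 0 for v in m.weights.ravel()) / m.weights.size
            )


class TestNODF:
    def test_perfect_staircase_is_100(self):
        stair = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
        assert nodf(make_matrix(stair)) == pytest.approx(100.0)

    def test_checkerboard_is_0(self):
        assert nodf(make_matrix([[1, 0], [0, 1]])) == pytest.approx(0.0)

    def test_equal_fill_pairs_contribute_zero(self):
        # all rows and columns with identical totals: no decreasing pairs
        assert nodf(make_matrix(np.ones((3, 3)))) == pytest.approx(0.0)

    def test_undefined_for_singleton(self):
        with pytest.raises(UndefinedMetricError):
            nodf(make_matrix([[1.0]]))

    def test_oracle_equivalence_random(self, rng):
        for _ in range(60):
            m = random_matrix(rng, fill=rng.uniform(0.2, 0.9))
            assert nodf(m) == pytest.approx(brute_nodf(m.weights), abs=1e-12)

    def test_matches_vegan_reference_values(self):
        """Frozen oracle: NODF of five seeded random 6x7 binary matrices,
        computed independently with R's vegan::nestednodf (order=TRUE)."""
        expected = [
            46.0648148148,
            69.8148148148,
            37.9629629630,
            52.7777777778,
            40.2777777778,
        ]
        gen = np.random.default_rng(7)
        for want in expected:
            B = (gen.random((6, 7)) < 0.5).astype(float)
            while B.sum(1).min() == 0 or B.sum(0).min() == 0:
                B = (gen.random((6, 7)) < 0.5).astype(float)
            assert nodf(make_matrix(B)) == pytest.approx(want, abs=1e-9)

    def test_permutation_invariance(self, rng):
        m = random_matrix(rng, 6, 7)
        ref = nodf(m)
        for _ in range(5):
            pi, bi = rng.permutation(6), rng.permutation(7)
            assert nodf(make_matrix(m.weights[np.ix_(pi, bi)])) == pytest.approx(ref)

    def test_scale_invariance(self, rng):
        m = random_matrix(rng, 5, 5)
        assert nodf(make_matrix(3.7 * m.weights)) == pytest.approx(nodf(m))


class TestH2:
    def test_perfect_specialization(self):
        assert specialization_h2(make_matrix([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_no_specialization_at_marginal_expectation(self):
        assert specialization_h2(make_matrix([[1, 1], [1, 1]])) == pytest.approx(0.0)

    def test_bounds_and_oracle(self, rng):
        for _ in range(40):
            m = random_matrix(rng, fill=rng.uniform(0.3, 1.0))
            got = specialization_h2(m)
            assert 0.0 <= got <= 1.0
            assert got == pytest.approx(brute_h2(m.weights), abs=1e-10)

    def test_scale_invariance(self, rng):
        m = random_matrix(rng, 5, 6)
        assert specialization_h2(make_matrix(2.5 * m.weights)) == pytest.approx(
            specialization_h2(m)
        )


class TestISA:
    def test_one_by_one_is_zero(self):
        assert interaction_strength_asymmetry(make_matrix([[4.0]])) == 0.0

    def test_transpose_negates(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 5, 5)
            mt = make_matrix(m.weights.T)
            assert interaction_strength_asymmetry(mt) == pytest.approx(
                -interaction_strength_asymmetry(m)
            )

    def test_oracle_equivalence(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 5, 5, fill=0.6)
            assert interaction_strength_asymmetry(m) == pytest.approx(
                brute_isa(m.weights)
            )

    def test_absolute_variant_non_negative(self, rng):
        m = random_matrix(rng, 4, 4)
        assert interaction_strength_asymmetry(m, signed=False) >= 0


class TestNicheOverlap:
    def test_identical_profiles_full_overlap(self):
        m = make_matrix([[2, 4], [1, 2]])  # birds proportional: overlap 1
        assert niche_overlap(m) == pytest.approx(1.0)

    def test_disjoint_profiles_zero(self):
        assert niche_overlap(make_matrix([[1, 0], [0, 1]])) == pytest.approx(0.0)

    def test_needs_two_species(self):
        with pytest.raises(UndefinedMetricError):
            niche_overlap(make_matrix([[1.0], [1.0]]), level="birds")

    def test_oracle_equivalence_both_levels(self, rng):
        for level in ("birds", "plants"):
            for _ in range(10):
                m = random_matrix(rng, 4, 4, fill=0.7)
                assert niche_overlap(m, level=level) == pytest.approx(
                    brute_horn_mean(m.weights, level)
                )


class TestCorePeriphery:
    def test_hand_computed_degrees(self):
        # bird degrees 5,1,1,1: mean 2, sample sd 2 -> Gc 1.5,-0.5,-0.5,-0.5
        w = np.zeros((5, 4))
        w[:, 0] = 1
        w[0, 1:] = 1
        res = core_periphery(make_matrix(w))
        assert res.degrees.tolist() == [5, 1, 1, 1]
        assert res.gc == pytest.approx([1.5, -0.5, -0.5, -0.5])
        assert res.core_species() == {"b0"}

    def test_equal_degrees_degenerate(self):
        res = core_periphery(make_matrix(np.ones((3, 3))))
        assert res.degenerate and res.core_species() == set()

    def test_standardization_identities(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 6, 6)
            res = core_periphery(m)
            if not res.degenerate:
                assert res.gc.mean() == pytest.approx(0.0, abs=1e-12)
                assert res.gc.std(ddof=1) == pytest.approx(1.0)

    def test_single_bird_undefined(self):
        with pytest.raises(UndefinedMetricError):
            core_periphery(make_matrix([[1.0], [2.0]]))


class TestMetricsTable:
    def test_one_row_per_period(self, paper_series):
        series, _, _ = paper_series
        table = metrics_table(series)
        assert len(table) == len(series)
        assert table["period"].tolist() == series.period_labels

    def test_degenerate_period_gets_missing_not_zero(self):
        series = TemporalNetworkSeries(matrices=[make_matrix([[1.0]], period="tiny")])
        table = metrics_table(series)
        row = table.iloc[0]
        assert np.isnan(row["nodf"]) and np.isnan(row["niche_overlap"])
        assert row["size"] == 2

    def test_cells_match_single_matrix_calls(self, paper_series):
        series, _, _ = paper_series
        table = metrics_table(series).set_index("period")
        m = series.matrices[3]
        assert table.loc[m.period_label, "nodf"] == pytest.approx(nodf(m))
        assert table.loc[m.period_label, "h2"] == pytest.approx(specialization_h2(m))
        assert table.loc[m.period_label, "isa"] == pytest.approx(
            interaction_strength_asymmetry(m)
        )
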