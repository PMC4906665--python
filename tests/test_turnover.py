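"""Composition matrices, Bray-Curtis and PERMANOVA, with external oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc

from tempoweb import (
    bray_curtis,
    composition_matrix,
    core_periphery,
    default_grouping,
    dissimilarity_matrix,
    permanova,
    turnover_analysis,
)
from tempoweb.errors import InvalidDataError, UndefinedMetricError
from tempoweb.turnover import HIGH_MIGRATION_PERIODS, LOW_MIGRATION_PERIODS, _pseudo_f

from conftest import make_matrix


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_formula_and_scipy_agree(self, rng):
        for _ in range(30):
            x = rng.integers(0, 10, 6).astype(float)
            y = rng.integers(0, 10, 6).astype(float)
            if x.sum() + y.sum() == 0:
                continue
            direct = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
            assert bray_curtis(x, y) == pytest.approx(direct)
            assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y))

    def test_binary_equals_sorensen(self, rng):
        for _ in range(20):
            x = (rng.random(8) < 0.5).astype(float)
            y = (rng.random(8) < 0.5).astype(float)
            a = np.logical_and(x, y).sum()
            b = np.logical_and(x, 1 - y).sum()
            c = np.logical_and(1 - x, y).sum()
            if 2 * a + b + c == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(1 - 2 * a / (2 * a + b + c))

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            bray_curtis([0, 0], [0, 0])


class TestCompositionMatrix:
    def _series(self):
        # period A: bird degrees 5,1,1,1 (core = b0); period B: degrees 1,1,1,5 (core = b3)
        wA = np.zeros((5, 4))
        wA[:, 0] = 1
        wA[0, 1:] = 1
        wB = wA[:, ::-1].copy()
        from tempoweb.io_model import TemporalNetworkSeries

        return TemporalNetworkSeries(
            matrices=[make_matrix(wA, period="A"), make_matrix(wB, period="B")]
        )

    def test_membership_by_period(self):
        series = self._series()
        comp = composition_matrix(series, stratum="core")
        assert comp.species == ["b0", "b3"]
        assert comp.presence.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_species_can_switch_strata(self):
        series = self._series()
        core = composition_matrix(series, stratum="core")
        peri = composition_matrix(series, stratum="periphery")
        assert "b0" in core.species and "b0" in peri.species

    def test_identical_cores_identical_rows(self):
        from tempoweb.io_model import TemporalNetworkSeries

        wA = np.zeros((5, 4))
        wA[:, 0] = 1
        wA[0, 1:] = 1
        series = TemporalNetworkSeries(
            matrices=[make_matrix(wA, period="A"), make_matrix(wA, period="B")]
        )
        comp = composition_matrix(series, stratum="core")
        assert (comp.presence[0] == comp.presence[1]).all()

    def test_matches_brute_set_construction(self, paper_series):
        series, _, _ = paper_series
        cp = [core_periphery(m) for m in series.matrices]
        comp = composition_matrix(series, cp, "periphery")
        for i, res in enumerate(cp):
            got = {s for s, v in zip(comp.species, comp.presence[i]) if v > 0}
            assert got == res.periphery_species()

    def test_empty_stratum_warns_and_keeps_row(self):
        from tempoweb.io_model import TemporalNetworkSeries

        series = TemporalNetworkSeries(
            matrices=[make_matrix(np.ones((3, 3)), period="flat")]
        )
        with pytest.warns(UserWarning, match="no core species"):
            comp = composition_matrix(series, stratum="core")
        assert comp.presence.shape[0] == 1 and comp.presence.sum() == 0


class TestPermanova:
    def _toy(self, rng, n=12, sep=0.0):
        pts = rng.normal(size=(n, 3))
        pts[n // 2 :] += sep
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = ["g1"] * (n // 2) + ["g2"] * (n - n // 2)
        return D, labels

    def test_maximal_separation(self):
        # fully disjoint groups: between-group d = 1, within-group d ~ 0.
        # p can only tie on relabelings that reproduce the partition, so at
        # n = 12 it sits at (or just above) the 1/(permutations+1) floor.
        n = 12
        D = np.ones((n, n)) - np.eye(n)
        D[: n // 2, : n // 2] *= 0.1
        D[n // 2 :, n // 2 :] *= 0.1
        np.fill_diagonal(D, 0)
        res = permanova(D, ["a"] * (n // 2) + ["b"] * (n // 2), permutations=99, seed=0)
        assert res.p_value <= 0.05
        assert res.pseudo_f > 50

    def test_determinism_and_p_range(self, rng):
        D, labels = self._toy(rng)
        a = permanova(D, labels, permutations=199, seed=5)
        b = permanova(D, labels, permutations=199, seed=5)
        assert a.p_value == b.p_value and a.pseudo_f == b.pseudo_f
        assert 0 < a.p_value <= 1
        assert a.df_among == 1 and a.df_within == 10

    def test_label_renaming_invariance(self, rng):
        D, labels = self._toy(rng)
        a = permanova(D, labels, permutations=99, seed=1)
        renamed = ["XX" if l == "g1" else "YY" for l in labels]
        b = permanova(D, renamed, permutations=99, seed=1)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_joint_permutation_invariance(self, rng):
        D, labels = self._toy(rng)
        perm = rng.permutation(len(labels))
        a = permanova(D, labels, permutations=0 + 99, seed=1)
        b = permanova(
            D[np.ix_(perm, perm)], [labels[i] for i in perm], permutations=99, seed=1
        )
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_exhaustive_oracle_n5(self, rng):
        """MC permutation p agrees with exhaustive label enumeration."""
        D, _ = self._toy(rng, n=5)
        labels = np.array(["a", "a", "b", "b", "b"])
        uniq = np.unique(labels)
        f_obs, _, _ = _pseudo_f(D**2, labels, uniq)
        fs = [
            _pseudo_f(D**2, labels[list(p)], uniq)[0]
            for p in itertools.permutations(range(5))
        ]
        exhaustive = np.mean([f >= f_obs - 1e-12 for f in fs])
        res = permanova(D, labels, permutations=999, seed=3)
        assert abs(res.p_value - exhaustive) < 0.08

    def test_against_scikit_bio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        D, labels = self._toy(rng, n=10, sep=1.0)
        res = permanova(D, labels, permutations=99, seed=0)
        dm = skbio_stats.DistanceMatrix(D, ids=[str(i) for i in range(10)])
        ref = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_invalid_inputs(self, rng):
        D, labels = self._toy(rng, n=6)
        with pytest.raises(UndefinedMetricError):
            permanova(D, ["same"] * 6)
        with pytest.raises(InvalidDataError):
            permanova(-D, labels)
        with pytest.raises(InvalidDataError):
            permanova(D[:5, :6], labels)


class TestTurnoverAnalysis:
    def test_default_grouping_is_study_assignment(self):
        labels = list(HIGH_MIGRATION_PERIODS) + list(LOW_MIGRATION_PERIODS)
        g = default_grouping(labels)
        assert all(g[p] == "high" for p in HIGH_MIGRATION_PERIODS)
        assert all(g[p] == "low" for p in LOW_MIGRATION_PERIODS)
        assert set(g) == set(labels)
        with pytest.raises(InvalidDataError):
            default_grouping(["weird-period"])

    def test_report_shape(self, paper_series):
        series, _, _ = paper_series
        rep = turnover_analysis(series, permutations=49, seed=0)
        assert rep["stratum"].tolist() == ["core", "periphery"]
        assert ((rep["p"] > 0) & (rep["p"] <= 1)).all()
        assert (rep["df_among"] == 1).all() and (rep["df_within"] == 8).all()

    def test_dissimilarity_matrix_symmetric_zero_diag(self, paper_series):
        series, _, _ = paper_series
        comp = composition_matrix(series, stratum="periphery")
        D = dissimilarity_matrix(comp).to_numpy()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
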